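"""AUROC motif evaluation against dinucleotide-shuffled nulls.

A motif's enrichment in a peak set is scored as the AUROC for separating
the top-N summit-window sequences from one dinucleotide-preserving shuffle
of each, where every sequence's score is its single maximum log-odds PWM
match (both strands). AUROC is computed exactly via the Mann-Whitney
statistic with midrank tie handling, so all-tied scores give exactly 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from motifbench.errors import EvaluationImpossibleError, UndefinedAUROCError
from motifbench.motifs import PWM, max_pwm_score, to_score_matrix
from motifbench.peaks import PeakSet, extract_window_sequences, top_n
from motifbench.rng import RngLike, as_rng
from motifbench.seq_null import dinucleotide_shuffle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AUROCGrid:
    """Motifs x peak sets AUROC table; NaN marks missing evaluations."""

    motif_names: tuple[str, ...]
    peakset_labels: tuple[tuple[str, str], ...]  # (protein, dataset)
    values: np.ndarray  # shape (len(motifs), len(peaksets))

    def value(self, motif_name: str, label: tuple[str, str]) -> float:
        i = self.motif_names.index(motif_name)
        j = self.peakset_labels.index(label)
        return float(self.values[i, j])

    def to_tsv(self) -> str:
        header = "motif\t" + "\t".join(f"{p}:{d}" for p, d in self.peakset_labels)
        lines = [header]
        for name, row in zip(self.motif_names, self.values):
            cells = ["" if math.isnan(v) else f"{v:.4f}" for v in row]
            lines.append(name + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def auroc(pos: list[float], neg: list[float]) -> float:
    """Exact AUROC of positive vs negative scores (Mann-Whitney form).

    (#{(p,n): p > n} + 0.5 * #{(p,n): p = n}) / (|pos| * |neg|), computed
    via midranks; ties count one half.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise UndefinedAUROCError("auroc requires nonempty score lists")
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    u = rank_sum - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def evaluate_motif(
    pwm: PWM,
    ps: PeakSet,
    genome,
    rng: RngLike,
    n: int = 500,
    flank: int = 250,
    pseudocount: float = 0.01,
    both_strands: bool = True,
) -> float:
    """AUROC of a motif separating top-n peak windows from their shuffles.

    Positives: max log-odds score of each top-n summit-window sequence.
    Negatives: the same score on one dinucleotide shuffle per window (1:1).
    Windows shorter than the motif are dropped from both classes.
    """
    gen = as_rng(rng)
    seqs = extract_window_sequences(top_n(ps, n), genome, flank)
    seqs = [s for s in seqs if len(s) >= pwm.width]
    if not seqs:
        raise EvaluationImpossibleError(
            f"no window of {ps.protein}/{ps.dataset} is >= width of {pwm.name}"
        )
    sm = to_score_matrix(pwm, pseudocount=pseudocount)
    pos = [max_pwm_score(s, sm, both_strands) for s in seqs]
    neg = [
        max_pwm_score(dinucleotide_shuffle(s, gen), sm, both_strands)
        for s in seqs
    ]
    return auroc(pos, neg)


def evaluate_grid(
    motifs: list[PWM],
    peaksets: list[PeakSet],
    genome,
    rng: RngLike,
    n: int = 500,
    flank: int = 250,
) -> AUROCGrid:
    """evaluate_motif over the motifs x peak-sets cross product.

    Negatives are shuffled once per (peak set, seed) and shared across
    motifs, so every motif is compared on identical nulls. Impossible
    evaluations are recorded as NaN with a logged warning.
    """
    gen = as_rng(rng)
    values = np.full((len(motifs), len(peaksets)), math.nan)
    for j, ps in enumerate(peaksets):
        seqs = extract_window_sequences(top_n(ps, n), genome, flank)
        shuffled = [dinucleotide_shuffle(s, gen) for s in seqs]
        for i, pwm in enumerate(motifs):
            keep = [k for k, s in enumerate(seqs) if len(s) >= pwm.width]
            if not keep:
                logger.warning(
                    "no window of %s/%s fits motif %s; recorded missing",
                    ps.protein, ps.dataset, pwm.name,
                )
                continue
            sm = to_score_matrix(pwm)
            pos = [max_pwm_score(seqs[k], sm) for k in keep]
            neg = [max_pwm_score(shuffled[k], sm) for k in keep]
            values[i, j] = auroc(pos, neg)
    return AUROCGrid(
        motif_names=tuple(m.name for m in motifs),
        peakset_labels=tuple((ps.protein, ps.dataset) for ps in peaksets),
        values=values,
    )
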