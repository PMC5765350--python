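"""Reference-motif selection: the ordered Class A-F decision procedure.

One motif is chosen per protein from candidates of mixed provenance (ChIP
derived, in vitro, external), each scored by AUROC on every available peak
set. A ChIP-derived candidate's own training peak set is marked "train";
every other peak set is a "test" set, and a candidate's test score is its
best AUROC on data it was not trained on. Rules are evaluated in order:

A. one motif predicts test data with AUROC at least 0.1 greater than all
   other motifs (uniquely predictive of test peaks);
B. failing A, an in-vitro motif predicts the test data better than, or
   almost as well as (gap < 0.1), the best ChIP motif;
C. failing A/B, a recognition-code-supported (RCADE) ChIP motif exists;
D. failing A-C, a ChIP motif predicts its training data with AUROC at
   least 0.1 greater than all other motifs' training AUROCs;
E. failing A-D, the best test motif leads the others by 0.01-0.09;
F. everything else, including proteins with a single motif — co-equal
   candidates are all reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from motifbench.errors import UnselectableProteinError
from motifbench.motif_similarity import SimilarityMatrix

_METHOD_PRIORITY = {"rcade": 0, "meme": 1, "external": 2}


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for selection classes and disagreement flags."""

    class_a_margin: float = 0.1
    class_b_gap: float = 0.1
    class_e_range: tuple[float, float] = (0.01, 0.09)
    auc_quality_bar: float = 0.6
    similarity_same: float = 0.5
    similarity_related: float = 0.2
    ere_disagreement: float = 0.3
    motif_disagreement: float = 0.2

    def __post_init__(self) -> None:
        if self.class_e_range[1] >= self.class_a_margin:
            raise ValueError("class_e_range upper bound must be < class_a_margin")


@dataclass(frozen=True)
class Candidate:
    """One candidate motif for a protein with its per-peak-set AUROCs.

    ``train`` names the peak set the motif was derived from (ChIP
    candidates have exactly one; in vitro and external candidates none).
    """

    name: str
    aurocs: dict[str, float]
    train: str | None = None
    method: str = "external"
    recognition_code_supported: bool = False
    is_in_vitro: bool = False
    source: str = "external:unknown"

    def __post_init__(self) -> None:
        if self.is_in_vitro and self.train is not None:
            raise ValueError(f"in vitro candidate {self.name!r} cannot have a train set")

    @property
    def is_chip(self) -> bool:
        return self.train is not None

    def test_score(self) -> float:
        """Best AUROC over test (non-training) peak sets; NaN if none."""
        vals = [
            v
            for label, v in self.aurocs.items()
            if label != self.train and not math.isnan(v)
        ]
        return max(vals) if vals else math.nan

    def train_score(self) -> float:
        if self.train is None:
            return math.nan
        return self.aurocs.get(self.train, math.nan)

    def any_score(self) -> float:
        vals = [v for v in self.aurocs.values() if not math.isnan(v)]
        return max(vals) if vals else math.nan


@dataclass(frozen=True)
class CandidateTable:
    """All candidate motifs for one protein."""

    protein: str
    candidates: tuple[Candidate, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "candidates", tuple(self.candidates))


@dataclass(frozen=True)
class SelectionResult:
    """Chosen reference motif(s) for one protein with confidence metrics.

    ``chosen`` holds one motif except for class F, where co-equal
    candidates are all reported; the first entry is the primary one.
    """

    protein: str
    chosen: tuple[str, ...]
    selection_class: str
    best_test_auroc: float
    best_cross_source_similarity: float
    method: str


def _rank_key(c: Candidate):
    t = c.test_score()
    return (
        -(t if not math.isnan(t) else -math.inf),
        _METHOD_PRIORITY.get(c.method, 3),
        c.name,
    )


def assign_class(table: CandidateTable, th: Thresholds = Thresholds()) -> SelectionResult:
    """Assign a selection class A-F and choose the reference motif(s).

    Rules are tried in order; within a class, ties break by higher test
    score, then RCADE over MEME over external, then motif name.
    """
    cands = [c for c in table.candidates if not math.isnan(c.any_score())]
    if not cands:
        raise UnselectableProteinError(
            f"{table.protein}: no candidate carries any defined AUROC"
        )

    def result(chosen: list[Candidate], cls: str) -> SelectionResult:
        primary = chosen[0]
        return SelectionResult(
            protein=table.protein,
            chosen=tuple(c.name for c in chosen),
            selection_class=cls,
            best_test_auroc=primary.test_score(),
            best_cross_source_similarity=math.nan,
            method=primary.method,
        )

    tested = sorted(
        (c for c in cands if not math.isnan(c.test_score())), key=_rank_key
    )

    # A: uniquely predictive of test peaks, margin >= class_a_margin
    if len(tested) >= 2:
        best, second = tested[0], tested[1]
        if best.test_score() - second.test_score() >= th.class_a_margin:
            return result([best], "A")

    # B: in vitro motif predicts test peaks almost as well as ChIP motifs
    iv = [c for c in tested if c.is_in_vitro]
    if iv:
        chip_tested = [c for c in tested if c.is_chip]
        best_chip = max((c.test_score() for c in chip_tested), default=-math.inf)
        best_iv = min(iv, key=_rank_key)
        if best_iv.test_score() > best_chip - th.class_b_gap:
            return result([best_iv], "B")

    # C: recognition-code-supported ChIP motif
    rcade = [c for c in cands if c.is_chip and c.recognition_code_supported]
    if rcade:
        def c_key(c: Candidate):
            t = c.test_score()
            if math.isnan(t):
                t = c.train_score()  # fallback when no test set exists
            return (-(t if not math.isnan(t) else -math.inf),
                    _METHOD_PRIORITY.get(c.method, 3), c.name)
        return result([min(rcade, key=c_key)], "C")

    # D: ChIP motif uniquely predictive of its training peaks
    trained = sorted(
        (c for c in cands if not math.isnan(c.train_score())),
        key=lambda c: (-c.train_score(), _METHOD_PRIORITY.get(c.method, 3), c.name),
    )
    if len(trained) >= 2:
        best = trained[0]
        if best.is_chip and best.train_score() - trained[1].train_score() >= th.class_a_margin:
            return result([best], "D")

    # E: best test motif leads by a small but real margin
    if len(tested) >= 2:
        margin = tested[0].test_score() - tested[1].test_score()
        lo, hi = th.class_e_range
        if lo <= margin <= hi:
            return result([tested[0]], "E")

    # F: everything else; co-equal candidates all reported
    return result(sorted(cands, key=_rank_key), "F")


@dataclass(frozen=True)
class ReferenceSet:
    """Selection results for a cohort plus per-protein failures."""

    results: tuple[SelectionResult, ...]
    errors: dict[str, str] = field(default_factory=dict)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.results:
            counts[r.selection_class] = counts.get(r.selection_class, 0) + 1
        return counts

    def to_tsv(self) -> str:
        lines = ["protein\tmotif\tclass\tmethod\tbest_test_auroc\tbest_similarity"]
        for r in self.results:
            auc = "" if math.isnan(r.best_test_auroc) else f"{r.best_test_auroc:.4f}"
            sim = (
                ""
                if math.isnan(r.best_cross_source_similarity)
                else f"{r.best_cross_source_similarity:.4f}"
            )
            for name in r.chosen:
                lines.append(
                    f"{r.protein}\t{name}\t{r.selection_class}\t{r.method}\t{auc}\t{sim}"
                )
        return "\n".join(lines) + "\n"


def _cross_source_similarity(
    chosen: str, table: CandidateTable, sim: SimilarityMatrix
) -> float:
    source = {c.name: c.source for c in table.candidates}
    if chosen not in sim.motif_names or chosen not in source:
        return math.nan
    best = math.nan
    for c in table.candidates:
        if c.name == chosen or c.source == source[chosen]:
            continue
        if c.name not in sim.motif_names:
            continue
        v = sim.value(chosen, c.name)
        if not math.isnan(v) and (math.isnan(best) or v > best):
            best = v
    return best


def build_reference_set(
    tables: list[CandidateTable],
    similarity: SimilarityMatrix | None = None,
    th: Thresholds = Thresholds(),
) -> ReferenceSet:
    """Select one reference motif per protein across a cohort.

    Per-protein failures (no scorable candidate) are collected, not fatal.
    When a similarity matrix is supplied, each result's confidence metric
    ``best_cross_source_similarity`` is the chosen motif's best similarity
    to a candidate from a different source.
    """
    results: list[SelectionResult] = []
    errors: dict[str, str] = {}
    for table in tables:
        try:
            r = assign_class(table, th)
        except UnselectableProteinError as exc:
            errors[table.protein] = str(exc)
            continue
        if similarity is not None:
            sim = _cross_source_similarity(r.chosen[0], table, similarity)
            r = SelectionResult(
                protein=r.protein,
                chosen=r.chosen,
                selection_class=r.selection_class,
                best_test_auroc=r.best_test_auroc,
                best_cross_source_similarity=sim,
                method=r.method,
            )
        results.append(r)
    return ReferenceSet(results=tuple(results), errors=errors)


def flag_disagreement(
    ere_r: float, motif_r: float, th: Thresholds = Thresholds()
) -> set[str]:
    """Flag cross-dataset disagreement on ERE profile and/or motif.

    ``ere_disagrees`` iff ere_r < 0.3; ``motif_disagrees`` iff motif_r < 0.2
    (strict <); a missing (NaN) input raises no flag.
    """
    flags: set[str] = set()
    if not math.isnan(ere_r) and ere_r < th.ere_disagreement:
        flags.add("ere_disagrees")
    if not math.isnan(motif_r) and motif_r < th.motif_disagreement:
        flags.add("motif_disagrees")
    return flags
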