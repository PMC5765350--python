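"""Affinity-correlation motif similarity.

Two motifs are compared by scoring the same large set of random sequences
with each motif's summed-probability affinity (both strands) and taking the
Pearson correlation of the two score vectors. The random background is
shared (one seed per matrix) so that all pairwise values are comparable.
Similarity > 0.5 is the level typically seen between experiments on the
same transcription factor; > 0.2 indicates related motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from motifbench.errors import BackgroundTooShortError
from motifbench.motifs import PWM, affinity_scores
from motifbench.rng import RngLike, as_rng
from motifbench.seq_null import random_index_matrix

SAME_TF_THRESHOLD = 0.5
RELATED_THRESHOLD = 0.2


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric motif-by-motif similarity table with its background spec."""

    motif_names: tuple[str, ...]
    values: np.ndarray
    background_spec: tuple[int, int, int]  # (n, l, seed)

    def value(self, a: str, b: str) -> float:
        return float(
            self.values[self.motif_names.index(a), self.motif_names.index(b)]
        )

    def to_tsv(self) -> str:
        n, l, seed = self.background_spec
        lines = [f"#n={n} l={l} seed={seed}"]
        lines.append("motif\t" + "\t".join(self.motif_names))
        for name, row in zip(self.motif_names, self.values):
            cells = ["" if math.isnan(v) else f"{v:.4f}" for v in row]
            lines.append(name + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def _correlate(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    if np.array_equal(x, y):
        return 1.0  # identical vectors correlate exactly, no rounding
    return float(np.corrcoef(x, y)[0, 1])


def similarity(
    a: PWM,
    b: PWM,
    n: int = 100_000,
    l: int = 100,
    rng: RngLike = 0,
    log_affinity: bool = False,
) -> float:
    """Pearson correlation of two motifs' affinities over a shared random
    background of n length-l sequences.

    Returns NaN if either motif's affinity vector is constant.
    ``log_affinity`` correlates log affinities instead (heavy-tail damping);
    off by default.
    """
    if l < max(a.width, b.width):
        raise BackgroundTooShortError(
            f"background length {l} < motif width {max(a.width, b.width)}"
        )
    idx = random_index_matrix(n, l, rng)
    xa = affinity_scores(idx, a)
    xb = affinity_scores(idx, b)
    if log_affinity:
        xa, xb = np.log(xa), np.log(xb)
    return _correlate(xa, xb)


def similarity_matrix(
    motifs: list[PWM],
    n: int = 100_000,
    l: int = 100,
    rng: int = 0,
    log_affinity: bool = False,
) -> SimilarityMatrix:
    """All pairwise similarities on one shared background.

    Each motif's affinity vector is computed once; the matrix is symmetric
    by construction with unit diagonal (NaN where a vector is constant).
    """
    seed = int(rng)
    idx = random_index_matrix(n, l, as_rng(seed))
    widths = [m.width for m in motifs]
    if motifs and l < max(widths):
        raise BackgroundTooShortError(
            f"background length {l} < widest motif ({max(widths)})"
        )
    vectors = []
    for m in motifs:
        v = affinity_scores(idx, m)
        vectors.append(np.log(v) if log_affinity else v)
    k = len(motifs)
    values = np.full((k, k), math.nan)
    for i in range(k):
        if np.ptp(vectors[i]) > 0:
            values[i, i] = 1.0
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = _correlate(vectors[i], vectors[j])
    return SimilarityMatrix(
        motif_names=tuple(m.name for m in motifs),
        values=values,
        background_spec=(n, l, seed),
    )


def classify_similarity(r: float) -> str:
    """Bucket a similarity value.

    > 0.5: the level of different experiments on the same TF
    (``same_tf_level``); > 0.2: ``related``; otherwise ``dissimilar``.
    """
    if math.isnan(r):
        raise ValueError("similarity undefined; cannot classify NaN")
    if r > SAME_TF_THRESHOLD:
        return "same_tf_level"
    if r > RELATED_THRESHOLD:
        return "related"
    return "dissimilar"
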