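"""ERE (endogenous retroelement) enrichment profiles.

A peak set's ERE profile is, for each repeat class, the fraction of its
top-N peaks whose summit windows overlap at least one genomic instance of
that class. Profiles from two experiments on the same protein should agree
even when the individual peaks only partly overlap, because both
experiments sample the same underlying binding-site pool; the
matched-vs-unmatched correlation decomposition quantifies that agreement
against the cross-protein background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from motifbench.errors import (
    InsufficientProteinsError,
    MalformedIntervalError,
    UndefinedProfileError,
)
from motifbench.peaks import PeakSet, summit_window, top_n


@dataclass(frozen=True)
class RepeatAnnotation:
    """Genomic intervals labeled with a repeat/ERE class name."""

    intervals: tuple[tuple[str, int, int, str], ...]
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        if not self.classes:
            seen: list[str] = []
            for _c, _s, _e, cls in self.intervals:
                if cls not in seen:
                    seen.append(cls)
            object.__setattr__(self, "classes", tuple(seen))
        for chrom, start, end, cls in self.intervals:
            if end <= start:
                raise MalformedIntervalError(
                    f"repeat {cls} {chrom}:{start}-{end}: end <= start"
                )
            if cls not in self.classes:
                raise MalformedIntervalError(
                    f"repeat class {cls!r} missing from class list"
                )


@dataclass(frozen=True)
class EREProfile:
    """Per-class fractions of top-N peaks overlapping each repeat class.

    Fractions may sum to more than 1: one peak window can hit instances of
    several classes and then counts toward each.
    """

    protein: str
    dataset: str
    classes: tuple[str, ...]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if f.shape != (len(self.classes),):
            raise ValueError("fractions length must equal number of classes")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class AgreementSummary:
    """Matched vs unmatched profile-correlation summary.

    For k proteins profiled in two datasets there are k matched (same
    protein, different dataset) pairs and C(2k,2) - k unmatched pairs among
    the pooled 2k profiles. Fractions are of correlations strictly above
    the threshold, among defined (non-NaN) correlations.
    """

    matched_correlations: tuple[float, ...]
    unmatched_correlations: tuple[float, ...]
    threshold: float
    frac_matched_above: float
    frac_unmatched_above: float


def read_repeats(text: str, format: str = "bed_class") -> RepeatAnnotation:
    """Parse repeat annotations.

    ``bed_class``: TSV chrom, start, end, class name. ``repeatmasker_out``:
    the whitespace table of RepeatMasker .out files (columns 5-7 genomic
    position, column 10 the repeat name, used as the class).
    """
    intervals: list[tuple[str, int, int, str]] = []
    if format == "bed_class":
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MalformedIntervalError(
                    f"line {lineno}: expected 4 tab-separated columns"
                )
            try:
                intervals.append(
                    (fields[0], int(fields[1]), int(fields[2]), fields[3])
                )
            except ValueError as exc:
                raise MalformedIntervalError(f"line {lineno}: {exc}") from exc
    elif format == "repeatmasker_out":
        for lineno, line in enumerate(text.splitlines(), start=1):
            fields = line.split()
            if not fields or not fields[0].replace(".", "").isdigit():
                continue  # header/blank lines
            if len(fields) < 10:
                raise MalformedIntervalError(
                    f"line {lineno}: expected >= 10 whitespace-separated columns"
                )
            try:
                chrom = fields[4]
                start = int(fields[5]) - 1  # RepeatMasker is 1-based inclusive
                end = int(fields[6])
                intervals.append((chrom, start, end, fields[9]))
            except ValueError as exc:
                raise MalformedIntervalError(f"line {lineno}: {exc}") from exc
    else:
        raise ValueError(f"unknown repeat format {format!r}")
    for chrom, start, end, cls in intervals:
        if end <= start:
            raise MalformedIntervalError(
                f"repeat {cls} {chrom}:{start}-{end}: end <= start"
            )
    return RepeatAnnotation(intervals=tuple(intervals))


def _class_trees(repeats: RepeatAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, cls in repeats.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, cls)
    return trees


def compute_profile(
    ps: PeakSet, repeats: RepeatAnnotation, n: int = 500, flank: int = 250
) -> EREProfile:
    """Fraction of top-n summit windows overlapping each repeat class.

    A window intersecting instances of several classes contributes to each
    class's numerator.
    """
    top = top_n(ps, n)
    if not top.peaks:
        raise UndefinedProfileError(
            f"no peaks for {ps.protein}/{ps.dataset}: profile undefined"
        )
    trees = _class_trees(repeats)
    class_index = {c: i for i, c in enumerate(repeats.classes)}
    counts = np.zeros(len(repeats.classes))
    for p in top.peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        start, end = summit_window(p, flank)
        hit_classes = {iv.data for iv in tree.overlap(start, end)}
        for cls in hit_classes:
            counts[class_index[cls]] += 1
    return EREProfile(
        protein=top.protein,
        dataset=top.dataset,
        classes=repeats.classes,
        fractions=counts / len(top.peaks),
    )


def profile_correlation(p: EREProfile, q: EREProfile) -> float:
    """Pearson correlation of two profiles' fraction vectors.

    Returns NaN (a missing value, never an arbitrary number) when either
    vector is constant. Requires identical class ordering.
    """
    if p.classes != q.classes:
        raise ValueError("profiles must share an identical class ordering")
    x, y = p.fractions, q.fractions
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def _frac_above(values: np.ndarray, t: float) -> float:
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        return math.nan
    return float(np.mean(defined > t))


def matched_vs_unmatched(
    profiles_a: list[EREProfile],
    profiles_b: list[EREProfile],
    threshold_rule: str | float = "best_separation",
) -> AgreementSummary:
    """Matched vs unmatched correlation decomposition over pooled profiles.

    Matched pairs are the k same-protein cross-dataset pairs; unmatched
    pairs are all other unordered pairs among the pooled 2k profiles —
    C(2k,2) - k comparisons, within-dataset different-protein pairs
    included. ``threshold_rule`` is either a number (fixed threshold) or
    ``"best_separation"``, which picks the threshold maximizing
    frac_matched_above - frac_unmatched_above (ties -> lowest threshold).
    "Above" is strict (>).
    """
    prot_a = {p.protein for p in profiles_a}
    prot_b = {p.protein for p in profiles_b}
    if prot_a != prot_b:
        raise InsufficientProteinsError(
            "the two profile lists must cover the same proteins"
        )
    k = len(profiles_a)
    if k < 2 or len(profiles_b) != k or len(prot_a) != k:
        raise InsufficientProteinsError(
            "need >= 2 shared proteins, one profile per protein per dataset"
        )
    by_protein_b = {p.protein: p for p in profiles_b}
    matched = [
        profile_correlation(pa, by_protein_b[pa.protein]) for pa in profiles_a
    ]
    pooled = list(profiles_a) + list(profiles_b)
    matched_keys = {
        frozenset({(pa.protein, pa.dataset), (by_protein_b[pa.protein].protein,
                                              by_protein_b[pa.protein].dataset)})
        for pa in profiles_a
    }
    unmatched: list[float] = []
    for i in range(len(pooled)):
        for j in range(i + 1, len(pooled)):
            key = frozenset(
                {(pooled[i].protein, pooled[i].dataset),
                 (pooled[j].protein, pooled[j].dataset)}
            )
            if key in matched_keys:
                continue
            unmatched.append(profile_correlation(pooled[i], pooled[j]))
    m = np.asarray(matched)
    u = np.asarray(unmatched)
    if isinstance(threshold_rule, str):
        if threshold_rule != "best_separation":
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        candidates = np.unique(np.concatenate([m, u]))
        candidates = candidates[~np.isnan(candidates)]
        best_t, best_sep = float(candidates[0]), -np.inf
        for t in candidates:
            sep = _frac_above(m, t) - _frac_above(u, t)
            if sep > best_sep:
                best_sep, best_t = sep, float(t)
        threshold = best_t
    else:
        threshold = float(threshold_rule)
    return AgreementSummary(
        matched_correlations=tuple(matched),
        unmatched_correlations=tuple(unmatched),
        threshold=threshold,
        frac_matched_above=_frac_above(m, threshold),
        frac_unmatched_above=_frac_above(u, threshold),
    )
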