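"""ChIP peak model: I/O, merging, top-N selection, summit windows,
sequence extraction, cross-dataset overlap and non-ERE filtering.

Coordinates are 0-based half-open throughout (BED convention); summits are
absolute 0-based positions. The peak file dialect is BED6-like TSV:
chrom, start, end, name, enrichment score, summit offset relative to start
(sentinel -1 = use the interval midpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

from motifbench.errors import (
    MalformedIntervalError,
    UndefinedOverlapError,
    UnknownChromosomeError,
)


@dataclass(frozen=True)
class Peak:
    """A scored genomic interval with a summit (point of maximal signal)."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise MalformedIntervalError(
                f"peak {self.chrom}:{self.start}-{self.end}: end <= start"
            )
        if not (self.start <= self.summit < self.end):
            raise MalformedIntervalError(
                f"peak {self.chrom}:{self.start}-{self.end}: "
                f"summit {self.summit} outside interval"
            )


@dataclass(frozen=True)
class PeakSet:
    """A named collection of peaks for one protein in one dataset."""

    protein: str
    dataset: str
    peaks: tuple[Peak, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)


def read_peaks(text: str, protein: str = "unknown", dataset: str = "unknown") -> PeakSet:
    """Parse the BED6-like peak dialect into a PeakSet.

    Column 5 is the enrichment score and column 6 the summit offset from
    ``start`` (-1 means midpoint). Raises with the 1-based line number on a
    malformed interval or coordinate.
    """
    peaks: list[Peak] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise MalformedIntervalError(
                f"line {lineno}: expected 6 tab-separated columns"
            )
        chrom, name = fields[0], fields[3]
        try:
            start, end = int(fields[1]), int(fields[2])
            score = float(fields[4])
            offset = int(fields[5])
        except ValueError as exc:
            raise MalformedIntervalError(f"line {lineno}: {exc}") from exc
        if end <= start:
            raise MalformedIntervalError(
                f"line {lineno}: end {end} <= start {start}"
            )
        summit = (start + end) // 2 if offset == -1 else start + offset
        peaks.append(Peak(chrom, start, end, summit, score, name))
    return PeakSet(protein=protein, dataset=dataset, peaks=tuple(peaks))


def write_peaks(ps: PeakSet) -> str:
    """Serialize a PeakSet in the BED6-like dialect read by read_peaks."""
    lines = [
        "\t".join(
            (
                p.chrom,
                str(p.start),
                str(p.end),
                p.name,
                repr(p.score),
                str(p.summit - p.start),
            )
        )
        for p in ps.peaks
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def merge_peaks(ps: PeakSet, max_gap: int = 50) -> PeakSet:
    """Union peaks that overlap or lie within ``max_gap`` bases.

    The merged peak takes the maximum member score, and the summit of the
    highest-scoring member (score ties broken by leftmost start).
    Idempotent: re-merging changes nothing.
    """
    ordered = sorted(ps.peaks, key=lambda p: (p.chrom, p.start, p.end))
    merged: list[Peak] = []
    for p in ordered:
        if merged and p.chrom == merged[-1].chrom and p.start - merged[-1].end <= max_gap:
            prev = merged[-1]
            if (p.score, -p.start) > (prev.score, -prev.start):
                score, summit, name = p.score, p.summit, p.name
            else:
                score, summit, name = prev.score, prev.summit, prev.name
            merged[-1] = Peak(
                prev.chrom,
                prev.start,
                max(prev.end, p.end),
                summit,
                score,
                name,
            )
        else:
            merged.append(p)
    return replace(ps, peaks=tuple(merged))


def top_n(ps: PeakSet, n: int = 500) -> PeakSet:
    """The min(n, len) highest-scoring peaks; ties broken by (chrom, start)."""
    ordered = sorted(ps.peaks, key=lambda p: (-p.score, p.chrom, p.start))
    return replace(ps, peaks=tuple(ordered[:n]))


def summit_window(p: Peak, flank: int = 250, chrom_len: int | None = None) -> tuple[int, int]:
    """[summit - flank, summit + flank + 1) clipped to the chromosome.

    Unclipped, the window spans 2*flank + 1 bases (501 at the default).
    """
    start = max(0, p.summit - flank)
    end = p.summit + flank + 1
    if chrom_len is not None:
        end = min(end, chrom_len)
    return start, end


def _chrom_seq(genome, chrom: str) -> str:
    try:
        return str(genome[chrom])
    except KeyError as exc:
        raise UnknownChromosomeError(f"chromosome {chrom!r} not in genome") from exc


def extract_window_sequences(ps: PeakSet, genome, flank: int = 250) -> list[str]:
    """One uppercase summit-window sequence per peak, in peak order.

    ``genome`` is any chrom -> sequence mapping (dict of strings or a
    pyfaidx.Fasta). Windows are clipped at chromosome boundaries.
    """
    seqs: list[str] = []
    cache: dict[str, str] = {}
    for p in ps.peaks:
        if p.chrom not in cache:
            cache[p.chrom] = _chrom_seq(genome, p.chrom).upper()
        chrom_seq = cache[p.chrom]
        start, end = summit_window(p, flank, len(chrom_seq))
        seqs.append(chrom_seq[start:end])
    return seqs


def _window_tree(peaks, flank: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        start, end = summit_window(p, flank)
        trees.setdefault(p.chrom, IntervalTree()).addi(start, end)
    return trees


def overlap_percentage(
    a: PeakSet,
    b: PeakSet,
    n: int = 500,
    flank: int = 250,
    summit_in_window: bool = False,
) -> float:
    """Percentage of top-n peaks of ``a`` whose summit window intersects a
    summit window of any top-n peak of ``b``.

    Directional: a-vs-b generally differs from b-vs-a. With
    ``summit_in_window`` the stricter rule is used instead: the summit of a
    peak of ``a`` must fall inside a window of ``b`` (distance <= flank
    rather than <= 2*flank).
    """
    ta, tb = top_n(a, n), top_n(b, n)
    if not ta.peaks or not tb.peaks:
        raise UndefinedOverlapError("overlap undefined for an empty top set")
    trees = _window_tree(tb.peaks, flank)
    hits = 0
    for p in ta.peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        if summit_in_window:
            if tree.overlaps_point(p.summit):
                hits += 1
        else:
            start, end = summit_window(p, flank)
            if tree.overlap(start, end):
                hits += 1
    return 100.0 * hits / len(ta.peaks)


def filter_non_ere(ps: PeakSet, repeats, flank: int = 250) -> PeakSet:
    """Keep peaks whose summit window intersects no repeat interval.

    Any overlap, even a single base, removes the peak. ``repeats`` is a
    RepeatAnnotation; an empty annotation keeps every peak.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _cls in repeats.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    kept = []
    for p in ps.peaks:
        tree = trees.get(p.chrom)
        if tree is not None:
            start, end = summit_window(p, flank)
            if tree.overlap(start, end):
                continue
        kept.append(p)
    return replace(ps, peaks=tuple(kept))
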