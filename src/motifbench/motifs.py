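"""PWM data model, motif file I/O and sequence scoring.

A motif is a position weight matrix (PWM): one probability distribution
over A, C, G, T per binding-site position. Two scoring views are provided:

* **log-odds max score** — each window of a sequence is scored as the sum
  of per-position log2(p/background) terms and the sequence score is the
  best window on either strand. This is the conventional "maximum PWM
  scoring match" used to discriminate peak sequences from shuffled nulls.
* **affinity score** — the sum over all windows (both strands) of the
  product of per-position base probabilities, a Boltzmann-like proxy for
  total predicted occupancy used by affinity-correlation motif similarity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from motifbench.errors import (
    InvalidBackgroundError,
    MalformedMotifError,
    SequenceTooShortError,
)

BASES = "ACGT"
ROW_SUM_TOLERANCE = 1e-3

# A,C,G,T -> 0..3; N (and any other IUPAC letter) -> 4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# complement permutation of the A,C,G,T columns
_COMPLEMENT = np.array([3, 2, 1, 0])


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 indices (A=0,C=1,G=2,T=3,N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifMetadata:
    """Provenance of a motif: protein, source dataset and derivation method.

    ``recognition_code_supported`` marks motifs backed by the C2H2 zinc
    finger recognition code; any motif derived with RCADE is by definition
    recognition-code supported.
    """

    protein: str = "unknown"
    source: str = "external:unknown"
    method: str = "external"  # rcade | meme | external
    recognition_code_supported: bool = False
    trained_on_non_ere_peaks: bool | None = None
    is_in_vitro: bool = False

    def __post_init__(self) -> None:
        if self.method == "rcade" and not self.recognition_code_supported:
            object.__setattr__(self, "recognition_code_supported", True)


@dataclass(frozen=True)
class PWM:
    """A named position weight matrix with provenance metadata.

    ``matrix`` is a (width, 4) array; columns ordered A, C, G, T; each row
    is a probability distribution.
    """

    name: str
    matrix: np.ndarray
    metadata: MotifMetadata = field(default_factory=MotifMetadata)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise MalformedMotifError(
                f"motif {self.name!r}: matrix must be (width, 4) with width >= 1"
            )
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise MalformedMotifError(
                f"motif {self.name!r}: probabilities outside [0, 1]"
            )
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise MalformedMotifError(
                f"motif {self.name!r}: row {bad} sums to {sums[bad]:.6g}, not 1"
            )

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PWM):
            return NotImplemented
        return (
            self.name == other.name
            and self.metadata == other.metadata
            and np.array_equal(self.matrix, other.matrix)
        )


@dataclass(frozen=True)
class ScoreMatrix:
    """Log-odds (base 2) scoring matrix derived from a PWM.

    A uniform PWM under a uniform background yields the all-zero matrix.
    """

    matrix: np.ndarray  # (width, 4) log2 odds

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


def to_score_matrix(
    pwm: PWM,
    background: np.ndarray | None = None,
    pseudocount: float = 0.01,
) -> ScoreMatrix:
    """Convert a PWM to a log2-odds scoring matrix.

    entry[i][b] = log2((p[i][b] + pseudocount*bg[b]) / ((1+pseudocount)*bg[b]))

    The pseudocount is distributed proportionally to the background so that
    a uniform PWM maps to the zero matrix regardless of pseudocount.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-6:
        raise InvalidBackgroundError(
            f"background must be 4 positive probabilities summing to 1, got {bg}"
        )
    if pseudocount < 0:
        raise InvalidBackgroundError("pseudocount must be nonnegative")
    num = pwm.matrix + pseudocount * bg
    den = (1.0 + pseudocount) * bg
    with np.errstate(divide="ignore"):
        return ScoreMatrix(np.log2(num / den))


def reverse_complement(pwm: PWM) -> PWM:
    """Reverse-complement a PWM: rows reversed, A<->T and C<->G swapped."""
    return replace(pwm, matrix=pwm.matrix[::-1, _COMPLEMENT])


def _revcomp_rows(matrix: np.ndarray) -> np.ndarray:
    return matrix[::-1, _COMPLEMENT]


def _window_scores(idx: np.ndarray, lookup: np.ndarray) -> np.ndarray:
    """Sum of per-position lookup values over every window of len(lookup)."""
    w = lookup.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return lookup[np.arange(w), windows].sum(axis=1)


def max_pwm_score(seq: str, sm: ScoreMatrix, both_strands: bool = True) -> float:
    """Best log-odds window score of ``seq`` under a scoring matrix.

    N positions contribute 0 (background-equivalent). With
    ``both_strands`` the reverse strand is scanned via the
    reverse-complemented matrix, so the sequence itself is read once.
    """
    idx = encode_sequence(seq)
    w = sm.width
    if idx.size < w:
        raise SequenceTooShortError(
            f"sequence length {idx.size} < motif width {w}"
        )
    lut = np.zeros((w, 5))
    lut[:, :4] = sm.matrix
    best = _window_scores(idx, lut).max()
    if both_strands:
        lut_rc = np.zeros((w, 5))
        lut_rc[:, :4] = _revcomp_rows(sm.matrix)
        best = max(best, _window_scores(idx, lut_rc).max())
    return float(best)


def _affinity_products(idx2d: np.ndarray, prob_lut: np.ndarray) -> np.ndarray:
    """Per-sequence sum over windows of per-position probability products.

    ``idx2d`` is (n, l) encoded sequences; returns an n-vector.
    """
    w = prob_lut.shape[0]
    n, l = idx2d.shape
    out_w = l - w + 1
    acc = np.ones((n, out_w))
    for j in range(w):
        acc *= prob_lut[j, idx2d[:, j : j + out_w]]
    return acc.sum(axis=1)


def _prob_lut(matrix: np.ndarray) -> np.ndarray:
    lut = np.full((matrix.shape[0], 5), 0.25)
    lut[:, :4] = matrix
    return lut


def affinity_scores(
    idx2d: np.ndarray, pwm: PWM, both_strands: bool = True
) -> np.ndarray:
    """Vectorized :func:`affinity_score` over pre-encoded sequences."""
    w = pwm.width
    if idx2d.shape[1] < w:
        raise SequenceTooShortError(
            f"sequence length {idx2d.shape[1]} < motif width {w}"
        )
    total = _affinity_products(idx2d, _prob_lut(pwm.matrix))
    if both_strands:
        total = total + _affinity_products(
            idx2d, _prob_lut(_revcomp_rows(pwm.matrix))
        )
    return total


def affinity_score(seq: str, pwm: PWM, both_strands: bool = True) -> float:
    """Summed-probability affinity of a sequence under a PWM.

    Sum over all windows (both strands if requested) of the product of
    per-position base probabilities; N counts as probability 0.25. For a
    uniform width-w motif this equals (number of windows scanned) * 0.25^w
    independent of sequence content.
    """
    idx = encode_sequence(seq)
    return float(affinity_scores(idx[None, :], pwm, both_strands)[0])


# ---------------------------------------------------------------------------
# motif file I/O


def _finish_motif(name: str, rows: list[list[float]], meta: MotifMetadata) -> PWM:
    m = np.array(rows, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise MalformedMotifError(f"motif {name!r}: expected 4 columns per row")
    sums = m.sum(axis=1)
    for i, s in enumerate(sums):
        if abs(s - 1.0) > ROW_SUM_TOLERANCE:
            raise MalformedMotifError(
                f"motif {name!r}: row {i} sums to {s:.6g} "
                f"(deviates from 1 by more than {ROW_SUM_TOLERANCE})"
            )
    m = m / sums[:, None]
    return PWM(name=name, matrix=m, metadata=meta)


def _parse_meme_minimal(text: str) -> list[PWM]:
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []
    in_matrix = False
    for line in io.StringIO(text):
        stripped = line.strip()
        fields = stripped.split()
        if stripped.startswith("MOTIF"):
            if name is not None:
                pwms.append(_finish_motif(name, rows, MotifMetadata()))
            name = fields[1] if len(fields) > 1 else f"motif_{len(pwms) + 1}"
            rows = []
            in_matrix = False
        elif stripped.startswith("letter-probability matrix"):
            in_matrix = True
        elif in_matrix and name is not None:
            if fields and all(_is_number(f) for f in fields):
                rows.append([float(f) for f in fields[:4]])
            else:
                in_matrix = False
        # "MEME version", "ALPHABET=" and anything else: ignored
    if name is not None:
        pwms.append(_finish_motif(name, rows, MotifMetadata()))
    return pwms


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _parse_tsv_matrix(text: str) -> list[PWM]:
    pwms: list[PWM] = []
    lines = [ln.rstrip("\n") for ln in io.StringIO(text)]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("#"):
            raise MalformedMotifError(
                f"tsv_matrix: expected '#name<TAB>width' header at line {i + 1}"
            )
        head = line[1:].split("\t")
        if len(head) != 2:
            raise MalformedMotifError(
                f"tsv_matrix: malformed header at line {i + 1}: {line!r}"
            )
        name, width = head[0], int(head[1])
        rows = []
        for j in range(width):
            fields = lines[i + 1 + j].split("\t")
            rows.append([float(f) for f in fields[:4]])
        pwms.append(_finish_motif(name, rows, MotifMetadata()))
        i += 1 + width
    return pwms


def read_pwms(text: str, format: str = "meme_minimal") -> list[PWM]:
    """Parse motifs from file content.

    Rows whose sum deviates from 1 by at most 1e-3 are renormalized;
    larger deviations raise :class:`MalformedMotifError` naming the motif
    and row. An empty file yields an empty list.
    """
    if format == "meme_minimal":
        return _parse_meme_minimal(text)
    if format == "tsv_matrix":
        return _parse_tsv_matrix(text)
    raise ValueError(f"unknown motif format {format!r}")


def write_pwms(pwms: list[PWM], format: str = "meme_minimal") -> str:
    """Serialize motifs; ``read_pwms(write_pwms(x))`` preserves matrices."""
    if format != "meme_minimal":
        raise ValueError(f"unknown motif format {format!r}")
    out = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
    ]
    for pwm in pwms:
        out.append(f"MOTIF {pwm.name}")
        out.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width}"
        )
        for row in pwm.matrix:
            out.append(" ".join(f"{p:.8f}" for p in row))
        out.append("")
    return "\n".join(out) + "\n"
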