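"""Sequence null models.

Two seedable nulls are provided: an exact dinucleotide-preserving shuffle
(the Altschul-Erickson Euler-path construction) used as the negative class
in AUROC motif evaluation, and i.i.d. uniform random sequences used as the
shared background for affinity-correlation motif similarity.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

from motifbench.rng import RngLike, as_rng

_ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(_ALPHABET)}


def _euler_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle one all-ACGT sequence preserving its dinucleotide multiset.

    Altschul-Erickson: pick, for every vertex other than the final
    character, a random last out-edge such that following last edges always
    reaches the final character; randomize the order of the remaining
    edges; walk the resulting Eulerian path from the first character.
    """
    n = len(seq)
    if n <= 2 or len(set(seq)) == 1:
        return seq
    first, last = seq[0], seq[-1]
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)

    sources = [v for v in edges if v != last]
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in sources}
        # every source must reach the sink by following last edges
        ok = True
        for v in sources:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    order: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        order[v] = rest

    out = [first]
    pos = {v: 0 for v in order}
    cur = first
    for _ in range(n - 1):
        nxt = order[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_shuffle(seq: str, rng: RngLike) -> str:
    """Return a random sequence with the same overlapping-dinucleotide
    multiset, length, and first/last characters as ``seq``.

    Runs of non-ACGT characters (masked bases such as N) are frozen in
    place and the ACGT segments between them are shuffled independently,
    so masked-region structure is preserved without inventing bases.
    """
    gen = as_rng(rng)
    if len(seq) <= 1:
        return seq
    seq = seq.upper()
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] in _IDX:
            j = i
            while j < n and seq[j] in _IDX:
                j += 1
            out.append(_euler_shuffle(seq[i:j], gen))
            i = j
        else:
            j = i
            while j < n and seq[j] not in _IDX:
                j += 1
            out.append(seq[i:j])
            i = j
    return "".join(out)


def dinucleotide_counts(seq: str) -> Counter:
    """Multiset of overlapping dinucleotides (independent census helper)."""
    return Counter(seq[i : i + 2] for i in range(len(seq) - 1))


def random_index_matrix(n: int, l: int, rng: RngLike) -> np.ndarray:
    """(n, l) int8 matrix of i.i.d. uniform base indices (A=0..T=3)."""
    return as_rng(rng).integers(0, 4, size=(n, l), dtype=np.int8)


def random_sequences(n: int, l: int, rng: RngLike) -> list[str]:
    """n i.i.d. uniform ACGT strings of length l, reproducible under seed."""
    if n < 1 or l < 1:
        raise ValueError("n and l must be positive")
    mat = random_index_matrix(n, l, rng)
    lut = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)
    bytes_mat = lut[mat]
    return [row.tobytes().decode("ascii") for row in bytes_mat]


# ---------------------------------------------------------------------------
# FASTA I/O for sequence lists


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA content into (name, sequence) pairs."""
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        elif name is not None:
            chunks.append(line.strip())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fasta(records: list[tuple[str, str]], width: int = 80) -> str:
    """Serialize (name, sequence) pairs as FASTA."""
    out: list[str] = []
    for name, seq in records:
        out.append(f">{name}")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width])
    return "\n".join(out) + "\n"
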