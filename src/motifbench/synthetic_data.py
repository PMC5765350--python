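"""Seeded synthetic study generator.

Produces, from one seed, every input the comparison pipeline consumes: a
genome containing mutated copies of ERE (retroelement) families related by
common descent, per-protein information-rich motifs planted both inside a
protein's assigned ERE classes and at non-repeat loci, two noisy peak sets
per protein drawn from one shared pool of true binding sites (so pairwise
peak overlap is partial while ERE profiles and motifs agree), and candidate
motifs of varying fidelity (the true motif, a column-corrupted copy, an
unrelated protein's motif, optionally a near-true "in vitro" motif).

All counts and noise levels live in :class:`SimConfig`; identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from motifbench.errors import OvercrowdedGenomeError, PoolExhaustedError
from motifbench.motifs import BASES, PWM, MotifMetadata
from motifbench.peaks import Peak, PeakSet
from motifbench.ere_profile import RepeatAnnotation
from motifbench.rng import RngLike, as_rng

DATASET_LABELS = ("setA", "setB")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults are desk-sized: a 2 Mb genome, 10 proteins, 10 ERE classes of
    40 copies each, a 200-site true pool per protein and two 150-peak
    datasets with 30% false peaks — large enough for stable AUROCs and
    clear matched/unmatched separation, small enough for seconds-scale runs.
    """

    n_proteins: int = 10
    n_ere_classes: int = 10
    ere_copies_per_class: int = 40
    ere_length: int = 300
    copy_mutation_rate: float = 0.10
    genome_length: int = 2_000_000
    motif_width: int = 12
    sites_per_protein: int | None = None  # None -> true_site_pool_size
    true_site_pool_size: int = 200
    peaks_per_dataset: int = 150
    false_peak_fraction: float = 0.3
    summit_jitter_sd: float = 20.0
    score_noise_sd: float = 1.0
    seed: int = 0
    # secondary knobs
    ere_site_fraction: float = 0.6  # fraction of a protein's sites inside its EREs
    min_classes_per_protein: int = 1
    max_classes_per_protein: int = 3
    peak_halfwidth: int = 100
    true_score_mean: float = 10.0
    false_score_mean: float = 8.0
    corruption_fraction: float = 0.6
    include_in_vitro: bool = False

    def __post_init__(self) -> None:
        for name in (
            "n_proteins", "n_ere_classes", "ere_copies_per_class", "ere_length",
            "genome_length", "motif_width", "true_site_pool_size",
            "peaks_per_dataset",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in (
            "copy_mutation_rate", "false_peak_fraction", "ere_site_fraction",
            "corruption_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def pool_size(self) -> int:
        return (
            self.true_site_pool_size
            if self.sites_per_protein is None
            else self.sites_per_protein
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    config: SimConfig
    chrom: str
    genome: dict[str, str]
    repeats: RepeatAnnotation
    proteins: tuple[str, ...] = ()
    true_pwms: dict[str, PWM] = field(default_factory=dict)
    site_pools: dict[str, tuple[int, ...]] = field(default_factory=dict)
    assigned_classes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    # (protein, dataset) -> per-peak True/False flags, peak order
    true_peak_flags: dict[tuple[str, str], tuple[bool, ...]] = field(
        default_factory=dict
    )
    # (protein, dataset) -> per-peak pool-site index (-1 for false peaks)
    peak_site_index: dict[tuple[str, str], tuple[int, ...]] = field(
        default_factory=dict
    )


_BASE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)


def _random_bases(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _to_string(idx: np.ndarray) -> str:
    return _BASE_LUT[idx].tobytes().decode("ascii")


def generate_ere_library(cfg: SimConfig, rng: RngLike) -> list[str]:
    """Random consensus sequence per ERE class.

    Random consensi are pairwise ~25% identical, so classes are distinct
    lineages; within-class copies later diverge by point substitution only.
    """
    gen = as_rng(rng)
    return [
        _to_string(_random_bases(cfg.ere_length, gen))
        for _ in range(cfg.n_ere_classes)
    ]


def _mutate(consensus_idx: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    copy = consensus_idx.copy()
    hits = np.flatnonzero(rng.random(copy.size) < rate)
    if hits.size:
        # substitute with one of the three other bases
        copy[hits] = (copy[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return copy


def generate_genome(
    cfg: SimConfig, rng: RngLike, library: list[str] | None = None
) -> GroundTruth:
    """Background genome with non-overlapping mutated ERE copies placed
    uniformly; the annotation records every copy with its class.

    Raises :class:`OvercrowdedGenomeError` if a copy cannot be placed after
    bounded retries (genome too small for the requested repeat load).
    """
    gen = as_rng(rng)
    if library is None:
        library = generate_ere_library(cfg, gen)
    total = cfg.n_ere_classes * cfg.ere_copies_per_class * cfg.ere_length
    if total > cfg.genome_length:
        raise OvercrowdedGenomeError(
            f"planted repeat material ({total} bp) exceeds genome length"
        )
    genome_idx = _random_bases(cfg.genome_length, gen)
    occupied = np.zeros(cfg.genome_length, dtype=bool)
    intervals: list[tuple[str, int, int, str]] = []
    chrom = "chr1"
    for c, consensus in enumerate(library):
        cls = f"ERE{c + 1:02d}"
        cons_idx = np.array([BASES.index(b) for b in consensus], dtype=np.int8)
        for _copy in range(cfg.ere_copies_per_class):
            for _attempt in range(1000):
                start = int(gen.integers(0, cfg.genome_length - cfg.ere_length))
                if not occupied[start : start + cfg.ere_length].any():
                    break
            else:
                raise OvercrowdedGenomeError(
                    f"could not place a copy of {cls} after 1000 attempts"
                )
            genome_idx[start : start + cfg.ere_length] = _mutate(
                cons_idx, cfg.copy_mutation_rate, gen
            )
            occupied[start : start + cfg.ere_length] = True
            intervals.append((chrom, start, start + cfg.ere_length, cls))
    intervals.sort(key=lambda iv: iv[1])
    repeats = RepeatAnnotation(
        intervals=tuple(intervals),
        classes=tuple(f"ERE{c + 1:02d}" for c in range(cfg.n_ere_classes)),
    )
    return GroundTruth(
        config=cfg,
        chrom=chrom,
        genome={chrom: _to_string(genome_idx)},
        repeats=repeats,
    )


def _random_rich_pwm(width: int, rng: np.random.Generator, name: str,
                     metadata: MotifMetadata) -> PWM:
    """Information-rich PWM: one dominant base (p=0.85) per column."""
    matrix = np.full((width, 4), 0.05)
    dominant = rng.integers(0, 4, size=width)
    matrix[np.arange(width), dominant] = 0.85
    return PWM(name=name, matrix=matrix, metadata=metadata)


def generate_protein_truth(
    cfg: SimConfig, truth: GroundTruth, rng: RngLike
) -> GroundTruth:
    """Assign each protein a motif, ERE classes and a true-site pool, and
    write the motif consensus into the genome at every pool site.

    A protein's pool mixes sites inside copies of its 1-3 assigned ERE
    classes (fraction ``ere_site_fraction``) with sites at non-repeat loci,
    mirroring ERE-associated and independent binding.
    """
    gen = as_rng(rng)
    cfg = truth.config if cfg is None else cfg
    chrom = truth.chrom
    genome_idx = np.frombuffer(
        truth.genome[chrom].encode("ascii"), dtype=np.uint8
    ).copy()
    encode = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        encode[ord(b)] = i
    genome_idx = encode[genome_idx]

    repeat_mask = np.zeros(cfg.genome_length, dtype=bool)
    for _c, s, e, _cls in truth.repeats.intervals:
        repeat_mask[s:e] = True
    site_mask = np.zeros(cfg.genome_length, dtype=bool)

    copies_by_class: dict[str, list[tuple[int, int]]] = {}
    for _c, s, e, cls in truth.repeats.intervals:
        copies_by_class.setdefault(cls, []).append((s, e))

    proteins = tuple(f"TF{i + 1:02d}" for i in range(cfg.n_proteins))
    truth.proteins = proteins
    w = cfg.motif_width
    for prot in proteins:
        pwm = _random_rich_pwm(
            w, gen, name=f"{prot}_true",
            metadata=MotifMetadata(protein=prot, source="setA", method="rcade"),
        )
        consensus = pwm.matrix.argmax(axis=1).astype(np.int8)
        k = int(gen.integers(cfg.min_classes_per_protein,
                             cfg.max_classes_per_protein + 1))
        classes = tuple(
            sorted(gen.choice(truth.repeats.classes, size=k, replace=False))
        )
        n_sites = cfg.pool_size
        n_ere = int(round(cfg.ere_site_fraction * n_sites))
        sites: list[int] = []
        for i in range(n_sites):
            inside_ere = i < n_ere
            for _attempt in range(2000):
                if inside_ere:
                    cls = classes[int(gen.integers(len(classes)))]
                    cs, _ce = copies_by_class[cls][
                        int(gen.integers(len(copies_by_class[cls])))
                    ]
                    start = cs + int(gen.integers(0, cfg.ere_length - w))
                else:
                    start = int(gen.integers(0, cfg.genome_length - w))
                    if repeat_mask[start : start + w].any():
                        continue
                if not site_mask[start : start + w].any():
                    break
            else:
                raise OvercrowdedGenomeError(
                    f"could not place site {i} for {prot} after 2000 attempts"
                )
            genome_idx[start : start + w] = consensus
            site_mask[start : start + w] = True
            sites.append(start)
        truth.true_pwms[prot] = pwm
        truth.site_pools[prot] = tuple(sites)
        truth.assigned_classes[prot] = classes
    truth.genome = {chrom: _to_string(genome_idx)}
    return truth


def generate_peaksets(
    cfg: SimConfig, truth: GroundTruth, rng: RngLike
) -> dict[str, dict[str, PeakSet]]:
    """Two noisy peak sets per protein drawn from its shared site pool.

    Each dataset independently samples its true peaks without replacement
    from the pool (so cross-dataset sharing follows the hypergeometric
    expectation), adds false peaks at uniform non-site loci, jitters
    summits with clipped Gaussian noise and draws enrichment scores with
    true peaks stochastically higher.
    """
    gen = as_rng(rng)
    chrom = truth.chrom
    chrom_len = cfg.genome_length
    half = cfg.peak_halfwidth
    w = cfg.motif_width
    n_true = int(round((1.0 - cfg.false_peak_fraction) * cfg.peaks_per_dataset))
    n_false = cfg.peaks_per_dataset - n_true
    out: dict[str, dict[str, PeakSet]] = {}
    for prot in truth.proteins:
        pool = truth.site_pools[prot]
        if n_true > len(pool):
            raise PoolExhaustedError(
                f"{prot}: {n_true} true peaks requested from a pool of {len(pool)}"
            )
        pool_arr = np.asarray(pool)
        out[prot] = {}
        for dataset in DATASET_LABELS:
            chosen_idx = gen.choice(len(pool_arr), size=n_true, replace=False)
            centers = list(pool_arr[chosen_idx] + w // 2)
            flags = [True] * n_true
            site_idx = [int(i) for i in chosen_idx]
            for _ in range(n_false):
                while True:
                    pos = int(gen.integers(half, chrom_len - half))
                    if np.min(np.abs(pool_arr - pos)) > 2 * half:
                        break
                centers.append(pos)
                flags.append(False)
                site_idx.append(-1)
            peaks = []
            for i, (center, is_true) in enumerate(zip(centers, flags)):
                jitter = float(gen.normal(0.0, cfg.summit_jitter_sd))
                jitter = float(np.clip(jitter, -3 * cfg.summit_jitter_sd,
                                       3 * cfg.summit_jitter_sd))
                summit = int(np.clip(round(center + jitter), half,
                                     chrom_len - half - 1))
                mean = cfg.true_score_mean if is_true else cfg.false_score_mean
                score = float(gen.normal(mean, cfg.score_noise_sd))
                peaks.append(
                    Peak(
                        chrom=chrom,
                        start=summit - half,
                        end=summit + half,
                        summit=summit,
                        score=score,
                        name=f"{prot}_{dataset}_p{i + 1:04d}",
                    )
                )
            out[prot][dataset] = PeakSet(
                protein=prot, dataset=dataset, peaks=tuple(peaks)
            )
            truth.true_peak_flags[(prot, dataset)] = tuple(flags)
            truth.peak_site_index[(prot, dataset)] = tuple(site_idx)
    return out


def _corrupt(pwm: PWM, fraction: float, rng: np.random.Generator) -> np.ndarray:
    matrix = pwm.matrix.copy()
    n_cols = int(round(fraction * matrix.shape[0]))
    if n_cols:
        cols = rng.choice(matrix.shape[0], size=n_cols, replace=False)
        matrix[cols] = 0.25
    return matrix


def generate_candidate_motifs(
    cfg: SimConfig, truth: GroundTruth, rng: RngLike
) -> dict[str, list[PWM]]:
    """Candidate motifs of varying fidelity per protein.

    The true PWM (recognition-code supported, nominally trained on setA), a
    column-corrupted copy (MEME-like, trained on setB), another protein's
    true PWM (external decoy), and optionally an "in vitro" near-true PWM
    obtained by a small Dirichlet perturbation.
    """
    gen = as_rng(rng)
    prots = truth.proteins
    out: dict[str, list[PWM]] = {}
    for i, prot in enumerate(prots):
        true_pwm = truth.true_pwms[prot]
        cands = [
            PWM(
                name=f"{prot}_rcade_setA",
                matrix=true_pwm.matrix,
                metadata=MotifMetadata(
                    protein=prot, source="setA", method="rcade"
                ),
            )
        ]
        corrupted = _corrupt(true_pwm, cfg.corruption_fraction, gen)
        cands.append(
            PWM(
                name=f"{prot}_meme_setB",
                matrix=corrupted,
                metadata=MotifMetadata(protein=prot, source="setB", method="meme"),
            )
        )
        other = prots[(i + 1) % len(prots)]
        cands.append(
            PWM(
                name=f"{prot}_external_decoy",
                matrix=truth.true_pwms[other].matrix,
                metadata=MotifMetadata(
                    protein=prot, source="external:decoy", method="external"
                ),
            )
        )
        if cfg.include_in_vitro:
            alpha = true_pwm.matrix * 200.0 + 1.0
            perturbed = np.vstack([gen.dirichlet(a) for a in alpha])
            cands.append(
                PWM(
                    name=f"{prot}_invitro",
                    matrix=perturbed,
                    metadata=MotifMetadata(
                        protein=prot,
                        source="external:invitro",
                        method="external",
                        is_in_vitro=True,
                    ),
                )
            )
        out[prot] = cands
    return out


@dataclass
class Study:
    """A complete synthetic study: inputs plus ground truth."""

    truth: GroundTruth
    peaksets: dict[str, dict[str, PeakSet]]
    candidates: dict[str, list[PWM]]

    @property
    def genome(self) -> dict[str, str]:
        return self.truth.genome

    @property
    def repeats(self) -> RepeatAnnotation:
        return self.truth.repeats

    @property
    def proteins(self) -> tuple[str, ...]:
        return self.truth.proteins


def generate_study(cfg: SimConfig | None = None, seed: int | None = None) -> Study:
    """Generate a full synthetic study from one seed.

    ``seed`` overrides ``cfg.seed``. Stage-level child seeds are spawned
    from the master seed, so adding a stage never perturbs earlier ones.
    """
    cfg = SimConfig() if cfg is None else cfg
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    truth = generate_genome(cfg, np.random.default_rng(children[0]))
    truth = generate_protein_truth(cfg, truth, np.random.default_rng(children[1]))
    peaksets = generate_peaksets(cfg, truth, np.random.default_rng(children[2]))
    candidates = generate_candidate_motifs(
        cfg, truth, np.random.default_rng(children[3])
    )
    return Study(truth=truth, peaksets=peaksets, candidates=candidates)
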