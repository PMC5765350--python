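"""Reading and writing a study directory.

A study directory holds everything the pipeline consumes as plain text:
genome FASTA, BED+class repeat annotation, one BED-dialect peak file per
(protein, dataset), a MEME-minimal candidate motif file, a motif metadata
table, a ground-truth site table, and a manifest with the seed, the config
echo and per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np

from motifbench.errors import ConfigError
from motifbench.ere_profile import read_repeats
from motifbench.motif_eval import AUROCGrid
from motifbench.motif_similarity import SimilarityMatrix
from motifbench.motifs import MotifMetadata, PWM, read_pwms, write_pwms
from motifbench.peaks import read_peaks, write_peaks
from motifbench.seq_null import read_fasta, write_fasta
from motifbench.synthetic_data import (
    DATASET_LABELS,
    GroundTruth,
    SimConfig,
    Study,
    generate_study,
)

MANIFEST = "manifest.json"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_study(study: Study, outdir) -> Path:
    """Write a study directory; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def emit(name: str, content: str) -> None:
        (outdir / name).write_text(content)
        files.append(name)

    truth = study.truth
    emit("genome.fa", write_fasta(sorted(truth.genome.items())))
    emit(
        "repeats.bed",
        "".join(
            f"{c}\t{s}\t{e}\t{cls}\n" for c, s, e, cls in truth.repeats.intervals
        ),
    )
    peak_files: dict[str, dict[str, str]] = {}
    for prot in sorted(study.peaksets):
        peak_files[prot] = {}
        for ds, ps in sorted(study.peaksets[prot].items()):
            name = f"peaks_{prot}_{ds}.bed"
            emit(name, write_peaks(ps))
            peak_files[prot][ds] = name
    all_motifs = [m for prot in sorted(study.candidates)
                  for m in study.candidates[prot]]
    emit("candidates.meme", write_pwms(all_motifs))
    meta_lines = ["name\tprotein\tsource\tmethod\trecognition_code_supported\tis_in_vitro"]
    for m in all_motifs:
        md = m.metadata
        meta_lines.append(
            f"{m.name}\t{md.protein}\t{md.source}\t{md.method}"
            f"\t{int(md.recognition_code_supported)}\t{int(md.is_in_vitro)}"
        )
    emit("motif_metadata.tsv", "\n".join(meta_lines) + "\n")
    site_lines = ["protein\tchrom\tstart\tclasses"]
    for prot in truth.proteins:
        classes = ",".join(truth.assigned_classes.get(prot, ()))
        for s in truth.site_pools.get(prot, ()):
            site_lines.append(f"{prot}\t{truth.chrom}\t{s}\t{classes}")
    emit("truth_sites.tsv", "\n".join(site_lines) + "\n")
    if truth.true_pwms:
        emit("truth_motifs.meme", write_pwms(list(truth.true_pwms.values())))

    manifest = {
        "seed": truth.config.seed,
        "config": asdict(truth.config),
        "dataset_labels": list(DATASET_LABELS),
        "peak_files": peak_files,
        "files": {name: _sha256(outdir / name) for name in files},
    }
    path = outdir / MANIFEST
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_study(indir) -> Study:
    """Reconstruct a Study from a directory written by write_study.

    Ground-truth internals (site pools, true PWMs) are not needed by the
    comparison pipeline and are left empty.
    """
    indir = Path(indir)
    manifest_path = indir / MANIFEST
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    cfg = SimConfig(**{
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in manifest["config"].items()
    })
    genome = dict(read_fasta((indir / "genome.fa").read_text()))
    repeats = read_repeats((indir / "repeats.bed").read_text(), "bed_class")
    motifs = read_pwms((indir / "candidates.meme").read_text())
    by_name = {m.name: m for m in motifs}
    meta_text = (indir / "motif_metadata.tsv").read_text().splitlines()
    candidates: dict[str, list[PWM]] = {}
    for line in meta_text[1:]:
        name, protein, source, method, rcade, invitro = line.split("\t")
        pwm = by_name[name]
        pwm = PWM(
            name=pwm.name,
            matrix=pwm.matrix,
            metadata=MotifMetadata(
                protein=protein,
                source=source,
                method=method,
                recognition_code_supported=bool(int(rcade)),
                is_in_vitro=bool(int(invitro)),
            ),
        )
        candidates.setdefault(protein, []).append(pwm)
    peaksets = {}
    for prot, by_ds in manifest["peak_files"].items():
        peaksets[prot] = {}
        for ds, fname in by_ds.items():
            peaksets[prot][ds] = read_peaks(
                (indir / fname).read_text(), protein=prot, dataset=ds
            )
    chrom = next(iter(genome))
    truth = GroundTruth(
        config=cfg,
        chrom=chrom,
        genome=genome,
        repeats=repeats,
        proteins=tuple(sorted(peaksets)),
    )
    return Study(truth=truth, peaksets=peaksets, candidates=candidates)


def simulate_to_dir(cfg: SimConfig, outdir) -> Path:
    """Generate a study and write it; returns the manifest path."""
    return write_study(generate_study(cfg), outdir)


# ---------------------------------------------------------------------------
# grid / similarity TSV parsers (round-trip for the report files)


def grid_from_tsv(text: str) -> AUROCGrid:
    lines = [ln for ln in text.splitlines() if ln]
    labels = []
    for cell in lines[0].split("\t")[1:]:
        prot, ds = cell.split(":")
        labels.append((prot, ds))
    names, rows = [], []
    for line in lines[1:]:
        cells = line.split("\t")
        names.append(cells[0])
        rows.append([float(c) if c else math.nan for c in cells[1:]])
    return AUROCGrid(
        motif_names=tuple(names),
        peakset_labels=tuple(labels),
        values=np.asarray(rows, dtype=float),
    )


def similarity_from_tsv(text: str) -> SimilarityMatrix:
    lines = [ln for ln in text.splitlines() if ln]
    if not lines[0].startswith("#"):
        raise ConfigError("similarity TSV must start with a '#n=... l=... seed=...' line")
    spec = dict(tok.split("=") for tok in lines[0][1:].split())
    names = tuple(lines[1].split("\t")[1:])
    rows = []
    for line in lines[2:]:
        cells = line.split("\t")
        rows.append([float(c) if c else math.nan for c in cells[1:]])
    return SimilarityMatrix(
        motif_names=names,
        values=np.asarray(rows, dtype=float),
        background_spec=(int(spec["n"]), int(spec["l"]), int(spec["seed"])),
    )
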