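"""End-to-end comparison pipeline over a synthetic or user-supplied study.

Stages mirror the analysis workflow: merge peaks, take top-N, compute
pairwise peak-overlap percentages, ERE enrichment profiles and their
matched-vs-unmatched correlation decomposition, per-protein motif
similarity matrices, the AUROC evaluation grid, and finally the Class A-F
reference-motif selection with confidence metrics and disagreement flags.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from motifbench.ere_profile import (
    AgreementSummary,
    EREProfile,
    RepeatAnnotation,
    compute_profile,
    matched_vs_unmatched,
    profile_correlation,
)
from motifbench.motif_eval import AUROCGrid, evaluate_grid
from motifbench.motif_similarity import SimilarityMatrix, similarity_matrix
from motifbench.motifs import PWM
from motifbench.peaks import PeakSet, merge_peaks, overlap_percentage, top_n
from motifbench.reference_selection import (
    Candidate,
    CandidateTable,
    ReferenceSet,
    Thresholds,
    build_reference_set,
    flag_disagreement,
)
from motifbench.synthetic_data import DATASET_LABELS, Study


@dataclass(frozen=True)
class CompareParams:
    """Pipeline parameters; defaults follow the analysis conventions
    (top 500 peaks, ±250 bp summit windows, 50 bp merge gap, similarity
    background n=100,000 and l=100)."""

    n_top: int = 500
    flank: int = 250
    merge_gap: int = 50
    similarity_n: int = 100_000
    similarity_l: int = 100
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)


@dataclass
class CompareReport:
    """All numbers the comparison pipeline produces."""

    params: CompareParams
    proteins: tuple[str, ...]
    dataset_labels: tuple[str, str]
    # protein -> {"a_vs_b": %, "b_vs_a": %, "a_vs_b_all": %, "b_vs_a_all": %}
    overlaps: dict[str, dict[str, float]]
    profiles: dict[tuple[str, str], EREProfile]
    agreement: AgreementSummary
    matched_correlation: dict[str, float]
    similarities: dict[str, SimilarityMatrix]
    grids: dict[str, AUROCGrid]
    reference: ReferenceSet
    flags: dict[str, set[str]]

    def class_counts(self) -> dict[str, int]:
        return self.reference.class_counts()

    def median_auroc_per_class(self) -> dict[str, float]:
        by_class: dict[str, list[float]] = {}
        for r in self.reference.results:
            if not math.isnan(r.best_test_auroc):
                by_class.setdefault(r.selection_class, []).append(r.best_test_auroc)
        return {
            cls: float(np.median(vals)) for cls, vals in sorted(by_class.items())
        }

    def summary(self) -> dict:
        ag = self.agreement
        return {
            "n_proteins": len(self.proteins),
            "class_counts": self.class_counts(),
            "median_auroc_per_class": self.median_auroc_per_class(),
            "mean_overlap_pct_top": float(
                np.mean([o["a_vs_b"] for o in self.overlaps.values()])
            ),
            "agreement_threshold": ag.threshold,
            "frac_matched_above": ag.frac_matched_above,
            "frac_unmatched_above": ag.frac_unmatched_above,
            "n_matched": len(ag.matched_correlations),
            "n_unmatched": len(ag.unmatched_correlations),
            "n_flagged": sum(1 for f in self.flags.values() if f),
        }


def candidate_table(
    protein: str, motifs: list[PWM], grid: AUROCGrid, dataset_labels: tuple[str, str]
) -> CandidateTable:
    """Build a CandidateTable from motif metadata and an AUROC grid.

    A motif whose metadata source names one of the datasets is ChIP-derived
    and trained on that dataset; any other source means no training set.
    """
    cands = []
    for m in motifs:
        aurocs = {
            ds: grid.value(m.name, (protein, ds)) for ds in dataset_labels
        }
        train = m.metadata.source if m.metadata.source in dataset_labels else None
        cands.append(
            Candidate(
                name=m.name,
                aurocs=aurocs,
                train=train,
                method=m.metadata.method,
                recognition_code_supported=m.metadata.recognition_code_supported,
                is_in_vitro=m.metadata.is_in_vitro,
                source=m.metadata.source,
            )
        )
    return CandidateTable(protein=protein, candidates=tuple(cands))


def compare_study(study: Study, params: CompareParams | None = None) -> CompareReport:
    """Run the full comparison pipeline on a study.

    Peak sets are merged (50 bp gap) before any top-N statistic. One child
    seed per stage keeps reruns byte-identical and stages independent.
    """
    params = CompareParams() if params is None else params
    genome = study.genome
    repeats: RepeatAnnotation = study.repeats
    labels = DATASET_LABELS
    children = np.random.SeedSequence(params.seed).spawn(2)
    grid_rng = np.random.default_rng(children[0])

    merged: dict[str, dict[str, PeakSet]] = {
        prot: {ds: merge_peaks(ps, params.merge_gap) for ds, ps in by_ds.items()}
        for prot, by_ds in study.peaksets.items()
    }
    proteins = tuple(sorted(merged))

    overlaps: dict[str, dict[str, float]] = {}
    profiles: dict[tuple[str, str], EREProfile] = {}
    for prot in proteins:
        a, b = merged[prot][labels[0]], merged[prot][labels[1]]
        overlaps[prot] = {
            "a_vs_b": overlap_percentage(a, b, params.n_top, params.flank),
            "b_vs_a": overlap_percentage(b, a, params.n_top, params.flank),
            "a_vs_b_all": overlap_percentage(a, b, max(len(a), 1) + len(b), params.flank),
            "b_vs_a_all": overlap_percentage(b, a, max(len(a), 1) + len(b), params.flank),
        }
        for ds in labels:
            profiles[(prot, ds)] = compute_profile(
                merged[prot][ds], repeats, params.n_top, params.flank
            )

    profiles_a = [profiles[(p, labels[0])] for p in proteins]
    profiles_b = [profiles[(p, labels[1])] for p in proteins]
    agreement = matched_vs_unmatched(profiles_a, profiles_b, "best_separation")
    matched_corr = {
        p: profile_correlation(profiles[(p, labels[0])], profiles[(p, labels[1])])
        for p in proteins
    }

    similarities: dict[str, SimilarityMatrix] = {}
    grids: dict[str, AUROCGrid] = {}
    tables: list[CandidateTable] = []
    flags: dict[str, set[str]] = {}
    results = []
    for prot in proteins:
        motifs = study.candidates[prot]
        similarities[prot] = similarity_matrix(
            motifs, params.similarity_n, params.similarity_l, rng=params.seed
        )
        grid = evaluate_grid(
            motifs,
            [merged[prot][ds] for ds in labels],
            genome,
            grid_rng,
            params.n_top,
            params.flank,
        )
        grids[prot] = grid
        table = candidate_table(prot, motifs, grid, labels)
        tables.append(table)
        ref = build_reference_set([table], similarities[prot], params.thresholds)
        results.extend(ref.results)
        # cross-dataset motif agreement: similarity between the two
        # ChIP-derived candidates, one per dataset
        chip = {c.train: c.name for c in table.candidates if c.train is not None}
        motif_r = math.nan
        if len(chip) == 2:
            motif_r = similarities[prot].value(chip[labels[0]], chip[labels[1]])
        flags[prot] = flag_disagreement(
            matched_corr[prot], motif_r, params.thresholds
        )

    reference = build_reference_set(
        tables,
        None,
        params.thresholds,
    )
    # re-attach per-protein cross-source similarities computed above
    reference = ReferenceSet(
        results=tuple(results), errors=reference.errors
    )

    return CompareReport(
        params=params,
        proteins=proteins,
        dataset_labels=labels,
        overlaps=overlaps,
        profiles=profiles,
        agreement=agreement,
        matched_correlation=matched_corr,
        similarities=similarities,
        grids=grids,
        reference=reference,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# report serialization


def profiles_to_tsv(profiles: dict[tuple[str, str], EREProfile]) -> str:
    """Profile matrix as TSV: rows = protein:dataset, columns = classes."""
    items = sorted(profiles.items())
    if not items:
        return "\n"
    classes = items[0][1].classes
    lines = ["profile\t" + "\t".join(classes)]
    for (prot, ds), prof in items:
        lines.append(
            f"{prot}:{ds}\t" + "\t".join(f"{v:.4f}" for v in prof.fractions)
        )
    return "\n".join(lines) + "\n"


def overlaps_to_tsv(overlaps: dict[str, dict[str, float]],
                    labels: tuple[str, str]) -> str:
    a, b = labels
    lines = [
        f"protein\t{a}_vs_{b}_top\t{b}_vs_{a}_top\t{a}_vs_{b}_all\t{b}_vs_{a}_all"
    ]
    for prot, o in sorted(overlaps.items()):
        lines.append(
            f"{prot}\t{o['a_vs_b']:.2f}\t{o['b_vs_a']:.2f}"
            f"\t{o['a_vs_b_all']:.2f}\t{o['b_vs_a_all']:.2f}"
        )
    return "\n".join(lines) + "\n"


def report_json(report: CompareReport, protein: str) -> dict:
    """Per-protein report (the per-protein web-panel analogue)."""
    ref = next(
        (r for r in report.reference.results if r.protein == protein), None
    )
    grid = report.grids[protein]
    sim = report.similarities[protein]
    return {
        "protein": protein,
        "overlap_pct": report.overlaps[protein],
        "ere_correlation": _nan_none(report.matched_correlation[protein]),
        "similarity": {
            "motifs": list(sim.motif_names),
            "values": [[_nan_none(v) for v in row] for row in sim.values],
        },
        "auroc": {
            "motifs": list(grid.motif_names),
            "peaksets": [f"{p}:{d}" for p, d in grid.peakset_labels],
            "values": [[_nan_none(v) for v in row] for row in grid.values],
        },
        "selection": None
        if ref is None
        else {
            "chosen": list(ref.chosen),
            "class": ref.selection_class,
            "method": ref.method,
            "best_test_auroc": _nan_none(ref.best_test_auroc),
            "best_cross_source_similarity": _nan_none(
                ref.best_cross_source_similarity
            ),
        },
        "flags": sorted(report.flags[protein]),
    }


def _nan_none(v: float):
    return None if isinstance(v, float) and math.isnan(v) else float(v)


def write_report(report: CompareReport, outdir) -> list[str]:
    """Write all report files; returns the file names written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(name: str, content: str) -> None:
        (outdir / name).write_text(content)
        written.append(name)

    emit("overlaps.tsv", overlaps_to_tsv(report.overlaps, report.dataset_labels))
    emit("ere_profiles.tsv", profiles_to_tsv(report.profiles))
    ag = report.agreement
    emit(
        "ere_agreement.json",
        json.dumps(
            {
                "threshold": ag.threshold,
                "frac_matched_above": ag.frac_matched_above,
                "frac_unmatched_above": ag.frac_unmatched_above,
                "matched_correlations": [_nan_none(v) for v in ag.matched_correlations],
                "n_unmatched": len(ag.unmatched_correlations),
            },
            indent=2,
        ),
    )
    for prot in report.proteins:
        emit(f"similarity_{prot}.tsv", report.similarities[prot].to_tsv())
        emit(f"auroc_{prot}.tsv", report.grids[prot].to_tsv())
        emit(
            f"report_{prot}.json",
            json.dumps(report_json(report, prot), indent=2),
        )
    emit("reference_set.tsv", report.reference.to_tsv())
    emit("summary.json", json.dumps(report.summary(), indent=2))
    return written
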