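"""Synthetic study generator: determinism, construction guarantees,
and the sampling structure the analysis relies on."""

import numpy as np
import pytest

from motifbench.errors import OvercrowdedGenomeError
from motifbench.motifs import max_pwm_score, to_score_matrix
from motifbench.synthetic_data import (
    DATASET_LABELS,
    SimConfig,
    generate_ere_library,
    generate_genome,
    generate_peaksets,
    generate_study,
)


class TestEreLibrary:
    def test_distinct_and_deterministic(self, tiny_cfg):
        lib1 = generate_ere_library(tiny_cfg, 3)
        lib2 = generate_ere_library(tiny_cfg, 3)
        assert lib1 == lib2
        assert len(set(lib1)) == tiny_cfg.n_ere_classes

    def test_pairwise_identity_low(self, tiny_cfg):
        lib = generate_ere_library(tiny_cfg, 1)
        for i in range(len(lib)):
            for j in range(i + 1, len(lib)):
                identity = np.mean(
                    [a == b for a, b in zip(lib[i], lib[j])]
                )
                assert identity < 0.6


class TestGenome:
    def test_annotation_count_conservation(self, tiny_cfg, tiny_study):
        expected = tiny_cfg.n_ere_classes * tiny_cfg.ere_copies_per_class
        assert len(tiny_study.repeats.intervals) == expected

    def test_zero_mutation_rate_copies_consensus_exactly(self, tiny_cfg):
        import dataclasses

        cfg = dataclasses.replace(tiny_cfg, copy_mutation_rate=0.0)
        lib = generate_ere_library(cfg, 0)
        truth = generate_genome(cfg, 0, library=lib)
        by_class = dict(zip(truth.repeats.classes, lib))
        chrom = truth.genome[truth.chrom]
        for _c, s, e, cls in truth.repeats.intervals:
            assert chrom[s:e] == by_class[cls]

    def test_mutation_rate_within_binomial_bounds(self, tiny_cfg):
        import dataclasses

        cfg = dataclasses.replace(tiny_cfg, copy_mutation_rate=0.2)
        lib = generate_ere_library(cfg, 2)
        truth = generate_genome(cfg, 2, library=lib)
        by_class = dict(zip(truth.repeats.classes, lib))
        chrom = truth.genome[truth.chrom]
        n = cfg.ere_length
        # substituted bases differ; a substitution never reproduces the original
        sd = np.sqrt(n * 0.2 * 0.8)
        for _c, s, e, cls in truth.repeats.intervals:
            diffs = sum(a != b for a, b in zip(chrom[s:e], by_class[cls]))
            assert abs(diffs - 0.2 * n) <= 3 * sd

    def test_overcrowded_genome_rejected(self, tiny_cfg):
        import dataclasses

        cfg = dataclasses.replace(tiny_cfg, genome_length=1000)
        with pytest.raises(OvercrowdedGenomeError):
            generate_genome(cfg, 0)


class TestProteinTruth:
    def test_pool_sizes_and_class_assignments(self, tiny_cfg, tiny_study):
        truth = tiny_study.truth
        assert len(truth.proteins) == tiny_cfg.n_proteins
        for prot in truth.proteins:
            assert len(truth.site_pools[prot]) == tiny_cfg.pool_size
            k = len(truth.assigned_classes[prot])
            assert tiny_cfg.min_classes_per_protein <= k <= tiny_cfg.max_classes_per_protein

    def test_planted_consensus_attains_near_max_score(self, tiny_cfg, tiny_study):
        truth = tiny_study.truth
        chrom = truth.genome[truth.chrom]
        for prot in truth.proteins[:1]:
            pwm = truth.true_pwms[prot]
            sm = to_score_matrix(pwm)
            best = sm.matrix.max(axis=1).sum()
            for site in truth.site_pools[prot][:20]:
                window = chrom[site : site + pwm.width]
                assert max_pwm_score(window, sm) >= 0.95 * best

    def test_ere_sites_inside_assigned_classes(self, tiny_cfg, tiny_study):
        truth = tiny_study.truth
        n_ere = int(round(tiny_cfg.ere_site_fraction * tiny_cfg.pool_size))
        for prot in truth.proteins:
            allowed = [
                (s, e)
                for _c, s, e, cls in truth.repeats.intervals
                if cls in truth.assigned_classes[prot]
            ]
            for site in truth.site_pools[prot][:n_ere]:
                assert any(s <= site < e for s, e in allowed)


class TestPeaksets:
    def test_deterministic_under_seed(self, tiny_cfg):
        s1 = generate_study(tiny_cfg)
        s2 = generate_study(tiny_cfg)
        assert s1.genome == s2.genome
        prot = s1.proteins[0]
        for ds in DATASET_LABELS:
            assert s1.peaksets[prot][ds].peaks == s2.peaksets[prot][ds].peaks

    def test_true_peak_summits_near_planted_sites(self, tiny_cfg, tiny_study):
        truth = tiny_study.truth
        prot = truth.proteins[0]
        pool = np.asarray(truth.site_pools[prot])
        flags = truth.true_peak_flags[(prot, DATASET_LABELS[0])]
        ps = tiny_study.peaksets[prot][DATASET_LABELS[0]]
        site_idx = truth.peak_site_index[(prot, DATASET_LABELS[0])]
        tol = 3 * tiny_cfg.summit_jitter_sd + tiny_cfg.motif_width
        for p, is_true, idx in zip(ps.peaks, flags, site_idx):
            if is_true:
                assert abs(pool[idx] + tiny_cfg.motif_width // 2 - p.summit) <= tol
            else:
                assert idx == -1
                dist = np.min(np.abs(pool + tiny_cfg.motif_width // 2 - p.summit))
                assert dist > (
                    2 * tiny_cfg.peak_halfwidth
                    - 3 * tiny_cfg.summit_jitter_sd
                    - tiny_cfg.motif_width
                )

    def test_true_sharing_follows_hypergeometric_expectation(self):
        cfg = SimConfig(
            n_proteins=1,
            n_ere_classes=3,
            ere_copies_per_class=8,
            ere_length=120,
            genome_length=200_000,
            motif_width=8,
            true_site_pool_size=200,
            peaks_per_dataset=150,
            false_peak_fraction=0.2,
            seed=0,
        )
        # 120 true peaks per dataset from a pool of 200:
        # expected shared sites = 120^2 / 200 = 72
        expected = 72.0
        var = (120 * 120 * 80 * 80) / (200 * 200 * 199)  # hypergeometric
        sd = np.sqrt(var)
        shared = []
        study = generate_study(cfg)
        truth = study.truth
        prot = truth.proteins[0]
        for seed in range(20):
            import dataclasses

            peaksets = generate_peaksets(
                dataclasses.replace(cfg, seed=seed), truth, seed
            )
            sets = [
                {i for i in truth.peak_site_index[(prot, ds)] if i >= 0}
                for ds in DATASET_LABELS
            ]
            shared.append(len(sets[0] & sets[1]))
        assert abs(np.mean(shared) - expected) <= 3 * sd

    def test_zero_false_fraction_full_pool_covers_identical_sites(self):
        cfg = SimConfig(
            n_proteins=1,
            n_ere_classes=2,
            ere_copies_per_class=5,
            ere_length=100,
            genome_length=100_000,
            motif_width=8,
            true_site_pool_size=50,
            peaks_per_dataset=50,
            false_peak_fraction=0.0,
            summit_jitter_sd=0.0,
            seed=3,
        )
        study = generate_study(cfg)
        prot = study.proteins[0]
        summits = [
            sorted(p.summit for p in study.peaksets[prot][ds].peaks)
            for ds in DATASET_LABELS
        ]
        assert summits[0] == summits[1]


class TestCandidateMotifs:
    def test_corruption_extremes(self, tiny_cfg, tiny_study):
        import dataclasses

        from motifbench.synthetic_data import generate_candidate_motifs

        truth = tiny_study.truth
        prot = truth.proteins[0]
        zero = generate_candidate_motifs(
            dataclasses.replace(tiny_cfg, corruption_fraction=0.0), truth, 0
        )
        full = generate_candidate_motifs(
            dataclasses.replace(tiny_cfg, corruption_fraction=1.0), truth, 0
        )
        true_m = truth.true_pwms[prot].matrix
        corrupted_zero = zero[prot][1].matrix
        corrupted_full = full[prot][1].matrix
        np.testing.assert_array_equal(corrupted_zero, true_m)
        np.testing.assert_array_equal(corrupted_full, np.full_like(true_m, 0.25))

    def test_true_motif_flagged_recognition_code(self, tiny_study):
        prot = tiny_study.proteins[0]
        true_cand = tiny_study.candidates[prot][0]
        assert true_cand.metadata.method == "rcade"
        assert true_cand.metadata.recognition_code_supported

    def test_true_beats_corrupted_over_seeds(self, default_study):
        # strict majority across 10 reruns of the peak noise
        import dataclasses

        from motifbench.motif_eval import evaluate_motif
        from motifbench.synthetic_data import generate_peaksets

        truth = default_study.truth
        cfg = truth.config
        prot = truth.proteins[0]
        true_pwm = default_study.candidates[prot][0]
        corrupted = default_study.candidates[prot][1]
        wins = 0
        for seed in range(10):
            peaksets = generate_peaksets(
                dataclasses.replace(cfg, seed=seed), truth, seed
            )
            ps = peaksets[prot][DATASET_LABELS[0]]
            a = evaluate_motif(true_pwm, ps, default_study.genome, rng=seed)
            b = evaluate_motif(corrupted, ps, default_study.genome, rng=seed)
            wins += a > b
        assert wins >= 9
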