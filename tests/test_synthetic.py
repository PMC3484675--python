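import dataclasses

import numpy as np
import pytest

from retrodate.clock import RateModel, age_interval
from retrodate.paralog_reads import reverse_complement, spans_junction
from retrodate.synthetic import (
    SimConfig,
    comparison_mask,
    recovery_experiment,
    save_bundle,
    simulate_history,
    simulate_reads,
)
from retrodate.varclass import FixationStatus, classify_fixation, count_fixed_differences


class TestDeterminism:
    def test_identical_seeds_identical_bundles(self):
        a = simulate_history(SimConfig(seed=5))
        b = simulate_history(SimConfig(seed=5))
        assert a.retro_locus == b.retro_locus
        assert a.ancestor_transcript == b.ancestor_transcript
        assert a.fixed_variants == b.fixed_variants
        assert [p.observations for p in a.parent_panels] == [
            p.observations for p in b.parent_panels
        ]

    def test_different_seeds_differ(self):
        a = simulate_history(SimConfig(seed=5))
        b = simulate_history(SimConfig(seed=6))
        assert a.retro_locus != b.retro_locus

    def test_saved_bundle_bytes_reproducible(self, tmp_path):
        cfg = SimConfig(seed=5, n_reads=30)
        d1, d2 = tmp_path / "b1", tmp_path / "b2"
        for d in (d1, d2):
            bundle = simulate_history(cfg)
            simulate_reads(bundle)
            save_bundle(bundle, d)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()


class TestSimulateHistory:
    def test_zero_rate_retrocopy_equals_ancestral_allele(self):
        cfg = SimConfig(seed=1, rate=0.0, n_poly_sites=0, repeat_retro_delta=0)
        bundle = simulate_history(cfg)
        # the retrocopy descends from the deletion-bearing parent allele
        t = bundle.ancestor_transcript
        s = bundle.deletion_transcript_start
        expected = t[: s - 1] + t[s - 1 + cfg.deletion_len :]
        assert bundle.retro_mrna == expected
        assert bundle.retro_fixed_count == 0

    def test_element_is_reverse_complement_of_mrna_plus_polya(self):
        bundle = simulate_history(SimConfig(seed=2))
        s, e = bundle.element_interval
        element = bundle.retro_locus[s:e]
        assert element == reverse_complement(
            bundle.retro_mrna + "A" * bundle.config.polya_len
        )

    def test_tsd_flanks_element(self):
        bundle = simulate_history(SimConfig(seed=3))
        s, e = bundle.element_interval
        assert bundle.retro_locus[s - len(bundle.tsd) : s] == bundle.tsd
        assert bundle.retro_locus[e : e + len(bundle.tsd)] == bundle.tsd
        assert len(bundle.tsd) == bundle.config.tsd_len

    def test_planted_fixed_count_matches_two_branch_poisson(self):
        # with the parent branch mutating at the full rate, planted fixed
        # differences accumulate on both branches: mean ~ 2 * L * r * t
        cfg = SimConfig(seed=4, parent_branch_rate_factor=1.0)
        counts, lengths = [], []
        for rep in range(400):
            b = simulate_history(
                dataclasses.replace(cfg, seed=cfg.seed + rep), with_panels=False
            )
            counts.append(len(b.fixed_variants))
            lengths.append(len(b.ancestor_transcript))
        counts = np.asarray(counts, dtype=float)
        compared = np.mean(lengths) - cfg.deletion_len - cfg.repeat_tract_len
        expected = 2 * compared * cfg.rate * cfg.retro_age
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_planted_fixed_equal_varclass_k_on_noise_free_panels(self):
        for seed in range(8):
            bundle = simulate_history(SimConfig(seed=seed))
            calls = classify_fixation(bundle.parent_panels, bundle.retro_panels)
            mask = comparison_mask(bundle)
            k, _ = count_fixed_differences(calls, mask)
            planted_in_mask = sum(
                1 for v in bundle.fixed_variants if v.position in mask
            )
            assert k == planted_in_mask

    def test_no_false_fixation_at_common_polymorphism(self):
        # planted polymorphic sites with maf >= 0.2 on panels of 20 must
        # essentially never classify as fixed (< 5% across 500 sites)
        n_sites = 0
        n_false = 0
        seed = 0
        while n_sites < 500:
            cfg = SimConfig(seed=seed, n_poly_sites=25, maf_range=(0.2, 0.45))
            bundle = simulate_history(cfg)
            calls = {
                str(c.position): c
                for c in classify_fixation(bundle.parent_panels, bundle.retro_panels)
            }
            for v in bundle.polymorphic_variants:
                n_sites += 1
                if calls[str(v.position)].status is FixationStatus.FIXED_DIFFERENCE:
                    n_false += 1
            seed += 1
        assert n_false / n_sites < 0.05

    def test_deletion_polymorphic_in_parent_fixed_in_retro(self):
        bundle = simulate_history(SimConfig(seed=9, deletion_freq=0.5))
        calls = classify_fixation(bundle.parent_panels, bundle.retro_panels)
        from retrodate.gene_coords import transcript_to_coding

        del_pos = transcript_to_coding(bundle.deletion_transcript_start, bundle.model)
        (call,) = [c for c in calls if c.position == del_pos]
        assert call.status in (
            FixationStatus.POLYMORPHIC_IN_PARENT,
            FixationStatus.FIXED_DIFFERENCE,  # possible by panel sampling
        )
        assert call.retro_alleles == frozenset({"del"})

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(retro_age=1e8)  # older than every outgroup
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.0, 0.4))
        with pytest.raises(ValueError):
            SimConfig(host_insertion_point=0)


class TestSimulateReads:
    def test_error_free_reads_match_origin(self):
        cfg = SimConfig(seed=10, n_reads=60, read_error_rate=0.0)
        bundle = simulate_history(cfg)
        sources = {
            "retro_locus": bundle.retro_locus,
            "parent_locus": bundle.model.sequence,
        }
        for read in simulate_reads(bundle):
            segment = sources[read.origin][read.start : read.start + len(read.sequence)]
            expected = segment if read.strand == "+" else reverse_complement(segment)
            assert read.sequence == expected

    def test_junction_targeted_reads_span(self):
        cfg = SimConfig(seed=11, n_reads=40, read_len_range=(57, 78))
        bundle = simulate_history(cfg)
        junction = bundle.element_interval[0]
        for read in simulate_reads(bundle, junction_targeted=True, min_overhang=15):
            assert spans_junction(read.sequence, bundle.retro_locus, junction, 15).spans

    def test_read_count_and_lengths_match_config(self):
        cfg = SimConfig(seed=12, n_reads=80, read_len_range=(30, 40))
        bundle = simulate_history(cfg)
        reads = simulate_reads(bundle)
        assert len(reads) == 80
        assert all(30 <= len(r.sequence) <= 40 for r in reads)

    def test_error_rate_plants_errors(self):
        cfg = SimConfig(seed=13, n_reads=50, read_error_rate=0.05)
        bundle = simulate_history(cfg)
        reads = simulate_reads(bundle)
        assert sum(r.n_errors for r in reads) > 0


class TestRecoveryExperiment:
    def test_single_replicate_reproducible(self):
        cfg = SimConfig(seed=21)
        a = recovery_experiment(cfg, replicates=1)
        b = recovery_experiment(cfg, replicates=1)
        assert a.equals(b)

    def test_mean_estimate_near_truth(self):
        cfg = SimConfig(seed=22, retro_age=1.0e6)
        frame = recovery_experiment(cfg, replicates=400)
        ests = frame["point_age"].to_numpy()
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 1.0e6) < 3 * se

    def test_coverage_matches_rate_interval_construction(self):
        from scipy import stats

        cfg = SimConfig(seed=23, retro_age=1.0e6)
        lo, hi = 0.5e-9, 1.35e-9
        frame = recovery_experiment(cfg, replicates=400, rate_low=lo, rate_high=hi)
        # analytic expectation: interval covers truth iff k lands between
        # L*lo*t and L*hi*t, with k ~ Poisson(L*r*t)
        expect = np.mean(
            [
                stats.poisson.cdf(np.floor(L * hi * 1.0e6), L * cfg.rate * 1.0e6)
                - stats.poisson.cdf(np.ceil(L * lo * 1.0e6) - 1, L * cfg.rate * 1.0e6)
                for L in frame["L"]
            ]
        )
        coverage = frame.attrs["coverage"]
        se = np.sqrt(expect * (1 - expect) / len(frame))
        assert abs(coverage - expect) < 4 * se + 0.02
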