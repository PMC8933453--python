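"""Cohort generator: determinism, truth invariants, closed-form Ct spacing,
methylation round-trip and downstream separability."""

import dataclasses

import numpy as np
import pytest

from bloodlcl.clock import predict_age
from bloodlcl.pipeline import build_panels, classify_samples
from bloodlcl.qpcr import call_ct
from bloodlcl.synthetic import (
    CohortConfig,
    Dist,
    SampleTruth,
    generate_cohort,
    mean_methylation_at_age,
)


def cohorts_equal(a, b):
    if len(a) != len(b):
        return False
    for s, t in zip(a, b):
        if s.truth != t.truth or s.methylation != t.methylation:
            return False
        for assay in s.amplification:
            if not np.array_equal(s.amplification[assay].fluorescence,
                                  t.amplification[assay].fluorescence):
                return False
        if not np.array_equal(s.melt.fluorescence, t.melt.fluorescence):
            return False
    return True


class TestConfig:
    def test_empty_cohort(self):
        assert generate_cohort(CohortConfig(n_blood=0, n_lcl=0, seed=1)) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_blood=-1)

    def test_invalid_distribution_names_offending_field(self):
        with pytest.raises(ValueError, match="lcl_ebv_copies"):
            CohortConfig(lcl_ebv_copies=Dist("loguniform", -2.0, 500.0))

    def test_tm_supports_must_respect_cutoff(self):
        with pytest.raises(ValueError, match="blood_product_tm"):
            CohortConfig(blood_product_tm=Dist("uniform", 89.0, 90.5))

    def test_truth_invariants_enforced(self):
        with pytest.raises(ValueError):
            SampleTruth("s", "LCL", 3000.0, 100.0, 0.2, 50.0)  # LCL with T cells
        with pytest.raises(ValueError):
            SampleTruth("s", "blood", 3000.0, 0.0, 0.0, 50.0)  # blood without


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = CohortConfig(n_blood=5, n_lcl=5, seed=42)
        assert cohorts_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_different_seed_different_cohort(self):
        a = generate_cohort(CohortConfig(n_blood=3, n_lcl=3, seed=1))
        b = generate_cohort(CohortConfig(n_blood=3, n_lcl=3, seed=2))
        assert not cohorts_equal(a, b)


class TestSignalStructure:
    def test_tcrg_delta_ct_matches_copy_ratio(self, noise_free_config):
        """With the T-cell fraction fixed at 0.2, TCRgamma templates are one
        tenth of the GAPDH alleles, so delta-Ct = log2(10) at efficiency 2."""
        cfg = noise_free_config.with_overrides(
            n_blood=1, blood_t_cell_fraction=Dist("constant", 0.2))
        sample = generate_cohort(cfg)[0]
        ct_g = call_ct(sample.amplification["GAPDH"]).ct
        ct_t = call_ct(sample.amplification["TCRG"]).ct
        assert ct_t - ct_g == pytest.approx(np.log2(10.0), abs=0.1)

    def test_high_ebv_load_lowers_ct_below_gapdh(self, noise_free_config):
        cfg = noise_free_config.with_overrides(
            n_lcl=1, lcl_ebv_copies=Dist("constant", 100.0))
        sample = generate_cohort(cfg)[0]
        ct_g = call_ct(sample.amplification["GAPDH"]).ct
        ct_e = call_ct(sample.amplification["EBV"]).ct
        assert ct_e < ct_g
        assert 100.0 * ct_g / ct_e > 100.0

    def test_truth_fields_respect_tissue_structure(self, small_cohort):
        for s in small_cohort:
            t = s.truth
            if t.tissue == "LCL":
                assert 2.0 <= t.ebv_copies_per_genome <= 500.0
                assert t.t_cell_fraction == 0.0
            else:
                assert t.ebv_copies_per_genome <= 0.01
                assert 0.05 <= t.t_cell_fraction <= 0.40
            dataclasses.asdict(t)  # intact record

    def test_blood_no_amplification_paths_are_exercised(self, small_cohort_calls):
        _, panels = small_cohort_calls
        blood = [p for p in panels.panels if p.sample_id.startswith("B")]
        lcl = [p for p in panels.panels if p.sample_id.startswith("L")]
        assert sum(p.ebv_imputed for p in blood) > 0       # most blood has no EBV
        assert all(p.ct_ebv == 40.0 for p in blood if p.ebv_imputed)
        assert all(p.tcrg_imputed and p.ct_tcrg == 45.0 for p in lcl)

    def test_melt_profiles_separate_at_cutoff(self, small_cohort_calls):
        _, panels = small_cohort_calls
        for p in panels.panels:
            if p.sample_id.startswith("B"):
                assert p.tcrb_max_tm is not None and p.tcrb_max_tm > 89.5
            else:
                assert p.tcrb_max_tm is None or p.tcrb_max_tm < 89.5


class TestMethylation:
    def test_noiseless_blood_round_trips_through_the_clock(self, noise_free_config):
        cfg = noise_free_config.with_overrides(n_blood=10)
        for s in generate_cohort(cfg):
            m = s.methylation
            assert predict_age(m.elovl2_cpg5, m.klf14_cpg2, m.trim59_cpg5) == \
                pytest.approx(m.chronological_age, abs=1e-9)

    def test_inverse_model_stays_in_percentage_range(self):
        vals = mean_methylation_at_age(np.array([0.0, 50.0, 110.0]))
        assert np.all(vals >= 0.0) and np.all(vals <= 100.0)


def test_default_cohort_is_separable_downstream(small_cohort, small_cohort_calls):
    """Well-separated defaults: the classifier recovers every label and abstains
    only where generator parameters overlap (none here)."""
    calls, panels = small_cohort_calls
    assert not panels.unclassifiable
    truth = {s.truth.sample_id: s.truth.tissue for s in small_cohort}
    assert all(c.combined == truth[c.sample_id] for c in calls)


def test_overlapping_degenerate_parameters_produce_uncertain_calls():
    """When LCL EBV load is forced to the per-genome level of the GAPDH alleles,
    the EBV ratio sits in the uncertain band and (with the other two assays
    degraded) combined abstentions appear."""
    cfg = CohortConfig(
        n_blood=0, n_lcl=30, seed=9,
        lcl_ebv_copies=Dist("constant", 2.0),      # ratio ~100: uncertain band
        dimer_tm=Dist("uniform", 88.0, 89.4),
        nonspecific_tm=Dist("uniform", 88.0, 89.4),
    )
    calls, _ = classify_samples(generate_cohort(cfg))
    assert any(c.label_ebv == "uncertain" for c in calls)
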