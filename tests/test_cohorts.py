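"""Synthetic cohort generator: marginal structure and determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbmeta._errors import ConfigurationError
from comorbmeta.cohorts import (
    COMORBIDITIES,
    COPD_PROFILE,
    DIABETES_PROFILE,
    HYPERTENSION_PROFILE,
    GroundTruth,
    TrialDesign,
    expand_count_pmf,
    generate_program,
    generate_trial,
    sample_comorbidity_profile,
)
from comorbmeta.io import read_trial_table, write_trial_table

from conftest import make_count_design


class TestComorbiditySampling:
    def test_degenerate_pmf_all_mass_on_zero(self):
        flags, counts = sample_comorbidity_profile((1.0, 0.0, 0.0, 0.0), 10, seed=0)
        assert counts.sum() == 0
        assert flags.sum() == 0

    def test_diabetes_count_distribution_matches_profile(self):
        """Empirical 0/1/2/3+ proportions of a 100k draw reproduce the
        configured diabetes cohort distribution within +/-0.01."""
        pmf = (0.186, 0.313, 0.263, 0.238)
        _, counts = sample_comorbidity_profile(pmf, 100_000, seed=1)
        props = [
            np.mean(counts == 0),
            np.mean(counts == 1),
            np.mean(counts == 2),
            np.mean(counts >= 3),
        ]
        assert np.allclose(props, pmf, atol=0.01)

    def test_mean_count_within_monte_carlo_error(self):
        pmf = (0.5, 0.5, 0.0, 0.0)
        _, counts = sample_comorbidity_profile(pmf, 10_000, seed=2)
        se = 0.5 / np.sqrt(10_000)  # binomial standard error
        assert abs(counts.mean() - 0.5) < 3 * se

    def test_count_equals_flag_sum(self):
        flags, counts = sample_comorbidity_profile((0.1, 0.2, 0.3, 0.4), 5000, seed=3)
        assert np.array_equal(flags.sum(axis=1), counts)
        assert flags.shape[1] == len(COMORBIDITIES)

    def test_weighted_allocation_favours_configured_conditions(self):
        w = DIABETES_PROFILE.comorbidity_weights
        flags, _ = sample_comorbidity_profile(
            (0.186, 0.313, 0.263, 0.238), 50_000, seed=4, weights=w
        )
        marginals = flags.mean(axis=0)
        six = {COMORBIDITIES.index(c) for c in DIABETES_PROFILE.six_comorbidities}
        top6 = set(np.argsort(-marginals)[:6])
        assert top6 == six

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        st.floats(0.1, 0.9),
    )
    @settings(max_examples=25, deadline=None)
    def test_expanded_pmf_is_a_distribution(self, raw, decay):
        pmf = tuple(np.asarray(raw) / np.sum(raw))
        full = expand_count_pmf(pmf, tail_decay=decay)
        assert full.shape == (22,)
        assert np.all(full >= 0)
        assert abs(full.sum() - 1.0) < 1e-9

    @pytest.mark.parametrize(
        "pmf", [(0.5, 0.5, 0.1, 0.0), (-0.1, 0.6, 0.3, 0.2), (0.25, 0.25, 0.25)]
    )
    def test_invalid_pmf_rejected_with_named_mass(self, pmf):
        with pytest.raises(ConfigurationError, match="comorbidity_pmf"):
            sample_comorbidity_profile(pmf, 10, seed=0)


class TestTrialGeneration:
    def test_requires_ground_truth(self):
        design = TrialDesign(
            "T", "diabetes", "x", "hba1c", "continuous", "higher_worse", 4.0, 100
        )
        with pytest.raises(ConfigurationError, match="GroundTruth"):
            generate_trial(design, DIABETES_PROFILE, seed=0)

    def test_cohort_moments_match_profile(self):
        design = make_count_design("BIG", 0.0, 100_000)
        tab = generate_trial(design, DIABETES_PROFILE, seed=5)
        n = len(tab)
        assert abs(tab.age.mean() - 58.7) < 3 * 10.0 / np.sqrt(n)
        assert abs(tab.age.std() - 10.0) < 0.1
        assert abs(tab.male.mean() - 0.586) < 3 * np.sqrt(0.586 * 0.414 / n)
        assert abs((tab.comorbidity_count == 0).mean() - 0.186) < 0.01
        # 1:1 randomisation is exactly balanced
        assert abs(tab.arm.sum() - n // 2) <= 1

    def test_flag_sum_invariant_on_generated_records(self, diabetes_trial):
        flag_cols = [c for c in diabetes_trial.columns if c.startswith("com_")]
        assert np.array_equal(
            diabetes_trial[flag_cols].sum(axis=1), diabetes_trial.comorbidity_count
        )

    def test_binary_family_null_coefficients_give_even_rates(self):
        design = TrialDesign(
            "B", "diabetes", "x", "events", "binary", "higher_worse", 1.0, 40_000,
            truth=GroundTruth(beta0=0.0, sigma=1.0),
        )
        tab = generate_trial(design, DIABETES_PROFILE, seed=6)
        for arm in (0, 1):
            rate = tab.loc[tab.arm == arm, "event"].mean()
            assert abs(rate - 0.5) < 3 * 0.5 / np.sqrt(len(tab) / 2)

    def test_same_seed_is_bit_identical(self, diabetes_design):
        a = generate_trial(diabetes_design, DIABETES_PROFILE, seed=7)
        b = generate_trial(diabetes_design, DIABETES_PROFILE, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_outcome_fields_match_family(self):
        d = TrialDesign(
            "C", "diabetes", "x", "headaches", "count", "higher_worse", 1.0, 200,
            truth=GroundTruth(beta0=0.5, sigma=1.0),
        )
        tab = generate_trial(d, DIABETES_PROFILE, seed=8)
        assert "event_count" in tab.columns
        assert {"final_outcome", "baseline_outcome", "event"}.isdisjoint(tab.columns)


class TestProgramGeneration:
    def test_manifest_groups_by_comparison(self):
        # a 22-trial programme spread over 9 comparisons, as in a large
        # diabetes portfolio
        sizes = [6, 4, 3, 2, 2, 1, 1, 2, 1]
        config = []
        k = 0
        for j, sz in enumerate(sizes):
            for _ in range(sz):
                k += 1
                d = dataclasses.replace(
                    make_count_design(f"T{k:02d}", 0.0, 100), comparison=f"cmp{j}"
                )
                config.append((d, DIABETES_PROFILE))
        tables, manifest = generate_program(config, seed=9)
        assert manifest["n_trials"] == 22
        assert len(manifest["groups"]) == 9
        assert sorted(len(g["trial_ids"]) for g in manifest["groups"]) == sorted(sizes)

    def test_empty_config_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_program([], seed=0)

    def test_duplicate_trial_ids_rejected(self):
        d = make_count_design("DUP", 0.0, 100)
        with pytest.raises(ConfigurationError, match="DUP"):
            generate_program([(d, DIABETES_PROFILE), (d, DIABETES_PROFILE)], seed=0)

    def test_same_seed_bit_identical_tables(self):
        config = [
            (make_count_design("A", 0.3, 120), DIABETES_PROFILE),
            (make_count_design("B", 0.3, 120), DIABETES_PROFILE),
        ]
        t1, _ = generate_program(config, seed=10)
        t2, _ = generate_program(config, seed=10)
        for tid in t1:
            pd.testing.assert_frame_equal(t1[tid], t2[tid])

    def test_csv_round_trip_is_lossless(self, tmp_path):
        tables, _ = generate_program(
            [(make_count_design("RT", 0.3, 150), DIABETES_PROFILE)], seed=11
        )
        path = tmp_path / "RT.csv"
        write_trial_table(tables["RT"], path)
        back = read_trial_table(path)
        pd.testing.assert_frame_equal(tables["RT"], back, check_exact=True)


def test_profiles_are_valid():
    for p in (DIABETES_PROFILE, HYPERTENSION_PROFILE, COPD_PROFILE):
        assert abs(sum(p.comorbidity_pmf) - 1.0) < 1e-9
        assert len(p.six_comorbidities) == 6
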