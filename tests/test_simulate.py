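"""Synthetic-study generator: determinism, planted structure, noise ops."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import detectome as dt
from detectome.model import DetectomeError, annotations_frame


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = dt.ScenarioConfig(seed=11)
        a = dt.generate(cfg)
        b = dt.generate(cfg)
        pd.testing.assert_frame_equal(a.levels.levels, b.levels.levels)
        pd.testing.assert_frame_equal(a.p_values, b.p_values)
        assert {k: v.members for k, v in a.truth.sets.items()} == {
            k: v.members for k, v in b.truth.sets.items()
        }

    def test_different_seed_differs(self):
        a = dt.generate(dt.ScenarioConfig(seed=1))
        b = dt.generate(dt.ScenarioConfig(seed=2))
        assert not a.levels.levels.equals(b.levels.levels)


class TestMinimalScenario:
    CFG = dict(
        n_mirnas=10,
        cohorts=(("case", "plasma", 1), ("control", "plasma", 1)),
        case_exclusive_plasma=1,
        control_exclusive_plasma=0,
        universal=0,
        case_exclusive_ev=0,
        shared_case_control_ev=0,
        control_exclusive_ev=0,
        female_exclusive=0,
        male_exclusive=0,
        signature_overlap=0,
    )

    def test_hand_checkable_matrices(self):
        study = dt.generate(dt.ScenarioConfig(**self.CFG, seed=3))
        calls = study.calls()
        assert calls.calls.shape == (10, 2)
        planted = study.truth.sets["plasma_case_exclusive"].sorted_members()
        assert len(planted) == 1
        (m,) = planted
        case, ctrl = calls.sample_ids
        assert calls.calls.loc[m, case]
        assert not calls.calls.loc[m, ctrl]

    def test_pvalues_respect_call_boundary(self):
        study = dt.generate(dt.ScenarioConfig(**self.CFG, seed=3))
        p = study.p_values.to_numpy()
        calls = study.calls().calls.to_numpy()
        assert (p[calls] < 0.05).all()
        assert (p[~calls] > 0.05).all()


class TestPlantedStructure:
    def test_universal_is_exactly_the_all_sample_shared_set(
        self, default_study, default_calls
    ):
        shared = dt.group_shared_set(default_calls)
        assert shared.members == default_study.truth.sets["universal"].members

    def test_partition_covers_and_matches_truth(self, default_study, default_calls):
        part = dt.partition_mirnome(default_calls)
        assert part.total == default_study.truth.config.n_mirnas
        assert (
            part.uniformly_present.members
            == default_study.truth.sets["universal"].members
        )

    def test_housekeeping_levels_low_variance(self, default_study):
        truth = default_study.truth
        hk = truth.sets["universal"].sorted_members()
        hk_var = default_study.levels.levels.loc[hk].var(axis=1, ddof=1)
        assert (hk_var < 1.0).all()

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(DetectomeError, match="overlap"):
            dt.generate(
                dt.ScenarioConfig(case_exclusive_plasma=3, signature_overlap=5)
            )

    def test_uncoverable_signature_rejected(self):
        # 2 signature members cannot cover 11 controls
        with pytest.raises(DetectomeError, match="cover"):
            dt.generate(
                dt.ScenarioConfig(case_exclusive_plasma=2, signature_overlap=0)
            )


class TestNoise:
    def test_degrade_identity_at_zero(self, default_calls):
        out = dt.degrade(default_calls, 0.0, 0.0, seed=5)
        pd.testing.assert_frame_equal(out.calls, default_calls.calls)

    def test_degrade_total_dropout(self, default_calls):
        out = dt.degrade(default_calls, 1.0, 0.0, seed=5)
        assert not out.calls.to_numpy().any()

    def test_degrade_seeded_determinism(self, default_calls):
        a = dt.degrade(default_calls, 0.1, 0.02, seed=8)
        b = dt.degrade(default_calls, 0.1, 0.02, seed=8)
        pd.testing.assert_frame_equal(a.calls, b.calls)

    def test_degrade_flip_count_distribution(self, rng):
        calls = dt.DetectionCallMatrix(
            calls=pd.DataFrame(
                True, index=[f"m{i}" for i in range(100)], columns=[f"s{j}" for j in range(10)]
            )
        )
        out = dt.degrade(calls, 0.1, 0.0, seed=13)
        flipped = int((~out.calls.to_numpy()).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.1)
        assert lo <= flipped <= hi

    def test_case_dropout_shrinks_recovered_signature(
        self, default_study, default_calls, scopes
    ):
        """Dropout restricted to case samples can only remove signature
        members, never add them (controls untouched)."""
        planted = default_study.truth.sets["plasma_case_exclusive"].members
        degraded = dt.degrade(default_calls, 0.05, 0.0, seed=21)
        merged = default_calls.calls.copy()
        merged[scopes["plasma_cases"]] = degraded.calls[scopes["plasma_cases"]]
        noisy = dt.DetectionCallMatrix(calls=merged)
        case_shared = dt.group_shared_set(noisy, scopes["plasma_cases"])
        ctrl_shared = dt.group_shared_set(noisy, scopes["plasma_controls"])
        sig = dt.derive_signature(case_shared, ctrl_shared)
        assert sig.members <= planted

    def test_global_dropout_stays_within_planted_and_universal(
        self, default_study, default_calls, scopes
    ):
        truth = default_study.truth.sets
        noisy = dt.degrade(default_calls, 0.05, 0.0, seed=22)
        sig = dt.derive_signature(
            dt.group_shared_set(noisy, scopes["plasma_cases"]),
            dt.group_shared_set(noisy, scopes["plasma_controls"]),
        )
        assert sig.members <= (
            truth["plasma_case_exclusive"].members | truth["universal"].members
        )


class TestAnnotationsAndLevels:
    def test_cohort_shapes(self, default_study):
        ann = annotations_frame(default_study.annotations)
        counts = ann.groupby(["group", "compartment"]).size()
        assert counts[("case", "plasma")] == 12
        assert counts[("control", "plasma")] == 11
        assert counts[("case", "EV")] == 11
        assert counts[("control", "EV")] == 10

    def test_both_sexes_in_every_cell(self, default_study):
        ann = annotations_frame(default_study.annotations)
        for (_, _), grp in ann.groupby(["group", "compartment"]):
            assert set(grp["sex"]) >= {"F", "M"}

    def test_undetected_levels_near_floor(self, default_study, default_calls):
        mask = ~default_calls.calls.to_numpy()
        floor_vals = default_study.levels.levels.to_numpy()[mask]
        assert floor_vals.mean() == pytest.approx(1.2, abs=0.05)
        assert floor_vals.std() < 0.1

    def test_level_shift_gives_differential_power(self):
        """A planted case-group level shift makes the signature miRNAs
        adjusted-significant, confirming the differential stage has power
        when the signal really lives in the levels."""
        study = dt.generate(dt.ScenarioConfig(level_shift=4.0, seed=9))
        ann = annotations_frame(study.annotations)
        plasma = [s for s in ann.index if ann.loc[s, "compartment"] == "plasma"]
        levels = dt.DetectionLevelMatrix(study.levels.levels[plasma].copy())
        table = dt.moderated_t(levels, study.annotations)
        sel = dt.select_and_report(table)
        assert sel.n_adjusted_significant > 0
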