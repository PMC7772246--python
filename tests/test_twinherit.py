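"""Falconer ACE estimation: closed-form identities on correlation-controlled
samples, significance and breakdown gating, gender residualization, pair
bookkeeping and kinship distance ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abilitytraits import synthgen, twinherit


def _paired_series(mz, dz):
    """Build a value series plus pair lists from (n,2) arrays."""
    n_mz, n_dz = len(mz), len(dz)
    ids = [f"m{i}_{j}" for i in range(n_mz) for j in (0, 1)] + [
        f"d{i}_{j}" for i in range(n_dz) for j in (0, 1)
    ]
    values = pd.Series(np.concatenate([mz.ravel(), dz.ravel()]), index=ids)
    mz_pairs = [(f"m{i}_0", f"m{i}_1") for i in range(n_mz)]
    dz_pairs = [(f"d{i}_0", f"d{i}_1") for i in range(n_dz)]
    return values, mz_pairs, dz_pairs


def _bivariate(r, n, seed):
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r], [r, 1.0]])
    return rng.multivariate_normal([0, 0], cov, size=n)


class TestFalconer:
    def test_reproduces_motor_endurance_components(self):
        """rMZ = 0.65, rDZ = 0.495 imply A/C/E = 0.31/0.34/0.35."""
        values, mz, dz = _paired_series(
            _bivariate(0.65, 200_000, 1), _bivariate(0.495, 200_000, 2)
        )
        est = twinherit.falconer_ace(values, mz, dz, n_boot=0)
        assert est.A == pytest.approx(0.31, abs=0.01)
        assert est.C == pytest.approx(0.34, abs=0.01)
        assert est.E == pytest.approx(0.35, abs=0.01)
        assert est.status == "ok"
        assert est.A + est.C + est.E == pytest.approx(1.0, abs=1e-10)

    def test_equal_resemblance_means_no_genetics(self):
        values, mz, dz = _paired_series(
            _bivariate(0.5, 100_000, 3), _bivariate(0.5, 100_000, 4)
        )
        est = twinherit.falconer_ace(values, mz, dz, n_boot=0)
        assert est.A == pytest.approx(0.0, abs=0.01)
        assert est.C == pytest.approx(0.5, abs=0.01)
        assert est.E == pytest.approx(0.5, abs=0.01)

    def test_higher_dz_resemblance_is_breakdown(self):
        values, mz, dz = _paired_series(
            _bivariate(0.3, 50_000, 5), _bivariate(0.4, 50_000, 6)
        )
        est = twinherit.falconer_ace(values, mz, dz, n_boot=0)
        assert est.status == "breakdown"
        assert est.A == pytest.approx(-0.2, abs=0.02)

    def test_insignificant_regression_gates_reporting(self):
        values, mz, dz = _paired_series(
            _bivariate(0.6, 50, 7), _bivariate(0.0, 10, 8)
        )
        est = twinherit.falconer_ace(values, mz, dz, n_boot=0)
        assert est.status == "not_significant"

    def test_bootstrap_se_positive_and_finite(self):
        values, mz, dz = _paired_series(
            _bivariate(0.65, 500, 9), _bivariate(0.5, 500, 10)
        )
        est = twinherit.falconer_ace(values, mz, dz, n_boot=100, seed=0)
        assert np.isfinite([est.se_A, est.se_C, est.se_E]).all()
        assert est.se_A > 0

    def test_consistency_over_component_grid(self):
        """Mean estimate over replicates stays within 0.02 of the
        generating components across an A x C grid."""
        for A, C in [(0.2, 0.0), (0.3, 0.35), (0.5, 0.2)]:
            E = 1.0 - A - C
            estimates = []
            for rep in range(60):
                rng = np.random.default_rng([rep, int(A * 100), int(C * 100)])
                acfg = synthgen.default_ace_config(
                    A=A, C=C, E=E, n_mz_pairs=1000, n_dz_pairs=1000,
                    n_sib_pairs=0, n_half_pairs=0, n_unrelated=0,
                )
                sim = synthgen.simulate_ace_pairs(acfg, rng=rng)
                values, mz, dz = _paired_series(
                    sim["MZ"]["values"][:, :, 0], sim["DZ"]["values"][:, :, 0]
                )
                est = twinherit.falconer_ace(values, mz, dz, n_boot=0)
                estimates.append([est.A, est.C, est.E])
            mean = np.mean(estimates, axis=0)
            assert abs(mean[0] - A) < 0.02
            assert abs(mean[1] - C) < 0.02
            assert abs(mean[2] - E) < 0.02

    def test_zero_variance_trait_rejected(self):
        values, mz, dz = _paired_series(np.ones((10, 2)), np.ones((10, 2)))
        with pytest.raises(ValueError, match="zero-variance"):
            twinherit.falconer_ace(values, mz, dz, n_boot=0)


class TestGenderCorrect:
    def test_additive_shift_removed(self):
        rng = np.random.default_rng(0)
        gender = pd.Series(rng.integers(0, 2, 400))
        base = pd.Series(rng.standard_normal(400))
        shifted = base + 2.0 * gender
        resid = twinherit.gender_correct(shifted, gender)
        # residuals equal the de-shifted values up to centering
        assert np.allclose(
            resid - resid.mean(), (base - base.mean()) - (base - base.mean()).groupby(gender).transform("mean"),
            atol=1e-10,
        )

    def test_residuals_orthogonal_to_gender(self):
        rng = np.random.default_rng(1)
        gender = pd.Series(rng.integers(0, 2, 300))
        values = pd.Series(rng.standard_normal(300) + 0.7 * gender)
        resid = twinherit.gender_correct(values, gender)
        assert abs(resid.mean()) < 1e-10
        assert abs(np.corrcoef(resid, gender)[0, 1]) < 1e-10

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), delta=st.floats(-3, 3))
    def test_orthogonality_holds_for_any_shift(self, seed, delta):
        rng = np.random.default_rng(seed)
        gender = pd.Series(np.r_[np.zeros(20), np.ones(20)][rng.permutation(40)])
        values = pd.Series(rng.standard_normal(40) + delta * gender)
        resid = twinherit.gender_correct(values, gender)
        assert abs(resid.mean()) < 1e-9
        assert abs(resid @ (gender - gender.mean())) < 1e-8

    def test_single_gender_rejected(self):
        values = pd.Series(np.arange(5.0))
        with pytest.raises(ValueError, match="both genders"):
            twinherit.gender_correct(values, pd.Series(np.zeros(5)))

    def test_corrected_matches_separated_when_no_gender_effect(self):
        """With no generating gender effect, pooled gender-corrected ACE
        agrees with the gender-separated analyses within MC error."""
        rng = np.random.default_rng(2)
        acfg = synthgen.default_ace_config(
            A=0.4, C=0.2, E=0.4, n_mz_pairs=4000, n_dz_pairs=4000,
            n_sib_pairs=0, n_half_pairs=0, n_unrelated=0,
        )
        sim = synthgen.simulate_ace_pairs(acfg, rng=rng)
        values, mz, dz = _paired_series(
            sim["MZ"]["values"][:, :, 0], sim["DZ"]["values"][:, :, 0]
        )
        gender = pd.Series(rng.integers(0, 2, len(values) // 2).repeat(2),
                           index=values.index)
        corrected = twinherit.gender_correct(values, gender)
        est_all = twinherit.falconer_ace(corrected, mz, dz, n_boot=0)
        for g in (0, 1):
            mz_g = [p for p in mz if gender[p[0]] == g and gender[p[1]] == g]
            dz_g = [p for p in dz if gender[p[0]] == g and gender[p[1]] == g]
            est_g = twinherit.falconer_ace(values, mz_g, dz_g, n_boot=0)
            assert abs(est_g.A - est_all.A) < 0.1  # ~2 MC SE at these sizes


class TestPairsAndDistances:
    def _kinship(self):
        rows = []
        for i in range(74):  # 148 MZ subjects
            rows.append({"subject_a": f"S{2*i:06d}", "subject_b": f"S{2*i+1:06d}",
                         "relation": "MZ", "same_gender": True})
        return pd.DataFrame(rows)

    def test_148_mz_subjects_make_74_pairs(self):
        kin = self._kinship()
        cohort = pd.Index([f"S{i:06d}" for i in range(200)])
        pairs = twinherit.enumerate_pairs(kin, cohort, n_unrelated=10, seed=0)
        assert len(pairs["MZ"]) == 74

    def test_absent_subject_named_in_error(self):
        kin = self._kinship()
        cohort = pd.Index([f"S{i:06d}" for i in range(100)])
        with pytest.raises(ValueError, match="absent"):
            twinherit.enumerate_pairs(kin, cohort)

    def test_unknown_relation_rejected(self):
        kin = pd.DataFrame([{"subject_a": "a", "subject_b": "b",
                             "relation": "cousin", "same_gender": True}])
        with pytest.raises(ValueError, match="cousin"):
            twinherit.enumerate_pairs(kin, pd.Index(["a", "b"]))

    def test_unrelated_sample_reproducible_and_disjoint_from_related(self):
        kin = self._kinship()
        cohort = pd.Index([f"S{i:06d}" for i in range(200)])
        p1 = twinherit.enumerate_pairs(kin, cohort, n_unrelated=30, seed=5)
        p2 = twinherit.enumerate_pairs(kin, cohort, n_unrelated=30, seed=5)
        assert p1["unrelated"] == p2["unrelated"]
        related = {frozenset(p) for p in p1["MZ"]}
        assert all(frozenset(p) not in related for p in p1["unrelated"])

    def test_identical_cotwins_have_zero_distance(self):
        scores = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        prof = twinherit.kinship_distance_profile(scores, {"MZ": [("a", "b")]})
        assert prof.loc["MZ", "mean"] == 0.0

    def test_distance_scales_homogeneously(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(rng.standard_normal((10, 4)),
                              index=[f"s{i}" for i in range(10)])
        pairs = {"unrelated": [("s0", "s1"), ("s2", "s3")]}
        d1 = twinherit.kinship_distance_profile(scores, pairs)
        d3 = twinherit.kinship_distance_profile(scores * 3.0, pairs)
        assert d3.loc["unrelated", "mean"] == pytest.approx(
            3 * d1.loc["unrelated", "mean"]
        )

    def test_distance_ordering_follows_genetic_overlap(self):
        """A = 0.6 cohorts: mean distance MZ < DZ ~ fullsib < halfsib <
        unrelated (DZ/fullsib tie allowed) over seeds."""
        violations = 0
        for seed in range(10):
            acfg = synthgen.default_ace_config(
                A=0.6, C=0.1, E=0.3, n_mz_pairs=500, n_dz_pairs=500,
                n_sib_pairs=500, n_half_pairs=500, n_unrelated=1000, seed=seed,
            )
            sim = synthgen.simulate_ace_pairs(acfg, n_traits=4)
            means = {}
            for rel in synthgen.RELATIONS:
                v = sim[rel]["values"]
                means[rel] = np.sqrt(((v[:, 0, :] - v[:, 1, :]) ** 2).sum(axis=1)).mean()
            ok = (
                means["MZ"] < means["DZ"]
                and means["DZ"] < means["halfsib"]
                and means["fullsib"] < means["halfsib"]
                and means["halfsib"] < means["unrelated"]
            )
            violations += not ok
        assert violations == 0


def test_ace_table_layout():
    est = twinherit.ACEEstimate(
        A=0.31, C=0.34, E=0.35, r_mz=0.65, r_dz=0.495, p_mz=1e-5, p_dz=1e-3,
        se_A=0.05, se_C=0.04, se_E=0.03, status="ok",
    )
    table = twinherit.ace_table({"Motor-endurance": est})
    assert table.loc["Motor-endurance", "A"] == 0.31
    assert set(table.columns) >= {"A", "se_A", "C", "E", "p_mz", "p_dz", "status"}
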