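"""PET quantification: Logan DVR, positivity/chronicity, onset, tau cut-offs."""

import numpy as np
import pandas as pd
import pytest

import cogstage as cs
from cogstage.pet import (
    LoganSettings,
    OnsetEstimationError,
    PETRecord,
    TrajectoryModel,
    apply_tau_positivity,
    biomarker_group_comparison,
    estimate_onset_age,
    logan_dvr,
    pib_status_and_chronicity,
    tau_thresholds,
)
from cogstage.simulate import TACPair, generate_tac_pair


class TestLoganDVR:
    def test_identical_curves_give_unit_dvr(self):
        tac = generate_tac_pair(1.0, mode="proportional")
        assert logan_dvr(tac) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("dvr", [0.8, 1.2, 2.0, 3.5])
    def test_proportional_curves_give_exact_slope(self, dvr):
        # analytic: the Logan ordinate is invariant to target scaling and the
        # abscissa scales by 1/dvr, so the points are exactly collinear
        tac = generate_tac_pair(dvr, mode="proportional")
        assert logan_dvr(tac) == pytest.approx(dvr, abs=1e-9)

    @pytest.mark.parametrize("dvr", [1.2, 1.5, 2.2])
    def test_compartmental_simulation_recovered_within_two_percent(self, dvr):
        tac = generate_tac_pair(dvr, mode="compartmental")
        assert logan_dvr(tac) == pytest.approx(dvr, rel=0.02)

    def test_invariance_to_common_rescaling_and_units(self):
        tac = generate_tac_pair(1.6)
        d0 = logan_dvr(tac)
        scaled = TACPair(tac.times, 7.3 * tac.target_activity, 7.3 * tac.reference_activity)
        assert logan_dvr(scaled) == pytest.approx(d0, abs=1e-12)
        seconds = TACPair(tac.times * 60.0, tac.target_activity, tac.reference_activity)
        s = LoganSettings(k2_prime=0.149 / 60.0, t_star=35.0 * 60.0)
        assert logan_dvr(seconds, s) == pytest.approx(d0, rel=1e-9)

    def test_window_errors(self):
        tac = generate_tac_pair(1.5)
        with pytest.raises(ValueError, match="t_star"):
            logan_dvr(tac, LoganSettings(t_star=100.0))
        with pytest.raises(ValueError, match="3 frames"):
            logan_dvr(tac, LoganSettings(t_star=62.0))


class TestPositivityAndChronicity:
    def test_threshold_is_inclusive_at_1p2(self):
        rec = PETRecord("P1", 70.0, 1.19)
        assert not pib_status_and_chronicity(rec, 70.0, None).pib_positive
        rec = PETRecord("P1", 70.0, 1.20)
        assert pib_status_and_chronicity(rec, 70.0, None).pib_positive

    @pytest.mark.parametrize("age, onset, expect", [(70.0, 65.0, 5.0), (60.0, 68.0, -8.0)])
    def test_signed_chronicity(self, age, onset, expect):
        rec = pib_status_and_chronicity(PETRecord("P1", age, 1.3), age, onset)
        assert rec.chronicity == pytest.approx(expect)

    def test_chronicity_antisymmetry(self):
        a, b = 63.0, 71.5
        r1 = pib_status_and_chronicity(PETRecord("P", a, 1.3), a, b).chronicity
        r2 = pib_status_and_chronicity(PETRecord("P", b, 1.3), b, a).chronicity
        assert r1 + r2 == pytest.approx(0.0)

    def test_unknown_onset_leaves_chronicity_missing(self):
        rec = pib_status_and_chronicity(PETRecord("P", 70.0, 1.3), 70.0, None)
        assert np.isnan(rec.chronicity)


class TestOnsetEstimation:
    def test_observation_at_threshold_is_fixed_point(self):
        m = TrajectoryModel()
        assert estimate_onset_age(m.threshold, 70.0, m) == pytest.approx(70.0, abs=1e-5)

    def test_forward_simulation_round_trip(self):
        # noise-free accumulators: recover onset within 0.5 y across 55-80
        m = TrajectoryModel()
        from cogstage.simulate import _default_amyloid_model, onset_to_midpoint, _sigmoid_dvr

        am = _default_amyloid_model()
        for onset in np.arange(55.0, 80.5, 2.5):
            mid = onset_to_midpoint(onset, am)
            scan_age = onset + 4.0
            dvr = _sigmoid_dvr(scan_age, am["floor"], am["ceiling"], am["rate"], mid)
            assert estimate_onset_age(float(dvr), scan_age, m) == pytest.approx(onset, abs=0.5)

    def test_out_of_range_dvr_rejected(self):
        m = TrajectoryModel()
        for bad in (m.floor, m.ceiling, 0.5, 3.0):
            with pytest.raises(OnsetEstimationError):
                estimate_onset_age(bad, 70.0, m)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryModel(floor=1.3)  # threshold below floor


class TestTauThresholds:
    def test_mean_plus_two_sd(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(1.0, 0.06, 400)
        df = pd.DataFrame({"suvr_hippocampus": vals, "suvr_entorhinal": vals + 0.1})
        thr = tau_thresholds(df, np.ones(400, bool))
        assert thr["hippocampus"] == pytest.approx(vals.mean() + 2 * vals.std(ddof=1))
        assert thr["entorhinal"] == pytest.approx(vals.mean() + 0.1 + 2 * vals.std(ddof=1))

    def test_zero_variance_makes_no_one_positive(self):
        df = pd.DataFrame({"suvr_hippocampus": [1.1] * 20, "suvr_entorhinal": [1.0] * 20})
        thr = tau_thresholds(df, np.ones(20, bool))
        flags = apply_tau_positivity(df, thr)
        assert thr["hippocampus"] == pytest.approx(1.1)
        assert not flags.any().any()  # strict >

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"suvr_hippocampus": rng.normal(1.0, 0.05, 100)})
        neg = np.ones(100, bool)
        t0 = tau_thresholds(df, neg, regions=("hippocampus",))["hippocampus"]
        t1 = tau_thresholds(df + 0.37, neg, regions=("hippocampus",))["hippocampus"]
        assert t1 == pytest.approx(t0 + 0.37)

    def test_too_few_negative_scans_omits_region(self):
        df = pd.DataFrame({"suvr_hippocampus": [1.0] * 5})
        assert tau_thresholds(df, np.ones(5, bool)) == {}


@pytest.fixture(scope="module")
def pet_with_status():
    rng = np.random.default_rng(2)
    n = 200
    rows = []
    for grp, dvr_mu, ent_mu in [("CU_S", 1.05, 1.02), ("CU_D", 1.12, 1.06), ("MCI", 1.45, 1.60)]:
        dvr = rng.normal(dvr_mu, 0.12, n)
        rows.append(pd.DataFrame(dict(
            participant_id=[f"{grp}{i}" for i in range(n)],
            global_pib_dvr=dvr,
            pib_positive=dvr >= 1.2,
            suvr_entorhinal=rng.normal(ent_mu, 0.15, n),
            status=grp,
        )))
    return pd.concat(rows, ignore_index=True)


class TestBiomarkerGroupComparison:
    def test_injected_shift_yields_large_effect(self, pet_with_status):
        out = biomarker_group_comparison(
            pet_with_status, pet_with_status["status"],
            quantities=("global_pib_dvr", "suvr_entorhinal"), flags=("pib_positive",),
        )
        row = out[(out["analysis"] == "global_pib_dvr") & (out["groups"] == "CU_S vs MCI")]
        assert abs(row.iloc[0]["effect_size"]) > 0.5
        omni = out[(out["analysis"] == "pib_positive") & (out["groups"] == "omnibus")]
        assert omni.iloc[0]["p"] < 0.001

    def test_null_groups_rarely_reject(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 200
        for _ in range(reps):
            df = pd.DataFrame(dict(global_pib_dvr=rng.normal(1.1, 0.1, 90)))
            status = np.repeat(["CU_S", "CU_D", "MCI"], 30)
            out = biomarker_group_comparison(df, status, quantities=("global_pib_dvr",), flags=())
            if out.iloc[0]["p"] < 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) < 3.5 * np.sqrt(0.05 * 0.95 / reps)

    def test_empty_group_skipped(self):
        df = pd.DataFrame(dict(global_pib_dvr=[1.0, 1.1, np.nan, np.nan]))
        status = np.array(["CU_S", "CU_S", "MCI", "MCI"])
        out = biomarker_group_comparison(df, status, quantities=("global_pib_dvr",), flags=())
        assert out.empty  # only one non-empty group -> comparison skipped


def test_generated_cohort_tau_ordering(small_pet):
    # MCI/dementia participants carry more tau than stable participants
    thr = tau_thresholds(small_pet, (small_pet["global_pib_dvr"] < 1.2).to_numpy())
    flags = apply_tau_positivity(small_pet, thr)
    state = small_pet["latent_state_last"]
    frac_mci = flags.loc[state.isin(["MCI", "DEMENTIA"]), "tau_positive_entorhinal"].mean()
    frac_cus = flags.loc[state == "CU_S", "tau_positive_entorhinal"].mean()
    assert frac_mci > frac_cus
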