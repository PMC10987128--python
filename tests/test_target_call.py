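import numpy as np
import pytest

from meltshift import (
    DEFAULT_GRADIENT,
    MeltProfile,
    SyntheticConfig,
    apply_fc_cutoff,
    apply_shift_criteria,
    call_targets,
    compute_shift_record,
    normalize_profile,
    simulate_experiment,
)
from meltshift.melt_fit import MeltingCurveFit, SigmoidParams
from meltshift.target_call import ShiftRecord

from conftest import make_profile


def _fit(tm, slope=-0.25, converged=True):
    params = SigmoidParams(3025.0, 55.0, 0.0)
    return MeltingCurveFit(params, tm if converged else None,
                           slope if converged else None, 0.99, 10, converged)


def _curves(tm_veh=(55.0, 54.5), tm_drug=(51.8, 51.7), slope=-0.25):
    fits = {
        ("vehicle", 1): _fit(tm_veh[0], slope),
        ("vehicle", 2): _fit(tm_veh[1], slope),
        ("drug", 1): _fit(tm_drug[0], slope),
        ("drug", 2): _fit(tm_drug[1], slope),
    }
    profiles = {
        key: make_profile(3025.0, 55.0, 0.0, protein_id="P1",
                          condition=key[0], replicate=key[1])
        for key in fits
    }
    return fits, profiles


class TestComputeShiftRecord:
    def test_dtm_triplet_and_flags(self, gradient):
        fits, profiles = _curves()
        rec = compute_shift_record(fits, profiles, gradient)
        assert rec.dtm_1 == pytest.approx(-3.2)
        assert rec.dtm_2 == pytest.approx(-2.8)
        assert rec.dtm_ctrl == pytest.approx(0.5)
        assert rec.sign_concordant and rec.exceeds_control and rec.slope_pass

    def test_identical_conditions_give_null_record(self, gradient):
        fits, profiles = _curves(tm_veh=(55.0, 55.0), tm_drug=(55.0, 55.0))
        rec = compute_shift_record(fits, profiles, gradient)
        assert rec.dtm_1 == rec.dtm_2 == rec.dtm_ctrl == 0.0
        assert max(abs(v) for v in rec.fc_profile) < 1e-9

    def test_abundance_halving_gives_unit_fc_peak(self, gradient):
        fits, profiles = _curves()
        flat = (1.0,) * 10
        profiles = {
            ("vehicle", 1): MeltProfile("P1", "vehicle", 1, (1.0, 1.0, 1.0, 0.50) + flat[4:]),
            ("vehicle", 2): MeltProfile("P1", "vehicle", 2, (1.0, 1.0, 1.0, 0.50) + flat[4:]),
            ("drug", 1): MeltProfile("P1", "drug", 1, (1.0, 1.0, 1.0, 0.25) + flat[4:]),
            ("drug", 2): MeltProfile("P1", "drug", 2, (1.0, 1.0, 1.0, 0.25) + flat[4:]),
        }
        rec = compute_shift_record(fits, profiles, gradient)
        assert rec.fc_profile[3] == pytest.approx(1.0)
        assert rec.max_fc_score == pytest.approx(1.0)

    def test_any_undefined_tm_marks_unfittable(self, gradient):
        fits, profiles = _curves()
        fits[("drug", 2)] = _fit(None, converged=False)
        rec = compute_shift_record(fits, profiles, gradient)
        assert rec.unfittable
        assert rec.dtm_1 is None and rec.sign_concordant is None

    def test_min_pairing_takes_smaller_magnitude_shift(self, gradient):
        fits, profiles = _curves(tm_veh=(55.0, 52.0), tm_drug=(51.8, 51.7))
        rec = compute_shift_record(fits, profiles, gradient, pairing="min")
        assert rec.dtm_1 == pytest.approx(-0.2)  # 51.8 vs vehicle rep2 (52.0)


class TestShiftCriteria:
    def _record(self, dtm_1, dtm_2, dtm_ctrl, slope_pass=True):
        return ShiftRecord(
            protein_id="P", dtm_1=dtm_1, dtm_2=dtm_2, dtm_ctrl=dtm_ctrl,
            sign_concordant=dtm_1 * dtm_2 > 0,
            exceeds_control=min(abs(dtm_1), abs(dtm_2)) > abs(dtm_ctrl),
            slope_pass=slope_pass, fc_profile=(0.0,) * 10, max_fc_score=0.0,
        )

    def test_all_criteria_met(self):
        ok, reason = apply_shift_criteria(self._record(-3.2, -2.8, 0.5))
        assert ok and reason == "none"

    def test_opposite_shift_signs_rejected(self):
        # mixed stabilization/destabilization trends across replicates
        ok, reason = apply_shift_criteria(self._record(-3.2, 1.5, 0.5))
        assert not ok and reason == "sign_discordant"

    def test_shift_within_control_noise_rejected(self):
        ok, reason = apply_shift_criteria(self._record(-3.2, -0.4, 0.5))
        assert not ok and reason == "below_control"

    def test_flat_slope_checked_first(self):
        ok, reason = apply_shift_criteria(self._record(-3.2, 1.5, 0.5, slope_pass=False))
        assert not ok and reason == "flat_slope"

    def test_matches_brute_force_truth_table(self, rng):
        """Criteria agree with direct enumeration on random ΔTm triplets,
        including sign-zero and boundary-magnitude cases."""
        d1 = rng.uniform(-5, 5, 10_000)
        d2 = rng.uniform(-5, 5, 10_000)
        dc = rng.uniform(-2, 2, 10_000)
        # inject exact edge cases
        d1[:3], d2[:3], dc[:3] = [0.0, 2.0, -2.0], [1.0, 0.0, -2.0], [0.5, 0.5, 2.0]
        for x, y, c in zip(d1, d2, dc):
            expected = (np.sign(x) == np.sign(y) != 0) and (abs(x) > abs(c)) and (abs(y) > abs(c))
            ok, _ = apply_shift_criteria(self._record(float(x), float(y), float(c)))
            assert ok == expected


class TestFcCutoff:
    @pytest.mark.parametrize(
        "score,expected",
        [(1.0, True), (-1.0, True), (0.4, False), (2.5, True)],
    )
    def test_symmetric_inclusive_cutoff(self, score, expected):
        rec = ShiftRecord("P", -3.0, -3.0, 0.1, True, True, True,
                          (score,) * 10, score)
        assert apply_fc_cutoff(rec) is expected


class TestCallTargets:
    def test_recovers_exactly_the_spiked_targets(self, gradient):
        cfg = SyntheticConfig(n_proteins=100, n_targets_destab=3, shift_mean=5.0,
                              noise_sd=0.01, seed=7)
        raw, truth = simulate_experiment(cfg, gradient)
        profiles = [normalize_profile(r) for r in raw]
        result = call_targets(profiles, gradient)
        called = {c.protein_id for c in result if c.classification != "excluded"}
        assert called == set(truth.target_ids)
        for c in result:
            if c.protein_id in called:
                assert c.classification == "candidate_destabilized"
                assert c.shift.dtm_1 < 0 and c.shift.dtm_2 < 0

    def test_every_protein_classified_exactly_once(self, gradient):
        cfg = SyntheticConfig(n_proteins=40, n_targets_destab=2, n_targets_stab=2,
                              noise_sd=0.03, seed=3)
        raw, _ = simulate_experiment(cfg, gradient)
        profiles = [normalize_profile(r) for r in raw]
        result = call_targets(profiles, gradient)
        assert len(result) == 40
        assert len({c.protein_id for c in result}) == 40
        for c in result:
            excluded = c.classification == "excluded"
            assert excluded == (c.exclusion_reason != "none")
        reasons = sum(
            v for k, v in result.summary.items() if k.startswith("n_excluded_")
        )
        assert reasons + result.summary["n_candidates"] == 40

    def test_empty_dataset_gives_empty_result(self, gradient):
        result = call_targets([], gradient)
        assert list(result) == [] and result.summary["n_proteins"] == 0

    def test_protein_with_missing_curve_is_unfittable(self, gradient):
        profiles = [
            make_profile(3025.0, 55.0, 0.0, protein_id="P1", condition=c, replicate=r)
            for c, r in [("vehicle", 1), ("vehicle", 2), ("drug", 1)]
        ]
        (call,) = call_targets(profiles, gradient)
        assert call.exclusion_reason == "unfittable"

    def test_candidates_ordered_by_fc_magnitude(self, gradient):
        cfg = SyntheticConfig(n_proteins=60, n_targets_destab=4, shift_mean=5.0,
                              noise_sd=0.01, seed=21)
        raw, _ = simulate_experiment(cfg, gradient)
        profiles = [normalize_profile(r) for r in raw]
        result = call_targets(profiles, gradient)
        scores = [abs(c.shift.max_fc_score) for c in result
                  if c.classification != "excluded"]
        assert scores == sorted(scores, reverse=True)
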