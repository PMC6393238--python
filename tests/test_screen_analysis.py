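"""Screen statistics: Z', normalization, hit calling, 4PL, retest."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from editscreen.plate_model import Role
from editscreen.reporter_model import Action, CompoundEffect, ReporterParams
from editscreen.screen_analysis import (
    DoseResponseFit,
    call_hits,
    ffl_inhibition,
    fit_4pl,
    hit_rate,
    pct_inhibition,
    qc_plate,
    retest,
    well_ratio,
    zprime,
)
from editscreen.synth_screen import (
    LibrarySpec,
    NoiseConfig,
    simulate_dose_plates,
    simulate_screen,
)


class TestWellRatio:
    def test_basic_ratio(self):
        assert well_ratio(150.0, 100.0) == pytest.approx(1.5)
        assert well_ratio(0.0, 100.0) == 0.0

    def test_dead_well_is_an_error_not_a_silent_zero(self):
        with pytest.raises(ValueError, match="dead well"):
            well_ratio(100.0, 0.0)
        with pytest.raises(ValueError):
            well_ratio(None, 100.0)


class TestZPrime:
    def test_perfect_separation_zero_sd(self):
        assert zprime([1.0] * 8, [0.0] * 8) == 1.0

    def test_constructed_moments_give_0_7(self):
        # two-point groups with exact mean 1.0/0.0 and sample SD 0.05
        d = 0.05 / math.sqrt(2)
        neg = [1.0 + d, 1.0 - d]
        pos = [0.0 + d, 0.0 - d]
        assert zprime(neg, pos) == pytest.approx(0.7, abs=1e-12)

    def test_equal_means_undefined(self):
        with pytest.raises(ValueError, match="equal"):
            zprime([1.0, 1.0], [1.0, 1.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            zprime([1.0], [0.0, 0.1])

    @given(
        shift=st.floats(-5, 5),
        scale=st.floats(0.1, 10),
        seed=st.integers(0, 100),
    )
    def test_affine_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        neg = rng.normal(1.0, 0.05, 16)
        pos = rng.normal(0.1, 0.03, 16)
        z0 = zprime(neg, pos)
        z1 = zprime(neg * scale + shift, pos * scale + shift)
        assert z1 == pytest.approx(z0, rel=1e-9, abs=1e-9)


class TestNormalization:
    def test_fixed_points_and_midpoint(self):
        assert pct_inhibition(1.0, mu_n=1.0, mu_p=0.1) == 0.0
        assert pct_inhibition(0.1, mu_n=1.0, mu_p=0.1) == pytest.approx(100.0)
        assert pct_inhibition(0.55, mu_n=1.0, mu_p=0.1) == pytest.approx(50.0)

    def test_activation_is_negative(self):
        assert pct_inhibition(1.9, mu_n=1.0, mu_p=0.1) == pytest.approx(-100.0)

    def test_equal_control_means_error(self):
        with pytest.raises(ValueError):
            pct_inhibition(0.5, 1.0, 1.0)

    @pytest.mark.parametrize(
        "ffl,expected", [(100.0, 0.0), (50.0, 50.0), (120.0, -20.0)]
    )
    def test_ffl_inhibition(self, ffl, expected):
        assert ffl_inhibition(ffl, 100.0) == pytest.approx(expected)

    def test_ffl_inhibition_needs_positive_reference(self):
        with pytest.raises(ValueError):
            ffl_inhibition(50.0, 0.0)

    @given(scale=st.floats(0.1, 10))
    def test_pct_inhibition_invariant_under_common_rescaling(self, scale):
        v, mu_n, mu_p = 0.4, 1.0, 0.1
        assert pct_inhibition(v * scale, mu_n * scale, mu_p * scale) == pytest.approx(
            pct_inhibition(v, mu_n, mu_p), rel=1e-9
        )


class TestQcPlate:
    def test_noiseless_plate_is_perfect(self, small_inactive_screen):
        plates, _ = small_inactive_screen
        qc = qc_plate(plates[0])
        assert qc.zprime == pytest.approx(1.0)
        assert qc.passed
        assert qc.n_neg == qc.n_pos == 16

    def test_degenerate_controls_fail_qc_without_raising(self, small_inactive_screen):
        plates, _ = small_inactive_screen
        plate = plates[0]
        # force pos controls equal to neg controls
        for w in plate.wells_with_role(Role.POS_CONTROL):
            neg = plate.wells_with_role(Role.NEG_CONTROL)[0]
            w.ffl, w.nluc = neg.ffl, neg.nluc
        qc = qc_plate(plate)
        assert not qc.passed
        assert qc.error is not None
        assert math.isnan(qc.zprime)


def _hand_plate(inhibitions):
    """A noiseless plate carrying 4 crafted compounds (see call_hits test)."""
    params = ReporterParams()
    lib = LibrarySpec(n_compounds=4, frac_by_action={Action.INACTIVE: 1.0})
    plates, _ = simulate_screen(params, lib, NoiseConfig(cv_ffl=0, cv_nluc=0, seed=0))
    return plates[0]


class TestCallHits:
    def test_hand_constructed_four_compound_table(self):
        plate = _hand_plate(None)
        qc = qc_plate(plate)
        compounds = [w for w in plate.wells_with_role(Role.COMPOUND)]
        # craft ratios at 80%, 65%, 90%-with-toxic-FFL, and -60% inhibition
        targets = [(80.0, False), (65.0, False), (90.0, True), (-60.0, False)]
        for w, (inhib, toxic) in zip(compounds, targets):
            ratio = qc.mu_n - inhib / 100.0 * (qc.mu_n - qc.mu_p)
            ffl = qc.mu_n_ffl * (0.5 if toxic else 1.0)  # 50% FFL loss > 40% filter
            w.ffl, w.nluc = ffl, ratio * ffl
        result = call_hits([plate])
        first, second, third, fourth = [w.compound_id for w in compounds]
        assert result.hits == [first]
        assert result.activators == [fourth]
        assert result.toxic == [third]

    def test_all_wells_at_negative_control_level_yields_zero_hits(
        self, small_inactive_screen
    ):
        plates, _ = small_inactive_screen
        result = call_hits(plates)
        assert result.hits == []
        assert result.activators == []
        assert (result.results["pct_inhibition"].abs() < 1e-9).all()

    def test_single_planted_saturating_inhibitor_is_the_only_hit(self, default_params):
        lib = LibrarySpec(n_compounds=352, frac_by_action={Action.INACTIVE: 1.0})
        plates, truth = simulate_screen(
            default_params, lib, NoiseConfig(cv_ffl=0, cv_nluc=0, seed=0)
        )
        plate = plates[0]
        target = plate.wells_with_role(Role.COMPOUND)[100]
        from editscreen.reporter_model import expected_signals

        eff = CompoundEffect(Action.EDITING_INHIBITOR, ic50=0.05, max_effect=1.0)
        target.ffl, target.nluc = expected_signals(default_params, eff, 10.0)
        result = call_hits([plate])
        assert result.hits == [target.compound_id]

    def test_hit_flag_boundary_inclusive_tox_strict(self):
        plate = _hand_plate(None)
        qc = qc_plate(plate)
        w_hit, w_tox = plate.wells_with_role(Role.COMPOUND)[:2]
        # exactly at the 70% hit threshold -> hit (>=)
        ratio = qc.mu_n - 0.70 * (qc.mu_n - qc.mu_p)
        w_hit.ffl, w_hit.nluc = qc.mu_n_ffl, ratio * qc.mu_n_ffl
        # exactly 40% FFL inhibition -> NOT filtered (strict >)
        ratio2 = qc.mu_n - 0.90 * (qc.mu_n - qc.mu_p)
        w_tox.ffl = qc.mu_n_ffl * 0.6
        w_tox.nluc = ratio2 * w_tox.ffl
        result = call_hits([plate])
        assert w_hit.compound_id in result.hits
        assert w_tox.compound_id in result.hits
        assert result.toxic == []

    def test_duplicate_compound_across_plates_is_error(self, default_params, quiet_noise):
        lib = LibrarySpec(n_compounds=352, frac_by_action={Action.INACTIVE: 1.0})
        plates_a, _ = simulate_screen(default_params, lib, quiet_noise)
        plates_b, _ = simulate_screen(default_params, lib, quiet_noise)
        plates_b[0].plate_id = "SYN-002"
        with pytest.raises(ValueError, match="appears on plates"):
            call_hits([plates_a[0], plates_b[0]])

    def test_order_and_permutation_invariance(self, default_params):
        lib = LibrarySpec(n_compounds=704)
        plates, _ = simulate_screen(
            default_params, lib, NoiseConfig(cv_ffl=0.05, cv_nluc=0.05, seed=9)
        )
        a = call_hits(plates).results
        b = call_hits(list(reversed(plates))).results
        pd.testing.assert_frame_equal(a, b)
        # permute wells within a plate (dict insertion order)
        import random

        rng = random.Random(0)
        for p in plates:
            items = list(p.wells.items())
            rng.shuffle(items)
            p.wells = dict(items)
        c = call_hits(plates).results
        pd.testing.assert_frame_equal(a, c)


class TestHitRate:
    def test_printed_campaign_numbers(self):
        assert hit_rate(300, 33000) == 0.9

    def test_extremes(self):
        assert hit_rate(0, 100) == 0.0
        assert hit_rate(100, 100) == 100.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hit_rate(1, 0)
        with pytest.raises(ValueError):
            hit_rate(5, 4)


def _4pl_curve(doses, bottom, top, ic50, hill):
    d = np.asarray(doses, dtype=float)
    return bottom + (top - bottom) / (1 + (ic50 / d) ** hill)


class TestFit4PL:
    def test_noiseless_self_consistency(self):
        doses = np.logspace(-3, 1, 8)
        resp = _4pl_curve(doses, 0.0, 100.0, 0.08, 1.0)
        fit = fit_4pl(doses, resp)
        assert fit.converged
        assert fit.ic50 == pytest.approx(0.08, rel=1e-4)
        assert fit.hill == pytest.approx(1.0, rel=1e-3)

    def test_flat_responses_do_not_converge(self):
        fit = fit_4pl([0.1, 1, 10, 100], [50.0, 50.0, 50.0, 50.0])
        assert not fit.converged
        assert math.isnan(fit.ic50)

    def test_constrained_two_parameter_variant(self):
        doses = [2.5, 5.0, 10.0]
        resp = _4pl_curve(doses, 0.0, 100.0, 1.0, 1.0)
        fit = fit_4pl(doses, resp, constrained=True)
        assert fit.converged
        assert (fit.bottom, fit.top) == (0.0, 100.0)
        assert fit.ic50 == pytest.approx(1.0, rel=1e-3)

    def test_noisy_recovery_median_within_25_pct(self):
        doses = np.logspace(-3, 1, 8)
        truth = 0.08
        clean = _4pl_curve(doses, 0.0, 100.0, truth, 1.0)
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = clean * rng.lognormal(0, 0.05, size=clean.size)
            fit = fit_4pl(doses, noisy)
            assert fit.converged
            estimates.append(fit.ic50)
        assert abs(np.median(estimates) - truth) / truth < 0.25

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_4pl([1, 2, 3], [1, 2, 3])  # too few for 4 parameters
        with pytest.raises(ValueError):
            fit_4pl([0, 1, 2, 3], [1, 2, 3, 4])  # non-positive dose


class TestRetest:
    def _planted_screen(self, cv, seed):
        params = ReporterParams()
        effects = {
            "TRUE-INHIB": CompoundEffect(Action.EDITING_INHIBITOR, ic50=0.2, max_effect=1.0),
            "DUD": CompoundEffect(Action.INACTIVE),
        }
        tables = simulate_dose_plates(
            effects, params, NoiseConfig(cv_ffl=cv, cv_nluc=cv, seed=seed)
        )
        return tables

    def test_true_inhibitor_confirms_noiseless(self):
        tables = self._planted_screen(cv=0.0, seed=0)
        out = retest(["TRUE-INHIB"], tables).set_index("compound_id")
        assert bool(out.loc["TRUE-INHIB", "confirmed"])
        inhibs = [out.loc["TRUE-INHIB", f"inhib_{d:g}"] for d in (2.5, 5, 10)]
        assert all(b >= a for a, b in zip(inhibs, inhibs[1:]))

    def test_inactive_compound_rarely_confirms(self):
        confirmed = 0
        for seed in range(30):
            tables = self._planted_screen(cv=0.05, seed=seed)
            out = retest(["DUD"], tables).set_index("compound_id")
            confirmed += bool(out.loc["DUD", "confirmed"])
        assert confirmed == 0  # a noise hit should not survive 3-dose retest

    def test_missing_dose_marks_untestable(self):
        tables = self._planted_screen(cv=0.0, seed=0)
        # drop the compound from the top-dose plate by renaming it
        for plate in tables[10.0]:
            for w in plate.wells_with_role(Role.COMPOUND):
                if w.compound_id == "TRUE-INHIB":
                    w.compound_id = "SOMETHING-ELSE"
        out = retest(["TRUE-INHIB"], tables).set_index("compound_id")
        assert bool(out.loc["TRUE-INHIB", "untestable"])
        assert not bool(out.loc["TRUE-INHIB", "confirmed"])
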