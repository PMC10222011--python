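"""Generator behavior: closed-form expectations, noise model, study layout."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import pfmetallome as pm
from pfmetallome.instrument import (
    DEFAULT_MATRIX_COMPONENTS,
    INTERNAL_STANDARDS,
    MODES,
    _PANEL_SENSITIVITY,
)


def clean_channel(baseline=0.0, s=2000.0):
    return pm.IsotopeChannel(
        element_symbol="Cd", isotope_mass=111, sensitivity_nogas=s,
        sensitivity_he=s / 2, baseline_cps=baseline,
    )


def fe_channel():
    return next(ch for ch in pm.default_panel() if ch.element_symbol == "Fe")


class TestExpectedIntensity:
    def test_zero_concentration_zero_baseline_gives_zero(self):
        ch = clean_channel(baseline=0.0)
        assert pm.expected_intensity(ch, 0.0, "no-gas", None, 1.0) == 0.0

    def test_linear_in_concentration(self):
        ch = clean_channel(baseline=7.0)
        lo = pm.expected_intensity(ch, 10.0, "no-gas", None, 1.0) - 7.0
        hi = pm.expected_intensity(ch, 20.0, "no-gas", None, 1.0) - 7.0
        assert hi == pytest.approx(2 * lo, rel=1e-12)

    def test_dilution_divides_solution_concentration(self, flat_matrix):
        ch = clean_channel(baseline=0.0)
        neat = pm.expected_intensity(ch, 40.0, "no-gas", flat_matrix, 1.0)
        diluted = pm.expected_intensity(ch, 40.0, "no-gas", flat_matrix, 4.0)
        assert neat == pytest.approx(4 * diluted, rel=1e-12)

    def test_unknown_mode_and_negative_conc_raise(self):
        ch = clean_channel()
        with pytest.raises(ValueError):
            pm.expected_intensity(ch, 1.0, "H2", None, 1.0)
        with pytest.raises(ValueError):
            pm.expected_intensity(ch, -1.0, "He", None, 1.0)

    def test_interference_requires_matrix_and_standard_load(self, flat_matrix):
        """Matrix polyatomics form only when matrix and spike acid load co-occur."""
        ch = fe_channel()
        base = pm.expected_intensity(ch, 0.0, "no-gas", None, 1.0)
        unspiked = pm.expected_intensity(ch, 0.0, "no-gas", flat_matrix, 4.0)
        spiked = pm.expected_intensity(ch, 0.0, "no-gas", flat_matrix, 4.0, standard_load=50.0)
        assert unspiked == pytest.approx(base)  # plasma background only
        assert spiked > unspiked * 100


class TestInterferenceClosedForm:
    """Spike recovery evaluated on noiseless expectations, per acquisition mode."""

    @staticmethod
    def _recovery(ch, mode, matrix, spike=100.0, df=4.0):
        spiked = pm.expected_intensity(ch, spike, mode, matrix, df, standard_load=spike)
        unspiked = pm.expected_intensity(ch, 0.0, mode, matrix, df)
        std = pm.expected_intensity(ch, spike / df, mode, None, 1.0)
        blank = pm.expected_intensity(ch, 0.0, mode, None, 1.0)
        return 100.0 * (spiked - unspiked) / (std - blank)

    def test_fe_no_gas_recovery_near_6000_pct(self):
        matrix = pm.default_matrix()
        r = self._recovery(fe_channel(), "no-gas", matrix)
        assert 5000 < r < 7000

    def test_fe_he_recovery_within_tolerance(self):
        matrix = pm.default_matrix()
        r = self._recovery(fe_channel(), "He", matrix)
        assert 90 <= r <= 110

    def test_recovery_monotone_in_interference_coefficient(self):
        """Raising a polyatomic coefficient never lowers no-gas recovery."""
        matrix = pm.default_matrix()
        ch = fe_channel()
        base = self._recovery(ch, "no-gas", matrix)
        boosted_terms = tuple(
            dataclasses.replace(t, coefficient_nogas=t.coefficient_nogas * 2)
            for t in ch.interference_terms
        )
        boosted = dataclasses.replace(ch, interference_terms=boosted_terms)
        assert self._recovery(boosted, "no-gas", matrix) >= base

    def test_arsenic_he_correction_ineffective(self):
        """The As overlap is flagged non-correctable and He barely helps."""
        matrix = pm.default_matrix()
        ch = next(c for c in pm.default_panel() if c.element_symbol == "As")
        assert all(not t.correctable_by_he for t in ch.interference_terms)
        r_ng = self._recovery(ch, "no-gas", matrix, spike=50.0)
        r_he = self._recovery(ch, "He", matrix, spike=50.0)
        assert abs(r_he - 100) > 10 and abs(r_ng - 100) > 10


class TestSimulateRecord:
    def test_noiseless_record_equals_expectation(self, noiseless_design, flat_matrix):
        rng = np.random.default_rng(0)
        ch = clean_channel(baseline=11.0)
        rec = pm.simulate_record(ch, 80.0, "no-gas", flat_matrix, noiseless_design,
                                 day=0, replicate=1, rng=rng)
        expected = pm.expected_intensity(ch, 80.0, "no-gas", flat_matrix,
                                         noiseless_design.dilution_factor)
        assert rec.analyte_intensity == pytest.approx(expected, rel=1e-12)

    def test_common_drift_cancels_in_ratio(self, noiseless_design):
        ch = clean_channel()
        d = dataclasses.replace(noiseless_design, drift_per_day=0.05)
        rng = np.random.default_rng(0)
        r0 = pm.simulate_record(ch, 50.0, "no-gas", None, d, day=0, replicate=1,
                                rng=rng, dilution_factor=1.0)
        r3 = pm.simulate_record(ch, 50.0, "no-gas", None, d, day=3, replicate=1,
                                rng=rng, dilution_factor=1.0)
        assert r3.analyte_intensity > r0.analyte_intensity  # drift is real ...
        ratio0 = r0.analyte_intensity / r0.is_intensity
        ratio3 = r3.analyte_intensity / r3.is_intensity
        assert ratio3 == pytest.approx(ratio0, rel=1e-12)  # ... and cancels

    def test_sample_cv_matches_noise_model(self, design):
        """1000 replicates at fixed high concentration reproduce the configured CV."""
        ch = clean_channel(s=20000.0)
        rng = np.random.default_rng(42)
        vals = np.array([
            pm.simulate_record(ch, 1000.0, "no-gas", None, design, day=0,
                               replicate=1, rng=rng, dilution_factor=1.0).analyte_intensity
            for _ in range(1000)
        ])
        expected = 20000.0 * 1000.0
        model_sd = np.sqrt(expected**2 * design.noise_cv**2 + expected)
        cv_hat = vals.std(ddof=1) / vals.mean()
        cv_model = model_sd / expected
        se = cv_model / np.sqrt(2 * (len(vals) - 1))
        assert abs(cv_hat - cv_model) < 3 * se


class TestGenerateStudy:
    def test_blank_and_validation_record_counts(self, records, design):
        blanks = records[records["role"] == "blank"]
        per = blanks.groupby(["element", "mode"]).size()
        assert (per == design.n_blank_replicates).all() and len(per) == 40

        spiked = records[(records["stage"] == "validation")
                         & (records["role"] == "spiked_sample")]
        per = spiked.groupby(["element", "mode"]).size()
        assert (per == design.n_rep * design.n_days).all()

    def test_cohort_size_and_modes(self, records, design):
        cohort = records[records["stage"] == "cohort"]
        per = cohort.groupby(["element", "mode"]).size()
        assert (per == design.cohort_size).all()

    def test_zero_truth_cohort_is_background_only(self, noiseless_design):
        truth = {el: np.zeros(noiseless_design.cohort_size) for el in _PANEL_SENSITIVITY}
        df = pm.generate_study(noiseless_design, truth=truth)
        cohort = df[(df["stage"] == "cohort") & (df["mode"] == "no-gas")]
        matrix = pm.default_matrix()
        for ch in pm.default_panel():
            got = cohort[cohort["element"] == ch.element_symbol]["analyte_cps"].unique()
            want = pm.expected_intensity(ch, 0.0, "no-gas", matrix,
                                         noiseless_design.dilution_factor)
            assert got == pytest.approx(want, rel=1e-9)

    def test_missing_truth_raises(self, design):
        with pytest.raises(KeyError):
            pm.generate_study(design, truth={"Cd": [1.0] * design.cohort_size})

    def test_determinism(self, design, records):
        again = pm.generate_study(design)
        pd.testing.assert_frame_equal(records, again)

    def test_seed_changes_output(self, design, records):
        other = pm.generate_study(dataclasses.replace(design, seed=design.seed + 1))
        assert not records["analyte_cps"].equals(other["analyte_cps"])


class TestMatrixProfile:
    def test_suppression_shrinks_with_dilution(self):
        matrix = pm.default_matrix()
        for el in _PANEL_SENSITIVITY:
            f2 = matrix.suppression_factor(el, 2.0)
            f4 = matrix.suppression_factor(el, 4.0)
            assert abs(f4 - 1) < abs(f2 - 1)
            assert matrix.suppression_factor(el, 1e9) == pytest.approx(1.0, abs=1e-6)

    def test_is_assignment_by_mass(self):
        for ch in pm.default_panel():
            assert ch.internal_standard in INTERNAL_STANDARDS
        masses = {ch.element_symbol: ch.internal_standard for ch in pm.default_panel()}
        assert masses["Fe"] == "Sc" and masses["Sr"] == "Ge"
        assert masses["Cd"] == "Rh" and masses["Pb"] == "Re"

    def test_channel_invariants_enforced(self):
        with pytest.raises(ValueError):
            pm.IsotopeChannel("X", 50, sensitivity_nogas=100.0, sensitivity_he=100.0)
        with pytest.raises(ValueError):
            pm.InterferenceTerm("Cl", -1.0)


class TestInternalStandardCancellation:
    def test_common_rescaling_leaves_concentrations_unchanged(
        self, noiseless_records, noiseless_design
    ):
        """Multiplying every intensity by a common factor is invisible downstream."""
        curves = pm.fit_all(noiseless_records, noiseless_design.is_concentration)
        scaled = noiseless_records.copy()
        scaled["analyte_cps"] *= 3.0
        scaled["is_cps"] *= 3.0
        curves2 = pm.fit_all(scaled, noiseless_design.is_concentration)
        for key, c in curves.items():
            assert curves2[key].slope == pytest.approx(c.slope, rel=1e-9)
            assert curves2[key].intercept == pytest.approx(c.intercept, abs=1e-12)
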