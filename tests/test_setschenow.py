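import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from setsolv.setschenow import (
    CMCSeries,
    Eq6Model,
    fit_ion_amplitudes,
    fit_ks,
    fit_surfactant_ab,
    load_experimental_ks,
    load_ion_params,
    load_surfactant_params,
    predict_ks,
    r_squared,
)


def make_series(ks, concs=(0.0, 0.5, 1.0, 2.0), cmc0=0.02, noise=None, rng=None):
    c = np.asarray(concs, dtype=float)
    cmc = cmc0 * np.exp(-ks * c)
    if noise is not None:
        cmc = cmc * rng.lognormal(0.0, noise, len(c))
    return CMCSeries("X", tuple(c), tuple(cmc), cmc0=cmc0)


class TestFitKs:
    def test_flat_series_gives_zero(self):
        series = CMCSeries("X", (0.0, 0.5, 1.0), (0.02, 0.02, 0.02))
        assert fit_ks(series).ks == pytest.approx(0.0, abs=1e-14)

    def test_exact_synthetic_recovery(self):
        fit = fit_ks(make_series(0.5))
        assert fit.ks == pytest.approx(0.5, abs=1e-14)
        assert fit.intercept == pytest.approx(0.0, abs=1e-14)

    def test_noisy_monte_carlo_recovery(self):
        """200 replicates of 6-point series with 5% lognormal noise average
        back to the planted coefficient."""
        rng = np.random.default_rng(7)
        concs = (0.0, 0.4, 0.8, 1.2, 1.6, 2.0)
        estimates = [
            fit_ks(make_series(0.8, concs, noise=0.05, rng=rng)).ks
            for _ in range(200)
        ]
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.02)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_ks(CMCSeries("X", (1.0, 1.0), (0.02, 0.02), cmc0=0.02))

    def test_nonpositive_cmc_rejected(self):
        with pytest.raises(ValueError):
            CMCSeries("X", (0.0, 1.0), (0.02, -0.01))

    def test_missing_reference_rejected(self):
        s = CMCSeries("X", (0.5, 1.0), (0.01, 0.005))
        with pytest.raises(ValueError, match="CMC0"):
            fit_ks(s)

    def test_salting_out_sign_convention(self):
        """CMC decreasing with salt must give a positive coefficient."""
        fit = fit_ks(make_series(1.2))
        assert fit.ks > 0
        fit_in = fit_ks(make_series(-0.3))  # salting in
        assert fit_in.ks == pytest.approx(-0.3, abs=1e-12)

    @given(
        ks=st.floats(-1.5, 2.0),
        cmc0=st.floats(1e-4, 0.5),
        scale=st.floats(0.2, 2.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_inversion_property(self, ks, cmc0, scale):
        concs = tuple(np.array([0.0, 0.5, 1.0, 1.7]) * scale)
        fit = fit_ks(make_series(ks, concs, cmc0))
        assert fit.ks == pytest.approx(ks, abs=1e-9)


class TestPredict:
    @pytest.fixture(scope="class")
    def model(self):
        return Eq6Model(load_surfactant_params(), load_ion_params())

    @pytest.mark.parametrize(
        "surf,cation,anion,expected",
        [
            ("GLUCO8", "Na+", "Cl-", 0.58),
            ("MEGA8", "Cs+", "Cl-", 0.39),
            ("MEGA9", "Li+", "Cl-", 0.41),
            ("C12E6", "K+", "Br-", 0.48),
        ],
    )
    def test_reference_rows_to_two_decimals(self, model, surf, cation, anion, expected):
        assert round(predict_ks(model, surf, cation, anion), 2) == expected

    def test_zero_a_reduces_to_b(self):
        model = Eq6Model({"S": (0.0, 0.7)}, {"X+": 50.0, "Y-": 80.0})
        assert predict_ks(model, "S", "X+", "Y-") == pytest.approx(0.7)

    def test_missing_parameter_names_culprit(self, model):
        with pytest.raises(KeyError, match="F-"):
            predict_ks(model, "MEGA8", "Na+", "F-")
        with pytest.raises(KeyError, match="SDS"):
            predict_ks(model, "SDS", "Na+", "Cl-")

    def test_monotone_in_each_amplitude(self, model):
        """With A < 0, weaker ion-tail repulsion lowers the coefficient."""
        base = predict_ks(model, "MEGA9", "Na+", "Cl-")
        weaker = Eq6Model(model.surfactants, {**model.ions, "Na+": 60.0})
        stronger = Eq6Model(model.surfactants, {**model.ions, "Na+": 90.0})
        assert predict_ks(weaker, "MEGA9", "Na+", "Cl-") < base
        assert predict_ks(stronger, "MEGA9", "Na+", "Cl-") > base

    def test_anion_swap_shift_scales_with_a(self, model):
        """Additivity: swapping the anion shifts ks by A * (1/a1 - 1/a2),
        identically for every cation."""
        for surf in ("MEGA8", "C12E6"):
            a_coef = model.surfactants[surf][0]
            expected = a_coef * (1 / model.ions["Br-"] - 1 / model.ions["I-"])
            for cation in ("Na+", "K+", "Li+"):
                shift = predict_ks(model, surf, cation, "Br-") - predict_ks(
                    model, surf, cation, "I-"
                )
                assert shift == pytest.approx(expected, abs=1e-12)


class TestFitSurfactantAB:
    def test_exact_inverse_problem(self):
        amps = load_ion_params()
        salts = [("Na+", "Cl-"), ("K+", "Br-"), ("Li+", "Cl-"), ("K+", "I-")]
        model = Eq6Model({"S": (-50.0, 2.0)}, amps)
        table = pd.DataFrame(
            [
                {"cation": c, "anion": a, "ks": predict_ks(model, "S", c, a)}
                for c, a in salts
            ]
        )
        A, B, ss = fit_surfactant_ab(table, amps)
        assert A == pytest.approx(-50.0, abs=1e-8)
        assert B == pytest.approx(2.0, abs=1e-8)
        assert ss == pytest.approx(0.0, abs=1e-16)

    def test_single_salt_rejected(self):
        amps = load_ion_params()
        table = pd.DataFrame([{"cation": "Na+", "anion": "Cl-", "ks": 0.5}])
        with pytest.raises(ValueError):
            fit_surfactant_ab(table, amps)

    def test_degenerate_design_rejected(self):
        amps = {"Na+": 72.0, "Cl-": 94.0, "K+": 94.0, "Br-": 72.0}
        table = pd.DataFrame(
            [
                {"cation": "Na+", "anion": "Cl-", "ks": 0.5},
                {"cation": "K+", "anion": "Br-", "ks": 0.6},  # same 1/a sum
            ]
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_surfactant_ab(table, amps)

    def test_recovers_published_constants_from_experiment(self):
        """MEGA8 experimental rows + packaged amplitudes give (A, B) within
        5% of the packaged surfactant constants."""
        table = load_experimental_ks(monovalent_only=True)
        table = table[table["surfactant"] == "MEGA8"]
        A, B, _ = fit_surfactant_ab(table, load_ion_params())
        assert A == pytest.approx(-29.42, rel=0.05)
        assert B == pytest.approx(1.24, rel=0.05)
        model = Eq6Model({"MEGA8": (A, B)}, load_ion_params())
        ref = Eq6Model(load_surfactant_params(), load_ion_params())
        for rec in table.itertuples():
            assert predict_ks(model, "MEGA8", rec.cation, rec.anion) == pytest.approx(
                predict_ks(ref, "MEGA8", rec.cation, rec.anion), abs=0.02
            )


class TestFitIonAmplitudes:
    def synthetic_table(self, model):
        rows = []
        for surf in model.surfactants:
            for cation in ("Li+", "Na+", "K+", "Cs+"):
                for anion in ("Cl-", "Br-", "I-"):
                    rows.append(
                        {
                            "surfactant": surf,
                            "cation": cation,
                            "anion": anion,
                            "ks": predict_ks(model, surf, cation, anion),
                        }
                    )
        return pd.DataFrame(rows)

    def test_noiseless_recovery_within_half_kbt(self):
        """With the cation/anion gauge pinned by one reference ion, noiseless
        data returns every planted amplitude."""
        model = Eq6Model(load_surfactant_params(), load_ion_params())
        table = self.synthetic_table(model)
        result = fit_ion_amplitudes(
            table, model.surfactants, fixed={"Cl-": model.ions["Cl-"]}
        )
        for ion, amp in result.amplitudes.items():
            assert amp == pytest.approx(model.ions[ion], abs=0.5)

    def test_unpinned_fit_recovers_identified_sums(self):
        """Without a reference ion only 1/a+ + 1/a- is identified; the fit
        still reproduces every salt combination exactly."""
        model = Eq6Model(load_surfactant_params(), load_ion_params())
        table = self.synthetic_table(model)
        result = fit_ion_amplitudes(table, model.surfactants)
        assert result.ss_res == pytest.approx(0.0, abs=1e-16)
        for rec in table.itertuples():
            planted = 1 / model.ions[rec.cation] + 1 / model.ions[rec.anion]
            fitted = (
                1 / result.amplitudes[rec.cation] + 1 / result.amplitudes[rec.anion]
            )
            assert fitted == pytest.approx(planted, abs=1e-10)

    def test_pinned_bounds_are_respected(self):
        model = Eq6Model(load_surfactant_params(), load_ion_params())
        table = self.synthetic_table(model)
        result = fit_ion_amplitudes(
            table, model.surfactants, fixed={"Na+": 60.0}
        )
        assert result.amplitudes["Na+"] == 60.0

    def test_experimental_fit_matches_published_ordering(self):
        """Fitting the experimental monovalent table reproduces the packaged
        sodium amplitude within 5 kBT and the cation ordering."""
        table = load_experimental_ks(monovalent_only=True)
        params = load_surfactant_params()
        result = fit_ion_amplitudes(table, params)
        amps = result.amplitudes
        assert amps["Na+"] == pytest.approx(72.0, abs=5.0)
        assert amps["Na+"] > amps["K+"] > amps["Cs+"] > amps["Li+"]
        assert "Cs+" in result.weakly_identified  # single CsCl measurement
        assert "SCN-" in result.weakly_identified

    def test_missing_surfactant_parameters_rejected(self):
        table = pd.DataFrame(
            [{"surfactant": "SDS", "cation": "Na+", "anion": "Cl-", "ks": 0.5}]
        )
        with pytest.raises(KeyError, match="SDS"):
            fit_ion_amplitudes(table, load_surfactant_params())


class TestRSquared:
    def test_perfect_agreement(self):
        assert r_squared([(0.3, 0.3), (0.5, 0.5), (0.7, 0.7)]) == 1.0

    def test_hand_computable_negative_case(self):
        # residuals (1, 1), total deviations (0.5, 0.5): R^2 = 1 - 2/0.5 = -3
        assert r_squared([(0.0, 1.0), (1.0, 0.0)]) == pytest.approx(-3.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([(0.5, 0.4), (0.5, 0.6)])

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            r_squared([(0.5, 0.5)])


class TestPipelineConsistency:
    def test_two_stage_round_trip_is_identity(self):
        """predict -> fit(A,B) -> fit(ion amplitudes) closes on the planted
        parameters to solver tolerance on noiseless data."""
        planted = Eq6Model(
            {"S1": (-30.0, 1.3), "S2": (-50.0, 2.0)},
            {"Na+": 72.0, "K+": 64.0, "Cl-": 94.0, "Br-": 66.0, "I-": 55.0},
        )
        rows = []
        for surf in planted.surfactants:
            for cation in ("Na+", "K+"):
                for anion in ("Cl-", "Br-", "I-"):
                    rows.append(
                        {
                            "surfactant": surf,
                            "cation": cation,
                            "anion": anion,
                            "ks": predict_ks(planted, surf, cation, anion),
                        }
                    )
        table = pd.DataFrame(rows)
        ab = {}
        for surf in planted.surfactants:
            sub = table[table["surfactant"] == surf]
            A, B, _ = fit_surfactant_ab(sub, planted.ions)
            ab[surf] = (A, B)
            assert A == pytest.approx(planted.surfactants[surf][0], abs=1e-6)
            assert B == pytest.approx(planted.surfactants[surf][1], abs=1e-6)
        ions = fit_ion_amplitudes(
            table, ab, fixed={"Cl-": planted.ions["Cl-"]}
        ).amplitudes
        for ion, amp in ions.items():
            assert amp == pytest.approx(planted.ions[ion], abs=1e-4)
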