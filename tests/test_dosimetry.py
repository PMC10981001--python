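"""Time-integrated activity closed forms, sphere S-values and dose chaining."""

import math

import numpy as np
import pytest
import yaml
from scipy.integrate import quad

from ssia_dosekit.cohort_io import ROUTE_IV, ROUTE_SSIA, PatientRecord, RouteSeries, UptakeMeasurement
from ssia_dosekit.dosimetry import (
    Emission,
    Nuclide,
    a_tilde_association,
    a_tilde_decay,
    a_tilde_with_teq,
    absorbed_dose,
    dose_per_cycle,
    sphere_s_value,
)

LU177_LAMBDA = math.log(2) / 159.528


class TestATildeDecay:
    def test_pure_physical_decay_limit(self, nuclides):
        lam_p = nuclides["lu177"].lambda_phys_per_h
        assert a_tilde_decay(1.0, 0.0, lam_p) == pytest.approx(230.16, abs=0.01)

    def test_closed_form_example(self):
        assert a_tilde_decay(100.0, 0.1, 0.004345) == pytest.approx(
            100.0 / 0.104345, rel=1e-12
        )

    def test_linearity_in_a0(self):
        one = a_tilde_decay(1.0, 0.2, 0.004)
        assert a_tilde_decay(2.0, 0.2, 0.004) == pytest.approx(2 * one)

    def test_matches_quadrature(self, rng):
        for _ in range(20):
            a0 = rng.uniform(1, 500)
            lb = rng.uniform(0, 0.5)
            lp = rng.uniform(1e-3, 0.1)
            num, _ = quad(lambda t: a0 * np.exp(-(lb + lp) * t), 0, np.inf)
            assert a_tilde_decay(a0, lb, lp) == pytest.approx(num, rel=1e-8)

    def test_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            a_tilde_decay(1.0, 0.0, 0.0)


class TestATildeWithTeq:
    def test_teq_zero_is_pure_physical(self):
        assert a_tilde_with_teq(5.0, 0.3, LU177_LAMBDA, 0.0) == pytest.approx(
            5.0 / LU177_LAMBDA
        )

    def test_large_teq_converges_to_decay_integral(self):
        full = a_tilde_decay(5.0, 0.3, LU177_LAMBDA)
        assert a_tilde_with_teq(5.0, 0.3, LU177_LAMBDA, 1e5) == pytest.approx(full, rel=1e-9)

    def test_matches_piecewise_quadrature(self):
        a0, lb, lp, teq = 100.0, 0.2, 0.004345, 5.0
        head, _ = quad(lambda t: a0 * np.exp(-(lb + lp) * t), 0, teq)
        a_teq = a0 * np.exp(-(lb + lp) * teq)
        tail, _ = quad(lambda t: a_teq * np.exp(-lp * (t - teq)), teq, np.inf)
        assert a_tilde_with_teq(a0, lb, lp, teq) == pytest.approx(head + tail, rel=1e-8)

    def test_monotone_nonincreasing_in_lambda_biol(self):
        lams = np.linspace(0.0, 1.0, 41)
        vals = [a_tilde_with_teq(10.0, lb, LU177_LAMBDA, 24.0) for lb in lams]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(10.0 / LU177_LAMBDA)

    def test_retention_after_teq_only_adds_dose(self):
        # freezing clearance at T_eq can only increase the integral
        for teq in (0.0, 2.0, 50.0, 500.0):
            assert a_tilde_with_teq(7.0, 0.25, LU177_LAMBDA, teq) >= a_tilde_decay(
                7.0, 0.25, LU177_LAMBDA
            ) - 1e-12


class TestATildeAssociation:
    def test_instant_uptake_limit(self):
        slow = a_tilde_association(50.0, 1e9, 0.004345)
        assert slow == pytest.approx(50.0 / 0.004345, rel=1e-6)

    def test_no_uptake_limit(self):
        assert a_tilde_association(50.0, 0.0, 0.004345) == 0.0

    def test_matches_quadrature(self):
        num, _ = quad(lambda t: 50.0 * (1 - np.exp(-0.5 * t)) * np.exp(-0.004345 * t), 0, np.inf)
        assert a_tilde_association(50.0, 0.5, 0.004345) == pytest.approx(num, rel=1e-8)


class TestSphereSValue:
    def test_unit_construction(self):
        # 1 MeV per decay fully absorbed in 10 mL (= 0.01 kg) of water:
        # 1.602e-13 J / 0.01 kg = 1.602e-11 Gy per decay
        nuc = Nuclide("toy", 10.0, (Emission("beta_or_electron", 1.0, 1.0),))
        s = sphere_s_value(nuc, 10.0)
        assert sum(s.values()) == pytest.approx(1.602176634e-11, rel=1e-9)

    def test_inverse_mass_scaling(self, nuclides):
        s10 = sum(sphere_s_value(nuclides["lu177"], 10.0).values())
        s5 = sum(sphere_s_value(nuclides["lu177"], 5.0).values())
        assert s5 == pytest.approx(2 * s10, rel=1e-12)

    def test_lu177_configured_electron_energy(self, nuclides):
        s = sphere_s_value(nuclides["lu177"], 10.0)
        assert s["beta_or_electron"] == pytest.approx(2.369e-12, rel=1e-3)
        assert s["photon"] == 0.0  # photons escape under local deposition

    def test_ac225_chain_energy_matches_manual_sum(self, nuclides):
        # independent oracle: walk the YAML file directly
        from importlib import resources

        raw = yaml.safe_load(
            resources.files("ssia_dosekit").joinpath("data/nuclides.yaml").read_text()
        )

        def manual_alpha(name, branch=1.0):
            total = sum(
                branch * e["energy_mev"] * e["yield"]
                for e in raw[name].get("emissions", [])
                if e["kind"] == "alpha"
            )
            for p in raw[name].get("progeny", []):
                total += manual_alpha(p["name"], branch * p["branching"])
            return total

        assert nuclides["ac225"].chain_energy_mev()["alpha"] == pytest.approx(
            manual_alpha("ac225"), rel=1e-12
        )

    def test_empty_emission_table_rejected(self):
        nuc = Nuclide("hollow", 1.0, ())
        with pytest.raises(ValueError, match="emission"):
            sphere_s_value(nuc, 1.0)


class TestAbsorbedDose:
    def test_zero_a_tilde(self):
        est = absorbed_dose(0.0, {"alpha": 1e-12}, {"alpha": 5.0})
        assert est.dose_gy == 0.0
        assert est.rbe_weighted_dose_gy == 0.0

    def test_unit_rbe_leaves_dose_unchanged(self):
        est = absorbed_dose(10.0, {"beta_or_electron": 2e-12})
        assert est.rbe_weighted_dose_gy == est.dose_gy

    def test_pure_alpha_rbe_scales_exactly_five(self, nuclides):
        nuc = Nuclide("alpha-only", 100.0, (Emission("alpha", 6.0, 1.0),), rbe={"alpha": 5.0})
        s = sphere_s_value(nuc, 5.0)
        est = absorbed_dose(20.0, s, {"alpha": 5.0})
        assert est.rbe_weighted_dose_gy == pytest.approx(5 * est.dose_gy, rel=1e-12)

    def test_unit_conversion(self):
        # 1 MBq·h = 3.6e9 decays per Bq·s scale
        est = absorbed_dose(1.0, {"alpha": 1.0})
        assert est.dose_gy == pytest.approx(3.6e9)


def _patient(iv_suvs, ia_suvs, times=(90.0, 165.0, 240.0), bw=80.0, vol=20.0):
    def series(route, suvs):
        ms = tuple(
            UptakeMeasurement("s", route, i + 1, t, suv_max_tumour=v)
            for i, (t, v) in enumerate(zip(times, suvs))
        )
        return RouteSeries(route, ms, injected_activity_mbq=120.0)

    return PatientRecord(
        "s",
        {ROUTE_IV: series(ROUTE_IV, iv_suvs), ROUTE_SSIA: series(ROUTE_SSIA, ia_suvs)},
        body_weight_kg=bw,
        tumour_ce_volume_ml=vol,
        uptake_volume_ml=vol,
    )


class TestDosePerCycle:
    def test_linearity_in_model_activity(self, nuclides):
        t = np.array([1.5, 2.75, 4.0])
        ia = 150 * np.exp(-0.08 * t)
        iv = 12 * (1 - np.exp(-0.5 * t))
        p = _patient(iv, ia)
        d1 = dose_per_cycle(p, ROUTE_SSIA, nuclides["lu177"], 7400.0)
        d2 = dose_per_cycle(p, ROUTE_SSIA, nuclides["lu177"], 14800.0)
        assert d2.dose_gy == pytest.approx(2 * d1.dose_gy, rel=1e-6)

    def test_ia_dose_at_least_iv_for_identical_kinetics(self, nuclides, rng):
        # with identical curves the post-crossover retention can only add
        for _ in range(10):
            lam = rng.uniform(0.02, 0.3)
            a0 = rng.uniform(20, 200)
            t = np.array([1.5, 2.75, 4.0])
            curve = a0 * np.exp(-lam * t)
            p = _patient(curve, curve)
            d_ia = dose_per_cycle(p, ROUTE_SSIA, nuclides["lu177"], 7400.0)
            d_iv = dose_per_cycle(p, ROUTE_IV, nuclides["lu177"], 7400.0)
            assert d_ia.dose_gy >= d_iv.dose_gy - 1e-9

    def test_uses_teq_when_curves_cross(self, nuclides):
        t = np.array([1.5, 2.75, 4.0])
        ia = 150 * np.exp(-0.08 * t)
        iv = 12 * (1 - np.exp(-0.5 * t))
        est = dose_per_cycle(_patient(iv, ia), ROUTE_SSIA, nuclides["lu177"], 7400.0)
        assert est.tia_model == "decay_teq"
        assert est.teq_h is not None and est.teq_h > 4.0

    def test_missing_volume_is_an_error(self, nuclides):
        t = np.array([1.5, 2.75, 4.0])
        p = _patient(12 * (1 - np.exp(-0.5 * t)), 150 * np.exp(-0.08 * t))
        import dataclasses

        p = dataclasses.replace(p, tumour_ce_volume_ml=None)
        with pytest.raises(ValueError, match="tumour_ce_volume_ml"):
            dose_per_cycle(p, ROUTE_SSIA, nuclides["lu177"], 7400.0)
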