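"""Synthetic two-route cohorts and PET phantoms with known ground truth.

The generator emulates the structure of a 10-patient two-route brain-tumour
PET study: three scans near 90/165/240 min post-injection, intravenous
tumour kinetics following a one-phase association (uptake to a plateau),
intra-arterial kinetics following a mono-exponential washout, organ SUVs
(parotid, liver, background) in the spans observed clinically, and
multiplicative lognormal measurement noise.  Default kinetic-rate ranges are
read off exponential fits to the packaged reference cohort (IV association
rates ~0.3–1.1 /h, ssIA washout rates ~0.01–0.12 /h; IV plateaus ~5–18 SUV;
ssIA peaks 7–25-fold the IV peak).

Every draw is reproducible from the seed, and the ground truth (true model,
amplitude, rate, peak SUV, and the absorbed dose each nuclide would deliver
under the true kinetics) is returned alongside the cohort so that any stage
of the analysis pipeline can be checked against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .cohort_io import (
    ROUTE_IV,
    ROUTE_SSIA,
    PatientRecord,
    RouteSeries,
    UptakeMeasurement,
)
from .dosimetry import (
    Nuclide,
    absorbed_dose,
    load_nuclides,
    sphere_s_value,
    time_integrated_activity,
)
from .tac_kinetics import (
    MODEL_ASSOCIATION,
    MODEL_DECAY,
    ExponentialFit,
    find_teq,
    suv_to_pctia_per_ml,
)

__all__ = ["CohortSimSpec", "TrueKinetics", "GroundTruth", "simulate_cohort", "simulate_pet_volume"]

#: therapy model activities in MBq used for ground-truth dose bookkeeping
MODEL_ACTIVITIES = {"lu177": 7400.0, "ac225": 8.0}


@dataclass(frozen=True)
class CohortSimSpec:
    """Study conditions for a simulated two-route cohort."""

    n_patients: int = 10
    seed: int = 0
    scan_times_min: tuple[float, float, float] = (90.0, 165.0, 240.0)
    scan_time_jitter_min: float = 10.0
    iv_plateau_suv: tuple[float, float] = (5.0, 18.0)
    iv_lambda_per_h: tuple[float, float] = (0.3, 1.1)
    ia_lambda_per_h: tuple[float, float] = (0.01, 0.12)
    ia_advantage: tuple[float, float] = (7.0, 25.0)
    noise_cv: float = 0.05
    body_weight_kg: tuple[float, float] = (80.0, 10.0)  # mean, sd (truncated)
    tumour_volume_ml: tuple[float, float] = (1.0, 60.0)  # log-uniform span
    parotid_suv: tuple[float, float] = (11.0, 33.0)
    liver_suv: tuple[float, float] = (2.4, 9.1)
    background_suv: tuple[float, float] = (0.02, 0.1)
    iv_activity_mbq_per_kg: float = 1.5

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.noise_cv <= 0.5:
            raise ValueError("noise_cv must be in [0, 0.5]")
        for name in (
            "iv_plateau_suv", "iv_lambda_per_h", "ia_lambda_per_h",
            "ia_advantage", "tumour_volume_ml", "parotid_suv", "liver_suv",
            "background_suv",
        ):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} range must be positive and ordered, got ({lo}, {hi})")


@dataclass(frozen=True)
class TrueKinetics:
    """Noise-free generating parameters of one (patient, route) series."""

    model: str
    amplitude_suv: float  # plateau (association) or t=0 value (washout)
    lambda_biol_per_h: float
    peak_suv: float  # noise-free SUVmax over the scheduled scan times
    amplitude_activity_mbq: dict[str, float] = field(default_factory=dict)
    dose_gy: dict[str, float] = field(default_factory=dict)
    rbe_weighted_dose_gy: dict[str, float] = field(default_factory=dict)
    teq_h: Optional[float] = None


@dataclass(frozen=True)
class GroundTruth:
    entries: dict[tuple[str, str], TrueKinetics]

    def of(self, patient_id: str, route: str) -> TrueKinetics:
        return self.entries[(patient_id, route)]

    def to_json(self) -> str:
        return json.dumps(
            {f"{pid}/{route}": asdict(tk) for (pid, route), tk in self.entries.items()},
            indent=2,
        )


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, n))  # mean-one noise


def _true_dose(
    model: str,
    amplitude_suv: float,
    lam: float,
    body_weight: float,
    uptake_volume: float,
    ce_volume: float,
    nuclides: dict[str, Nuclide],
    iv_fit: Optional[ExponentialFit] = None,
) -> tuple[dict, dict, dict, Optional[float]]:
    amps, doses, weighted = {}, {}, {}
    teq_out = None
    for name, activity in MODEL_ACTIVITIES.items():
        nuc = nuclides[name]
        a0 = suv_to_pctia_per_ml(amplitude_suv, body_weight) * uptake_volume / 100.0 * activity
        fit = ExponentialFit(model=model, a0=a0, lambda_biol=lam, sse=0.0, n_points=3)
        teq = None
        if model == MODEL_DECAY and iv_fit is not None:
            iv_a0 = (
                suv_to_pctia_per_ml(iv_fit.a0, body_weight) * uptake_volume / 100.0 * activity
            )
            teq = find_teq(
                fit,
                ExponentialFit(
                    model=MODEL_ASSOCIATION,
                    a0=iv_a0,
                    lambda_biol=iv_fit.lambda_biol,
                    sse=0.0,
                    n_points=3,
                ),
            )
            teq_out = teq
        tia = time_integrated_activity(fit, nuc.lambda_phys_per_h, teq)
        s = sphere_s_value(nuc, ce_volume)
        est = absorbed_dose(
            tia.a_tilde_mbq_h, s, {k: nuc.rbe_for(k) for k in s}, nuclide_name=name
        )
        amps[name] = a0
        doses[name] = est.dose_gy
        weighted[name] = est.rbe_weighted_dose_gy
    return amps, doses, weighted, teq_out


def simulate_cohort(spec: CohortSimSpec) -> tuple[list[PatientRecord], GroundTruth]:
    """Draw a cohort in the long-table schema plus its generating ground truth.

    The ssIA amplitude is constructed so that, at zero noise, the measured
    peak-SUVmax fold change (ssIA/IV) equals the drawn advantage factor
    exactly.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nuclides = load_nuclides()
    cohort: list[PatientRecord] = []
    truth: dict[tuple[str, str], TrueKinetics] = {}

    for i in range(spec.n_patients):
        pid = str(i + 1)
        # patient metadata
        mu, sd = spec.body_weight_kg
        bw = float(np.clip(rng.normal(mu, sd), mu - 3 * sd, mu + 3 * sd))
        lo, hi = spec.tumour_volume_ml
        ce_vol = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        uptake_vol = ce_vol * float(rng.uniform(0.9, 1.4))

        times = {}
        for route in (ROUTE_IV, ROUTE_SSIA):
            jitter = rng.uniform(0.0, spec.scan_time_jitter_min, 3)
            times[route] = np.asarray(spec.scan_times_min) + jitter
        t_iv_h = times[ROUTE_IV] / 60.0
        t_ia_h = times[ROUTE_SSIA] / 60.0

        # kinetics
        iv_lam = float(rng.uniform(*spec.iv_lambda_per_h))
        iv_plateau = float(rng.uniform(*spec.iv_plateau_suv))
        fold = float(np.exp(rng.uniform(*np.log(spec.ia_advantage))))
        ia_lam = float(rng.uniform(*spec.ia_lambda_per_h))
        iv_true = iv_plateau * (1.0 - np.exp(-iv_lam * t_iv_h))
        iv_peak = float(iv_true.max())
        # place the ssIA curve so its first-scan (peak) value is fold x IV peak
        ia_a0 = fold * iv_peak / float(np.exp(-ia_lam * t_ia_h[0]))
        ia_true = ia_a0 * np.exp(-ia_lam * t_ia_h)

        iv_act = spec.iv_activity_mbq_per_kg * bw
        ia_act = iv_act * float(rng.uniform(0.55, 0.85))

        series = {}
        for route, t_min, true_suv in (
            (ROUTE_IV, times[ROUTE_IV], iv_true),
            (ROUTE_SSIA, times[ROUTE_SSIA], ia_true),
        ):
            noisy = true_suv * _lognormal_factors(rng, spec.noise_cv, 3)
            parotid = rng.uniform(*spec.parotid_suv, 3)
            background = rng.uniform(*spec.background_suv, 3)
            ms = tuple(
                UptakeMeasurement(
                    patient_id=pid,
                    route=route,
                    scan_index=k + 1,
                    time_min=float(t_min[k]),
                    suv_max_tumour=float(noisy[k]),
                    suv_mean_background=float(background[k]),
                    suv_mean_parotid=float(parotid[k]),
                )
                for k in range(3)
            )
            series[route] = RouteSeries(
                route=route,
                measurements=ms,
                suv_mean_liver=float(rng.uniform(*spec.liver_suv)),
                injected_activity_mbq=iv_act if route == ROUTE_IV else ia_act,
            )
        record = PatientRecord(
            patient_id=pid,
            series=series,
            body_weight_kg=bw,
            tumour_ce_volume_ml=ce_vol,
            uptake_volume_ml=uptake_vol,
        )
        cohort.append(record)

        iv_fit_true = ExponentialFit(
            model=MODEL_ASSOCIATION, a0=iv_plateau, lambda_biol=iv_lam, sse=0.0, n_points=3
        )
        amps, doses, weighted, _ = _true_dose(
            MODEL_ASSOCIATION, iv_plateau, iv_lam, bw, uptake_vol, ce_vol, nuclides
        )
        truth[(pid, ROUTE_IV)] = TrueKinetics(
            model=MODEL_ASSOCIATION,
            amplitude_suv=iv_plateau,
            lambda_biol_per_h=iv_lam,
            peak_suv=iv_peak,
            amplitude_activity_mbq=amps,
            dose_gy=doses,
            rbe_weighted_dose_gy=weighted,
        )
        amps, doses, weighted, teq = _true_dose(
            MODEL_DECAY, ia_a0, ia_lam, bw, uptake_vol, ce_vol, nuclides, iv_fit=iv_fit_true
        )
        truth[(pid, ROUTE_SSIA)] = TrueKinetics(
            model=MODEL_DECAY,
            amplitude_suv=ia_a0,
            lambda_biol_per_h=ia_lam,
            peak_suv=float(ia_true.max()),
            amplitude_activity_mbq=amps,
            dose_gy=doses,
            rbe_weighted_dose_gy=weighted,
            teq_h=teq,
        )

    return cohort, GroundTruth(entries=truth)


def simulate_pet_volume(
    peak_suv: float,
    background_suv: float = 0.05,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    lesion_center_vox: Optional[tuple[int, int, int]] = None,
    lesion_radius_mm: float = 12.0,
    whole_body: bool = False,
):
    """Deterministic SUV phantom: ellipsoidal brain, one hot lesion.

    The lesion has a quadratic falloff profile peaking exactly at a voxel
    center (``peak_suv`` is recovered by SUVmax), inside an ellipsoidal
    "brain" of uniform background SUV.  With ``whole_body`` two parotid
    spheres and a liver block are added below the brain.  Returns a nibabel
    image.
    """
    import nibabel as nib

    if any(s > 128 for s in shape):
        raise ValueError("phantom grids are capped at 128^3")
    data = np.zeros(shape, dtype=float)
    affine = np.diag(list(spacing_mm) + [1.0])
    idx = np.indices(shape, dtype=float)
    center = np.array([(s - 1) / 2.0 for s in shape])
    spacing = np.asarray(spacing_mm)

    # ellipsoidal brain occupying the upper part of the grid
    brain_center = center + np.array([0.0, 0.0, shape[2] * 0.2])
    semi_axes_mm = np.array([shape[0] * 0.4, shape[1] * 0.4, shape[2] * 0.25]) * spacing
    rel = (idx - brain_center.reshape(3, 1, 1, 1)) * spacing.reshape(3, 1, 1, 1)
    brain = np.sum((rel / semi_axes_mm.reshape(3, 1, 1, 1)) ** 2, axis=0) <= 1.0
    data[brain] = background_suv

    if lesion_center_vox is None:
        lesion_center_vox = tuple(
            int(c) for c in brain_center + np.array([shape[0] * 0.18, 0, 0])
        )
    lesion_center_vox = tuple(int(c) for c in lesion_center_vox)
    if not all(0 <= c < s for c, s in zip(lesion_center_vox, shape)):
        raise ValueError(f"lesion center {lesion_center_vox} outside grid {shape}")
    d_mm = np.sqrt(
        np.sum(
            ((idx - np.array(lesion_center_vox).reshape(3, 1, 1, 1)) * spacing.reshape(3, 1, 1, 1))
            ** 2,
            axis=0,
        )
    )
    profile = peak_suv * np.clip(1.0 - (d_mm / lesion_radius_mm) ** 2, 0.0, None)
    data = np.maximum(data, profile)

    if whole_body:
        for side in (-1, 1):
            c = center + np.array([side * shape[0] * 0.3, 0.0, shape[2] * 0.1])
            d = np.sqrt(np.sum(((idx - c.reshape(3, 1, 1, 1)) * spacing.reshape(3, 1, 1, 1)) ** 2, axis=0))
            data[d <= 5.0] = 20.0  # parotid spheres
        liver = (
            (np.abs(idx[0] - center[0]) < shape[0] * 0.25)
            & (np.abs(idx[1] - center[1]) < shape[1] * 0.25)
            & (idx[2] < shape[2] * 0.15)
        )
        data[liver] = 6.0
    return nib.Nifti1Image(data, affine)
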