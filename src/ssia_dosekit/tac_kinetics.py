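"""Time–activity curves from SUV measurements and two-parameter exponential fits.

A tumour SUV measured at time t converts to percentage of injected activity
per millilitre as

    %IA(t)/mL = 100 * SUV(t) / (1000 * BW)

with BW the body weight in kg (SUV is tissue concentration times body mass
over injected activity, body mass in grams).  Multiplying by the PET uptake
volume gives the total %IA in the lesion and, for a given administered
activity, the absolute activity in MBq.

Two kinetic shapes are supported, each with two free parameters:

* ``mono_decay``             A(t) = A0 * exp(-λ_biol * t)        (washout)
* ``one_phase_association``  A(t) = A0 * (1 - exp(-λ_biol * t))  (uptake to a plateau A0)

SUVs are assumed decay-corrected to injection time (the standard PET
convention), so λ_biol is purely biological and carries over to a therapeutic
nuclide unchanged.  ``find_teq`` locates the first time at which a fitted
intra-arterial washout curve drops to the level of a fitted intravenous
uptake curve — the crossover beyond which the intra-arterial advantage ends.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "MODEL_DECAY",
    "MODEL_ASSOCIATION",
    "Tac",
    "ExponentialFit",
    "FitError",
    "suv_to_pctia_per_ml",
    "build_tac",
    "fit_tac",
    "find_teq",
]

log = logging.getLogger("ssia_dosekit.tac_kinetics")

MODEL_DECAY = "mono_decay"
MODEL_ASSOCIATION = "one_phase_association"
_MODELS = (MODEL_DECAY, MODEL_ASSOCIATION)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the attempted diagnostics."""


def suv_to_pctia_per_ml(suv: float, body_weight_kg: float) -> float:
    """Convert an SUV to percentage of injected activity per mL of tissue."""
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if suv < 0:
        raise ValueError("SUV must be non-negative")
    return 100.0 * suv / (1000.0 * body_weight_kg)


@dataclass(frozen=True)
class Tac:
    """A time–activity curve in the three equivalent scales used downstream."""

    times_h: tuple[float, ...]
    pctia_per_ml: tuple[float, ...]
    pctia_total: tuple[float, ...]
    activity_mbq: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.times_h)
        if not (len(self.pctia_per_ml) == len(self.pctia_total) == len(self.activity_mbq) == n):
            raise ValueError("TAC arrays must have equal length")
        if any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValueError("TAC times must be strictly increasing")
        if any(v < 0 for arr in (self.pctia_per_ml, self.pctia_total, self.activity_mbq) for v in arr):
            raise ValueError("TAC values must be non-negative")


def build_tac(
    series,
    body_weight_kg: Optional[float],
    uptake_volume_ml: Optional[float],
    administered_activity_mbq: Optional[float],
) -> Tac:
    """Build a lesion TAC from a measurement series plus patient metadata.

    ``series`` is a :class:`~ssia_dosekit.cohort_io.RouteSeries`; only scans
    with a tumour value contribute points.  Times convert minutes to hours.
    """
    for name, v in (
        ("body_weight_kg", body_weight_kg),
        ("uptake_volume_ml", uptake_volume_ml),
        ("administered_activity_mbq", administered_activity_mbq),
    ):
        if v is None:
            raise ValueError(f"missing metadata field {name!r} required to build a TAC")
    ms = [m for m in series.measurements if m.has_tumour_value]
    times = tuple(m.time_min / 60.0 for m in ms)
    per_ml = tuple(suv_to_pctia_per_ml(m.suv_max_tumour, body_weight_kg) for m in ms)
    total = tuple(v * uptake_volume_ml for v in per_ml)
    act = tuple(v / 100.0 * administered_activity_mbq for v in total)
    return Tac(times_h=times, pctia_per_ml=per_ml, pctia_total=total, activity_mbq=act)


@dataclass(frozen=True)
class ExponentialFit:
    """A fitted two-parameter exponential TAC model.

    ``a0`` is the t=0 activity for ``mono_decay`` and the plateau for
    ``one_phase_association``; its unit follows whatever the fitted series
    was expressed in.  ``lambda_biol`` is per hour.
    """

    model: str
    a0: float
    lambda_biol: float
    sse: float
    n_points: int

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.a0 < 0 or self.lambda_biol < 0:
            raise ValueError("a0 and lambda_biol must be non-negative")

    def value(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self.model == MODEL_DECAY:
            out = self.a0 * np.exp(-self.lambda_biol * t)
        else:
            out = self.a0 * (1.0 - np.exp(-self.lambda_biol * t))
        return out if out.ndim else float(out)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _model_values(model: str, t: np.ndarray, a0: float, lam: float) -> np.ndarray:
    if model == MODEL_DECAY:
        return a0 * np.exp(-lam * t)
    return a0 * (1.0 - np.exp(-lam * t))


_LAMBDA_STARTS = (0.01, 0.1, 1.0)


def _fit_single(times: np.ndarray, values: np.ndarray, model: str) -> ExponentialFit:
    """Multi-start bounded least squares for one model."""
    vmax = float(np.max(values))
    if vmax == 0.0:
        return ExponentialFit(model=model, a0=0.0, lambda_biol=0.0, sse=0.0, n_points=len(times))
    a0_starts = {max(values[0], 1e-12), max(values[-1], 1e-12), vmax}

    def residuals(p):
        return _model_values(model, times, p[0], p[1]) - values

    best = None
    # a fit this close to machine precision cannot be improved by more starts
    perfect_sse = (1e-12 * vmax) ** 2 * len(times)
    diagnostics = []
    for a0 in a0_starts:
        for lam in _LAMBDA_STARTS:
            try:
                res = least_squares(
                    residuals,
                    x0=[a0, lam],
                    bounds=([0.0, 0.0], [np.inf, np.inf]),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception as exc:  # pragma: no cover - defensive
                diagnostics.append(f"start ({a0:g}, {lam:g}): {exc}")
                continue
            sse = float(np.sum(res.fun**2))
            if res.success and (best is None or sse < best[0]):
                best = (sse, res.x)
            diagnostics.append(f"start ({a0:g}, {lam:g}): sse={sse:.3e} success={res.success}")
            if best is not None and best[0] <= perfect_sse:
                break
        else:
            continue
        break
    if best is None:
        raise FitError(f"{model} fit failed from every start:\n" + "\n".join(diagnostics))
    sse, (a0, lam) = best
    return ExponentialFit(model=model, a0=float(a0), lambda_biol=float(lam), sse=sse, n_points=len(times))


def fit_tac(
    times_h: Sequence[float],
    values: Sequence[float],
    model: Optional[str] = None,
) -> ExponentialFit:
    """Fit a TAC with a washout or uptake exponential (or auto-select).

    Auto-selection fits both models and keeps the one with the lower sum of
    squared errors; exact ties break toward ``mono_decay`` when the series
    ends below where it starts and toward the association model otherwise.
    """
    times = np.asarray(times_h, dtype=float)
    vals = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != vals.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if len(times) < 2:
        raise ValueError("need at least 2 points to fit a two-parameter model")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if model is not None:
        if model not in _MODELS:
            raise ValueError(f"unknown model {model!r}; expected one of {_MODELS}")
        return _fit_single(times, vals, model)
    decay = _fit_single(times, vals, MODEL_DECAY)
    assoc = _fit_single(times, vals, MODEL_ASSOCIATION)
    if decay.sse == assoc.sse:
        return decay if vals[-1] < vals[0] else assoc
    return decay if decay.sse < assoc.sse else assoc


def find_teq(
    fit_ia: ExponentialFit,
    fit_iv: ExponentialFit,
    horizon_h: float = 14 * 24.0,
) -> Optional[float]:
    """First t > 0 where the IA washout curve meets the IV uptake curve.

    Returns None when the curves do not cross within ``horizon_h`` (for
    instance a non-clearing IA plateau that stays above the IV plateau), or
    when the IA curve does not start meaningfully above the IV curve: a
    crossover below ~1e-6 h means there is no advantage period at all, and
    treating it as a real T_eq would spuriously freeze a negligible uptake
    into pure physical decay.
    """
    if fit_ia.model != MODEL_DECAY:
        raise ValueError("fit_ia must be a mono_decay fit")
    if fit_iv.model != MODEL_ASSOCIATION:
        raise ValueError("fit_iv must be a one_phase_association fit")
    if fit_ia.a0 <= fit_iv.value(0.0):
        return None

    def gap(t: float) -> float:
        return fit_ia.value(t) - fit_iv.value(t)

    # bracket the first sign change on a geometric-ish grid, then refine
    grid = np.linspace(0.0, horizon_h, 4097)
    g = fit_ia.a0 * np.exp(-fit_ia.lambda_biol * grid) - fit_iv.a0 * (
        1.0 - np.exp(-fit_iv.lambda_biol * grid)
    )
    sign_change = np.nonzero((g[:-1] > 0) & (g[1:] <= 0))[0]
    if len(sign_change) == 0:
        return None
    i = sign_change[0]
    if g[i + 1] == 0.0:
        return float(grid[i + 1])
    root = brentq(gap, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-15)
    if root < 1e-6:
        return None
    log.debug("T_eq = %.6f h", root)
    return float(root)
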