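"""Bounded least-squares fitting of the core-triple-shell (+peak) model.

The fit minimises the weighted squared deviation between a measured 1D
scattering curve and the polydisperse core-triple-shell model, optionally
combined with the Gaussian quasi-Bragg peak.  Convention for real LNP data,
where several of the model's parameters cannot be resolved: the solvent SLD
is pinned at 0, the headgroup-layer thickness t2 at 0.3 nm and the PEG-layer
thickness t3 at 4 nm; the core SLD is also pinned because the overall scale
factor already absorbs one contrast degree of freedom.

Optimisation is bounded trust-region nonlinear least squares (lmfit's
``least_squares`` backend); parameter standard errors come from the
Jacobian-based covariance at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import lmfit
import numpy as np
import pandas as pd

from .model import (
    GaussianPeakParams,
    LNPModelParams,
    ScatteringCurve,
    ShellStack,
    d_spacing,
    intensity_polydisperse,
    polydispersity_index,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "BatchResult",
    "IdentifiabilityError",
    "initial_guess",
    "make_initial_from_truth",
    "fit_curve",
    "derive_metrics",
    "batch_fit",
    "write_fit_report",
]

PARAM_NAMES = (
    "sigma",
    "Rc0",
    "t1",
    "t2",
    "t3",
    "rho_c",
    "rho_1",
    "rho_2",
    "rho_3",
    "rho_s",
    "scale",
    "background",
    "peak_amplitude",
    "peak_center",
    "peak_width",
)
SLD_NAMES = ("rho_c", "rho_1", "rho_2", "rho_3", "rho_s")
PEAK_NAMES = ("peak_amplitude", "peak_center", "peak_width")

# Bounds spanning all fitted values reported for LNP systems, with margin.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "sigma": (0.1, 10.0),
    "Rc0": (5.0, 100.0),
    "t1": (0.5, 6.0),
    "t2": (0.0, 2.0),
    "t3": (0.0, 10.0),
    "rho_c": (-0.01, 0.01),
    "rho_1": (-0.01, 0.01),
    "rho_2": (-0.01, 0.01),
    "rho_3": (-0.01, 0.01),
    "rho_s": (-0.01, 0.01),
    "scale": (1e-8, 1e8),
    "background": (0.0, 1e4),
    "peak_amplitude": (0.0, 1e4),
    "peak_center": (0.8, 2.0),
    "peak_width": (0.05, 1.0),
}

# Fixed-parameter convention for real LNP curves.
DEFAULT_FIXED = {"rho_s": 0.0, "t3": 4.0, "t2": 0.3}

# First zero of the uniform-sphere shape function, q*R ~ 4.4934.
_FIRST_SPHERE_ZERO = 4.4934095


class IdentifiabilityError(ValueError):
    """Raised when the requested free-parameter set is structurally degenerate."""


@dataclass
class FitConfig:
    """What to fit and how.

    free_params and fixed_params must be disjoint; any parameter in neither
    is held at its initial value.  weights_mode 'auto' resolves to
    'reported-uncertainty' when the curve carries an error column, else
    'proportional' (w = 1/I, equalising decades on log-scale data).
    """

    free_params: tuple[str, ...]
    fixed_params: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED))
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    weights_mode: str = "auto"
    max_evaluations: int = 20000
    n_starts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.free_params = tuple(self.free_params)
        unknown = set(self.free_params) | set(self.fixed_params) - set(PARAM_NAMES)
        unknown -= set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        overlap = set(self.free_params) & set(self.fixed_params)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        if self.weights_mode not in (
            "auto",
            "reported-uncertainty",
            "proportional",
            "unweighted",
        ):
            raise ValueError(f"unknown weights_mode {self.weights_mode!r}")
        if self.max_evaluations < 1:
            raise ValueError("max_evaluations must be positive")
        for name in self.free_params:
            lo, hi = self.bound(name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"free parameter {name} needs finite bounds")
        if "scale" in self.free_params:
            free_slds = [n for n in SLD_NAMES if n in self.free_params]
            if len(free_slds) == len(SLD_NAMES):
                raise IdentifiabilityError(
                    "scale and all five SLDs cannot be simultaneously free; "
                    "pin at least one SLD (e.g. rho_s=0)"
                )

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])

    @property
    def with_peak(self) -> bool:
        names = set(self.free_params) | set(self.fixed_params)
        return bool(names & set(PEAK_NAMES))

    @classmethod
    def for_params(cls, params: LNPModelParams, **kwargs) -> "FitConfig":
        """Standard recovery configuration for a given truth: sigma, R0, t1,
        the three shell SLDs, scale and background free (plus the peak trio
        when the truth carries a peak); solvent SLD, t2, t3 and the core SLD
        fixed at the truth values."""
        free = ["sigma", "Rc0", "t1", "rho_1", "rho_2", "rho_3", "scale", "background"]
        fixed = {
            "rho_s": params.shells.rho_s,
            "t2": params.shells.t2,
            "t3": params.shells.t3,
            "rho_c": params.shells.rho_c,
        }
        if params.peak is not None:
            free += list(PEAK_NAMES)
        return cls(free_params=tuple(free), fixed_params=fixed, **kwargs)


@dataclass
class FitResult:
    """Fitted parameters with uncertainties, fit quality and derived metrics."""

    params: LNPModelParams
    uncertainties: dict[str, Optional[float]]
    reduced_chi2: float
    initial_reduced_chi2: float
    converged: bool
    n_evaluations: int
    residuals: np.ndarray
    config: FitConfig
    derived: dict[str, float] = field(default_factory=dict)
    message: str = ""


def params_to_dict(params: LNPModelParams) -> dict[str, float]:
    sh = params.shells
    out = {
        "sigma": sh.sigma,
        "Rc0": sh.Rc0,
        "t1": sh.t1,
        "t2": sh.t2,
        "t3": sh.t3,
        "rho_c": sh.rho_c,
        "rho_1": sh.rho_1,
        "rho_2": sh.rho_2,
        "rho_3": sh.rho_3,
        "rho_s": sh.rho_s,
        "scale": params.scale,
        "background": params.background,
    }
    if params.peak is not None:
        out["peak_amplitude"] = params.peak.amplitude
        out["peak_center"] = params.peak.center
        out["peak_width"] = params.peak.width
    return out


def dict_to_params(values: Mapping[str, float], with_peak: bool) -> LNPModelParams:
    shells = ShellStack(
        Rc0=values["Rc0"],
        sigma=max(values["sigma"], 0.0),
        t1=values["t1"],
        t2=values["t2"],
        t3=values["t3"],
        rho_c=values["rho_c"],
        rho_1=values["rho_1"],
        rho_2=values["rho_2"],
        rho_3=values["rho_3"],
        rho_s=values["rho_s"],
    )
    peak = None
    if with_peak:
        peak = GaussianPeakParams(
            amplitude=max(values["peak_amplitude"], 0.0),
            center=values["peak_center"],
            width=values["peak_width"],
        )
    return LNPModelParams(
        shells=shells,
        peak=peak,
        scale=max(values["scale"], 1e-300),
        background=max(values["background"], 0.0),
    )


def initial_guess(curve: ScatteringCurve, with_peak: bool = False) -> LNPModelParams:
    """Heuristic starting values from the curve itself.

    The core radius is read off the first form-factor minimum: the first
    windowed local minimum of I q^4 below q = 0.5 nm^-1 is mapped through
    the uniform-sphere first zero (q R ~ 4.493) to the radius of the
    dominant scattering interface, then reduced by the nominal t1 + t2 so
    the guess refers to the core.  The background is the median intensity of
    the top-q decile, and the peak center (when requested) the argmax of the
    background-subtracted intensity on 1-2 nm^-1.  When no oscillation
    minimum is detectable the guess falls back to documented defaults and
    the returned object carries ``low_confidence = True``.
    """
    q, inten = curve.q, curve.intensity
    bg = float(np.median(inten[q >= np.quantile(q, 0.9)]))

    low_confidence = False
    y = inten * q**4
    window = 5
    min_idx = None
    for i in range(window, y.size - window):
        if q[i] > 0.5:
            break
        seg = y[i - window : i + window + 1]
        if y[i] == seg.min() and np.sum(seg == seg.min()) == 1:
            min_idx = i
            break
    if min_idx is not None:
        r_interface = _FIRST_SPHERE_ZERO / q[min_idx]
        r0 = max(r_interface - 2.3, 5.0)  # nominal t1 + t2 ride on the core
    else:
        r0 = 25.0
        low_confidence = True

    values = {
        "sigma": 0.1 * r0,
        "Rc0": r0,
        "t1": 2.0,
        "t2": 0.3,
        "t3": 4.0,
        "rho_c": 0.01,
        "rho_1": -0.01,
        "rho_2": 0.01,
        "rho_3": 0.001,
        "rho_s": 0.0,
        "scale": 1.0,
        "background": max(bg, 0.0),
    }
    if with_peak:
        sel = (q >= 1.0) & (q <= 2.0)
        if np.any(sel):
            resid = inten[sel] - bg
            # 7-point moving average so a single noisy point cannot set the center
            if resid.size >= 7:
                kernel = np.ones(7) / 7.0
                smooth = np.convolve(resid, kernel, mode="same")
            else:
                smooth = resid
            center = float(q[sel][int(np.argmax(smooth))])
            amp = max(float(np.max(smooth)), 1e-6 * float(np.max(inten)))
        else:
            center, amp = 1.2, 0.1 * bg + 1e-12
            low_confidence = True
        values["peak_amplitude"] = amp
        values["peak_center"] = min(max(center, 0.85), 1.95)
        values["peak_width"] = 0.3

    # calibrate scale so the model matches the data at low q
    trial = dict_to_params(values, with_peak)
    model_low = intensity_polydisperse(q[:5], trial)
    ratio = np.median(inten[:5] / np.maximum(model_low, 1e-300))
    values["scale"] = max(float(ratio), 1e-8)

    guess = dict_to_params(values, with_peak)
    guess.low_confidence = low_confidence  # type: ignore[attr-defined]
    return guess


def make_initial_from_truth(
    params: LNPModelParams, relative: float = 0.10, seed: int = 0
) -> LNPModelParams:
    """Truth perturbed by independent uniform relative factors in
    +-relative — the standard starting point of a recovery experiment."""
    values = params_to_dict(params)
    rng = np.random.default_rng(seed)
    perturb = (
        "sigma",
        "Rc0",
        "t1",
        "rho_1",
        "rho_2",
        "rho_3",
        "scale",
        "background",
        "peak_amplitude",
        "peak_center",
        "peak_width",
    )
    for name in perturb:
        if name in values and values[name] != 0:
            values[name] *= 1.0 + rng.uniform(-relative, relative)
    return dict_to_params(values, params.peak is not None)


def _reconcile_sld_scale(initial: LNPModelParams, config: FitConfig) -> LNPModelParams:
    """Bring the heuristic initial's SLD set onto the scale of a pinned core SLD.

    SLDs are only defined up to an overall factor that the scale parameter
    absorbs, so a heuristic initial on a different arbitrary-unit scale than
    a fixed rho_c would start the fit with inconsistent contrasts.  Multiply
    the shell SLDs by fixed_rho_c / initial_rho_c and divide scale by the
    square of that factor, leaving the initial model curve unchanged.
    """
    fixed_rho_c = config.fixed_params.get("rho_c")
    if fixed_rho_c is None or fixed_rho_c == 0 or initial.shells.rho_c == 0:
        return initial
    factor = fixed_rho_c / initial.shells.rho_c
    if factor == 1.0:
        return initial
    values = params_to_dict(initial)
    for name in ("rho_c", "rho_1", "rho_2", "rho_3", "rho_s"):
        values[name] *= factor
    values["scale"] /= factor**2
    return dict_to_params(values, initial.peak is not None)


def _weights(curve: ScatteringCurve, mode: str) -> np.ndarray:
    if mode == "auto":
        mode = "reported-uncertainty" if curve.uncertainty is not None else "proportional"
    if mode == "reported-uncertainty":
        if curve.uncertainty is None:
            raise ValueError("curve has no uncertainty column")
        return 1.0 / curve.uncertainty
    if mode == "proportional":
        return 1.0 / np.maximum(curve.intensity, 1e-300)
    return np.ones_like(curve.intensity)


def _build_lmfit_params(
    config: FitConfig, initial: Mapping[str, float]
) -> lmfit.Parameters:
    params = lmfit.Parameters()
    names = list(config.free_params) + list(config.fixed_params)
    for name in PARAM_NAMES:
        if name in PEAK_NAMES and not config.with_peak:
            continue
        lo, hi = config.bound(name)
        if name in config.fixed_params:
            params.add(name, value=float(config.fixed_params[name]), vary=False)
        elif name in config.free_params:
            value = float(np.clip(initial[name], lo, hi))
            # strictly interior start so the trust region can move both ways
            span = hi - lo
            value = float(np.clip(value, lo + 1e-12 * span, hi - 1e-12 * span))
            params.add(name, value=value, min=lo, max=hi)
        else:
            params.add(name, value=float(initial.get(name, 0.0)), vary=False)
    return params


def fit_curve(
    curve: ScatteringCurve,
    config: FitConfig,
    initial: Optional[LNPModelParams] = None,
) -> FitResult:
    """Weighted bounded least-squares fit of the model to one curve.

    Deterministic given (curve, config, initial, config.seed).  With
    ``config.n_starts > 1`` the initial point is additionally perturbed
    n_starts-1 times (seeded) and the best final objective wins.
    Non-convergence is reported via ``FitResult.converged``, not raised.
    """
    if not config.free_params:
        raise ValueError("at least one parameter must be free")
    if len(curve) <= len(config.free_params):
        raise ValueError("curve must have more points than free parameters")
    if initial is None:
        initial = initial_guess(curve, with_peak=config.with_peak)
        initial = _reconcile_sld_scale(initial, config)
    init_values = params_to_dict(initial)
    for name in PEAK_NAMES:
        if config.with_peak and name not in init_values:
            lo, hi = config.bound(name)
            init_values[name] = 0.5 * (lo + hi)

    weights = _weights(curve, config.weights_mode)
    q = curve.q

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = intensity_polydisperse(q, dict_to_params(p.valuesdict(), config.with_peak))
        return (curve.intensity - model) * weights

    starts = [dict(init_values)]
    if config.n_starts > 1:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.n_starts - 1):
            alt = dict(init_values)
            for name in config.free_params:
                if alt.get(name, 0.0) != 0.0:
                    alt[name] *= 1.0 + rng.uniform(-0.2, 0.2)
            starts.append(alt)

    best = None
    for start in starts:
        lmpars = _build_lmfit_params(config, start)
        minimizer = lmfit.Minimizer(residual, lmpars)
        try:
            out = minimizer.minimize(
                method="least_squares", max_nfev=config.max_evaluations
            )
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError("all fit starts failed with non-finite model values")

    init_resid = residual(_build_lmfit_params(config, init_values))
    dof = max(len(curve) - len(config.free_params), 1)

    fitted_values = best.params.valuesdict()
    fitted = dict_to_params(fitted_values, config.with_peak)
    uncertainties = {
        name: (best.params[name].stderr if best.params[name].stderr else None)
        for name in config.free_params
    }
    result = FitResult(
        params=fitted,
        uncertainties=uncertainties,
        reduced_chi2=float(best.chisqr) / dof,
        initial_reduced_chi2=float(np.sum(init_resid**2)) / dof,
        converged=bool(best.success),
        n_evaluations=int(best.nfev),
        residuals=np.asarray(best.residual),
        config=config,
        message=str(getattr(best, "message", "")),
    )
    return derive_metrics(result)


def derive_metrics(result: FitResult) -> FitResult:
    """Fill the derived structural metrics: sigma/R0 always, and the repeat
    distance d = 2 pi / C when a peak was fitted.  Idempotent."""
    sh = result.params.shells
    result.derived["sigma_over_R0"] = polydispersity_index(sh.sigma, sh.Rc0)
    if result.params.peak is not None:
        result.derived["d_spacing_nm"] = d_spacing(result.params.peak.center)
    return result


# Column order of the standard structural-parameter table.
TABLE_COLUMNS = [
    "sigma",
    "R0",
    "t1",
    "rho_1",
    "rho_2",
    "rho_3",
    "C_Gaussian",
    "W_Peak",
]


@dataclass
class BatchResult:
    table: pd.DataFrame
    results: dict[str, FitResult]
    failures: dict[str, str]


def batch_fit(
    curves: Mapping[str, ScatteringCurve],
    config: FitConfig,
    initials: Optional[Mapping[str, LNPModelParams]] = None,
) -> BatchResult:
    """Fit every tagged curve; per-curve failures are recorded and the batch
    continues.  The summary table follows the standard column order
    (sigma, R0, t1, rho_1, rho_2, rho_3, C, W)."""
    rows = {}
    results: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for tag, curve in curves.items():
        try:
            initial = initials.get(tag) if initials else None
            res = fit_curve(curve, config, initial)
        except Exception as exc:
            failures[tag] = str(exc)
            continue
        results[tag] = res
        sh = res.params.shells
        row = {
            "sigma": sh.sigma,
            "R0": sh.Rc0,
            "t1": sh.t1,
            "rho_1": sh.rho_1,
            "rho_2": sh.rho_2,
            "rho_3": sh.rho_3,
            "C_Gaussian": res.params.peak.center if res.params.peak else np.nan,
            "W_Peak": res.params.peak.width if res.params.peak else np.nan,
            "reduced_chi2": res.reduced_chi2,
            "converged": res.converged,
        }
        rows[tag] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table = table[TABLE_COLUMNS + ["reduced_chi2", "converged"]]
    else:
        table = pd.DataFrame(columns=TABLE_COLUMNS + ["reduced_chi2", "converged"])
    return BatchResult(table=table, results=results, failures=failures)


def write_fit_report(result: FitResult, path) -> None:
    """Serialise one fit as JSON: parameters, uncertainties, fit quality and
    derived metrics."""
    payload = {
        "parameters": params_to_dict(result.params),
        "uncertainties": result.uncertainties,
        "reduced_chi2": result.reduced_chi2,
        "converged": result.converged,
        "n_evaluations": result.n_evaluations,
        "derived": result.derived,
        "free_params": list(result.config.free_params),
        "fixed_params": result.config.fixed_params,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
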