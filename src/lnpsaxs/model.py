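"""Core-triple-shell scattering model for lipid nanoparticles.

A lipid nanoparticle (LNP) is modelled as a spherical core of radius ``Rc``
wrapped in three concentric shells: the inner lipid layer (thickness ``t1``),
the hydrophilic headgroup layer (``t2``) and the hydrated PEG corona (``t3``).
Each region carries a uniform scattering length density (SLD); only contrasts
against the solvent SLD ``rho_s`` are observable, so SLDs are kept in
arbitrary units with the solvent conventionally at zero.

The single-particle amplitude is the telescoping sum of four uniform-sphere
amplitudes weighted by the SLD steps across the interfaces::

    A(q) = (rho_c - rho_1) V(Rc)      j(q Rc)
         + (rho_1 - rho_2) V(Rc+t1)   j(q (Rc+t1))
         + (rho_2 - rho_3) V(Rc+t1+t2) j(q (Rc+t1+t2))
         + (rho_3 - rho_s) V(Rc+t1+t2+t3) j(q (Rc+t1+t2+t3))

with V(R) = (4/3) pi R^3 and j(x) = 3 (sin x - x cos x) / x^3.

Size polydispersity enters through a Gaussian distribution of the core radius
(mean ``Rc0``, standard deviation ``sigma``); the shell thicknesses ride
rigidly on the core.  The measured intensity is the number-weighted average
of A(q)^2 over that distribution, plus an optional Gaussian quasi-Bragg peak
describing the quasi-periodic mRNA/ionizable-lipid packing, plus a flat
background.

All lengths are in nm and momentum transfer q in nm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats

__all__ = [
    "ScatteringCurve",
    "ShellStack",
    "GaussianPeakParams",
    "LNPModelParams",
    "sphere_shape",
    "sphere_volume",
    "amplitude",
    "forward_amplitude",
    "size_distribution",
    "intensity_polydisperse",
    "quasi_bragg_peak",
    "d_spacing",
    "polydispersity_index",
    "contrast_change",
]

# Below this argument the closed form of j(x) loses precision to cancellation;
# the even Taylor series is exact to ~1e-16 there.
_SPHERE_SHAPE_SERIES_CUTOFF = 1e-2

# sigma below this (nm) is treated as monodisperse.
_MONODISPERSE_SIGMA = 0.0


@dataclass
class ScatteringCurve:
    """A 1D reduced SAXS curve: q (nm^-1), intensity, optional uncertainty."""

    q: np.ndarray
    intensity: np.ndarray
    uncertainty: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("q and intensity must be one-dimensional")
        if self.q.size != self.intensity.size:
            raise ValueError("q and intensity must have equal length")
        if self.q.size < 2:
            raise ValueError("a curve needs at least 2 points")
        if not np.all(self.q > 0):
            raise ValueError("all q must be positive")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if self.uncertainty.shape != self.q.shape:
                raise ValueError("uncertainty must match q in length")
            if not np.all(self.uncertainty > 0):
                raise ValueError("uncertainty entries must be positive")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class ShellStack:
    """Geometry and SLDs of the polydisperse core plus three shells.

    Rc0/sigma are the mean and standard deviation of the Gaussian core-radius
    distribution; t1..t3 the shell thicknesses (inner lipid layer, headgroup
    layer, PEG corona); rho_* the SLDs of core, shells and solvent in
    arbitrary units.
    """

    Rc0: float = 25.0
    sigma: float = 0.0
    t1: float = 2.0
    t2: float = 0.3
    t3: float = 4.0
    rho_c: float = 0.01
    rho_1: float = -0.01
    rho_2: float = 0.01
    rho_3: float = 0.001
    rho_s: float = 0.0

    def __post_init__(self) -> None:
        if self.Rc0 <= 0:
            raise ValueError("Rc0 must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        for name in ("t1", "t2", "t3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("rho_c", "rho_1", "rho_2", "rho_3", "rho_s"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def contrasts(self) -> np.ndarray:
        """SLD steps across the four interfaces, inside minus outside."""
        return np.array(
            [
                self.rho_c - self.rho_1,
                self.rho_1 - self.rho_2,
                self.rho_2 - self.rho_3,
                self.rho_3 - self.rho_s,
            ]
        )

    def radii(self, Rc: float | np.ndarray) -> np.ndarray:
        """Outer radii of core and shells for core radius Rc; shape (4, ...)."""
        Rc = np.asarray(Rc, dtype=float)
        return np.stack(
            [
                Rc,
                Rc + self.t1,
                Rc + self.t1 + self.t2,
                Rc + self.t1 + self.t2 + self.t3,
            ]
        )


@dataclass
class GaussianPeakParams:
    """Gaussian quasi-Bragg peak: amplitude, center (nm^-1), width = Gaussian
    standard deviation (nm^-1)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")
        if self.center <= 0:
            raise ValueError("peak center must be positive")
        if self.width <= 0:
            raise ValueError("peak width must be positive")


@dataclass
class LNPModelParams:
    """Full forward-model parameter set: geometry + optional peak + scale + Bg.

    ``scale`` absorbs the particle number density n together with the overall
    contrast magnitude (only their product is identifiable from
    relative-intensity data); ``background`` is the flat additive term.
    """

    shells: ShellStack
    peak: Optional[GaussianPeakParams] = None
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")


def sphere_shape(x: float | np.ndarray) -> float | np.ndarray:
    """Sphere shape function j(x) = 3 (sin x - x cos x) / x^3, with j(0) = 1.

    Switches to the Taylor series 1 - x^2/10 + x^4/280 below x = 1e-2 to
    avoid catastrophic cancellation.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    small = x < _SPHERE_SHAPE_SERIES_CUTOFF
    xs = np.where(small, 1.0, x)  # dummy to avoid 0/0 warnings
    closed = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    x2 = x * x
    series = 1.0 - x2 / 10.0 + x2 * x2 / 280.0
    out = np.where(small, series, closed)
    return out.item() if out.ndim == 0 else out


def sphere_volume(R: float | np.ndarray) -> float | np.ndarray:
    """Volume of a sphere, (4/3) pi R^3."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("radius must be non-negative")
    out = 4.0 / 3.0 * np.pi * R**3
    return out.item() if out.ndim == 0 else out


def amplitude(
    q: float | np.ndarray, Rc: float | np.ndarray, shells: ShellStack
) -> np.ndarray:
    """Scattering amplitude A(q) of one core-triple-shell particle.

    ``Rc`` is the explicit core radius of this particle (not the distribution
    mean).  Broadcasts q against Rc: with q of shape (nq,) and Rc of shape
    (nr,), returns shape (nr, nq).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("q must be positive (the q=0 delta term is excluded)")
    radii = shells.radii(Rc)  # (4,) or (4, nr)
    contrasts = shells.contrasts
    if radii.ndim == 1:
        x = q[None, :] * radii[:, None]  # (4, nq)
        terms = contrasts[:, None] * sphere_volume(radii)[:, None] * sphere_shape(x)
        return terms.sum(axis=0)
    x = radii[:, :, None] * q[None, None, :]  # (4, nr, nq)
    vols = sphere_volume(radii)  # (4, nr)
    terms = contrasts[:, None, None] * vols[:, :, None] * sphere_shape(x)
    return terms.sum(axis=0)


def forward_amplitude(Rc: float, shells: ShellStack) -> float:
    """q -> 0 limit of the amplitude: sum of contrast * volume over interfaces."""
    radii = shells.radii(Rc)
    return float(np.sum(shells.contrasts * sphere_volume(radii)))


def size_distribution(
    Rc: float | np.ndarray, Rc0: float, sigma: float, n: float = 1.0
) -> float | np.ndarray:
    """Gaussian number density of core radii, n-normalised.

    N(Rc) = n / (sigma sqrt(2 pi)) * exp(-(Rc - Rc0)^2 / (2 sigma^2)).
    A zero sigma is rejected: callers must take the monodisperse path.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive; use the monodisperse path for sigma=0")
    out = n * stats.norm.pdf(np.asarray(Rc, dtype=float), loc=Rc0, scale=sigma)
    return out.item() if out.ndim == 0 else out


def _quadrature_nodes(Rc0: float, sigma: float, n_nodes: int, n_sigma: float):
    lo = max(1e-3, Rc0 - n_sigma * sigma)
    hi = Rc0 + n_sigma * sigma
    x, w = leggauss(n_nodes)
    half = 0.5 * (hi - lo)
    return lo + half * (x + 1.0), w * half


def intensity_polydisperse(
    q: np.ndarray,
    params: LNPModelParams,
    n_nodes: int = 201,
    n_sigma: float = 6.0,
) -> np.ndarray:
    """Model intensity I(q): polydispersity-averaged amplitude squared,
    plus the quasi-Bragg peak when present, plus the flat background.

    The size average is a fixed Gauss-Legendre quadrature with ``n_nodes``
    nodes on [max(1e-3, Rc0 - n_sigma*sigma), Rc0 + n_sigma*sigma]; the
    clipped negative-radius tail is simply truncated (its mass is < 1e-8 for
    all relevant sigma/Rc0 <= 0.3).  With sigma = 0 the monodisperse closed
    form scale * A(q)^2 + peak + Bg is used.
    """
    q = np.asarray(q, dtype=float)
    sh = params.shells
    if sh.sigma <= _MONODISPERSE_SIGMA:
        form = params.scale * amplitude(q, sh.Rc0, sh) ** 2
    else:
        nodes, weights = _quadrature_nodes(sh.Rc0, sh.sigma, n_nodes, n_sigma)
        pdf = size_distribution(nodes, sh.Rc0, sh.sigma)
        a = amplitude(q, nodes, sh)  # (n_nodes, nq)
        form = params.scale * np.einsum("i,ij->j", weights * pdf, a**2)
    out = form + params.background
    if params.peak is not None:
        out = out + quasi_bragg_peak(q, params.peak)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite intensity: invalid parameters")
    return out


def quasi_bragg_peak(
    q: float | np.ndarray, peak: GaussianPeakParams
) -> float | np.ndarray:
    """Gaussian quasi-Bragg contribution A_p exp(-(q - C)^2 / (2 W^2)).

    W is the Gaussian standard deviation (not the FWHM).
    """
    q = np.asarray(q, dtype=float)
    out = peak.amplitude * np.exp(-((q - peak.center) ** 2) / (2.0 * peak.width**2))
    return out.item() if out.ndim == 0 else out


def d_spacing(center: float) -> float:
    """Repeat distance of the quasi-periodic packing, d = 2 pi / center (nm)."""
    if center <= 0:
        raise ValueError("peak center must be positive")
    return 2.0 * np.pi / center


def polydispersity_index(sigma: float, Rc0: float) -> float:
    """Relative size spread sigma / Rc0 of the core-radius distribution."""
    if Rc0 <= 0:
        raise ValueError("Rc0 must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return sigma / Rc0


def contrast_change(value_a: float, value_b: float) -> float:
    """Signed percent reduction of b relative to a: 100 (a - b) / a."""
    if value_a == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (value_a - value_b) / value_a
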