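"""Ensemble light-scattering analysis: cumulant fits and PSD reweighting.

Dynamic light scattering measures the intensity autocorrelation

.. math::

    g_2(\\tau) = 1 + \\beta\\,|g_1(\\tau)|^2, \\qquad
    g_1(\\tau) = \\sum_i w_i e^{-q^2 D_i \\tau},

where :math:`w_i` are intensity weights, :math:`D_i = k_B T / (3\\pi\\eta d_i)`
is the Stokes–Einstein diffusion coefficient of a particle of hydrodynamic
diameter :math:`d_i`, and :math:`q = (4\\pi \\hat n/\\lambda)\\sin(\\theta/2)`
is the scattering vector.  The second-order cumulant expansion

.. math::

    \\tfrac12 \\ln\\frac{g_2 - 1}{\\beta}
        \\simeq c_0 - \\bar\\Gamma\\tau + \\tfrac{\\mu_2}{2}\\tau^2

yields the Z-average diameter (the intensity-weighted harmonic-mean
hydrodynamic diameter, via :math:`\\bar\\Gamma = q^2 \\bar D`) and the
polydispersity index :math:`\\mathrm{PDI} = \\mu_2/\\bar\\Gamma^2`; a PDI
near 0.05 indicates a highly monodisperse sample.

Intensity, number and volume particle-size distributions are related in
the Rayleigh regime by :math:`I \\propto N d^6` and :math:`V \\propto N d^3`;
:func:`reweight_psd` converts between them on a fixed diameter grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BOLTZMANN_J_PER_K",
    "WEIGHTINGS",
    "DlsError",
    "FitFailureError",
    "DegenerateDistributionError",
    "SizeDistribution",
    "InstrumentParams",
    "Correlogram",
    "CumulantModel",
    "CumulantFit",
    "cumulant_fit",
    "stokes_einstein_diffusion",
    "hydrodynamic_diameter",
    "scattering_vector",
    "reweight_psd",
    "psd_mode",
    "lognormal_psd",
]

BOLTZMANN_J_PER_K = 1.380649e-23

WEIGHTINGS = ("intensity", "number", "volume")
# Rayleigh-regime exponent of d relative to the number weighting.
_WEIGHT_EXPONENT = {"number": 0, "volume": 3, "intensity": 6}


class DlsError(ValueError):
    pass


class FitFailureError(RuntimeError):
    """Correlogram does not decay, or the decay rate fits non-positive."""


class DegenerateDistributionError(DlsError):
    """All weight vanished, e.g. after a reweighting of a point mass at 0."""


@dataclass(frozen=True)
class SizeDistribution:
    """A particle-size distribution on a discrete diameter grid.

    ``weights`` are probability masses per grid point under the stated
    ``weighting`` convention (intensity / number / volume); they are
    renormalised on construction, with a warning when they were off by more
    than one part in 1e9.
    """

    diameters_nm: np.ndarray
    weights: np.ndarray
    weighting: str = "intensity"

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_nm, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if self.weighting not in WEIGHTINGS:
            raise DlsError(f"weighting must be one of {WEIGHTINGS}")
        if d.size == 0:
            raise DlsError("empty size distribution")
        if d.shape != w.shape or d.ndim != 1:
            raise DlsError("diameters and weights must be 1-D arrays of equal length")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise DlsError("diameter grid must be positive and strictly increasing")
        if np.any(w < 0):
            raise DlsError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise DegenerateDistributionError("weights sum to zero")
        if abs(total - 1.0) > 1e-9:
            warnings.warn("weights were not normalised; renormalising", stacklevel=2)
        object.__setattr__(self, "diameters_nm", d)
        object.__setattr__(self, "weights", w / total)

    def mean_nm(self) -> float:
        return float(np.sum(self.weights * self.diameters_nm))

    def harmonic_mean_nm(self) -> float:
        return float(1.0 / np.sum(self.weights / self.diameters_nm))


@dataclass(frozen=True)
class InstrumentParams:
    """Optical and solvent parameters of the correlator.

    Defaults reflect a backscatter instrument running aqueous samples at
    4 °C: 173° detection, 633 nm He-Ne illumination, water viscosity
    1.567 mPa·s and refractive index 1.333.
    """

    angle_deg: float = 173.0
    wavelength_nm: float = 633.0
    temperature_k: float = 277.15
    viscosity_mpas: float = 1.567
    refractive_index: float = 1.333

    def __post_init__(self) -> None:
        if not (0 < self.angle_deg <= 180):
            raise DlsError("angle_deg must lie in (0, 180]")
        for name in ("wavelength_nm", "temperature_k", "viscosity_mpas", "refractive_index"):
            if getattr(self, name) <= 0:
                raise DlsError(f"{name} must be > 0")

    @property
    def q_per_m(self) -> float:
        return scattering_vector(self.wavelength_nm, self.refractive_index, self.angle_deg)


@dataclass(frozen=True)
class Correlogram:
    """Measured or simulated intensity autocorrelation ``g2(τ)``."""

    lags_s: np.ndarray
    g2: np.ndarray
    beta: float = 0.8
    instrument: InstrumentParams = field(default_factory=InstrumentParams)

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_s, dtype=float)
        g2 = np.asarray(self.g2, dtype=float)
        if lags.shape != g2.shape or lags.ndim != 1 or lags.size < 3:
            raise DlsError("lags and g2 must be equal-length 1-D arrays, length >= 3")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise DlsError("lag grid must be positive and strictly increasing")
        if self.beta <= 0:
            raise DlsError("beta must be > 0")
        object.__setattr__(self, "lags_s", lags)
        object.__setattr__(self, "g2", g2)


def stokes_einstein_diffusion(
    diameter_nm: float, temperature_k: float, viscosity_mpas: float
):
    """Translational diffusion coefficient, m²/s: ``kB·T / (3π·η·d)``."""
    d = np.asarray(diameter_nm, dtype=float)
    if np.any(d <= 0) or temperature_k <= 0 or viscosity_mpas <= 0:
        raise DlsError("diameter, temperature and viscosity must all be > 0")
    out = BOLTZMANN_J_PER_K * temperature_k / (3.0 * math.pi * viscosity_mpas * 1e-3 * d * 1e-9)
    return float(out) if out.ndim == 0 else out


def hydrodynamic_diameter(
    diffusion_m2_s: float, temperature_k: float, viscosity_mpas: float
) -> float:
    """Inverse Stokes–Einstein: hydrodynamic diameter in nm."""
    if diffusion_m2_s <= 0 or temperature_k <= 0 or viscosity_mpas <= 0:
        raise DlsError("all inputs must be > 0")
    d_m = BOLTZMANN_J_PER_K * temperature_k / (3.0 * math.pi * viscosity_mpas * 1e-3 * diffusion_m2_s)
    return d_m * 1e9


def scattering_vector(wavelength_nm: float, refractive_index: float, angle_deg: float) -> float:
    """Scattering vector magnitude q in 1/m."""
    if not (0 < angle_deg <= 180):
        raise DlsError("angle_deg must lie in (0, 180]")
    if wavelength_nm <= 0 or refractive_index <= 0:
        raise DlsError("wavelength and refractive index must be > 0")
    return (
        4.0 * math.pi * refractive_index / (wavelength_nm * 1e-9)
        * math.sin(math.radians(angle_deg) / 2.0)
    )


@dataclass(frozen=True)
class CumulantFit:
    """Result of a second-order cumulant fit.

    ``z_ave_nm`` is the intensity-weighted harmonic-mean hydrodynamic
    diameter; ``pdi`` is :math:`\\mu_2/\\bar\\Gamma^2`, clamped at 0 (with
    ``pdi_clamped`` set) when the quadratic coefficient fits negative.
    """

    z_ave_nm: float
    pdi: float
    gamma_bar: float
    mu2: float
    fit_rmse: float
    pdi_clamped: bool
    n_points: int
    fit_window: float

    def summary(self) -> str:
        lines = [
            "Cumulant fit (second order)",
            "---------------------------",
            f"Z-average diameter   {self.z_ave_nm:10.2f} nm",
            f"PDI                  {self.pdi:10.4f}" + ("  (clamped at 0)" if self.pdi_clamped else ""),
            f"mean decay rate      {self.gamma_bar:10.4g} 1/s",
            f"second cumulant      {self.mu2:10.4g} 1/s^2",
            f"fit RMSE             {self.fit_rmse:10.3g}",
            f"points in window     {self.n_points:10d}  (threshold {self.fit_window:g})",
        ]
        return "\n".join(lines)


class CumulantModel:
    """Second-order cumulant model for a correlogram.

    The fit window keeps lags where ``(g2 - 1)/beta`` is at least
    ``fit_window`` (default 0.1), avoiding the log-noise blow-up of the
    correlation tail; the least squares is weighted by the squared
    normalised amplitude, the standard counterweight to the log transform.
    An intercept is estimated, so results are invariant to a uniform
    rescaling of the supplied ``beta``.
    """

    def __init__(self, correlogram: Correlogram, fit_window: float = 0.1):
        if not (0 < fit_window < 1):
            raise DlsError("fit_window must lie in (0, 1)")
        self.correlogram = correlogram
        self.fit_window = fit_window

    def fit(self) -> CumulantFit:
        corr = self.correlogram
        amp = (corr.g2 - 1.0) / corr.beta
        mask = amp >= self.fit_window
        if mask.sum() < 3:
            raise FitFailureError(
                "fewer than 3 lags above the fit window; g2 may not decay or may sit below 1"
            )
        tau = corr.lags_s[mask]
        y = 0.5 * np.log(amp[mask])
        design = np.column_stack([np.ones_like(tau), -tau, 0.5 * tau**2])
        w = amp[mask]  # sqrt of amp² weights
        coef, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
        gamma_bar, mu2 = float(coef[1]), float(coef[2])
        if gamma_bar <= 0:
            raise FitFailureError("decay rate fitted non-positive; correlogram does not decay")
        resid = y - design @ coef
        pdi = mu2 / gamma_bar**2
        clamped = pdi < 0
        inst = corr.instrument
        d_bar = gamma_bar / inst.q_per_m**2
        z_ave = hydrodynamic_diameter(d_bar, inst.temperature_k, inst.viscosity_mpas)
        return CumulantFit(
            z_ave_nm=z_ave,
            pdi=max(pdi, 0.0),
            gamma_bar=gamma_bar,
            mu2=mu2,
            fit_rmse=float(np.sqrt(np.mean(resid**2))),
            pdi_clamped=bool(clamped),
            n_points=int(mask.sum()),
            fit_window=self.fit_window,
        )


def cumulant_fit(correlogram: Correlogram, fit_window: float = 0.1) -> CumulantFit:
    """Convenience wrapper: ``CumulantModel(correlogram, fit_window).fit()``."""
    return CumulantModel(correlogram, fit_window).fit()


def reweight_psd(psd: SizeDistribution, target: str) -> SizeDistribution:
    """Convert a PSD between intensity, number and volume weighting.

    Rayleigh-regime algebra on the fixed grid: intensity ∝ number·d⁶,
    volume ∝ number·d³.  Exact inverse under round trips.
    """
    if target not in WEIGHTINGS:
        raise DlsError(f"target weighting must be one of {WEIGHTINGS}")
    if target == psd.weighting:
        return psd
    exponent = _WEIGHT_EXPONENT[target] - _WEIGHT_EXPONENT[psd.weighting]
    w = psd.weights * psd.diameters_nm**exponent
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise DegenerateDistributionError("reweighting produced zero or non-finite total weight")
    return SizeDistribution(psd.diameters_nm, w / total, target)


def psd_mode(psd: SizeDistribution) -> float:
    """Grid diameter of maximum weight; ties resolve to the smallest diameter."""
    return float(psd.diameters_nm[int(np.argmax(psd.weights))])


def lognormal_psd(
    z_ave_nm: float = 122.04,
    pdi: float = 0.045,
    n_points: int = 2001,
    span_sigmas: float = 6.0,
) -> SizeDistribution:
    """Intensity-weighted lognormal PSD with prescribed Z-average and PDI.

    For lognormal intensity weights with log-scale parameters (μ, σ) the
    intensity-weighted harmonic-mean diameter is ``exp(μ - σ²/2)`` and the
    PDI (relative variance of the decay rate) is ``exp(σ²) - 1``, so
    ``σ² = ln(1 + pdi)`` and ``μ = ln(z_ave) + σ²/2``.  Masses are assigned
    on a log-uniform grid, where the lognormal density in log-diameter is a
    plain Gaussian.
    """
    if z_ave_nm <= 0 or pdi < 0:
        raise DlsError("z_ave_nm must be > 0 and pdi >= 0")
    sigma2 = math.log1p(pdi)
    sigma = math.sqrt(max(sigma2, 1e-16))
    mu = math.log(z_ave_nm) + sigma2 / 2.0
    x = np.linspace(mu - span_sigmas * sigma, mu + span_sigmas * sigma, n_points)
    if x[0] == x[-1]:  # pdi == 0: collapse to (nearly) a point mass
        x = np.array([mu - 1e-9, mu, mu + 1e-9])
    w = np.exp(-((x - mu) ** 2) / (2.0 * max(sigma2, 1e-16)))
    return SizeDistribution(np.exp(x), w / w.sum(), "intensity")
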