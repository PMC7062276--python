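"""Synthetic measurement generator for the cross-technique sizing study.

Produces every input the analysis pipeline consumes, without any external
data: per-technique apparent-diameter datasets calibrated to published
group statistics for Pdu microcompartments, ultra-thin-section datasets
derived by actually sectioning a simulated population, DLS correlograms,
and per-particle NTA samples contaminated by a small aggregate
subpopulation.

The shipped calibration (N = 300 per technique as 3 biological replicates
of 100 measurements) is::

    negative-stain TEM        102 ± 17 nm
    TEM + HMDS exchange       124 ± 17 nm
    SEM                       126 ± 17 nm
    cryo-TEM                  138 ± 21 nm
    ultra-thin-section TEM     99 ± 32 nm

Within-replicate noise is Gaussian (box-whisker summaries of such data are
roughly symmetric); DLS/NTA populations are lognormal, the standard choice
for particle sizing.  Between-replicate mean offsets default to an SD of
5 nm — replicate-level spread is a free calibration knob, as pooled group
statistics do not constrain it.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import geometry
from .dls import Correlogram, InstrumentParams, SizeDistribution, reweight_psd

__all__ = [
    "SyntheticError",
    "TechniqueSpec",
    "GeneratorConfig",
    "DiameterDataset",
    "DEFAULT_CALIBRATION",
    "generate_technique_dataset",
    "generate_uts_dataset_by_sectioning",
    "simulate_correlogram",
    "simulate_nta_sample",
]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class TechniqueSpec:
    """Calibration of one imaging technique's apparent-diameter population."""

    label: str
    mean_nm: float
    sd_nm: float
    n_replicates: int = 3
    n_per_replicate: int = 100
    replicate_effect_sd_nm: float = 5.0

    def __post_init__(self) -> None:
        if self.mean_nm <= 0 or self.sd_nm < 0 or self.replicate_effect_sd_nm < 0:
            raise SyntheticError(f"invalid calibration for {self.label!r}")
        if self.n_replicates < 1 or self.n_per_replicate < 1:
            raise SyntheticError("replicate counts must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_replicates * self.n_per_replicate


#: Published group statistics (mean, SD) in nm per technique.
DEFAULT_CALIBRATION = {
    "TEM": (102.0, 17.0),
    "TEM+HMDS": (124.0, 17.0),
    "SEM": (126.0, 17.0),
    "cryo-TEM": (138.0, 21.0),
    "UTS-TEM": (99.0, 32.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic-data generator.

    ``exact_moments`` affinely standardises each pooled technique sample so
    its mean and (n−1) SD hit the calibration exactly; ``uts_mode`` selects
    whether the ultra-thin-section dataset is drawn directly from its
    calibrated moments (``direct``) or produced by random sectioning of a
    source population (``sectioned``).  The NTA population is a lognormal
    mixture: a main population parameterised by its mode and log-scale
    sigma plus a rare, large aggregate component.
    """

    techniques: tuple = tuple(
        TechniqueSpec(label, m, s) for label, (m, s) in DEFAULT_CALIBRATION.items()
    )
    seed: int = 0
    exact_moments: bool = True
    uts_mode: str = "direct"
    nta_mode_nm: float = 130.7
    nta_sigma_log: float = 0.13
    nta_aggregate_fraction: float = 0.03
    nta_aggregate_mean_nm: float = 650.0
    nta_aggregate_sd_nm: float = 160.0

    def __post_init__(self) -> None:
        if self.uts_mode not in ("direct", "sectioned"):
            raise SyntheticError("uts_mode must be 'direct' or 'sectioned'")
        if not (0 <= self.nta_aggregate_fraction < 1):
            raise SyntheticError("nta_aggregate_fraction must lie in [0, 1)")
        if self.nta_mode_nm <= 0 or self.nta_sigma_log <= 0:
            raise SyntheticError("NTA main-population parameters must be > 0")
        if self.nta_aggregate_mean_nm <= 0 or self.nta_aggregate_sd_nm <= 0:
            raise SyntheticError("NTA aggregate parameters must be > 0")
        labels = [t.label for t in self.techniques]
        if len(set(labels)) != len(labels):
            raise SyntheticError("duplicate technique labels")

    def technique(self, label: str) -> TechniqueSpec:
        for spec in self.techniques:
            if spec.label == label:
                return spec
        raise KeyError(f"unknown technique {label!r}; have {[t.label for t in self.techniques]}")

    @property
    def labels(self) -> list:
        return [t.label for t in self.techniques]

    def child_seed(self, *tags) -> np.random.SeedSequence:
        """Deterministic per-stage seed derived from the global seed.

        Tags are hashed with CRC-32 so the expansion is stable across
        processes (unlike Python's salted string hash)."""
        material = [self.seed] + [zlib.crc32(str(t).encode()) for t in tags]
        return np.random.SeedSequence(material)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["techniques"] = [asdict(t) for t in self.techniques]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        if "techniques" in data:
            data["techniques"] = tuple(TechniqueSpec(**t) for t in data["techniques"])
        return cls(**data)


@dataclass(frozen=True)
class DiameterDataset:
    """Per-particle apparent diameters for one technique, in nm."""

    technique: str
    replicate_ids: np.ndarray
    diameters_nm: np.ndarray

    def __post_init__(self) -> None:
        rep = np.asarray(self.replicate_ids, dtype=int)
        d = np.asarray(self.diameters_nm, dtype=float)
        if rep.shape != d.shape or d.ndim != 1 or d.size == 0:
            raise SyntheticError("replicate_ids and diameters_nm must be equal-length 1-D arrays")
        if np.any(d <= 0):
            raise SyntheticError("all diameters must be strictly positive")
        object.__setattr__(self, "replicate_ids", rep)
        object.__setattr__(self, "diameters_nm", d)

    @property
    def n(self) -> int:
        return int(self.diameters_nm.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "technique": self.technique,
                "replicate": self.replicate_ids,
                "diameter_nm": self.diameters_nm,
            }
        )


def _positive_normal(rng, mean, sd, size):
    """Gaussian draws with negative values redrawn (keeps moments clean;
    redraws are vanishingly rare at the shipped calibrations)."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def generate_technique_dataset(
    config: GeneratorConfig, technique: str, seed=None
) -> DiameterDataset:
    """Draw one technique's replicated apparent-diameter dataset.

    Replicate-level mean offsets are zero-mean Gaussian with SD
    ``replicate_effect_sd_nm``; measurements within a replicate are Gaussian
    around the offset mean.  With ``config.exact_moments`` the pooled sample
    is affinely standardised to the calibrated mean and SD.
    """
    spec = config.technique(technique)
    if seed is None:
        seed = config.child_seed("technique", technique)
    rng = np.random.default_rng(seed)
    reps, diams = [], []
    for j in range(spec.n_replicates):
        offset = rng.normal(0.0, spec.replicate_effect_sd_nm) if spec.replicate_effect_sd_nm else 0.0
        if spec.sd_nm == 0 and spec.replicate_effect_sd_nm == 0:
            x = np.full(spec.n_per_replicate, spec.mean_nm)
        else:
            x = _positive_normal(rng, spec.mean_nm + offset, max(spec.sd_nm, 0.0), spec.n_per_replicate)
        reps.append(np.full(spec.n_per_replicate, j + 1))
        diams.append(x)
    pooled = np.concatenate(diams)
    if config.exact_moments and pooled.size > 1:
        s = pooled.std(ddof=1)
        if s > 0:
            pooled = spec.mean_nm + (pooled - pooled.mean()) * (spec.sd_nm / s)
        else:
            pooled = np.full_like(pooled, spec.mean_nm)
    return DiameterDataset(spec.label, np.concatenate(reps), pooled)


def generate_uts_dataset_by_sectioning(
    config: GeneratorConfig,
    true_size_source: str = "cryo-TEM",
    model: geometry.SectioningModel | None = None,
    n_particles: int | None = None,
    seed=None,
) -> DiameterDataset:
    """Simulate an ultra-thin-section dataset by sectioning a population.

    True diameters are drawn from the named source technique's calibrated
    Gaussian (default cryo-TEM, the least-perturbed modality); each particle
    contributes one random section under ``model.scheme``, and sections
    below ``model.detection_limit`` go unrecorded — additional particles are
    sectioned until ``n_particles`` recorded measurements accumulate.  The
    resulting mean sits below the true-size mean and its spread exceeds the
    true-size spread (sectioning both shrinks and disperses).
    """
    if config.uts_mode != "sectioned":
        raise SyntheticError("config.uts_mode must be 'sectioned' for this generator")
    spec = config.technique(true_size_source)
    if model is None:
        model = geometry.SectioningModel(spec.mean_nm)
    if n_particles is None:
        n_particles = spec.n_total
    if n_particles < 1:
        raise SyntheticError("n_particles must be >= 1")
    if seed is None:
        seed = config.child_seed("uts-sectioned", true_size_source)
    rng = np.random.default_rng(seed)
    recorded = []
    n_left = n_particles
    while n_left > 0:
        batch = max(int(n_left * 1.8) + 16, 64)
        true_d = _positive_normal(rng, spec.mean_nm, spec.sd_nm, batch)
        radius = true_d / 2.0
        u = rng.random(batch)
        r = radius * (np.cbrt(u) if model.scheme == geometry.VOLUME_WEIGHTED else u)
        d_sec = 2.0 * np.sqrt(np.clip(radius**2 - r**2, 0.0, None))
        d_sec = d_sec[d_sec >= model.detection_limit]
        recorded.append(d_sec[:n_left])
        n_left -= len(d_sec[:n_left])
    diams = np.concatenate(recorded)
    rep = 1 + (np.arange(n_particles) * spec.n_replicates) // n_particles
    return DiameterDataset(f"{spec.label}-sectioned", rep, diams)


def simulate_correlogram(
    psd: SizeDistribution,
    instrument: InstrumentParams | None = None,
    beta: float = 0.8,
    noise_sd: float = 0.0,
    lag_grid_s: np.ndarray | None = None,
    seed=None,
) -> Correlogram:
    """Simulate the intensity autocorrelation of a particle population.

    ``g2(τ) = 1 + beta·[Σ wᵢ exp(−q² Dᵢ τ)]² + ε``, with intensity weights
    (the PSD is converted if supplied in another weighting), Stokes–Einstein
    diffusion coefficients, and i.i.d. Gaussian noise of SD ``noise_sd``.
    Without an explicit lag grid, 400 linear lags spanning eight mean decay
    times are used.
    """
    if instrument is None:
        instrument = InstrumentParams()
    if beta <= 0:
        raise SyntheticError("beta must be > 0")
    if noise_sd < 0:
        raise SyntheticError("noise_sd must be >= 0")
    from .dls import stokes_einstein_diffusion

    intensity = reweight_psd(psd, "intensity")
    q = instrument.q_per_m
    diff = stokes_einstein_diffusion(
        intensity.diameters_nm, instrument.temperature_k, instrument.viscosity_mpas
    )
    rates = q * q * diff
    gamma_bar = float(np.sum(intensity.weights * rates))
    if lag_grid_s is None:
        lag_grid_s = np.linspace(1e-7, 8.0 / gamma_bar, 400)
    lags = np.asarray(lag_grid_s, dtype=float)
    if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise SyntheticError("lag grid must be positive and strictly increasing")
    g1 = np.exp(-np.outer(lags, rates)) @ intensity.weights
    g2 = 1.0 + beta * g1**2
    if noise_sd > 0:
        g2 = g2 + np.random.default_rng(seed).normal(0.0, noise_sd, size=g2.shape)
    return Correlogram(lags, g2, beta=beta, instrument=instrument)


def simulate_nta_sample(config: GeneratorConfig, n_particles: int, seed=None) -> np.ndarray:
    """Per-particle NTA diameters, nm: a lognormal mixture.

    With probability ``1 − nta_aggregate_fraction`` a particle comes from
    the main population (lognormal with mode ``nta_mode_nm`` and log-sigma
    ``nta_sigma_log``), otherwise from the aggregate population (lognormal
    matched to the configured arithmetic mean and SD).  Tracking analysis
    sizes particles one by one, so rare large aggregates pull the sample
    mean well above its mode while barely moving the mode itself.
    """
    if n_particles < 1:
        raise SyntheticError("n_particles must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else config.child_seed("nta"))
    s = config.nta_sigma_log
    mu_main = math.log(config.nta_mode_nm) + s * s  # lognormal mode = exp(mu − σ²)
    cv2 = (config.nta_aggregate_sd_nm / config.nta_aggregate_mean_nm) ** 2
    s_agg = math.sqrt(math.log1p(cv2))
    mu_agg = math.log(config.nta_aggregate_mean_nm) - s_agg * s_agg / 2.0
    is_agg = rng.random(n_particles) < config.nta_aggregate_fraction
    out = np.where(
        is_agg,
        rng.lognormal(mu_agg, s_agg, n_particles),
        rng.lognormal(mu_main, s, n_particles),
    )
    return out
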