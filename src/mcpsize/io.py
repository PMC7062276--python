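"""CSV interchange for sizing data, PSDs and correlograms.

The sizing format mirrors a raw per-measurement export from image
analysis: one row per traced particle with columns
``technique, replicate, diameter_nm`` (all lengths in nm).  Correlogram and
PSD files are two-column CSVs with instrument parameters or the weighting
tag carried in ``# key: value`` header comments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dls import Correlogram, InstrumentParams, SizeDistribution, WEIGHTINGS
from .synthetic import DiameterDataset

__all__ = [
    "SizingFormatError",
    "read_sizing_csv",
    "write_sizing_csv",
    "read_correlogram_csv",
    "write_correlogram_csv",
    "read_psd_csv",
    "write_psd_csv",
    "RunManifest",
]

SIZING_COLUMNS = ["technique", "replicate", "diameter_nm"]


class SizingFormatError(ValueError):
    pass


def read_sizing_csv(path) -> list:
    """Parse a sizing CSV into one :class:`DiameterDataset` per technique.

    Techniques keep their order of first appearance.  Non-numeric or
    non-positive diameters are rejected with the offending file row number
    (header = row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SizingFormatError(f"{path}: file is empty") from exc
    missing = [c for c in SIZING_COLUMNS if c not in df.columns]
    if missing:
        raise SizingFormatError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise SizingFormatError(f"{path}: no data rows")
    diam = pd.to_numeric(df["diameter_nm"], errors="coerce")
    bad = df.index[diam.isna() | (diam <= 0)]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])
        raise SizingFormatError(
            f"{path}: non-numeric or non-positive diameter_nm at row(s) {rows}"
        )
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    bad = df.index[rep.isna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])
        raise SizingFormatError(f"{path}: non-numeric replicate at row(s) {rows}")
    out = []
    for label in df["technique"].drop_duplicates():
        sel = df["technique"] == label
        out.append(
            DiameterDataset(
                str(label),
                rep[sel].to_numpy(dtype=int),
                diam[sel].to_numpy(dtype=float),
            )
        )
    return out


def write_sizing_csv(datasets, path) -> None:
    """Write datasets to the sizing CSV format (stable column order)."""
    frames = [d.to_dataframe() for d in datasets]
    pd.concat(frames, ignore_index=True)[SIZING_COLUMNS].to_csv(path, index=False)


def _read_commented_header(path):
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, val = line[1:].split(":", 1)
                meta[key.strip()] = val.strip()
    return meta


def write_correlogram_csv(corr: Correlogram, path) -> None:
    inst = corr.instrument
    with open(path, "w") as fh:
        fh.write(f"# beta: {corr.beta!r}\n")
        for key in ("angle_deg", "wavelength_nm", "temperature_k", "viscosity_mpas", "refractive_index"):
            fh.write(f"# {key}: {getattr(inst, key)!r}\n")
        fh.write("lag_s,g2\n")
        for lag, g in zip(corr.lags_s, corr.g2):
            fh.write(f"{float(lag)!r},{float(g)!r}\n")


def read_correlogram_csv(path) -> Correlogram:
    meta = _read_commented_header(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if not {"lag_s", "g2"} <= set(df.columns):
        raise SizingFormatError(f"{path}: expected columns lag_s,g2")
    inst = InstrumentParams(
        **{
            k: float(meta[k])
            for k in ("angle_deg", "wavelength_nm", "temperature_k", "viscosity_mpas", "refractive_index")
            if k in meta
        }
    )
    return Correlogram(
        df["lag_s"].to_numpy(float),
        df["g2"].to_numpy(float),
        beta=float(meta.get("beta", 0.8)),
        instrument=inst,
    )


def write_psd_csv(psd: SizeDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# weighting: {psd.weighting}\n")
        fh.write("diameter_nm,weight\n")
        for d, w in zip(psd.diameters_nm, psd.weights):
            fh.write(f"{float(d)!r},{float(w)!r}\n")


def read_psd_csv(path) -> SizeDistribution:
    meta = _read_commented_header(path)
    weighting = meta.get("weighting", "intensity")
    if weighting not in WEIGHTINGS:
        raise SizingFormatError(f"{path}: unknown weighting {weighting!r}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if not {"diameter_nm", "weight"} <= set(df.columns):
        raise SizingFormatError(f"{path}: expected columns diameter_nm,weight")
    return SizeDistribution(
        df["diameter_nm"].to_numpy(float), df["weight"].to_numpy(float), weighting
    )


@dataclass
class RunManifest:
    """Record of one end-to-end run: configuration, seeds, and outputs.

    ``outputs`` maps relative file names to their byte sizes; reruns with
    the same config and seed reproduce the listed CSV outputs byte for
    byte.  ``created`` is informational and excluded from reproducibility
    comparisons.
    """

    config: dict
    seed: int
    stage_seeds: dict
    package_version: str
    created: str
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def reproducible_view(self) -> dict:
        d = asdict(self)
        d.pop("created")
        return d
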