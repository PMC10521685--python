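"""Delimited-text readers and writers for every data product of the package.

All formats are headered, comma-separated text:

* kinetic curves — ``time_min, od340`` (or another value column name);
* trajectories — ``time_min, A_mM, B_mM, N_mM`` with ``# key=value``
  metadata lines (A0, variant) above the header;
* CD spectra — ``wavelength_nm, ellipticity``; a series is one file per
  time point plus a manifest ``filename, time_min``;
* fibril snapshots — ``time_min, fibril_id, length_monomers``;
* length histograms — ``bin_lo_nm, bin_hi_nm, count``;
* Ct tables — ``gene, group, replicate, ct``;
* fit results and generator configs — YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cd import CDSpectrum
from .curves import KineticCurve
from .errors import DomainError
from .kinetics import Trajectory
from .stochastic import FibrilPopulation

__all__ = [
    "read_curve", "write_curve",
    "read_trajectory", "write_trajectory",
    "read_spectrum", "write_spectrum",
    "read_cd_series", "write_cd_series",
    "read_ct_table", "write_ct_table",
    "write_snapshots", "read_snapshots",
    "write_fit_result", "read_fit_result",
]


def read_curve(path, value_col: str = "od340", label: str = "OD340") -> KineticCurve:
    df = pd.read_csv(path, comment="#")
    for col in ("time_min", value_col):
        if col not in df.columns:
            raise DomainError(f"{path}: missing required column {col!r}")
    return KineticCurve(df["time_min"].to_numpy(), df[value_col].to_numpy(), label=label)


def write_curve(curve: KineticCurve, path, value_col: str = "od340") -> None:
    curve.to_dataframe(value_col).to_csv(path, index=False)


def write_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# A0_mM={traj.A0!r}\n")
        fh.write(f"# variant={traj.variant}\n")
        traj.to_dataframe().to_csv(fh, index=False)


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    if "A0_mM" not in meta or "variant" not in meta:
        raise DomainError(f"{path}: missing '# A0_mM=' / '# variant=' metadata lines")
    df = pd.read_csv(path, comment="#")
    return Trajectory(
        times=df["time_min"].to_numpy(),
        A=df["A_mM"].to_numpy(),
        B=df["B_mM"].to_numpy(),
        N=df["N_mM"].to_numpy(),
        A0=float(meta["A0_mM"]),
        variant=meta["variant"],
    )


def read_spectrum(path, time: float | None = None) -> CDSpectrum:
    df = pd.read_csv(path, comment="#")
    for col in ("wavelength_nm", "ellipticity"):
        if col not in df.columns:
            raise DomainError(f"{path}: missing required column {col!r}")
    return CDSpectrum(df["wavelength_nm"].to_numpy(), df["ellipticity"].to_numpy(), time=time)


def write_spectrum(spec: CDSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "ellipticity": spec.ellipticity}
    ).to_csv(path, index=False)


def write_cd_series(series, directory, stem: str = "cd") -> Path:
    """Write one file per spectrum plus a ``manifest.csv``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(series):
        if spec.time is None:
            raise DomainError("every spectrum in a series needs a time stamp")
        name = f"{stem}_{i:04d}.csv"
        write_spectrum(spec, directory / name)
        rows.append({"filename": name, "time_min": spec.time})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cd_series(manifest_path) -> list[CDSpectrum]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    return [
        read_spectrum(manifest_path.parent / row.filename, time=float(row.time_min))
        for row in df.itertuples()
    ]


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("gene", "group", "replicate", "ct") if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing required columns {missing}")
    return df


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_snapshots(snapshots, path) -> None:
    rows = []
    for pop in snapshots:
        for fid, length in enumerate(pop.lengths):
            rows.append({"time_min": pop.time, "fibril_id": fid,
                         "length_monomers": int(length)})
    pd.DataFrame(rows, columns=["time_min", "fibril_id", "length_monomers"]).to_csv(
        path, index=False)


def read_snapshots(path, system_size: int) -> list[FibrilPopulation]:
    """Rebuild populations from a snapshot file (free monomers inferred
    from conservation against ``system_size``)."""
    df = pd.read_csv(path, comment="#")
    pops = []
    for t, sub in df.groupby("time_min"):
        lengths = sub["length_monomers"].to_numpy(dtype=np.int64)
        pops.append(FibrilPopulation(free=system_size - int(lengths.sum()),
                                     lengths=lengths, time=float(t),
                                     system_size=system_size))
    return pops


def write_fit_result(result, path) -> None:
    """Serialise a TurbidityKineticsResults (or any .to_dict() object) as YAML."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(result.to_dict(), fh, sort_keys=False)


def read_fit_result(path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)
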