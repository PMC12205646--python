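"""Delimited-text and trajectory input/output.

All tabular formats are plain tab-separated text.  Per-dataset metadata
travels in ``# key=value`` header lines (temperature_c, field_mhz, label),
truth/fit records in JSON.  Trajectories are read through MDAnalysis
(PDB topology plus DCD/XTC coordinates, or a multi-model PDB alone).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atpase import DeltaMatrix, ProgressCurve
from .cpmg import DispersionProfile, FitResult
from .dccm import DCCMResult, TrajectoryWindow
from .lineshape import BuildupSeries, PeakFit, Spectrum1D

__all__ = [
    "read_dispersion_table",
    "write_dispersion_table",
    "read_spectrum",
    "write_spectrum",
    "read_buildup",
    "write_buildup",
    "read_plate",
    "write_plate",
    "write_peak_table",
    "write_fit_report",
    "write_delta_matrix",
    "load_trajectory",
    "write_dccm",
    "write_json",
    "read_json",
]


def _read_headers(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _meta_float(meta: dict[str, str], key: str) -> float | None:
    return float(meta[key]) if key in meta else None


def read_dispersion_table(path: str | Path) -> DispersionProfile:
    """Read a dispersion table: # metadata headers then columns
    nu_cpmg_hz, r2_s[, r2_err_s]."""
    path = Path(path)
    meta = _read_headers(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in ("nu_cpmg_hz", "r2_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    err = df["r2_err_s"].to_numpy() if "r2_err_s" in df.columns else None
    if err is not None and np.all(~np.isfinite(err)):
        err = None
    return DispersionProfile(
        nu_cpmg=df["nu_cpmg_hz"].to_numpy(),
        r2_obs=df["r2_s"].to_numpy(),
        r2_err=err,
        temperature=_meta_float(meta, "temperature_c"),
        field_mhz=_meta_float(meta, "field_mhz"),
        label=meta.get("label", path.stem),
    )


def write_dispersion_table(profile: DispersionProfile, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if profile.temperature is not None:
            fh.write(f"# temperature_c={profile.temperature}\n")
        if profile.field_mhz is not None:
            fh.write(f"# field_mhz={profile.field_mhz}\n")
        if profile.label:
            fh.write(f"# label={profile.label}\n")
        cols = {"nu_cpmg_hz": profile.nu_cpmg, "r2_s": profile.r2_obs}
        if profile.r2_err is not None:
            cols["r2_err_s"] = profile.r2_err
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_spectrum(path: str | Path) -> Spectrum1D:
    """Read a two-column (ppm, intensity) spectrum with # metadata headers."""
    path = Path(path)
    meta = _read_headers(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum1D(
        ppm=df.iloc[:, 0].to_numpy(),
        intensity=df.iloc[:, 1].to_numpy(),
        field_mhz=_meta_float(meta, "field_mhz"),
        temperature=_meta_float(meta, "temperature_c"),
    )


def write_spectrum(spec: Spectrum1D, path: str | Path) -> None:
    with open(path, "w") as fh:
        if spec.field_mhz is not None:
            fh.write(f"# field_mhz={spec.field_mhz}\n")
        if spec.temperature is not None:
            fh.write(f"# temperature_c={spec.temperature}\n")
        pd.DataFrame({"ppm": spec.ppm, "intensity": spec.intensity}).to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )


def read_buildup(path: str | Path) -> BuildupSeries:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("time_s", "area_nm", "area_closed"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return BuildupSeries(
        time=df["time_s"].to_numpy(),
        area_nm=df["area_nm"].to_numpy(),
        area_closed=df["area_closed"].to_numpy(),
    )


def write_buildup(series: BuildupSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": series.time,
            "area_nm": series.area_nm,
            "area_closed": series.area_closed,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_plate(
    plate_path: str | Path, wellmap_path: str | Path
) -> tuple[list[ProgressCurve], pd.DataFrame]:
    """Read a long-format plate (well_id, time_min, a340) and its well-map."""
    plate = pd.read_csv(plate_path, sep="\t", comment="#")
    for col in ("well_id", "time_min", "a340"):
        if col not in plate.columns:
            raise ValueError(f"{plate_path}: missing column {col!r}")
    wellmap = pd.read_csv(wellmap_path, sep="\t", comment="#")
    need = {"well_id", "sample_label", "subunit1", "subunit2",
            "inhibited", "aha1", "hsp90_um", "replicate"}
    missing = need - set(wellmap.columns)
    if missing:
        raise ValueError(f"{wellmap_path}: missing columns {sorted(missing)}")
    for col in ("inhibited", "aha1"):
        wellmap[col] = wellmap[col].astype(bool)
    wm = wellmap.set_index("well_id")
    curves = []
    for well, grp in plate.groupby("well_id", sort=True):
        grp = grp.sort_values("time_min")
        row = wm.loc[well]
        curves.append(
            ProgressCurve(
                time=grp["time_min"].to_numpy(),
                a340=grp["a340"].to_numpy(),
                well_id=str(well),
                sample_label=str(row["sample_label"]),
                inhibited=bool(row["inhibited"]),
            )
        )
    return curves, wellmap


def write_plate(
    curves: list[ProgressCurve],
    wellmap: pd.DataFrame,
    plate_path: str | Path,
    wellmap_path: str | Path,
) -> None:
    rows = []
    for c in curves:
        for t, a in zip(c.time, c.a340):
            rows.append({"well_id": c.well_id, "time_min": t, "a340": a})
    pd.DataFrame(rows).to_csv(plate_path, sep="\t", index=False,
                              float_format="%.10g")
    wellmap.to_csv(wellmap_path, sep="\t", index=False, float_format="%.10g")


def write_peak_table(peaks: list[PeakFit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "center_ppm": p.center_ppm,
                "fwhm_hz": p.fwhm_hz,
                "t2_ms": p.t2_ms,
                "area": p.area,
                "label": p.state_label,
            }
            for p in peaks
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_fit_report(fit: FitResult, path: str | Path) -> None:
    """JSON record of one dispersion fit (parameters, MC errors, seed)."""
    rec = {
        "label": fit.label,
        "temperature_c": fit.temperature,
        "r2_0": fit.params.r2_0,
        "rex": fit.params.rex,
        "kex": fit.params.kex,
        "rex_plateau": fit.params.rex_plateau,
        "sse": fit.sse,
        "n_points": fit.n_points,
        "converged": fit.converged,
        "param_errs": fit.param_errs,
        "mc_draws": None if fit.mc_samples is None else int(len(fit.mc_samples)),
        "mc_seed": fit.mc_seed,
        "error": fit.error,
    }
    write_json(rec, path)


def write_delta_matrix(matrix: DeltaMatrix, path: str | Path) -> None:
    """Lower-triangular Δ table: diagonal Δ_symm, off-diagonal Δ_asymm."""
    n = len(matrix.labels)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(matrix.labels) + "\n")
        for i in range(n):
            cells = []
            for j in range(n):
                if j > i:
                    cells.append("")
                else:
                    v = matrix.values[i, j]
                    cells.append("NA" if np.isnan(v) else f"{v:.6g}")
            fh.write(matrix.labels[i] + "\t" + "\t".join(cells) + "\n")


def load_trajectory(
    topology: str | Path, trajectory: str | Path | None = None
) -> TrajectoryWindow:
    """Load frames through MDAnalysis.

    ``topology`` is a PDB (a multi-model PDB may carry the frames itself);
    ``trajectory`` is an optional DCD/XTC/PDB coordinate file.
    """
    import MDAnalysis as mda

    args = (str(topology),) if trajectory is None else (str(topology), str(trajectory))
    u = mda.Universe(*args)
    n_frames = len(u.trajectory)
    if n_frames < 2:
        raise ValueError("trajectory must hold at least 2 frames")
    atoms = u.atoms
    coords = np.empty((n_frames, len(atoms), 3))
    for k, _ in enumerate(u.trajectory):
        coords[k] = atoms.positions
    dt_ns = None
    try:
        dt_ps = float(u.trajectory.dt)
        if dt_ps > 0:
            dt_ns = dt_ps / 1000.0
    except Exception:
        pass
    return TrajectoryWindow(
        coords=coords,
        residues=atoms.resids.astype(int),
        atom_names=atoms.names.astype(object),
        frame_spacing_ns=dt_ns,
    )


def write_dccm(result: DCCMResult, path: str | Path) -> None:
    """Square DCCM as TSV with residue numbers as header row/column."""
    df = pd.DataFrame(result.matrix, index=result.residues, columns=result.residues)
    df.to_csv(path, sep="\t", float_format="%.8g", index_label="residue")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
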