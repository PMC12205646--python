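"""Dynamical cross-correlation analysis of trajectory windows.

After rigid-body superposition of every frame onto a reference, the
dynamical cross-correlation matrix (DCCM) over selected atoms (Cα by
default) is

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>)

with Δr_i the displacement of atom i from its time-averaged position and
<> the average over frames.  C_ij ∈ [−1, 1]: +1 for perfectly correlated
motion, −1 for equal-and-opposite motion.

Region-pair coupling is summarised by the *total correlation*: the sum of
off-diagonal C_ij over the residue pairs spanned by two regions, counting
each unordered pair once and never including the diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

__all__ = [
    "TrajectoryWindow",
    "RegionDefinition",
    "DCCMResult",
    "DynamicalCrossCorrelation",
    "superpose",
    "compute_dccm",
    "total_correlation",
    "windowed_dccm_series",
]


@dataclass(frozen=True)
class TrajectoryWindow:
    """A block of trajectory frames with a fixed atom roster.

    ``coords``: (n_frames, n_atoms, 3) Cartesian coordinates in Å.
    ``residues`` / ``atom_names``: per-atom residue number (topology
    numbering, 1-based) and atom name.
    """

    coords: np.ndarray
    residues: np.ndarray
    atom_names: np.ndarray
    frame_spacing_ns: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        res = np.asarray(self.residues, dtype=int)
        names = np.asarray(self.atom_names, dtype=object)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if c.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if res.shape != (c.shape[1],) or names.shape != (c.shape[1],):
            raise ValueError("residues and atom_names must have one entry per atom")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "residues", res)
        object.__setattr__(self, "atom_names", names)

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def atom_mask(
        self,
        first_res: int | None = None,
        last_res: int | None = None,
        atom_names: tuple[str, ...] | None = ("CA",),
    ) -> np.ndarray:
        """Boolean mask selecting atoms by residue range and atom name."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if first_res is not None:
            mask &= self.residues >= first_res
        if last_res is not None:
            mask &= self.residues <= last_res
        if atom_names is not None:
            mask &= np.isin(self.atom_names.astype(str), atom_names)
        return mask


@dataclass(frozen=True)
class RegionDefinition:
    """Named inclusive residue range (e.g. helix 1 = residues 9–22)."""

    name: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.last < self.first:
            raise ValueError(f"empty region {self.name}: {self.first}..{self.last}")


@dataclass(frozen=True)
class DCCMResult:
    """Residue × residue correlation matrix plus region-pair totals."""

    matrix: np.ndarray
    residues: np.ndarray
    region_totals: dict[str, float] = field(default_factory=dict)


def _kabsch_apply(mobile: np.ndarray, mob_fit: np.ndarray, ref_fit: np.ndarray) -> np.ndarray:
    """Rigid-body transform all of ``mobile`` so ``mob_fit`` best matches ``ref_fit``."""
    mob_c = mob_fit.mean(axis=0)
    ref_c = ref_fit.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_fit - ref_c, mob_fit - mob_c)
    return rot.apply(mobile - mob_c) + ref_c


def superpose(
    window: TrajectoryWindow,
    fit_first_res: int | None = None,
    fit_last_res: int | None = None,
    fit_atom_names: tuple[str, ...] | None = ("N", "CA", "C"),
    reference_frame: int = 0,
) -> TrajectoryWindow:
    """Least-squares superpose every frame onto a reference frame.

    The optimal rotation/translation (Kabsch) is computed on the fit
    selection (main-chain N, Cα, C of a residue range by default) and
    applied to all atoms of the frame.  Fit-selection RMSD to the
    reference never increases.
    """
    mask = window.atom_mask(fit_first_res, fit_last_res, fit_atom_names)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"superposition is underdetermined with {int(mask.sum())} fit atoms"
        )
    ref_fit = window.coords[reference_frame][mask]
    out = np.empty_like(window.coords)
    for k in range(window.n_frames):
        out[k] = _kabsch_apply(window.coords[k], window.coords[k][mask], ref_fit)
    return TrajectoryWindow(
        coords=out,
        residues=window.residues,
        atom_names=window.atom_names,
        frame_spacing_ns=window.frame_spacing_ns,
    )


class DynamicalCrossCorrelation(BaseEstimator):
    """Normalised displacement cross-correlation over frames.

    Covariance-style estimator: ``fit(X)`` with X of shape
    (n_frames, n_atoms, 3) computes the DCCM into ``correlation_``.
    Assumes frames are already superposed.

    Attributes
    ----------
    correlation_ : (n_atoms, n_atoms) ndarray
    mean_ : (n_atoms, 3) ndarray of time-averaged positions
    """

    def __init__(self, min_frames_warn: int = 10):
        self.min_frames_warn = min_frames_warn

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 3:
            raise ValueError("X must have shape (n_frames, n_atoms, 3)")
        n_frames = X.shape[0]
        if n_frames < 2:
            raise ValueError("need at least 2 frames")
        if n_frames < self.min_frames_warn:
            warnings.warn(
                f"only {n_frames} frames: DCCM sampling error will be large"
            )
        self.mean_ = X.mean(axis=0)
        d = X - self.mean_
        cov = np.einsum("fai,fbi->ab", d, d) / n_frames
        var = np.diag(cov).copy()
        zero = np.flatnonzero(var <= 0)
        if zero.size:
            raise ValueError(
                f"zero-variance atom(s) at index {zero.tolist()}: "
                "correlation is undefined"
            )
        denom = np.sqrt(np.outer(var, var))
        corr = cov / denom
        corr = 0.5 * (corr + corr.T)
        np.fill_diagonal(corr, 1.0)
        self.correlation_ = np.clip(corr, -1.0, 1.0)
        return self


def compute_dccm(
    window: TrajectoryWindow,
    first_res: int | None = None,
    last_res: int | None = None,
    atom_name: str = "CA",
) -> DCCMResult:
    """Cα (by default) DCCM of a superposed trajectory window."""
    mask = window.atom_mask(first_res, last_res, (atom_name,))
    if int(mask.sum()) == 0:
        raise ValueError("selection matches no atoms")
    residues = window.residues[mask]
    if np.unique(residues).size != residues.size:
        raise ValueError("selection yields duplicate residues")
    est = DynamicalCrossCorrelation().fit(window.coords[:, mask, :])
    return DCCMResult(matrix=est.correlation_, residues=residues)


def total_correlation(
    dccm: DCCMResult, region_a: RegionDefinition, region_b: RegionDefinition
) -> float:
    """Sum of off-diagonal correlations over a region pair.

    Each unordered residue pair {i, j}, i ≠ j, with i in region A and j in
    region B contributes C_ij exactly once; the diagonal never contributes.
    For A = B this is the sum over i < j within the region.  Symmetric in
    its region arguments and additive over disjoint sub-regions.
    """
    res = dccm.residues
    ia = np.flatnonzero((res >= region_a.first) & (res <= region_a.last))
    ib = np.flatnonzero((res >= region_b.first) & (res <= region_b.last))
    if ia.size == 0 or ib.size == 0:
        raise ValueError(
            f"region {region_a.name if ia.size == 0 else region_b.name} "
            "shares no residues with the matrix"
        )
    pairs = {
        (min(i, j), max(i, j))
        for i in ia
        for j in ib
        if i != j
    }
    return float(sum(dccm.matrix[i, j] for i, j in pairs))


def windowed_dccm_series(
    window: TrajectoryWindow,
    step_ns: float,
    window_ns: float,
    first_res: int | None = None,
    last_res: int | None = None,
    atom_name: str = "CA",
    fit_atom_names: tuple[str, ...] | None = None,
    fit_first_res: int | None = None,
    fit_last_res: int | None = None,
    mode: str = "final",
) -> list[DCCMResult]:
    """DCCM(s) from frames sampled every ``step_ns`` over ``window_ns``.

    ``mode="final"`` (default) analyses one window covering the final
    ``window_ns`` of the trajectory; ``mode="tile"`` tiles the trajectory
    with non-overlapping windows.  Each window is superposed onto its own
    first frame before analysis.
    """
    if step_ns > window_ns:
        raise ValueError("step_ns must not exceed window_ns")
    if window.frame_spacing_ns is None or window.frame_spacing_ns <= 0:
        raise ValueError("trajectory frame_spacing_ns is required")
    dt = window.frame_spacing_ns
    duration = (window.n_frames - 1) * dt
    if duration < window_ns:
        raise ValueError(
            f"trajectory spans {duration} ns < requested window {window_ns} ns"
        )
    stride = max(int(round(step_ns / dt)), 1)
    frames_per_window = int(round(window_ns / step_ns)) + 1

    starts: list[int]
    if mode == "final":
        last_start = window.n_frames - 1 - (frames_per_window - 1) * stride
        starts = [last_start]
    elif mode == "tile":
        starts = list(
            range(0, window.n_frames - (frames_per_window - 1) * stride,
                  (frames_per_window - 1) * stride)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    results = []
    for s in starts:
        sel = np.arange(s, s + frames_per_window * stride, stride)[:frames_per_window]
        sub = TrajectoryWindow(
            coords=window.coords[sel],
            residues=window.residues,
            atom_names=window.atom_names,
            frame_spacing_ns=step_ns,
        )
        sub = superpose(
            sub,
            fit_first_res=fit_first_res,
            fit_last_res=fit_last_res,
            fit_atom_names=fit_atom_names,
        )
        results.append(
            compute_dccm(sub, first_res=first_res, last_res=last_res,
                         atom_name=atom_name)
        )
    return results
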