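"""Synthetic-data generators with recorded ground truth.

Every input class the analysis modules consume can be generated here with
known parameters, a stated Gaussian noise model, and a recorded seed, so
the whole pipeline is testable without measured data.  Defaults emulate
the study conditions: 11-point ¹⁹F CPMG grids at 657 MHz, Lorentzian
two-state spectra, linear NADH-depletion plates with inhibitor-background
wells and 1:2:1 dimer mixtures (four replicates), exponential clamp-closure
build-ups, and block-correlated Gaussian atomic displacements sampled every
10 ns over an 800 ns window (80 analysis frames), optionally embedded in
random rigid-body motion.

Each generator returns ``(data, truth)`` where ``truth`` is a plain dict
(JSON-serialisable) recording all generating parameters and the seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .atpase import ProgressCurve, EPSILON_NADH_M, delta_symm, heterodimer_activity, delta_asymm
from .cpmg import DispersionProfile
from .dccm import TrajectoryWindow
from .exchange import DEFAULT_F19_FIELD_MHZ, FastExchangeParams, r2_fast_exchange
from .lineshape import BuildupSeries, Spectrum1D

__all__ = [
    "default_cpmg_grid",
    "gen_cpmg_profile",
    "gen_spectrum",
    "gen_plate",
    "gen_buildup",
    "gen_correlated_trajectory",
    "nearest_positive_definite_correlation",
]


def default_cpmg_grid(n_points: int = 11, lo_hz: float = 50.0, hi_hz: float = 1000.0) -> np.ndarray:
    """The default 11-point ν_CPMG grid, linearly spaced 50–1000 Hz."""
    return np.linspace(lo_hz, hi_hz, n_points)


def gen_cpmg_profile(
    params: FastExchangeParams,
    nu_cpmg: np.ndarray | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    temperature: float = 25.0,
    field_mhz: float = DEFAULT_F19_FIELD_MHZ,
    label: str = "synthetic",
) -> tuple[DispersionProfile, dict]:
    """Dispersion profile obeying the fast-exchange model plus iid Gaussian noise.

    ``noise_sd`` (s⁻¹) is also recorded as the per-point error of the
    profile (when > 0), mirroring an experimentally estimated uncertainty.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    nu = default_cpmg_grid() if nu_cpmg is None else np.asarray(nu_cpmg, dtype=float)
    rng = np.random.default_rng(seed)
    r2_true = r2_fast_exchange(params, nu)
    r2_obs = r2_true + rng.normal(0.0, noise_sd, nu.size) if noise_sd > 0 else r2_true.copy()
    profile = DispersionProfile(
        nu_cpmg=nu,
        r2_obs=r2_obs,
        r2_err=np.full(nu.size, noise_sd) if noise_sd > 0 else None,
        temperature=temperature,
        field_mhz=field_mhz,
        label=label,
    )
    truth = {
        "generator": "gen_cpmg_profile",
        "seed": int(seed),
        "noise_sd": float(noise_sd),
        "r2_0": params.r2_0,
        "rex": params.rex,
        "kex": params.kex,
        "nu_cpmg": nu.tolist(),
    }
    return profile, truth


def gen_spectrum(
    peaks: list[tuple[float, float, float]],
    sw_ppm: tuple[float, float] = (-63.0, -58.0),
    points: int = 2048,
    noise_sd: float = 0.0,
    seed: int = 0,
    field_mhz: float = DEFAULT_F19_FIELD_MHZ,
    temperature: float = 25.0,
) -> tuple[Spectrum1D, dict]:
    """Sum-of-Lorentzians 1-D spectrum plus Gaussian noise.

    ``peaks`` is a list of (center_ppm, t2_ms, area); each peak has
    FWHM (Hz) = 1000/(π·T₂[ms]) and noise-free height 2·area/(π·FWHM_ppm)
    at its centre.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ppm = np.linspace(sw_ppm[0], sw_ppm[1], points)
    intensity = np.zeros_like(ppm)
    for center, t2_ms, area in peaks:
        if t2_ms <= 0 or area < 0:
            raise ValueError("peak t2 must be > 0 and area >= 0")
        fwhm_hz = 1000.0 / (np.pi * t2_ms)
        hw_ppm = fwhm_hz / field_mhz / 2.0
        amp = area / (np.pi * hw_ppm)
        intensity += amp * hw_ppm**2 / ((ppm - center) ** 2 + hw_ppm**2)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, points)
    spec = Spectrum1D(ppm=ppm, intensity=intensity, field_mhz=field_mhz,
                      temperature=temperature)
    truth = {
        "generator": "gen_spectrum",
        "seed": int(seed),
        "noise_sd": float(noise_sd),
        "field_mhz": float(field_mhz),
        "peaks": [
            {"center_ppm": c, "t2_ms": t2, "area": a} for c, t2, a in peaks
        ],
    }
    return spec, truth


def gen_buildup(
    k_obs: float,
    closed_plateau: float = 0.6,
    nm_initial: float = 1.0,
    nm_plateau: float = 0.4,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BuildupSeries, dict]:
    """Exponential clamp-closure build-up with shared rate k_obs (s⁻¹)."""
    if k_obs < 0 or noise_sd < 0:
        raise ValueError("k_obs and noise_sd must be >= 0")
    t = np.linspace(0.0, 3600.0, 25) if times is None else np.asarray(times, dtype=float)
    decay = np.exp(-k_obs * t)
    closed = closed_plateau * (1.0 - decay)
    nm = nm_plateau + (nm_initial - nm_plateau) * decay
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        closed = closed + rng.normal(0.0, noise_sd, t.size)
        nm = nm + rng.normal(0.0, noise_sd, t.size)
    series = BuildupSeries(
        time=t, area_nm=np.clip(nm, 0, None), area_closed=np.clip(closed, 0, None)
    )
    truth = {
        "generator": "gen_buildup",
        "seed": int(seed),
        "noise_sd": float(noise_sd),
        "k_obs": float(k_obs),
        "closed_plateau": float(closed_plateau),
        "nm_initial": float(nm_initial),
        "nm_plateau": float(nm_plateau),
    }
    return series, truth


def gen_plate(
    subunit_activity: dict[str, float] | None = None,
    mixtures: list[tuple[str, str]] | None = None,
    heterodimer_activity_override: dict[tuple[str, str], float] | None = None,
    aha1_fold: dict[str, float] | None = None,
    background_rate: float = 0.05,
    noise_sd: float = 0.0,
    n_reps: int = 4,
    homodimer_um: float = 2.5,
    mixture_um: float = 5.0,
    wt_label: str = "WT",
    times_min: np.ndarray | None = None,
    a340_start: float = 3.4,
    eps_nadh: float = EPSILON_NADH_M,
    seed: int = 0,
) -> tuple[list[ProgressCurve], pd.DataFrame, dict]:
    """Synthetic coupled-assay plate with known per-dimer activities.

    ``subunit_activity`` maps subunit variant -> per-subunit rate
    contribution (µM ATP·min⁻¹ per µM dimer); a homodimer turns over at
    2× its subunit contribution, and a heterodimer at the sum of its two
    contributions unless overridden (asymmetric stimulation or repression).
    Mixture wells contain the binomial 1:2:1 dimer species mix.  Inhibited
    companion wells carry only ``background_rate``.  ``aha1_fold`` adds
    +Aha1 conditions whose rates are fold × the basal dimer rate.

    The default panel is a WT / helix-1 / strap+helix-1 variant trio in
    which the WT homodimer turns over at 0.5 µM·min⁻¹·µM⁻¹ (per-subunit
    contribution 0.25), one variant is 2.5× stimulated, and one is dead,
    with an asymmetric mixture pinned so that the dead:stimulated
    heterodimer runs at 1.6× WT.

    Returns (curves, well-map DataFrame, truth) where truth records every
    generating rate plus the implied Δ matrix entries.
    """
    if subunit_activity is None:
        subunit_activity = {wt_label: 0.25, "L18D": 0.625, "F6D/F8D/L18D": 0.0}
    if mixtures is None:
        mixtures = [
            (a, b)
            for i, a in enumerate(subunit_activity)
            for b in list(subunit_activity)[i + 1:]
        ]
    overrides = heterodimer_activity_override or {}
    aha1_fold = aha1_fold or {}
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.linspace(0.0, 40.0, 21) if times_min is None else np.asarray(times_min, float)
    rng = np.random.default_rng(seed)

    wt_rate = 2.0 * subunit_activity[wt_label]
    if wt_rate <= 0:
        raise ValueError("WT subunit activity must be > 0 for normalisation")

    def het_rate(a: str, b: str) -> float:
        for key in ((a, b), (b, a)):
            if key in overrides:
                return overrides[key]
        return subunit_activity[a] + subunit_activity[b]

    # per-dimer rates (µM ATP/min per µM dimer) for every sample condition
    samples: dict[str, tuple[str, str, float, float]] = {}
    for v, act in subunit_activity.items():
        samples[v] = (v, v, 2.0 * act, homodimer_um)
    for a, b in mixtures:
        mix = (
            0.25 * 2.0 * subunit_activity[a]
            + 0.5 * het_rate(a, b)
            + 0.25 * 2.0 * subunit_activity[b]
        )
        samples[f"{a}:{b}"] = (a, b, mix, mixture_um)

    curves: list[ProgressCurve] = []
    rows = []
    well_no = 0

    def add_wells(sample: str, s1: str, s2: str, dimer_rate: float,
                  conc: float, aha1: bool) -> None:
        nonlocal well_no
        for inhibited in (False, True):
            for rep in range(n_reps):
                well_no += 1
                well = f"W{well_no:03d}"
                rate_um_min = background_rate + (0.0 if inhibited else dimer_rate * conc)
                a340 = a340_start - eps_nadh * rate_um_min * 1e-6 * t
                if noise_sd > 0:
                    a340 = a340 + rng.normal(0.0, noise_sd, t.size)
                curves.append(
                    ProgressCurve(
                        time=t, a340=a340, well_id=well,
                        sample_label=sample, inhibited=inhibited,
                    )
                )
                rows.append(
                    {
                        "well_id": well,
                        "sample_label": sample,
                        "subunit1": s1,
                        "subunit2": s2,
                        "inhibited": inhibited,
                        "aha1": aha1,
                        "hsp90_um": conc,
                        "replicate": rep + 1,
                    }
                )

    for sample, (s1, s2, dimer_rate, conc) in samples.items():
        add_wells(sample, s1, s2, dimer_rate, conc, aha1=False)
        if sample in aha1_fold:
            add_wells(sample, s1, s2, dimer_rate * aha1_fold[sample],
                      conc, aha1=True)
    wellmap = pd.DataFrame(rows)

    frac = {s: samples[s][2] / wt_rate for s in samples}
    truth_delta: dict[str, float] = {
        v: delta_symm(frac[v]) for v in subunit_activity
    }
    truth_dasymm: dict[str, float] = {}
    for a, b in mixtures:
        hetd = heterodimer_activity(frac[f"{a}:{b}"], frac[a], frac[b])
        truth_dasymm[f"{a}:{b}"] = delta_asymm(hetd, frac[f"{a}:{b}"])
    truth = {
        "generator": "gen_plate",
        "seed": int(seed),
        "noise_sd": float(noise_sd),
        "n_reps": int(n_reps),
        "background_rate": float(background_rate),
        "subunit_activity": dict(subunit_activity),
        "dimer_rates": {s: samples[s][2] for s in samples},
        "fractional_wt": frac,
        "delta_symm": truth_delta,
        "delta_asymm": truth_dasymm,
        "aha1_fold": dict(aha1_fold),
        "eps_nadh": float(eps_nadh),
    }
    return curves, wellmap, truth


def nearest_positive_definite_correlation(
    corr: np.ndarray, eig_floor: float = 1e-10
) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix to the nearest positive-definite
    correlation matrix (eigenvalue clipping + unit-diagonal rescale).

    Returns (projected matrix, Frobenius projection distance).
    """
    c = 0.5 * (corr + corr.T)
    w, v = np.linalg.eigh(c)
    if np.all(w > eig_floor):
        return c, 0.0
    w = np.clip(w, eig_floor, None)
    c2 = (v * w) @ v.T
    d = np.sqrt(np.diag(c2))
    c2 = c2 / np.outer(d, d)
    np.fill_diagonal(c2, 1.0)
    return c2, float(np.linalg.norm(c2 - c))


def gen_correlated_trajectory(
    region_sizes: tuple[int, ...] = (14, 32),
    within_corr: float | tuple[float, ...] = 0.8,
    between_corr: float | np.ndarray = -0.5,
    n_frames: int = 80,
    displacement_sd: float = 1.0,
    rigid_motion: bool = False,
    frame_spacing_ns: float = 10.0,
    seed: int = 0,
) -> tuple[TrajectoryWindow, dict]:
    """Cα pseudo-trajectory with a prescribed block correlation structure.

    Atoms are grouped into contiguous regions (default sizes mirror
    helix 1, residues 9–22, and the ATP gate, residues 94–125: 14 and 32
    residues).  Per-frame displacements of each Cartesian axis are iid
    draws from N(0, σ²·R) with R the block correlation matrix
    (``within_corr`` on diagonal blocks, ``between_corr`` between blocks);
    a non-positive-definite request is projected to the nearest valid
    correlation matrix, with the projection distance recorded in the truth
    record.  With ``rigid_motion`` a random rotation and translation is
    applied to every frame, to be removed downstream by superposition.
    """
    sizes = tuple(int(s) for s in region_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("region sizes must be >= 1")
    n_atoms = sum(sizes)
    n_regions = len(sizes)
    within = (
        tuple(float(within_corr) for _ in sizes)
        if np.isscalar(within_corr)
        else tuple(float(w) for w in within_corr)
    )
    if len(within) != n_regions:
        raise ValueError("within_corr must give one value per region")
    between = np.asarray(between_corr, dtype=float)
    if between.ndim == 0:
        between = np.full((n_regions, n_regions), float(between))
    if between.shape != (n_regions, n_regions):
        raise ValueError("between_corr must be scalar or (n_regions, n_regions)")

    corr = np.empty((n_atoms, n_atoms))
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for i in range(n_regions):
        si = slice(offsets[i], offsets[i + 1])
        for j in range(n_regions):
            sj = slice(offsets[j], offsets[j + 1])
            corr[si, sj] = within[i] if i == j else between[i, j]
    np.fill_diagonal(corr, 1.0)
    corr_pd, proj_dist = nearest_positive_definite_correlation(corr)
    if proj_dist > 0:
        warnings.warn(
            f"requested correlation matrix projected to positive definite "
            f"(Frobenius distance {proj_dist:.3g})"
        )

    rng = np.random.default_rng(seed)
    # extended-chain mean structure, 3.8 Å Cα spacing
    mean = np.zeros((n_atoms, 3))
    mean[:, 0] = 3.8 * np.arange(n_atoms)
    chol = np.linalg.cholesky(corr_pd)
    # iid N(0, σ² R) per frame and Cartesian axis
    z = rng.standard_normal((n_frames, 3, n_atoms))
    disp = displacement_sd * np.einsum("ab,fxb->fxa", chol, z)
    coords = mean[None, :, :] + np.transpose(disp, (0, 2, 1))

    if rigid_motion:
        for k in range(n_frames):
            rot = Rotation.random(rng=rng)
            shift = rng.normal(0.0, 5.0, 3)
            coords[k] = rot.apply(coords[k]) + shift

    window = TrajectoryWindow(
        coords=coords,
        residues=np.arange(1, n_atoms + 1),
        atom_names=np.array(["CA"] * n_atoms, dtype=object),
        frame_spacing_ns=frame_spacing_ns,
    )
    truth = {
        "generator": "gen_correlated_trajectory",
        "seed": int(seed),
        "region_sizes": list(sizes),
        "within_corr": list(within),
        "between_corr": between.tolist(),
        "n_frames": int(n_frames),
        "displacement_sd": float(displacement_sd),
        "rigid_motion": bool(rigid_motion),
        "projection_distance": proj_dist,
        "frame_spacing_ns": float(frame_spacing_ns),
    }
    return window, truth
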