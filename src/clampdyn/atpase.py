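"""Coupled ATPase-assay analysis and heterodimer deconvolution.

In the NADH-coupled, ATP-regenerating assay, each ATP turnover oxidises one
NADH, so the ATPase rate is read from the initial linear loss of A340.
Rates are background-subtracted against inhibitor-blocked wells and
expressed as a fraction of WT homodimer activity.

Mixing two subunit variants 1:1 yields a binomial 1:2:1 distribution of
homodimer1 : heterodimer : homodimer2 species.  The pure-heterodimer
activity is deconvolved from the mixture as

    hetD = [homhetmix − 0.25·homD1 − 0.25·homD2] / 0.5

and the modulation statistics are

    Δ_asymm = hetD − homhetmix          (off-diagonal, heterodimers)
    Δ_symm  = homD − WT                 (diagonal, homodimers)

collected into a lower-triangular matrix over subunit variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProgressCurve",
    "ActivityRecord",
    "MixtureResult",
    "DeltaMatrix",
    "UndefinedFoldError",
    "EPSILON_NADH_M",
    "rate_from_curve",
    "subtract_background",
    "mixture_composition",
    "heterodimer_activity",
    "delta_asymm",
    "delta_symm",
    "deconvolve_mixture",
    "build_delta_matrix",
    "analyze_plate",
    "fold_stimulation",
]

#: NADH molar extinction coefficient at 340 nm, M⁻¹·cm⁻¹ (1 cm path).
EPSILON_NADH_M = 6220.0


class UndefinedFoldError(ValueError):
    """Fold stimulation is undefined (basal rate is zero or near zero)."""


@dataclass(frozen=True)
class ProgressCurve:
    """One well's A340 progress curve (path-length corrected)."""

    time: np.ndarray  # min
    a340: np.ndarray
    well_id: str = ""
    sample_label: str = ""
    inhibited: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.a340, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("time and a340 must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(~np.isfinite(a)):
            raise ValueError("a340 must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "a340", a)

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class ActivityRecord:
    """Background-subtracted, WT-normalised activity of one sample.

    ``subunit1``/``subunit2`` name the constituent subunits (equal for a
    homodimer; a 1:1 mixture sample carries the two different labels).
    """

    sample_label: str
    rate: float  # µM ATP·min⁻¹·(µM dimer)⁻¹
    rate_sd: float
    fractional_wt: float
    n_reps: int
    subunit1: str = ""
    subunit2: str = ""
    fractional_wt_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.rate_sd < 0:
            raise ValueError("rate_sd must be >= 0")

    @property
    def is_homodimer(self) -> bool:
        return self.subunit1 == self.subunit2


@dataclass(frozen=True)
class MixtureResult:
    """Deconvolution of one 1:2:1 mixture into its pure-heterodimer activity."""

    subunit1: str
    subunit2: str
    homhetmix: float
    homd1: float
    homd2: float
    hetd: float
    delta_asymm: float
    hetd_sd: float = np.nan
    delta_asymm_sd: float = np.nan


@dataclass(frozen=True)
class DeltaMatrix:
    """Lower-triangular Δ_symm / Δ_asymm matrix over subunit variants.

    ``values[i, j]`` for i >= j holds Δ_symm (i == j) or Δ_asymm (i > j);
    the upper triangle is NaN (undefined).  Missing pairs are NaN with a
    message in ``annotations``.
    """

    labels: list[str]
    values: np.ndarray
    sds: np.ndarray
    annotations: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _linear_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R² (R² := 1 for an exactly flat fit)."""
    res = stats.linregress(t, y)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return float(res.slope), 1.0
    pred = res.intercept + res.slope * t
    ss_res = float(np.sum((y - pred) ** 2))
    return float(res.slope), 1.0 - ss_res / ss_tot


def rate_from_curve(
    curve: ProgressCurve,
    hsp90_conc: float,
    window: tuple[float, float] | None = None,
    eps_nadh: float = EPSILON_NADH_M,
    r2_min: float = 0.98,
    min_points: int = 5,
) -> float:
    """ATPase rate (µM ATP·min⁻¹ per µM dimer) from an A340 progress curve.

    rate = −slope(A340 vs t) / ε_NADH · 10⁶ / hsp90_conc, slope from a
    least-squares line over ``window`` (min).  When no window is given, the
    largest initial stretch of the curve with linear-fit R² >= ``r2_min``
    (at least ``min_points`` points) is used, which avoids the late-time
    curvature caused by NADH depletion without manual gating.

    A slope that is positive beyond its standard error triggers an
    assay-anomaly warning (A340 should not rise).
    """
    if hsp90_conc <= 0:
        raise ValueError("hsp90_conc must be > 0")
    t, y = curve.time, curve.a340
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
        if t.size < min_points:
            raise ValueError(
                f"window holds {t.size} points; need >= {min_points}"
            )
    else:
        if t.size < min_points:
            raise ValueError(f"curve holds {t.size} points; need >= {min_points}")
        chosen = None
        for k in range(t.size, min_points - 1, -1):
            _, r2 = _linear_slope(t[:k], y[:k])
            if r2 >= r2_min:
                chosen = k
                break
        if chosen is None:
            warnings.warn(
                "no initial window reaches the linearity threshold; "
                f"using the first {min_points} points"
            )
            chosen = min_points
        t, y = t[:chosen], y[:chosen]
    res = stats.linregress(t, y)
    if res.stderr is not None and res.slope > 2.0 * (res.stderr or 0.0) and res.slope > 0:
        warnings.warn(
            f"well {curve.well_id or '?'}: A340 increases with time "
            "(assay anomaly)"
        )
    # slope in A340/min; ε in M⁻¹cm⁻¹ (1 cm path) -> M/min -> µM/min
    return float(-res.slope / eps_nadh * 1e6 / hsp90_conc)


def subtract_background(
    sample_rates, inhibited_rates
) -> tuple[float, float]:
    """Net rate = mean(sample) − mean(inhibited), SD in quadrature.

    Replicate standard deviations of the two groups are combined as
    sqrt(sd_sample² + sd_inhibited²).  A negative net rate is clamped to 0
    with a warning (the sample is treated as lacking ATPase activity).
    """
    s = np.asarray(sample_rates, dtype=float).ravel()
    b = np.asarray(inhibited_rates, dtype=float).ravel()
    if s.size < 1 or b.size < 1:
        raise ValueError("need at least one replicate in each group")
    net = float(np.mean(s) - np.mean(b))
    sd_s = float(np.std(s, ddof=1)) if s.size > 1 else 0.0
    sd_b = float(np.std(b, ddof=1)) if b.size > 1 else 0.0
    sd = float(np.hypot(sd_s, sd_b))
    if net < 0:
        warnings.warn(
            f"net rate {net:.4g} < 0 after background subtraction; clamped to 0"
        )
        net = 0.0
    return net, sd


def mixture_composition(f1: float) -> tuple[float, float, float]:
    """Dimer species proportions from a subunit-1 mixing fraction.

    Random subunit pairing gives binomial (Pascal's-triangle) proportions
    (f1², 2·f1·(1−f1), (1−f1)²) of homodimer1 : heterodimer : homodimer2;
    equimolar mixing (f1 = 1/2) yields 1:2:1.
    """
    if not 0.0 <= f1 <= 1.0:
        raise ValueError(f"mixing fraction must lie in [0, 1], got {f1}")
    return (f1**2, 2.0 * f1 * (1.0 - f1), (1.0 - f1) ** 2)


def heterodimer_activity(homhetmix: float, homd1: float, homd2: float) -> float:
    """Pure-heterodimer fractional WT activity from a 1:2:1 mixture.

    hetD = [homhetmix − (0.25·homD1 + 0.25·homD2)] / 0.5 — the exact
    inverse of the composition-weighted mixture mean.
    """
    for name, v in (("homhetmix", homhetmix), ("homd1", homd1), ("homd2", homd2)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    return (homhetmix - (0.25 * homd1 + 0.25 * homd2)) / 0.5


def delta_asymm(hetd: float, homhetmix: float) -> float:
    """Asymmetric modulation Δ_asymm = hetD − homhetmix."""
    if not (np.isfinite(hetd) and np.isfinite(homhetmix)):
        raise ValueError("inputs must be finite")
    return hetd - homhetmix


def delta_symm(homd: float, wt: float = 1.0) -> float:
    """Symmetric modulation Δ_symm = homD − WT (WT normalised to 1)."""
    if not (np.isfinite(homd) and np.isfinite(wt)):
        raise ValueError("inputs must be finite")
    return homd - wt


def deconvolve_mixture(
    mixture: ActivityRecord, homd1: ActivityRecord, homd2: ActivityRecord
) -> MixtureResult:
    """Deconvolve one 1:2:1 mixture record into its pure-heterodimer
    activity and Δ_asymm, with first-order error propagation."""
    hetd = heterodimer_activity(
        mixture.fractional_wt, homd1.fractional_wt, homd2.fractional_wt
    )
    dasymm = delta_asymm(hetd, mixture.fractional_wt)
    hetd_sd = float(
        np.sqrt(
            (2.0 * mixture.fractional_wt_sd) ** 2
            + (0.5 * homd1.fractional_wt_sd) ** 2
            + (0.5 * homd2.fractional_wt_sd) ** 2
        )
    )
    dasymm_sd = float(
        np.sqrt(
            mixture.fractional_wt_sd**2
            + 0.25 * homd1.fractional_wt_sd**2
            + 0.25 * homd2.fractional_wt_sd**2
        )
    )
    return MixtureResult(
        subunit1=mixture.subunit1,
        subunit2=mixture.subunit2,
        homhetmix=mixture.fractional_wt,
        homd1=homd1.fractional_wt,
        homd2=homd2.fractional_wt,
        hetd=hetd,
        delta_asymm=dasymm,
        hetd_sd=hetd_sd,
        delta_asymm_sd=dasymm_sd,
    )


def build_delta_matrix(
    records: list[ActivityRecord], wt_label: str = "WT"
) -> DeltaMatrix:
    """Assemble the lower-triangular Δ_symm/Δ_asymm matrix.

    Diagonal entries are Δ_symm of each homodimer; off-diagonal entries are
    Δ_asymm of each measured pair, computed by deconvolving the mixture
    record through :func:`heterodimer_activity`.  Pairs without a mixture
    record, and mixtures missing a constituent homodimer record, are left
    NaN with an explanatory annotation.

    Error propagation is first order: since
    Δ_asymm = homhetmix − (homD1 + homD2)/2, its SD is
    sqrt(sd_mix² + sd_1²/4 + sd_2²/4).
    """
    homod = {r.subunit1: r for r in records if r.is_homodimer}
    mixtures = [r for r in records if not r.is_homodimer]

    labels = list(dict.fromkeys(r.subunit1 for r in records if r.is_homodimer))
    for r in mixtures:
        for s in (r.subunit1, r.subunit2):
            if s not in labels:
                labels.append(s)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    values = np.full((n, n), np.nan)
    sds = np.full((n, n), np.nan)
    annotations: dict[tuple[str, str], str] = {}

    for lab, rec in homod.items():
        i = idx[lab]
        values[i, i] = delta_symm(rec.fractional_wt)
        sds[i, i] = rec.fractional_wt_sd

    for mix in mixtures:
        s1, s2 = mix.subunit1, mix.subunit2
        i, j = idx[s1], idx[s2]
        if i < j:
            i, j = j, i
            s1, s2 = s2, s1
        missing = [s for s in (mix.subunit1, mix.subunit2) if s not in homod]
        if missing:
            annotations[(s1, s2)] = (
                f"missing homodimer reference for {', '.join(missing)}"
            )
            continue
        h1 = homod[mix.subunit1]
        h2 = homod[mix.subunit2]
        hetd = heterodimer_activity(
            mix.fractional_wt, h1.fractional_wt, h2.fractional_wt
        )
        values[i, j] = delta_asymm(hetd, mix.fractional_wt)
        sds[i, j] = float(
            np.sqrt(
                mix.fractional_wt_sd**2
                + 0.25 * h1.fractional_wt_sd**2
                + 0.25 * h2.fractional_wt_sd**2
            )
        )
    if wt_label not in homod:
        annotations[(wt_label, wt_label)] = (
            f"no '{wt_label}' homodimer record: fractional activities assumed "
            "pre-normalised"
        )
    return DeltaMatrix(labels=labels, values=values, sds=sds, annotations=annotations)


def analyze_plate(
    curves: list[ProgressCurve],
    wellmap: pd.DataFrame,
    eps_nadh: float = EPSILON_NADH_M,
    wt_label: str = "WT",
    window: tuple[float, float] | None = None,
) -> tuple[list[ActivityRecord], DeltaMatrix, dict[str, float]]:
    """Full plate reduction: curves -> activities -> Δ matrix -> Aha1 folds.

    ``wellmap`` columns: well_id, sample_label, subunit1, subunit2,
    inhibited, aha1, hsp90_um, replicate.  Each (sample, ±Aha1) condition
    needs matching inhibited wells for background subtraction and the plate
    needs a ``wt_label`` homodimer condition for normalisation.

    Returns the activity records (basal conditions), the Δ matrix, and a
    map sample_label -> Aha1 fold stimulation for samples measured both
    with and without Aha1 (samples with no detectable basal activity are
    omitted from the fold map — their fold is undefined).
    """
    wm = wellmap.set_index("well_id")
    rates: dict[tuple[str, bool, bool], list[float]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for curve in curves:
        if curve.well_id not in wm.index:
            raise ValueError(f"well {curve.well_id!r} absent from well-map")
        row = wm.loc[curve.well_id]
        rate = rate_from_curve(
            curve, hsp90_conc=float(row["hsp90_um"]), eps_nadh=eps_nadh,
            window=window,
        )
        key = (str(row["sample_label"]), bool(row["inhibited"]), bool(row["aha1"]))
        rates.setdefault(key, []).append(rate)
        meta[str(row["sample_label"])] = (str(row["subunit1"]), str(row["subunit2"]))

    def net(sample: str, aha1: bool) -> tuple[float, float, int]:
        s = rates.get((sample, False, aha1))
        b = rates.get((sample, True, aha1))
        if s is None or b is None:
            raise ValueError(
                f"sample {sample!r} (aha1={aha1}) lacks "
                f"{'assay' if s is None else 'inhibited'} wells"
            )
        r, sd = subtract_background(s, b)
        return r, sd, len(s)

    basal = sorted({k[0] for k in rates if not k[2]})
    wt_samples = [s for s in basal if meta[s] == (wt_label, wt_label)]
    if not wt_samples:
        raise ValueError(
            f"normalisation failure: no '{wt_label}' homodimer condition on plate"
        )
    wt_rate, wt_sd, wt_n = net(wt_samples[0], False)
    if wt_rate <= 0:
        raise ValueError("normalisation failure: WT net rate is non-positive")

    records = []
    for sample in basal:
        r, sd, n = net(sample, False)
        s1, s2 = meta[sample]
        records.append(
            ActivityRecord(
                sample_label=sample,
                rate=r,
                rate_sd=sd,
                fractional_wt=r / wt_rate,
                fractional_wt_sd=(sd / np.sqrt(n)) / wt_rate,
                n_reps=n,
                subunit1=s1,
                subunit2=s2,
            )
        )
    matrix = build_delta_matrix(records, wt_label=wt_label)

    folds: dict[str, float] = {}
    stim = sorted({k[0] for k in rates if k[2] and not k[1]})
    for sample in stim:
        if sample not in basal:
            continue
        plus, _, _ = net(sample, True)
        minus, _, _ = net(sample, False)
        try:
            folds[sample] = fold_stimulation(plus, minus)
        except UndefinedFoldError:
            pass
    return records, matrix, folds


def fold_stimulation(
    rate_plus_aha1: float, rate_minus_aha1: float, min_rate: float = 1e-9
) -> float:
    """Cochaperone fold stimulation: stimulated / basal net rate.

    Raises :class:`UndefinedFoldError` when the basal rate is zero or
    below ``min_rate`` (fold stimulation has no meaning for an inactive
    sample).
    """
    if not np.isfinite(rate_minus_aha1) or rate_minus_aha1 <= min_rate:
        raise UndefinedFoldError(
            f"basal rate {rate_minus_aha1!r} is zero or near zero; "
            "fold stimulation is undefined"
        )
    return rate_plus_aha1 / rate_minus_aha1
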