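"""Amyloid and tau PET quantification.

Global amyloid burden is quantified as a distribution volume ratio (DVR) by
Logan graphical analysis against a cerebellar gray-matter reference region
with a fixed reference efflux constant k2' = 0.149 /min.  Amyloid positivity
is DVR >= 1.2; "chronicity" is the signed number of years since (positive)
or until (negative) the estimated age of crossing that threshold, obtained by
anchoring a sigmoid accumulation trajectory through the observed scan point.
Regional tau SUVR positivity thresholds are data-derived: mean + 2 SD of the
amyloid-negative subset, with strict > for positivity.

The module consumes precomputed regional values or time-activity curves; no
image-domain processing happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .simulate import TACPair
from .stats import cliffs_delta, group_compare

__all__ = [
    "LoganSettings",
    "PETRecord",
    "TrajectoryModel",
    "PIB_THRESHOLD",
    "logan_dvr",
    "pib_status_and_chronicity",
    "estimate_onset_age",
    "tau_thresholds",
    "apply_tau_positivity",
    "biomarker_group_comparison",
    "OnsetEstimationError",
]

#: global amyloid positivity threshold (DVR)
PIB_THRESHOLD = 1.2


class OnsetEstimationError(ValueError):
    """Observed DVR outside the trajectory model's invertible range."""


@dataclass(frozen=True)
class LoganSettings:
    """Logan graphical-analysis settings.

    ``t_star`` is the start (minutes) of the late linear window; frames with
    mid-time >= t_star enter the fit.  Integrals run from time zero by the
    trapezoid rule with an implicit (0, 0) origin.
    """

    k2_prime: float = 0.149
    t_star: float = 35.0

    def __post_init__(self) -> None:
        if self.k2_prime <= 0:
            raise ValueError("k2_prime must be positive")


@dataclass
class PETRecord:
    participant_id: str
    scan_age: float
    global_pib_dvr: float
    suvr: dict[str, float] = field(default_factory=dict)
    pib_positive: bool | None = None
    chronicity: float = float("nan")
    tau_positive: dict[str, bool] = field(default_factory=dict)


def _cumtrapz_from_zero(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    tt = np.concatenate([[0.0], t])
    yy = np.concatenate([[0.0], y])
    return np.cumsum(np.diff(tt) * (yy[:-1] + yy[1:]) / 2.0)


def logan_dvr(tac: TACPair, settings: LoganSettings | None = None) -> float:
    """Distribution volume ratio by Logan graphical analysis.

    Slope of the OLS fit of y(T) = int_0^T Ct / Ct(T) on
    x(T) = [int_0^T Cref + Cref(T)/k2'] / Ct(T) over frames with mid-time
    >= t_star.  For a target curve proportional to the reference the points
    are exactly collinear and the slope equals the proportionality constant.
    """
    s = settings or LoganSettings()
    t = np.asarray(tac.times, float)
    ct = np.asarray(tac.target_activity, float)
    cref = np.asarray(tac.reference_activity, float)
    if s.t_star >= t[-1]:
        raise ValueError("t_star beyond scan duration")
    win = t >= s.t_star
    if win.sum() < 3:
        raise ValueError("fewer than 3 frames after t_star")
    if (ct[win] <= 0).any():
        raise ValueError("zero/negative target activity in the linear window")
    int_ct = _cumtrapz_from_zero(t, ct)
    int_cref = _cumtrapz_from_zero(t, cref)
    y = int_ct[win] / ct[win]
    x = (int_cref[win] + cref[win] / s.k2_prime) / ct[win]
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def pib_status_and_chronicity(
    record: PETRecord,
    assessment_age: float,
    onset_age: float | None,
    threshold: float = PIB_THRESHOLD,
) -> PETRecord:
    """Set amyloid positivity (DVR >= threshold) and signed chronicity.

    Chronicity = assessment age minus estimated onset age; negative values
    mean estimated years *until* positivity.  Unknown onset leaves chronicity
    missing.
    """
    record.pib_positive = bool(record.global_pib_dvr >= threshold)
    if onset_age is None or not np.isfinite(onset_age):
        record.chronicity = float("nan")
    else:
        record.chronicity = float(assessment_age - onset_age)
    return record


@dataclass(frozen=True)
class TrajectoryModel:
    """Sigmoid amyloid-accumulation trajectory: age -> expected DVR.

    DVR(age) = floor + (ceiling - floor) / (1 + exp(-rate * (age - midpoint))).
    A functional stand-in for published group-based accumulation trajectories;
    strictly increasing, with the positivity threshold between floor and
    ceiling.
    """

    floor: float = 1.00
    ceiling: float = 2.30
    rate: float = 0.18
    midpoint: float = 75.0
    threshold: float = PIB_THRESHOLD

    def __post_init__(self) -> None:
        if not (self.floor < self.threshold < self.ceiling):
            raise ValueError("threshold must lie strictly between floor and ceiling")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def dvr(self, age: float, midpoint: float | None = None) -> float:
        m = self.midpoint if midpoint is None else midpoint
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + np.exp(-self.rate * (age - m))
        )


def estimate_onset_age(
    observed_dvr: float,
    scan_age: float,
    model: TrajectoryModel | None = None,
    tol: float = 1e-6,
) -> float:
    """Estimated age of crossing the positivity threshold.

    The individual's curve is the model sigmoid shifted along the age axis to
    pass through (scan_age, observed_dvr); the onset age solves
    curve(age*) = threshold by monotone root finding to ``tol`` years.  An
    observed DVR at or outside (floor, ceiling) is not invertible and raises
    :class:`OnsetEstimationError`.
    """
    m = model or TrajectoryModel()
    if not (m.floor < observed_dvr < m.ceiling):
        raise OnsetEstimationError(
            f"observed DVR {observed_dvr:g} outside open range "
            f"({m.floor:g}, {m.ceiling:g})"
        )
    # shift s such that sigmoid(scan_age; midpoint + s) == observed_dvr
    def anchored(shift: float) -> float:
        return m.dvr(scan_age, m.midpoint + shift) - observed_dvr

    lo, hi = -200.0, 200.0
    shift = brentq(anchored, lo, hi, xtol=tol)
    mid = m.midpoint + shift

    def at_threshold(age: float) -> float:
        return m.dvr(age, mid) - m.threshold

    return float(brentq(at_threshold, scan_age - 200.0, scan_age + 200.0, xtol=tol))


def tau_thresholds(
    suvr: pd.DataFrame,
    pib_negative: np.ndarray | pd.Series,
    regions: tuple[str, ...] = ("entorhinal", "hippocampus"),
    min_negatives: int = 10,
) -> dict[str, float]:
    """Data-derived tau positivity thresholds: mean + 2 SD of the
    amyloid-negative subset per region (sample SD, n-1 denominator).

    Regions with fewer than ``min_negatives`` amyloid-negative scans get no
    threshold.
    """
    neg = np.asarray(pib_negative, bool)
    out: dict[str, float] = {}
    for region in regions:
        col = f"suvr_{region}" if f"suvr_{region}" in suvr.columns else region
        if col not in suvr.columns:
            continue
        vals = suvr.loc[neg, col].dropna().to_numpy(float)
        if len(vals) < min_negatives:
            continue
        out[region] = float(vals.mean() + 2.0 * vals.std(ddof=1))
    return out


def apply_tau_positivity(
    suvr: pd.DataFrame, thresholds: dict[str, float]
) -> pd.DataFrame:
    """Positivity flags by strict > against each region's threshold."""
    out = pd.DataFrame(index=suvr.index)
    for region, thr in thresholds.items():
        col = f"suvr_{region}" if f"suvr_{region}" in suvr.columns else region
        out[f"tau_positive_{region}"] = suvr[col].to_numpy(float) > thr
    return out


def biomarker_group_comparison(
    pet: pd.DataFrame,
    status: pd.Series | np.ndarray,
    quantities: tuple[str, ...] = ("global_pib_dvr", "chronicity", "suvr_entorhinal", "suvr_hippocampus"),
    flags: tuple[str, ...] = ("pib_positive", "tau_positive_entorhinal", "tau_positive_hippocampus"),
    alpha: float = 0.05,
    logger=None,
) -> pd.DataFrame:
    """Compare biomarker quantities and positivity flags across status groups.

    Continuous quantities: Kruskal-Wallis omnibus with pairwise rank-sum
    follow-ups and Cliff's delta.  Positivity flags: exact tests on the
    status x positive/negative table with pairwise follow-ups.  Empty groups
    are excluded (and logged when a logger is supplied).
    """
    status = np.asarray(status)
    rows = []
    levels = [g for g in pd.unique(status) if pd.notna(g)]
    levels.sort()
    for q in quantities:
        if q not in pet.columns:
            continue
        vals = pet[q].to_numpy(float)
        ok = np.isfinite(vals) & pd.notna(status)
        use_levels = [g for g in levels if (ok & (status == g)).sum() > 0]
        skipped = set(levels) - set(use_levels)
        if skipped and logger is not None:
            logger.warning("%s: empty group(s) skipped: %s", q, sorted(skipped))
        if len(use_levels) < 2:
            continue
        keep = ok & np.isin(status, use_levels)
        res = group_compare(vals[keep], status[keep], family="kruskal_wallis", alpha=alpha)
        rows.append(dict(analysis=q, groups="omnibus", estimate=np.nan,
                         p=res["omnibus_p"], effect_size=np.nan, magnitude=""))
        for _, r in res["pairwise"].iterrows():
            rows.append(dict(analysis=q, groups=f"{r['group_a']} vs {r['group_b']}",
                             estimate=np.nan, p=r["p"], effect_size=r["effect_size"],
                             magnitude=r["magnitude"]))
    for f in flags:
        if f not in pet.columns:
            continue
        flag = pet[f]
        ok = flag.notna().to_numpy() & pd.notna(status)
        use_levels = [g for g in levels if (ok & (status == g)).sum() > 0]
        if len(use_levels) < 2:
            continue
        T = np.array(
            [
                [
                    int((ok & (status == g) & flag.astype("boolean").fillna(False).to_numpy()).sum()),
                    int((ok & (status == g) & ~flag.astype("boolean").fillna(True).to_numpy()).sum()),
                ]
                for g in use_levels
            ]
        )
        res = group_compare(T, family="fisher_exact", alpha=alpha)
        rows.append(dict(analysis=f, groups="omnibus", estimate=np.nan,
                         p=res["omnibus_p"], effect_size=res["effect_size"],
                         magnitude=res["magnitude"]))
        for _, r in res["pairwise"].iterrows():
            a, b = use_levels[int(r["group_a"])], use_levels[int(r["group_b"])]
            rows.append(dict(analysis=f, groups=f"{a} vs {b}", estimate=np.nan,
                             p=r["p"], effect_size=np.nan, magnitude=""))
    return pd.DataFrame(rows)
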