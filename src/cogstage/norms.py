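"""Robust internal norms: demographically adjusted z-scores and composites.

Raw neuropsychological test scores are converted to demographically adjusted
z-scores by regressing each (orientation-corrected) score on age, sex and a
literacy standard score over a "robust" subsample — visits of participants who
never show evidence of impairment — so that declining or impaired individuals
do not distort the normative expectations.  Composite scores are the mean of
contributing z-scores, rescaled to a standard-score metric (mean 100, SD 15).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TestSpec",
    "NormModel",
    "CompositeSet",
    "DEFAULT_BATTERY",
    "COMPOSITE_MEMBERS",
    "DOMAIN_TESTS",
    "fit_robust_norms",
    "zscore",
    "zscore_frame",
    "composites",
    "composites_frame",
    "NormFitError",
]

STANDARD_MEAN = 100.0
STANDARD_SD = 15.0

#: minimum robust visits per test for a norm fit
MIN_ROBUST_N = 50

#: minimum contributing tests per composite; CogState global tolerates 3 of 4
MIN_TESTS_FULL = "all"
COGSTATE_MIN_TESTS = 3


class NormFitError(ValueError):
    """Raised when a normative regression cannot be fitted."""


@dataclass(frozen=True)
class TestSpec:
    """One neuropsychological test: identity, orientation, composite roles."""

    name: str
    orientation: str  # "higher_better" | "lower_better"
    composites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_better", "lower_better"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def sign(self) -> float:
        return 1.0 if self.orientation == "higher_better" else -1.0


# The battery: pencil-and-paper memory/executive tests, four computerized
# (CogState) tests, and the two screening instruments used only for raw
# cut-off flagging (MMSE, Clock Draw — members of no composite).
DEFAULT_BATTERY: dict[str, TestSpec] = {
    s.name: s
    for s in [
        TestSpec("avlt_total", "higher_better", ("immediate", "pacc3")),
        TestSpec("avlt_delay", "higher_better", ("delayed",)),
        TestSpec("lm_i", "higher_better", ("immediate",)),
        TestSpec("lm_ii", "higher_better", ("delayed", "pacc3")),
        TestSpec("bvmt_total", "higher_better", ("immediate",)),
        TestSpec("bvmt_delay", "higher_better", ("delayed",)),
        TestSpec("stroop_cw", "higher_better", ("executive",)),
        TestSpec("tmt_b", "lower_better", ("executive",)),
        TestSpec("digit_symbol", "higher_better", ("executive", "pacc3")),
        TestSpec("cpal", "lower_better", ("cogstate_global",)),
        TestSpec("gml_mps", "higher_better", ("cogstate_global",)),
        TestSpec("gml_ct", "lower_better", ("cogstate_global",)),
        TestSpec("ocl", "higher_better", ("cogstate_global",)),
        TestSpec("mmse", "higher_better", ()),
        TestSpec("clock_draw", "higher_better", ()),
    ]
}

COMPOSITE_NAMES = ("immediate", "delayed", "executive", "pacc3", "cogstate_global")


def _members(battery: Mapping[str, TestSpec]) -> dict[str, tuple[str, ...]]:
    out: dict[str, list[str]] = {c: [] for c in COMPOSITE_NAMES}
    for spec in battery.values():
        for c in spec.composites:
            out[c].append(spec.name)
    return {c: tuple(v) for c, v in out.items()}


COMPOSITE_MEMBERS: dict[str, tuple[str, ...]] = _members(DEFAULT_BATTERY)

# Theoretical domains used for domain-level flagging and the multi-test
# actuarial impairment rule (PACC3 is an outcome composite, not a domain).
DOMAIN_TESTS: dict[str, tuple[str, ...]] = {
    "immediate": COMPOSITE_MEMBERS["immediate"],
    "delayed": COMPOSITE_MEMBERS["delayed"],
    "executive": COMPOSITE_MEMBERS["executive"],
    "cogstate_global": COMPOSITE_MEMBERS["cogstate_global"],
}

PREDICTORS = ("age", "sex", "wrat3_std")


@dataclass
class NormModel:
    """Per-test regression norms fitted on a robust subsample.

    ``coef[test]`` holds (intercept, age_slope, sex_offset, literacy_slope)
    for the orientation-corrected score; ``resid_sd[test]`` the residual
    standard deviation; ``robust_n[test]`` the number of fitting visits.
    """

    coef: dict[str, np.ndarray] = field(default_factory=dict)
    resid_sd: dict[str, float] = field(default_factory=dict)
    robust_n: dict[str, int] = field(default_factory=dict)
    battery: Mapping[str, TestSpec] = field(default_factory=lambda: DEFAULT_BATTERY)

    def predict(self, test: str, age: float, sex: float, literacy: float) -> float:
        b = self.coef[test]
        return float(b[0] + b[1] * age + b[2] * sex + b[3] * literacy)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.coef:
            b = self.coef[t]
            rows.append(
                dict(
                    test=t,
                    intercept=b[0],
                    age_slope=b[1],
                    sex_offset=b[2],
                    literacy_slope=b[3],
                    resid_sd=self.resid_sd[t],
                    robust_n=self.robust_n[t],
                )
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, battery: Mapping[str, TestSpec] | None = None
    ) -> "NormModel":
        m = cls(battery=battery or DEFAULT_BATTERY)
        for _, r in df.iterrows():
            m.coef[r["test"]] = np.array(
                [r["intercept"], r["age_slope"], r["sex_offset"], r["literacy_slope"]]
            )
            m.resid_sd[r["test"]] = float(r["resid_sd"])
            m.robust_n[r["test"]] = int(r["robust_n"])
        return m


def fit_robust_norms(
    visits: pd.DataFrame,
    robust_mask: Iterable[bool] | np.ndarray | pd.Series,
    battery: Mapping[str, TestSpec] | None = None,
    min_robust_n: int = MIN_ROBUST_N,
) -> NormModel:
    """Fit per-test OLS norms on the robust subsample.

    The orientation-corrected raw score is regressed on age, sex and the
    literacy standard score; ``resid_sd`` is the residual standard deviation
    (denominator n - p).  Degenerate designs (a constant predictor, or
    zero-variance residuals) and undersized subsamples raise
    :class:`NormFitError`.
    """
    battery = battery or DEFAULT_BATTERY
    mask = np.asarray(robust_mask, dtype=bool)
    if mask.shape[0] != len(visits):
        raise ValueError("robust_mask length does not match visits")
    sub = visits.loc[mask]
    model = NormModel(battery=battery)
    for name, spec in battery.items():
        if name not in sub.columns:
            continue
        cols = sub[["age", "sex", "wrat3_std", name]].dropna()
        n = len(cols)
        if n < min_robust_n:
            raise NormFitError(
                f"test {name!r}: only {n} robust visits (< {min_robust_n})"
            )
        X = cols[list(PREDICTORS)].to_numpy(float)
        for j, pname in enumerate(PREDICTORS):
            if np.ptp(X[:, j]) == 0:
                raise NormFitError(f"degenerate design: predictor {pname!r} constant")
        y = spec.sign * cols[name].to_numpy(float)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        sd = float(np.sqrt(fit.mse_resid))
        if not np.isfinite(sd) or sd <= 1e-9:
            raise NormFitError(f"test {name!r}: zero-variance residuals (degenerate)")
        model.coef[name] = np.asarray(fit.params, float)
        model.resid_sd[name] = sd
        model.robust_n[name] = n
    return model


def zscore(record: Mapping[str, object], model: NormModel) -> dict[str, float]:
    """Demographically adjusted z-scores for one visit.

    z = (oriented score - predicted score) / residual SD, with lower-is-better
    tests sign-flipped before prediction so higher z is always better.  Missing
    raw scores or demographics yield NaN, never an imputation.
    """
    out: dict[str, float] = {}
    demo = [record.get("age"), record.get("sex"), record.get("wrat3_std")]
    demo_ok = all(v is not None and np.isfinite(float(v)) for v in demo)
    for name in model.coef:
        raw = record.get(name)
        if raw is None or not demo_ok or not np.isfinite(float(raw)):
            out[name] = float("nan")
            continue
        spec = model.battery[name]
        pred = model.predict(name, float(demo[0]), float(demo[1]), float(demo[2]))
        out[name] = (spec.sign * float(raw) - pred) / model.resid_sd[name]
    return out


def zscore_frame(visits: pd.DataFrame, model: NormModel) -> pd.DataFrame:
    """Vectorized :func:`zscore` over a visits table (columns = test names)."""
    X = visits[["age", "sex", "wrat3_std"]].to_numpy(float)
    demo_ok = np.isfinite(X).all(axis=1)
    out = {}
    for name in model.coef:
        if name not in visits.columns:
            continue
        spec = model.battery[name]
        b = model.coef[name]
        pred = b[0] + X[:, 0] * b[1] + X[:, 1] * b[2] + X[:, 2] * b[3]
        raw = visits[name].to_numpy(float)
        z = (spec.sign * raw - pred) / model.resid_sd[name]
        z[~demo_ok] = np.nan
        out[name] = z
    return pd.DataFrame(out, index=visits.index)


@dataclass
class CompositeSet:
    """Composite standard scores (nominal mean 100, SD 15) for one visit."""

    scores: dict[str, float]
    n_tests: dict[str, int]

    def get(self, name: str) -> float:
        return self.scores.get(name, float("nan"))


def _composite_from_z(
    z: Mapping[str, float], members: tuple[str, ...], min_present: int
) -> tuple[float, int]:
    vals = [z[t] for t in members if t in z and np.isfinite(z[t])]
    if len(vals) < min_present:
        return float("nan"), len(vals)
    return STANDARD_MEAN + STANDARD_SD * float(np.mean(vals)), len(vals)


def composites(
    z: Mapping[str, float],
    battery: Mapping[str, TestSpec] | None = None,
) -> CompositeSet:
    """Standard-score composites: 100 + 15 x mean of contributing z-scores.

    All listed tests must be present, except the CogState global composite
    which tolerates three of four.  Unknown test names in the battery's
    composite assignments raise a configuration error.
    """
    battery = battery or DEFAULT_BATTERY
    members = _members(battery) if battery is not DEFAULT_BATTERY else COMPOSITE_MEMBERS
    scores: dict[str, float] = {}
    n_tests: dict[str, int] = {}
    for comp, mem in members.items():
        for t in mem:
            if t not in battery:
                raise ValueError(f"composite {comp!r} references unknown test {t!r}")
        min_present = COGSTATE_MIN_TESTS if comp == "cogstate_global" else len(mem)
        scores[comp], n_tests[comp] = _composite_from_z(z, mem, min_present)
    return CompositeSet(scores, n_tests)


def composites_frame(
    zf: pd.DataFrame, battery: Mapping[str, TestSpec] | None = None
) -> pd.DataFrame:
    """Vectorized composites over a z-score table; NaN where too few tests."""
    battery = battery or DEFAULT_BATTERY
    members = _members(battery) if battery is not DEFAULT_BATTERY else COMPOSITE_MEMBERS
    out = {}
    for comp, mem in members.items():
        cols = [t for t in mem if t in zf.columns]
        block = zf[cols].to_numpy(float) if cols else np.empty((len(zf), 0))
        n_ok = np.isfinite(block).sum(axis=1)
        min_present = COGSTATE_MIN_TESTS if comp == "cogstate_global" else len(mem)
        with np.errstate(invalid="ignore"):
            mean_z = np.nanmean(block, axis=1) if block.shape[1] else np.full(len(zf), np.nan)
        score = STANDARD_MEAN + STANDARD_SD * mean_z
        score[n_ok < min_present] = np.nan
        out[comp] = score
    return pd.DataFrame(out, index=zf.index)
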