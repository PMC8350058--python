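"""Two-tier cognitive staging: flagging algorithm and actuarial status rules.

Tier 1 screens every visit with a flagging algorithm built to minimize false
negatives: fixed raw-score cut-offs on screening and memory tests, informant
report cut-offs, and robust-norm domain-composite z cut-offs.  Unflagged
visits are cognitively unimpaired-stable (CU_S) by definition.  Tier 2 —
a consensus review panel in practice — is codified here as a deterministic
actuarial rule set in the multi-test-per-domain tradition: two or more tests
within one cognitive domain at z <= -1.5 (or a clinical raw cut-off) defines
impairment; preserved daily function separates MCI from dementia; flagged
visits not meeting impairment criteria are cognitively unimpaired-declining
(CU_D, subclinical decline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import norms as _norms
from .norms import DOMAIN_TESTS, CompositeSet, NormModel
from .stats import exact_binomial_ci

__all__ = [
    "FlagThresholds",
    "FlagResult",
    "CognitiveStatus",
    "StatusTimeline",
    "STATUS_ORDER",
    "flag_visit",
    "assign_status",
    "stage_cohort",
    "progression_outcomes",
    "reversion_summary",
]

#: impairment ordering used for reversion (strictly less-impaired moves)
STATUS_ORDER = {"CU_S": 0, "CU_D": 1, "MCI": 2, "DEMENTIA": 3}

#: labels a staged visit may carry; IMPAIRED_NON_MCI is accepted on input
#: (an exclusion label) but never produced by assign_status
CognitiveStatus = str
STATUS_LABELS = ("CU_S", "CU_D", "MCI", "DEMENTIA", "IMPAIRED_NON_MCI")

CLINICAL = ("MCI", "DEMENTIA")

#: domains consulted by the domain-z flag rule and the multi-test impairment
#: rule: pencil-and-paper domains only — the review stage is blind to the
#: computerized (CogState) battery so that CogState outcomes stay independent
#: of status assignment
STAGING_DOMAINS = ("immediate", "delayed", "executive")
FLAG_DOMAINS = STAGING_DOMAINS


@dataclass(frozen=True)
class FlagThresholds:
    """Cut-offs of the flagging algorithm and the actuarial impairment rule.

    Inequality directions follow the printed clinical conventions exactly:
    flag when Clock Draw <= 7, MMSE <= 26, AVLT Delayed <= 5, Logical Memory
    II <= 16, CDR >= 0.5, QDRS >= 0.5, IADL < 14, IQCODE > 52, or any domain
    composite z <= -1.5.
    """

    clock_draw_max_pass: float = 7.0
    mmse_max_pass: float = 26.0
    avlt_delay_max_pass: float = 5.0
    lm2_delay_max_pass: float = 16.0
    cdr_flag_min: float = 0.5
    qdrs_flag_min: float = 0.5
    iadl_flag_below: float = 14.0
    iqcode_flag_above: float = 52.0
    domain_z_flag: float = -1.5
    mci_z_cut: float = -1.5
    mci_min_tests_per_domain: int = 2
    dementia_cdr_min: float = 1.0

    def __post_init__(self) -> None:
        vals = [
            self.clock_draw_max_pass, self.mmse_max_pass, self.avlt_delay_max_pass,
            self.lm2_delay_max_pass, self.cdr_flag_min, self.qdrs_flag_min,
            self.iadl_flag_below, self.iqcode_flag_above, self.domain_z_flag,
            self.mci_z_cut,
        ]
        if not all(np.isfinite(vals)):
            raise ValueError("all thresholds must be finite")
        if self.domain_z_flag >= 0:
            raise ValueError("domain_z_flag must be negative")


@dataclass
class FlagResult:
    flagged: bool
    fired: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.flagged == bool(self.fired)


RAW_CUTOFFS = (
    ("clock_draw", "clock_draw_max_pass"),
    ("mmse", "mmse_max_pass"),
    ("avlt_delay", "avlt_delay_max_pass"),
    ("lm_ii", "lm2_delay_max_pass"),
)


def _present(value) -> bool:
    if value is None:
        return False
    try:
        return bool(np.isfinite(float(value)))
    except (TypeError, ValueError):
        return False


def flag_visit(
    record: Mapping[str, object],
    z: Mapping[str, float],
    composites: CompositeSet | Mapping[str, float],
    thresholds: FlagThresholds | None = None,
) -> FlagResult:
    """Tier-1 screen of one visit; missing inputs never fire a criterion."""
    th = thresholds or FlagThresholds()
    fired: list[str] = []
    for test, attr in RAW_CUTOFFS:
        v = record.get(test)
        if _present(v) and float(v) <= getattr(th, attr):
            fired.append(test)
    cdr = record.get("cdr_global")
    if _present(cdr) and float(cdr) >= th.cdr_flag_min:
        fired.append("cdr")
    qdrs = record.get("qdrs_global")
    if _present(qdrs) and float(qdrs) >= th.qdrs_flag_min:
        fired.append("qdrs")
    iadl = record.get("iadl")
    if _present(iadl) and float(iadl) < th.iadl_flag_below:
        fired.append("iadl")
    iqc = record.get("iqcode")
    if _present(iqc) and float(iqc) > th.iqcode_flag_above:
        fired.append("iqcode")
    comp_get = composites.get if hasattr(composites, "get") else composites.__getitem__
    for dom in FLAG_DOMAINS:
        c = comp_get(dom)
        if c is None or not np.isfinite(c):
            continue
        # composite is on the standard-score scale; convert back to z
        cz = (c - _norms.STANDARD_MEAN) / _norms.STANDARD_SD
        if cz <= th.domain_z_flag:
            fired.append(f"domain:{dom}")
    return FlagResult(bool(fired), fired)


def _mci_cognitive_criteria(
    fired: Sequence[str], z: Mapping[str, float], th: FlagThresholds
) -> bool:
    if any(f in dict(RAW_CUTOFFS) for f in fired):
        return True
    for dom in STAGING_DOMAINS:
        tests = DOMAIN_TESTS[dom]
        n_low = sum(
            1
            for t in tests
            if t in z and np.isfinite(z[t]) and z[t] <= th.mci_z_cut
        )
        if n_low >= th.mci_min_tests_per_domain:
            return True
    return False


def assign_status(
    flag: FlagResult,
    z: Mapping[str, float],
    composites: CompositeSet | Mapping[str, float],
    record: Mapping[str, object],
    thresholds: FlagThresholds | None = None,
) -> CognitiveStatus:
    """Tier-2 actuarial status for one flagged (or unflagged) visit.

    CU_S iff not flagged.  Otherwise: impairment criteria are >= 2 tests
    within one domain at z <= -1.5 or any clinical raw cut-off; DEMENTIA when
    impairment criteria hold with lost daily function (IADL < 14) and a CDR
    global of >= 1; MCI when impairment criteria hold with preserved daily
    function (IADL >= 14 or missing); CU_D for every other flagged visit.
    """
    th = thresholds or FlagThresholds()
    if not flag.flagged:
        return "CU_S"
    cognitive = _mci_cognitive_criteria(flag.fired, z, th)
    iadl = record.get("iadl")
    iadl_low = _present(iadl) and float(iadl) < th.iadl_flag_below
    cdr = record.get("cdr_global")
    cdr_dem = _present(cdr) and float(cdr) >= th.dementia_cdr_min
    if cognitive and iadl_low and cdr_dem:
        return "DEMENTIA"
    if cognitive and not iadl_low:
        return "MCI"
    return "CU_D"


def stage_cohort(
    visits: pd.DataFrame,
    model: NormModel,
    thresholds: FlagThresholds | None = None,
) -> pd.DataFrame:
    """Flag and stage every visit of a cohort table.

    Returns a table aligned with ``visits``: participant_id, visit_index,
    label, fired_criteria (semicolon-joined), and the domain composites.
    """
    th = thresholds or FlagThresholds()
    zf = _norms.zscore_frame(visits, model)
    comps = _norms.composites_frame(zf)
    labels: list[str] = []
    fired_all: list[str] = []
    zcols = {c: zf[c].to_numpy() for c in zf.columns}
    comp_cols = {c: comps[c].to_numpy() for c in comps.columns}
    recs = visits.to_dict("records")
    for i, rec in enumerate(recs):
        zrow = {t: zcols[t][i] for t in zcols}
        crow = {c: comp_cols[c][i] for c in comp_cols}
        fl = flag_visit(rec, zrow, crow, th)
        labels.append(assign_status(fl, zrow, crow, rec, th))
        fired_all.append(";".join(fl.fired))
    out = visits[["participant_id", "visit_index"]].copy()
    out["label"] = labels
    out["fired_criteria"] = fired_all
    for c in comps.columns:
        out[c] = comps[c].to_numpy()
    return out


@dataclass
class StatusTimeline:
    """Per-participant longitudinal status sequence and derived outcomes."""

    participant_id: str
    statuses: list[CognitiveStatus]
    primary_progression: bool
    anyvisit_progression: bool
    nextvisit_events: list[tuple[CognitiveStatus, CognitiveStatus]]


def progression_outcomes(
    statuses: Sequence[CognitiveStatus], participant_id: str = ""
) -> StatusTimeline:
    """Progression outcomes from one ordered label sequence.

    Primary progression: clinical (MCI/dementia) at some visit >= 2 AND
    clinical at the most recent visit.  Any-visit progression: clinical at
    some visit >= 2, reverted or not.  Single-visit timelines are rejected
    explicitly rather than defaulted.
    """
    statuses = list(statuses)
    if len(statuses) < 2:
        raise ValueError("progression outcomes need at least two visits")
    for s in statuses:
        if s not in STATUS_LABELS:
            raise ValueError(f"unknown status label {s!r}")
    later_clinical = any(s in CLINICAL for s in statuses[1:])
    return StatusTimeline(
        participant_id=participant_id,
        statuses=statuses,
        primary_progression=later_clinical and statuses[-1] in CLINICAL,
        anyvisit_progression=later_clinical,
        nextvisit_events=list(zip(statuses[:-1], statuses[1:])),
    )


def reversion_summary(
    timelines: Iterable[StatusTimeline | Sequence[CognitiveStatus]],
    from_statuses: tuple[str, ...] = ("CU_D", "MCI"),
    level: float = 0.95,
) -> pd.DataFrame:
    """Next-visit reversion counts and exact CIs, pooled over visit-pairs.

    Denominators are status-visits with a follow-up (repeat statuses within a
    person each count); numerators are next-visit moves to any strictly
    less-impaired status.  Per-destination rows break the numerator down.
    """
    events: list[tuple[str, str]] = []
    for tl in timelines:
        seq = tl.statuses if isinstance(tl, StatusTimeline) else list(tl)
        events.extend(zip(seq[:-1], seq[1:]))
    rows = []
    for frm in from_statuses:
        pairs = [e for e in events if e[0] == frm]
        denom = len(pairs)
        dests = sorted(
            {d for _, d in pairs if STATUS_ORDER.get(d, 99) < STATUS_ORDER[frm]},
            key=lambda d: STATUS_ORDER[d],
        )
        total_rev = sum(
            1 for _, d in pairs if STATUS_ORDER.get(d, 99) < STATUS_ORDER[frm]
        )
        for scope, k in [("any_less_impaired", total_rev)] + [
            (d, sum(1 for _, x in pairs if x == d)) for d in dests
        ]:
            if denom == 0:
                rows.append(
                    dict(from_status=frm, to=scope, reverted=0, denominator=0,
                         proportion=np.nan, ci_lower=np.nan, ci_upper=np.nan)
                )
                continue
            ci = exact_binomial_ci(k, denom, level)
            rows.append(
                dict(
                    from_status=frm,
                    to=scope,
                    reverted=k,
                    denominator=denom,
                    proportion=k / denom,
                    ci_lower=ci.lower,
                    ci_upper=ci.upper,
                )
            )
    return pd.DataFrame(rows)
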