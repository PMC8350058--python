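"""Pipeline orchestration: robust-norm driver and the validation run.

``run_validate`` ties the stages together on one cohort: simulate (or load)
visits and PET scans, fit robust norms, stage every visit, then run the four
validity analyses — concurrent group separation on composite scores,
within-person change, progression risk (proportions and an adjusted logistic
model), visit-to-visit reversion, and PET biomarker separation — writing every
table as tidy CSV plus a plain-text report stamped with the seed and a config
hash.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import norms as cnorms
from . import pet as cpet
from . import staging as cstaging
from . import stats as cstats
from .simulate import generate_cohort

__all__ = ["robust_norms_auto", "progression_table", "run_validate"]


def _preliminary_flag_mask(visits: pd.DataFrame, th: cstaging.FlagThresholds) -> pd.Series:
    """Per-visit raw-cut-off + informant-cut-off screen (no z-scores yet)."""
    f = pd.Series(False, index=visits.index)
    for test, attr in cstaging.RAW_CUTOFFS:
        if test in visits.columns:
            f |= visits[test] <= getattr(th, attr)
    if "cdr_global" in visits.columns:
        f |= visits["cdr_global"] >= th.cdr_flag_min
    if "qdrs_global" in visits.columns:
        f |= visits["qdrs_global"] >= th.qdrs_flag_min
    if "iadl" in visits.columns:
        f |= visits["iadl"] < th.iadl_flag_below
    if "iqcode" in visits.columns:
        f |= visits["iqcode"] > th.iqcode_flag_above
    return f.fillna(False)


def robust_norms_auto(
    visits: pd.DataFrame,
    thresholds: cstaging.FlagThresholds | None = None,
    min_robust_n: int = cnorms.MIN_ROBUST_N,
) -> tuple[cnorms.NormModel, pd.Series]:
    """Two-pass robust norming.

    Pass 1 fits norms on visits of participants never caught by the raw-score
    or informant cut-offs alone.  Pass 2 stages the whole cohort with those
    provisional norms and refits on visits of participants never assigned
    CU_D, MCI or dementia.  Returns the final model and the final robust mask.
    """
    th = thresholds or cstaging.FlagThresholds()
    prelim = _preliminary_flag_mask(visits, th)
    ever = visits.loc[prelim, "participant_id"].unique()
    mask1 = ~visits["participant_id"].isin(ever)
    model1 = cnorms.fit_robust_norms(visits, mask1, min_robust_n=min_robust_n)
    staged = cstaging.stage_cohort(visits, model1, th)
    impaired = staged.loc[staged["label"] != "CU_S", "participant_id"].unique()
    mask2 = ~visits["participant_id"].isin(impaired)
    model2 = cnorms.fit_robust_norms(visits, mask2, min_robust_n=min_robust_n)
    return model2, mask2


def progression_table(staged: pd.DataFrame) -> pd.DataFrame:
    """Per-participant baseline status and progression outcomes."""
    rows = []
    for pid, grp in staged.sort_values("visit_index").groupby("participant_id", sort=False):
        seq = grp["label"].tolist()
        if len(seq) < 2:
            continue
        tl = cstaging.progression_outcomes(seq, pid)
        rows.append(
            dict(
                participant_id=pid,
                baseline_status=seq[0],
                n_visits=len(seq),
                primary_progression=tl.primary_progression,
                anyvisit_progression=tl.anyvisit_progression,
            )
        )
    return pd.DataFrame(rows)


def _tidy(rows: list[dict]) -> pd.DataFrame:
    cols = ["analysis", "groups", "estimate", "ci_lower", "ci_upper", "p",
            "effect_size", "magnitude"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]


def _concurrent_tables(visits, staged, alpha, fdr_q):
    """Status-group separation on composites at the most recent visit."""
    last = staged.sort_values("visit_index").groupby("participant_id").tail(1)
    last = last[last["label"].isin(["CU_S", "CU_D", "MCI", "DEMENTIA"])].copy()
    last["group"] = last["label"].replace({"DEMENTIA": "MCI"})  # MCI/Dementia pooled
    rows = []
    pvals = []
    per_comp = []
    for comp in cnorms.COMPOSITE_NAMES:
        vals = last[comp].to_numpy(float)
        ok = np.isfinite(vals)
        res = cstats.group_compare(vals[ok], last["group"].to_numpy()[ok],
                                   family="anova", alpha=alpha)
        per_comp.append((comp, res))
        pvals.append(res["omnibus_p"])
    rejected = cstats.bh_fdr(pvals, fdr_q)
    for (comp, res), rej in zip(per_comp, rejected):
        rows.append(dict(analysis=f"concurrent:{comp}", groups="omnibus",
                         p=res["omnibus_p"], magnitude="fdr_reject" if rej else ""))
        for _, r in res["pairwise"].iterrows():
            rows.append(dict(analysis=f"concurrent:{comp}",
                             groups=f"{r['group_a']} vs {r['group_b']}", p=r["p"],
                             effect_size=r["effect_size"], magnitude=r["magnitude"]))
    return _tidy(rows)


def _change_tables(visits, staged, alpha):
    """Change between the last two visits among those CU_S at the earlier one."""
    s = staged.sort_values("visit_index")
    rows = []
    merged = []
    for pid, grp in s.groupby("participant_id", sort=False):
        if len(grp) < 2:
            continue
        prev, lastv = grp.iloc[-2], grp.iloc[-1]
        if prev["label"] != "CU_S":
            continue
        a_prev = visits.loc[(visits["participant_id"] == pid)
                            & (visits["visit_index"] == prev["visit_index"]), "age"]
        a_last = visits.loc[(visits["participant_id"] == pid)
                            & (visits["visit_index"] == lastv["visit_index"]), "age"]
        merged.append((pid, prev, lastv, float(a_last.iloc[0] - a_prev.iloc[0])))
    for comp in cnorms.COMPOSITE_NAMES:
        ch, gr, base, itv = [], [], [], []
        for pid, prev, lastv, dt in merged:
            b, l = prev[comp], lastv[comp]
            if np.isfinite(b) and np.isfinite(l):
                ch.append(l - b)
                gr.append(lastv["label"] if lastv["label"] in ("CU_S", "CU_D") else "MCI")
                base.append(b)
                itv.append(dt)
        gr_s = pd.Series(gr)
        if gr_s.nunique() < 2 or gr_s.value_counts().min() < 2:
            continue
        res = cstats.change_ancova(ch, gr, base, itv)
        rows.append(dict(analysis=f"change:{comp}", groups="omnibus",
                         p=res["omnibus_p"], magnitude=f"KW p={res['kruskal_p']:.3g}"))
        for lev, m in res["adjusted_means"].items():
            rows.append(dict(analysis=f"change:{comp}", groups=f"lsmean {lev}", estimate=m))
        for (a, b), c in res["contrasts"].items():
            rows.append(dict(analysis=f"change:{comp}", groups=f"{a} vs {b}",
                             estimate=c["estimate"], p=c["p"]))
    return _tidy(rows)


def _progression_tables(visits, staged, alpha):
    prog = progression_table(staged)
    prog = prog[prog["baseline_status"].isin(["CU_S", "CU_D"])].copy()
    rows = []
    for status, grp in prog.groupby("baseline_status"):
        k = int(grp["primary_progression"].sum())
        n = len(grp)
        ci = cstats.wald_binomial_ci(k, n)
        rows.append(dict(analysis="progression:primary", groups=f"baseline {status}",
                         estimate=k / n, ci_lower=ci.lower, ci_upper=ci.upper))
    base = visits.sort_values("visit_index").groupby("participant_id").head(1)
    fup = (visits.groupby("participant_id")["age"].max()
           - visits.groupby("participant_id")["age"].min())
    m = prog.merge(base, on="participant_id").merge(
        fup.rename("followup_years"), left_on="participant_id", right_index=True
    )
    cov = pd.DataFrame(
        dict(
            cu_d_baseline=(m["baseline_status"] == "CU_D").astype(float),
            baseline_age=m["age"],
            sex=m["sex"],
            literacy=m["wrat3_std"],
            followup_years=m["followup_years"],
        )
    )
    try:
        ors = cstats.logistic_progression(m["primary_progression"].astype(int), cov)
        for _, r in ors.iterrows():
            rows.append(dict(analysis="progression:logistic", groups=r["term"],
                             estimate=r["odds_ratio"], ci_lower=r["ci_lower"],
                             ci_upper=r["ci_upper"], p=r["p"]))
    except cstats.SeparationError as exc:
        rows.append(dict(analysis="progression:logistic", groups="error",
                         magnitude=str(exc)))
    rev = cstaging.reversion_summary(
        [grp["label"].tolist()
         for _, grp in staged.sort_values("visit_index").groupby("participant_id")]
    )
    for _, r in rev.iterrows():
        rows.append(dict(analysis=f"reversion:{r['from_status']}", groups=r["to"],
                         estimate=r["proportion"], ci_lower=r["ci_lower"],
                         ci_upper=r["ci_upper"]))
    return _tidy(rows), prog


def _nearest_status(staged: pd.DataFrame, visits: pd.DataFrame, pet: pd.DataFrame) -> pd.Series:
    """Status at the cognitive assessment nearest each scan (prior on ties)."""
    sv = staged.merge(visits[["participant_id", "visit_index", "age"]],
                      on=["participant_id", "visit_index"])
    out = {}
    for _, scan in pet.iterrows():
        g = sv[sv["participant_id"] == scan["participant_id"]]
        if g.empty:
            out[scan["participant_id"]] = np.nan
            continue
        d = (g["age"] - scan["scan_age"]).to_numpy(float)
        # ties in |distance| resolve to the earlier (prior) assessment
        order = np.lexsort((g["age"].to_numpy(), np.abs(d)))
        out[scan["participant_id"]] = g.iloc[order[0]]["label"]
    return pet["participant_id"].map(out)


def _biomarker_tables(visits, staged, pet, alpha, logger=None):
    pet = pet.copy()
    pet["pib_positive"] = pet["global_pib_dvr"] >= cpet.PIB_THRESHOLD
    model = cpet.TrajectoryModel()
    onset = []
    for _, r in pet.iterrows():
        try:
            onset.append(cpet.estimate_onset_age(r["global_pib_dvr"], r["scan_age"], model))
        except cpet.OnsetEstimationError:
            onset.append(np.nan)
    pet["estimated_onset_age"] = onset
    pet["chronicity"] = pet["scan_age"] - pet["estimated_onset_age"]
    thr = cpet.tau_thresholds(pet, ~pet["pib_positive"].to_numpy())
    flags = cpet.apply_tau_positivity(pet, thr)
    pet = pd.concat([pet, flags], axis=1)
    status = _nearest_status(staged, visits, pet)
    status = status.replace({"DEMENTIA": "MCI"})
    comp = cpet.biomarker_group_comparison(pet, status, alpha=alpha, logger=logger)
    comp["analysis"] = "biomarker:" + comp["analysis"]
    return _tidy(comp.to_dict("records")), pet, thr


def run_validate(config: cio.RunConfig) -> dict:
    """Run the full validation pipeline; returns tables and writes CSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = cio.get_logger(out / "run.log")
    chash = cio.config_hash(config)
    logger.info("run_validate seed=%d config=%s", config.seed, chash)

    if config.visits_path:
        visits = cio.read_visits(config.visits_path)
        pet = cio.read_pet(config.pet_path) if config.pet_path else None
    else:
        config.sim.seed = config.seed
        visits, pet = generate_cohort(config.sim)
        logger.info("simulated cohort: %d visits, %d participants",
                    len(visits), visits["participant_id"].nunique())

    if config.norms_path:
        model = cio.read_norm_model(config.norms_path)
    else:
        model, robust_mask = robust_norms_auto(visits, config.thresholds)
        logger.info("robust subsample: %d of %d visits", int(robust_mask.sum()), len(visits))
    staged = cstaging.stage_cohort(visits, model, config.thresholds)
    counts = staged["label"].value_counts().to_dict()
    logger.info("status counts: %s", counts)

    tables: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []
    if config.run_concurrent:
        tables["concurrent"] = _concurrent_tables(visits, staged, config.alpha, config.fdr_q)
    else:
        skipped.append("concurrent")
    if config.run_change:
        tables["change"] = _change_tables(visits, staged, config.alpha)
    else:
        skipped.append("change")
    prog_df = None
    if config.run_progression:
        tables["progression"], prog_df = _progression_tables(visits, staged, config.alpha)
    else:
        skipped.append("progression")
    if config.run_biomarker and pet is not None:
        tables["biomarker"], pet_aug, tau_thr = _biomarker_tables(
            visits, staged, pet, config.alpha, logger
        )
    else:
        skipped.append("biomarker")
        pet_aug, tau_thr = None, {}

    stamp = f"# seed={config.seed} config_hash={chash}\n"
    cio.write_norm_model(model, out / "norms.csv")
    staged.to_csv(out / "statuses.csv", index=False)
    if prog_df is not None:
        prog_df.to_csv(out / "outcomes.csv", index=False)
    lines = [f"cogstage validation report (seed={config.seed}, config={chash})", ""]
    for name, tbl in tables.items():
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(stamp)
            tbl.to_csv(fh, index=False)
        lines.append(f"== {name} ==")
        lines.append(tbl.to_string(index=False, max_rows=200))
        lines.append("")
    for name in skipped:
        lines.append(f"== {name} == skipped (disabled or no input)")
    if tau_thr:
        lines.append(f"tau thresholds (mean + 2 SD of PiB(-)): {tau_thr}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    logger.info("report written to %s", out / "report.txt")
    return dict(tables=tables, staged=staged, model=model, visits=visits,
                pet=pet_aug, tau_thresholds=tau_thr, config_hash=chash,
                skipped=skipped)
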