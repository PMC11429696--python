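"""Pipeline orchestration: simulate -> score gaze -> morphometrics -> analyses.

``run_simulate`` writes a complete synthetic dataset (four data tables, the
competence sidecar, the generating truth, and a run manifest). ``run_analyze``
executes the stage graph on any dataset in the gaze_io schemas and emits a
figure-keyed ``analysis_report.json`` plus tabular outputs; every reported
number carries the name of the operation that produced it and its n.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._version import __version__
from .errors import ConfigError, DataValidationError
from .election_analysis import (
    classify_state_lean,
    correlate,
    fit_joint_model,
    partial_correlate,
    stratified_summary,
)
from .facial_morphometrics import (
    METRIC_FEATURES,
    aggregate_raters,
    group_contrast,
    metrics_table,
    read_landmark_table,
)
from .gaze_io import (
    read_competence_table,
    read_election_table,
    read_fixation_table,
    read_layout_table,
)
from .gaze_scoring import (
    VOTE_RULES,
    accuracy_by_session,
    accuracy_summary,
    candidate_fixation_profile,
    paired_gaze_test,
    tally_table_from_frame,
    unpaired_gaze_test,
)
from .synthetic_data import SimConfig, simulate_dataset

logger = logging.getLogger("gazevote")

DECISIONS = [
    "ties earn half credit; every race stays in the accuracy denominator",
    "vote shares two-party normalized at ingestion",
    "predicted winner = less-looked-at candidate under every rule",
    "accuracy unit = one proportion per session, mean +/- SEM across sessions",
    "raw p-values reported; Tukey HSD adjustment only within an ANOVA family",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest(command: str, inputs: Mapping[str, Path], outputs: Mapping[str, Path],
              config: dict, started: float) -> dict:
    return {
        "command": command,
        "tool_version": __version__,
        "config": config,
        "input_digests": {k: _sha256(Path(p)) for k, p in inputs.items()},
        "output_files": {k: str(p) for k, p in outputs.items()},
        "output_digests": {k: _sha256(Path(p)) for k, p in outputs.items()},
        "started_unix": started,
        "ended_unix": time.time(),
    }


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(config: SimConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Generate and write a synthetic dataset; returns the run manifest."""
    out = Path(out_dir)
    started = time.time()
    existing = [p for p in ("fixations.csv", "elections.csv") if (out / p).exists()]
    if existing and not force:
        raise ConfigError(f"output files already exist in {out} (use force=True): {existing}")
    sim = simulate_dataset(config)
    paths = sim.write(out)
    manifest = _manifest("simulate", {}, paths, config.model_dump(), started)
    manifest["n_sessions"] = int(sim.layouts.shape[0])
    manifest["n_monkey_days"] = int(config.n_days)
    manifest["n_races"] = int(sim.elections["race_id"].nunique())
    manifest["warnings"] = []
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("simulate: %d races, %d sessions -> %s",
                manifest["n_races"], manifest["n_sessions"], out)
    return manifest


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def _corr_entry(res, operation: str, extra: dict | None = None) -> dict:
    out = {"operation": operation, "r": res.r, "ci95": [res.ci_low, res.ci_high],
           "p": res.p_two_sided, "n": res.n, "method": res.method}
    if extra:
        out.update(extra)
    return out


def _apply_subsets(races_df: pd.DataFrame, subsets: Mapping[str, str]) -> pd.DataFrame:
    df = races_df
    for key, val in subsets.items():
        if key == "office":
            df = df[df["office"] == val]
        elif key == "gender":
            comp = {"male-male": "MM", "mixed": "FM", "female-female": "FF"}.get(val)
            if comp is None:
                raise ConfigError(f"unknown gender subset {val!r}")
            df = df[df["pair_gender"] == comp]
        elif key == "incumbency":
            want = val == "with"
            if val not in ("with", "without"):
                raise ConfigError(f"unknown incumbency subset {val!r}")
            df = df[df["has_incumbent"] == want]
        elif key == "lean":
            if val not in ("blue", "swing", "red"):
                raise ConfigError(f"unknown lean subset {val!r}")
            df = df[df["lean"] == val]
        else:
            raise ConfigError(f"unknown subset key {key!r}")
    if df.empty:
        raise ConfigError(f"subset filter {dict(subsets)} leaves no races")
    return df


def run_analyze(
    data_dir: str | Path,
    out_dir: str | Path,
    subsets: Mapping[str, str] | None = None,
    rules: Sequence[str] = VOTE_RULES,
) -> dict:
    """Run the full analysis stage graph and write the figure-keyed report.

    Raises :class:`DataValidationError` (with the violation report attached)
    when the dataset fails cross-validation.
    """
    from .gaze_io import validate_dataset

    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    subsets = dict(subsets or {})

    inputs = {name: data / f"{name}.csv"
              for name in ("fixations", "elections", "landmarks", "layout")}
    sessions = read_fixation_table(inputs["fixations"])
    races, candidates = read_election_table(inputs["elections"])
    layouts = read_layout_table(inputs["layout"])
    landmark_df = read_landmark_table(inputs["landmarks"])
    competence_path = data / "competence.csv"
    competence = read_competence_table(competence_path) if competence_path.exists() else {}
    if competence_path.exists():
        inputs["competence"] = competence_path

    violations = validate_dataset(sessions, races, candidates)
    if violations:
        err = DataValidationError(
            f"dataset failed validation with {len(violations)} violation(s)")
        err.violations = violations
        raise err
    logger.info("validated: %d sessions, %d races, %d candidates",
                len(sessions), len(races), len(candidates))

    # --- assemble working frames ------------------------------------------
    cand_df = pd.DataFrame([asdict(c) for c in candidates])
    race_df = pd.DataFrame([{
        "race_id": r.race_id, "office": r.office, "year": r.year, "state": r.state,
        "margin": r.ref_presidential_margin_pct, "winner_id": r.winner_id,
    } for r in races])
    race_df["lean"] = race_df["margin"].map(classify_state_lean)
    genders = cand_df.groupby("race_id")["gender"].agg(
        lambda g: "".join(sorted(g))).rename("pair_gender")  # FF, FM, MM
    race_df = race_df.merge(genders.reset_index(), on="race_id")
    race_df = race_df.merge(
        cand_df.groupby("race_id")["incumbent"].any().rename("has_incumbent").reset_index(),
        on="race_id")
    race_df = _apply_subsets(race_df, subsets)
    keep_races = set(race_df["race_id"])
    cand_df = cand_df[cand_df["race_id"].isin(keep_races)].copy()
    cand_df["age"] = cand_df.apply(
        lambda r: race_df.set_index("race_id").loc[r["race_id"], "year"] - r["birth_year"],
        axis=1)
    if competence:
        cand_df["competence"] = cand_df["candidate_id"].map(competence)

    fix_df = pd.read_csv(inputs["fixations"], dtype={
        "session_id": str, "monkey_id": str, "race_id": str,
        "left_candidate_id": str, "right_candidate_id": str})
    fix_df = fix_df[fix_df["race_id"].isin(keep_races)]
    layout_df = pd.read_csv(inputs["layout"], dtype={"session_id": str})
    tally = tally_table_from_frame(fix_df, layout_df)
    winner_by_race = dict(zip(race_df["race_id"], race_df["winner_id"]))

    report: dict = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "subsets": subsets,
        "decisions": DECISIONS,
        "n": {"sessions": len(sessions), "races": int(race_df.shape[0]),
              "candidates": int(cand_df.shape[0]), "trials": int(tally.shape[0])},
    }

    # --- gaze bias by outcome and gender (fig 1b/1c) -----------------------
    prof = candidate_fixation_profile(tally_df=tally)
    prof = prof.merge(cand_df, on="candidate_id", how="inner")
    prof = prof.merge(race_df[["race_id", "lean", "pair_gender", "has_incumbent"]],
                      on="race_id", how="left")
    winners = prof[prof["winner"]].set_index("race_id")
    losers = prof[~prof["winner"].astype(bool)].set_index("race_id")
    common = winners.index.intersection(losers.index)
    lw, ww = (losers.loc[common, "mean_fixations"].to_numpy(),
              winners.loc[common, "mean_fixations"].to_numpy())
    report["fig1b"] = {
        "operation": "paired_gaze_test",
        "loser_mean_fixations": float(lw.mean()), "winner_mean_fixations": float(ww.mean()),
        "p_loser_vs_winner": paired_gaze_test(lw, ww), "n_races": int(common.size),
    }
    fem = prof[prof["gender"] == "F"]["mean_fixations"].to_numpy()
    male = prof[prof["gender"] == "M"]["mean_fixations"].to_numpy()
    if fem.size and male.size:
        report["fig1b"]["gender"] = {
            "operation": "unpaired_gaze_test",
            "female_mean_fixations": float(fem.mean()), "male_mean_fixations": float(male.mean()),
            "p_female_vs_male": unpaired_gaze_test(fem, male),
            "n_female": int(fem.size), "n_male": int(male.size),
        }
    mm = race_df[race_df["pair_gender"] == "MM"]["race_id"]
    mm_common = common.intersection(mm)
    if mm_common.size >= 2:
        report["fig1c"] = {
            "operation": "paired_gaze_test", "subset": "male-male",
            "p_loser_vs_winner": paired_gaze_test(
                losers.loc[mm_common, "mean_fixations"].to_numpy(),
                winners.loc[mm_common, "mean_fixations"].to_numpy()),
            "n_races": int(mm_common.size),
        }

    # --- prediction accuracy (fig 1d, s1e) ---------------------------------
    report["fig1d"] = {}
    for rule in rules:
        per_sess = accuracy_by_session(tally, winner_by_race, rule)
        summ = accuracy_summary(per_sess.to_list())
        report["fig1d"][rule] = {
            "operation": "accuracy_summary",
            "per_session": list(summ.per_session_accuracy),
            "mean": summ.mean, "sem": summ.sem, "t": summ.t_statistic,
            "p": summ.p_two_sided, "n_sessions": summ.n_sessions,
            "tie_policy": "half credit",
        }
    report["s1e"] = {rule: report["fig1d"][rule]["mean"] for rule in rules}

    # --- fixations vs vote share (fig 1e, s1f) -----------------------------
    report["fig1e"] = _corr_entry(
        correlate(prof["mean_fixations"], prof["vote_share_pct"]),
        "correlate(mean_fixations, vote_share)")
    inc_prof = prof[prof["has_incumbent"]]
    if inc_prof.shape[0] >= 3:
        report["s1f"] = _corr_entry(
            correlate(inc_prof["mean_fixations"], inc_prof["vote_share_pct"]),
            "correlate(mean_fixations, vote_share | incumbent races)")

    # --- morphometrics ------------------------------------------------------
    landmark_df = landmark_df[landmark_df["candidate_id"].isin(set(cand_df["candidate_id"]))]
    per_rater = metrics_table(landmark_df)
    metrics, concordance = aggregate_raters(per_rater)
    metrics_out = out / "metrics.csv"
    metrics.to_csv(metrics_out, index=False)
    mdf = metrics.merge(cand_df, on="candidate_id").merge(
        race_df[["race_id", "lean"]], on="race_id")
    report["rater_concordance"] = {"operation": "aggregate_raters",
                                   "concordance": concordance,
                                   "n_candidates": int(metrics.shape[0])}

    report["fig2b"] = _corr_entry(
        correlate(mdf["jaw_prominence"], mdf["vote_share_pct"]),
        "correlate(jaw_prominence, vote_share)")
    report["fig2c"] = {
        feat: _corr_entry(correlate(mdf[feat], mdf["vote_share_pct"]),
                          f"correlate({feat}, vote_share)")
        for feat in METRIC_FEATURES}
    gprof = prof[["candidate_id", "mean_fixations", "mean_bias"]]
    gm = mdf.merge(gprof, on="candidate_id", how="inner").dropna(subset=["mean_bias"])
    report["fig2d"] = {
        "gaze_bias_vs_vote_share": _corr_entry(
            correlate(gm["mean_bias"], gm["vote_share_pct"]),
            "correlate(mean_gaze_bias, vote_share)"),
        "jaw_vs_gaze_bias": _corr_entry(
            correlate(gm["jaw_prominence"], gm["mean_bias"]),
            "correlate(jaw_prominence, mean_gaze_bias)"),
    }

    # --- contrasts (s2c, s2d) ----------------------------------------------
    strata_rows = []
    if (mdf["gender"] == "F").sum() >= 2 and (mdf["gender"] == "M").sum() >= 2:
        gc = group_contrast(mdf, "gender")
        report["s2c"] = {"operation": "group_contrast(gender)",
                         "table": gc.to_dict(orient="records")}
    oc = group_contrast(mdf, "outcome")
    jaw_row = oc[oc["feature"] == "jaw_prominence"].iloc[0]
    report["s2d"] = {"operation": "group_contrast(outcome)",
                     "table": oc.to_dict(orient="records"),
                     "jaw_pct_diff_winner_vs_loser": float(jaw_row["pct_diff"]),
                     "jaw_p": float(jaw_row["p"])}

    # --- competence (partial correlations, joint model) --------------------
    if "competence" in mdf.columns and mdf["competence"].notna().all():
        report["competence"] = {
            "jaw_vs_competence": _corr_entry(
                correlate(mdf["jaw_prominence"], mdf["competence"]),
                "correlate(jaw_prominence, competence)"),
            "partial_competence_vote_given_jaw": _corr_entry(
                partial_correlate(mdf["competence"], mdf["vote_share_pct"],
                                  mdf["jaw_prominence"]),
                "partial_correlate(competence, vote_share | jaw)"),
            "partial_jaw_vote_given_competence": _corr_entry(
                partial_correlate(mdf["jaw_prominence"], mdf["vote_share_pct"],
                                  mdf["competence"]),
                "partial_correlate(jaw_prominence, vote_share | competence)"),
        }
        jm = fit_joint_model(mdf["vote_share_pct"], mdf["jaw_prominence"], mdf["competence"])
        report["competence"]["joint_model"] = {
            "operation": "fit_joint_model", "intercept": jm.intercept,
            "coef_jaw": jm.coef_jaw, "coef_competence": jm.coef_competence,
            "r_squared": jm.r_squared, "n": jm.n,
            "p_jaw": jm.p_jaw, "p_competence": jm.p_competence,
        }
    else:
        logger.warning("competence ratings absent or incomplete; skipping "
                       "partial-correlation and joint-model analyses")

    # --- state lean (fig 2e, fig 2f) ----------------------------------------
    if race_df["lean"].nunique() > 1:
        dem = cand_df[cand_df["party"] == "D"].merge(
            race_df[["race_id", "lean"]], on="race_id")
        if not dem.empty:
            tbl = dem.groupby("lean")["winner"].agg(["mean", "size"])
            report["fig2e"] = {
                "operation": "stratified_summary(democratic winner rate)",
                "groups": {str(k): {"p_dem_win": float(v["mean"]), "n": int(v["size"])}
                           for k, v in tbl.iterrows()}}
        loser_bias = (losers["mean_fixations"] - winners.loc[losers.index.intersection(
            winners.index), "mean_fixations"]).rename("loser_bias").reset_index()
        lb = loser_bias.merge(race_df[["race_id", "lean"]], on="race_id")
        if lb["lean"].nunique() > 1 and lb.groupby("lean").size().min() >= 2:
            strat = stratified_summary(lb["loser_bias"].to_numpy(), lb["lean"].to_numpy())
            report["fig2f"] = {
                "operation": "stratified_summary(loser-directed gaze bias by lean)",
                "groups": strat["groups"].to_dict(orient="records"),
                "anova_p": strat["anova_p"],
                "contrasts": (strat["contrasts"].to_dict(orient="records")
                              if strat["contrasts"] is not None else None)}
            for rec in strat["groups"].to_dict(orient="records"):
                strata_rows.append({"analysis": "fig2f", **rec})

    # --- age (s2h) ----------------------------------------------------------
    report["s2h"] = {
        "age_vs_vote_share": _corr_entry(
            correlate(cand_df["age"], cand_df["vote_share_pct"]),
            "correlate(age, vote_share)"),
        "age_vs_jaw": _corr_entry(
            correlate(mdf["age"], mdf["jaw_prominence"]),
            "correlate(age, jaw_prominence)"),
    }

    # --- outputs ------------------------------------------------------------
    preds_frames = []
    from .gaze_scoring import predictions_from_tallies
    for rule in rules:
        p = predictions_from_tallies(tally, rule)
        true_winner = p["race_id"].map(winner_by_race)
        p["correct"] = np.where(p["predicted_winner_id"].isna(), np.nan,
                                (p["predicted_winner_id"] == true_winner).astype(float))
        preds_frames.append(p[["session_id", "race_id", "rule",
                               "predicted_winner_id", "correct"]])
    preds_out = out / "predictions.csv"
    pd.concat(preds_frames, ignore_index=True).to_csv(preds_out, index=False)
    accuracy_out = out / "accuracy.json"
    accuracy_out.write_text(json.dumps(report["fig1d"], indent=2, default=float))
    strata_out = out / "strata.csv"
    pd.DataFrame(strata_rows).to_csv(strata_out, index=False)
    report_out = out / "analysis_report.json"
    report_out.write_text(json.dumps(report, indent=2, default=float))

    outputs = {"analysis_report": report_out, "predictions": preds_out,
               "accuracy": accuracy_out, "metrics": metrics_out, "strata": strata_out}
    manifest = _manifest("analyze", inputs, outputs,
                         {"subsets": subsets, "rules": list(rules)}, started)
    manifest["warnings"] = []
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return report


def render_report_markdown(report: dict) -> str:
    """Human-readable summary of an analysis report."""
    lines = ["# gazevote analysis report", ""]
    n = report.get("n", {})
    lines.append(f"Sessions: {n.get('sessions')}; races: {n.get('races')}; "
                 f"candidates: {n.get('candidates')}; trials: {n.get('trials')}")
    if report.get("subsets"):
        lines.append(f"Subsets: {report['subsets']}")
    lines.append("")
    fig1d = report.get("fig1d", {})
    if fig1d:
        lines.append("## Prediction accuracy (mean +/- SEM vs chance 0.5)")
        for rule, e in fig1d.items():
            p = "n/a" if e["p"] is None else f"{e['p']:.3g}"
            lines.append(f"- {rule}: {e['mean']:.3f} +/- {e['sem']:.3f} "
                         f"(n={e['n_sessions']} sessions, p={p})")
        lines.append("")
    for key in ("fig1e", "fig2b"):
        e = report.get(key)
        if e:
            lines.append(f"## {key}: {e['operation']}")
            lines.append(f"r = {e['r']:.3f} [{e['ci95'][0]:.3f}, {e['ci95'][1]:.3f}], "
                         f"p = {e['p']:.3g}, n = {e['n']}")
            lines.append("")
    comp = report.get("competence", {})
    if comp.get("joint_model"):
        jm = comp["joint_model"]
        lines.append("## Joint appearance model (vote share ~ jaw + competence)")
        lines.append(f"R^2 = {jm['r_squared']:.3f} (n = {jm['n']})")
        lines.append("")
    return "\n".join(lines)
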