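"""End-to-end wiring of the analysis stages on the CSV interfaces."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from cogrci import battery, models, rci, report
from cogrci.simulate import SimulationConfig, apply_missingness, generate_control_cohort, generate_surgical_cohort, write_cohort_tables


def simulate_stage(config: SimulationConfig, outdir) -> None:
    """Generate control + surgical cohorts and write all tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cbase, cretest = generate_control_cohort(config)
    sbase, sfollow, cov, truth = generate_surgical_cohort(config)
    if config.missing_rate_item > 0:
        import numpy as np

        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x3A]))
        cbase = apply_missingness(cbase, config.missing_rate_item, rng)
        cretest = apply_missingness(cretest, config.missing_rate_item, rng)
        sbase = apply_missingness(sbase, config.missing_rate_item, rng)
        sfollow = apply_missingness(sfollow, config.missing_rate_item, rng)
    write_cohort_tables(outdir, sbase, sfollow, cov, truth)
    rows = []
    for session, frame in (("baseline", cbase), ("followup", cretest)):
        block = frame.reset_index()
        block.insert(1, "session", session)
        rows.append(block)
    pd.concat(rows, ignore_index=True).to_csv(outdir / "control_assessments.csv", index=False)


def classify_stage(
    assessments_path,
    control_assessments_path,
    outdir,
    threshold: float = rci.DEFAULT_THRESHOLD,
    min_available: int = rci.DEFAULT_MIN_AVAILABLE,
) -> pd.DataFrame:
    """Fit the control reference, z-score the surgical cohort, classify.

    Writes ``outcomes.csv`` (both preCI and POCD rows) and
    ``control_reference.json``; returns the outcomes frame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sbase, sfollow = battery.load_assessments(assessments_path)
    cbase, cretest = battery.load_assessments(control_assessments_path)

    control_baseline = battery.orient_frame(cbase)
    control_change = battery.change_frame(cbase, cretest)
    ref = rci.fit_control_reference(control_change, control_baseline)

    zb = rci.zscore_frame(battery.orient_frame(sbase), ref, "baseline", min_available)
    pre = rci.classify_frame(zb, threshold, "preCI")

    zc = rci.zscore_frame(battery.change_frame(sbase, sfollow), ref, "change", min_available)
    pocd = rci.classify_frame(zc, threshold, "POCD")

    outcomes = pd.concat([pre, pocd]).rename_axis("subject_id").reset_index()
    outcomes.to_csv(outdir / "outcomes.csv", index=False)
    ref.to_json(outdir / "control_reference.json")
    return outcomes


def _outcome_column(outcomes: pd.DataFrame, kind: str) -> pd.Series:
    sub = outcomes[outcomes["outcome_kind"] == kind].set_index("subject_id")
    imp = sub["impaired"]
    if imp.dtype == object:
        imp = imp.map({"True": True, "False": False, True: True, False: False})
    return imp.astype("boolean").astype("Float64")


def associate_stage(outcomes_path, covariates_path, outdir) -> pd.DataFrame:
    """Fit the unadjusted and adjusted logistic models for both outcomes.

    Writes ``model_results.csv`` and ``model_report.txt``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outcomes = pd.read_csv(outcomes_path)
    cov = pd.read_csv(covariates_path).set_index("subject_id")

    fits: dict[str, models.LogisticFit] = {}
    for kind in ("preCI", "POCD"):
        y = _outcome_column(outcomes, kind)
        data = cov.join(y.rename(kind))
        for label, spec in (
            (f"{kind}_unadjusted", models.ModelSpec.unadjusted(kind)),
            (f"{kind}_adjusted", models.ModelSpec.adjusted(kind)),
        ):
            try:
                fits[label] = models.fit_logistic(data, spec)
            except (ValueError, models.SeparationError) as exc:
                with open(outdir / "model_report.txt", "a") as fh:
                    fh.write(f"{label}: not estimable ({exc})\n")
    table = models.logistic_results_table(fits)
    table.to_csv(outdir / "model_results.csv", index=False)
    with open(outdir / "model_report.txt", "a") as fh:
        for label, fit in fits.items():
            thal = "thalamus_cm3"
            lo, hi = fit.ci95[thal]
            fh.write(
                f"{label}: OR per cm3 {fit.odds_ratios[thal]:.2f} "
                f"[95% CI {lo:.2f}-{hi:.2f}] p={fit.p_values[thal]:.3f} "
                f"AUC={fit.auc:.2f} (p={fit.auc_p:.3f}) n={fit.n_used} "
                f"converged={fit.converged} max_vif={max(fit.vif.values()):.2f}\n"
            )
    return table


def flow_status_table(assessments_path, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Derive a per-subject flow status table from the pipeline outputs.

    The synthetic generator withholds follow-up without a reason, so all
    losses are booked as ``alive_not_tested``; POD is not simulated and is
    set to False throughout.
    """
    sbase, sfollow = battery.load_assessments(assessments_path)
    pre = _outcome_column(outcomes, "preCI").astype("boolean")
    pocd = _outcome_column(outcomes, "POCD").astype("boolean")
    status = pd.DataFrame(index=sbase.index)
    status["status"] = "alive_not_tested"
    status.loc[status.index.isin(sfollow.index), "status"] = "followup_tested"
    status["preCI"] = pre.reindex(status.index)
    status["POCD"] = pocd.reindex(status.index)
    status.loc[status["status"] != "followup_tested", "POCD"] = pd.NA
    status["POD"] = False
    return status


def report_stage(assessments_path, covariates_path, outcomes_path, outdir) -> None:
    """Flow ledger, characteristics table and group boxplot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outcomes = pd.read_csv(outcomes_path)
    cov = pd.read_csv(covariates_path).set_index("subject_id")
    status = flow_status_table(assessments_path, outcomes)
    ledger = report.build_flow(status)
    ledger.to_frame().to_csv(outdir / "flow_ledger.csv")

    pre_idx = status.index[status["preCI"].fillna(False).astype(bool)]
    pocd_idx = status.index[status["POCD"].fillna(False).astype(bool)]
    groups = {"all": status.index, "preCI": pre_idx, "POCD": pocd_idx}
    numeric = cov.drop(columns=[c for c in ("surgery_type",) if c not in cov.columns], errors="ignore")
    report.characteristics_table(numeric, groups).to_csv(outdir / "characteristics.csv")
    report.boxplot_groups(cov["thalamus_cm3"], groups, outdir / "thalamus_boxplot.svg")
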