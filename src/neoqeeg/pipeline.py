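"""End-to-end orchestration: simulate -> features -> classify -> stats.

Each stage is seeded from the single configuration seed, every report
carries the resolved configuration hash, and a run with the same
(config, seed) is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import family_report
from .features import extract_features, features_table
from .io import PipelineConfig, cohort_frame, config_hash, write_cohort_csv
from .simulate import generate_cohort, generate_eeg, profile_for_subject
from .stats import (ContingencyTable2x2, diagnostic_metrics, logistic_fit,
                    mann_whitney_u, odds_ratio, round_half_up, transform_dq)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "cohort_statistics"]


def _subject_seed(seed: int, i: int) -> int:
    return (seed * 100003 + 7919 * i + 1) % (2**31 - 1)


def cohort_statistics(df: pd.DataFrame) -> dict:
    """Outcome statistics of a cohort table (2x2, logistic, Mann-Whitney).

    Subjects without outcome data are excluded (with a logged count).
    Returns a JSON-serialisable dict with the dysmature-EEG and
    abnormal-EEG exposure tables, odds ratios, diagnostic metrics, a
    univariable and a multivariable logistic model, and Mann-Whitney
    comparisons of the developmental quotients by dysmaturity.
    """
    have_outcome = df["asd_24m"].notna()
    n_excluded = int((~have_outcome).sum())
    if n_excluded:
        logger.info("excluding %d subject(s) without outcome data", n_excluded)
    d = df[have_outcome].copy()
    d["asd"] = d["asd_24m"].astype(bool)

    out = {"n_with_outcome": int(len(d)), "n_excluded": n_excluded}
    out["asd_prevalence_pct"] = round_half_up(100.0 * d["asd"].mean())

    for expo in ("dysmature_eeg", "abnormal_eeg"):
        t = ContingencyTable2x2.from_binary(d[expo].astype(bool), d["asd"])
        orr = odds_ratio(t)
        dm = diagnostic_metrics(t).as_percent()
        out[expo] = {
            "table": [t.a, t.b, t.c, t.d],
            "odds_ratio": round_half_up(orr.odds_ratio, 1),
            "ci": [round_half_up(orr.ci_low, 1), round_half_up(orr.ci_high, 1)],
            **dm,
        }

    # univariable logistic: ASD ~ dysmature background
    X = pd.DataFrame({"dysmature_eeg": d["dysmature_eeg"].astype(float)})
    uni = logistic_fit(X, d["asd"].astype(int))
    out["logistic_univariable"] = {
        "B": float(uni.table.loc["dysmature_eeg", "B"]),
        "OR": round_half_up(uni.odds_ratio("dysmature_eeg"), 1),
        "p": float(uni.table.loc["dysmature_eeg", "p"]),
    }

    # multivariable: ASD ~ abnormal EEG + treatment + mutation, in block
    Xm = pd.DataFrame({
        "abnormal_eeg": d["abnormal_eeg"].astype(float),
        "conventional": (d["treatment"] == "conventional").astype(float),
        "tsc2": (d["mutation"] == "TSC2").astype(float),
    })
    try:
        multi = logistic_fit(Xm, d["asd"].astype(int))
        out["logistic_multivariable"] = {
            "OR_abnormal_eeg": round_half_up(multi.odds_ratio("abnormal_eeg"), 1),
            "model_chi2": round_half_up(multi.model_chi2, 3),
            "nagelkerke_r2": round_half_up(multi.nagelkerke_r2, 3),
            "converged": multi.converged,
        }
    except Exception as err:
        logger.warning("multivariable logistic model failed: %s", err)
        out["logistic_multivariable"] = {"error": str(err)}

    dq_tests = {}
    for col, kind in (("dq_cognitive", "log"), ("dq_language", "reciprocal"),
                      ("dq_motor", None)):
        sub = d[d[col].notna()]
        x = sub.loc[sub["dysmature_eeg"].astype(bool), col].to_numpy(float)
        y = sub.loc[~sub["dysmature_eeg"].astype(bool), col].to_numpy(float)
        if x.size and y.size:
            mw = mann_whitney_u(x, y)
            entry = {"median_dysmature": float(np.median(x)),
                     "median_mature": float(np.median(y)),
                     "U": mw.u, "p": mw.p}
            if kind is not None:  # transform used by the linear models
                entry["transform"] = kind
                _ = transform_dq(np.concatenate([x, y]), kind)
            dq_tests[col] = entry
    out["dq_mann_whitney"] = dq_tests
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run simulate -> features -> classify -> stats and write all reports.

    Writes ``cohort.csv``, ``features.csv``, ``classifier_report.csv``,
    ``stats_report.json`` and ``summary.json`` under ``out_dir`` and
    returns the summary dict. Fully reproducible from (config, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    logger.info("pipeline start: seed=%d config=%s", config.seed, chash)

    # 1. cohort
    design = config.cohort.to_design()
    records = generate_cohort(config.cohort.n, design, seed=config.seed)
    write_cohort_csv(records, out_dir / "cohort.csv")
    df = cohort_frame(records)

    # 2. EEG + features
    fcfg = config.features.to_feature_config()
    fvs = []
    for i, rec in enumerate(records):
        eeg = generate_eeg(profile_for_subject(rec), config.eeg.duration_s,
                           config.eeg.fs, config.eeg.channels,
                           seed=_subject_seed(config.seed, i))
        eeg.subject_id = rec.subject_id
        fvs.append(extract_features(eeg, fcfg))
    feats = features_table(fvs, aggregate="median")
    feats.index.name = "subject_id"
    feats.to_csv(out_dir / "features.csv", na_rep="NA")

    # 3. classification per feature family
    have = df["asd_24m"].notna().to_numpy()
    y = df.loc[have, "asd_24m"].astype(bool).astype(int).to_numpy()
    clf_report = None
    classes, counts = np.unique(y, return_counts=True)
    if classes.size == 2 and counts.min() >= config.classifier.folds:
        clf_report = family_report(
            feats.iloc[np.flatnonzero(have)],
            y, k_features=config.classifier.k_features, seed=config.seed,
            repetitions=config.classifier.repetitions)
        clf_report.index.name = "family"
        clf_report.to_csv(out_dir / "classifier_report.csv")
    else:
        logger.warning("outcome classes too imbalanced for %d-fold testing; "
                       "classification skipped", config.classifier.folds)

    # 4. outcome statistics
    stats = cohort_statistics(df)
    with open(out_dir / "stats_report.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_subjects": len(records),
        "stats": stats,
        "classifier": (None if clf_report is None
                       else {fam: {"E_pct": round(row["E_pct"], 2),
                                   "auc_pct": round(row["auc_pct"], 2)}
                             for fam, row in clf_report.iterrows()}),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline done: %s", out_dir)
    return summary
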