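"""Cohort report tables: per-grade score summaries and detection statistics.

Two standard layouts are produced from a per-subject score table (as
returned by :func:`fidnav.pipeline.score_cohort`):

* a per-grade summary — mean and SD of every integrated score variant within
  each image grade, with a Spearman-correlation footer row; the ccc scores
  are reported x100;
* a detection summary — AUC and Youden's J (mean +- SD over bootstrap
  replicates), the full-sample optimal threshold, and the 0.632-bootstrap
  sensitivity and specificity, per metric and dichotomization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fidnav.detection import bootstrap_632, dichotomize, spearman
from fidnav.integration import REPORT_SCALE
from fidnav.metrics import METRIC_NAMES


def _score_columns(scores: pd.DataFrame) -> list[str]:
    cols = [m for m in METRIC_NAMES if m in scores.columns]
    cols += [f"w_{m}" for m in METRIC_NAMES if f"w_{m}" in scores.columns]
    return cols


def _display(col: str, values: pd.Series) -> pd.Series:
    metric = col[2:] if col.startswith("w_") else col
    return values * REPORT_SCALE.get(metric, 1.0)


def grade_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-grade mean +- SD of every score variant, plus a Spearman row."""
    cols = _score_columns(scores)
    rows = []
    for grade, grp in scores.groupby("grade"):
        row: dict[str, object] = {"grade": grade, "n": len(grp)}
        for c in cols:
            v = _display(c, grp[c])
            row[f"{c}_mean"] = v.mean()
            row[f"{c}_sd"] = v.std(ddof=1) if len(grp) > 1 else 0.0
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("grade").reset_index(drop=True)
    footer: dict[str, object] = {"grade": "spearman_rho", "n": len(scores)}
    for c in cols:
        rho, _ = spearman(scores[c].to_numpy(), scores["grade"].to_numpy())
        footer[f"{c}_mean"] = rho
        footer[f"{c}_sd"] = np.nan
    return pd.concat([out, pd.DataFrame([footer])], ignore_index=True)


def detection_summary(
    scores: pd.DataFrame,
    b: int = 1000,
    seed: int = 0,
    metrics: tuple[str, ...] = METRIC_NAMES,
    schemes: tuple[str, ...] = ("12v345", "123v45"),
) -> pd.DataFrame:
    """AUC / J / threshold / SE / SP per metric and grade dichotomization."""
    rows = []
    grades = scores["grade"].to_numpy()
    for scheme in schemes:
        labels = dichotomize(grades, scheme)
        for m in metrics:
            vals = scores[m].to_numpy()
            res = bootstrap_632(vals, labels, b=b, seed=seed)
            scale = REPORT_SCALE.get(m, 1.0)
            rows.append(
                {
                    "metric": m,
                    "dichotomization": scheme,
                    "auc_mean": res.auc_mean,
                    "auc_sd": res.auc_sd,
                    "j_mean": res.j_mean,
                    "j_sd": res.j_sd,
                    "threshold": res.threshold * scale,
                    "se_632": res.se_632,
                    "sp_632": res.sp_632,
                }
            )
    return pd.DataFrame(rows)
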