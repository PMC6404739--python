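"""Sensitivity and symptom-level analyses on the LOCF-completed m-ITT sample.

Both analyses compare baseline and outcome (week 6), so the group x time
interaction in a two-timepoint repeated-measures model is fitted through its
algebraic equivalent: an ordinary least-squares model for the baseline-to-
outcome change score.  The sensitivity model additionally adjusts for baseline
severity and the number of training sessions completed, mirroring the trial's
covariate set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ..trial import ITEM_COLS, TrialDataset, apply_locf

__all__ = ["SensitivityResult", "locf_sensitivity_model", "item_level_analysis"]

OUTCOME_WEEK = 6


@dataclass
class SensitivityResult:
    F: float
    df1: int
    df2: int
    p: float
    group_effect: float      # adjusted EFMT-minus-CT effect on Ham-D change
    n: int
    collinear: bool
    covariates: tuple[str, ...] = ("baseline_hamd", "sessions_total")


def _mitt_changes(dataset: TrialDataset, column: str) -> pd.DataFrame:
    """Per-participant baseline and LOCF week-6 values of ``column`` (m-ITT)."""
    ds = dataset if dataset.locf is not None else apply_locf(dataset)
    d = ds.locf[ds.locf["mitt"]]
    base = d[d["week"] == 0].set_index("participant_id")[column]
    outc = d[d["week"] == OUTCOME_WEEK].set_index("participant_id")[column]
    arm = d[d["week"] == 0].set_index("participant_id")["arm"]
    out = pd.DataFrame({"arm": arm, "baseline": base, "outcome": outc})
    out["change"] = out["outcome"] - out["baseline"]
    return out.dropna()


def locf_sensitivity_model(dataset: TrialDataset) -> SensitivityResult:
    """Group x time test of Ham-D change, adjusted for baseline severity and
    sessions completed, in the LOCF-completed m-ITT sample."""
    ch = _mitt_changes(dataset, "hamd_total")
    sess = dataset.participants.set_index("participant_id")["sessions_total"]
    ch = ch.join(sess, how="inner")
    y = ch["change"].to_numpy(float)
    X = pd.DataFrame({
        "const": 1.0,
        "efmt": (ch["arm"] == "EFMT").astype(float),
        "baseline_hamd": ch["baseline"].astype(float),
        "sessions_total": ch["sessions_total"].astype(float),
    }, index=ch.index)
    collinear = bool(np.linalg.matrix_rank(X.to_numpy()) < X.shape[1])
    fit = sm.OLS(y, X).fit()
    ftest = fit.f_test("efmt = 0")
    return SensitivityResult(
        F=float(ftest.fvalue), df1=int(ftest.df_num), df2=int(ftest.df_denom),
        p=float(ftest.pvalue), group_effect=float(fit.params["efmt"]),
        n=len(ch), collinear=collinear)


def item_level_analysis(dataset: TrialDataset) -> pd.DataFrame:
    """Per-item group x time tests at baseline vs outcome, uncorrected.

    One row per Ham-D item (17 rows): F(1, n-2), p, and a ``significant``
    flag at the trial's exploratory alpha of 0.05.  No multiple-comparison
    correction is applied (``multiplicity_correction`` column says so
    explicitly).  Items constant across the sample yield NA rows.
    """
    rows = []
    for i, col in enumerate(ITEM_COLS, start=1):
        ch = _mitt_changes(dataset, col)
        y = ch["change"].to_numpy(float)
        g = (ch["arm"] == "EFMT").to_numpy(float)
        n = len(ch)
        if n < 3 or np.var(y) == 0 or np.var(g) == 0:
            rows.append({"item": i, "F": np.nan, "df1": 1, "df2": max(n - 2, 0),
                         "p": np.nan, "significant": False,
                         "multiplicity_correction": "none"})
            continue
        X = np.column_stack([np.ones(n), g])
        fit = sm.OLS(y, X).fit()
        t = fit.tvalues[1]
        F = float(t * t)
        p = float(stats.f.sf(F, 1, n - 2))
        rows.append({"item": i, "F": F, "df1": 1, "df2": n - 2, "p": p,
                     "significant": bool(p < 0.05),
                     "multiplicity_correction": "none"})
    out = pd.DataFrame(rows)
    assert len(out) == 17
    return out
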