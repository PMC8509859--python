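"""Covariate-adjusted association battery with Benjamini-Hochberg FDR control.

Every sleep measure (outcome) is regressed on every exposure (diagnosis
status or polygenic risk score) by ordinary least squares, adjusting for age
and season at accelerometry, sex, Townsend deprivation index, and the top 10
genotype principal components.  Outcome and exposure are both z-scored
(binary exposures on their 0/1 coding), so the exposure coefficient is a
standardized beta comparable across measures and exposures.  Confidence
intervals and p-values use normal critical values, appropriate for cohort
sizes in the thousands.  Benjamini-Hochberg adjustment is applied across the
whole battery by default (or per exposure via ``family="per_exposure"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

FDR_Q = 0.05
SEASONS = ["winter", "spring", "summer", "autumn"]
COVARIATE_COLUMNS = ["age", "sex", "townsend", "season"] + [f"pc{i}" for i in range(1, 11)]
MIN_N = 30  # fits below this n are flagged, not fitted

RESULT_COLUMNS = [
    "exposure", "outcome", "beta_std", "ci_low", "ci_high", "p", "fdr",
    "n", "n_cases", "n_controls", "status",
]


def season_of(date) -> str:
    """Meteorological season of a date (Dec-Feb winter, Mar-May spring, ...)."""
    month = pd.Timestamp(date).month
    return SEASONS[(month % 12) // 3]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate exposure: zero variance")
    return (x - x.mean()) / sd


def design_matrix(covars: pd.DataFrame) -> np.ndarray:
    """Intercept + covariates, with season one-hot encoded (winter reference)."""
    missing = [c for c in COVARIATE_COLUMNS if c not in covars.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    n = len(covars)
    cols = [np.ones(n)]
    for c in ["age", "sex", "townsend"] + [f"pc{i}" for i in range(1, 11)]:
        cols.append(covars[c].to_numpy(dtype=float))
    season = covars["season"].astype(str)
    unknown = set(season) - set(SEASONS)
    if unknown:
        raise ValueError(f"unknown season label(s): {sorted(unknown)}")
    for s in SEASONS[1:]:
        cols.append((season == s).to_numpy(dtype=float))
    return np.column_stack(cols)


@dataclass(frozen=True)
class AssociationResult:
    exposure: str
    outcome: str
    beta_std: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_cases: int | None
    n_controls: int | None
    status: str = "ok"


def fit_one(
    outcome: pd.Series,
    exposure: pd.Series,
    covars: pd.DataFrame,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    min_n: int = MIN_N,
) -> AssociationResult:
    """OLS of one z-scored outcome on one z-scored exposure plus covariates.

    Participants with a missing outcome, exposure or covariate are dropped
    (for diagnosis exposures, excluded participants arrive as NaN).  Binary
    exposures also report case/control counts.  A constant exposure raises;
    an n below ``min_n`` returns a flagged, unfitted row.
    """
    df = pd.concat(
        [outcome.rename("_y"), exposure.rename("_x"), covars[COVARIATE_COLUMNS]],
        axis=1, join="inner",
    ).dropna()
    n = len(df)
    y_raw = df["_y"].to_numpy(dtype=float)
    x_raw = df["_x"].to_numpy(dtype=float)
    binary = set(np.unique(x_raw)) <= {0.0, 1.0}
    n_cases = int(x_raw.sum()) if binary else None
    n_controls = int(n - x_raw.sum()) if binary else None
    if n < min_n:
        return AssociationResult(exposure_name, outcome_name, np.nan, np.nan,
                                 np.nan, np.nan, n, n_cases, n_controls,
                                 status="insufficient_n")
    y = _zscore(y_raw)
    x = _zscore(x_raw)
    X = np.column_stack([x, design_matrix(df[COVARIATE_COLUMNS])])
    fit = sm.OLS(y, X).fit()
    b = float(fit.params[0])
    se = float(fit.bse[0])
    zcrit = float(stats.norm.ppf(0.975))
    p = float(2.0 * stats.norm.sf(abs(b) / se)) if se > 0 else np.nan
    return AssociationResult(
        exposure_name, outcome_name, b, b - zcrit * se, b + zcrit * se,
        max(p, np.finfo(float).tiny), n, n_cases, n_controls,
    )


def bh_adjust(p_values: np.ndarray, q: float = FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; a test is
    flagged when its adjusted value is <= ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out, out <= q


def run_battery(
    measures: pd.DataFrame,
    exposures: pd.DataFrame,
    covars: pd.DataFrame,
    q: float = FDR_Q,
    family: str = "battery",
    min_n: int = MIN_N,
) -> pd.DataFrame:
    """All-by-all battery: every exposure column against every measure column.

    All three tables are indexed by participant id.  Returns one row per
    exposure x measure in deterministic order (exposures then measures, in
    their given column order), with BH-adjusted FDR computed within the
    chosen family (``"battery"``: all fitted tests together;
    ``"per_exposure"``: separately for each exposure's 10 tests).  Flagged
    fits (insufficient n) keep their row with an NaN effect rather than
    disappearing.
    """
    if family not in ("battery", "per_exposure"):
        raise ValueError(f"unknown FDR family: {family!r}")
    rows = []
    for exp_name in exposures.columns:
        for meas_name in measures.columns:
            try:
                res = fit_one(
                    measures[meas_name], exposures[exp_name], covars,
                    exposure_name=exp_name, outcome_name=meas_name, min_n=min_n,
                )
            except ValueError:
                res = AssociationResult(exp_name, meas_name, np.nan, np.nan,
                                        np.nan, np.nan, 0, None, None,
                                        status="degenerate_exposure")
            rows.append(vars(res).copy())
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    ok = out["status"] == "ok"
    if family == "battery":
        groups = [ok]
    else:
        groups = [ok & (out["exposure"] == e) for e in exposures.columns]
    out["significant"] = False
    for g in groups:
        if g.any():
            adj, flag = bh_adjust(out.loc[g, "p"].to_numpy(), q=q)
            out.loc[g, "fdr"] = adj
            out.loc[g, "significant"] = flag
    return out[RESULT_COLUMNS + ["significant"]]
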