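"""Per-probe regression on parity and q-value multiple-testing control.

The per-probe models share one design matrix, so fitting is vectorized:
a single least-squares solve yields every probe's parity coefficient,
t statistic and two-sided p value.  Final gene lists are meant to use the
multiple-regression p values; single-regression results are kept for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from paritysig.io_config import CohortMetadata, ExpressionMatrix

CYCLE_LEVELS = ("luteal", "ovulatory", "follicular", "hormonal_IUD", "missing")
NUMERIC_COVARIATES = ("age_years", "bmi", "smoking_duration_years")
DEFAULT_COVARIATES = ("age_years", "bmi", "smoking_duration_years", "cycle_iud")

COMPARISON_ALL = "all_P_vs_NP"
COMPARISON_TSLP_LE5 = "tslp_le5_vs_NP"


@dataclass
class ProbeTestResult:
    probe_id: str
    beta_parity: float
    fold_change: float
    p_value: float
    q_value: float | None
    model: str  # 'single' | 'multiple'
    comparison: str

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


def _comparison_samples(metadata: CohortMetadata, comparison: str) -> list[str]:
    df = metadata.data
    if comparison == COMPARISON_ALL:
        return list(df.index)
    if comparison == COMPARISON_TSLP_LE5:
        keep = (df["parity"] == "nulliparous") | (
            (df["parity"] == "parous") & (df["tslp_years"] <= 5.0)
        )
        return list(df.index[keep])
    raise ValueError(f"unknown comparison: {comparison!r}")


def build_design(
    metadata: CohortMetadata,
    covariates: tuple[str, ...] | list[str] = (),
    samples: list[str] | None = None,
) -> tuple[np.ndarray, list[str], int]:
    """Design matrix with intercept and parity indicator first.

    cycle_iud enters as a 5-level categorical with 'missing' kept as its own
    level.  Returns (X, column names, index of the parity column).
    """
    df = metadata.data
    if samples is not None:
        df = df.loc[samples]
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    cols.append((df["parity"] == "parous").to_numpy(dtype=float))
    names.append("parity")
    for cov in covariates:
        if cov in NUMERIC_COVARIATES:
            cols.append(df[cov].to_numpy(dtype=float))
            names.append(cov)
        elif cov == "cycle_iud":
            for level in CYCLE_LEVELS[1:]:  # first level is the reference
                cols.append((df["cycle_iud"] == level).to_numpy(dtype=float))
                names.append(f"cycle_iud[{level}]")
        else:
            raise ValueError(f"covariate not in metadata: {cov!r}")
    X = np.column_stack(cols)
    return X, names, 1


def fit_parity_ols(
    expr: ExpressionMatrix,
    metadata: CohortMetadata,
    covariates: tuple[str, ...] | list[str] = (),
    comparison: str = COMPARISON_ALL,
) -> pd.DataFrame:
    """OLS of every probe on parity (plus covariates); frame of estimates.

    Returns columns probe_id, beta_parity, fold_change, p_value, t, df.
    """
    samples = _comparison_samples(metadata, comparison)
    X, names, j = build_design(metadata, covariates, samples)
    # drop constant columns (e.g. an unoccupied cycle level) before the
    # rank check so tiny cohorts remain estimable
    keep = [0, j] + [
        k for k in range(X.shape[1]) if k not in (0, j) and np.ptp(X[:, k]) > 0
    ]
    X = X[:, keep]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    n, k = X.shape
    if n <= k:
        raise ValueError("more parameters than samples")

    Y = expr.data[samples].to_numpy(dtype=float).T  # samples x probes
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)  # k x probes
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    b = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), dof), np.where(b != 0, 0.0, 1.0))
    return pd.DataFrame(
        {
            "probe_id": expr.probe_ids,
            "beta_parity": b,
            "fold_change": np.power(2.0, b),
            "p_value": p,
            "t": t,
            "df": dof,
        }
    )


def fit_probe_model(
    expr: ExpressionMatrix,
    metadata: CohortMetadata,
    covariates: tuple[str, ...] | list[str] = (),
    comparison: str = COMPARISON_ALL,
) -> list[ProbeTestResult]:
    """Per-probe regression results with q-values attached."""
    frame = fit_parity_ols(expr, metadata, covariates, comparison)
    q = estimate_qvalues(frame["p_value"].to_numpy())
    model = "multiple" if covariates else "single"
    return [
        ProbeTestResult(
            probe_id=row.probe_id,
            beta_parity=float(row.beta_parity),
            fold_change=float(row.fold_change),
            p_value=float(row.p_value),
            q_value=float(qv),
            model=model,
            comparison=comparison,
        )
        for row, qv in zip(frame.itertuples(), q)
    ]


def results_frame(results: list[ProbeTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in results],
            "beta_parity": [r.beta_parity for r in results],
            "fold_change": [r.fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "model": [r.model for r in results],
            "comparison": [r.comparison for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p_values: np.ndarray) -> float:
    """Estimate the null proportion by the cubic-smoother-over-lambda method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid 0.05..0.95 is
    smoothed with a cubic fit and read off at the grid's right end.  When the
    smoothed value leaves (0, 1], fall back to min(1, max(pi0(0.5), 0.05)).
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    if pi0 <= 0.0 or pi0 > 1.0:
        at_half = float(pi0_lam[np.argmin(np.abs(lambdas - 0.5))])
        pi0 = min(1.0, max(at_half, 0.05))
    return pi0


def estimate_qvalues(
    p_values: np.ndarray | list[float], pi0: float | None = None
) -> np.ndarray:
    """Storey q-values: q_i = pi0 * min_{p_j >= p_i} (m p_j / rank_j).

    With pi0 forced to 1 this reduces exactly to Benjamini-Hochberg
    adjusted p values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0,1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
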