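"""Whole-tissue mixture regression and paired epithelium-vs-stroma tests.

Per subject, whole-tissue expression is regressed across probes on the
matched epithelial and stromal profiles (with an intercept, which absorbs
global normalization offsets).  The paired comparison runs a per-probe
paired t-test on log-scale differences with BH FDR control; fold changes
are the anti-logged median within-subject log ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from paritysig.diffexpr import estimate_qvalues
from paritysig.io_config import ExpressionMatrix, ValidationError
from paritysig.synthetic_data import TissueTriplet

logger = logging.getLogger(__name__)


@dataclass
class DecompositionFit:
    subject_id: str
    beta_epithelium: float
    beta_stroma: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise ValidationError("R^2 must lie in [0,1]")
        for v in (self.beta_epithelium, self.beta_stroma, self.intercept):
            if not np.isfinite(v):
                raise ValidationError("coefficients must be finite")


@dataclass
class PairedDEResult:
    probe_id: str
    fold_change: float
    p_value: float
    q_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValidationError("fold change must be positive")


def fit_mixture_regression(triplet: TissueTriplet) -> DecompositionFit:
    """OLS of whole-tissue on (epithelium, stroma) across probes."""
    if len(triplet.probe_ids) < 100:
        raise ValueError("need at least 100 shared probes")
    e = np.asarray(triplet.epithelium, dtype=float)
    s = np.asarray(triplet.stroma, dtype=float)
    w = np.asarray(triplet.whole, dtype=float)
    r = np.corrcoef(e, s)[0, 1]
    if abs(r) > 0.999:
        cond = np.linalg.cond(np.column_stack([np.ones_like(e), e, s]))
        logger.warning(
            "epithelium and stroma nearly collinear (r=%.4f, cond=%.3g)", r, cond
        )
    X = np.column_stack([np.ones_like(e), e, s])
    beta, *_ = np.linalg.lstsq(X, w, rcond=None)
    resid = w - X @ beta
    ss_res = float((resid**2).sum())
    ss_tot = float(((w - w.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DecompositionFit(
        subject_id=triplet.subject_id,
        beta_epithelium=float(beta[1]),
        beta_stroma=float(beta[2]),
        intercept=float(beta[0]),
        r_squared=min(max(r2, 0.0), 1.0),
    )


def decomposition_table(fits: list[DecompositionFit]) -> pd.DataFrame:
    """Table mirroring the per-subject coefficient/R^2 report schema."""
    return pd.DataFrame(
        {
            "subject": [f.subject_id for f in fits],
            "beta_epithelium": [f.beta_epithelium for f in fits],
            "beta_stroma": [f.beta_stroma for f in fits],
            "intercept": [f.intercept for f in fits],
            "r_squared": [f.r_squared for f in fits],
        }
    )


def epithelium_stroma_de(
    epithelium: ExpressionMatrix,
    stroma: ExpressionMatrix,
    subjects: list[tuple[str, str]] | None = None,
    fdr: float = 0.10,
    fc: float = 1.2,
) -> list[PairedDEResult]:
    """Per-probe paired t-test of epithelium vs stroma across subjects.

    ``subjects`` pairs epithelium columns with stroma columns; when omitted,
    identically named columns are paired.  Significance requires q < fdr and
    a fold change of at least fc in either direction.
    """
    if epithelium.probe_ids != stroma.probe_ids:
        raise ValidationError("matrices must share an identical probe set")
    if subjects is None:
        if set(epithelium.sample_ids) != set(stroma.sample_ids):
            raise ValidationError("cannot infer pairing: column names differ")
        subjects = [(s, s) for s in epithelium.sample_ids]
    for e_col, s_col in subjects:
        if e_col not in epithelium.data.columns:
            raise ValidationError(f"unpaired epithelium column {e_col!r}")
        if s_col not in stroma.data.columns:
            raise ValidationError(f"unpaired stroma column {s_col!r}")
    if len(subjects) < 3:
        raise ValueError("need at least 3 paired subjects")

    e = epithelium.data[[a for a, _ in subjects]].to_numpy(dtype=float)
    s = stroma.data[[b for _, b in subjects]].to_numpy(dtype=float)
    diff = e - s  # log2 within-subject ratios
    mean = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    n = diff.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    # zero-variance differences: a constant nonzero shift is maximally
    # significant, a constant zero difference is null
    p = np.where(
        sd > 0,
        2.0 * stats.t.sf(np.abs(t), n - 1),
        np.where(np.abs(mean) > 0, 0.0, 1.0),
    )
    q = estimate_qvalues(p, pi0=1.0)  # Benjamini-Hochberg
    fold = np.power(2.0, np.median(diff, axis=1))
    results = []
    for pid, f, pv, qv in zip(epithelium.probe_ids, fold, p, q):
        sig = bool(qv < fdr and max(f, 1.0 / f) >= fc)
        results.append(
            PairedDEResult(
                probe_id=pid,
                fold_change=float(f),
                p_value=float(pv),
                q_value=float(qv),
                significant=sig,
            )
        )
    return results
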