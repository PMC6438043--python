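"""RT-PCR fold-change estimation and cross-platform concordance.

Expression is normalized to a housekeeping control (delta-Ct); group fold
changes come from the difference of group mean delta-Ct values (minus
delta-delta-Ct), with batch-adjusted significance from a linear regression
of delta-Ct on parity and batch.  Cross-platform agreement pairs the
RT-PCR proxy (-delta-Ct, so both platforms increase with expression)
with the array log2 intensity; the ICC variant is one-way random effects,
single measure, computed on standardized series because the two platforms
live on different scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from paritysig.io_config import CohortMetadata, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FoldEstimate:
    gene: str
    mean_delta_ct_parous: float
    mean_delta_ct_nulliparous: float
    neg_delta_delta_ct: float
    fold_change: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValidationError("fold change must be positive")


@dataclass
class PlatformConcordance:
    gene: str
    icc: float
    spearman: float

    def __post_init__(self) -> None:
        for v in (self.icc, self.spearman):
            if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
                raise ValidationError("correlations must lie in [-1, 1]")


def compute_delta_ct(ct: pd.DataFrame, control: str = "18S") -> pd.DataFrame:
    """delta-Ct(gene, sample) = Ct(gene, sample) - Ct(control, sample).

    ``ct`` is long format with columns gene, sample_id, ct; the result is a
    gene x sample matrix (control row removed).
    """
    wide = ct.pivot_table(index="gene", columns="sample_id", values="ct")
    if control not in wide.index:
        raise ValidationError(f"control gene {control!r} missing from Ct table")
    ctrl = wide.loc[control]
    if ctrl.isna().any():
        missing = list(ctrl.index[ctrl.isna()])
        raise ValidationError(f"control Ct missing for sample(s): {missing}")
    delta = wide.sub(ctrl, axis=1)
    return delta.drop(index=control)


def group_fold_change(
    delta_ct: pd.DataFrame,
    metadata: CohortMetadata,
    batch_adjust: bool = True,
    p_threshold: float = 0.10,
    fc_threshold: float = 1.2,
) -> list[FoldEstimate]:
    """-delta-delta-Ct fold changes with batch-adjusted regression p values.

    -ddCt = mean dCt(nulliparous) - mean dCt(parous); fold change 2^(-ddCt).
    """
    samples = [s for s in delta_ct.columns if s in set(metadata.sample_ids)]
    if len(samples) < len(delta_ct.columns):
        raise ValidationError("Ct table contains samples absent from metadata")
    meta = metadata.data.loc[samples]
    parous = meta.index[meta["parity"] == "parous"]
    nullip = meta.index[meta["parity"] == "nulliparous"]
    if len(parous) == 0 or len(nullip) == 0:
        raise ValueError("both parity groups must be nonempty")

    cols = [np.ones(len(samples)), (meta["parity"] == "parous").to_numpy(float)]
    batches = meta["batch"].unique()
    if batch_adjust and len(batches) > 1:
        for b in batches[1:]:
            cols.append((meta["batch"] == b).to_numpy(float))
    elif batch_adjust:
        logger.info("single batch: batch adjustment skipped")
    X = np.column_stack(cols)
    xtx_inv = np.linalg.inv(X.T @ X)
    n, k = X.shape

    out = []
    for gene, row in delta_ct.iterrows():
        y = row[samples].to_numpy(dtype=float)
        mean_p = float(y[meta["parity"].to_numpy() == "parous"].mean())
        mean_np = float(y[meta["parity"].to_numpy() == "nulliparous"].mean())
        ndd = mean_np - mean_p
        beta = xtx_inv @ (X.T @ y)
        resid = y - X @ beta
        dof = n - k
        sigma2 = float((resid**2).sum()) / dof if dof > 0 else np.nan
        se = np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0))
        if se > 0:
            p = float(2.0 * stats.t.sf(abs(beta[1]) / se, dof))
        else:
            p = 0.0 if beta[1] != 0 else 1.0
        fc = float(2.0**ndd)
        out.append(
            FoldEstimate(
                gene=str(gene),
                mean_delta_ct_parous=mean_p,
                mean_delta_ct_nulliparous=mean_np,
                neg_delta_delta_ct=float(ndd),
                fold_change=fc,
                p_value=p,
                significant=bool(
                    p < p_threshold and max(fc, 1.0 / fc) >= fc_threshold
                ),
            )
        )
    return out


def intraclass_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """One-way random-effects, single-measure ICC for two paired series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    data = np.column_stack([x, y])  # subjects x 2 measurements
    grand = data.mean()
    subj_means = data.mean(axis=1)
    k = 2
    msb = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    msw = ((data - subj_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return 1.0
    return float((msb - msw) / denom)


def platform_concordance(
    rtpcr_values, array_values, gene: str = ""
) -> PlatformConcordance:
    """ICC (on standardized series) and Spearman correlation for one gene.

    ``rtpcr_values`` are per-sample -delta-Ct, ``array_values`` per-sample
    log2 intensity, in the same sample order.
    """
    x = np.asarray(rtpcr_values, dtype=float)
    y = np.asarray(array_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise FloatingPointError("zero variance in a platform series")
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    icc = intraclass_correlation(zx, zy)
    rho = float(stats.spearmanr(x, y).statistic)
    return PlatformConcordance(gene=gene, icc=icc, spearman=rho)


def median_group_ratio(values_a, values_b) -> float:
    """median(values_a) / median(values_b) for positive measurements."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("measurements must be positive")
    mb = float(np.median(b))
    if mb == 0:
        raise FloatingPointError("denominator median is zero")
    return float(np.median(a)) / mb
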