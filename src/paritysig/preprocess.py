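"""Probe filtering, empirical-Bayes batch adjustment, and replicate QC.

Filter order matters and is fixed: the present-call filter runs first, then
the CV quartile filter is computed among its survivors.  The CV is taken on
anti-logged (linear-scale) intensities; the quartile uses numpy's default
linear interpolation and probes strictly below it are dropped, so exact ties
at the quartile survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paritysig.io_config import (
    CohortMetadata,
    ExpressionMatrix,
    PresenceCalls,
    ValidationError,
)


@dataclass
class FilterReport:
    """Bookkeeping for the two-stage probe filter."""

    n_input_probes: int
    n_after_presence: int
    n_after_cv: int | None
    kept_probe_ids: list[str]
    per_probe: pd.DataFrame  # presence fractions (overall/parous/nulliparous), cv
    notes: str = (
        "presence first clause uses the overall P fraction; "
        "CV computed on linear-scale intensities"
    )

    def __post_init__(self) -> None:
        if self.n_after_cv is not None and not (
            self.n_after_cv <= self.n_after_presence <= self.n_input_probes
        ):
            raise ValidationError("filter kept-sets must be nested")


@dataclass
class BatchAdjustment:
    """Empirical-Bayes location/scale batch adjustment (ComBat-style)."""

    gamma: pd.DataFrame  # probe x batch location shifts (standardized scale)
    delta2: pd.DataFrame  # probe x batch variance factors
    hyperparameters: dict
    adjusted: ExpressionMatrix

    def __post_init__(self) -> None:
        if (self.delta2.to_numpy() <= 0).any():
            raise ValidationError("batch scale factors must be positive")


@dataclass
class ConcordanceResult:
    pair_id: str
    sample_a: str
    sample_b: str
    ccc: float
    flagged: bool

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.ccc <= 1.0 + 1e-12:
            raise ValidationError("CCC must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# present-call filter
# ---------------------------------------------------------------------------

def filter_by_presence(
    calls: PresenceCalls,
    metadata: CohortMetadata,
    overall_threshold: float = 0.75,
    diff_threshold: float = 0.25,
) -> FilterReport:
    """Drop probes with a low overall fraction of 'P' calls and no
    compensating parity-group difference.

    A probe is removed iff its overall P fraction is below
    ``overall_threshold`` AND the absolute difference of P fractions between
    parous and nulliparous samples is below ``diff_threshold``; marginal (M)
    calls do not count as present.
    """
    samples = calls.sample_ids
    if set(samples) != set(metadata.sample_ids):
        raise ValidationError("calls and metadata must cover identical samples")
    parous = [s for s in samples if s in set(metadata.parous_ids)]
    nullip = [s for s in samples if s in set(metadata.nulliparous_ids)]
    if not parous or not nullip:
        raise ValueError("need at least one parous and one nulliparous sample")

    is_p = calls.data.to_numpy(dtype=str) == "P"
    cols = pd.Index(samples)
    overall = is_p.mean(axis=1)
    frac_par = is_p[:, cols.get_indexer(parous)].mean(axis=1)
    frac_nul = is_p[:, cols.get_indexer(nullip)].mean(axis=1)

    removed = (overall < overall_threshold) & (
        np.abs(frac_par - frac_nul) < diff_threshold
    )
    kept = [p for p, r in zip(calls.probe_ids, removed) if not r]
    per_probe = pd.DataFrame(
        {
            "presence_overall": overall,
            "presence_parous": frac_par,
            "presence_nulliparous": frac_nul,
            "kept_presence": ~removed,
        },
        index=pd.Index(calls.probe_ids, name="probe_id"),
    )
    return FilterReport(
        n_input_probes=len(calls.probe_ids),
        n_after_presence=len(kept),
        n_after_cv=None,
        kept_probe_ids=kept,
        per_probe=per_probe,
    )


def filter_by_cv(
    expr: ExpressionMatrix,
    report: FilterReport,
    quantile: float = 0.25,
) -> FilterReport:
    """Among presence-kept probes, drop those whose linear-scale CV falls
    strictly below the given quantile of kept-probe CVs."""
    kept = report.kept_probe_ids
    if not kept:
        raise ValueError("no probes survived the presence filter")
    linear = np.power(2.0, expr.data.loc[kept].to_numpy(dtype=float))
    means = linear.mean(axis=1)
    if (means <= 0).any():
        raise FloatingPointError("nonpositive linear-scale probe mean")
    cv = linear.std(axis=1, ddof=1) / means
    cutoff = float(np.quantile(cv, quantile))
    keep_mask = cv >= cutoff
    kept_final = [p for p, k in zip(kept, keep_mask) if k]

    per_probe = report.per_probe.copy()
    per_probe["cv"] = np.nan
    per_probe.loc[kept, "cv"] = cv
    per_probe["kept_cv"] = False
    per_probe.loc[kept_final, "kept_cv"] = True
    return FilterReport(
        n_input_probes=report.n_input_probes,
        n_after_presence=report.n_after_presence,
        n_after_cv=len(kept_final),
        kept_probe_ids=kept_final,
        per_probe=per_probe,
        notes=report.notes,
    )


def filter_probes(
    expr: ExpressionMatrix,
    calls: PresenceCalls,
    metadata: CohortMetadata,
    overall_threshold: float = 0.75,
    diff_threshold: float = 0.25,
    cv_quantile: float = 0.25,
    combine: str = "and",
) -> FilterReport:
    """Run both filters in order.

    ``combine='and'`` is the main-study rule (presence filter then CV filter
    on survivors).  ``combine='or'`` removes probes failing either criterion,
    the variant used for the microdissection substudy.
    """
    pres = filter_by_presence(calls, metadata, overall_threshold, diff_threshold)
    if combine == "and":
        return filter_by_cv(expr, pres, cv_quantile)
    if combine != "or":
        raise ValueError("combine must be 'and' or 'or'")
    # OR variant: CV quantile over all probes, probe kept iff it passes both
    full = FilterReport(
        n_input_probes=pres.n_input_probes,
        n_after_presence=pres.n_input_probes,
        n_after_cv=None,
        kept_probe_ids=list(calls.probe_ids),
        per_probe=pres.per_probe,
    )
    cvrep = filter_by_cv(expr, full, cv_quantile)
    kept = [
        p
        for p in calls.probe_ids
        if pres.per_probe.at[p, "kept_presence"] and cvrep.per_probe.at[p, "kept_cv"]
    ]
    per_probe = cvrep.per_probe
    return FilterReport(
        n_input_probes=pres.n_input_probes,
        n_after_presence=pres.n_after_presence,
        n_after_cv=len(kept),
        kept_probe_ids=kept,
        per_probe=per_probe,
        notes=pres.notes + "; OR-combination variant",
    )


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------

def _eb_iterate(
    z: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a_prior: float,
    b_prior: float,
    n: int,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative solution of the parametric EB posterior for one batch.

    z is probes x batch-samples (standardized); returns shrunken location
    and variance arrays over probes.
    """
    g = gamma_hat.copy()
    d2 = delta2_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * gamma_hat + d2 * gamma_bar) / (n * tau2 + d2)
        sum2 = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d2_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g)), np.max(np.abs(d2_new - d2))
        )
        g, d2 = g_new, d2_new
        if change < tol:
            break
    return g, d2


def combat_adjust(
    expr: ExpressionMatrix, batches: pd.Series | list | dict
) -> BatchAdjustment:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per probe: standardize against the batch-size-weighted grand mean and
    pooled variance, estimate per-batch location and scale on the
    standardized data, shrink them toward pooled priors (normal prior for
    location, inverse-gamma for scale, hyperparameters by method of
    moments), remove them, and restore each probe's grand mean.  No
    covariates enter the batch model.
    """
    if isinstance(batches, dict):
        batches = pd.Series(batches)
    if not isinstance(batches, pd.Series):
        batches = pd.Series(list(batches), index=expr.sample_ids)
    batches = batches.reindex(expr.sample_ids)
    if batches.isna().any():
        raise ValidationError("every sample needs a batch label")
    labels = list(dict.fromkeys(batches))
    if len(labels) < 2:
        raise ValueError("need at least two batches")
    counts = batches.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"batch(es) with a single sample: {small}")

    y = expr.values
    n_probes, n_samples = y.shape
    idx = {b: np.flatnonzero((batches == b).to_numpy()) for b in labels}
    n_b = {b: len(idx[b]) for b in labels}

    batch_means = np.column_stack([y[:, idx[b]].mean(axis=1) for b in labels])
    w = np.array([n_b[b] / n_samples for b in labels])
    alpha = batch_means @ w
    fitted = np.zeros_like(y)
    for k, b in enumerate(labels):
        fitted[:, idx[b]] = batch_means[:, k : k + 1]
    var_pooled = ((y - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sigma = np.sqrt(var_pooled)

    z = (y - alpha[:, None]) / sigma[:, None]

    gamma_star = np.empty((n_probes, len(labels)))
    delta2_star = np.empty((n_probes, len(labels)))
    hyper = {}
    for k, b in enumerate(labels):
        zb = z[:, idx[b]]
        n = n_b[b]
        gamma_hat = zb.mean(axis=1)
        # population variance so that a zero-batch-signal input is returned
        # unchanged
        delta2_hat = zb.var(axis=1, ddof=0)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1)) if n_probes > 1 else 0.0
        m = float(delta2_hat.mean())
        v = float(delta2_hat.var(ddof=1)) if n_probes > 1 else 0.0
        if tau2 < 1e-12 or v < 1e-12:
            # degenerate prior: no information to shrink with
            g, d2 = gamma_hat, np.maximum(delta2_hat, 1e-12)
            a_prior = b_prior = np.nan
        else:
            a_prior = (2.0 * v + m**2) / v
            b_prior = (m * v + m**3) / v
            g, d2 = _eb_iterate(
                zb, gamma_hat, delta2_hat, gamma_bar, tau2, a_prior, b_prior, n
            )
        gamma_star[:, k] = g
        delta2_star[:, k] = np.maximum(d2, 1e-12)
        hyper[b] = {
            "gamma_bar": gamma_bar,
            "tau2": tau2,
            "a_prior": a_prior,
            "b_prior": b_prior,
        }

    z_adj = z.copy()
    for k, b in enumerate(labels):
        z_adj[:, idx[b]] = (z[:, idx[b]] - gamma_star[:, k : k + 1]) / np.sqrt(
            delta2_star[:, k : k + 1]
        )
    y_adj = sigma[:, None] * z_adj + alpha[:, None]
    # restore each probe's original grand mean
    y_adj += (y.mean(axis=1) - y_adj.mean(axis=1))[:, None]

    adjusted = ExpressionMatrix(
        pd.DataFrame(y_adj, index=expr.probe_ids, columns=expr.sample_ids)
    )
    return BatchAdjustment(
        gamma=pd.DataFrame(gamma_star, index=expr.probe_ids, columns=labels),
        delta2=pd.DataFrame(delta2_star, index=expr.probe_ids, columns=labels),
        hyperparameters=hyper,
        adjusted=adjusted,
    )


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------

def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length vectors")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0
    return float(2.0 * cov / denom)


def replicate_concordance(
    expr: ExpressionMatrix,
    metadata: CohortMetadata,
    threshold: float = 0.98,
) -> list[ConcordanceResult]:
    """Lin's CCC over probes for every replicate pair, flagging low pairs."""
    pairs = metadata.replicate_pairs()
    if not pairs:
        raise ValueError("no replicate_of links in metadata")
    present = set(expr.sample_ids)
    results = []
    for a, b in pairs:
        if a not in present or b not in present:
            raise ValidationError(f"replicate pair ({a}, {b}) missing from matrix")
        ccc = lin_ccc(
            expr.data[a].to_numpy(dtype=float), expr.data[b].to_numpy(dtype=float)
        )
        results.append(
            ConcordanceResult(
                pair_id=f"{a}~{b}",
                sample_a=a,
                sample_b=b,
                ccc=ccc,
                flagged=ccc < threshold,
            )
        )
    return results
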