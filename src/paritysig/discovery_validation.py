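"""Stratified discovery/validation resampling selection of robust probes.

Each of the n_pairs rounds splits the cohort into a discovery set (2/3 of
each parity stratum, round-half-up) and its complement.  A probe validates
in a round iff its discovery q-value clears the discovery FDR, its
validation p clears the validation threshold, and the effect direction
agrees between the two fits; the final set keeps probes validating in at
least min_pairs rounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from paritysig.diffexpr import (
    COMPARISON_ALL,
    estimate_qvalues,
    fit_parity_ols,
)
from paritysig.io_config import CohortMetadata, ExpressionMatrix, ValidationError


@dataclass
class PartitionPair:
    pair_index: int
    discovery: list[str]
    validation: list[str]

    def __post_init__(self) -> None:
        if set(self.discovery) & set(self.validation):
            raise ValidationError("discovery and validation sets overlap")


@dataclass
class DVSelectionResult:
    table: pd.DataFrame  # probe_id, n_validated, validated
    per_pair: pd.DataFrame  # pair, probe_id, discovery_q, validation_p, ...
    min_pairs: int

    @property
    def validated_probes(self) -> list[str]:
        return list(self.table.loc[self.table["validated"], "probe_id"])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_partition_pairs(
    metadata: CohortMetadata,
    n_pairs: int = 12,
    fraction: float = 2.0 / 3.0,
    seed: int | None = None,
) -> list[PartitionPair]:
    """Independent stratified random discovery/validation splits."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if seed is None:
        raise ValueError("seed is required")
    strata = [metadata.parous_ids, metadata.nulliparous_ids]
    for s in strata:
        if len(s) < 3:
            raise ValueError("each parity stratum needs at least 3 samples")
    sizes = [_round_half_up(fraction * len(s)) for s in strata]
    for s, k in zip(strata, sizes):
        if k >= len(s):
            raise ValueError("discovery fraction leaves an empty validation set")
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        disc: list[str] = []
        val: list[str] = []
        for s, k in zip(strata, sizes):
            perm = rng.permutation(len(s))
            disc.extend(s[j] for j in perm[:k])
            val.extend(s[j] for j in perm[k:])
        pairs.append(PartitionPair(pair_index=i + 1, discovery=disc, validation=val))
    return pairs


def run_discovery_validation(
    expr: ExpressionMatrix,
    metadata: CohortMetadata,
    pairs: list[PartitionPair],
    discovery_fdr: float = 0.20,
    validation_p: float = 0.05,
    min_pairs: int = 2,
    covariates: tuple[str, ...] | list[str] = (),
) -> DVSelectionResult:
    """Run the per-pair discovery fit, q-value gate, and validation fit.

    q-values are computed within each discovery set independently.  A probe
    must validate with the same effect direction it showed in discovery.
    """
    universe = set(expr.sample_ids)
    for pair in pairs:
        if set(pair.discovery) | set(pair.validation) != set(metadata.sample_ids):
            raise ValidationError("partition does not cover the metadata samples")
        if not set(pair.discovery) <= universe or not set(pair.validation) <= universe:
            raise ValidationError("partition samples missing from expression matrix")

    probes = expr.probe_ids
    counts = np.zeros(len(probes), dtype=int)
    records = []
    for pair in pairs:
        disc_meta = metadata.subset(pair.discovery)
        val_meta = metadata.subset(pair.validation)
        disc = fit_parity_ols(expr, disc_meta, covariates, COMPARISON_ALL)
        disc_q = estimate_qvalues(disc["p_value"].to_numpy())
        selected = disc_q < discovery_fdr
        val = fit_parity_ols(expr, val_meta, covariates, COMPARISON_ALL)
        agree = np.sign(disc["beta_parity"].to_numpy()) == np.sign(
            val["beta_parity"].to_numpy()
        )
        ok = selected & (val["p_value"].to_numpy() < validation_p) & agree
        counts += ok.astype(int)
        records.append(
            pd.DataFrame(
                {
                    "pair": pair.pair_index,
                    "probe_id": probes,
                    "discovery_q": disc_q,
                    "discovery_beta": disc["beta_parity"].to_numpy(),
                    "validation_p": val["p_value"].to_numpy(),
                    "validation_beta": val["beta_parity"].to_numpy(),
                    "validated_in_pair": ok,
                }
            )
        )
    table = pd.DataFrame(
        {
            "probe_id": probes,
            "n_validated": counts,
            "validated": counts >= min_pairs,
        }
    )
    return DVSelectionResult(
        table=table, per_pair=pd.concat(records, ignore_index=True), min_pairs=min_pairs
    )
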