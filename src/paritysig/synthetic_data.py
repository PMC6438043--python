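"""Seeded generators for cohorts, expression matrices, ontologies, tissue
mixtures and RT-PCR tables.

The expression generator plants parity effects that follow five temporal
trajectories over time since last pregnancy (TSLP): three upregulated
(transient, long-term changing, long-term constant) and two downregulated
(constant, transient).  Transient decay is exponential in TSLP so planted
effects have closed forms usable as test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from paritysig.io_config import CohortMetadata, ExpressionMatrix, PresenceCalls

PATTERNS = (
    "null",
    "up_transient",
    "up_longterm_changing",
    "up_longterm_constant",
    "down_constant",
    "down_transient",
)

# TSLP stratum occupancy and bounds mirroring the cohort's three strata
_TSLP_STRATA = ((1.0, 5.0), (5.0, 10.0), (10.0, 20.0))
_TSLP_PROBS = np.array([0.39, 0.37, 0.25])
_TSLP_PROBS = _TSLP_PROBS / _TSLP_PROBS.sum()

_CYCLE_LEVELS = ("luteal", "ovulatory", "follicular", "hormonal_IUD", "missing")
_CYCLE_PROBS_PAROUS = np.array([0.27, 0.13, 0.26, 0.29, 0.05])
_CYCLE_PROBS_NULLIP = np.array([0.45, 0.13, 0.23, 0.09, 0.10])


@dataclass
class TruthSpec:
    """Parameters of the generative model for planted parity effects."""

    n_up_transient: int = 0
    n_up_longterm_changing: int = 0
    n_up_longterm_constant: int = 0
    n_down_constant: int = 0
    n_down_transient: int = 0
    base_log2fc_low: float = 0.8
    base_log2fc_high: float = 1.6
    transient_decay: float = 0.25
    changing_decay: float = 0.4
    changing_plateau: float = 0.3
    noise_sd: float = 0.5
    batch_location_sd: float = 0.3
    batch_scale_low: float = 0.8
    batch_scale_high: float = 1.25
    covariate_coef_sd: float = 0.03
    mu_low: float = 4.0
    mu_high: float = 12.0
    presence_center: float = 8.41
    presence_scale: float = 0.6
    marginal_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.changing_plateau <= 1.0:
            raise ValueError("changing_plateau must be in [0,1]")

    @property
    def n_effect(self) -> int:
        return (
            self.n_up_transient
            + self.n_up_longterm_changing
            + self.n_up_longterm_constant
            + self.n_down_constant
            + self.n_down_transient
        )


@dataclass
class SimulationTruth:
    """Realized per-probe generative parameters."""

    table: pd.DataFrame  # probe_id, pattern, base_log2fc, decay, plateau, mu
    batch_locations: dict[str, float]
    batch_scales: dict[str, float]
    covariate_coefs: pd.DataFrame  # probe x covariate
    noise_sd: float

    def __post_init__(self) -> None:
        t = self.table
        if not set(t["pattern"]) <= set(PATTERNS):
            raise ValueError("unknown pattern label in truth table")
        null = t["pattern"] == "null"
        if (t.loc[null, "base_log2fc"] != 0).any():
            raise ValueError("null probes must have base_log2fc == 0")
        up = t["pattern"].str.startswith("up_")
        down = t["pattern"].str.startswith("down_")
        if (t.loc[up, "base_log2fc"] <= 0).any():
            raise ValueError("up patterns need base_log2fc > 0")
        if (t.loc[down, "base_log2fc"] >= 0).any():
            raise ValueError("down patterns need base_log2fc < 0")
        if any(v <= 0 for v in self.batch_scales.values()):
            raise ValueError("batch scales must be positive")

    def planted_effect(self, probe_id: str, tslp: float) -> float:
        row = self.table.set_index("probe_id").loc[probe_id]
        return float(
            _effect(
                np.array([row["pattern"]], dtype=object),
                np.array([row["base_log2fc"]]),
                np.array([row["decay"]]),
                np.array([row["plateau"]]),
                float(tslp),
            )[0]
        )


@dataclass
class TissueTriplet:
    """Matched epithelium / stroma / whole-tissue expression vectors."""

    subject_id: str
    probe_ids: list[str]
    epithelium: np.ndarray
    stroma: np.ndarray
    whole: np.ndarray
    true_weight: float | None = None

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        if not (len(self.epithelium) == len(self.stroma) == len(self.whole) == n):
            raise ValueError("triplet vectors must share the probe set")
        if self.true_weight is not None and not 0.0 <= self.true_weight <= 1.0:
            raise ValueError("true_weight must lie in [0,1]")


def _effect(
    pattern: np.ndarray,
    base: np.ndarray,
    decay: np.ndarray,
    plateau: np.ndarray,
    tslp: float,
) -> np.ndarray:
    """Planted parity effect (log2 units) at a given TSLP, vectorized over probes."""
    out = np.zeros(len(pattern))
    ex = np.exp(-decay * tslp)
    transient = (pattern == "up_transient") | (pattern == "down_transient")
    out[transient] = base[transient] * ex[transient]
    changing = pattern == "up_longterm_changing"
    out[changing] = base[changing] * (
        plateau[changing] + (1.0 - plateau[changing]) * ex[changing]
    )
    constant = (pattern == "up_longterm_constant") | (pattern == "down_constant")
    out[constant] = base[constant]
    return out


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_parous: int, n_nulliparous: int, seed: int
) -> CohortMetadata:
    """Generate a cohort with TSLP strata, covariates, batches and QC replicates.

    Parous TSLP is drawn from three strata with probabilities matching the
    study's stratum occupancy, then uniformly within stratum.  Samples are
    assigned to batches of 9-12 and each batch past the first carries one
    cross-batch duplicate flagged via ``replicate_of``.
    """
    if n_parous < 1 or n_nulliparous < 1:
        raise ValueError("group counts must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_parous + n_nulliparous

    parity = np.array(["parous"] * n_parous + ["nulliparous"] * n_nulliparous)
    rng.shuffle(parity)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    tslp = np.full(n, np.nan)
    parous_mask = parity == "parous"
    strata = rng.choice(3, size=parous_mask.sum(), p=_TSLP_PROBS)
    lows = np.array([_TSLP_STRATA[s][0] for s in strata])
    highs = np.array([_TSLP_STRATA[s][1] for s in strata])
    tslp[parous_mask] = rng.uniform(lows, highs)

    age = rng.uniform(30.0, 47.0, size=n)
    bmi = rng.uniform(18.7, 38.0, size=n)
    # smoking duration is longer among nulliparous women, mimicking the
    # parity-confounded covariate
    smoking = np.where(
        parous_mask, rng.uniform(0.0, 16.0, size=n), rng.uniform(5.0, 30.0, size=n)
    )
    cycle = np.empty(n, dtype=object)
    cycle[parous_mask] = rng.choice(
        _CYCLE_LEVELS, size=parous_mask.sum(), p=_CYCLE_PROBS_PAROUS
    )
    cycle[~parous_mask] = rng.choice(
        _CYCLE_LEVELS, size=(~parous_mask).sum(), p=_CYCLE_PROBS_NULLIP
    )

    # batches of 9-12 in sample order (order already random); sizes are
    # balanced so every batch lands in range (small cohorts get one batch)
    n_batches = max(1, int(round(n / 10.5)))
    base_size, rem = divmod(n, n_batches)
    batch = np.empty(n, dtype=object)
    start = 0
    for b in range(n_batches):
        size = base_size + (1 if b < rem else 0)
        batch[start : start + size] = f"B{b + 1:02d}"
        start += size

    df = pd.DataFrame(
        {
            "parity": parity,
            "tslp_years": tslp,
            "age_years": age,
            "bmi": bmi,
            "smoking_duration_years": smoking,
            "cycle_iud": cycle,
            "batch": batch,
            "replicate_of": np.array([None] * n, dtype=object),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # one cross-batch duplicate per batch (skipping the first): the chosen
    # sample becomes a re-assay of a same-parity sample from another batch,
    # so its subject-level covariates are copied from the source
    batches = list(dict.fromkeys(batch))
    for bl in batches[1:]:
        in_batch = df.index[df["batch"] == bl]
        target = in_batch[int(rng.integers(len(in_batch)))]
        cand = df.index[
            (df["batch"] != bl)
            & (df["parity"] == df.at[target, "parity"])
            & df["replicate_of"].isna()
            & (df.index != target)
        ]
        cand = cand[~cand.isin(df["replicate_of"].dropna())]
        if len(cand) == 0:
            continue
        source = cand[int(rng.integers(len(cand)))]
        for col in (
            "tslp_years",
            "age_years",
            "bmi",
            "smoking_duration_years",
            "cycle_iud",
        ):
            df.at[target, col] = df.at[source, col]
        df.at[target, "replicate_of"] = source

    return CohortMetadata(df)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    cohort: CohortMetadata,
    n_probes: int,
    spec: TruthSpec | None = None,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, PresenceCalls, SimulationTruth]:
    """Generate a log2 expression matrix with batch effects, covariate-linked
    expression and planted parity effects, plus matched presence calls.

    value(i, j) = mu_i + loc(b_j) + scale(b_j)*eps + covariate terms
                  + parity_effect_i(TSLP_j)

    Replicate samples share the source sample's signal and receive their own
    batch effect and independent noise.
    """
    if seed is None:
        raise ValueError("seed is required; all randomness must be seeded")
    spec = spec or TruthSpec()
    if n_probes < spec.n_effect:
        raise ValueError("n_probes smaller than the number of non-null probes")
    rng = np.random.default_rng(seed)
    meta = cohort.data
    n_samples = len(meta)
    probe_ids = [f"probe_{i + 1:05d}" for i in range(n_probes)]

    pattern = np.array(["null"] * n_probes, dtype=object)
    slots = rng.permutation(n_probes)[: spec.n_effect]
    counts = [
        ("up_transient", spec.n_up_transient),
        ("up_longterm_changing", spec.n_up_longterm_changing),
        ("up_longterm_constant", spec.n_up_longterm_constant),
        ("down_constant", spec.n_down_constant),
        ("down_transient", spec.n_down_transient),
    ]
    pos = 0
    for name, k in counts:
        pattern[slots[pos : pos + k]] = name
        pos += k

    base = np.zeros(n_probes)
    nonnull = pattern != "null"
    mag = rng.uniform(spec.base_log2fc_low, spec.base_log2fc_high, size=n_probes)
    sign = np.where(np.char.startswith(pattern.astype(str), "down"), -1.0, 1.0)
    base[nonnull] = (mag * sign)[nonnull]

    decay = np.zeros(n_probes)
    decay[(pattern == "up_transient") | (pattern == "down_transient")] = (
        spec.transient_decay
    )
    decay[pattern == "up_longterm_changing"] = spec.changing_decay
    plateau = np.zeros(n_probes)
    plateau[pattern == "up_longterm_changing"] = spec.changing_plateau

    mu = rng.uniform(spec.mu_low, spec.mu_high, size=n_probes)

    covs = ["age_years", "bmi", "smoking_duration_years"]
    covz = {}
    for c in covs:
        v = meta[c].to_numpy(dtype=float)
        sd = v.std()
        covz[c] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    coefs = pd.DataFrame(
        rng.normal(0.0, spec.covariate_coef_sd, size=(n_probes, len(covs))),
        index=probe_ids,
        columns=covs,
    )
    cycle_offsets = pd.DataFrame(
        rng.normal(0.0, spec.covariate_coef_sd, size=(n_probes, len(_CYCLE_LEVELS))),
        index=probe_ids,
        columns=list(_CYCLE_LEVELS),
    )

    batches = list(dict.fromkeys(meta["batch"]))
    batch_loc = {b: float(rng.normal(0.0, spec.batch_location_sd)) for b in batches}
    batch_scale = {
        b: float(rng.uniform(spec.batch_scale_low, spec.batch_scale_high))
        for b in batches
    }

    # per-sample signal (no batch, no noise); replicates inherit the source's
    # signal automatically because their metadata was copied at cohort time
    signal = np.tile(mu[:, None], (1, n_samples))
    for k, c in enumerate(covs):
        signal += coefs.to_numpy()[:, k : k + 1] * covz[c][None, :]
    cyc_idx = np.array([_CYCLE_LEVELS.index(v) for v in meta["cycle_iud"]])
    signal += cycle_offsets.to_numpy()[:, cyc_idx]
    parous_mask = (meta["parity"] == "parous").to_numpy()
    tslp_vals = meta["tslp_years"].to_numpy(dtype=float)
    for j in np.flatnonzero(parous_mask):
        signal[:, j] += _effect(pattern, base, decay, plateau, tslp_vals[j])

    loc = np.array([batch_loc[b] for b in meta["batch"]])
    scale = np.array([batch_scale[b] for b in meta["batch"]])
    eps = rng.normal(0.0, spec.noise_sd, size=(n_probes, n_samples))
    values = signal + loc[None, :] + scale[None, :] * eps

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=meta.index)
    )

    # presence calls: P-probability is logistic in baseline intensity, with a
    # rare marginal call
    p_present = 1.0 / (1.0 + np.exp(-(mu - spec.presence_center) / spec.presence_scale))
    r = rng.random(size=(n_probes, n_samples))
    calls = np.full((n_probes, n_samples), "A", dtype=object)
    calls[r < spec.marginal_rate] = "M"
    is_p = (r >= spec.marginal_rate) & (
        r < spec.marginal_rate + (1.0 - spec.marginal_rate) * p_present[:, None]
    )
    calls[is_p] = "P"
    presence = PresenceCalls(
        pd.DataFrame(calls, index=probe_ids, columns=meta.index)
    )

    truth = SimulationTruth(
        table=pd.DataFrame(
            {
                "probe_id": probe_ids,
                "pattern": pattern,
                "base_log2fc": base,
                "decay": decay,
                "plateau": plateau,
                "mu": mu,
            }
        ),
        batch_locations=batch_loc,
        batch_scales=batch_scale,
        covariate_coefs=coefs,
        noise_sd=spec.noise_sd,
    )
    return expr, presence, truth


# ---------------------------------------------------------------------------
# tissue triplets
# ---------------------------------------------------------------------------

def simulate_tissue_triplets(
    n_subjects: int,
    weights: list[float] | float,
    noise_sd: float,
    seed: int,
    n_probes: int = 500,
) -> list[TissueTriplet]:
    """Whole tissue = w*epithelium + (1-w)*stroma + Gaussian noise.

    Epithelium and stroma are drawn around distinct probe-level means so the
    two compartments are distinguishable by regression.
    """
    if np.isscalar(weights):
        weights = [float(weights)] * n_subjects
    weights = [float(w) for w in weights]
    if len(weights) != n_subjects:
        raise ValueError("need one weight per subject")
    if any(w < 0.0 or w > 1.0 for w in weights):
        raise ValueError("mixing weights must lie in [0,1]")
    rng = np.random.default_rng(seed)
    probe_ids = [f"probe_{i + 1:05d}" for i in range(n_probes)]
    mu_epi = rng.uniform(4.0, 12.0, size=n_probes)
    mu_str = rng.uniform(4.0, 12.0, size=n_probes)
    out = []
    for s, w in enumerate(weights):
        epi = mu_epi + rng.normal(0.0, 1.0, size=n_probes)
        stro = mu_str + rng.normal(0.0, 1.0, size=n_probes)
        whole = w * epi + (1.0 - w) * stro
        if noise_sd > 0:
            whole = whole + rng.normal(0.0, noise_sd, size=n_probes)
        out.append(
            TissueTriplet(
                subject_id=f"LCM{s + 1:02d}",
                probe_ids=probe_ids,
                epithelium=epi,
                stroma=stro,
                whole=whole,
                true_weight=w,
            )
        )
    return out


# ---------------------------------------------------------------------------
# toy ontology
# ---------------------------------------------------------------------------

def simulate_toy_ontology(
    n_terms_per_branch: int, n_genes: int, seed: int
):
    """Rooted DAG with developmental / immune / other branches and leaf
    annotations.

    Returns an :class:`paritysig.enrichment.Ontology` and a two-column
    gene-to-leaf annotation table; ancestor propagation is left to the
    enrichment module.
    """
    from paritysig.enrichment import Ontology

    if n_terms_per_branch < 1 or n_genes < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    branches = {
        "DEV": "developmental process",
        "IMM": "immune response",
        "OTH": "other",
    }
    edges: list[tuple[str, str]] = []
    names = {"ROOT": "biological process"}
    leaves: list[str] = []
    for bid, bname in branches.items():
        names[bid] = bname
        edges.append(("ROOT", bid))
        for k in range(n_terms_per_branch):
            leaf = f"{bid}:{k + 1:03d}"
            names[leaf] = f"{bname} leaf {k + 1}"
            edges.append((bid, leaf))
            leaves.append(leaf)
    ontology = Ontology.from_edges(
        edges,
        names=names,
        branch_roots={"developmental": "DEV", "immune": "IMM", "other": "OTH"},
    )

    genes = [f"gene_{i + 1:04d}" for i in range(n_genes)]
    records = []
    for g in genes:
        k = int(rng.integers(1, min(3, len(leaves)) + 1))
        for leaf in rng.choice(leaves, size=k, replace=False):
            records.append((g, str(leaf)))
    annotation = pd.DataFrame(records, columns=["gene", "term"])
    return ontology, annotation


# ---------------------------------------------------------------------------
# RT-PCR
# ---------------------------------------------------------------------------

def simulate_rtpcr(
    truth: SimulationTruth,
    cohort: CohortMetadata,
    genes: list[str],
    seed: int,
    noise_sd: float = 0.2,
    control: str = "18S",
) -> pd.DataFrame:
    """Long-format Ct table: Ct = c_gene - planted log2 expression + noise.

    Lower Ct means higher expression.  A near-constant control row is added
    for every sample.
    """
    t = truth.table.set_index("probe_id")
    unknown = set(genes) - set(t.index)
    if unknown:
        raise ValueError(f"unknown gene(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    meta = cohort.data
    records = []
    for g in genes:
        row = t.loc[g]
        pat = np.array([row["pattern"]], dtype=object)
        b = np.array([row["base_log2fc"]])
        d = np.array([row["decay"]])
        pl = np.array([row["plateau"]])
        c_gene = 30.0
        for sid, srow in meta.iterrows():
            eff = 0.0
            if srow["parity"] == "parous":
                eff = float(_effect(pat, b, d, pl, float(srow["tslp_years"]))[0])
            ct = c_gene - (float(row["mu"]) + eff)
            if noise_sd > 0:
                ct += rng.normal(0.0, noise_sd)
            records.append((g, sid, ct))
    for sid in meta.index:
        ct = 12.0
        if noise_sd > 0:
            ct += rng.normal(0.0, noise_sd / 4.0)
        records.append((control, sid, ct))
    return pd.DataFrame(records, columns=["gene", "sample_id", "ct"])
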