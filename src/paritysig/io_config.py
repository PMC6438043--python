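"""Domain types, on-disk formats, and configuration.

All matrices are stored probes-as-rows, samples-as-columns, tab-delimited
with a header row of sample identifiers and the probe identifier in the
first column.  Floats are written with 6 significant digits so write/read
round-trips are byte-stable.  Missing values are disallowed in expression
matrices and allowed (empty string) only in metadata fields declared
optional.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

FLOAT_FORMAT = "%.6g"

PARITY_VALUES = frozenset({"parous", "nulliparous"})
CALL_ALPHABET = frozenset({"P", "M", "A"})
CYCLE_IUD_VALUES = frozenset(
    {"luteal", "ovulatory", "follicular", "hormonal_IUD", "missing"}
)

METADATA_COLUMNS = [
    "sample_id",
    "parity",
    "tslp_years",
    "age_years",
    "bmi",
    "smoking_duration_years",
    "cycle_iud",
    "batch",
    "replicate_of",
]


class ValidationError(ValueError):
    """A table violated a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed into a domain type."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Probe-by-sample matrix of log2-scale intensities."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite expression value at probe "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_probes(self, probes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(probes)].copy())

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)].copy())


@dataclass
class PresenceCalls:
    """Per-cell P/M/A detection calls aligned with an expression matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        flat = set(np.unique(self.data.to_numpy(dtype=str)))
        bad = flat - CALL_ALPHABET
        if bad:
            raise ValidationError(f"presence calls outside {{P,M,A}}: {sorted(bad)}")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CohortMetadata:
    """Per-sample parity, TSLP, covariates, batch and replicate links.

    Backed by a DataFrame indexed by sample_id.  TSLP is defined only for
    parous samples; ``replicate_of``, when set, names another sample in the
    table.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        df.index = df.index.astype(str)
        bad_parity = set(df["parity"]) - PARITY_VALUES
        if bad_parity:
            raise ParseError(f"unknown parity value(s): {sorted(bad_parity)}")
        parous = df["parity"] == "parous"
        tslp = df["tslp_years"]
        if tslp[parous].isna().any():
            who = df.index[parous & tslp.isna()][0]
            raise ValidationError(f"parous sample {who!r} has no TSLP")
        if tslp[~parous].notna().any():
            who = df.index[(~parous) & tslp.notna()][0]
            raise ValidationError(f"nulliparous sample {who!r} has TSLP set")
        if (tslp[parous] < 0).any():
            raise ValidationError("negative TSLP")
        if df["batch"].isna().any() or (df["batch"].astype(str) == "").any():
            raise ValidationError("every sample needs a batch label")
        rep = df["replicate_of"].dropna()
        unknown = set(rep) - set(df.index)
        if unknown:
            raise ValidationError(
                f"replicate_of points to unknown sample(s): {sorted(unknown)}"
            )
        bad_cycle = set(df["cycle_iud"].dropna()) - CYCLE_IUD_VALUES
        if bad_cycle:
            raise ParseError(f"unknown cycle/IUD value(s): {sorted(bad_cycle)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def parous_ids(self) -> list[str]:
        return list(self.data.index[self.data["parity"] == "parous"])

    @property
    def nulliparous_ids(self) -> list[str]:
        return list(self.data.index[self.data["parity"] == "nulliparous"])

    def subset(self, samples: Iterable[str]) -> "CohortMetadata":
        sub = self.data.loc[list(samples)].copy()
        # replicate links may point outside the subset; drop those
        keep = sub["replicate_of"].isin(sub.index)
        sub.loc[~keep, "replicate_of"] = np.nan
        return CohortMetadata(sub)

    def replicate_pairs(self) -> list[tuple[str, str]]:
        rep = self.data["replicate_of"].dropna()
        return [(str(src), str(s)) for s, src in rep.items()]


@dataclass
class AnalysisConfig:
    """Every threshold and seed used by the pipeline, with study defaults."""

    presence_threshold: float = 0.75
    presence_diff_threshold: float = 0.25
    cv_quantile: float = 0.25
    discovery_fdr: float = 0.20
    validation_p: float = 0.05
    n_pairs: int = 12
    min_pairs: int = 2
    resample_fraction: float = 2.0 / 3.0
    candidate_fdr: float = 0.10
    candidate_fc: float = 1.2
    go_alpha: float = 0.01
    paired_fdr: float = 0.10
    paired_fc: float = 1.2
    rtpcr_p: float = 0.10
    rtpcr_fc: float = 1.2
    pattern_delta_fc: float = 1.1
    ccc_threshold: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "presence_threshold",
            "presence_diff_threshold",
            "cv_quantile",
            "discovery_fdr",
            "validation_p",
            "candidate_fdr",
            "go_alpha",
            "paired_fdr",
            "rtpcr_p",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        for name in ("candidate_fc", "paired_fc", "rtpcr_fc", "pattern_delta_fc"):
            if getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must be >= 1")
        if not self.n_pairs >= self.min_pairs >= 1:
            raise ValidationError("need n_pairs >= min_pairs >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# matrix / table readers and writers
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = index_name
    return df


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited probe-by-sample log2 expression matrix."""
    df = _read_matrix(path, "probe_id")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric expression value at probe {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"missing expression value at probe {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(numeric.astype(float))


def save_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="probe_id")


def load_calls(path: str | Path) -> PresenceCalls:
    return PresenceCalls(_read_matrix(path, "probe_id"))


def save_calls(calls: PresenceCalls, path: str | Path) -> None:
    calls.data.to_csv(path, sep="\t", index_label="probe_id")


def load_metadata(path: str | Path) -> CohortMetadata:
    """Read the tab-delimited sample metadata table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"metadata missing column(s): {sorted(missing)}")
    df = df.set_index("sample_id")
    for col in ("tslp_years", "age_years", "bmi", "smoking_duration_years"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["replicate_of"] = df["replicate_of"].replace("", np.nan)
    return CohortMetadata(df)


def save_metadata(metadata: CohortMetadata, path: str | Path) -> None:
    out = metadata.data.copy()
    for col in ("tslp_years", "age_years", "bmi", "smoking_duration_years"):
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else (FLOAT_FORMAT % v)
        )
    out["replicate_of"] = out["replicate_of"].fillna("")
    out.to_csv(path, sep="\t", index_label="sample_id")


def load_table(path: str | Path) -> pd.DataFrame:
    """Generic tab-delimited results table reader."""
    return pd.read_csv(path, sep="\t")


def save_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def load_annotation(path: str | Path) -> pd.DataFrame:
    """Two-column gene<->term annotation pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "term"):
        if col not in df.columns:
            raise ParseError(f"annotation table missing column {col!r}")
    return df[["gene", "term"]]


def load_ontology_edges(path: str | Path) -> pd.DataFrame:
    """Two-column parent-child term edge list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("parent", "child"):
        if col not in df.columns:
            raise ParseError(f"ontology edge list missing column {col!r}")
    return df[["parent", "child"]]


def load_ct_table(path: str | Path) -> pd.DataFrame:
    """Long-format RT-PCR table with columns gene, sample_id, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample_id": str})
    for col in ("gene", "sample_id", "ct"):
        if col not in df.columns:
            raise ParseError(f"Ct table missing column {col!r}")
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    if (df["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive")
    return df
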