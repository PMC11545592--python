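"""Tabular input/output and the core in-memory containers.

Three inputs drive a diet-metabarcoding analysis:

* a sample x OTU read-count table (TSV),
* a per-OTU best-hit taxonomy table in BLAST-tabular style
  (OTU id, binomial taxon or ``"no match"``, percent identity,
  query coverage, max score, accession),
* a field-survey availability table (group, genus, species, count).

All files are tab-separated UTF-8 with ``.`` as the decimal mark. Count
tables may be laid out with samples as rows (default) or as columns;
the ``dialect`` switch of :func:`read_count_table` handles both.

Result tables are written at full float precision so that a write/read
round trip is lossless; one-decimal rounding is applied only when a
table is formatted for display (see :func:`format_report`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class DietError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DietError):
    """Raised when an input file or container violates its contract."""


GROUP_FISH = "fish"
GROUP_INVERT = "benthic_invertebrate"
PREY_GROUPS = (GROUP_FISH, GROUP_INVERT)

_GROUP_ALIASES = {
    "fish": GROUP_FISH,
    "benthic_invertebrate": GROUP_INVERT,
    "benthic invertebrate": GROUP_INVERT,
    "benthic_invertebrates": GROUP_INVERT,
    "benthic invertebrates": GROUP_INVERT,
    "benthic_macroinvertebrate": GROUP_INVERT,
    "benthic macro invertebrates": GROUP_INVERT,
    "invertebrate": GROUP_INVERT,
}

NO_MATCH = "no match"


def normalise_group(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _GROUP_ALIASES:
        raise ValidationError(
            f"unknown prey-group label {label!r}; expected one of {sorted(set(_GROUP_ALIASES))}"
        )
    return _GROUP_ALIASES[key]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention used in printed reports."""
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# read-count table


@dataclass
class ReadCountTable:
    """Samples x OTUs matrix of non-negative integer read counts.

    ``counts`` is indexed by sample id with one column per OTU id.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0:
            raise ValidationError("no samples in read-count table")
        if df.shape[1] == 0:
            raise ValidationError("no OTUs in read-count table")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample id(s): {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate OTU id(s): {dup}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("read counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise ValidationError(
                f"read count must be a non-negative integer at sample "
                f"{df.index[bad[0]]!r}, OTU {df.columns[bad[1]]!r} "
                f"(value {arr[bad[0], bad[1]]!r})"
            )
        self.counts = df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_otus(self, otu_ids: Sequence[str]) -> "ReadCountTable":
        return ReadCountTable(self.counts.loc[:, list(otu_ids)].copy())


def read_count_table(path: str | Path, dialect: str = "samples-as-rows") -> ReadCountTable:
    """Read a TSV count table; ``dialect`` selects the matrix orientation."""
    if dialect not in ("samples-as-rows", "samples-as-columns"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: no samples (empty table body)")
    if dialect == "samples-as-columns":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric count at sample {df.index[r]!r}, OTU "
            f"{df.columns[c]!r} (value {df.iat[r, c]!r})"
        )
    arr = numeric.to_numpy()
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        r, c = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
        raise ValidationError(
            f"{path}: invalid count at sample {df.index[r]!r}, OTU "
            f"{df.columns[c]!r} (value {df.iat[r, c]!r}); counts must be "
            "non-negative integers"
        )
    numeric = numeric.rename_axis(index=None, columns=None)
    return ReadCountTable(numeric)


def write_count_table(
    table: ReadCountTable, path: str | Path, dialect: str = "samples-as-rows"
) -> None:
    df = table.counts if dialect == "samples-as-rows" else table.counts.T
    df.to_csv(path, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# taxonomy hits


@dataclass(frozen=True)
class TaxonomyHit:
    """Best BLAST-style hit for one OTU.

    ``taxon`` is a binomial name (optionally a genus-level placeholder such
    as ``"Zacco sp."``) or the literal ``"no match"``.
    """

    otu_id: str
    taxon: str
    percent_identity: float
    query_coverage_pct: float
    max_score: float
    accession: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"OTU {self.otu_id!r}: percent_identity {self.percent_identity} "
                "outside [0, 100]"
            )
        if not 0.0 <= self.query_coverage_pct <= 100.0:
            raise ValidationError(
                f"OTU {self.otu_id!r}: query_coverage_pct {self.query_coverage_pct} "
                "outside [0, 100]"
            )

    @property
    def is_no_match(self) -> bool:
        return self.taxon.strip().lower() == NO_MATCH

    @property
    def genus(self) -> str:
        return self.taxon.split()[0] if self.taxon.strip() else ""


TAXONOMY_COLUMNS = [
    "otu_id",
    "taxon",
    "percent_identity",
    "query_coverage_pct",
    "max_score",
    "accession",
]


def read_taxonomy_hits(path: str | Path) -> list[TaxonomyHit]:
    """Read one best hit per OTU from a headed, outfmt-6-like TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df["otu_id"].duplicated().any():
        dup = df.loc[df["otu_id"].duplicated(), "otu_id"].tolist()
        raise ValidationError(
            f"{path}: duplicate otu_id(s) {dup}; the file must hold one "
            "best hit per OTU"
        )
    hits = []
    for _, row in df.iterrows():
        try:
            hits.append(
                TaxonomyHit(
                    otu_id=str(row["otu_id"]),
                    taxon=str(row["taxon"]),
                    percent_identity=float(row["percent_identity"]),
                    query_coverage_pct=float(row["query_coverage_pct"]),
                    max_score=float(row["max_score"]),
                    accession=str(row["accession"]),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: bad numeric field in row {row.to_dict()}") from exc
    return hits


def write_taxonomy_hits(hits: Iterable[TaxonomyHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (h.otu_id, h.taxon, h.percent_identity, h.query_coverage_pct, h.max_score, h.accession)
            for h in hits
        ],
        columns=TAXONOMY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# field survey


def _epithet(species: str) -> str:
    """Specific epithet of a possibly abbreviated binomial ('Z. temminckii')."""
    parts = str(species).split()
    return parts[-1].lower() if parts else ""


@dataclass
class FieldSurveyTable:
    """Availability counts from a field survey: (group, genus, species, count).

    ``species`` may be empty for genus-level (or family-level) records.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        required = ["group", "genus", "species", "count"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"field survey missing column(s) {missing}")
        df["group"] = df["group"].map(normalise_group)
        df["genus"] = df["genus"].astype(str).str.strip()
        df["species"] = df["species"].fillna("").astype(str).str.strip()
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any() or (counts < 0).any() or (counts != np.floor(counts)).any():
            bad = df.loc[counts.isna() | (counts < 0) | (counts != np.floor(counts))].iloc[0]
            raise ValidationError(
                f"field survey: count must be a non-negative integer "
                f"(group {bad['group']!r}, genus {bad['genus']!r}, value {bad['count']!r})"
            )
        df["count"] = counts.astype(np.int64)
        key = df[["group", "genus", "species"]]
        if key.duplicated().any():
            dup = key.loc[key.duplicated()].iloc[0].tolist()
            raise ValidationError(f"field survey: duplicate record for {tuple(dup)}")
        self.records = df.reset_index(drop=True)

    def genera(self, group: str | None = None) -> set[str]:
        df = self.records
        if group is not None:
            df = df[df["group"] == normalise_group(group)]
        return set(df["genus"])

    def has_species(self, genus: str, species: str) -> bool:
        """True if any record matches the genus and the specific epithet."""
        target = _epithet(species)
        if not target or target.startswith("sp."):
            return False
        df = self.records
        sub = df[df["genus"].str.lower() == genus.lower()]
        return any(_epithet(s) == target for s in sub["species"] if s)

    def genus_counts(self, group: str) -> pd.Series:
        """Total individuals per genus within one prey group."""
        df = self.records[self.records["group"] == normalise_group(group)]
        return df.groupby("genus")["count"].sum()


def read_field_survey(path: str | Path) -> FieldSurveyTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return FieldSurveyTable(df)


def write_field_survey(survey: FieldSurveyTable, path: str | Path) -> None:
    survey.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# prey table (post-filter, post-collapse)


@dataclass
class PreyTable:
    """Samples x prey-item read counts after filtering and taxon collapse.

    ``counts`` is indexed by sample id, one column per prey item;
    ``groups`` maps each item to its prey group. In the usual symbols,
    ``counts.iat[k, i]`` is n_{i,k}, ``n_samples`` is S and ``n_items`` is T.
    """

    counts: pd.DataFrame
    groups: dict[str, str]
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.counts
        if df.columns.duplicated().any():
            raise ValidationError("duplicate prey-item names")
        arr = df.to_numpy()
        if arr.size == 0:
            raise ValidationError("empty prey table")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValidationError("prey-table counts must be non-negative integers")
        if np.any(arr.sum(axis=1) == 0):
            empty = df.index[arr.sum(axis=1) == 0].tolist()
            raise ValidationError(
                f"sample(s) with zero prey reads must be dropped before "
                f"building a PreyTable: {empty}"
            )
        unknown = [i for i in df.columns if i not in self.groups]
        if unknown:
            raise ValidationError(f"prey item(s) without a group: {unknown}")
        self.groups = {i: normalise_group(self.groups[i]) for i in df.columns}
        self.counts = df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def items(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_items(self) -> int:
        return self.counts.shape[1]

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def group_items(self, group: str) -> list[str]:
        g = normalise_group(group)
        return [i for i in self.items if self.groups[i] == g]


def write_prey_table(prey: PreyTable, counts_path: str | Path, groups_path: str | Path) -> None:
    prey.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    pd.DataFrame(
        {"item": prey.items, "prey_group": [prey.groups[i] for i in prey.items]}
    ).to_csv(groups_path, sep="\t", index=False)


def read_prey_table(counts_path: str | Path, groups_path: str | Path) -> PreyTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts = counts.rename_axis(index=None, columns=None)
    groups_df = pd.read_csv(groups_path, sep="\t", dtype=str)
    groups = dict(zip(groups_df["item"], groups_df["prey_group"]))
    return PreyTable(counts, groups)


# ---------------------------------------------------------------------------
# result tables


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table at full precision (lossless round trip)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def format_report(df: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Copy of a result table with percentage columns rounded for display.

    Columns whose name starts with ``pct_`` are rounded half-up to
    ``ndigits`` decimals; everything else is left untouched.
    """
    out = df.copy()
    for col in out.columns:
        if str(col).startswith("pct_"):
            out[col] = [
                round_half_up(v, ndigits) if pd.notna(v) else v for v in out[col]
            ]
    return out
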