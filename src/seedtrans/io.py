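"""Data model and file I/O for longitudinal OTU studies.

The observational unit is an integer OTU-by-sample count table joined to
per-sample metadata (plant compartment, host age in days after
transplanting, year, site, biological and technical replicate) and a
taxonomy table (kingdom through genus). All downstream stages —
normalization, transmitted-OTU calls, neutral-model fits, source tracking
and network inference — consume these three objects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Compartment codes used in the longitudinal rice study design: bulk soil,
#: rhizosphere, root endosphere, stem sections S1-S9 (10 cm height bands),
#: leaf sections L1-L3, flag leaf, and seed.
COMPARTMENTS = (
    "BS", "RS", "R",
    "S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9",
    "L1", "L2", "L3", "FL", "Se",
)

SITES = ("CC1", "CC2", "SW")

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

META_COLUMNS = (
    "sample_id", "compartment", "age_days", "year", "site", "bio_rep", "tech_rep",
)


class DataError(ValueError):
    """Raised when an input table violates a data-model invariant."""


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise DataError(f"duplicate {what} id(s): {sorted(set(dups))}")


@dataclass
class CountTable:
    """Non-negative integer OTU x sample count matrix.

    ``counts`` is a pandas DataFrame with OTU ids on the index and sample
    ids on the columns. Construction enforces: unique ids on both axes,
    all counts >= 0, and every sample column sum > 0.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "OTU")
        _check_unique(df.columns, "sample")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("count table contains non-numeric cells")
        if np.any(arr < 0):
            raise DataError("count table contains negative counts")
        if np.any(arr != np.round(arr)):
            raise DataError("count table contains non-integer counts")
        colsums = arr.sum(axis=0)
        empty = [c for c, s in zip(df.columns, colsums) if s == 0]
        if empty:
            raise DataError(f"empty sample column(s): {empty}")
        self.counts = df.astype(np.int64)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depths(self) -> pd.Series:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts.loc[:, list(sample_ids)].copy())

    def subset_otus(self, otu_ids) -> "CountTable":
        return CountTable(self.counts.loc[list(otu_ids), :].copy())

    def checksum(self) -> str:
        """sha256 of the table contents, for run manifests."""
        h = hashlib.sha256()
        h.update(",".join(map(str, self.counts.index)).encode())
        h.update(",".join(map(str, self.counts.columns)).encode())
        h.update(np.ascontiguousarray(self.counts.to_numpy()).tobytes())
        return h.hexdigest()


@dataclass
class SampleMeta:
    """Per-sample study-design annotations.

    ``table`` holds one row per sample with the columns
    ``sample_id, compartment, age_days, year, site, bio_rep, tech_rep``.
    ``age_days`` is days after transplanting; 0 marks parent seeds at the
    sowing stage (Se0). The tuple (compartment, age_days, year, site,
    bio_rep, tech_rep) must identify each sample uniquely.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"sample metadata missing column(s): {missing}")
        _check_unique(df["sample_id"], "sample")
        bad_comp = sorted(set(df["compartment"]) - set(COMPARTMENTS))
        if bad_comp:
            raise DataError(f"unknown compartment code(s): {bad_comp}")
        bad_site = sorted(set(df["site"]) - set(SITES))
        if bad_site:
            raise DataError(f"unknown site code(s): {bad_site}")
        if (df["age_days"].astype(int) < 0).any():
            raise DataError("age_days must be >= 0")
        key = df[["compartment", "age_days", "year", "site", "bio_rep", "tech_rep"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].to_dict()
            raise DataError(f"design key not unique, first duplicate: {dup}")
        self.table = df.reset_index(drop=True)

    def samples(self, **conditions) -> list[str]:
        """Sample ids matching equality conditions, e.g. compartment='Se'.

        A condition value may be a scalar or a collection of admissible
        values.
        """
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            if col not in self.table.columns:
                raise DataError(f"unknown metadata column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.table[col].isin(list(val))
            else:
                mask &= self.table[col] == val
        return list(self.table.loc[mask, "sample_id"])

    def lookup(self, sample_id: str) -> pd.Series:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise DataError(f"unknown sample id {sample_id!r}")
        return row.iloc[0]

    def check_join(self, t: CountTable) -> None:
        """Require the metadata sample set to equal the count table's."""
        meta_ids = set(self.table["sample_id"])
        tab_ids = set(t.sample_ids)
        if meta_ids != tab_ids:
            raise DataError(
                f"metadata/count-table sample mismatch: "
                f"{sorted(tab_ids - meta_ids)[:5]} only in table, "
                f"{sorted(meta_ids - tab_ids)[:5]} only in metadata"
            )


@dataclass
class TaxonomyTable:
    """OTU -> (kingdom, phylum, class, order, family, genus) assignments.

    Kingdom must be present for every OTU ('Bacteria' or 'Fungi'); lower
    ranks may be missing (NaN / 'unclassified').
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in TAXONOMY_RANKS if c not in df.columns]
        if missing:
            raise DataError(f"taxonomy missing rank column(s): {missing}")
        _check_unique(df.index, "OTU")
        if df["kingdom"].isna().any():
            bad = list(df.index[df["kingdom"].isna()])[:5]
            raise DataError(f"kingdom missing for OTU(s): {bad}")
        bad_k = sorted(set(df["kingdom"]) - {"Bacteria", "Fungi"})
        if bad_k:
            raise DataError(f"unknown kingdom value(s): {bad_k}")

    def check_covers(self, t: CountTable) -> None:
        missing = sorted(set(t.otu_ids) - set(self.table.index))
        if missing:
            raise DataError(f"taxonomy missing OTU(s): {missing[:5]}")

    def labels(self, level: str, otu_ids=None) -> pd.Series:
        """Labels at a rank, with missing values binned as 'unclassified'."""
        if level not in TAXONOMY_RANKS:
            raise DataError(f"unknown taxonomy rank {level!r}")
        col = self.table[level]
        if otu_ids is not None:
            col = col.reindex(list(otu_ids))
        return col.fillna("unclassified").astype(str)

    def kingdom(self, otu_id: str) -> str:
        return str(self.table.loc[otu_id, "kingdom"])


@dataclass
class NormalizedTable:
    """Real-valued OTU x sample matrix with a normalization method tag.

    method is one of 'CSS_log', 'relative_abundance', 'CLR'.
    relative-abundance columns sum to 1; CLR columns sum to 0.
    """

    values: pd.DataFrame
    method: str

    _METHODS = ("CSS_log", "relative_abundance", "CLR")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise DataError(f"unknown normalization method {self.method!r}")
        _check_unique(self.values.index, "OTU")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        colsum = arr.sum(axis=0)
        if self.method == "relative_abundance":
            if np.any(arr < 0) or not np.allclose(colsum, 1.0, atol=1e-9):
                raise DataError("relative-abundance columns must be >=0 and sum to 1")
        elif self.method == "CLR":
            if not np.allclose(colsum, 0.0, atol=1e-9):
                raise DataError("CLR columns must sum to 0")
        else:  # CSS_log
            if np.any(arr < 0):
                raise DataError("CSS_log values must be >= 0")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DistMatrix:
    """Symmetric sample x sample dissimilarity matrix in [0, 1]."""

    matrix: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        if self.metric not in ("bray_curtis", "jaccard"):
            raise DataError(f"unknown distance metric {self.metric!r}")
        m = self.matrix.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1] or list(self.matrix.index) != list(self.matrix.columns):
            raise DataError("distance matrix must be square with matching ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal must be 0")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise DataError("distances must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.index)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.matrix.to_numpy(dtype=float), checks=False)


@dataclass
class TestResult:
    """Generic hypothesis-test record with BH-adjusted q-value."""

    statistic: float
    p_value: float
    q_value: float | None = None
    df: int | None = None
    n_perm: int | None = None
    groups: tuple | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DataError(f"p-value {self.p_value} outside [0, 1]")
        if self.q_value is not None and not (0.0 <= self.q_value <= 1.0):
            raise DataError(f"q-value {self.q_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# File readers / writers (plain TSV dialects)
# ---------------------------------------------------------------------------

def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read an OTU count table from TSV (first column OTU ids, header samples).

    ``format='biom_tsv'`` accepts the classic BIOM text export whose header
    line starts with ``#OTU ID`` (and an optional leading
    ``# Constructed from biom file`` comment).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("tsv", "biom_tsv"):
        raise DataError(f"unknown count-table format {format!r}")
    skiprows = 0
    if format == "biom_tsv":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#OTU ID"):
                    break
                skiprows += 1
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skiprows)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"non-numeric cell in count table: {exc}") from exc
    if np.isnan(arr).any():
        raise DataError("count table contains missing values")
    return CountTable(pd.DataFrame(arr, index=df.index, columns=df.columns))


def read_sample_meta(path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("age_days", "year", "bio_rep", "tech_rep"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return SampleMeta(df)


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return TaxonomyTable(df)


def write_tsv(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def write_dist_matrix(d: DistMatrix, path) -> None:
    write_tsv(d.matrix, path, index_label="sample_id")
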