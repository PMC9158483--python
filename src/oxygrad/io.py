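"""Tabular data model and readers/writers.

The pipeline operates on four plain-text inputs that mirror the usual
post-clustering amplicon deliverables:

* an OTU count table (TSV, OTUs x samples, integer reads),
* a taxonomy table (TSV, one lineage row per OTU down to family),
* sample metadata (TSV: sample_id, core_id, depth_cmbsf),
* discrete oxygen measurements per core (CSV or TSV: core_id,
  depth_cmbsf, o2_uM).

All matrices are oriented OTUs x samples (rows = features), depths are
centimetres below seafloor (cmbsf) and oxygen concentrations are in uM.
Taxonomy ranks that a classifier could not resolve are padded with the
explicit string ``"unassigned"`` at parse time so that aggregation to a
higher rank is total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "order", "family")
UNASSIGNED = "unassigned"

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "CountTable",
    "TaxonomyTable",
    "SampleMetadata",
    "OxygenMeasurementSet",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_oxygen_measurements",
    "write_oxygen_measurements",
    "aggregate_to_rank",
    "unassigned_fraction",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected schema."""


def _check_unique(values, what: str) -> None:
    dupes = pd.Index(values)[pd.Index(values).duplicated()].unique()
    if len(dupes):
        raise FormatError(f"duplicate {what}: {', '.join(map(str, dupes[:5]))}")


@dataclass
class CountTable:
    """Integer read counts, OTUs x samples.

    ``counts`` is a DataFrame indexed by OTU id with sample ids as
    columns. Counts are non-negative integers; identifier order is
    preserved from the source.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts.index.name = "otu_id"
        self.counts.columns.name = None
        _check_unique(self.counts.index, "OTU ids")
        _check_unique(self.counts.columns, "sample ids")
        if self.counts.shape[1] == 0:
            raise FormatError("no samples")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at OTU {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset(self, otus=None, samples=None) -> "CountTable":
        """Pure subsetting: no surviving count is modified."""
        df = self.counts
        if otus is not None:
            df = df.loc[otus]
        if samples is not None:
            df = df[samples]
        return CountTable(df.copy())


@dataclass
class TaxonomyTable:
    """Per-OTU lineage, fixed rank order phylum > class > order > family."""

    lineages: pd.DataFrame  # index otu_id, columns RANKS

    def __post_init__(self) -> None:
        self.lineages.index.name = "otu_id"
        _check_unique(self.lineages.index, "OTU ids")
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise FormatError(f"taxonomy missing ranks: {missing}")
        lin = self.lineages[list(RANKS)].astype("string")
        lin = lin.fillna(UNASSIGNED)
        lin = lin.where(lin.apply(lambda c: c.str.strip() != ""), UNASSIGNED)
        self.lineages = lin.astype(str)

    def lineage_for(self, table: CountTable) -> pd.DataFrame:
        """Lineages aligned to a count table; unknown OTUs are unassigned."""
        return self.lineages.reindex(table.otu_ids).fillna(UNASSIGNED)


@dataclass
class SampleMetadata:
    """Sample id, parent core and depth (cmbsf, >= 0)."""

    records: pd.DataFrame  # index sample_id, columns core_id, depth_cmbsf

    def __post_init__(self) -> None:
        self.records.index.name = "sample_id"
        _check_unique(self.records.index, "sample ids")
        for col in ("core_id", "depth_cmbsf"):
            if col not in self.records.columns:
                raise FormatError(f"metadata missing column {col!r}")
        depth = pd.to_numeric(self.records["depth_cmbsf"], errors="raise")
        if (depth < 0).any():
            raise FormatError("negative depth_cmbsf")
        self.records = self.records.assign(depth_cmbsf=depth.astype(float))

    @property
    def sample_ids(self) -> pd.Index:
        return self.records.index

    @property
    def core_ids(self) -> list[str]:
        return sorted(self.records["core_id"].unique())

    def depth(self) -> pd.Series:
        return self.records["depth_cmbsf"]

    def core(self) -> pd.Series:
        return self.records["core_id"]


@dataclass
class OxygenMeasurementSet:
    """Discrete oxygen measurements for one core, sorted by depth.

    The optode used downcore has a lower detection limit (default
    3 uM); measurements below it are conventionally not recorded.
    """

    core_id: str
    depths: np.ndarray
    concentrations: np.ndarray
    detection_limit: float = 3.0

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.depths.shape != self.concentrations.shape:
            raise FormatError(f"core {self.core_id}: depth/concentration length mismatch")
        if not np.all(np.isfinite(self.concentrations)):
            raise FormatError(f"core {self.core_id}: non-finite concentration")
        if (self.concentrations < 0).any():
            raise FormatError(f"core {self.core_id}: negative concentration")
        if len(self.depths) > 1 and not np.all(np.diff(self.depths) > 0):
            raise FormatError(
                f"core {self.core_id}: depths must be strictly increasing"
            )

    @property
    def n_points(self) -> int:
        return len(self.depths)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path) -> CountTable:
    """Read a TSV count table (first column OTU ids, header sample ids)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise FormatError("no samples")
    parsed = {}
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (numeric % 1 != 0) | (numeric < 0)
        if bad.any():
            otu = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"non-integer or negative count at OTU {otu!r}, sample {col!r}"
            )
        parsed[col] = numeric.astype(np.int64)
    counts = pd.DataFrame(parsed, index=raw.index)
    counts.index = counts.index.astype(str)
    counts.index.name = "otu_id"
    return CountTable(counts)


def write_count_table(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="otu_id")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "otu_id"
    for rank in RANKS:
        if rank not in df.columns:
            df[rank] = UNASSIGNED
    return TaxonomyTable(df[list(RANKS)])


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.lineages.to_csv(path, sep="\t", index_label="otu_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "core_id": str})
    for col in ("sample_id", "core_id", "depth_cmbsf"):
        if col not in df.columns:
            raise FormatError(f"metadata missing column {col!r}")
    df = df.set_index("sample_id")
    return SampleMetadata(df[["core_id", "depth_cmbsf"]])


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.records.to_csv(path, sep="\t", index_label="sample_id")


def read_oxygen_measurements(path, detection_limit: float = 3.0) -> dict[str, OxygenMeasurementSet]:
    """Read per-core oxygen measurements (comma- or tab-separated)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"core_id": str})
    for col in ("core_id", "depth_cmbsf", "o2_uM"):
        if col not in df.columns:
            raise FormatError(f"oxygen file missing column {col!r}")
    sets = {}
    for core_id, grp in df.groupby("core_id", sort=False):
        grp = grp.sort_values("depth_cmbsf", kind="stable")
        if grp["depth_cmbsf"].duplicated().any():
            raise FormatError(f"core {core_id}: duplicate measurement depth")
        sets[str(core_id)] = OxygenMeasurementSet(
            core_id=str(core_id),
            depths=grp["depth_cmbsf"].to_numpy(float),
            concentrations=grp["o2_uM"].to_numpy(float),
            detection_limit=detection_limit,
        )
    return sets


def write_oxygen_measurements(sets: dict[str, OxygenMeasurementSet], path) -> None:
    frames = [
        pd.DataFrame(
            {"core_id": s.core_id, "depth_cmbsf": s.depths, "o2_uM": s.concentrations}
        )
        for s in sets.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_to_rank(table: CountTable, tax: TaxonomyTable, rank: str) -> CountTable:
    """Sum OTU counts into taxa at ``rank``; column sums are preserved.

    Reads whose OTU lacks an assignment at that rank land in an explicit
    ``"unassigned"`` row (only present when non-empty, i.e. when at
    least one OTU is unassigned).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = tax.lineage_for(table)[rank]
    agg = table.counts.groupby(labels.to_numpy()).sum()
    # deterministic order: taxa alphabetically, unassigned last
    names = sorted(n for n in agg.index if n != UNASSIGNED)
    if UNASSIGNED in agg.index:
        names.append(UNASSIGNED)
    agg = agg.loc[names]
    agg.index.name = rank
    return CountTable(agg)


def unassigned_fraction(aggregated: CountTable) -> float:
    """Fraction of all reads not assigned at the aggregation rank."""
    total = aggregated.total_reads()
    if total == 0:
        return 0.0
    if UNASSIGNED not in aggregated.otu_ids:
        return 0.0
    return float(aggregated.counts.loc[UNASSIGNED].sum() / total)
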