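"""Post-processing filters applied to the OTU table before analysis.

The filters run in a fixed order — singleton removal, shallow-sample
removal (< 1,000 reads), rare-OTU removal (< 100 reads dataset-wide,
recounted after sample removal), then per-core selection of the
uppermost three anoxic samples. Every stage is pure subsetting:
surviving counts are never modified, and each stage emits a
:class:`FilterReport` so the chain can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _alpha

from .io import CountTable, SampleMetadata

__all__ = [
    "FilterReport",
    "drop_singletons",
    "drop_shallow_samples",
    "drop_rare_otus",
    "select_top_anoxic",
    "alpha_diversity",
    "apply_standard_filters",
]


@dataclass
class FilterReport:
    """Bookkeeping for one filter stage."""

    stage: str
    removed: list[str]
    n_retained: int
    reads_before: int
    reads_after: int

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_removed": self.n_removed,
            "removed": list(self.removed),
            "n_retained": self.n_retained,
            "reads_before": self.reads_before,
            "reads_after": self.reads_after,
        }


def drop_singletons(table: CountTable) -> tuple[CountTable, FilterReport]:
    """Remove OTUs whose dataset-wide total count is exactly 1."""
    totals = table.otu_totals()
    removed = totals.index[totals == 1]
    kept = table.subset(otus=totals.index[totals != 1])
    report = FilterReport(
        stage="drop_singletons",
        removed=list(removed),
        n_retained=kept.n_otus,
        reads_before=table.total_reads(),
        reads_after=kept.total_reads(),
    )
    return kept, report


def drop_shallow_samples(
    table: CountTable, min_reads: int = 1000
) -> tuple[CountTable, FilterReport]:
    """Remove samples with fewer than ``min_reads`` total reads.

    A sample with exactly ``min_reads`` is retained.
    """
    totals = table.sample_totals()
    keep = totals.index[totals >= min_reads]
    if len(keep) == 0:
        raise ValueError("empty dataset: all samples below read threshold")
    removed = totals.index[totals < min_reads]
    kept = table.subset(samples=keep)
    report = FilterReport(
        stage="drop_shallow_samples",
        removed=list(removed),
        n_retained=kept.n_samples,
        reads_before=table.total_reads(),
        reads_after=kept.total_reads(),
    )
    return kept, report


def drop_rare_otus(
    table: CountTable, min_total: int = 100
) -> tuple[CountTable, FilterReport]:
    """Remove OTUs represented by fewer than ``min_total`` reads overall.

    Totals are recomputed on the table as given, i.e. after any sample
    removal. An OTU with exactly ``min_total`` reads is retained.
    """
    totals = table.otu_totals()
    keep = totals.index[totals >= min_total]
    if len(keep) == 0:
        raise ValueError("empty dataset: all OTUs below read threshold")
    removed = totals.index[totals < min_total]
    kept = table.subset(otus=keep)
    report = FilterReport(
        stage="drop_rare_otus",
        removed=list(removed),
        n_retained=kept.n_otus,
        reads_before=table.total_reads(),
        reads_after=kept.total_reads(),
    )
    return kept, report


def select_top_anoxic(
    table: CountTable,
    metadata: SampleMetadata,
    categories: pd.Series,
    per_core_max: int = 3,
) -> tuple[CountTable, FilterReport]:
    """Keep, per core, only the uppermost ``per_core_max`` anoxic samples.

    "Uppermost" means smallest depth (cmbsf). Oxic samples (categories
    1-6) are all retained; anoxic samples (category 7) deeper than the
    shallowest ``per_core_max`` in their core are removed. Ties in depth
    are broken by sample id (lexicographic) for determinism.
    """
    samples = table.sample_ids
    missing = [s for s in samples if s not in categories.index]
    if missing:
        raise ValueError(f"no category for samples: {missing[:5]}")
    removed: list[str] = []
    meta = metadata.records
    for core_id, core_meta in meta.loc[meta.index.intersection(samples)].groupby("core_id"):
        anoxic = [s for s in core_meta.index if categories.loc[s] == 7]
        anoxic.sort(key=lambda s: (core_meta.loc[s, "depth_cmbsf"], s))
        removed.extend(anoxic[per_core_max:])
    keep = [s for s in samples if s not in set(removed)]
    kept = table.subset(samples=keep)
    report = FilterReport(
        stage="select_top_anoxic",
        removed=removed,
        n_retained=kept.n_samples,
        reads_before=table.total_reads(),
        reads_after=kept.total_reads(),
    )
    return kept, report


def alpha_diversity(table: CountTable, index: str = "shannon") -> pd.Series:
    """Per-sample Shannon (natural log) or Simpson (1 - sum p^2) diversity."""
    if index not in ("shannon", "simpson"):
        raise ValueError(f"unknown diversity index {index!r}")
    values = {}
    for sample in table.sample_ids:
        counts = table.counts[sample].to_numpy()
        if counts.sum() == 0:
            raise ValueError(f"zero-sum sample {sample!r}")
        if index == "shannon":
            values[sample] = float(_alpha.shannon(counts, base=np.e))
        else:
            values[sample] = float(_alpha.simpson(counts))
    return pd.Series(values, name=index)


def apply_standard_filters(
    table: CountTable,
    metadata: SampleMetadata,
    categories: pd.Series,
    min_reads: int = 1000,
    min_otu_total: int = 100,
    per_core_max_anoxic: int = 3,
) -> tuple[CountTable, list[FilterReport]]:
    """Run the full filter chain in its canonical order."""
    reports = []
    table, rep = drop_singletons(table)
    reports.append(rep)
    table, rep = drop_shallow_samples(table, min_reads=min_reads)
    reports.append(rep)
    table, rep = drop_rare_otus(table, min_total=min_otu_total)
    reports.append(rep)
    table, rep = select_top_anoxic(
        table, metadata, categories, per_core_max=per_core_max_anoxic
    )
    reports.append(rep)
    return table, reports
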