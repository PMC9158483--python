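"""End-to-end orchestration: simulate/load -> oxygen -> filter ->
transform -> classify -> differential abundance -> combined report.

The pipeline is fully reproducible from (config, seed): the master seed
spawns independent child streams for simulation, each classifier run
and each permutation screen, so stages can be re-run in isolation
without perturbing one another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import coda as _coda
from . import diffprop as _diffprop
from . import filtering as _filtering
from . import oxygen as _oxygen
from .io import (
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    read_count_table,
    read_metadata,
    read_oxygen_measurements,
    read_taxonomy,
)
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("oxygrad")

__all__ = [
    "DiffAbundConfig",
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "interpretation_matrix",
]


@dataclass
class DiffAbundConfig:
    """Parameters of the pairwise theta_d screen."""

    category_pairs: list[tuple[int, int]] = field(default_factory=lambda: [(1, 6), (1, 7)])
    n_perm: int = 100
    theta_max: float = 0.50
    fdr_max: float = 0.0005
    retain_frac: float = 0.25
    max_otus: int = _diffprop.DEFAULT_MAX_OTUS


@dataclass
class PipelineConfig:
    """One structured config drives the whole run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None  # read the four standard files instead
    anoxic_threshold: float = 5.0  # uM; 3 for the sensitivity variant
    groupings: list[str] = field(default_factory=lambda: ["binary", "ternary", "quaternary"])
    rank: str = "class"
    min_taxon_otus: int = 5
    top_k_features: int | None = 30
    classifier: _classify.ClassifierConfig = field(default_factory=_classify.ClassifierConfig)
    diffabund: DiffAbundConfig = field(default_factory=DiffAbundConfig)
    min_reads: int = 1000
    min_otu_total: int = 100
    per_core_max_anoxic: int = 3
    accuracy_iqr_multiplier: float = 2.0  # "high accuracy" = null median + mult * null IQR
    never_da_cut: float = 0.5  # "high" never-DA read fraction
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "simulation" in data and isinstance(data["simulation"], dict):
            sim = dict(data["simulation"])
            sim.pop("class_design", None)  # class designs are code-level objects
            data["simulation"] = SimulationConfig(**sim)
        if "classifier" in data and isinstance(data["classifier"], dict):
            data["classifier"] = _classify.ClassifierConfig(**data["classifier"])
        if "diffabund" in data and isinstance(data["diffabund"], dict):
            da = dict(data["diffabund"])
            if "category_pairs" in da:
                da["category_pairs"] = [tuple(p) for p in da["category_pairs"]]
            data["diffabund"] = DiffAbundConfig(**da)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    """Everything a reader needs to audit one pipeline run."""

    seed: int
    anoxic_threshold: float
    filter_reports: list
    sample_table: pd.DataFrame  # per-sample oxygen, category, groups
    classification: pd.DataFrame  # per taxon/grouping accuracy summary
    per_sample_accuracy: pd.Series
    correlations: dict
    da_counts: dict
    never_da: _diffprop.NeverDAReport | None
    interpretation: pd.DataFrame
    timings: dict

    def category_counts(self) -> pd.Series:
        return self.sample_table["category"].value_counts().sort_index()

    def data_sections_json(self) -> str:
        """Deterministic JSON of the data-bearing sections (used for
        reproducibility checks)."""
        payload = {
            "seed": self.seed,
            "anoxic_threshold": self.anoxic_threshold,
            "filters": [r.to_dict() for r in self.filter_reports],
            "sample_table": self.sample_table.round(9).to_dict(orient="index"),
            "classification": self.classification.round(9).to_dict(orient="records"),
            "correlations": {k: list(v) for k, v in self.correlations.items()},
            "da_counts": {str(k): v for k, v in self.da_counts.items()},
            "never_da": self.never_da.to_dict() if self.never_da else None,
            "interpretation": self.interpretation.to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True, default=float)


def interpretation_matrix(
    classification: pd.DataFrame,
    never_da_per_class: pd.DataFrame,
    rank: str = "class",
    iqr_multiplier: float = 2.0,
    never_da_cut: float = 0.5,
) -> pd.DataFrame:
    """Quadrant labels combining classifier skill and never-DA fraction.

    A taxon classifies "high" when its real median accuracy exceeds the
    matched null median by ``iqr_multiplier`` times the null IQR; its
    never-DA read fraction is "high" above ``never_da_cut``. The four
    quadrants: high accuracy + low never-DA fraction = oxygen-dependent;
    high + high = covariate-suspected (the taxon classifies well but its
    OTUs are individually too variable within categories); low + high =
    weak signal; low + low = ambiguous.
    """
    if rank not in never_da_per_class.columns:
        raise ValueError(
            f"never-DA table has no {rank!r} column; ranks must match"
        )
    nda = never_da_per_class.set_index(rank)["fraction"]
    rows = []
    for _, rec in classification.iterrows():
        taxon = rec["taxon"]
        high_acc = rec["median_accuracy"] > rec["null_median"] + iqr_multiplier * rec["null_iqr"]
        frac = float(nda.get(taxon, 0.0))
        high_nda = frac > never_da_cut
        if high_acc and not high_nda:
            label = "oxygen-dependent"
        elif high_acc and high_nda:
            label = "covariate-suspected"
        elif not high_acc and high_nda:
            label = "weak signal"
        else:
            label = "ambiguous"
        rows.append(
            {
                "taxon": taxon,
                "grouping": rec["grouping"],
                "median_accuracy": rec["median_accuracy"],
                "null_median": rec["null_median"],
                "never_da_fraction": frac,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def _load_inputs(config: PipelineConfig):
    if config.input_dir is not None:
        d = Path(config.input_dir)
        table = read_count_table(d / "count_table.tsv")
        tax = read_taxonomy(d / "taxonomy.tsv")
        meta = read_metadata(d / "metadata.tsv")
        oxygen = read_oxygen_measurements(d / "oxygen.csv")
        return table, tax, meta, oxygen
    ds = simulate_dataset(config.simulation, seed=config.seed)
    return ds.table, ds.taxonomy, ds.metadata, ds.oxygen


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> RunReport:
    """Execute all stages in order and assemble the combined report."""
    config = config or PipelineConfig()
    t0 = time.time()
    timings: dict[str, float] = {}
    ss = np.random.SeedSequence(config.seed)
    seed_classify, seed_diffabund = ss.spawn(2)

    table, tax, meta, oxygen_sets = _load_inputs(config)
    timings["inputs"] = time.time() - t0
    logger.info(json.dumps({"stage": "inputs", "n_otus": table.n_otus,
                            "n_samples": table.n_samples}))

    # --- oxygen models -----------------------------------------------------
    fits = {}
    for core_id, ms in oxygen_sets.items():
        try:
            fits[core_id] = _oxygen.fit_oxygen_decay(ms)
        except _oxygen.InsufficientOxygenDataError as exc:
            logger.warning(json.dumps({"stage": "oxygen", "dropped_core": core_id,
                                       "reason": str(exc)}))
    if not fits:
        raise RuntimeError("oxygen stage: no core could be fitted")
    sample_table = _oxygen.categorise_samples(meta, fits, config.anoxic_threshold)
    table = table.subset(samples=[s for s in table.sample_ids if s in sample_table.index])
    timings["oxygen"] = time.time() - t0
    logger.info(json.dumps({"stage": "oxygen", "n_cores_fit": len(fits)}))

    # --- filters -----------------------------------------------------------
    categories = sample_table["category"]
    table, reports = _filtering.apply_standard_filters(
        table,
        meta,
        categories,
        min_reads=config.min_reads,
        min_otu_total=config.min_otu_total,
        per_core_max_anoxic=config.per_core_max_anoxic,
    )
    sample_table = sample_table.loc[table.sample_ids]
    timings["filter"] = time.time() - t0
    logger.info(json.dumps({"stage": "filter",
                            "chain": [r.to_dict() | {"removed": len(r.removed)}
                                      for r in reports]}))

    # --- transform ---------------------------------------------------------
    comp = _coda.impute_zeros(table)
    clr_mat = _coda.clr(comp)
    otu_totals = table.otu_totals()
    lineage = tax.lineage_for(table)[config.rank]
    taxa = {
        name: list(members)
        for name, members in lineage.groupby(lineage.to_numpy()).groups.items()
        if len(members) >= config.min_taxon_otus
    }
    timings["transform"] = time.time() - t0

    # --- classification ----------------------------------------------------
    class_rows = []
    correct = pd.Series(0.0, index=table.sample_ids)
    tested = pd.Series(0.0, index=table.sample_ids)
    cls_children = iter(seed_classify.spawn(2 * len(config.groupings) * max(len(taxa), 1)))
    for grouping in config.groupings:
        labels = sample_table[grouping]
        try:
            _classify.dominance_guard(labels, config.classifier.dominance_max)
        except (_classify.DominanceError, ValueError) as exc:
            logger.warning(json.dumps({"stage": "classify", "grouping": grouping,
                                       "skipped": str(exc)}))
            continue
        for taxon, otus in sorted(taxa.items()):
            feats = _classify.build_features(
                clr_mat, otus, otu_totals, top_k=config.top_k_features
            )
            real = _classify.run_classification(
                feats, labels, config.classifier, shuffle=False,
                taxon=taxon, grouping=grouping,
                rng=np.random.default_rng(next(cls_children)),
            )
            null = _classify.run_classification(
                feats, labels, config.classifier, shuffle=True,
                taxon=taxon, grouping=grouping,
                rng=np.random.default_rng(next(cls_children)),
            )
            class_rows.append(
                {
                    "taxon": taxon,
                    "grouping": grouping,
                    "n_otus": feats.shape[1],
                    "median_accuracy": real.median_accuracy,
                    "null_median": null.median_accuracy,
                    "null_iqr": null.iqr,
                }
            )
            correct += real.per_sample_correct
            tested += real.per_sample_tested
    classification = pd.DataFrame(
        class_rows,
        columns=["taxon", "grouping", "n_otus", "median_accuracy",
                 "null_median", "null_iqr"],
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_sample_accuracy = correct / tested
    timings["classify"] = time.time() - t0
    logger.info(json.dumps({"stage": "classify", "n_models": len(class_rows)}))

    # --- correlations ------------------------------------------------------
    if per_sample_accuracy.notna().sum() >= 4 and len(class_rows):
        correlations = _classify.accuracy_correlations(
            per_sample_accuracy,
            sample_table["category"],
            sample_table["depth_cmbsf"],
        )
    else:
        correlations = {}

    # --- differential abundance -------------------------------------------
    da_sets: dict[tuple, _diffprop.DAPairSet] = {}
    da_counts: dict[tuple, dict] = {}
    da_children = iter(seed_diffabund.spawn(max(len(config.diffabund.category_pairs), 1)))
    for pair in config.diffabund.category_pairs:
        pair = tuple(pair)
        present = categories.loc[table.sample_ids]
        sizes = present.value_counts()
        if any(sizes.get(c, 0) < 2 for c in pair):
            logger.warning(json.dumps({"stage": "diffabund", "pair": list(pair),
                                       "skipped": "a category has < 2 samples"}))
            next(da_children)
            continue
        ds = _diffprop.differential_pairs(
            comp,
            present,
            pair,
            n_perm=config.diffabund.n_perm,
            theta_max=config.diffabund.theta_max,
            fdr_max=config.diffabund.fdr_max,
            retain_frac=config.diffabund.retain_frac,
            rng=np.random.default_rng(next(da_children)),
            max_otus=config.diffabund.max_otus,
        )
        da_sets[pair] = ds
        da_counts[pair] = ds.counts
    never = _diffprop.never_da(da_sets, table, tax, rank=config.rank) if da_sets else None
    timings["diffabund"] = time.time() - t0
    logger.info(json.dumps({"stage": "diffabund",
                            "pairs": {str(k): v for k, v in da_counts.items()}}))

    # --- interpretation ----------------------------------------------------
    if never is not None and len(classification):
        interp = interpretation_matrix(
            classification,
            never.per_class,
            rank=config.rank,
            iqr_multiplier=config.accuracy_iqr_multiplier,
            never_da_cut=config.never_da_cut,
        )
    else:
        interp = pd.DataFrame(
            columns=["taxon", "grouping", "median_accuracy", "null_median",
                     "never_da_fraction", "label"]
        )

    report = RunReport(
        seed=config.seed,
        anoxic_threshold=config.anoxic_threshold,
        filter_reports=reports,
        sample_table=sample_table,
        classification=classification,
        per_sample_accuracy=per_sample_accuracy,
        correlations=correlations,
        da_counts=da_counts,
        never_da=never,
        interpretation=interp,
        timings=timings,
    )
    if out_dir is not None:
        _write_outputs(report, da_sets, out_dir)
    return report


def _write_outputs(report: RunReport, da_sets, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.sample_table.to_csv(out / "sample_oxygen.tsv", sep="\t")
    report.classification.to_csv(out / "classification.tsv", sep="\t", index=False)
    report.per_sample_accuracy.rename("mean_accuracy").to_csv(
        out / "per_sample_accuracy.tsv", sep="\t"
    )
    for pair, ds in da_sets.items():
        name = f"da_pairs_{pair[0]}v{pair[1]}.tsv"
        ds.retained.to_csv(out / name, sep="\t", index=False)
    if report.never_da is not None:
        report.never_da.per_class.to_csv(out / "never_da_per_class.tsv", sep="\t", index=False)
        (out / "never_da.json").write_text(json.dumps(report.never_da.to_dict(), indent=1))
    report.interpretation.to_csv(out / "interpretation.tsv", sep="\t", index=False)
    (out / "report.json").write_text(report.data_sections_json())
    (out / "filter_reports.json").write_text(
        json.dumps([r.to_dict() for r in report.filter_reports], indent=1)
    )
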