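"""Synthetic multi-core sediment datasets with known ground truth.

The generator emulates the structure of a post-processed amplicon
survey of deep-sea sediment cores sampled along an oxygen gradient:

* per core, a true oxygen profile ``O2(z) = O2_surface * exp(-lambda z)``
  whose 5 uM crossing (the operational anoxic onset) falls in a
  configured penetration-depth range, plus noisy discrete measurements
  that stop once the reading drops below the optode detection limit;
* per OTU, a response archetype: ``threshold_responder`` (logistic drop
  in abundance once oxygen falls below a threshold), ``gradual_responder``
  (linear in log-oxygen), ``non_responder`` (no oxygen signal, with a
  deliberately large within-category spread), ``covariate_tracker``
  (follows a nitrate-like covariate that peaks near the anoxic onset),
  and ``uniform_noise``;
* latent per-sample compositions via a logistic-normal construction
  (Gaussian log-abundances, exponentiated and closed), then integer
  reads by multinomial sampling at log-normally distributed depths, with
  a configured fraction of samples forced below 1,000 reads and a few
  injected singleton OTUs.

Everything is driven by one integer seed through numpy's Generator, so
datasets are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    RANKS,
    UNASSIGNED,
    CountTable,
    OxygenMeasurementSet,
    SampleMetadata,
    TaxonomyTable,
    write_count_table,
    write_metadata,
    write_oxygen_measurements,
    write_taxonomy,
)
from .oxygen import assign_categories

__all__ = [
    "ArchetypeSpec",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "default_class_design",
    "simulate_oxygen_profiles",
    "simulate_community",
    "sample_reads",
    "simulate_dataset",
    "write_fixture",
]

ARCHETYPES = (
    "threshold_responder",
    "gradual_responder",
    "non_responder",
    "covariate_tracker",
    "uniform_noise",
)
_ZERO_EFFECT_OK = ("non_responder", "uniform_noise")


@dataclass
class ArchetypeSpec:
    """One block of OTUs sharing a response archetype.

    ``effect_size`` is the log-scale abundance shift between the
    high-oxic and anoxic ends of the archetype's response;
    ``within_category_sd`` is the log-scale noise applied per sample on
    top of the oxygen-driven mean, i.e. the spread seen *within* an
    oxygen category.
    """

    name: str
    n_otus: int
    baseline_log_abundance: float = 0.0
    baseline_sd: float = 1.0  # per-OTU spread of baselines
    effect_size: float = 0.0
    threshold_uM: float = 25.0
    within_category_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.name!r}")
        if self.n_otus < 1:
            raise ValueError("n_otus must be positive")
        if self.within_category_sd <= 0:
            raise ValueError("within_category_sd must be > 0")
        if self.effect_size == 0 and self.name not in _ZERO_EFFECT_OK:
            raise ValueError(f"effect_size = 0 only allowed for {_ZERO_EFFECT_OK}")


def default_class_design() -> dict[str, list[ArchetypeSpec]]:
    """Five 100-OTU classes, one response archetype each.

    Threshold and gradual responders carry a 2 log-unit oxygen effect at
    0.5 log-units within-category spread; the non-responder class has no
    oxygen effect but a deliberately large within-category spread
    (1.5 log-units), the behaviour that makes abundant taxa escape the
    pairwise differential-abundance screen; the covariate-tracking class
    follows the nitrate-like covariate instead of oxygen.
    """
    return {
        "Thresholdia": [ArchetypeSpec("threshold_responder", n_otus=100, effect_size=2.0)],
        "Gradientia": [ArchetypeSpec("gradual_responder", n_otus=100, effect_size=2.0)],
        "Stochastia": [ArchetypeSpec("non_responder", n_otus=100, within_category_sd=1.5)],
        "Nitratia": [ArchetypeSpec("covariate_tracker", n_otus=100, effect_size=2.0)],
        "Backgroundia": [ArchetypeSpec("uniform_noise", n_otus=100)],
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic survey (desk scale by default:
    11 cores x 17 horizons, 500 OTUs)."""

    n_cores: int = 11
    depths_per_core: int = 17
    max_depth: float = 190.0
    penetration_depth_range: tuple[float, float] = (10.0, 116.0)
    surface_o2_range: tuple[float, float] = (150.0, 300.0)
    anoxic_threshold: float = 5.0  # uM concentration defining the crossing
    detection_limit: float = 3.0
    o2_noise_sd: float = 2.0
    o2_measurement_spacing: float = 4.0
    class_design: dict[str, list[ArchetypeSpec]] = field(default_factory=default_class_design)
    threshold_width_uM: float = 5.0  # logistic softness of threshold responses
    nitrate_baseline_uM: float = 2.0
    nitrate_peak_uM: float = 30.0
    nitrate_onset_uM: float = 50.0  # oxygen level below which nitrate accumulates
    nitrate_anoxic_decay_cm: float = 30.0
    nitrate_noise_sd: float = 2.0
    read_depth_log_mean: float = float(np.log(15000.0))
    read_depth_log_sd: float = 0.6
    low_depth_sample_fraction: float = 0.05
    singleton_rate: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.penetration_depth_range
        if not (0 < lo <= hi < self.max_depth):
            raise ValueError("penetration_depth_range must lie within (0, max_depth)")
        if self.n_cores < 1 or self.depths_per_core < 1:
            raise ValueError("counts must be positive")
        if self.surface_o2_range[0] <= self.anoxic_threshold:
            raise ValueError(
                "surface oxygen range must exceed the anoxic threshold, "
                "otherwise no 5 uM crossing exists"
            )

    @property
    def n_otus(self) -> int:
        return sum(spec.n_otus for specs in self.class_design.values() for spec in specs)

    def otu_frame(self) -> pd.DataFrame:
        """One row per designed OTU: id, class, archetype parameters."""
        rows = []
        i = 0
        for cls, specs in self.class_design.items():
            for spec in specs:
                for _ in range(spec.n_otus):
                    rows.append(
                        {
                            "otu_id": f"OTU_{i:04d}",
                            "class": cls,
                            "archetype": spec.name,
                            "baseline_log_abundance": spec.baseline_log_abundance,
                            "baseline_sd": spec.baseline_sd,
                            "effect_size": spec.effect_size,
                            "threshold_uM": spec.threshold_uM,
                            "within_category_sd": spec.within_category_sd,
                        }
                    )
                    i += 1
        return pd.DataFrame(rows).set_index("otu_id")


@dataclass
class TrueProfile:
    """Noise-free oxygen profile for one simulated core."""

    core_id: str
    surface_o2: float
    decay_rate: float  # per cm
    crossing_depth: float  # depth of the anoxic-threshold crossing, cmbsf

    def o2_at(self, depth) -> np.ndarray:
        return self.surface_o2 * np.exp(-self.decay_rate * np.asarray(depth, float))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    otus: pd.DataFrame  # per-OTU archetype and drawn parameters
    samples: pd.DataFrame  # per-sample true O2, category, nitrate
    latent: pd.DataFrame  # strictly positive compositions, OTUs x samples


@dataclass
class SyntheticDataset:
    table: CountTable
    taxonomy: TaxonomyTable
    metadata: SampleMetadata
    oxygen: dict[str, OxygenMeasurementSet]
    profiles: dict[str, TrueProfile]
    truth: GroundTruth


def simulate_oxygen_profiles(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, OxygenMeasurementSet], dict[str, TrueProfile]]:
    """Draw per-core true decay profiles and censored noisy measurements.

    The decay rate of each core is solved from a uniformly drawn
    anoxic-threshold crossing depth, so crossings always fall inside
    ``penetration_depth_range``. Measurements are taken at regular
    spacing and stop at the first reading below the detection limit,
    mimicking shipboard practice.
    """
    measurements: dict[str, OxygenMeasurementSet] = {}
    profiles: dict[str, TrueProfile] = {}
    for i in range(config.n_cores):
        core_id = f"core{i:02d}"
        crossing = rng.uniform(*config.penetration_depth_range)
        surface = rng.uniform(*config.surface_o2_range)
        lam = np.log(surface / config.anoxic_threshold) / crossing
        profile = TrueProfile(core_id, surface, lam, crossing)
        depths = np.arange(0.0, config.max_depth, config.o2_measurement_spacing)
        true_vals = profile.o2_at(depths)
        noisy = true_vals + rng.normal(0.0, config.o2_noise_sd, size=len(depths))
        noisy = np.maximum(noisy, 0.0)
        below = np.flatnonzero(noisy < config.detection_limit)
        cut = below[0] if len(below) else len(depths)
        measurements[core_id] = OxygenMeasurementSet(
            core_id=core_id,
            depths=depths[:cut],
            concentrations=noisy[:cut],
            detection_limit=config.detection_limit,
        )
        profiles[core_id] = profile
    return measurements, profiles


def _nitrate(config: SimulationConfig, true_o2: np.ndarray, depth: np.ndarray,
             crossing: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Peaked nitrate-like covariate: accumulates as oxygen falls below
    the onset level, peaks near the anoxic transition, then decays with
    depth into anoxia. Independent Gaussian noise on top."""
    o2 = np.asarray(true_o2, float)
    base, peak, onset = (
        config.nitrate_baseline_uM,
        config.nitrate_peak_uM,
        config.nitrate_onset_uM,
    )
    rise = base + (peak - base) * np.clip((onset - o2) / (onset - config.anoxic_threshold), 0, 1)
    anoxic = o2 < config.anoxic_threshold
    depth_below = np.maximum(np.asarray(depth, float) - np.asarray(crossing, float), 0.0)
    decay = peak * np.exp(-depth_below / config.nitrate_anoxic_decay_cm)
    values = np.where(anoxic, decay, rise)
    values = values + rng.normal(0.0, config.nitrate_noise_sd, size=values.shape)
    return np.maximum(values, 0.0)


def _responses(config: SimulationConfig, otus: pd.DataFrame,
               true_o2: np.ndarray, nitrate: np.ndarray) -> np.ndarray:
    """Archetype response in [0, 1] per OTU x sample.

    Responses are high at the oxic end and fall toward anoxia (or, for
    covariate trackers, are complemented so they rise with nitrate), so
    a positive effect size means "more abundant under oxic conditions".
    """
    n_samples = len(true_o2)
    out = np.zeros((len(otus), n_samples))
    max_o2 = config.surface_o2_range[1]
    for row, (_, spec) in enumerate(otus.iterrows()):
        kind = spec["archetype"]
        if kind == "threshold_responder":
            out[row] = 1.0 / (
                1.0 + np.exp(-(true_o2 - spec["threshold_uM"]) / config.threshold_width_uM)
            )
        elif kind == "gradual_responder":
            out[row] = np.log1p(true_o2) / np.log1p(max_o2)
        elif kind == "covariate_tracker":
            out[row] = nitrate / config.nitrate_peak_uM
        # non_responder / uniform_noise: response stays 0
    return out


def simulate_community(
    config: SimulationConfig,
    profiles: dict[str, TrueProfile],
    rng: np.random.Generator,
) -> tuple[SampleMetadata, GroundTruth]:
    """Latent logistic-normal compositions for every core x horizon.

    Per sample and OTU the log abundance is
    ``baseline + effect * response(O2) + N(0, within_category_sd)``;
    exponentiating and closing each sample yields a strictly positive
    composition summing to one.
    """
    sample_rows = []
    horizons = np.linspace(0.0, config.max_depth, config.depths_per_core)
    for core_id, profile in profiles.items():
        for depth in horizons:
            sample_rows.append(
                {
                    "sample_id": f"{core_id}_d{depth:05.1f}",
                    "core_id": core_id,
                    "depth_cmbsf": float(depth),
                    "true_o2_uM": float(profile.o2_at(depth)),
                    "crossing_depth": profile.crossing_depth,
                }
            )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    samples["true_category"] = assign_categories(samples["true_o2_uM"])
    samples["nitrate_uM"] = _nitrate(
        config,
        samples["true_o2_uM"].to_numpy(),
        samples["depth_cmbsf"].to_numpy(),
        samples["crossing_depth"].to_numpy(),
        rng,
    )

    otus = config.otu_frame()
    baselines = otus["baseline_log_abundance"].to_numpy() + rng.normal(
        0.0, otus["baseline_sd"].to_numpy()
    )
    otus = otus.assign(baseline_drawn=baselines)

    response = _responses(
        config, otus, samples["true_o2_uM"].to_numpy(), samples["nitrate_uM"].to_numpy()
    )
    mean_log = baselines[:, None] + otus["effect_size"].to_numpy()[:, None] * response
    log_abund = mean_log + rng.normal(
        0.0, otus["within_category_sd"].to_numpy()[:, None], size=mean_log.shape
    )
    # logistic-normal closure
    log_abund -= log_abund.max(axis=0, keepdims=True)
    latent = np.exp(log_abund)
    latent /= latent.sum(axis=0, keepdims=True)
    latent_df = pd.DataFrame(latent, index=otus.index, columns=samples.index)

    metadata = SampleMetadata(samples[["core_id", "depth_cmbsf"]].copy())
    truth = GroundTruth(
        otus=otus,
        samples=samples[["core_id", "depth_cmbsf", "true_o2_uM", "true_category", "nitrate_uM"]],
        latent=latent_df,
    )
    return metadata, truth


def sample_reads(
    latent: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CountTable:
    """Multinomial read sampling at heterogeneous depths.

    Totals are log-normal; a configured fraction of samples is forced
    below 1,000 reads (the rest are clipped to at least 1,000 so the
    forced fraction is exact by construction). Singleton OTUs — extra
    OTUs carrying exactly one read in one random sample — are appended
    at ``singleton_rate`` x the designed OTU count.
    """
    n_samples = latent.shape[1]
    totals = np.rint(
        rng.lognormal(config.read_depth_log_mean, config.read_depth_log_sd, size=n_samples)
    ).astype(int)
    totals = np.maximum(totals, 1000)
    n_low = int(round(config.low_depth_sample_fraction * n_samples))
    if n_low:
        low_idx = rng.choice(n_samples, size=n_low, replace=False)
        totals[low_idx] = rng.integers(100, 1000, size=n_low)
    counts = np.column_stack(
        [
            rng.multinomial(totals[j], latent.iloc[:, j].to_numpy())
            for j in range(n_samples)
        ]
    )
    table = pd.DataFrame(counts, index=latent.index, columns=latent.columns)

    n_single = int(round(config.singleton_rate * config.n_otus))
    if n_single:
        single = pd.DataFrame(
            0,
            index=[f"OTU_S{i:03d}" for i in range(n_single)],
            columns=latent.columns,
        )
        hit_samples = rng.integers(0, n_samples, size=n_single)
        for i, j in enumerate(hit_samples):
            single.iloc[i, j] = 1
        table = pd.concat([table, single])
    return CountTable(table.astype(np.int64))


def _taxonomy_for(config: SimulationConfig, table: CountTable,
                  otus: pd.DataFrame, rng: np.random.Generator) -> TaxonomyTable:
    classes = list(config.class_design)
    lineages = {}
    for otu in table.otu_ids:
        if otu in otus.index:
            cls = otus.loc[otu, "class"]
        else:  # injected singleton: random existing class
            cls = classes[rng.integers(0, len(classes))]
        lineages[otu] = {
            "phylum": f"{cls}_phylum",
            "class": cls,
            "order": f"{cls}_order",
            "family": UNASSIGNED,
        }
    df = pd.DataFrame.from_dict(lineages, orient="index")
    df.index.name = "otu_id"
    return TaxonomyTable(df[list(RANKS)])


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> SyntheticDataset:
    """End-to-end dataset generation from one seed."""
    config = config or SimulationConfig()
    if seed is None:
        seed = config.rng_seed
    ss = np.random.SeedSequence(seed)
    rng_o2, rng_comm, rng_reads, rng_tax = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    measurements, profiles = simulate_oxygen_profiles(config, rng_o2)
    metadata, truth = simulate_community(config, profiles, rng_comm)
    table = sample_reads(truth.latent, config, rng_reads)
    taxonomy = _taxonomy_for(config, table, truth.otus, rng_tax)
    injected = [o for o in table.otu_ids if o not in truth.otus.index]
    if injected:
        extra = pd.DataFrame(
            {
                "class": taxonomy.lineages.loc[injected, "class"],
                "archetype": "singleton",
                "baseline_log_abundance": 0.0,
                "baseline_sd": 0.0,
                "effect_size": 0.0,
                "threshold_uM": 0.0,
                "within_category_sd": 0.0,
                "baseline_drawn": 0.0,
            },
            index=pd.Index(injected, name="otu_id"),
        )
        truth.otus = pd.concat([truth.otus, extra])
    return SyntheticDataset(
        table=table,
        taxonomy=taxonomy,
        metadata=metadata,
        oxygen=measurements,
        profiles=profiles,
        truth=truth,
    )


def write_fixture(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the four standard files plus a ground-truth JSON sidecar.

    The sidecar records per-OTU archetypes and per-sample truth; the
    latent composition matrix stays in memory only (it is large and
    recomputable from the seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "count_table.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
        "oxygen": out / "oxygen.csv",
        "truth": out / "ground_truth.json",
    }
    write_count_table(dataset.table, paths["counts"])
    write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    write_metadata(dataset.metadata, paths["metadata"])
    write_oxygen_measurements(dataset.oxygen, paths["oxygen"])
    truth = {
        "otus": dataset.truth.otus.reset_index().to_dict(orient="records"),
        "samples": dataset.truth.samples.reset_index().to_dict(orient="records"),
        "profiles": {
            cid: dataclasses.asdict(p) for cid, p in dataset.profiles.items()
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
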