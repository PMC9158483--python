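"""Generator: oxygen profiles, community archetypes, read sampling."""

import numpy as np
import pandas as pd
import pytest

from oxygrad.coda import clr, impute_zeros
from oxygrad.filtering import drop_singletons
from oxygrad.io import read_count_table, read_metadata, read_oxygen_measurements
from oxygrad.simulate import (
    ArchetypeSpec,
    SimulationConfig,
    sample_reads,
    simulate_community,
    simulate_dataset,
    simulate_oxygen_profiles,
    write_fixture,
)


def test_archetype_validation():
    with pytest.raises(ValueError, match="unknown archetype"):
        ArchetypeSpec("weird", n_otus=5)
    with pytest.raises(ValueError, match="effect_size"):
        ArchetypeSpec("threshold_responder", n_otus=5, effect_size=0.0)
    ArchetypeSpec("non_responder", n_otus=5, effect_size=0.0)  # allowed


def test_config_validation():
    with pytest.raises(ValueError, match="penetration"):
        SimulationConfig(penetration_depth_range=(10.0, 300.0))
    with pytest.raises(ValueError, match="anoxic threshold"):
        SimulationConfig(surface_o2_range=(4.0, 5.0))


def test_noiseless_measurements_on_curve():
    cfg = SimulationConfig(n_cores=3, o2_noise_sd=0.0)
    ms, profiles = simulate_oxygen_profiles(cfg, np.random.default_rng(0))
    for core_id, m in ms.items():
        np.testing.assert_allclose(
            m.concentrations, profiles[core_id].o2_at(m.depths), rtol=1e-12
        )
        assert (m.concentrations >= cfg.detection_limit).all()


def test_crossings_within_configured_range():
    cfg = SimulationConfig(n_cores=1000, depths_per_core=2)
    _, profiles = simulate_oxygen_profiles(cfg, np.random.default_rng(1))
    crossings = np.array([p.crossing_depth for p in profiles.values()])
    assert crossings.min() >= 10.0 and crossings.max() <= 116.0
    # the crossing really is where the true profile hits the threshold
    for p in list(profiles.values())[:20]:
        assert p.o2_at(p.crossing_depth) == pytest.approx(cfg.anoxic_threshold)


def test_oxygen_determinism():
    cfg = SimulationConfig(n_cores=4)
    a, _ = simulate_oxygen_profiles(cfg, np.random.default_rng(9))
    b, _ = simulate_oxygen_profiles(cfg, np.random.default_rng(9))
    for core in a:
        np.testing.assert_array_equal(a[core].concentrations, b[core].concentrations)


def test_latent_composition_closure(small_sim_config):
    _, profiles = simulate_oxygen_profiles(small_sim_config, np.random.default_rng(2))
    _, truth = simulate_community(small_sim_config, profiles, np.random.default_rng(3))
    np.testing.assert_allclose(truth.latent.sum(axis=0), 1.0, atol=1e-12)
    assert (truth.latent.to_numpy() > 0).all()


def test_null_design_exchangeable_categories():
    """All effects zero: mean CLR of a block is statistically equal
    between extreme categories (two-sample t on a null generator)."""
    from scipy.stats import ttest_ind

    design = {"Null": [ArchetypeSpec("non_responder", n_otus=30)]}
    cfg = SimulationConfig(n_cores=8, depths_per_core=14, class_design=design)
    rejections = 0
    n_runs = 20
    for seed in range(n_runs):
        ss = np.random.SeedSequence(seed)
        r1, r2 = (np.random.default_rng(s) for s in ss.spawn(2))
        _, profiles = simulate_oxygen_profiles(cfg, r1)
        _, truth = simulate_community(cfg, profiles, r2)
        cats = truth.samples["true_category"]
        hi = truth.latent.loc[:, (cats <= 2).to_numpy()]
        lo = truth.latent.loc[:, (cats == 7).to_numpy()]
        if hi.shape[1] < 3 or lo.shape[1] < 3:
            continue
        mean_clr_hi = np.log(hi).mean(axis=0)
        mean_clr_lo = np.log(lo).mean(axis=0)
        _, p = ttest_ind(mean_clr_hi, mean_clr_lo)
        rejections += p < 0.01
    assert rejections <= max(2, int(0.2 * n_runs))


def test_threshold_responders_more_abundant_when_oxic():
    """Large-effect threshold responders: category-1 mean proportion
    exceeds category-7 mean proportion in nearly every seed."""
    design = {
        "T": [ArchetypeSpec("threshold_responder", n_otus=10, effect_size=2.0)],
        "N": [ArchetypeSpec("uniform_noise", n_otus=40)],
    }
    cfg = SimulationConfig(n_cores=6, depths_per_core=10, class_design=design)
    wins = trials = 0
    for seed in range(25):
        ss = np.random.SeedSequence(1000 + seed)
        r1, r2 = (np.random.default_rng(s) for s in ss.spawn(2))
        _, profiles = simulate_oxygen_profiles(cfg, r1)
        _, truth = simulate_community(cfg, profiles, r2)
        cats = truth.samples["true_category"]
        if (cats == 1).sum() < 2 or (cats == 7).sum() < 2:
            continue
        responders = truth.otus.index[truth.otus["archetype"] == "threshold_responder"]
        p1 = truth.latent.loc[responders, (cats == 1).to_numpy()].mean(axis=1)
        p7 = truth.latent.loc[responders, (cats == 7).to_numpy()].mean(axis=1)
        trials += 1
        wins += (p1.mean() > p7.mean())
    assert trials >= 15
    assert wins == trials


def test_multinomial_expected_counts(rng):
    """Empirical mean count tracks depth x proportion (multinomial)."""
    design = {"N": [ArchetypeSpec("uniform_noise", n_otus=5)]}
    cfg = SimulationConfig(
        n_cores=1, depths_per_core=1, class_design=design,
        low_depth_sample_fraction=0.0, singleton_rate=0.0,
        read_depth_log_sd=1e-9, read_depth_log_mean=float(np.log(5000)),
    )
    probs = np.array([0.5, 0.2, 0.15, 0.1, 0.05])
    latent = pd.DataFrame(
        np.tile(probs[:, None], (1, 400)),
        index=[f"o{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(400)],
    )
    table = sample_reads(latent, cfg, rng)
    emp = table.counts.mean(axis=1).to_numpy()
    expected = probs * 5000
    se = np.sqrt(5000 * probs * (1 - probs) / 400)
    assert (np.abs(emp - expected) <= 2.5 * se).all()


def test_forced_low_depth_count_exact(rng):
    design = {"N": [ArchetypeSpec("uniform_noise", n_otus=20)]}
    cfg = SimulationConfig(
        n_cores=5, depths_per_core=10, class_design=design,
        low_depth_sample_fraction=0.1, singleton_rate=0.0,
    )
    latent = pd.DataFrame(
        np.full((20, 50), 1 / 20),
        index=[f"o{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(50)],
    )
    table = sample_reads(latent, cfg, rng)
    assert (table.sample_totals() < 1000).sum() == 5


def test_read_sampling_determinism(small_sim_config):
    a = simulate_dataset(small_sim_config, seed=7)
    b = simulate_dataset(small_sim_config, seed=7)
    pd.testing.assert_frame_equal(a.table.counts, b.table.counts)
    c = simulate_dataset(small_sim_config, seed=8)
    assert not a.table.counts.equals(c.table.counts)


def test_singleton_injection_bookkeeping(default_dataset):
    ds = default_dataset
    injected = ds.truth.otus.index[ds.truth.otus["archetype"] == "singleton"]
    assert len(injected) == 10  # 2% of 500
    assert (ds.table.counts.loc[injected].sum(axis=1) == 1).all()
    kept, _ = drop_singletons(ds.table)
    assert set(injected).isdisjoint(kept.otu_ids)


def test_truth_sidecar_lists_every_otu_once(default_dataset, tmp_path):
    import json

    paths = write_fixture(default_dataset, tmp_path / "fix")
    truth = json.loads(paths["truth"].read_text())
    ids = [rec["otu_id"] for rec in truth["otus"]]
    assert len(ids) == len(set(ids))
    assert set(ids) == set(default_dataset.table.otu_ids)


def test_fixture_roundtrip(default_dataset, tmp_path):
    paths = write_fixture(default_dataset, tmp_path / "fix")
    table = read_count_table(paths["counts"])
    pd.testing.assert_frame_equal(table.counts, default_dataset.table.counts)
    meta = read_metadata(paths["metadata"])
    pd.testing.assert_frame_equal(meta.records, default_dataset.metadata.records)
    o2 = read_oxygen_measurements(paths["oxygen"])
    assert set(o2) == set(default_dataset.oxygen)
    for core in o2:
        np.testing.assert_allclose(
            o2[core].concentrations, default_dataset.oxygen[core].concentrations
        )


def test_nitrate_peaks_near_transition(default_dataset):
    """The covariate rises as oxygen declines toward the threshold and
    decays with depth into anoxia."""
    s = default_dataset.truth.samples
    oxic_rich = s[s["true_o2_uM"] > 100]["nitrate_uM"].mean()
    transition = s[(s["true_o2_uM"] < 20) & (s["true_o2_uM"] > 5)]["nitrate_uM"].mean()
    assert transition > oxic_rich + 10
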