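"""theta_d, the all-pairs screen, permutation FDR and never-DA binning."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from oxygrad.io import CountTable, TaxonomyTable, RANKS
from oxygrad.coda import Composition, impute_zeros
from oxygrad.diffprop import (
    all_pairs_theta,
    covariate_screen,
    differential_pairs,
    never_da,
    permutation_fdr,
    select_da_pairs,
    theta_d,
)


def _random_comp(rng, p=20, n=16):
    raw = rng.lognormal(0, 1, size=(p, n))
    props = raw / raw.sum(axis=0)
    return Composition(
        pd.DataFrame(
            props,
            index=[f"o{i:02d}" for i in range(p)],
            columns=[f"s{j:02d}" for j in range(n)],
        )
    )


def _labels(comp, n_a):
    return pd.Series(
        ["A"] * n_a + ["B"] * (len(comp.sample_ids) - n_a), index=comp.sample_ids
    )


def test_theta_no_group_signal_is_one():
    values = np.tile([1.0, 2.0, 3.0], 2)  # identical groups
    labels = ["A"] * 3 + ["B"] * 3
    assert theta_d(values, labels) == pytest.approx(1.0)


def test_theta_boundary_half():
    """Between-group offset tuned so SS_total = 2 x SS_within -> 0.5."""
    within = np.array([-1.5, -0.5, 0.5, 1.5] * 2 + [-1.0, 1.0])  # 10 values
    ssw_half = np.sum(within**2)
    n = 10  # per group
    # SS_within = 2*ssw_half; equal groups: SS_between = n * d^2 / 2;
    # demand SS_between = SS_within  =>  d^2 = 4*ssw_half/n
    d = np.sqrt(4 * ssw_half / n)
    values = np.concatenate([within - d / 2, within + d / 2])
    labels = ["A"] * n + ["B"] * n
    assert theta_d(values, labels) == pytest.approx(0.5, abs=1e-12)


def test_theta_anova_oracle(rng):
    """theta_d equals 1 - R^2 of regressing the log-ratio on the group."""
    for _ in range(50):
        n_a, n_b = (int(v) for v in rng.integers(3, 12, size=2))
        offset = rng.normal(0, 2)
        values = rng.normal(0, 1, n_a + n_b) + np.r_[np.zeros(n_a), np.full(n_b, offset)]
        labels = ["A"] * n_a + ["B"] * n_b
        indicator = np.r_[np.zeros(n_a), np.ones(n_b)]
        r = linregress(indicator, values).rvalue
        assert theta_d(values, labels) == pytest.approx(1 - r**2, abs=1e-12)


def test_theta_degenerate_total_ss():
    assert theta_d(np.zeros(8), ["A"] * 4 + ["B"] * 4) == 1.0


def test_theta_small_group_errors():
    with pytest.raises(ValueError, match="fewer than 2"):
        theta_d([1.0, 2.0, 3.0], ["A", "B", "B"])


def test_theta_label_swap_and_reorder_invariance(rng):
    values = rng.normal(size=12)
    labels = np.array(["A"] * 5 + ["B"] * 7)
    base = theta_d(values, labels)
    swapped = np.where(labels == "A", "B", "A")
    assert theta_d(values, swapped) == pytest.approx(base, abs=1e-15)
    perm = rng.permutation(12)
    assert theta_d(values[perm], labels[perm]) == pytest.approx(base, abs=1e-12)


def test_all_pairs_matches_looped_oracle(rng):
    comp = _random_comp(rng, p=12, n=14)
    labels = _labels(comp, 6)
    pairs = all_pairs_theta(comp, labels)
    assert len(pairs) == 12 * 11 // 2
    log_props = np.log(comp.props.to_numpy())
    lab = labels.to_numpy()
    for _, row in pairs.sample(30, random_state=0).iterrows():
        i = comp.otu_ids.get_loc(row["otu_i"])
        j = comp.otu_ids.get_loc(row["otu_j"])
        expected = theta_d(log_props[i] - log_props[j], lab)
        assert row["theta_d"] == pytest.approx(expected, abs=1e-10)


def test_all_pairs_count_three():
    rng = np.random.default_rng(0)
    comp = _random_comp(rng, p=3, n=8)
    assert len(all_pairs_theta(comp, _labels(comp, 4))) == 3


def test_theta_closure_invariance(rng):
    """theta_d of a pair is unchanged by subsetting + reclosure
    (subcompositional coherence of the log-ratio)."""
    counts = rng.poisson(80, size=(10, 12)) + 1
    table = CountTable(
        pd.DataFrame(
            counts,
            index=[f"o{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(12)],
        ).astype(np.int64)
    )
    comp = impute_zeros(table)
    labels = _labels(comp, 6)
    full = all_pairs_theta(comp, labels).set_index(["otu_i", "otu_j"])["theta_d"]
    from oxygrad.coda import subcomposition

    keep = list(comp.otu_ids[:6])
    sub = all_pairs_theta(subcomposition(comp, keep), labels)
    sub = sub.set_index(["otu_i", "otu_j"])["theta_d"]
    for key, value in sub.items():
        assert value == pytest.approx(full.loc[key], abs=1e-12)


def test_permutation_fdr_properties(rng):
    comp = _random_comp(rng, p=15, n=20)
    labels = _labels(comp, 10)
    pairs = all_pairs_theta(comp, labels)
    scored = permutation_fdr(pairs, comp, labels, n_perm=30, rng=rng)
    assert ((scored["fdr"] >= 0) & (scored["fdr"] <= 1)).all()
    ordered = scored.sort_values("theta_d")
    assert (np.diff(ordered["fdr"].to_numpy()) >= -1e-12).all()


def test_permutation_fdr_strong_pair_zero(rng):
    """A pair whose theta beats every permutation gets FDR 0."""
    comp = _random_comp(rng, p=6, n=24)
    props = comp.props.copy()
    shift = np.r_[np.ones(12) * 50.0, np.ones(12)]
    props.loc["o00"] = props.loc["o00"] * shift
    props = props / props.sum(axis=0)
    comp = Composition(props)
    labels = _labels(comp, 12)
    pairs = all_pairs_theta(comp, labels)
    scored = permutation_fdr(pairs, comp, labels, n_perm=50, rng=rng)
    best = scored.sort_values("theta_d").iloc[0]
    assert {best["otu_i"], best["otu_j"]} & {"o00"}
    assert best["fdr"] == 0.0


def test_null_calibration_few_passes(rng):
    """Exchangeable groups: ~no pair passes theta < 0.5 with FDR <= 5e-4."""
    passes, total = 0, 0
    for seed in range(3):
        local = np.random.default_rng(seed)
        comp = _random_comp(local, p=25, n=30)
        labels = _labels(comp, 15)
        pairs = all_pairs_theta(comp, labels)
        scored = permutation_fdr(pairs, comp, labels, n_perm=40, rng=local)
        passes += ((scored["theta_d"] < 0.5) & (scored["fdr"] <= 5e-4)).sum()
        total += len(scored)
    assert passes / total <= 1e-3


def test_select_da_pairs_retention_count():
    pairs = pd.DataFrame(
        {
            "otu_i": [f"a{i}" for i in range(8)],
            "otu_j": [f"b{i}" for i in range(8)],
            "theta_d": np.linspace(0.05, 0.4, 8),
            "fdr": 0.0,
        }
    )
    ds = select_da_pairs(pairs)
    assert ds.counts == {"computed": 8, "pass_theta": 8, "pass_fdr": 8, "retained": 2}
    assert ds.retained["theta_d"].max() <= 0.1


def test_select_da_pairs_all_above_threshold_empty():
    pairs = pd.DataFrame(
        {"otu_i": ["a"], "otu_j": ["b"], "theta_d": [0.6], "fdr": [0.0]}
    )
    ds = select_da_pairs(pairs)
    assert ds.retained.empty and ds.counts["retained"] == 0


def test_select_da_pairs_brute_force_oracle(rng):
    pairs = pd.DataFrame(
        {
            "otu_i": [f"x{i}" for i in range(20)],
            "otu_j": [f"y{i}" for i in range(20)],
            "theta_d": rng.uniform(0, 1, 20).round(3),
            "fdr": rng.choice([0.0, 1e-5, 1e-3], 20),
        }
    )
    ds = select_da_pairs(pairs, theta_max=0.5, fdr_max=5e-4, retain_frac=0.25)
    # independent reimplementation of the three rules
    surv = [
        (t, k)
        for k, (t, f) in enumerate(zip(pairs["theta_d"], pairs["fdr"]))
        if t < 0.5 and f <= 5e-4
    ]
    n_keep = int(np.ceil(0.25 * len(surv)))
    expected = {k for _, k in sorted(surv)[:n_keep]}
    got = {
        pairs.index[
            (pairs["otu_i"] == r["otu_i"]) & (pairs["otu_j"] == r["otu_j"])
        ][0]
        for _, r in ds.retained.iterrows()
    }
    assert got == expected


def _tax_for(otus, cls="C1"):
    df = pd.DataFrame(
        {r: cls if r == "class" else "unassigned" for r in RANKS},
        index=pd.Index(otus, name="otu_id"),
    )
    return TaxonomyTable(df)


def _count_table_for(otus, samples=4):
    return CountTable(
        pd.DataFrame(
            np.ones((len(otus), samples), dtype=np.int64) * 10,
            index=otus,
            columns=[f"s{j}" for j in range(samples)],
        )
    )


def test_never_da_all_flagged_empty():
    otus = ["a", "b", "c"]
    retained = pd.DataFrame(
        {"otu_i": ["a", "b"], "otu_j": ["b", "c"], "theta_d": [0.1, 0.2], "fdr": [0.0, 0.0]}
    )
    ds = select_da_pairs(retained.assign(fdr=0.0), retain_frac=1.0, universe=otus)
    report = never_da({(1, 7): ds}, _count_table_for(otus), _tax_for(otus))
    assert report.never_da_otus == []
    assert (report.per_class["fraction"] == 0).all()


def test_never_da_no_pairs_everything():
    otus = ["a", "b", "c"]
    empty = select_da_pairs(
        pd.DataFrame({"otu_i": [], "otu_j": [], "theta_d": [], "fdr": []}),
        universe=otus,
    )
    report = never_da({(1, 7): empty}, _count_table_for(otus), _tax_for(otus))
    assert set(report.never_da_otus) == set(otus)
    assert (report.per_class["fraction"] == 1.0).all()
    assert report.read_share == 1.0


def test_never_da_universe_mismatch_errors():
    empty = select_da_pairs(
        pd.DataFrame({"otu_i": [], "otu_j": [], "theta_d": [], "fdr": []}),
        universe=["a", "b"],
    )
    with pytest.raises(ValueError, match="universe"):
        never_da({(1, 7): empty}, _count_table_for(["a", "b", "c"]), _tax_for(["a", "b", "c"]))


def test_covariate_screen_consistency_with_direct_pathway(rng):
    """Binning a covariate at the same breakpoints reproduces the direct
    category screen."""
    comp = _random_comp(rng, p=10, n=24)
    o2 = pd.Series(
        np.r_[rng.uniform(160, 300, 12), rng.uniform(0, 4.9, 12)],
        index=comp.sample_ids,
    )
    cats = pd.Series(np.where(o2 >= 5, 1, 2), index=comp.sample_ids)
    direct = differential_pairs(
        comp, cats, (1, 2), n_perm=20, rng=np.random.default_rng(7)
    )
    via_covariate = covariate_screen(
        comp, o2, breakpoints=[5.0], n_perm=20, rng=np.random.default_rng(7)
    )
    ds = via_covariate[(1, 2)]
    pd.testing.assert_frame_equal(ds.retained, direct.retained)


def test_covariate_trackers_da_against_their_own_gradient():
    """OTUs tracking a noisy nitrate-like covariate are flagged DA far
    more often when samples are binned by that covariate than by
    oxygen category."""
    from oxygrad.simulate import (
        ArchetypeSpec,
        SimulationConfig,
        sample_reads,
        simulate_community,
        simulate_oxygen_profiles,
    )

    design = {
        "Trackers": [ArchetypeSpec("covariate_tracker", n_otus=30, effect_size=2.0)],
        "Noise": [ArchetypeSpec("uniform_noise", n_otus=30)],
    }
    cfg = SimulationConfig(
        n_cores=8, depths_per_core=14, class_design=design,
        nitrate_noise_sd=8.0, singleton_rate=0.0, low_depth_sample_fraction=0.0,
    )
    ss = np.random.SeedSequence(0)
    r1, r2, r3 = (np.random.default_rng(s) for s in ss.spawn(3))
    _, profiles = simulate_oxygen_profiles(cfg, r1)
    _, truth = simulate_community(cfg, profiles, r2)
    comp = impute_zeros(sample_reads(truth.latent, cfg, r3))
    trackers = set(truth.otus.index[truth.otus["archetype"] == "covariate_tracker"])

    oxygen_screen = differential_pairs(
        comp, truth.samples["true_category"], (1, 7),
        n_perm=50, rng=np.random.default_rng(0),
    )
    rate_oxygen = len(oxygen_screen.member_otus() & trackers) / len(trackers)

    nitrate_screen = covariate_screen(
        comp, truth.samples["nitrate_uM"], breakpoints=[10.0, 22.0],
        comparisons=[(1, 3)], n_perm=50, rng=np.random.default_rng(0),
    )
    rate_nitrate = len(nitrate_screen[(1, 3)].member_otus() & trackers) / len(trackers)
    assert rate_nitrate > rate_oxygen
    assert rate_nitrate >= 0.5


def test_covariate_screen_null_duplicated_categories(rng):
    comp = _random_comp(rng, p=12, n=24)
    cov = pd.Series(rng.uniform(0, 100, 24), index=comp.sample_ids)
    out = covariate_screen(comp, cov, breakpoints=[50.0], n_perm=40, rng=rng)
    for ds in out.values():
        assert ds.counts["retained"] == 0
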