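"""Pairwise differential proportionality (theta_d) screening.

For an OTU pair (i, j) and two groups of samples, the disjointed
proportionality statistic is

    theta_d = SS_within / SS_total

computed on the per-sample log-ratio ``l = ln(x_i / x_j)``, where
``SS_within`` pools squared deviations from the group means and
``SS_total`` is squared deviation from the grand mean. It equals
``1 - R^2`` of a one-way two-group ANOVA on the log-ratio, lies in
[0, 1], and ``theta_d < 0.5`` means the total ("between-group")
log-ratio variance is at least twice the within-group variance — the
pass criterion for calling a pair differentially abundant. A degenerate
pair with ``SS_total = 0`` is defined to have ``theta_d = 1`` (no
group signal).

The screen over all C(p, 2) pairs is vectorised through per-group
moment (Gram) matrices, an FDR is attached to each pair by label
permutation, and three filters follow: theta_d below a cutoff, FDR at
most a cutoff, then retention of the fraction of surviving pairs with
lowest theta_d. OTUs present in no retained pair across the designated
category comparisons are "never differentially abundant"; their read
fractions per taxonomic class summarise which lineages track the
gradient only weakly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coda import Composition
from .io import CountTable, TaxonomyTable, aggregate_to_rank

__all__ = [
    "PAIR_COLUMNS",
    "DAPairSet",
    "NeverDAReport",
    "theta_d",
    "all_pairs_theta",
    "permutation_fdr",
    "select_da_pairs",
    "never_da",
    "covariate_screen",
    "differential_pairs",
]

PAIR_COLUMNS = ("otu_i", "otu_j", "theta_d")

#: soft cap on the number of OTUs entering the all-pairs screen; above
#: this the O(p^2) pair matrices get large enough to warrant explicit
#: opt-in.
DEFAULT_MAX_OTUS = 2000


@dataclass
class DAPairSet:
    """Retained differentially abundant pairs for one group comparison."""

    comparison: tuple
    retained: pd.DataFrame  # otu_i, otu_j, theta_d, fdr
    counts: dict[str, int]
    universe: list[str]
    group_sizes: dict = field(default_factory=dict)

    def member_otus(self) -> set[str]:
        if self.retained.empty:
            return set()
        return set(self.retained["otu_i"]) | set(self.retained["otu_j"])


@dataclass
class NeverDAReport:
    """OTUs absent from every retained pair, and the reads they carry."""

    never_da_otus: list[str]
    per_class: pd.DataFrame  # class, class_reads, never_da_reads, fraction
    n_otus: int
    otu_share: float
    read_share: float

    def to_dict(self) -> dict:
        return {
            "n_never_da_otus": self.n_otus,
            "otu_share": self.otu_share,
            "read_share": self.read_share,
            "per_class": self.per_class.to_dict(orient="records"),
        }


def theta_d(logratios, group_labels) -> float:
    """Disjointed proportionality for one log-ratio series and two groups."""
    values = np.asarray(logratios, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    ss_within = 0.0
    for g in groups:
        member = values[labels == g]
        if len(member) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        ss_within += float(np.sum((member - member.mean()) ** 2))
    ss_total = float(np.sum((values - values.mean()) ** 2))
    if ss_total == 0.0:
        return 1.0
    return min(ss_within / ss_total, 1.0)


def _pair_ss(log_mat: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Sum-of-squares matrix of l_ij = L_i - L_j over a sample subset.

    Uses SS_ij = q_i + q_j - 2 G_ij - (r_i - r_j)^2 / n with q the row
    sums of squares, r the row sums and G the Gram matrix, so the whole
    p x p matrix costs one matmul.
    """
    sub = log_mat[:, cols]
    n = sub.shape[1]
    q = np.einsum("ij,ij->i", sub, sub)
    r = sub.sum(axis=1)
    gram = sub @ sub.T
    ss = q[:, None] + q[None, :] - 2.0 * gram - (r[:, None] - r[None, :]) ** 2 / n
    np.maximum(ss, 0.0, out=ss)  # clip tiny negative round-off
    return ss


def _theta_matrix(log_mat: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    ss_within = _pair_ss(log_mat, idx_a) + _pair_ss(log_mat, idx_b)
    ss_total = _pair_ss(log_mat, np.concatenate([idx_a, idx_b]))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(ss_total > 0, ss_within / ss_total, 1.0)
    return np.minimum(theta, 1.0)


def _two_group_indices(comp: Composition, group_labels: pd.Series):
    labels = group_labels.reindex(comp.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample in the composition needs a group label")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    idx_a = np.flatnonzero((labels == groups[0]).to_numpy())
    idx_b = np.flatnonzero((labels == groups[1]).to_numpy())
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    return groups, idx_a, idx_b


def all_pairs_theta(
    comp: Composition,
    group_labels: pd.Series,
    max_otus: int = DEFAULT_MAX_OTUS,
) -> pd.DataFrame:
    """theta_d for all canonical OTU pairs (i < j by row order).

    ``group_labels`` maps every sample of the composition onto one of
    exactly two groups. Returns a DataFrame with columns
    otu_i, otu_j, theta_d.
    """
    p = len(comp.otu_ids)
    if p < 2:
        raise ValueError("need at least 2 OTUs for pairwise analysis")
    if p > max_otus:
        raise ValueError(
            f"{p} OTUs exceed the pair-screen cap of {max_otus}; "
            "pass a larger max_otus explicitly to accept the O(p^2) cost"
        )
    _, idx_a, idx_b = _two_group_indices(comp, group_labels)
    theta = _theta_matrix(comp.log_values(), idx_a, idx_b)
    iu, ju = np.triu_indices(p, k=1)
    otus = comp.otu_ids.to_numpy()
    return pd.DataFrame(
        {"otu_i": otus[iu], "otu_j": otus[ju], "theta_d": theta[iu, ju]}
    )


def permutation_fdr(
    pair_results: pd.DataFrame,
    comp: Composition,
    group_labels: pd.Series,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach a permutation-based FDR to every pair.

    For each observed theta t, FDR(t) is the permutation-mean count of
    null pairs with theta* <= t divided by the observed count of pairs
    with theta <= t. Permutations shuffle the group labels over the
    pooled samples, preserving group sizes; SS_total is permutation-
    invariant so only the within-group sums are recomputed. The FDR is
    clipped to [0, 1] and made monotone non-decreasing in theta.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    _, idx_a, idx_b = _two_group_indices(comp, group_labels)
    log_mat = comp.log_values()
    pooled = np.concatenate([idx_a, idx_b])
    n_a = len(idx_a)
    p = len(comp.otu_ids)
    iu, ju = np.triu_indices(p, k=1)

    ss_total = _pair_ss(log_mat, pooled)

    observed = pair_results["theta_d"].to_numpy()
    order = np.argsort(observed, kind="stable")
    obs_sorted = observed[order]
    n_obs_leq = np.arange(1, len(obs_sorted) + 1)

    null_counts = np.zeros(len(obs_sorted), dtype=float)
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        ss_within = _pair_ss(log_mat, perm[:n_a]) + _pair_ss(log_mat, perm[n_a:])
        with np.errstate(divide="ignore", invalid="ignore"):
            theta_star = np.where(ss_total > 0, ss_within / ss_total, 1.0)
        star = np.minimum(theta_star[iu, ju], 1.0)
        star.sort()
        null_counts += np.searchsorted(star, obs_sorted, side="right")

    fdr_sorted = (null_counts / n_perm) / n_obs_leq
    np.clip(fdr_sorted, 0.0, 1.0, out=fdr_sorted)
    fdr_sorted = np.maximum.accumulate(fdr_sorted)
    fdr = np.empty_like(fdr_sorted)
    fdr[order] = fdr_sorted
    out = pair_results.copy()
    out["fdr"] = fdr
    return out


def select_da_pairs(
    pair_results: pd.DataFrame,
    comparison: tuple = ("A", "B"),
    theta_max: float = 0.50,
    fdr_max: float = 0.0005,
    retain_frac: float = 0.25,
    universe: list[str] | None = None,
    group_sizes: dict | None = None,
) -> DAPairSet:
    """Apply the three-stage retention rule to scored pairs.

    1. keep pairs with theta_d < ``theta_max``;
    2. keep pairs with FDR <= ``fdr_max``;
    3. keep the ``ceil(retain_frac * remaining)`` pairs with lowest
       theta_d (ties broken by canonical pair order).
    """
    counts = {"computed": len(pair_results)}
    stage1 = pair_results[pair_results["theta_d"] < theta_max]
    counts["pass_theta"] = len(stage1)
    stage2 = stage1[stage1["fdr"] <= fdr_max]
    counts["pass_fdr"] = len(stage2)
    if len(stage2):
        n_keep = math.ceil(retain_frac * len(stage2))
        retained = stage2.sort_values(
            "theta_d", kind="stable"
        ).head(n_keep).sort_index()
    else:
        retained = stage2
    counts["retained"] = len(retained)
    if universe is None:
        universe = sorted(set(pair_results["otu_i"]) | set(pair_results["otu_j"]))
    return DAPairSet(
        comparison=tuple(comparison),
        retained=retained.reset_index(drop=True),
        counts=counts,
        universe=list(universe),
        group_sizes=dict(group_sizes or {}),
    )


def never_da(
    da_sets: dict[tuple, DAPairSet],
    table: CountTable,
    tax: TaxonomyTable,
    rank: str = "class",
) -> NeverDAReport:
    """OTUs in no retained pair across the designated comparisons.

    Reports, per taxon at ``rank``, the fraction of that taxon's reads
    carried by never-DA OTUs, plus dataset-level OTU and read shares.
    """
    universe = list(table.otu_ids)
    for key, ds in da_sets.items():
        if set(ds.universe) != set(universe):
            raise ValueError(f"OTU universe mismatch for comparison {key}")
    flagged: set[str] = set()
    for ds in da_sets.values():
        flagged |= ds.member_otus()
    never = [o for o in universe if o not in flagged]

    lineage = tax.lineage_for(table)[rank]
    otu_reads = table.otu_totals()
    class_reads = otu_reads.groupby(lineage.to_numpy()).sum()
    never_reads = (
        otu_reads.loc[never].groupby(lineage.loc[never].to_numpy()).sum()
        if never
        else pd.Series(dtype=float)
    )
    per_class = pd.DataFrame(
        {
            rank: class_reads.index,
            "class_reads": class_reads.to_numpy(),
            "never_da_reads": never_reads.reindex(class_reads.index).fillna(0).to_numpy(),
        }
    )
    per_class["fraction"] = per_class["never_da_reads"] / per_class["class_reads"]
    total_reads = float(otu_reads.sum())
    return NeverDAReport(
        never_da_otus=never,
        per_class=per_class,
        n_otus=len(never),
        otu_share=len(never) / len(universe) if universe else 0.0,
        read_share=float(otu_reads.loc[never].sum()) / total_reads if total_reads else 0.0,
    )


def differential_pairs(
    comp: Composition,
    categories: pd.Series,
    comparison: tuple,
    n_perm: int = 100,
    theta_max: float = 0.50,
    fdr_max: float = 0.0005,
    retain_frac: float = 0.25,
    rng: np.random.Generator | None = None,
    max_otus: int = DEFAULT_MAX_OTUS,
) -> DAPairSet:
    """Full screen for one category pair: subset samples, score all OTU
    pairs, attach permutation FDR and apply the retention rules."""
    cat_a, cat_b = comparison
    labels = categories.reindex(comp.sample_ids)
    samples = labels.index[labels.isin([cat_a, cat_b])]
    if labels.loc[samples].nunique() != 2:
        raise ValueError(f"comparison {comparison} does not yield two groups")
    sub = Composition(comp.props[samples] / comp.props[samples].sum(axis=0))
    group = labels.loc[samples]
    pairs = all_pairs_theta(sub, group, max_otus=max_otus)
    pairs = permutation_fdr(pairs, sub, group, n_perm=n_perm, rng=rng)
    sizes = group.value_counts().to_dict()
    return select_da_pairs(
        pairs,
        comparison=comparison,
        theta_max=theta_max,
        fdr_max=fdr_max,
        retain_frac=retain_frac,
        universe=list(comp.otu_ids),
        group_sizes=sizes,
    )


def covariate_screen(
    comp: Composition,
    covariate: pd.Series,
    breakpoints,
    comparisons=None,
    **kwargs,
) -> dict[tuple, DAPairSet]:
    """Run the pairwise screen against categories of another gradient.

    ``breakpoints`` are ascending concentration cut points; samples are
    binned into categories 1..len(breakpoints)+1 with category 1 the
    highest concentrations (matching the oxygen convention). The
    standard theta_d -> FDR -> retention pathway is then reused
    unchanged for every requested category comparison (default: all
    pairs of categories with at least 2 samples each).
    """
    bp = np.asarray(sorted(breakpoints), dtype=float)
    values = covariate.reindex(comp.sample_ids)
    if values.isna().any():
        raise ValueError("every sample needs a covariate value")
    n_cats = len(bp) + 1
    cats = pd.Series(
        n_cats - np.searchsorted(bp, values.to_numpy(), side="right"),
        index=values.index,
    )
    sizes = cats.value_counts()
    usable = sorted(sizes.index[sizes >= 2])
    if len(usable) < 2:
        raise ValueError("covariate breakpoints yield fewer than 2 usable categories")
    if comparisons is None:
        comparisons = list(itertools.combinations(usable, 2))
    return {
        tuple(cmp_pair): differential_pairs(comp, cats, tuple(cmp_pair), **kwargs)
        for cmp_pair in comparisons
    }
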