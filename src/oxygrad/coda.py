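"""Compositional machinery: zero imputation, CLR, variance of log-ratios.

Read counts carry only relative information — library sizes are imposed
by sample preparation and sequencing — so all downstream statistics work
on log-ratios. Zeros are replaced by a count-zero-multiplicative scheme:
for a sample with total ``N`` reads, each zero becomes
``delta = delta_factor / N`` (default factor 0.65, i.e. 65% of the
per-sample detection limit ``1/N``) and the non-zero proportions are
shrunk multiplicatively so the sample still sums to one.

Log-ratio statistics (CLR, VLR) use natural logarithms throughout;
variance ratios such as theta_d are base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr

from .io import CountTable

__all__ = [
    "Composition",
    "ClrMatrix",
    "impute_zeros",
    "clr",
    "vlr",
    "subcomposition",
    "aitchison_distance",
]

_CLOSE_TOL = 1e-9


@dataclass
class Composition:
    """Strictly positive proportions, OTUs x samples, columns sum to 1."""

    props: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.props.to_numpy()
        if (values <= 0).any():
            raise ValueError("composition entries must be strictly positive")
        colsums = values.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=_CLOSE_TOL):
            raise ValueError("composition columns must sum to 1")

    @property
    def otu_ids(self) -> pd.Index:
        return self.props.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.props.columns

    def log_values(self) -> np.ndarray:
        return np.log(self.props.to_numpy())


@dataclass
class ClrMatrix:
    """Centred log-ratio values; every sample (column) sums to 0."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        colsums = self.values.to_numpy().sum(axis=0)
        if not np.allclose(colsums, 0.0, atol=1e-6):
            raise ValueError("CLR columns must sum to 0")

    @property
    def otu_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def features(self) -> pd.DataFrame:
        """Samples x OTUs orientation for classifiers."""
        return self.values.T


def impute_zeros(table: CountTable, delta_factor: float = 0.65) -> Composition:
    """Count-zero-multiplicative replacement to a strictly positive
    composition.

    Per sample with total ``N``: zeros become ``delta_factor / N`` and
    non-zero proportions are multiplied by ``1 - n_zeros * delta`` so
    closure is preserved exactly.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.sample_ids[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"all-zero sample {bad!r}")
    props = counts / totals
    zeros = counts == 0
    delta = delta_factor / totals  # per-sample replacement value
    replaced_mass = zeros.sum(axis=0) * delta
    if (replaced_mass >= 1).any():
        bad = table.sample_ids[np.flatnonzero(replaced_mass >= 1)[0]]
        raise ValueError(
            f"sample {bad!r} has too many zeros for multiplicative "
            "replacement; filter rare OTUs or low-depth samples first"
        )
    out = props * (1.0 - replaced_mass)
    out[zeros] = np.broadcast_to(delta, counts.shape)[zeros]
    return Composition(pd.DataFrame(out, index=table.otu_ids, columns=table.sample_ids))


def clr(comp: Composition) -> ClrMatrix:
    """Centred log-ratio transform: ln x_i minus the per-sample mean ln x."""
    transformed = _skbio_clr(comp.props.to_numpy().T).T
    return ClrMatrix(pd.DataFrame(transformed, index=comp.otu_ids, columns=comp.sample_ids))


def vlr(comp: Composition, otu_i: str, otu_j: str, samples=None) -> float:
    """Sample variance (ddof=1) of ln(x_i / x_j) across samples.

    Zero for perfectly proportional pairs; invariant to closure and to
    subsetting the composition to any superset of the pair.
    """
    props = comp.props if samples is None else comp.props[list(samples)]
    if props.shape[1] < 2:
        raise ValueError("need at least 2 samples for a variance")
    logratio = np.log(props.loc[otu_i].to_numpy() / props.loc[otu_j].to_numpy())
    return float(np.var(logratio, ddof=1))


def subcomposition(comp: Composition, otu_subset) -> Composition:
    """Reclose a composition to a subset of OTUs."""
    otu_subset = list(otu_subset)
    if not otu_subset:
        raise ValueError("empty OTU subset")
    sub = comp.props.loc[otu_subset]
    return Composition(sub / sub.sum(axis=0))


def aitchison_distance(comp: Composition, sample_a: str, sample_b: str) -> float:
    """Euclidean distance between two samples in CLR coordinates."""
    log_a = np.log(comp.props[sample_a].to_numpy())
    log_b = np.log(comp.props[sample_b].to_numpy())
    clr_a = log_a - log_a.mean()
    clr_b = log_b - log_b.mean()
    return float(np.linalg.norm(clr_a - clr_b))
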