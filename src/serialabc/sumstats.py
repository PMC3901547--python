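"""Summary statistics comparing observed and simulated temporal datasets.

The default statistic vector is the standard microsatellite menu of eight
categories: per sample group the locus-averaged number of alleles (nal),
unbiased expected heterozygosity (het), allele-size variance (var) and
Garza–Williamson M (mgw); and per adjacent-in-time pair of groups the same
three diversity measures on the pooled pair (nal2/het2/var2) plus the
multilocus Weir–Cockerham F_ST (fst).  For S groups the vector has
4S + 4(S-1) entries (44 for the six-sample study design).

Two-sample pooled statistics follow the convention of treating the pair as a
single sample; F_ST is the Weir–Cockerham (1984) estimator combined over
loci as a ratio of sums.  Note the WC estimator is unbiased, not
non-negative: for identical finite samples it is slightly negative, of order
1/n.  Heterozygosity is invariant to relabelling allele sizes; the size
variance and M are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import one_sample_locus_stats, pair_locus_stats
from .dataset import SampleGroup, TemporalGenotypeDataset

__all__ = [
    "StatVector",
    "ONE_SAMPLE_CATEGORIES",
    "TWO_SAMPLE_CATEGORIES",
    "stat_layout",
    "one_sample_stats",
    "two_sample_stats",
    "stat_vector",
]

ONE_SAMPLE_CATEGORIES = ("nal", "het", "var", "mgw")
TWO_SAMPLE_CATEGORIES = ("nal2", "het2", "var2", "fst")


def stat_layout(n_groups: int) -> tuple[list[str], dict[str, np.ndarray]]:
    """Names and per-category column indices of the statistic vector."""
    names: list[str] = []
    categories: dict[str, np.ndarray] = {}
    for cat in ONE_SAMPLE_CATEGORIES:
        idx = []
        for g in range(n_groups):
            idx.append(len(names))
            names.append(f"{cat}_{g + 1}")
        categories[cat] = np.array(idx)
    for cat in TWO_SAMPLE_CATEGORIES:
        idx = []
        for g in range(n_groups - 1):
            idx.append(len(names))
            names.append(f"{cat}_{g + 1}_{g + 2}")
        categories[cat] = np.array(idx)
    return names, categories


@dataclass
class StatVector:
    """Ordered, named summary-statistic values for one dataset."""

    values: np.ndarray
    names: list[str]
    n_groups: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names must align")

    @property
    def categories(self) -> dict[str, np.ndarray]:
        return stat_layout(self.n_groups)[1]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _locus_means(per_locus: np.ndarray, what: str) -> np.ndarray:
    """Average per-locus statistics over loci, dropping all-missing loci."""
    bad = np.isnan(per_locus[:, 0])
    if bad.all():
        raise ValueError(f"no typed loci in {what}")
    if bad.any():
        warnings.warn(f"{what}: dropped {int(bad.sum())} locus/loci with no data")
    return np.nanmean(per_locus, axis=0)


def one_sample_stats(group: SampleGroup, max_allele: int | None = None) -> dict[str, float]:
    """Locus-averaged {A, He, V, M} for one sample group."""
    if max_allele is None:
        max_allele = int(group.genotypes.max(initial=0))
    per_locus = one_sample_locus_stats(group.genotypes, max_allele)
    a, he, v, m = _locus_means(per_locus, f"group dated {group.date}")
    return {"nal": a, "het": he, "var": v, "mgw": m}


def two_sample_stats(
    group1: SampleGroup, group2: SampleGroup, max_allele: int | None = None
) -> dict[str, float]:
    """Pooled {A, He, V} plus multilocus Weir–Cockerham F_ST for a pair."""
    if group1.n_loci != group2.n_loci:
        raise ValueError("groups must share the same loci")
    if max_allele is None:
        max_allele = int(max(group1.genotypes.max(initial=0), group2.genotypes.max(initial=0)))
    per_locus = pair_locus_stats(group1.genotypes, group2.genotypes, max_allele)
    a, he, v, _, _ = _locus_means(per_locus, f"pair {group1.date}/{group2.date}")
    num = np.nansum(per_locus[:, 3])
    den = np.nansum(per_locus[:, 4])
    fst = num / den if den != 0 else 0.0
    return {"nal2": a, "het2": he, "var2": v, "fst": fst}


def stat_vector(dataset: TemporalGenotypeDataset) -> StatVector:
    """The full ordered statistic vector for a temporal dataset.

    Deterministic; invariant to permuting individuals within groups.
    """
    names, _ = stat_layout(dataset.n_groups)
    max_allele = dataset.max_allele
    ones = [one_sample_stats(g, max_allele) for g in dataset.groups]
    pairs = [
        two_sample_stats(g1, g2, max_allele)
        for g1, g2 in zip(dataset.groups, dataset.groups[1:])
    ]
    values: list[float] = []
    for cat in ONE_SAMPLE_CATEGORIES:
        values.extend(d[cat] for d in ones)
    for cat in TWO_SAMPLE_CATEGORIES:
        values.extend(d[cat] for d in pairs)
    return StatVector(np.array(values), names, dataset.n_groups)


def stat_vector_from_copies(
    copies: np.ndarray, group_sizes: np.ndarray, max_allele: int
) -> np.ndarray:
    """Fast path used by reference-table simulation.

    ``copies`` is the (2*n_ind_total, n_loci) repeat-unit matrix emitted by
    the simulator, individuals contiguous by group; returns the raw statistic
    vector without building dataset objects.
    """
    n_loci = copies.shape[1]
    genos = []
    off = 0
    for n in group_sizes:
        block = copies[off : off + 2 * n]
        genos.append(np.ascontiguousarray(block.reshape(n, 2, n_loci).transpose(0, 2, 1)))
        off += 2 * n
    ones = np.empty((len(genos), 4))
    for i, g in enumerate(genos):
        ones[i] = np.nanmean(one_sample_locus_stats(g, max_allele), axis=0)
    pairs = np.empty((len(genos) - 1, 4))
    for i in range(len(genos) - 1):
        pl = pair_locus_stats(genos[i], genos[i + 1], max_allele)
        pairs[i, :3] = np.nanmean(pl[:, :3], axis=0)
        den = np.nansum(pl[:, 4])
        pairs[i, 3] = np.nansum(pl[:, 3]) / den if den != 0 else 0.0
    return np.concatenate([ones.T.ravel(), pairs.T.ravel()])
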