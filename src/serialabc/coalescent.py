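"""Serial (heterochronous) coalescent simulation of microsatellite datasets.

Gene genealogies are generated backwards in time under a piecewise-constant
diploid Ne trajectory: lineages enter the active set at their sample's
collection time (converted to fractional generations by the study clock) and
coalesce at exponential rate k(k-1)/(4N) while k lineages are active in an
epoch of size N — the continuous-time approximation to the diploid
Wright–Fisher model, which also accommodates real-valued sampling times.

Mutations follow the generalized stepwise model (GSM): Poisson numbers of
mutations per branch, each changing the repeat count by a geometrically
distributed number of units (parameter ``p_geom``; 0 gives the strict
single-step model, larger values add the multi-step component that mimics
infinite-allele behaviour).  Allele states live on a bounded ladder with
reflecting edges.  Per-locus rates are drawn from a Gamma prior scaled to a
fixed median rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from . import _kernels
from .dataset import SampleGroup, TemporalGenotypeDataset
from .scenarios import EpochTrajectory, GenerationClock, SamplingDesign

__all__ = [
    "Genealogy",
    "MutationModel",
    "simulate_genealogy",
    "apply_mutations",
    "simulate_dataset",
]

MEDIAN_MICROSAT_RATE = 6.34e-4  # study prior median, per locus per generation


def _seed32(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**32 - 1))


@dataclass
class Genealogy:
    """A coalescent tree over heterochronously sampled gene copies.

    Nodes 0..n-1 are tips in sampling order; internal nodes follow in
    coalescence-time order, so a parent always has a larger index than its
    children.  ``tip_labels`` holds (group index, individual, copy) triples.
    """

    parent: np.ndarray
    time: np.ndarray  # generations before reference
    n_tips: int
    tip_labels: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.parent.shape != self.time.shape:
            raise ValueError("parent and time must align")
        if self.parent.size != 2 * self.n_tips - 1:
            raise ValueError("a binary genealogy over n tips has 2n-1 nodes")

    @property
    def n_coalescences(self) -> int:
        return self.n_tips - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        has_parent = self.parent >= 0
        out = np.zeros_like(self.time)
        out[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return out

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time[-1])


@dataclass
class MutationModel:
    """Generalized stepwise mutation model for microsatellites.

    ``median_rate``: median per-locus per-generation rate (study prior
    median 6.34e-4); per-locus rates are median_rate * G / median(G) with
    G ~ Gamma(``rate_shape``, 1), so the configured median is exact.
    ``p_geom``: geometric step parameter in [0, 1); mean step 1/(1-p).
    ``n_states``: contiguous allele ladder size, reflecting edges.
    """

    median_rate: float = MEDIAN_MICROSAT_RATE
    p_geom: float = 0.36
    n_states: int = 40
    rate_shape: float = 0.7

    def __post_init__(self) -> None:
        if self.median_rate < 0:
            raise ValueError("mutation rate must be non-negative")
        if not 0.0 <= self.p_geom < 1.0:
            raise ValueError("p_geom must be in [0, 1)")
        if self.n_states < 2:
            raise ValueError("need at least 2 allele states")
        if self.rate_shape <= 0:
            raise ValueError("rate_shape must be positive")

    def draw_locus_rates(self, n_loci: int, rng: np.random.Generator) -> np.ndarray:
        """Per-locus rates from the Gamma prior (exact configured median)."""
        if self.median_rate == 0:
            return np.zeros(n_loci)
        g = rng.gamma(self.rate_shape, 1.0, size=n_loci)
        return self.median_rate * g / _gamma_dist.ppf(0.5, self.rate_shape)


def simulate_genealogy(
    trajectory: EpochTrajectory,
    design: SamplingDesign,
    clock: GenerationClock,
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy of all 2n gene copies in the design."""
    tip_times = design.tip_times(clock)
    if tip_times.size < 2:
        raise ValueError("need at least two gene copies")
    order = np.argsort(tip_times, kind="stable")  # kernel wants ascending times
    bnds_asc, sizes_asc = trajectory.ascending()
    _kernels.seed_numba(_seed32(rng))
    parent_s, time_s = _kernels.sim_genealogy(tip_times[order], bnds_asc, sizes_asc)
    # relabel tips back to design order (internal nodes are unaffected:
    # tips are never parents)
    n = tip_times.size
    parent = parent_s.copy()
    time = time_s.copy()
    parent[order] = parent_s[:n]
    time[order] = time_s[:n]
    labels = []
    for g, ngrp in enumerate(design.sample_sizes):
        for i in range(ngrp):
            labels.append((g, i, 0))
            labels.append((g, i, 1))
    return Genealogy(parent=parent, time=time, n_tips=n, tip_labels=labels)


def apply_mutations(
    genealogy: Genealogy,
    model: MutationModel,
    rng: np.random.Generator,
    rate: float | None = None,
) -> np.ndarray:
    """Drop GSM mutations on a genealogy; returns tip alleles in repeat units.

    The root allele starts at the ladder midpoint; ``rate`` overrides the
    model's median rate (used when per-locus rates were drawn upstream).
    """
    mu = model.median_rate if rate is None else rate
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    if genealogy.n_tips < 1:
        raise ValueError("empty genealogy")
    _kernels.seed_numba(_seed32(rng))
    tips = _kernels.drop_mutations(
        genealogy.parent, genealogy.time, genealogy.n_tips, mu, model.p_geom, model.n_states
    )
    return tips.astype(np.int16) + 1


def _copies_to_dataset(
    copies: np.ndarray, design: SamplingDesign, locus_names: list[str] | None = None
) -> TemporalGenotypeDataset:
    n_loci = copies.shape[1]
    groups = []
    off = 0
    for date, n in zip(design.sample_dates, design.sample_sizes):
        block = copies[off : off + 2 * n]
        geno = np.ascontiguousarray(block.reshape(n, 2, n_loci).transpose(0, 2, 1))
        groups.append(SampleGroup(date=date, genotypes=geno))
        off += 2 * n
    return TemporalGenotypeDataset(groups=groups, locus_names=locus_names or [])


def simulate_dataset(
    trajectory: EpochTrajectory,
    design: SamplingDesign,
    clock: GenerationClock,
    mutation: MutationModel,
    rng: np.random.Generator,
    locus_rates: np.ndarray | None = None,
) -> TemporalGenotypeDataset:
    """Simulate a full temporal dataset: one independent genealogy per locus,
    two gene copies per individual, per-locus mutation rates from the prior
    (or supplied).  Deterministic under a seeded ``rng``."""
    tip_times = design.tip_times(clock)
    if locus_rates is None:
        locus_rates = mutation.draw_locus_rates(design.n_loci, rng)
    locus_rates = np.asarray(locus_rates, dtype=float)
    if locus_rates.shape != (design.n_loci,):
        raise ValueError("need one mutation rate per locus")
    bnds_asc, sizes_asc = trajectory.ascending()
    copies = simulate_copies_raw(
        tip_times, bnds_asc, sizes_asc, locus_rates, mutation, _seed32(rng)
    )
    return _copies_to_dataset(copies, design)


def simulate_copies_raw(
    tip_times: np.ndarray,
    bnds_asc: np.ndarray,
    sizes_asc: np.ndarray,
    locus_rates: np.ndarray,
    mutation: MutationModel,
    seed: int,
) -> np.ndarray:
    """Kernel wrapper returning the (2n, L) repeat-unit matrix in input tip
    order (the kernel itself consumes tips sorted by sampling time)."""
    order = np.argsort(tip_times, kind="stable")
    sorted_copies = _kernels.simulate_copies(
        seed, tip_times[order], bnds_asc, sizes_asc,
        np.asarray(locus_rates, dtype=float), mutation.p_geom, mutation.n_states,
    )
    out = np.empty_like(sorted_copies)
    out[order] = sorted_copies
    return out
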