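"""Numba kernels: serial coalescent, stepwise-mutation drop, summary stats.

These are the inner loops of ABC reference-table simulation.  Everything here
operates on plain arrays; the friendly object layer lives in `coalescent.py`
and `sumstats.py`.

Conventions
-----------
* Times are real-valued generations before the reference date (present = 0).
* A genealogy over n tips is stored as parent/time arrays of length 2n-1:
  tips 0..n-1, internal nodes n..2n-2 created in coalescence-time order, so
  every parent has a larger index than its children.
* Allele states are integers 0..n_states-1; repeat units on output are
  state + 1 (always positive).  Missing genotypes are coded 0.
* Epoch input is ascending: bnds_asc[i] is the i-th boundary going backwards
  in time and sizes_asc[0] is the most recent epoch's diploid Ne.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "sim_genealogy",
    "drop_mutations",
    "simulate_copies",
    "one_sample_locus_stats",
    "pair_locus_stats",
    "seed_numba",
]


@njit(cache=True)
def seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True)
def sim_genealogy(tip_times, bnds_asc, sizes_asc):
    """Heterochronous coalescent with piecewise-constant diploid Ne.

    Backwards in time: lineages enter at their tips' sampling times; while k
    lineages are active in an epoch of size N, the next coalescence is
    exponential with rate k(k-1)/(4N) per generation, truncated at epoch
    boundaries and lineage-entry times.

    tip_times must be sorted ascending.  Returns (parent, time) arrays of
    length 2n-1; the root's parent is -1.  Uses numba's global RNG: seed via
    `seed_numba` before calling.
    """
    n = tip_times.shape[0]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    for i in range(n):
        time[i] = tip_times[i]

    active = np.empty(n, dtype=np.int64)
    k = 0
    next_tip = 0
    next_node = n
    t = tip_times[0]
    n_bnd = bnds_asc.shape[0]
    while next_node < n_nodes:
        while next_tip < n and tip_times[next_tip] <= t:
            active[k] = next_tip
            k += 1
            next_tip += 1
        # next horizon: first tip entry or epoch boundary beyond t
        horizon = np.inf
        if next_tip < n:
            horizon = tip_times[next_tip]
        e = np.searchsorted(bnds_asc, t, side="right")
        if e < n_bnd and bnds_asc[e] < horizon:
            horizon = bnds_asc[e]
        if k >= 2:
            rate = k * (k - 1) / (4.0 * sizes_asc[e])
            wait = np.random.exponential(1.0 / rate)
            if t + wait < horizon:
                t = t + wait
                i = np.random.randint(0, k)
                j = np.random.randint(0, k - 1)
                if j >= i:
                    j += 1
                a, b = active[i], active[j]
                parent[a] = next_node
                parent[b] = next_node
                time[next_node] = t
                # replace i with the new node, swap-remove j
                active[i] = next_node
                active[j] = active[k - 1]
                k -= 1
                next_node += 1
                continue
        t = horizon
    return parent, time


@njit(cache=True)
def _reflect(a, n_states):
    hi = n_states - 1
    while a < 0 or a > hi:
        if a < 0:
            a = -a
        else:
            a = 2 * hi - a
    return a


@njit(cache=True)
def drop_mutations(parent, time, n_tips, mu, p_geom, n_states):
    """Generalized stepwise mutations along a genealogy; tip states returned.

    Branch mutation counts are Poisson(mu * branch length); each mutation
    steps the repeat count by +-k with k ~ Geometric (P(k) = (1-p) p^(k-1),
    so p_geom = 0 is the strict single-step model); out-of-range states are
    reflected.  The root starts at the range midpoint.
    """
    n_nodes = parent.shape[0]
    state = np.empty(n_nodes, dtype=np.int16)
    state[n_nodes - 1] = (n_states - 1) // 2
    for node in range(n_nodes - 2, -1, -1):
        pa = parent[node]
        bl = time[pa] - time[node]
        a = int(state[pa])
        n_mut = np.random.poisson(mu * bl)
        for _ in range(n_mut):
            if p_geom > 0.0:
                step = np.random.geometric(1.0 - p_geom)
            else:
                step = 1
            if np.random.random() < 0.5:
                step = -step
            a = _reflect(a + step, n_states)
        state[node] = np.int16(a)
    return state[:n_tips]


@njit(cache=True)
def simulate_copies(seed, tip_times, bnds_asc, sizes_asc, mus, p_geom, n_states):
    """Simulate all loci of one dataset: (2*n_ind, n_loci) repeat units.

    One independent genealogy per locus over the same tips; per-locus rates
    in ``mus``.  Deterministic for a given seed.
    """
    np.random.seed(seed)
    n_copies = tip_times.shape[0]
    n_loci = mus.shape[0]
    out = np.empty((n_copies, n_loci), dtype=np.int16)
    for l in range(n_loci):
        parent, time = sim_genealogy(tip_times, bnds_asc, sizes_asc)
        tips = drop_mutations(parent, time, n_copies, mus[l], p_geom, n_states)
        for i in range(n_copies):
            out[i, l] = tips[i] + 1  # repeat units are positive
    return out


# -- summary statistics ------------------------------------------------------

@njit(cache=True)
def one_sample_locus_stats(geno, max_allele):
    """Per-locus (A, He, V, M) for one sample group.

    geno: (n_ind, n_loci, 2) int16, 0 = missing (an individual missing either
    allele is excluded at that locus).  Returns (n_loci, 4); NaN row when a
    locus has no typed individuals.
    A  = number of distinct alleles
    He = unbiased expected heterozygosity, (2n/(2n-1)) (1 - sum p_i^2)
    V  = unbiased variance of allele size over the 2n gene copies
    M  = Garza-Williamson ratio A / (allelic range + 1)
    """
    n_ind, n_loci = geno.shape[0], geno.shape[1]
    out = np.full((n_loci, 4), np.nan)
    counts = np.zeros(max_allele + 1, dtype=np.int64)
    for l in range(n_loci):
        counts[:] = 0
        n = 0
        s = 0.0
        s2 = 0.0
        for i in range(n_ind):
            a1 = geno[i, l, 0]
            a2 = geno[i, l, 1]
            if a1 == 0 or a2 == 0:
                continue
            counts[a1] += 1
            counts[a2] += 1
            n += 1
            s += a1 + a2
            s2 += a1 * a1 + a2 * a2
        if n == 0:
            continue
        m = 2 * n
        A = 0
        lo = max_allele + 1
        hi = 0
        sum_p2 = 0.0
        for a in range(1, max_allele + 1):
            c = counts[a]
            if c > 0:
                A += 1
                if a < lo:
                    lo = a
                if a > hi:
                    hi = a
                sum_p2 += (c / m) ** 2
        he = (m / (m - 1.0)) * (1.0 - sum_p2) if m > 1 else 0.0
        v = (s2 - s * s / m) / (m - 1.0) if m > 1 else 0.0
        out[l, 0] = A
        out[l, 1] = he
        out[l, 2] = v
        out[l, 3] = A / (hi - lo + 1.0)
    return out


@njit(cache=True)
def pair_locus_stats(geno1, geno2, max_allele):
    """Per-locus pooled (A, He, V) and Weir-Cockerham variance components
    for a pair of sample groups.

    Returns (n_loci, 5): pooled A, He, V over the two groups treated as one
    sample, then the WC84 theta numerator (sum of a over alleles) and
    denominator (sum of a+b+c); the multilocus estimator is the
    ratio of sums over loci.  NaN rows where either group lacks data.
    """
    n_loci = geno1.shape[1]
    out = np.full((n_loci, 5), np.nan)
    c1 = np.zeros(max_allele + 1, dtype=np.int64)
    c2 = np.zeros(max_allele + 1, dtype=np.int64)
    h1 = np.zeros(max_allele + 1, dtype=np.int64)
    h2 = np.zeros(max_allele + 1, dtype=np.int64)
    for l in range(n_loci):
        c1[:] = 0
        c2[:] = 0
        h1[:] = 0
        h2[:] = 0
        n1 = 0
        n2 = 0
        s = 0.0
        s2 = 0.0
        for i in range(geno1.shape[0]):
            a1 = geno1[i, l, 0]
            a2 = geno1[i, l, 1]
            if a1 == 0 or a2 == 0:
                continue
            c1[a1] += 1
            c1[a2] += 1
            n1 += 1
            s += a1 + a2
            s2 += a1 * a1 + a2 * a2
            if a1 != a2:
                h1[a1] += 1
                h1[a2] += 1
        for i in range(geno2.shape[0]):
            a1 = geno2[i, l, 0]
            a2 = geno2[i, l, 1]
            if a1 == 0 or a2 == 0:
                continue
            c2[a1] += 1
            c2[a2] += 1
            n2 += 1
            s += a1 + a2
            s2 += a1 * a1 + a2 * a2
            if a1 != a2:
                h2[a1] += 1
                h2[a2] += 1
        if n1 == 0 or n2 == 0:
            continue
        m = 2 * (n1 + n2)
        A = 0
        sum_p2 = 0.0
        wc_num = 0.0
        wc_den = 0.0
        nbar = 0.5 * (n1 + n2)
        nc = (n1 + n2) - (n1 * n1 + n2 * n2) / (n1 + n2)
        for a in range(1, max_allele + 1):
            ctot = c1[a] + c2[a]
            if ctot == 0:
                continue
            A += 1
            sum_p2 += (ctot / m) ** 2
            p1 = c1[a] / (2.0 * n1)
            p2 = c2[a] / (2.0 * n2)
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2p = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # r-1 = 1
            hbar = (h1[a] + h2[a]) / (n1 + n2)
            inner = pbar * (1.0 - pbar) - 0.5 * s2p - 0.25 * hbar
            wa = (nbar / nc) * (s2p - inner / (nbar - 1.0))
            wb = (nbar / (nbar - 1.0)) * (
                pbar * (1.0 - pbar) - 0.5 * s2p - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
            )
            wc = 0.5 * hbar
            wc_num += wa
            wc_den += wa + wb + wc
        he = (m / (m - 1.0)) * (1.0 - sum_p2)
        v = (s2 - s * s / m) / (m - 1.0)
        out[l, 0] = A
        out[l, 1] = he
        out[l, 2] = v
        out[l, 3] = wc_num
        out[l, 4] = wc_den
    return out
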