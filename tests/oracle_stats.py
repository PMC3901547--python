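"""Independent brute-force summary statistics for oracle tests.

Direct frequency counting with python dicts; shares no code with the
package implementation.
"""

from collections import Counter


def _typed(genotypes_locus):
    return [(a, b) for a, b in genotypes_locus if a != 0 and b != 0]


def one_sample(group_genotypes, locus):
    """(A, He, V, M) for one locus of one group; None if no data.

    group_genotypes: list over individuals of list over loci of (a1, a2).
    """
    pairs = _typed([ind[locus] for ind in group_genotypes])
    if not pairs:
        return None
    copies = [a for pair in pairs for a in pair]
    m = len(copies)
    counts = Counter(copies)
    a_count = len(counts)
    sum_p2 = sum((c / m) ** 2 for c in counts.values())
    he = (m / (m - 1)) * (1 - sum_p2) if m > 1 else 0.0
    mean = sum(copies) / m
    v = sum((x - mean) ** 2 for x in copies) / (m - 1) if m > 1 else 0.0
    mgw = a_count / (max(copies) - min(copies) + 1)
    return a_count, he, v, mgw


def wc_fst_locus(g1, g2, locus):
    """Weir-Cockerham (1984) per-locus variance components (a_sum, abc_sum)
    for two populations; None if either lacks data."""
    p1 = _typed([ind[locus] for ind in g1])
    p2 = _typed([ind[locus] for ind in g2])
    if not p1 or not p2:
        return None
    n1, n2 = len(p1), len(p2)
    nbar = (n1 + n2) / 2
    nc = (n1 + n2) - (n1 * n1 + n2 * n2) / (n1 + n2)
    alleles = set(a for pair in p1 + p2 for a in pair)
    c1 = Counter(a for pair in p1 for a in pair)
    c2 = Counter(a for pair in p2 for a in pair)
    h1 = Counter()
    h2 = Counter()
    for a, b in p1:
        if a != b:
            h1[a] += 1
            h1[b] += 1
    for a, b in p2:
        if a != b:
            h2[a] += 1
            h2[b] += 1
    a_sum = abc_sum = 0.0
    for al in alleles:
        f1 = c1[al] / (2 * n1)
        f2 = c2[al] / (2 * n2)
        pbar = (n1 * f1 + n2 * f2) / (n1 + n2)
        s2 = (n1 * (f1 - pbar) ** 2 + n2 * (f2 - pbar) ** 2) / nbar
        hbar = (h1[al] + h2[al]) / (n1 + n2)
        inner = pbar * (1 - pbar) - s2 / 2 - hbar / 4
        wa = (nbar / nc) * (s2 - inner / (nbar - 1))
        wb = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        wc = hbar / 2
        a_sum += wa
        abc_sum += wa + wb + wc
    return a_sum, abc_sum


def dataset_to_lists(dataset):
    out = []
    for g in dataset.groups:
        out.append([[tuple(g.genotypes[i, l]) for l in range(g.n_loci)] for i in range(g.n_individuals)])
    return out


def mean_over_loci(values):
    vals = [v for v in values if v is not None]
    cols = list(zip(*vals))
    return [sum(c) / len(c) for c in cols]


def full_vector(dataset):
    """Brute-force equivalent of the package's stat_vector, same ordering."""
    lists = dataset_to_lists(dataset)
    n_loci = dataset.n_loci
    ones = [mean_over_loci([one_sample(g, l) for l in range(n_loci)]) for g in lists]
    out = []
    for stat in range(4):
        out.extend(g[stat] for g in ones)
    pair_pool = []
    fsts = []
    for g1, g2 in zip(lists, lists[1:]):
        pooled = g1 + g2
        pair_pool.append(mean_over_loci([one_sample(pooled, l) for l in range(n_loci)]))
        comps = [wc_fst_locus(g1, g2, l) for l in range(n_loci)]
        comps = [c for c in comps if c is not None]
        num = sum(c[0] for c in comps)
        den = sum(c[1] for c in comps)
        fsts.append(num / den if den != 0 else 0.0)
    for stat in range(3):
        out.extend(p[stat] for p in pair_pool)
    out.extend(fsts)
    return out
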