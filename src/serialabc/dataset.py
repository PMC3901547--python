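"""Temporal diploid microsatellite genotype container."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampleGroup", "TemporalGenotypeDataset"]


@dataclass
class SampleGroup:
    """One dated collection of diploid genotypes.

    genotypes: (n_individuals, n_loci, 2) integer allele sizes in repeat
    units; 0 codes a missing allele.
    """

    date: dt.date
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 3 or g.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_individuals, n_loci, 2)")
        if np.any(g < 0):
            raise ValueError("allele sizes must be positive (0 = missing)")
        self.genotypes = g.astype(np.int16)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class TemporalGenotypeDataset:
    """Diploid allele-size genotypes for L loci in S dated sample groups."""

    groups: list[SampleGroup]
    locus_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("dataset needs at least one sample group")
        n_loci = {g.n_loci for g in self.groups}
        if len(n_loci) != 1:
            raise ValueError("all groups must share the same loci")
        if not self.locus_names:
            self.locus_names = [f"locus_{i + 1}" for i in range(self.groups[0].n_loci)]
        if len(self.locus_names) != self.groups[0].n_loci:
            raise ValueError("locus_names length must match the genotype matrices")
        if any(g1.date > g2.date for g1, g2 in zip(self.groups, self.groups[1:])):
            raise ValueError("groups must be in chronological order")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_loci(self) -> int:
        return self.groups[0].n_loci

    @property
    def max_allele(self) -> int:
        return int(max(g.genotypes.max(initial=0) for g in self.groups))

    def equal_to(self, other: "TemporalGenotypeDataset") -> bool:
        return (
            self.locus_names == other.locus_names
            and len(self.groups) == len(other.groups)
            and all(
                a.date == b.date and np.array_equal(a.genotypes, b.genotypes)
                for a, b in zip(self.groups, other.groups)
            )
        )
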