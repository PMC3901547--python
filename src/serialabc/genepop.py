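"""GenePop reading/writing and the study's missingness filter.

POP blocks map to temporal sample groups in file order; sampling dates are
carried in the block's first individual label when written by this package
(``<ISO-date>_<index>``) and may be supplied explicitly when reading files
from elsewhere.  Alleles are repeat units internally (1-based positive
integers, 0 = missing) and 3-digit codes on disk (2-digit input accepted).
"""

from __future__ import annotations

import datetime as dt
import re
import warnings
from pathlib import Path

import numpy as np
from Bio.PopGen import GenePop as _BioGenePop

from .dataset import SampleGroup, TemporalGenotypeDataset

__all__ = ["read_genepop", "write_genepop", "filter_missingness"]

_DATE_RE = re.compile(r"(\d{4}-\d{2}-\d{2})")


def write_genepop(dataset: TemporalGenotypeDataset, path, title: str | None = None) -> None:
    """Write a dataset as GenePop (one POP block per temporal sample,
    3-digit allele coding, missing = 000000)."""
    lines = [title or "serialabc temporal microsatellite dataset"]
    lines.extend(dataset.locus_names)
    for group in dataset.groups:
        lines.append("POP")
        for i in range(group.n_individuals):
            alleles = [
                f"{group.genotypes[i, l, 0]:03d}{group.genotypes[i, l, 1]:03d}"
                for l in range(group.n_loci)
            ]
            lines.append(f"{group.date.isoformat()}_{i + 1} , " + " ".join(alleles))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path, dates: list[dt.date] | None = None) -> TemporalGenotypeDataset:
    """Parse a GenePop file into a temporal dataset.

    Group dates come from ``dates`` (one per POP block) or, failing that,
    from ISO dates embedded in the first individual label of each block;
    blocks without either are dated by index from an arbitrary epoch so the
    container's chronology invariant still holds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with open(path) as fh:
            record = _BioGenePop.read(fh)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed GenePop file: {exc}") from exc
    if not record.populations:
        raise ValueError(f"{path}: no POP blocks found")
    if dates is not None and len(dates) != len(record.populations):
        raise ValueError("need one date per POP block")
    n_loci = len(record.loci_list)
    groups = []
    for b, block in enumerate(record.populations):
        geno = np.zeros((len(block), n_loci, 2), dtype=np.int16)
        label0 = str(block[0][0])
        for i, (_, genotypes) in enumerate(block):
            if len(genotypes) != n_loci:
                raise ValueError(
                    f"{path}: POP {b + 1}, individual {i + 1}: expected {n_loci} loci"
                )
            for l, g in enumerate(genotypes):
                if g is None:
                    continue
                a1, a2 = (g[0] or 0), (g[1] if len(g) > 1 and g[1] is not None else 0)
                geno[i, l, 0] = a1
                geno[i, l, 1] = a2
        if dates is not None:
            date = dates[b]
        else:
            m = _DATE_RE.search(label0)
            date = dt.date.fromisoformat(m.group(1)) if m else dt.date(2000, 1, 1) + dt.timedelta(days=b)
        groups.append(SampleGroup(date=date, genotypes=geno))
    return TemporalGenotypeDataset(groups=groups, locus_names=list(record.loci_list))


def filter_missingness(
    dataset: TemporalGenotypeDataset, max_failed_loci: int = 2
) -> tuple[TemporalGenotypeDataset, dict]:
    """Drop individuals with >= ``max_failed_loci`` missing loci.

    Mirrors the study's exclusion rule (an individual failing genotyping at
    two of the 13 loci was excluded).  Returns the filtered dataset and a
    per-group report of removals; a group losing all its individuals is
    dropped with a warning.
    """
    if max_failed_loci < 1:
        raise ValueError("max_failed_loci must be >= 1")
    groups = []
    report: dict = {"removed_per_group": [], "dropped_groups": []}
    for g in dataset.groups:
        missing = (g.genotypes == 0).any(axis=2).sum(axis=1)  # failed loci per individual
        keep = missing < max_failed_loci
        report["removed_per_group"].append(int((~keep).sum()))
        if not keep.any():
            warnings.warn(f"group dated {g.date} lost all individuals; dropped")
            report["dropped_groups"].append(g.date.isoformat())
            continue
        groups.append(SampleGroup(date=g.date, genotypes=g.genotypes[keep]))
    if not groups:
        raise ValueError("all groups were emptied by the missingness filter")
    return TemporalGenotypeDataset(groups=groups, locus_names=list(dataset.locus_names)), report
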