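"""Genome model for a fragmented draft assembly.

The mapping analysis works in two coordinate systems: the *chromosome*
coordinates in which inheritance actually happens, and the *scaffold*
coordinates of the draft assembly in which variants are reported (VCF).
Scaffolds tile their source chromosome without overlap and may be
assembled in either orientation, so a variant's scaffold position can run
antiparallel to its chromosome position.  ``GenomeMap`` holds both systems
and converts between them.

Chromosome coordinates are 0-based internally; scaffold coordinates follow
the VCF convention (1-based).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Chromosome", "Scaffold", "GenomeMap", "random_genome"]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_morgans: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"chromosome {self.name}: length must be >= 1 bp")
        if self.length_morgans < 0:
            raise ValueError(f"chromosome {self.name}: genetic length must be >= 0")


@dataclass(frozen=True)
class Scaffold:
    name: str
    chrom: str
    start: int  # 0-based inclusive, chromosome coordinates
    end: int    # exclusive
    orientation: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"scaffold {self.name}: length must be >= 1")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"scaffold {self.name}: orientation must be '+' or '-'")

    def to_scaffold_pos(self, chrom_pos: int) -> int:
        """Chromosome position (0-based) -> scaffold position (1-based)."""
        if not self.start <= chrom_pos < self.end:
            raise ValueError(f"position {chrom_pos} outside scaffold {self.name}")
        if self.orientation == "+":
            return chrom_pos - self.start + 1
        return self.end - chrom_pos

    def to_chrom_pos(self, scaffold_pos: int) -> int:
        """Scaffold position (1-based) -> chromosome position (0-based)."""
        if not 1 <= scaffold_pos <= self.length:
            raise ValueError(f"position {scaffold_pos} outside scaffold {self.name}")
        if self.orientation == "+":
            return self.start + scaffold_pos - 1
        return self.end - scaffold_pos


@dataclass
class GenomeMap:
    """Chromosomes, their scaffold tiling, and the causal locus.

    ``causal_chrom``/``causal_pos`` give the location of the semidominant
    mutation in chromosome coordinates; :meth:`causal_scaffold` reports it
    in assembly coordinates, which is what every downstream file uses.
    """

    chromosomes: list[Chromosome]
    scaffolds: list[Scaffold]
    causal_chrom: str
    causal_pos: int  # 0-based chromosome coordinate
    min_scaffold_len: int = 5000
    variant_density: float = 0.0  # background variants per bp (informational)
    _by_chrom: dict = field(init=False, repr=False, default_factory=dict)
    _by_name: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._by_name = {s.name: s for s in self.scaffolds}
        if len(self._by_name) != len(self.scaffolds):
            raise ValueError("duplicate scaffold names")
        chrom_names = {c.name for c in self.chromosomes}
        for c in self.chromosomes:
            scafs = sorted(
                (s for s in self.scaffolds if s.chrom == c.name), key=lambda s: s.start
            )
            pos = 0
            for s in scafs:
                if s.start != pos:
                    raise ValueError(
                        f"scaffolds do not tile chromosome {c.name} (gap/overlap at {pos})"
                    )
                pos = s.end
            if scafs and pos != c.length_bp:
                raise ValueError(f"scaffolds do not cover chromosome {c.name}")
            self._by_chrom[c.name] = scafs
        if self.causal_chrom not in chrom_names:
            raise ValueError(f"causal chromosome {self.causal_chrom} unknown")
        self.scaffold_of(self.causal_chrom, self.causal_pos)  # must exist

    # -- lookups -----------------------------------------------------------
    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def scaffold(self, name: str) -> Scaffold:
        return self._by_name[name]

    def scaffold_of(self, chrom: str, pos: int) -> Scaffold:
        scafs = self._by_chrom[chrom]
        ends = np.array([s.end for s in scafs])
        i = int(np.searchsorted(ends, pos, side="right"))
        if i >= len(scafs) or not scafs[i].start <= pos < scafs[i].end:
            raise ValueError(f"position {pos} not on chromosome {chrom}")
        return scafs[i]

    # -- coordinate conversion --------------------------------------------
    def to_scaffold_coords(self, chrom: str, pos: int) -> tuple[str, int]:
        s = self.scaffold_of(chrom, pos)
        return s.name, s.to_scaffold_pos(pos)

    def to_chrom_coords(self, scaffold: str, pos: int) -> tuple[str, int]:
        s = self.scaffold(scaffold)
        return s.chrom, s.to_chrom_pos(pos)

    @property
    def causal_scaffold(self) -> tuple[str, int]:
        """(scaffold name, 1-based scaffold position) of the causal locus."""
        return self.to_scaffold_coords(self.causal_chrom, self.causal_pos)

    def small_scaffolds(self) -> list[str]:
        """Scaffolds below the minimum-length cutoff, flagged for exclusion."""
        return [s.name for s in self.scaffolds if s.length < self.min_scaffold_len]

    def scaffold_lengths(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scaffold": [s.name for s in self.scaffolds],
             "length": [s.length for s in self.scaffolds]}
        )


def random_genome(
    rng: np.random.Generator,
    n_chromosomes: int = 5,
    chrom_length: int = 4_000_000,
    morgans_per_chrom: float = 1.25,
    scaffolds_per_chrom: int = 40,
    causal_chrom_index: int = 0,
    causal_fraction: float = 0.5,
    min_scaffold_len: int = 5000,
) -> GenomeMap:
    """Draw a fragmented-assembly genome.

    Scaffold boundaries are uniform random cuts, giving roughly
    exponential scaffold lengths (a handful fall under the 5 kb cutoff, as
    in a real draft assembly).  Scaffold names are shuffled so that the
    assembly order carries no information about chromosome order, and each
    scaffold is assembled in a random orientation.

    The causal locus is placed at ``causal_fraction`` along one chromosome;
    if the containing scaffold is shorter than 20 kb (too small to carry a
    mapping signal or survive the length filter) it is moved to the
    midpoint of the longest scaffold on that chromosome.
    """
    if n_chromosomes < 1 or scaffolds_per_chrom < 1:
        raise ValueError("need at least one chromosome and one scaffold")
    chroms = [
        Chromosome(f"chr{i + 1}", chrom_length, morgans_per_chrom)
        for i in range(n_chromosomes)
    ]
    # random scaffold tiling
    boundaries = []
    for c in chroms:
        while True:
            cuts = np.sort(rng.integers(1, c.length_bp, scaffolds_per_chrom - 1))
            edges = np.concatenate([[0], cuts, [c.length_bp]])
            if np.all(np.diff(edges) >= 1):
                break
        boundaries.append(edges)
    n_total = n_chromosomes * scaffolds_per_chrom
    order = rng.permutation(n_total)
    scaffolds = []
    k = 0
    for c, edges in zip(chroms, boundaries):
        for j in range(len(edges) - 1):
            scaffolds.append(
                Scaffold(
                    name=f"scaffold_{order[k] + 1}",
                    chrom=c.name,
                    start=int(edges[j]),
                    end=int(edges[j + 1]),
                    orientation=rng.choice(["+", "-"]),
                )
            )
            k += 1
    causal_chrom = chroms[causal_chrom_index].name
    causal_pos = int(causal_fraction * chrom_length)
    gmap = GenomeMap(
        chromosomes=chroms,
        scaffolds=scaffolds,
        causal_chrom=causal_chrom,
        causal_pos=causal_pos,
        min_scaffold_len=min_scaffold_len,
    )
    if gmap.scaffold_of(causal_chrom, causal_pos).length < 20_000:
        best = max(gmap._by_chrom[causal_chrom], key=lambda s: s.length)
        gmap = dataclasses.replace(
            gmap, causal_pos=(best.start + best.end) // 2
        )
    return gmap
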