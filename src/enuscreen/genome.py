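"""Autosomal genetic maps, the Haldane map function, and gamete simulation.

Meiotic mapping rests on a physical fact: two loci that lie close together on
a chromosome are co-inherited through meiosis unless a crossover happens to
fall between them, while loci on different chromosomes assort independently.
This module provides the minimal machinery for that process — an ordered
autosomal map in centimorgans, the Haldane distance-to-recombination
conversion, and a crossover simulator that draws gametes from a heterozygous
parent.

Crossovers are modeled as a Poisson process along each chromosome with mean
``length_cM / 100`` (one expected crossover per Morgan) and uniform crossover
positions, i.e. no interference.  Under this model the recombination fraction
between loci ``d`` cM apart is exactly the Haldane map function
``r = (1 - exp(-2d/100)) / 2``, so the simulator and the closed form are
mutually consistent.

Coordinates are continuous cM positions, 0-based at the chromosome start.
There are no physical (bp) coordinates anywhere in the package; sex
chromosomes are excluded.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "Locus",
    "Haplotype",
    "haldane_recombination_fraction",
    "simulate_gamete",
    "default_mouse_map",
    "chrom_sort_key",
]

REFERENCE_STRAND = 0
MUTANT_STRAND = 1


def chrom_sort_key(chrom: str):
    """Natural sort key for chromosome labels ('2' before '10', letters last)."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class Locus:
    """A map position: chromosome label plus centimorgans from the chromosome start."""

    chrom: str
    pos_cM: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pos_cM) or self.pos_cM < 0:
            raise ValueError(f"locus position must be finite and >= 0, got {self.pos_cM}")


@dataclass(frozen=True)
class Haplotype:
    """Strand-of-origin flags for one gamete, aligned with the locus list it was drawn for.

    Flag 0 means the reference strand, 1 the mutant (ENU-carrying) strand.
    A heterozygous parent transmits the mutant allele at locus *i* exactly
    when ``flags[i] == 1``.
    """

    flags: tuple

    def __len__(self) -> int:
        return len(self.flags)

    def __getitem__(self, i: int) -> int:
        return self.flags[i]


class GeneticMap:
    """An ordered set of autosomes with strictly positive cM lengths."""

    def __init__(self, chromosomes: Sequence[tuple[str, float]]):
        chroms = [(str(c), float(length)) for c, length in chromosomes]
        ids = [c for c, _ in chroms]
        if len(set(ids)) != len(ids):
            raise ValueError("chromosome ids on a genetic map must be unique")
        for c, length in chroms:
            if not math.isfinite(length) or length <= 0:
                raise ValueError(f"chromosome {c!r}: length must be finite and > 0, got {length}")
        self._chromosomes = chroms
        self._lengths = dict(chroms)
        self._order = {c: i for i, (c, _) in enumerate(chroms)}

    @property
    def chromosomes(self) -> list[tuple[str, float]]:
        return list(self._chromosomes)

    @property
    def total_length_cM(self) -> float:
        return float(sum(self._lengths.values()))

    def __len__(self) -> int:
        return len(self._chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneticMap) and self._chromosomes == other._chromosomes

    def length_of(self, chrom: str) -> float:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} is not on the map") from None

    def order_index(self, chrom: str) -> int:
        return self._order[chrom]

    def validate_locus(self, locus: Locus) -> None:
        if locus.chrom not in self._lengths:
            raise ValueError(f"locus on chromosome {locus.chrom!r} is off the map")
        length = self._lengths[locus.chrom]
        if not (0.0 <= locus.pos_cM <= length):
            raise ValueError(
                f"locus position {locus.pos_cM} cM outside chromosome "
                f"{locus.chrom!r} (length {length} cM)"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        """Read a map from a TSV with header ``chrom<TAB>length_cM``."""
        path = Path(path)
        rows: list[tuple[str, float]] = []
        with open(path, encoding="utf-8-sig", newline="") as fh:
            header = fh.readline().rstrip("\r\n").split("\t")
            if header != ["chrom", "length_cM"]:
                raise ValueError(
                    f"{path}: expected header 'chrom\\tlength_cM', got {header!r}"
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\r\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected two tab-separated fields")
                try:
                    length = float(parts[1])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: bad length {parts[1]!r}") from None
                rows.append((parts[0], length))
        return cls(rows)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("chrom\tlength_cM\n")
            for chrom, length in self._chromosomes:
                fh.write(f"{chrom}\t{length:g}\n")


def default_mouse_map() -> GeneticMap:
    """The packaged 19-autosome mouse map (plausible cM lengths; a modeling default)."""
    ref = resources.files("enuscreen.data").joinpath("mouse_autosomes_cM.tsv")
    with resources.as_file(ref) as path:
        return GeneticMap.from_tsv(path)


def haldane_recombination_fraction(distance_cM: float) -> float:
    """Recombination fraction between loci ``distance_cM`` apart, Haldane model.

    ``r = (1 - exp(-2 d / 100)) / 2`` for a distance ``d`` in centimorgans;
    monotonically increasing in ``d`` and bounded below 0.5 for finite ``d``.
    """
    d = float(distance_cM)
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"map distance must be finite and >= 0, got {distance_cM}")
    r = -0.5 * math.expm1(-2.0 * d / 100.0)
    # the closed form saturates to 0.5 in double precision near d ~ 1850 cM;
    # keep the strict r < 0.5 contract for finite distances
    return min(r, math.nextafter(0.5, 0.0))


def simulate_gamete(
    loci: Sequence[Locus],
    genetic_map: GeneticMap,
    rng: np.random.Generator,
) -> Haplotype:
    """Draw one gamete from a parent heterozygous at ``loci``.

    Per chromosome carrying at least one locus: the starting strand is a fair
    coin, the crossover count is Poisson with mean ``length/100``, crossover
    positions are uniform along the chromosome, and the strand of origin flips
    at every crossover.  Chromosomes are processed in map order so that draws
    are reproducible for a fixed seed.

    Returns a :class:`Haplotype` whose flags align with the input ``loci``.
    """
    flags = [REFERENCE_STRAND] * len(loci)
    by_chrom: dict[str, list[int]] = {}
    for i, locus in enumerate(loci):
        genetic_map.validate_locus(locus)
        by_chrom.setdefault(locus.chrom, []).append(i)

    for chrom, length in genetic_map.chromosomes:
        idx = by_chrom.get(chrom)
        if not idx:
            continue
        start = int(rng.integers(0, 2))
        n_crossovers = int(rng.poisson(length / 100.0))
        crossovers = np.sort(rng.uniform(0.0, length, size=n_crossovers))
        for i in idx:
            flips = int(np.searchsorted(crossovers, loci[i].pos_cM, side="right"))
            flags[i] = (start + flips) % 2
    return Haplotype(tuple(flags))
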