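"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based half-open everywhere.  A hybrid carries two
whole parental genomes side by side, so an "allele" of an ortholog is
simply the copy residing on one parent's replicons; the two parents are
identified throughout by the species labels of :class:`GenomePair`
(by default ``"v"`` and ``"m"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Replicon", "GenomePair", "UnitLocus", "OrthologUnit", "CoverageTrack",
    "CHROMOSOME", "PLASMID",
]

CHROMOSOME = "chromosome"
PLASMID = "plasmid"


@dataclass
class Replicon:
    """One replicon (main chromosome or plasmid) of one parent."""

    name: str
    seq: str
    replicon_class: str  # "chromosome" | "plasmid"

    def __post_init__(self) -> None:
        if self.replicon_class not in (CHROMOSOME, PLASMID):
            raise ValueError(
                f"replicon {self.name}: class must be '{CHROMOSOME}' or "
                f"'{PLASMID}', got {self.replicon_class!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomePair:
    """The two parental genomes; the coordinate frame for everything else.

    ``replicons`` maps each species label to an ordered list of its
    replicons.  Replicon names must be unique within a species.
    """

    species: tuple[str, str]
    replicons: dict[str, list[Replicon]]

    def __post_init__(self) -> None:
        if len(self.species) != 2 or self.species[0] == self.species[1]:
            raise ValueError("GenomePair needs exactly two distinct species labels")
        for sp in self.species:
            if sp not in self.replicons:
                raise ValueError(f"no replicons given for species {sp!r}")
            names = [r.name for r in self.replicons[sp]]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate replicon names for species {sp!r}")

    def other(self, species: str) -> str:
        a, b = self.species
        if species == a:
            return b
        if species == b:
            return a
        raise KeyError(species)

    def replicon(self, species: str, name: str) -> Replicon:
        for rep in self.replicons[species]:
            if rep.name == name:
                return rep
        raise KeyError(f"species {species!r} has no replicon {name!r}")

    def seq(self, species: str, name: str) -> str:
        return self.replicon(species, name).seq

    def lengths(self, species: str) -> dict[str, int]:
        return {r.name: len(r.seq) for r in self.replicons[species]}

    def chromosome(self, species: str) -> Replicon:
        chroms = [r for r in self.replicons[species] if r.replicon_class == CHROMOSOME]
        if len(chroms) != 1:
            raise ValueError(
                f"species {species!r} has {len(chroms)} chromosomes; expected exactly 1")
        return chroms[0]


@dataclass
class UnitLocus:
    """Placement of one ortholog unit on one parent's genome.

    ``member_coords`` optionally gives each member gene's (start, end)
    within the same replicon, in the unit's member order; required only
    by analyses that need per-gene resolution inside operons.
    """

    replicon: str
    replicon_class: str
    start: int
    end: int
    strand: str
    member_coords: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) (0-based half-open)")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.replicon_class not in (CHROMOSOME, PLASMID):
            raise ValueError(f"bad replicon class {self.replicon_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OrthologUnit:
    """A gene or operon matched one-to-one between the parents.

    This is the unit at which ASE is measured: single genes carry one
    member (themselves); operons carry >= 2 member genes that share a
    promoter and hence an allelic expression ratio.
    """

    ortholog_id: str
    unit_type: str  # "gene" | "operon"
    members: list[str]
    loci: dict[str, UnitLocus]  # species -> locus

    def __post_init__(self) -> None:
        if self.unit_type not in ("gene", "operon"):
            raise ValueError(
                f"{self.ortholog_id}: unit_type must be 'gene' or 'operon'")
        if self.unit_type == "operon" and len(self.members) < 2:
            raise ValueError(f"operon {self.ortholog_id} lists < 2 member genes")
        if self.unit_type == "gene" and len(self.members) != 1:
            raise ValueError(f"gene unit {self.ortholog_id} must list exactly 1 member")
        for sp, loc in self.loci.items():
            if loc.member_coords is not None:
                if len(loc.member_coords) != len(self.members):
                    raise ValueError(
                        f"{self.ortholog_id}/{sp}: member_gene_coords count "
                        f"does not match member_gene_ids")
                prev_end = None
                for (s, e) in sorted(loc.member_coords):
                    if not (loc.start <= s < e <= loc.end):
                        raise ValueError(
                            f"{self.ortholog_id}/{sp}: member gene [{s},{e}) "
                            f"outside unit [{loc.start},{loc.end})")
                    if prev_end is not None and s < prev_end:
                        raise ValueError(
                            f"{self.ortholog_id}/{sp}: overlapping member genes")
                    prev_end = e

    def locus(self, species: str) -> UnitLocus:
        try:
            return self.loci[species]
        except KeyError:
            raise KeyError(
                f"ortholog {self.ortholog_id} has no record for species {species!r}")

    @property
    def is_operon(self) -> bool:
        return self.unit_type == "operon"


@dataclass
class CoverageTrack:
    """Dense per-base coverage of one replicon for one allele/assay/replicate."""

    replicon: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be a 1-D vector")
        if np.any(self.values < 0):
            raise ValueError(f"negative coverage in track for {self.replicon!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def total(self) -> float:
        return float(self.values.sum())
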