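"""Per-ortholog coverage summaries and the filters defining the analysis set.

Coverage is summed over uniquely mappable bases only.  DNA-seq RPKM
(with mappable length as the gene length) is the ploidy proxy used to
flag local copy-number variants; plasmid units, CNV-flagged units and
units with insufficient RNA reads are excluded before ASE testing.
Chromosome coverage of the higher-coverage parent is linearly scaled
down so total chromosomal coverage matches the lower-coverage parent,
removing genome-wide abundance imbalance from allelic ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .data import CHROMOSOME, PLASMID, CoverageTrack, GenomePair, OrthologUnit, UnitLocus
from .mappability import MappabilityMask

__all__ = [
    "UnitCoverageSummary", "AnalysisSet",
    "summarize_unit", "summarize_all", "detect_cnv",
    "scale_chromosome_coverage", "scale_coverage_sets", "build_analysis_set",
]

SUMMARY_COLUMNS = ["ortholog_id", "species", "assay", "replicate",
                   "sum_coverage", "mappable_length", "reads_equivalent", "rpkm",
                   "replicon_class"]


@dataclass
class UnitCoverageSummary:
    """Coverage of one ortholog for one allele/assay/replicate."""

    ortholog_id: str
    species: str
    assay: str
    replicate: int
    sum_coverage: float
    mappable_length: int
    read_length: int
    total_assigned_reads: float
    replicon_class: str

    @property
    def reads_equivalent(self) -> float:
        return self.sum_coverage / self.read_length

    @property
    def rpkm(self) -> float:
        """Reads per kilobase of mappable length per million assigned reads.

        NaN when the unit has no mappable bases (flagged downstream).
        """
        if self.mappable_length == 0:
            return float("nan")
        return (self.sum_coverage / self.read_length) * 1e9 / (
            self.mappable_length * self.total_assigned_reads)

    def as_row(self) -> dict:
        return {
            "ortholog_id": self.ortholog_id, "species": self.species,
            "assay": self.assay, "replicate": self.replicate,
            "sum_coverage": self.sum_coverage,
            "mappable_length": self.mappable_length,
            "reads_equivalent": self.reads_equivalent, "rpkm": self.rpkm,
            "replicon_class": self.replicon_class,
        }


def summarize_unit(track: CoverageTrack, unit: OrthologUnit, species: str,
                   mask: MappabilityMask, read_length: int,
                   total_assigned_reads: float, assay: str = "RNA",
                   replicate: int = 1) -> UnitCoverageSummary:
    """Sum a unit's coverage over its mappable positions and form RPKM."""
    if total_assigned_reads <= 0:
        raise ValueError("total_assigned_reads must be positive")
    loc = unit.locus(species)
    if loc.end > len(track):
        raise ValueError(
            f"unit {unit.ortholog_id} extends beyond track {track.replicon!r}")
    m = mask.mappable[species][loc.replicon][loc.start:loc.end]
    vals = track.values[loc.start:loc.end]
    return UnitCoverageSummary(
        ortholog_id=unit.ortholog_id, species=species, assay=assay,
        replicate=replicate, sum_coverage=float(vals[m].sum()),
        mappable_length=int(m.sum()), read_length=read_length,
        total_assigned_reads=total_assigned_reads,
        replicon_class=loc.replicon_class)


def _unit_mappable_sum(tracks: dict[str, CoverageTrack], unit: OrthologUnit,
                       species: str, mask: MappabilityMask) -> tuple[float, int]:
    loc = unit.locus(species)
    m = mask.mappable[species][loc.replicon][loc.start:loc.end]
    vals = tracks[loc.replicon].values[loc.start:loc.end]
    return float(vals[m].sum()), int(m.sum())


def summarize_all(coverages: dict, units: list[OrthologUnit], pair: GenomePair,
                  mask: MappabilityMask, read_length: int) -> pd.DataFrame:
    """Summaries for all units across species x assay x replicate.

    ``coverages[assay][replicate][species]`` maps replicon name to
    :class:`CoverageTrack`.  The library size (total assigned reads) of
    each series is the summed mappable coverage over all orthologs
    divided by the read length.
    """
    rows = []
    for assay, by_rep in coverages.items():
        for replicate, by_sp in by_rep.items():
            for species in pair.species:
                tracks = by_sp[species]
                sums, lengths = {}, {}
                for u in units:
                    sums[u.ortholog_id], lengths[u.ortholog_id] = \
                        _unit_mappable_sum(tracks, u, species, mask)
                total_reads = sum(sums.values()) / read_length
                if total_reads <= 0:
                    raise ValueError(
                        f"no ortholog coverage at all for {species}/{assay}/rep{replicate}")
                for u in units:
                    s = UnitCoverageSummary(
                        ortholog_id=u.ortholog_id, species=species, assay=assay,
                        replicate=replicate, sum_coverage=sums[u.ortholog_id],
                        mappable_length=lengths[u.ortholog_id],
                        read_length=read_length, total_assigned_reads=total_reads,
                        replicon_class=u.locus(species).replicon_class)
                    rows.append(s.as_row())
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def detect_cnv(summaries: pd.DataFrame, threshold_sd: float,
               pooling: str = "any") -> set[str]:
    """Flag chromosome units whose DNA RPKM is a >= threshold_sd-SD outlier.

    Mean and sample SD are computed across chromosome units, per
    allele x replicate series (``pooling="any"``: a unit flagged in any
    series is returned) or over all four series pooled
    (``pooling="pooled"``).  A degenerate series (SD 0) flags nothing.
    """
    dna = summaries[(summaries["assay"] == "DNA")
                    & (summaries["replicon_class"] == CHROMOSOME)
                    & summaries["rpkm"].notna()]
    if dna["ortholog_id"].nunique() < 3:
        raise ValueError("need >= 3 chromosome units with defined DNA RPKM")
    flagged: set[str] = set()
    groups = [g for _, g in dna.groupby(["species", "replicate"])] \
        if pooling == "any" else [dna]
    for g in groups:
        mean = g["rpkm"].mean()
        sd = g["rpkm"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        out = g.loc[(g["rpkm"] - mean).abs() > threshold_sd * sd, "ortholog_id"]
        flagged.update(out)
    return flagged


def scale_chromosome_coverage(high: CoverageTrack, low: CoverageTrack) -> CoverageTrack:
    """Scale the higher-coverage parent's chromosome track down linearly
    so that its total equals the lower-coverage parent's total."""
    total_low, total_high = low.total, high.total
    if total_low <= 0:
        raise ValueError("lower-coverage track sums to zero; cannot scale")
    if total_high < total_low:
        raise ValueError("'high' track has smaller total than 'low' track")
    return CoverageTrack(high.replicon, high.values * (total_low / total_high))


def scale_coverage_sets(coverages: dict, pair: GenomePair, mask: MappabilityMask,
                        ) -> dict:
    """Remove chromosomal-abundance imbalance between the parents.

    Per replicate, the higher-coverage parent and the scaling factor
    are both determined from the *DNA* chromosome totals over mappable
    positions — DNA coverage is the ploidy proxy, so the factor
    estimates the parental chromosome copy ratio.  That parent's DNA
    and RNA chromosome tracks are scaled down by the factor: DNA totals
    become equal, and RNA ratios are measured against the copy-number
    baseline rather than forced to a zero genome-wide mean (which would
    re-center every allelic ratio and turn a genuinely asymmetric
    expression shift into apparent bias of the null genes).  Plasmid
    tracks are left untouched (their units are excluded from ASE).
    Returns a new nested dict of the same shape as ``coverages``.
    """
    sp1, sp2 = pair.species
    chrom = {sp: pair.chromosome(sp).name for sp in pair.species}

    def mappable_total(assay, rep, sp):
        track = coverages[assay][rep][sp][chrom[sp]]
        m = mask.mappable[sp][chrom[sp]]
        return float(track.values[m].sum())

    scaled = {assay: {rep: {sp: dict(tracks) for sp, tracks in by_sp.items()}
                      for rep, by_sp in by_rep.items()}
              for assay, by_rep in coverages.items()}
    for rep in coverages["DNA"]:
        dna_totals = {sp: mappable_total("DNA", rep, sp) for sp in pair.species}
        if min(dna_totals.values()) <= 0:
            raise ValueError(f"zero chromosomal DNA coverage in replicate {rep}")
        high_sp = sp1 if dna_totals[sp1] >= dna_totals[sp2] else sp2
        low_sp = pair.other(high_sp)
        factor = dna_totals[low_sp] / dna_totals[high_sp]
        for assay in coverages:
            track = scaled[assay][rep][high_sp][chrom[high_sp]]
            scaled[assay][rep][high_sp][chrom[high_sp]] = CoverageTrack(
                track.replicon, track.values * factor)
    return scaled


@dataclass
class AnalysisSet:
    """The orthologs retained for ASE testing, and why the rest were dropped.

    Exclusion reasons (first matching wins): plasmid, cnv, low_reads,
    zero_mappable.
    """

    retained: list[str]
    excluded: dict[str, str] = field(default_factory=dict)

    def __contains__(self, ortholog_id: str) -> bool:
        return ortholog_id in set(self.retained)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"ortholog_id": oid, "retained": True, "reason": ""}
                for oid in self.retained]
        rows += [{"ortholog_id": oid, "retained": False, "reason": why}
                 for oid, why in self.excluded.items()]
        return pd.DataFrame(rows).sort_values("ortholog_id").reset_index(drop=True)


def build_analysis_set(summaries: pd.DataFrame, units: list[OrthologUnit],
                       config: PipelineConfig, cnv_flagged: set[str] | None = None,
                       ) -> AnalysisSet:
    """Apply the plasmid / CNV / read-count / mappability filters.

    A unit passes only if it sits on the main chromosomes, is not a
    DNA-coverage outlier, and has at least ``min_reads`` allele-summed
    RNA read equivalents in *every* replicate.
    """
    if cnv_flagged is None:
        cnv_flagged = detect_cnv(summaries, config.cnv_sd_threshold, config.cnv_pooling)
    rna = summaries[summaries["assay"] == "RNA"]
    reads_by_rep = rna.groupby(["ortholog_id", "replicate"])["reads_equivalent"].sum()
    min_len = summaries.groupby("ortholog_id")["mappable_length"].min()

    retained, excluded = [], {}
    for u in units:
        oid = u.ortholog_id
        if any(loc.replicon_class == PLASMID for loc in u.loci.values()):
            excluded[oid] = "plasmid"
        elif oid in cnv_flagged:
            excluded[oid] = "cnv"
        elif bool((reads_by_rep.loc[oid] < config.min_reads).any()):
            excluded[oid] = "low_reads"
        elif min_len.loc[oid] == 0:
            excluded[oid] = "zero_mappable"
        else:
            retained.append(oid)
    return AnalysisSet(retained=retained, excluded=excluded)
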