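"""Synthetic hybrid-experiment generator with known ground truth.

Emulates an interspecific hybrid carrying two complete, syntenic
parental genomes: orthologous gene/operon units laid out along a main
chromosome (plus optional plasmids), nucleotide divergence between the
orthologous sequences, per-replicon copy-number imbalance between the
parental chromosomes and plasmids, optional local amplifications, and
per-base DNA/RNA coverage with planted allelic (log2) expression
effects.  Every stochastic quantity derives from one scenario seed, so
a scenario is byte-reproducible; the returned ground truth drives
parameter-recovery and calibration tests downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import stage_rng
from .data import CHROMOSOME, PLASMID, CoverageTrack, GenomePair, OrthologUnit, Replicon, UnitLocus
from . import io as hio

__all__ = [
    "PlantedSet", "CnvRegion", "ScenarioConfig", "GroundTruth", "Scenario",
    "generate_genome_pair", "generate_scenario", "simulate_coverage",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
DNA, RNA = "DNA", "RNA"


@dataclass
class PlantedSet:
    """A gene-set category with a coordinated directional expression shift.

    ``directional_fraction`` of its ``n_members`` members receive a true
    log2 allelic ratio of ``-effect_shift`` (favoring the second-listed
    species, mirroring a lineage-specific up-regulation); the rest keep
    background-drawn effects.
    """

    category_id: str = "planted"
    n_members: int = 20
    directional_fraction: float = 0.8
    effect_shift: float = 1.0


@dataclass
class CnvRegion:
    """A local copy-number change on one parent: fold applied to coverage."""

    species: str
    replicon: str
    start: int
    end: int
    fold: float


@dataclass
class ScenarioConfig:
    """All knobs of one in-silico hybrid experiment.

    Defaults describe the emulated study system at desk scale: two
    ~60%-GC parental genomes at 13.4% coding-sequence divergence,
    roughly a quarter of transcriptional units being operons, a quarter
    of each genome on a plasmid with its own copy number, two hybrid
    replicates with a mild chromosomal depth imbalance, ~50x mean
    coverage, and half of orthologs carrying true cis effects with SD
    1 log2 unit.
    """

    genome_length: int = 300_000
    n_orthologs: int = 500
    operon_fraction: float = 0.23
    genes_per_operon: tuple[int, int] = (2, 4)
    gene_length: tuple[int, int] = (200, 400)
    intergenic: tuple[int, int] = (20, 100)
    divergence: float = 0.134
    gc_content: float = 0.60
    substitution_gc_bias: float = 0.0
    ase_null_fraction: float = 0.5
    ase_effect_sd: float = 1.0
    planted_set: PlantedSet | None = None
    n_background_categories: int = 5
    background_category_size: int = 20
    mean_dna_depth: float = 50.0
    mean_rna_depth: float = 50.0
    locus_efficiency_sd: float = 0.1
    plasmid_fraction: float = 0.25
    plasmid_copy_range: tuple[float, float] = (0.5, 3.0)
    cnv_regions: list[CnvRegion] = field(default_factory=list)
    replicate_depth_imbalance: float = 1.2
    n_replicates: int = 2
    species: tuple[str, str] = ("v", "m")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must lie in [0, 1)")
        for name in ("operon_fraction", "ase_null_fraction", "plasmid_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if not 0.0 <= self.substitution_gc_bias <= 1.0:
            raise ValueError("substitution_gc_bias must lie in [0, 1]")
        if self.mean_dna_depth <= 0 or self.mean_rna_depth <= 0:
            raise ValueError("depths must be positive")
        if self.locus_efficiency_sd < 0:
            raise ValueError("locus_efficiency_sd must be non-negative")
        if self.replicate_depth_imbalance <= 0:
            raise ValueError("replicate_depth_imbalance must be positive")
        if self.n_orthologs < 1 or self.genome_length < 1 or self.n_replicates < 1:
            raise ValueError("counts must be positive")
        for name in ("genes_per_operon", "gene_length", "intergenic"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < (2 if name == "genes_per_operon" else 1):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    # serialization (configs are plain YAML) -------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.planted_set is not None:
            d["planted_set"] = dataclasses.asdict(self.planted_set)
        d["cnv_regions"] = [dataclasses.asdict(r) for r in self.cnv_regions]
        for key in ("genes_per_operon", "gene_length", "intergenic",
                    "plasmid_copy_range", "species"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if d.get("planted_set") is not None:
            d["planted_set"] = PlantedSet(**d["planted_set"])
        d["cnv_regions"] = [CnvRegion(**r) for r in d.get("cnv_regions", [])]
        for key in ("genes_per_operon", "gene_length", "intergenic",
                    "plasmid_copy_range", "species"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests.

    ``effects`` has one row per ortholog: true log2 allelic ratio
    (positive = first species higher) and planted-category membership.
    ``cnv_regions`` echoes the true amplifications; ``copy_factors``
    maps (species, replicate, replicon) to the simulated depth factor.
    """

    effects: pd.DataFrame
    cnv_regions: list[CnvRegion]
    copy_factors: dict[tuple[str, int, str], float]

    def true_ratio(self, ortholog_id: str) -> float:
        return float(self.effects.set_index("ortholog_id").loc[ortholog_id, "true_log2_ratio"])

    def write(self, path) -> None:
        self.effects.to_csv(path, sep="\t", index=False)


@dataclass
class Scenario:
    """A fully specified in-silico experiment ready to simulate from."""

    config: ScenarioConfig
    pair: GenomePair
    units: list[OrthologUnit]
    truth: GroundTruth
    catalog: pd.DataFrame

    def write(self, outdir) -> None:
        """Write genome FASTA, annotations, catalog, truth, config and
        per-allele/assay/replicate bedGraph coverage under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_genome_pair(self.pair, outdir / "genomes.fasta")
        hio.write_annotations(self.units, outdir / "annotations.tsv")
        hio.write_catalog(self.catalog, outdir / "catalog.tsv")
        self.truth.write(outdir / "ground_truth.tsv")
        self.config.to_yaml(outdir / "scenario.yaml")
        for assay in (DNA, RNA):
            for rep in range(1, self.config.n_replicates + 1):
                tracks = simulate_coverage(self, assay, rep)
                for sp in self.config.species:
                    fname = outdir / f"coverage_{assay}_{sp}_rep{rep}.bedgraph"
                    with open(fname, "w"):
                        pass
                    for track in tracks[sp].values():
                        hio.write_bedgraph(track, fname, mode="a")


# --------------------------------------------------------------------------
# genome + annotation generation
# --------------------------------------------------------------------------

def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _substitute(codes: np.ndarray, rate: float, gc_bias: float,
                rng: np.random.Generator) -> np.ndarray:
    """I.i.d. substitutions at `rate` per site, uniform over the 3
    alternative bases, optionally re-weighted toward G/C."""
    out = codes.copy()
    hit = np.flatnonzero(rng.random(len(codes)) < rate)
    if len(hit) == 0:
        return out
    # weights over the 3 alternatives; A=0,C=1,G=2,T=3
    is_gc = np.array([0.0, 1.0, 1.0, 0.0])
    for b in range(4):
        idx = hit[codes[hit] == b]
        if len(idx) == 0:
            continue
        alts = np.array([a for a in range(4) if a != b])
        w = 1.0 + gc_bias * is_gc[alts]
        w /= w.sum()
        out[idx] = rng.choice(alts, size=len(idx), p=w)
    return out


def _draw_unit_structures(config: ScenarioConfig, rng: np.random.Generator):
    """Decide, per ortholog unit, its type, member count and gene lengths."""
    n_operons = int(round(config.operon_fraction * config.n_orthologs))
    is_operon = np.zeros(config.n_orthologs, dtype=bool)
    if n_operons:
        is_operon[rng.choice(config.n_orthologs, size=n_operons, replace=False)] = True
    structures = []
    for i in range(config.n_orthologs):
        if is_operon[i]:
            k = int(rng.integers(config.genes_per_operon[0], config.genes_per_operon[1] + 1))
        else:
            k = 1
        lengths = rng.integers(config.gene_length[0], config.gene_length[1] + 1, size=k)
        structures.append((bool(is_operon[i]), [int(x) for x in lengths]))
    return structures


_INTRA_OPERON_GAP = 10  # bases between member genes inside an operon


def generate_genome_pair(config: ScenarioConfig):
    """Generate the syntenic parental genome pair and its annotations.

    The second species is derived from the first by i.i.d. substitutions
    at the configured divergence inside ortholog bodies (synteny and
    coordinates are preserved); intergenic sequence is shared.  Units
    are laid out sequentially on one chromosome plus (if
    ``plasmid_fraction`` > 0) one plasmid.

    Returns ``(GenomePair, list[OrthologUnit])``.
    """
    rng = stage_rng(config.rng_seed, "genome")
    structures = _draw_unit_structures(config, rng)

    chr_len = int(round(config.genome_length * (1 - config.plasmid_fraction)))
    pls_len = config.genome_length - chr_len
    replicon_names = {"chr": "chr", "pls": "pls1"}
    have_plasmid = pls_len > 0

    n_pls_units = int(round(config.plasmid_fraction * config.n_orthologs)) if have_plasmid else 0
    on_plasmid = np.zeros(config.n_orthologs, dtype=bool)
    if n_pls_units:
        on_plasmid[rng.choice(config.n_orthologs, size=n_pls_units, replace=False)] = True

    cursors = {"chr": 0, "pls": 0}
    limits = {"chr": chr_len, "pls": pls_len}
    units: list[OrthologUnit] = []
    width = len(str(config.n_orthologs))
    for i, (is_op, gene_lengths) in enumerate(structures):
        where = "pls" if on_plasmid[i] else "chr"
        gap = int(rng.integers(config.intergenic[0], config.intergenic[1] + 1))
        start = cursors[where] + gap
        member_coords = []
        pos = start
        for j, gl in enumerate(gene_lengths):
            if j > 0:
                pos += _INTRA_OPERON_GAP
            member_coords.append((pos, pos + gl))
            pos += gl
        end = pos
        if end > limits[where]:
            raise ValueError(
                f"scenario does not fit: unit {i} needs [{start}, {end}) on "
                f"{where} of length {limits[where]}; increase genome_length "
                f"or reduce n_orthologs/gene sizes")
        cursors[where] = end
        strand = "+" if rng.random() < 0.5 else "-"
        oid = f"og{i + 1:0{width}d}"
        members = [oid] if not is_op else [f"{oid}.g{j + 1}" for j in range(len(gene_lengths))]
        rep_name = replicon_names["pls" if on_plasmid[i] else "chr"]
        klass = PLASMID if on_plasmid[i] else CHROMOSOME
        loci = {
            sp: UnitLocus(replicon=f"{sp}_{rep_name}", replicon_class=klass,
                          start=start, end=end, strand=strand,
                          member_coords=list(member_coords))
            for sp in config.species
        }
        units.append(OrthologUnit(
            ortholog_id=oid, unit_type="operon" if is_op else "gene",
            members=members, loci=loci))

    sp1, sp2 = config.species
    replicons: dict[str, list[Replicon]] = {sp1: [], sp2: []}
    layout = [("chr", chr_len, CHROMOSOME)]
    if have_plasmid:
        layout.append(("pls", pls_len, PLASMID))
    for short, length, klass in layout:
        seq1 = _random_sequence(length, config.gc_content, rng)
        seq2 = seq1.copy()
        for u in units:
            loc = u.loci[sp1]
            if loc.replicon == f"{sp1}_{replicon_names[short]}":
                body = slice(loc.start, loc.end)
                seq2[body] = _substitute(
                    seq1[body], config.divergence, config.substitution_gc_bias, rng)
        name = replicon_names[short]
        replicons[sp1].append(Replicon(f"{sp1}_{name}", _codes_to_str(seq1), klass))
        replicons[sp2].append(Replicon(f"{sp2}_{name}", _codes_to_str(seq2), klass))

    return GenomePair(species=(sp1, sp2), replicons=replicons), units


def _generate_truth(config: ScenarioConfig, units: list[OrthologUnit]) -> tuple[GroundTruth, pd.DataFrame]:
    """Draw true per-unit log2 allelic ratios, plant the directional
    category, and build the gene-set catalog."""
    rng = stage_rng(config.rng_seed, "truth")
    ids = [u.ortholog_id for u in units]
    n = len(ids)
    is_null = rng.random(n) < config.ase_null_fraction
    t = np.where(is_null, 0.0, rng.normal(0.0, config.ase_effect_sd, size=n))

    chrom_idx = [i for i, u in enumerate(units)
                 if u.loci[config.species[0]].replicon_class == CHROMOSOME]
    planted_member = np.zeros(n, dtype=bool)
    cat_rows = []
    if config.planted_set is not None:
        ps = config.planted_set
        if ps.n_members > len(chrom_idx):
            raise ValueError("planted_set larger than the number of chromosome units")
        members = rng.choice(chrom_idx, size=ps.n_members, replace=False)
        planted_member[members] = True
        n_dir = int(round(ps.directional_fraction * ps.n_members))
        directional = members[:n_dir]
        # negative ratio = favors the second-listed species
        t[directional] = -abs(ps.effect_shift)
        cat_rows += [(ps.category_id, ids[i]) for i in sorted(members)]

    pool = [i for i in chrom_idx if not planted_member[i]]
    for c in range(config.n_background_categories):
        size = min(config.background_category_size, len(pool))
        if size == 0:
            break
        chosen = rng.choice(pool, size=size, replace=False)
        cat_rows += [(f"bg{c + 1:02d}", ids[i]) for i in sorted(chosen)]

    # shared per-locus sequencing efficiency (capture/mappability bias):
    # one factor per unit, common to both alleles, assays and replicates,
    # so it disperses across-unit coverage without touching allelic ratios
    efficiency = np.exp(rng.normal(0.0, config.locus_efficiency_sd, size=n))

    effects = pd.DataFrame({
        "ortholog_id": ids,
        "true_log2_ratio": t,
        "in_planted_category": planted_member,
        "locus_efficiency": efficiency,
    })
    catalog = pd.DataFrame(cat_rows, columns=["category_id", "ortholog_id"])
    return effects, catalog


def _copy_factors(config: ScenarioConfig, pair: GenomePair) -> dict[tuple[str, int, str], float]:
    """Depth multipliers per (species, replicate, replicon).

    The chromosomal imbalance alternates which parent is over-represented
    across replicates; each plasmid draws an independent copy ratio per
    species and replicate, emulating the variable plasmid:chromosome
    coverage of real hybrids.
    """
    rng = stage_rng(config.rng_seed, "copy")
    sp1, sp2 = config.species
    factors: dict[tuple[str, int, str], float] = {}
    lo, hi = config.plasmid_copy_range
    for rep in range(1, config.n_replicates + 1):
        high_parent = sp1 if rep % 2 == 1 else sp2
        for sp in (sp1, sp2):
            for replicon in pair.replicons[sp]:
                if replicon.replicon_class == CHROMOSOME:
                    f = config.replicate_depth_imbalance if sp == high_parent else 1.0
                else:
                    f = float(rng.uniform(lo, hi))
                factors[(sp, rep, replicon.name)] = f
    return factors


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate genomes, annotations, ground truth and catalog for one scenario."""
    pair, units = generate_genome_pair(config)
    effects, catalog = _generate_truth(config, units)
    truth = GroundTruth(effects=effects, cnv_regions=list(config.cnv_regions),
                        copy_factors=_copy_factors(config, pair))
    return Scenario(config=config, pair=pair, units=units, truth=truth, catalog=catalog)


# --------------------------------------------------------------------------
# coverage simulation
# --------------------------------------------------------------------------

def _fold_profile(scenario: Scenario, species: str, replicon: Replicon) -> np.ndarray:
    fold = np.ones(len(replicon), dtype=float)
    for region in scenario.truth.cnv_regions:
        if region.species == species and region.replicon == replicon.name:
            fold[region.start:region.end] *= region.fold
    return fold


def simulate_coverage(scenario: Scenario, assay: str, replicate: int,
                      ) -> dict[str, dict[str, CoverageTrack]]:
    """Simulate per-base coverage for one assay and replicate.

    Per-base counts are independent Poisson draws.  DNA coverage has
    mean ``mean_dna_depth x copy_factor x cnv_fold`` everywhere; RNA
    coverage is restricted to unit bodies, where the two alleles split
    the expression effect symmetrically (factors ``2^(+t/2)`` and
    ``2^(-t/2)``), so the expected allelic log2 ratio equals the true
    value ``t``.  Operon member genes share their unit's ratio by
    construction.

    Returns ``{species: {replicon_name: CoverageTrack}}``.
    """
    if assay not in (DNA, RNA):
        raise ValueError(f"assay must be '{DNA}' or '{RNA}'")
    config = scenario.config
    if not 1 <= replicate <= config.n_replicates:
        raise ValueError(f"replicate {replicate} out of range")
    rng = stage_rng(config.rng_seed, f"coverage:{assay}:{replicate}")
    depth = config.mean_dna_depth if assay == DNA else config.mean_rna_depth
    eff = scenario.truth.effects.set_index("ortholog_id")
    truth_map = eff["true_log2_ratio"].to_dict()
    efficiency_map = eff["locus_efficiency"].to_dict() \
        if "locus_efficiency" in eff else {}
    sp1 = config.species[0]

    out: dict[str, dict[str, CoverageTrack]] = {}
    for sp in config.species:
        out[sp] = {}
        for replicon in scenario.pair.replicons[sp]:
            factor = scenario.truth.copy_factors[(sp, replicate, replicon.name)]
            mean = depth * factor * _fold_profile(scenario, sp, replicon)
            unit_factor = np.ones(len(replicon), dtype=float)
            for u in scenario.units:
                loc = u.loci[sp]
                if loc.replicon != replicon.name:
                    continue
                unit_factor[loc.start:loc.end] = \
                    efficiency_map.get(u.ortholog_id, 1.0)
            if assay == RNA:
                expressed = np.zeros(len(replicon), dtype=float)
                for u in scenario.units:
                    loc = u.loci[sp]
                    if loc.replicon != replicon.name:
                        continue
                    t = truth_map[u.ortholog_id]
                    half = t / 2.0 if sp == sp1 else -t / 2.0
                    expressed[loc.start:loc.end] = 2.0 ** half
                mean = mean * expressed
            mean = mean * unit_factor
            counts = rng.poisson(mean).astype(float)
            out[sp][replicon.name] = CoverageTrack(replicon.name, counts)
    return out
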