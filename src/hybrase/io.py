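"""Readers and writers for the on-disk formats.

All formats are plain text: FASTA for genomes (replicon metadata in the
header description), a BED-like TSV for ortholog annotations, bedGraph
for per-base coverage, and two-column TSV for gene-set catalogs.
Readers validate and fail loudly, naming the offending record; nothing
is silently coerced.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data import CHROMOSOME, PLASMID, CoverageTrack, GenomePair, OrthologUnit, Replicon, UnitLocus

__all__ = [
    "read_genome_pair", "write_genome_pair",
    "load_annotations", "write_annotations",
    "load_coverage", "load_coverage_set", "write_bedgraph",
    "load_catalog", "write_catalog",
    "write_table", "read_table",
]

ANNOTATION_COLUMNS = [
    "ortholog_id", "species", "replicon_id", "replicon_class",
    "start", "end", "strand", "unit_type", "member_gene_ids",
]
OPTIONAL_ANNOTATION_COLUMNS = ["member_gene_coords"]


# --------------------------------------------------------------------------
# genomes (FASTA)
# --------------------------------------------------------------------------

_HEADER_RE = re.compile(r"(\w+)=(\S+)")


def write_genome_pair(pair: GenomePair, path) -> None:
    """Write both parental genomes to one FASTA.

    Each record id is the replicon name; the description carries
    ``species=<label> class=<chromosome|plasmid>``.
    """
    records = []
    for sp in pair.species:
        for rep in pair.replicons[sp]:
            records.append(SeqRecord(
                Seq(rep.seq), id=rep.name,
                description=f"species={sp} class={rep.replicon_class}"))
    SeqIO.write(records, str(path), "fasta")


def read_genome_pair(path) -> GenomePair:
    """Read a genome pair from FASTA written by :func:`write_genome_pair`."""
    replicons: dict[str, list[Replicon]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(_HEADER_RE.findall(rec.description))
        if "species" not in meta or "class" not in meta:
            raise ValueError(
                f"FASTA record {rec.id!r}: header must carry species= and class=")
        sp = meta["species"]
        if sp not in replicons:
            replicons[sp] = []
            order.append(sp)
        replicons[sp].append(Replicon(rec.id, str(rec.seq).upper(), meta["class"]))
    if len(order) != 2:
        raise ValueError(f"expected replicons from exactly 2 species, found {order}")
    return GenomePair(species=(order[0], order[1]), replicons=replicons)


# --------------------------------------------------------------------------
# ortholog annotations (BED-like TSV)
# --------------------------------------------------------------------------

def _format_member_coords(coords) -> str:
    return ";".join(f"{s}-{e}" for s, e in coords)


def _parse_member_coords(text: str, ortholog_id: str) -> list[tuple[int, int]]:
    out = []
    for token in text.split(";"):
        m = re.fullmatch(r"(\d+)-(\d+)", token)
        if not m:
            raise ValueError(
                f"ortholog {ortholog_id}: malformed member_gene_coords token {token!r}")
        out.append((int(m.group(1)), int(m.group(2))))
    return out


def write_annotations(units: list[OrthologUnit], path) -> None:
    rows = []
    for u in units:
        for sp, loc in u.loci.items():
            row = {
                "ortholog_id": u.ortholog_id,
                "species": sp,
                "replicon_id": loc.replicon,
                "replicon_class": loc.replicon_class,
                "start": loc.start,
                "end": loc.end,
                "strand": loc.strand,
                "unit_type": u.unit_type,
                "member_gene_ids": ",".join(u.members),
            }
            if loc.member_coords is not None:
                row["member_gene_coords"] = _format_member_coords(loc.member_coords)
            rows.append(row)
    df = pd.DataFrame(rows)
    cols = ANNOTATION_COLUMNS + [c for c in OPTIONAL_ANNOTATION_COLUMNS if c in df]
    df[cols].to_csv(path, sep="\t", index=False)


def load_annotations(path) -> list[OrthologUnit]:
    """Load ortholog units from the BED-like annotation TSV.

    Every ortholog must have exactly one record per species (the file
    must name exactly two species overall); operons must list >= 2
    non-overlapping member genes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path}: missing columns {missing}")
    species = sorted(df["species"].unique())
    if len(species) != 2:
        raise ValueError(
            f"annotation file {path}: expected exactly 2 species, found {species}")

    units: list[OrthologUnit] = []
    for oid, grp in df.groupby("ortholog_id", sort=False):
        seen = sorted(grp["species"])
        if seen != species:
            raise ValueError(
                f"ortholog {oid}: needs exactly one record per species "
                f"{species}, found records for {seen}")
        types = set(grp["unit_type"])
        if len(types) != 1:
            raise ValueError(f"ortholog {oid}: inconsistent unit_type across species")
        member_lists = set(grp["member_gene_ids"])
        if len(member_lists) != 1:
            raise ValueError(f"ortholog {oid}: inconsistent member_gene_ids across species")
        members = [m for m in member_lists.pop().split(",") if m]
        loci = {}
        for _, row in grp.iterrows():
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError:
                raise ValueError(f"ortholog {oid}: non-integer coordinates") from None
            coords = None
            raw = row.get("member_gene_coords", "")
            if raw:
                coords = _parse_member_coords(raw, oid)
            loci[row["species"]] = UnitLocus(
                replicon=row["replicon_id"], replicon_class=row["replicon_class"],
                start=start, end=end, strand=row["strand"], member_coords=coords)
        try:
            units.append(OrthologUnit(
                ortholog_id=oid, unit_type=types.pop(), members=members, loci=loci))
        except ValueError as exc:
            raise ValueError(f"ortholog {oid}: {exc}") from None
    return units


# --------------------------------------------------------------------------
# coverage (bedGraph)
# --------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path, mode: str = "w") -> None:
    """Write one replicon's dense coverage as run-length bedGraph.

    Zero runs are omitted (the loader restores them), keeping files
    compact and round-trip exact for integer-valued tracks.
    """
    v = track.values
    with open(path, mode) as fh:
        if len(v):
            # run-length encode
            change = np.flatnonzero(np.diff(v) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(v)]))
            for s, e in zip(starts, ends):
                val = v[s]
                if val != 0:
                    val_repr = int(val) if float(val).is_integer() else repr(float(val))
                    fh.write(f"{track.replicon}\t{s}\t{e}\t{val_repr}\n")


def load_coverage(path, genome_length: int, replicon: str | None = None) -> CoverageTrack:
    """Load a single-replicon bedGraph into a dense per-base vector.

    Positions absent from the file are zero.  Intervals beyond
    ``genome_length`` or negative values are rejected.
    """
    values = np.zeros(genome_length, dtype=float)
    name = replicon
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
            chrom, s, e, val = parts
            if name is None:
                name = chrom
            elif chrom != name:
                raise ValueError(
                    f"{path}:{ln}: replicon {chrom!r} does not match {name!r}")
            s, e, val = int(s), int(e), float(val)
            if not (0 <= s < e):
                raise ValueError(f"{path}:{ln}: invalid interval [{s}, {e})")
            if e > genome_length:
                raise ValueError(
                    f"{path}:{ln}: interval end {e} beyond genome length {genome_length}")
            if val < 0:
                raise ValueError(f"{path}:{ln}: negative coverage {val}")
            values[s:e] = val
    return CoverageTrack(replicon=name if name is not None else "", values=values)


def load_coverage_set(path, lengths: dict[str, int]) -> dict[str, CoverageTrack]:
    """Load a multi-replicon bedGraph into one dense track per replicon."""
    arrays = {name: np.zeros(n, dtype=float) for name, n in lengths.items()}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, val = line.split("\t")
            if chrom not in arrays:
                raise ValueError(f"{path}:{ln}: unknown replicon {chrom!r}")
            s, e, val = int(s), int(e), float(val)
            if not (0 <= s < e) or e > lengths[chrom]:
                raise ValueError(f"{path}:{ln}: interval [{s}, {e}) out of bounds")
            if val < 0:
                raise ValueError(f"{path}:{ln}: negative coverage {val}")
            arrays[chrom][s:e] = val
    return {name: CoverageTrack(name, arr) for name, arr in arrays.items()}


# --------------------------------------------------------------------------
# gene-set catalog
# --------------------------------------------------------------------------

def load_catalog(path) -> pd.DataFrame:
    """Load a gene-set catalog TSV (category_id, ortholog_id; one pair per line)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("category_id", "ortholog_id"):
        if col not in df.columns:
            raise ValueError(f"catalog {path}: missing column {col!r}")
        if df[col].isna().any():
            bad = df.index[df[col].isna()][0]
            raise ValueError(f"catalog {path}: empty {col} at data row {bad}")
    if df.duplicated(["category_id", "ortholog_id"]).any():
        dup = df[df.duplicated(["category_id", "ortholog_id"])].iloc[0]
        raise ValueError(
            f"catalog {path}: duplicate pair ({dup.category_id}, {dup.ortholog_id})")
    return df[["category_id", "ortholog_id"]]


def write_catalog(df: pd.DataFrame, path) -> None:
    df[["category_id", "ortholog_id"]].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# results tables
# --------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, config=None, extra_comments: list[str] | None = None) -> None:
    """Write a results TSV with a leading comment block recording the config."""
    with open(path, "w") as fh:
        if config is not None:
            for key, val in sorted(config.to_dict().items()):
                fh.write(f"# {key} = {val}\n")
        for line in extra_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
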