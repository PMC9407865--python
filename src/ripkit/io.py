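"""Readers and writers for every file format the pipeline touches.

Sequence files are FASTA (via Biopython). Tabular files are
tab-separated with a mandatory header row. Optional exports are BED6
(0-based half-open) and a minimal VCF 4.2 with symbolic ``<INS>``/``<DEL>``
ALT alleles.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    DNA_ALPHABET,
    GENOTYPES,
    CandidateSV,
    GeneModel,
    GenotypeCounts,
    LocusSequence,
    RepeatConsensus,
    RipRecord,
)

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_repeat_library",
    "write_repeat_library",
    "read_gene_models",
    "write_gene_models",
    "write_rip_table",
    "write_rip_bed",
    "write_rip_vcf",
    "read_candidates",
    "write_candidates",
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotype_table",
    "read_ct_table",
    "read_luciferase_table",
    "rip_report_interval",
]


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def _parse_header_tokens(description: str) -> dict[str, str]:
    tokens = {}
    for word in description.split()[1:]:
        if "=" in word:
            key, _, value = word.partition("=")
            tokens[key] = value
    return tokens


def read_fasta(path: str | os.PathLike) -> list[LocusSequence]:
    """Read a FASTA file into :class:`LocusSequence` records.

    Sequences are uppercased. The breed label is taken from a
    ``breed=...`` token in the header when present, otherwise from the
    first header word (the record id). ``chrom=`` and ``offset=`` tokens
    restore chromosomal anchoring written by :func:`write_fasta`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-DNA symbol(s) "
                f"{sorted(bad)!r}"
            )
        tokens = _parse_header_tokens(rec.description)
        records.append(
            LocusSequence(
                name=rec.id,
                seq=seq,
                breed=tokens.get("breed", rec.id),
                offset=int(tokens.get("offset", 0)),
                chrom=tokens.get("chrom", ""),
            )
        )
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    return records


def write_fasta(records: Iterable[LocusSequence], path: str | os.PathLike) -> None:
    out = []
    for loc in records:
        desc = f"breed={loc.breed}" if loc.breed else ""
        if loc.chrom:
            desc += f" chrom={loc.chrom}"
        if loc.offset:
            desc += f" offset={loc.offset}"
        out.append(SeqRecord(Seq(loc.seq), id=loc.name, description=desc.strip()))
    SeqIO.write(out, str(path), "fasta")


def read_repeat_library(path: str | os.PathLike) -> list[RepeatConsensus]:
    """Read a consensus library FASTA; ``class=`` header token sets the class.

    Without a token the class defaults to SINE. Names must be unique.
    """
    lib = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate consensus name {rec.id!r}")
        seen.add(rec.id)
        tokens = _parse_header_tokens(rec.description)
        lib.append(
            RepeatConsensus(
                name=rec.id,
                repeat_class=tokens.get("class", "SINE"),
                seq=str(rec.seq).upper(),
            )
        )
    if not lib:
        raise FormatError(f"{path}: empty or not FASTA")
    return lib


def write_repeat_library(
    library: Iterable[RepeatConsensus], path: str | os.PathLike
) -> None:
    out = [
        SeqRecord(Seq(c.seq), id=c.name, description=f"class={c.repeat_class}")
        for c in library
    ]
    SeqIO.write(out, str(path), "fasta")


# --- gene models -----------------------------------------------------------

def read_gene_models(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Read an exon table (gene_name, strand, exon_start, exon_end) into models."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_name", "strand", "exon_start", "exon_end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: gene model table needs columns {sorted(required)}")
    models = {}
    for name, grp in df.groupby("gene_name", sort=False):
        strands = grp["strand"].unique()
        if len(strands) != 1:
            raise FormatError(f"{path}: gene {name!r} mixes strands")
        exons = sorted(zip(grp["exon_start"].astype(int), grp["exon_end"].astype(int)))
        models[str(name)] = GeneModel(str(name), str(strands[0]), tuple(exons))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    rows = [
        {"gene_name": m.gene_name, "strand": m.strand, "exon_start": s, "exon_end": e}
        for m in models
        for s, e in m.exons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- RIP reports -----------------------------------------------------------

RIP_TABLE_COLUMNS = [
    "loci",
    "feature",
    "length_bp",
    "direction",
    "type",
    "chromosome",
    "identity",
    "coverage",
    "tsd",
]


def rip_report_interval(rec: RipRecord) -> tuple[int, int]:
    """1-based inclusive report interval of a RIP on the bait frame.

    Insertions absent from the reference frame are point features
    reported as the 2-bp interval flanking the breakpoint; deletions
    (element present in the reference) span the deleted segment.
    """
    p = rec.sv.bait_pos
    if rec.sv.sv_type == "INS":
        return (max(p, 1), max(p, 1) + 1)
    return (p + 1, p + rec.sv.length)


def write_rip_table(records: Sequence[RipRecord], path: str | os.PathLike) -> None:
    """Write the annotated RIP report (tab-separated, header always present)."""
    rows = [
        {
            "loci": r.rip_name,
            "feature": r.feature_label,
            "length_bp": r.element_length,
            "direction": r.direction,
            "type": r.family,
            "chromosome": r.chrom_span,
            "identity": round(r.identity, 4),
            "coverage": round(r.insertion_coverage, 4),
            "tsd": r.tsd,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RIP_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_rip_bed(records: Sequence[RipRecord], path: str | os.PathLike) -> None:
    """BED6 export: insertion points as 1-bp features, deletions as spans."""
    with open(path, "w") as fh:
        for r in records:
            start1, end1 = rip_report_interval(r)
            if r.sv.sv_type == "INS":
                # breakpoint as the 2-bp flanking interval, clamped at origin
                bed_start, bed_end = max(r.sv.bait_pos - 1, 0), r.sv.bait_pos + 1
            else:
                bed_start, bed_end = start1 - 1, end1
            strand = r.direction if r.direction in "+-" else "."
            fh.write(
                f"{r.chrom_span.split(':')[0]}\t{bed_start}\t{bed_end}"
                f"\t{r.rip_name}\t0\t{strand}\n"
            )


def write_rip_vcf(
    records: Sequence[RipRecord], bait: LocusSequence, path: str | os.PathLike
) -> None:
    """Minimal VCF 4.2 with symbolic ALT records on the bait frame."""
    contig = bait.chrom or bait.name
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(bait.seq)}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda x: x.sv.bait_pos):
            p = r.sv.bait_pos  # VCF pads with the base before the event
            pos1 = max(p, 1)
            ref = bait.seq[pos1 - 1]
            svlen = r.sv.length if r.sv.sv_type == "INS" else -r.sv.length
            fh.write(
                f"{contig}\t{pos1}\t{r.rip_name}\t{ref}\t<{r.sv.sv_type}>\t.\t.\t"
                f"SVTYPE={r.sv.sv_type};SVLEN={svlen}\n"
            )


# --- candidate SV tables ---------------------------------------------------

def write_candidates(svs: Sequence[CandidateSV], path: str | os.PathLike) -> None:
    rows = [
        {
            "sv_type": sv.sv_type,
            "bait_pos": sv.bait_pos + 1,  # 1-based report coordinate
            "length": sv.length,
            "n_sources": len(sv.sources),
            "sources": ",".join(sorted(sv.sources)),
            "seq": sv.seq,
        }
        for sv in svs
    ]
    cols = ["sv_type", "bait_pos", "length", "n_sources", "sources", "seq"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | os.PathLike) -> list[CandidateSV]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        sources = frozenset(s for s in str(row.sources).split(",") if s)
        out.append(
            CandidateSV(
                sv_type=row.sv_type,
                bait_pos=int(row.bait_pos) - 1,
                length=int(row.length),
                seq=str(row.seq),
                sources=sources,
            )
        )
    return out


# --- genotype / phenotype / assay tables -----------------------------------

def write_genotype_table(
    rows: Sequence[tuple[str, GenotypeCounts]], path: str | os.PathLike
) -> None:
    """Rows are (locus, counts)."""
    pd.DataFrame(
        [
            {
                "breed": c.breed,
                "locus": locus,
                "n_ins_ins": c.n_ins_ins,
                "n_ins_del": c.n_ins_del,
                "n_del_del": c.n_del_del,
            }
            for locus, c in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | os.PathLike) -> list[tuple[str, GenotypeCounts]]:
    df = pd.read_csv(path, sep="\t")
    required = {"breed", "locus", "n_ins_ins", "n_ins_del", "n_del_del"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: genotype table needs columns {sorted(required)}")
    return [
        (
            str(row.locus),
            GenotypeCounts(
                breed=str(row.breed),
                n_ins_ins=int(row.n_ins_ins),
                n_ins_del=int(row.n_ins_del),
                n_del_del=int(row.n_del_del),
            ),
        )
        for row in df.itertuples(index=False)
    ]


def read_phenotype_table(path: str | os.PathLike) -> pd.DataFrame:
    """Animal-level phenotype rows: animal_id, genotype, one column per trait."""
    df = pd.read_csv(path, sep="\t")
    if "genotype" not in df.columns or "animal_id" not in df.columns:
        raise FormatError(f"{path}: phenotype table needs animal_id and genotype")
    bad = set(df["genotype"]) - set(GENOTYPES)
    if bad:
        raise FormatError(f"{path}: invalid genotype label(s) {sorted(bad)!r}")
    traits = [c for c in df.columns if c not in ("animal_id", "genotype")]
    for t in traits:
        vals = pd.to_numeric(df[t], errors="coerce")
        if not vals.map(math.isfinite).all():
            raise FormatError(f"{path}: non-finite value in trait {t!r}")
        df[t] = vals
    return df


def read_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "ct_target", "ct_reference"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: Ct table needs columns {sorted(required)}")
    for c in ("ct_target", "ct_reference"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if not ((vals > 0) & vals.map(math.isfinite)).all():
            raise FormatError(f"{path}: Ct values must be finite and > 0 ({c})")
        df[c] = vals
    return df


def read_luciferase_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"construct", "firefly", "renilla"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: luciferase table needs columns {sorted(required)}")
    if not (pd.to_numeric(df["renilla"]) > 0).all():
        raise FormatError(f"{path}: renilla readings must be positive")
    return df
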