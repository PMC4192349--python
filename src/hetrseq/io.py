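"""Readers and writers for FASTA, BED6, GFF3-lite, TSS and peak tables.

All on-disk interval formats are converted explicitly to the internal
1-based, end-exclusive convention (see :mod:`hetrseq.intervals`).
Malformed rows raise rather than being silently coerced.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomeInterval

logger = logging.getLogger("hetrseq")

PathLike = Union[str, Path]

_ACGT_RE = re.compile(r"^[ACGT]*$")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a FASTA file into ``{replicon: sequence}``.

    Sequences are uppercased.  Letters outside {A, C, G, T} are preserved
    but flagged with a warning.  Empty files and duplicate record ids are
    rejected.
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate replicon id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not _ACGT_RE.match(seq):
            logger.warning("replicon %s contains non-ACGT letters", rec.id)
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED6

class BedRecord(NamedTuple):
    interval: GenomeInterval
    name: str = "."
    score: float = 0.0


def to_bed_coords(iv: GenomeInterval) -> tuple[int, int]:
    """Internal 1-based end-exclusive -> BED 0-based half-open."""
    return iv.start - 1, iv.end - 1


def from_bed_coords(replicon: str, start: int, end: int, strand: str = ".") -> GenomeInterval:
    """BED 0-based half-open -> internal 1-based end-exclusive."""
    return GenomeInterval(replicon, start + 1, end + 1, strand)


def write_bed(records: Iterable[Union[BedRecord, GenomeInterval]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            if isinstance(rec, GenomeInterval):
                rec = BedRecord(rec, f"r{i}", 0.0)
            s0, e0 = to_bed_coords(rec.interval)
            fh.write(
                f"{rec.interval.replicon}\t{s0}\t{e0}\t{rec.name}\t{rec.score:g}\t"
                f"{rec.interval.strand}\n"
            )


def read_bed(path: PathLike) -> List[BedRecord]:
    out: List[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                replicon, s0, e0 = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            out.append(BedRecord(from_bed_coords(replicon, s0, e0, strand), name, score))
    return out


def read_alignments_bed(path: PathLike) -> List[GenomeInterval]:
    """Read aligned-read intervals; every record must carry a strand."""
    records = read_bed(path)
    for rec in records:
        if rec.interval.strand == ".":
            raise ValueError(f"{path}: alignment record {rec.name!r} lacks a strand")
    return [rec.interval for rec in records]


# ---------------------------------------------------------------------------
# GFF3 (genes + optional five_prime_UTR features)

def write_gene_models(genes: Sequence[GeneModel], path: PathLike, source: str = "hetrseq") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            # GFF3 is 1-based with an inclusive end
            fh.write(
                f"{iv.replicon}\t{source}\tgene\t{iv.start}\t{iv.end - 1}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            if g.utr5 is not None:
                u = g.utr5
                fh.write(
                    f"{u.replicon}\t{source}\tfive_prime_UTR\t{u.start}\t{u.end - 1}\t.\t"
                    f"{u.strand}\t.\tID={g.gene_id}.utr5;Parent={g.gene_id}\n"
                )


def _gff_attrs(field: str) -> Dict[str, str]:
    out = {}
    for part in field.split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gene_models(path: PathLike) -> List[GeneModel]:
    genes: Dict[str, GenomeInterval] = {}
    utrs: Dict[str, GenomeInterval] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            replicon, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            iv = GenomeInterval(replicon, int(start), int(end) + 1, strand)
            a = _gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError(f"{path}: line {lineno}: gene without ID")
                genes[gid] = iv
                order.append(gid)
            elif ftype == "five_prime_UTR":
                parent = a.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}: line {lineno}: UTR without Parent")
                utrs[parent] = iv
    models = [GeneModel(gid, genes[gid], utrs.get(gid)) for gid in order]
    models.sort(key=lambda g: (g.interval.replicon, g.interval.start))
    return models


# ---------------------------------------------------------------------------
# TSS table (replicon, position, strand)

class TSS(NamedTuple):
    replicon: str
    position: int
    strand: str


def write_tss(tss: Sequence[TSS], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("replicon\tposition\tstrand\n")
        for t in tss:
            fh.write(f"{t.replicon}\t{t.position}\t{t.strand}\n")


def read_tss(path: PathLike) -> List[TSS]:
    out: List[TSS] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["replicon", "position", "strand"]:
            raise ValueError(f"{path}: unexpected TSS header {header!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or fields[2] not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: malformed TSS row")
            out.append(TSS(fields[0], int(fields[1]), fields[2]))
    return out


# ---------------------------------------------------------------------------
# Peak tables (BED6+: fold_enrichment, min_p, support, summit)

def write_peaks(peaks, path: PathLike) -> None:
    from .peaks import Peak  # local import to avoid a cycle

    with open(path, "w") as fh:
        fh.write(
            "#replicon\tstart0\tend0\tname\tscore\tstrand\t"
            "fold_enrichment\tmin_p\tsupport\tsummit\n"
        )
        for i, pk in enumerate(peaks):
            s0, e0 = to_bed_coords(pk.interval)
            support = pk.support if pk.support is not None else -1
            fh.write(
                f"{pk.interval.replicon}\t{s0}\t{e0}\tpeak_{i}\t{pk.k_ip}\t.\t"
                f"{pk.fold_enrichment:.6g}\t{pk.min_p:.6g}\t{support}\t{pk.summit}\n"
            )


def read_peaks(path: PathLike):
    from .peaks import Peak

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 10:
                raise ValueError(f"{path}: line {lineno}: expected 10 peak columns")
            iv = from_bed_coords(f[0], int(f[1]), int(f[2]))
            support: Optional[int] = int(f[8])
            if support < 0:
                support = None
            out.append(
                Peak(
                    interval=iv,
                    k_ip=int(f[4]),
                    k_ctrl_norm=0.0,
                    fold_enrichment=float(f[6]),
                    min_p=float(f[7]),
                    summit=int(f[9]),
                    support=support,
                )
            )
    return out
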