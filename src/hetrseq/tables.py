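"""Curated-region and expression tables, with their sentinel domains.

Fold-change cells form a closed domain: a signed numeric fold (|value|
>= 1; negative means lower in the hetR-null mutant), or one of the
sentinels ``NA``, ``Low coverage`` and ``n / 0`` (n wild-type reads
dropping to zero mutant reads, which compares as infinite magnitude).
Sentinels are never silently treated as numbers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib.resources import files
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from .intervals import GenomeInterval

PathLike = Union[str, Path]

_ZERO_MUTANT_RE = re.compile(r"^(\d+)\s*/\s*0$")


class Proximity(Enum):
    """Peak-to-gene proximity categories.

    These map one-to-one onto the curated-region table's footnote codes:
    no footnote = within 500 bp upstream of the ORF, ``c`` = downstream
    of a potential TSS, ``d`` = more than 500 bp upstream, ``b`` = not
    applicable (the peak cannot regulate the ORF).
    """

    WITHIN_500BP_UPSTREAM = "-"
    DOWNSTREAM_OF_TSS = "c"
    BEYOND_500BP_UPSTREAM = "d"
    NOT_APPLICABLE = "b"


FOOTNOTE_TO_PROXIMITY = {p.value: p for p in Proximity}


@dataclass(frozen=True)
class FoldChange:
    """A signed expression fold change or one of its sentinels.

    ``kind`` is one of ``'value'``, ``'na'``, ``'low_coverage'`` or
    ``'zero_mutant'``.  ``magnitude`` is ``abs(value)`` for numeric
    entries, ``inf`` for ``zero_mutant``, and ``None`` when the fold is
    indeterminate.
    """

    kind: str
    value: Optional[float] = None
    wt_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("value", "na", "low_coverage", "zero_mutant"):
            raise ValueError(f"unknown fold-change kind {self.kind!r}")
        if self.kind == "value":
            if self.value is None or abs(self.value) < 1.0 - 1e-9:
                raise ValueError(
                    f"signed fold changes have magnitude >= 1, got {self.value!r}"
                )
        if self.kind == "zero_mutant" and (self.wt_reads is None or self.wt_reads <= 0):
            raise ValueError("zero_mutant sentinel requires a positive WT read count")

    @property
    def magnitude(self) -> Optional[float]:
        if self.kind == "value":
            return abs(self.value)  # type: ignore[arg-type]
        if self.kind == "zero_mutant":
            return math.inf
        return None

    @property
    def is_sentinel(self) -> bool:
        return self.kind != "value"

    @classmethod
    def parse(cls, token: str) -> "FoldChange":
        token = token.strip().replace("−", "-")
        if token in ("NA", "--", ""):
            return cls("na")
        if token == "Low coverage":
            return cls("low_coverage")
        m = _ZERO_MUTANT_RE.match(token)
        if m:
            return cls("zero_mutant", wt_reads=int(m.group(1)))
        try:
            value = float(token)
        except ValueError as exc:
            raise ValueError(f"unknown fold-change token {token!r}") from exc
        return cls("value", value=value)

    def format(self) -> str:
        if self.kind == "na":
            return "NA"
        if self.kind == "low_coverage":
            return "Low coverage"
        if self.kind == "zero_mutant":
            return f"{self.wt_reads} / 0"
        return f"{self.value:g}"


@dataclass
class ExpressionRecord:
    """Signed RPKM fold changes for one gene, WT vs hetR-null mutant."""

    gene_id: str
    fc_0h: FoldChange
    fc_6h: FoldChange
    wt_timecourse: Dict[str, FoldChange] = field(default_factory=dict)


@dataclass
class CuratedRegion:
    """One curated-region-table row: a ChIP peak with flanking-gene context."""

    interval: GenomeInterval
    gene_left: Optional[str]
    fc_left: FoldChange
    gene_right: Optional[str]
    fc_right: FoldChange
    proximity_left: Proximity
    proximity_right: Proximity
    has_binding_site: bool
    region_id: str = ""
    printed_length: Optional[int] = None
    end_reliable: bool = True
    audit: Optional[dict] = None


# ---------------------------------------------------------------------------
# Region table I/O (Table-1 schema)

_REGION_COLUMNS = [
    "region_id",
    "start",
    "end",
    "length_bp",
    "gene_left",
    "footnote_left",
    "fc_left",
    "gene_right",
    "footnote_right",
    "fc_right",
    "binding_site",
    "end_reliable",
]


def read_region_table(path: PathLike, replicon: str = "chromosome") -> List[CuratedRegion]:
    """Parse a curated-region TSV into :class:`CuratedRegion` records.

    The header must match the documented schema; malformed rows raise a
    :class:`ValueError` naming the line number.
    """
    regions: List[CuratedRegion] = []
    with open(path) as fh:
        lineno = 0
        header: Optional[List[str]] = None
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != _REGION_COLUMNS:
                    raise ValueError(f"{path}: unexpected region-table header {header!r}")
                continue
            fields = line.split("\t")
            if len(fields) != len(_REGION_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: expected {len(_REGION_COLUMNS)} columns")
            row = dict(zip(_REGION_COLUMNS, fields))
            try:
                region = CuratedRegion(
                    interval=GenomeInterval(replicon, int(row["start"]), int(row["end"])),
                    gene_left=row["gene_left"] or None,
                    fc_left=FoldChange.parse(row["fc_left"]),
                    gene_right=row["gene_right"] or None,
                    fc_right=FoldChange.parse(row["fc_right"]),
                    proximity_left=FOOTNOTE_TO_PROXIMITY[row["footnote_left"]],
                    proximity_right=FOOTNOTE_TO_PROXIMITY[row["footnote_right"]],
                    has_binding_site={"Yes": True, "No": False}[row["binding_site"]],
                    region_id=row["region_id"],
                    printed_length=int(row["length_bp"]),
                    end_reliable={"y": True, "n": False}[row["end_reliable"]],
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from exc
            regions.append(region)
    return regions


def write_region_table(regions: Sequence[CuratedRegion], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REGION_COLUMNS) + "\n")
        for r in regions:
            fh.write(
                "\t".join(
                    [
                        r.region_id,
                        str(r.interval.start),
                        str(r.interval.end),
                        str(r.printed_length if r.printed_length is not None else r.interval.length),
                        r.gene_left or "",
                        r.proximity_left.value,
                        r.fc_left.format(),
                        r.gene_right or "",
                        r.proximity_right.value,
                        r.fc_right.format(),
                        "Yes" if r.has_binding_site else "No",
                        "y" if r.end_reliable else "n",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expression table I/O (Table-2 schema)

_EXPR_REQUIRED = ["gene_id", "fc_wt0_vs_hetr0", "fc_wt6_vs_hetr6"]
_EXPR_TIMECOURSE = ["fc_wt0_vs_wt6", "fc_wt0_vs_wt12", "fc_wt0_vs_wt21"]


def read_expression_table(path: PathLike) -> List[ExpressionRecord]:
    records: List[ExpressionRecord] = []
    with open(path) as fh:
        lineno = 0
        header: Optional[List[str]] = None
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                missing = [c for c in _EXPR_REQUIRED if c not in header]
                if missing:
                    raise ValueError(f"{path}: expression header missing columns {missing}")
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}: line {lineno}: column count mismatch")
            row = dict(zip(header, fields))
            try:
                timecourse = {
                    col: FoldChange.parse(row[col]) for col in _EXPR_TIMECOURSE if col in row
                }
                records.append(
                    ExpressionRecord(
                        gene_id=row["gene_id"],
                        fc_0h=FoldChange.parse(row["fc_wt0_vs_hetr0"]),
                        fc_6h=FoldChange.parse(row["fc_wt6_vs_hetr6"]),
                        wt_timecourse=timecourse,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from exc
    return records


def write_expression_table(records: Sequence[ExpressionRecord], path: PathLike) -> None:
    timecourse_cols = sorted({c for r in records for c in r.wt_timecourse})
    with open(path, "w") as fh:
        fh.write("\t".join(_EXPR_REQUIRED + timecourse_cols) + "\n")
        for r in records:
            row = [r.gene_id, r.fc_0h.format(), r.fc_6h.format()]
            row += [r.wt_timecourse.get(c, FoldChange("na")).format() for c in timecourse_cols]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Category annotations (gene_id, category); genes may carry several rows

def read_category_annotations(path: PathLike) -> Dict[str, set]:
    out: Dict[str, set] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "category"]:
            raise ValueError(f"{path}: unexpected annotation header {header!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: line {lineno}: malformed annotation row")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def write_category_annotations(annotations: Dict[str, set], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\n")
        for gene in sorted(annotations):
            for cat in sorted(annotations[gene]):
                fh.write(f"{gene}\t{cat}\n")


# ---------------------------------------------------------------------------
# Packaged fixtures

def packaged_region_table() -> List[CuratedRegion]:
    """The curated HetR ChIP peak-region table shipped with the package."""
    return read_region_table(files("hetrseq.data") / "table1_regions.tsv")


def packaged_expression_table() -> List[ExpressionRecord]:
    """The candidate-target expression table shipped with the package."""
    return read_expression_table(files("hetrseq.data") / "table2_expression.tsv")
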