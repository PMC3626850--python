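"""Data model and I/O for ultraconserved regions and host-gene exon annotation.

An ultraconserved region (UCR) is a genomic segment of at least 200 bp with
perfect human/mouse/rat sequence identity.  Each UCR can give rise to two
transcripts (T-UCRs), one per genomic strand, and is classified by its
position relative to a protein-coding "host" gene: intergenic, intronic,
exonic or partly exonic.  All coordinates are 0-based half-open (BED
convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REGION_CLASSES = ("intergenic", "intronic", "exonic", "partly_exonic", "unclassified")

#: minimum length of an ultraconserved region, by definition
MIN_UCR_LENGTH = 200

_MISSING = {"", "0", ".", "na", "nan", "none"}


@dataclass
class UCRegion:
    """One ultraconserved region.

    Parameters
    ----------
    id:
        Region identifier, e.g. ``"uc.300a"``.
    chrom, start, end:
        Genomic interval, 0-based half-open.
    region_class:
        One of :data:`REGION_CLASSES`.
    host_gene, host_strand:
        Host gene symbol and its transcriptional strand for intragenic
        regions; ``None`` for intergenic regions.
    orientation:
        Optional orientation of the region's transcript of interest relative
        to the host gene (``"sense"`` / ``"anti-sense"``), as printed in
        published region tables.  Purely descriptive.
    short_flag:
        Set when the interval is shorter than the 200 bp UCR definition
        (tolerated for toy-scale fixtures, flagged).
    """

    id: str
    chrom: str
    start: int
    end: int
    region_class: str = "unclassified"
    host_gene: str | None = None
    host_strand: str | None = None
    orientation: str | None = None
    short_flag: bool = False

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"region {self.id}: unknown region_class {self.region_class!r}"
            )
        if self.end <= self.start:
            raise ValueError(
                f"region {self.id}: degenerate interval [{self.start}, {self.end})"
            )
        if self.region_class == "intergenic":
            if self.host_gene is not None:
                raise ValueError(f"region {self.id}: intergenic but host_gene set")
        elif self.region_class != "unclassified":
            if self.host_gene is None or self.host_strand is None:
                raise ValueError(
                    f"region {self.id}: intragenic regions need host_gene and host_strand"
                )
        if self.host_strand is not None and self.host_strand not in ("+", "-"):
            raise ValueError(f"region {self.id}: bad host_strand {self.host_strand!r}")
        if self.length < MIN_UCR_LENGTH and not self.short_flag:
            logger.warning(
                "region %s is %d bp, below the %d bp UCR definition",
                self.id, self.length, MIN_UCR_LENGTH,
            )
            self.short_flag = True

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_intragenic(self) -> bool:
        return self.host_gene is not None

    @property
    def orientation_strand(self) -> str:
        """Strand defining 'upstream'/'downstream' for the tiled window.

        The host-gene strand for intragenic regions, the + genomic strand
        otherwise.
        """
        return self.host_strand if self.host_strand is not None else "+"


REGION_COLUMNS = [
    "chrom", "start", "end", "id", "region_class",
    "host_gene", "host_strand", "orientation",
]


def _opt(value) -> str | None:
    s = str(value).strip()
    return None if s.lower() in _MISSING else s


def read_regions(path: str | Path) -> list[UCRegion]:
    """Read UCR regions from an 8-column tab-separated file.

    Columns: chrom, start, end, id, region_class, host_gene, host_strand,
    orientation (BED-style extension; a header line is detected and skipped).
    Duplicate ids and degenerate intervals are rejected; sub-200 bp rows are
    accepted with a warning flag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=REGION_COLUMNS, dtype=str,
        comment="#", skip_blank_lines=True,
    )
    if df.empty:
        logger.warning("region file %s is empty", path)
        return []
    # tolerate a header line
    if df.iloc[0]["chrom"].lower() == "chrom":
        df = df.iloc[1:]
    if df.empty:
        logger.warning("region file %s holds no region rows", path)
        return []
    regions: list[UCRegion] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        rid = str(row["id"]).strip()
        if rid in seen:
            raise ValueError(f"duplicate region id {rid!r} in {path}")
        seen.add(rid)
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"region {rid}: non-numeric coordinates") from exc
        regions.append(
            UCRegion(
                id=rid,
                chrom=str(row["chrom"]).strip(),
                start=start,
                end=end,
                region_class=str(row["region_class"]).strip(),
                host_gene=_opt(row["host_gene"]),
                host_strand=_opt(row["host_strand"]),
                orientation=_opt(row["orientation"]),
            )
        )
    return regions


def regions_to_frame(regions: Iterable[UCRegion]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom, "start": r.start, "end": r.end, "id": r.id,
            "region_class": r.region_class,
            "host_gene": r.host_gene or "0",
            "host_strand": r.host_strand or "0",
            "orientation": r.orientation or "0",
        }
        for r in regions
    ]
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def write_regions(regions: Iterable[UCRegion], path: str | Path) -> None:
    """Write regions as headered TSV; round-trips bit-exactly with read_regions."""
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


@dataclass
class ExonAnnotation:
    """Merged exon intervals of one host gene (0-based half-open)."""

    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene}: strand must be + or -")
        self.exons = merge_intervals(self.exons)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals, sorted by start."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if e <= s:
            raise ValueError(f"degenerate exon interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_exons(path: str | Path) -> list[ExonAnnotation]:
    """Read host-gene exon annotation from BED6 (one exon per row, gene in the
    name column) or GFF3 (``exon`` features grouped by the Parent/gene ID)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_exons_gff3(path)
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str, "gene": str, "strand": str},
    )
    if not df.empty and str(df.iloc[0]["chrom"]).lower() == "chrom":
        df = df.iloc[1:].reset_index(drop=True)
    out = []
    for (gene, chrom, strand), grp in df.groupby(["gene", "chrom", "strand"], sort=True):
        out.append(
            ExonAnnotation(
                gene=gene, chrom=chrom, strand=strand,
                exons=[(int(s), int(e)) for s, e in zip(grp["start"], grp["end"])],
            )
        )
    return out


def _read_exons_gff3(path: Path) -> list[ExonAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_gene: dict[str, ExonAnnotation] = {}
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("gene_id") or feat.attributes.get("Parent") or ["?"]
        gene = parents[0]
        # GFF is 1-based closed; convert to 0-based half-open
        iv = (feat.start - 1, feat.end)
        if gene in by_gene:
            by_gene[gene].exons = merge_intervals(by_gene[gene].exons + [iv])
        else:
            by_gene[gene] = ExonAnnotation(gene, feat.seqid, feat.strand, [iv])
    return list(by_gene.values())


def write_exons(exons: Iterable[ExonAnnotation], path: str | Path) -> None:
    """Write exon annotation as BED6 (one exon per row)."""
    rows = [
        (a.chrom, s, e, a.gene, 0, a.strand)
        for a in exons
        for s, e in a.exons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
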