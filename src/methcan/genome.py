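"""Genomic interval model, gene/probe annotations, and readers for BED-family formats.

All coordinates are 0-based half-open throughout the package; BED and bedGraph
are native in this convention, and any 1-based input must be converted at the
reader boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

VALID_STRANDS = {"+", "-", "."}


class BedFormatError(ValueError):
    """Raised for a malformed record in a BED/bedGraph file (carries line number)."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")

    def __len__(self) -> int:
        return self.end - self.start

    def intersects(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene: TSS, strand and ordered non-overlapping exons.

    The TSS coincides with the 5' end of the first exon on the annotated
    strand; exons are stored in genomic (left-to-right) order.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError("gene strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) is empty")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e
        expected_tss = self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1
        if self.tss != expected_tss:
            raise ValueError(
                f"gene {self.gene_id}: TSS {self.tss} does not match 5' end "
                f"of first exon ({expected_tss})"
            )

    @property
    def body_span(self) -> GenomicInterval:
        """Interval from the start of the first exon to the end of the last."""
        return GenomicInterval(self.chrom, self.exons[0][0], self.exons[-1][1], self.strand)

    @property
    def first_exon(self) -> tuple[int, int]:
        """First exon in transcription order."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]


class IntervalSet:
    """Collection of intervals indexed by chromosome with fast overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._intervals.append(iv)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def overlaps(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        return sorted(hits, key=lambda x: (x.chrom, x.start, x.end))

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self):
        return iter(sorted(self._intervals, key=lambda x: (x.chrom, x.start, x.end)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)


@dataclass
class ProbeManifest:
    """450k-style probe manifest: probe positions and region memberships.

    ``table`` has one row per (probe, assignment) with columns:
    probe_id, chrom, pos, gene_id, region_class ('TSS200' or 'Body'), cgi_id.
    A probe may map to several regions; gene_id/cgi_id may be empty strings.
    """

    table: pd.DataFrame
    REGION_CLASSES = ("TSS200", "Body")

    def __post_init__(self):
        required = {"probe_id", "chrom", "pos", "gene_id", "region_class", "cgi_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        bad = set(self.table["region_class"]) - {*self.REGION_CLASSES, ""}
        if bad:
            raise ValueError(f"unknown region_class values: {sorted(bad)}")

    def probes_for_gene(self, gene_id: str, region_class: str) -> list[str]:
        t = self.table
        sel = (t["gene_id"] == gene_id) & (t["region_class"] == region_class)
        return t.loc[sel, "probe_id"].tolist()

    def probes_for_cgi(self, cgi_id: str) -> list[str]:
        return self.table.loc[self.table["cgi_id"] == cgi_id, "probe_id"].tolist()

    def region_members(self, region_class: str) -> pd.Series:
        """Mapping region id -> list of member probe ids.

        region_class 'promoter' uses TSS200 assignments, 'gene_body' uses Body
        assignments, 'cgi' groups by cgi_id.
        """
        t = self.table
        if region_class == "promoter":
            sub = t[t["region_class"] == "TSS200"]
            return sub.groupby("gene_id")["probe_id"].apply(list)
        if region_class == "gene_body":
            sub = t[t["region_class"] == "Body"]
            return sub.groupby("gene_id")["probe_id"].apply(list)
        if region_class == "cgi":
            sub = t[t["cgi_id"] != ""]
            return sub.groupby("cgi_id")["probe_id"].apply(list)
        raise ValueError(f"unknown region_class {region_class!r}")


# ---------------------------------------------------------------------------
# Window / region operations
# ---------------------------------------------------------------------------

def promoter_window(gene: GeneAnnotation, w: int, mode: str = "symmetric") -> GenomicInterval:
    """Promoter window around the TSS.

    mode='symmetric': [tss-w, tss+w), strand-agnostic (clipped at 0).
    mode='upstream_only': the w bp upstream of the TSS in transcription
    direction — [tss-w, tss) on '+', reflected to [tss, tss+w) on '-'.
    """
    if w <= 0:
        raise ValueError("window size must be positive")
    if mode == "symmetric":
        return GenomicInterval(gene.chrom, max(0, gene.tss - w), gene.tss + w, ".")
    if mode == "upstream_only":
        if gene.strand == "+":
            return GenomicInterval(gene.chrom, max(0, gene.tss - w), gene.tss, "+")
        return GenomicInterval(gene.chrom, gene.tss, gene.tss + w, "-")
    raise ValueError(f"unknown promoter window mode {mode!r}")


def gene_body_interval(gene: GeneAnnotation, mode: str = "with_introns") -> list[GenomicInterval]:
    """Gene-body region(s) under the two definitions in use.

    mode='with_introns': one interval from the first exon to the last,
    introns included.  mode='exons_after_first': the exon intervals from the
    end of the first (transcription-order) exon onward, introns excluded; a
    single-exon gene yields an empty list.
    """
    if mode == "with_introns":
        return [gene.body_span]
    if mode == "exons_after_first":
        if len(gene.exons) < 2:
            return []
        if gene.strand == "+":
            rest = gene.exons[1:]
        else:
            rest = gene.exons[:-1]
        return [GenomicInterval(gene.chrom, s, e, gene.strand) for s, e in rest]
    raise ValueError(f"unknown gene body mode {mode!r}")


def overlaps(iv: GenomicInterval, interval_set: IntervalSet) -> bool:
    """True iff ``iv`` intersects any interval in the set (half-open semantics)."""
    return interval_set.overlaps(iv)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> IntervalSet:
    """Read a 3+ column BED file (0-based half-open) into an IntervalSet.

    ``track``/``browser``/``#`` lines and blank lines are skipped; a record
    with end <= start raises :class:`BedFormatError` with its line number.
    """
    out = IntervalSet()
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"expected >=3 tab-separated fields, got {len(fields)}", ln)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"non-integer coordinate: {exc}", ln) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            if start < 0 or end <= start:
                raise BedFormatError(f"invalid interval [{start}, {end})", ln)
            out.add(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(interval_set: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in interval_set:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write genes as a tab-separated table with comma-listed exon bounds."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        genes.append(
            GeneAnnotation(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
                exons=tuple(zip(starts, ends)),
            )
        )
    return genes


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> ProbeManifest:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"probe_id": str, "chrom": str, "gene_id": str, "region_class": str, "cgi_id": str},
        keep_default_na=False,
    )
    df["pos"] = df["pos"].astype(int)
    return ProbeManifest(df)
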