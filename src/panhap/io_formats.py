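"""Readers and writers for the tabular formats the pipeline consumes.

All internal coordinates are 1-based and inclusive, matching MUMmer
show-coords and BLAST conventions. BED is the only 0-based, half-open
surface, and the conversion happens exclusively in :func:`write_bed_blocks`
and :func:`read_bed_blocks`.

Reverse-strand alignments are kept lossless: a query interval with
``query_start > query_end`` encodes the minus strand, exactly as
show-coords prints it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

#: column order of the show-coords tabular dialect we accept
#: (``show-coords -T -l`` minus the LEN_R/LEN_Q columns)
COORDS_COLUMNS = [
    "ref_start", "ref_end", "query_start", "query_end",
    "len1", "len2", "identity_pct", "ref_name", "query_name",
]

#: 13-column BLAST tabular dialect: standard outfmt-6 minus evalue, plus
#: per-HSP N counts for the aligned query/subject sequence
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "bitscore", "qNs", "sNs",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise alignment segment between a reference and a query.

    ``mismatches`` counts SNP plus small-indel columns; ``n_count`` counts N
    positions within the aligned span. ``identity_pct`` is the match
    fraction, 100*(1 - mismatches/aln_length).
    """

    ref_name: str
    query_name: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    aln_length: int
    mismatches: int = 0
    n_count: int = 0
    identity_pct: float = 100.0

    def __post_init__(self):
        if self.ref_end < self.ref_start:
            raise ValueError(
                f"ref_end {self.ref_end} < ref_start {self.ref_start}")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not 0 <= self.mismatches <= self.aln_length:
            raise ValueError("mismatches outside [0, aln_length]")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0, 100]")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def ref_midpoint(self) -> int:
        return (self.ref_start + self.ref_end) // 2

    @property
    def is_reverse(self) -> bool:
        return self.query_start > self.query_end


@dataclass(frozen=True)
class GeneProjection:
    """Placement of a reference gene model on one assembly."""

    gene_id: str
    assembly: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    ref_rank: int = 0
    multi_projection: bool = False

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")


@dataclass(frozen=True)
class SnpRecord:
    """A SNP between the reference and one query assembly."""

    ref_chrom: str
    ref_pos: int
    ref_allele: str
    alt_allele: str
    query_assembly: str
    flank_seq: str | None = None


@dataclass
class GenotypeMatrix:
    """Line x marker call matrix with marker genomic metadata.

    ``calls`` is a pandas DataFrame indexed by line id with one column per
    marker id; cells hold allele codes (``0``/``1`` strings or IUPAC bases)
    with NaN for missing. ``markers`` carries (marker_id, chrom, pos_bp)
    in column order, positions non-decreasing within a chromosome.
    """

    markers: list[tuple[str, str, int]]
    calls: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        ids = [m[0] for m in self.markers]
        if list(self.calls.columns) != ids:
            raise ValueError("marker metadata does not match call columns")
        bychrom: dict[str, int] = {}
        for _, chrom, pos in self.markers:
            if pos < bychrom.get(chrom, 0):
                raise ValueError(
                    f"marker positions decrease within chromosome {chrom}")
            bychrom[chrom] = pos

    @property
    def lines(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return [m[0] for m in self.markers]

    def restrict(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """Sub-matrix of markers within [start, end] on ``chrom``."""
        kept = [m for m in self.markers if m[1] == chrom and start <= m[2] <= end]
        return GenotypeMatrix(kept, self.calls[[m[0] for m in kept]].copy())


class ParseError(ValueError):
    """Malformed row in an input file; message names the line number."""


def _is_header(fields: list[str]) -> bool:
    # show-coords prefixes output with the command line, a blank line and
    # a [S1] [E1] ... header; tolerate any row whose first field is not an int
    try:
        int(fields[0])
        return False
    except ValueError:
        return True


def read_coords(path) -> list[AlignmentRecord]:
    """Parse a show-coords ``-T`` style tabular file.

    Mismatch counts are reconstructed from the printed %IDY and LEN1
    (``round(len1 * (1 - idy/100))``), which is exact for files we write
    ourselves and a faithful inverse of MUMmer's own rounding otherwise.
    """
    records: list[AlignmentRecord] = []
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if _is_header(fields):
                continue
            if len(fields) < len(COORDS_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected >= "
                    f"{len(COORDS_COLUMNS)} columns, got {len(fields)}")
            n_data += 1
            try:
                s1, e1, s2, e2 = (int(x) for x in fields[:4])
                len1, len2 = int(fields[4]), int(fields[5])
                idy = float(fields[6])
                ref_name, query_name = fields[7], fields[8]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            aln_length = max(len1, len2)
            mismatches = int(round(aln_length * (1.0 - idy / 100.0)))
            records.append(AlignmentRecord(
                ref_name=ref_name, query_name=query_name,
                ref_start=s1, ref_end=e1, query_start=s2, query_end=e2,
                aln_length=aln_length, mismatches=mismatches,
                identity_pct=idy))
    if n_data == 0:
        logger.warning("%s: no data rows", path)
    return records


def write_coords(records: list[AlignmentRecord], path) -> None:
    """Emit records in the show-coords tabular dialect read by read_coords."""
    with open(path, "w") as fh:
        fh.write("\t".join(
            ["[S1]", "[E1]", "[S2]", "[E2]", "[LEN 1]", "[LEN 2]",
             "[% IDY]", "[REF TAG]", "[QUERY TAG]"]) + "\n")
        for r in records:
            qlen = abs(r.query_end - r.query_start) + 1
            fh.write("\t".join(map(str, [
                r.ref_start, r.ref_end, r.query_start, r.query_end,
                r.aln_length, qlen, f"{r.identity_pct:.6f}",
                r.ref_name, r.query_name])) + "\n")


def read_blast_tab(path) -> pd.DataFrame:
    """Read the 13-column BLAST tabular dialect (no filtering, no HSP choice).

    Returns a DataFrame with one row per HSP; selection of the largest HSP
    per gene pair happens downstream in gene_window_blocks.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=BLAST_COLUMNS, dtype={"qseqid": str, "sseqid": str})
    except pd.errors.EmptyDataError:
        logger.warning("%s: no data rows", path)
        return pd.DataFrame(columns=BLAST_COLUMNS)
    if df.shape[1] != len(BLAST_COLUMNS):
        raise ParseError(
            f"{path}: expected 13 tab-separated columns "
            f"({' '.join(BLAST_COLUMNS)})")
    # a malformed row surfaces as NaN in a required integer column
    bad = df["length"].isna() | df["pident"].isna()
    if bad.any():
        raise ParseError(
            f"{path}: malformed row(s) at data line(s) "
            f"{[i + 1 for i in df.index[bad][:5].tolist()]}")
    return df


def write_blast_tab(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=BLAST_COLUMNS, float_format="%.6f")


def read_gff3_projections(path, assembly: str) -> list[GeneProjection]:
    """Load gene features from a GFF3 projection file for one assembly.

    ``ref_rank`` is assigned per chromosome by sorting gene start
    coordinates; genes appearing more than once (multi-projection) are all
    kept and flagged so downstream filters can remove them.
    """
    rows = []
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end,
                     feat.strand if feat.strand in "+-" else "+"))
    counts: dict[str, int] = {}
    for gid, *_ in rows:
        counts[gid] = counts.get(gid, 0) + 1
    out: list[GeneProjection] = []
    by_chrom: dict[str, list] = {}
    for row in rows:
        by_chrom.setdefault(row[1], []).append(row)
    for chrom, crows in by_chrom.items():
        crows.sort(key=lambda r: (r[2], r[3], r[0]))
        for rank, (gid, _, start, end, strand) in enumerate(crows, 1):
            out.append(GeneProjection(
                gene_id=gid, assembly=assembly, chrom=chrom,
                start=start, end=end, strand=strand, ref_rank=rank,
                multi_projection=counts[gid] > 1))
    return out


def write_gff3_projections(projections: list[GeneProjection], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in sorted(projections, key=lambda p: (p.chrom, p.start)):
            fh.write("\t".join([
                p.chrom, "panhap", "gene", str(p.start), str(p.end),
                ".", p.strand, ".", f"ID={p.gene_id}"]) + "\n")


# --- BED surface (the only 0-based, half-open convention in the package) ---

def write_bed_blocks(blocks, path) -> None:
    """Write PairwiseBlock-like objects to BED.

    Internal 1-based inclusive [start, end] maps to BED [start-1, end); the
    name field is ``ref|query|source|binsize``.
    """
    rows = sorted(blocks, key=lambda b: (b.chrom, b.start, b.end))
    with open(path, "w") as fh:
        fh.write('track name="panhap_blocks"\n')
        for b in rows:
            bin_size = getattr(b, "bin_size", None)
            name = "|".join([b.ref_cultivar, b.query_cultivar, b.source,
                             str(bin_size if bin_size is not None else ".")])
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{name}\n")


def read_bed_blocks(path):
    """Read BED written by write_bed_blocks back into PairwiseBlock objects."""
    from .nucmer_blocks import PairwiseBlock  # local import avoids a cycle

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >=4 columns")
            chrom, start0, end, name = fields[:4]
            ref, query, source, bin_s = (name.split("|") + ["."] * 4)[:4]
            out.append(PairwiseBlock(
                ref_cultivar=ref, query_cultivar=query, chrom=chrom,
                start=int(start0) + 1, end=int(end), source=source,
                bin_size=None if bin_s == "." else int(bin_s)))
    return out


def read_snp_tsv(path) -> list[SnpRecord]:
    """Read a SNP table (ref_chrom, ref_pos, ref_allele, alt_allele, query;
    tab-separated with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"ref_chrom": str,
                                            "query": str})
    return [SnpRecord(ref_chrom=str(r.ref_chrom), ref_pos=int(r.ref_pos),
                      ref_allele=str(r.ref_allele),
                      alt_allele=str(r.alt_allele),
                      query_assembly=str(r.query))
            for r in df.itertuples()]


def read_genotype_tsv(path, marker_positions=None) -> GenotypeMatrix:
    """Read a genotype TSV: first column line id, remaining columns markers.

    ``marker_positions`` optionally maps marker id -> (chrom, pos_bp); when
    absent, markers get chrom "." and increasing dummy positions.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     na_values=["NA", "", "."])
    df.index = df.index.astype(str)
    markers = []
    for i, mid in enumerate(df.columns):
        if marker_positions and mid in marker_positions:
            chrom, pos = marker_positions[mid]
        else:
            chrom, pos = ".", i + 1
        markers.append((str(mid), chrom, int(pos)))
    return GenotypeMatrix(markers, df)


def write_genotype_tsv(matrix: GenotypeMatrix, path) -> None:
    matrix.calls.to_csv(path, sep="\t", index_label="line", na_rep="NA")
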