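"""Input/output for genomes, gene models, tag files and auxiliary tables.

All coordinates are 0-based half-open internally (BED convention).  GFF3 is
converted at the boundary.  Tag files are BED3+; strand is taken from column
6 when present and defaults to ``+``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRANDS = ("+", "-")
# unicode minus occasionally appears in hand-edited tables
_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}


class InputError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class GenomeModel:
    """Chromosome names/lengths plus an optional heterochromatin mask.

    The mask is a set of half-open intervals flagged heterochromatic; the
    complement is the euchromatic analysis space.
    """

    chromosomes: list[tuple[str, int]]
    het_mask: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InputError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise InputError(f"non-positive length for chromosome {name!r}")
        if len(self.het_mask):
            self.het_mask = normalize_intervals(self.het_mask)
            lengths = self.lengths
            for row in self.het_mask.itertuples():
                if row.chrom not in lengths:
                    raise InputError(f"mask interval on unknown chromosome {row.chrom!r}")
                if row.start < 0 or row.end > lengths[row.chrom] or row.start >= row.end:
                    raise InputError(
                        f"mask interval {row.chrom}:{row.start}-{row.end} outside chromosome"
                    )

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def with_mask(self, mask: pd.DataFrame) -> "GenomeModel":
        return GenomeModel(list(self.chromosomes), mask)


def normalize_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort intervals by (chrom, start) and merge overlapping/adjacent ones."""
    if not len(df):
        return df.reset_index(drop=True)
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    out: list[tuple[str, int, int]] = []
    for row in df.itertuples():
        if out and out[-1][0] == row.chrom and row.start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (prev[0], prev[1], max(prev[2], row.end))
        else:
            out.append((row.chrom, int(row.start), int(row.end)))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


@dataclass(frozen=True)
class GeneModel:
    """One gene interval with strand-derived TSS and polyA anchors.

    ``tss`` is the 5'-most transcribed base; ``polyA`` is the 3'-most base of
    the annotation, the only polyadenylation proxy derivable from a gene model.
    One interval per gene id: callers must pre-collapse isoforms.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise InputError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        if not self.start < self.end:
            raise InputError(f"gene {self.gene_id}: start >= end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def polyA(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class TagSet:
    """Mapped sequencing tags for one sample.

    ``tags`` holds columns chrom, start, end, strand.  ``total_unique`` is the
    tag count after optional deduplication of identical
    (chrom, start, end, strand) records; ``n_excluded`` counts records dropped
    because they fell on undeclared chromosomes or outside chromosome bounds.
    """

    sample_id: str
    tags: pd.DataFrame
    total_unique: int
    n_excluded: int = 0


def read_chrom_sizes(path: str | Path) -> GenomeModel:
    """Read a UCSC-style two-column chrom.sizes file (name, length)."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise InputError(f"{path}: malformed line {lineno}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise InputError(f"{path}: non-integer length on line {lineno}") from None
            if name in seen:
                raise InputError(f"{path}: duplicate chromosome {name!r} on line {lineno}")
            if length <= 0:
                raise InputError(f"{path}: non-positive length on line {lineno}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise InputError(f"{path}: no chromosomes")
    return GenomeModel(chroms)


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a (chrom, start, end[, name, score, strand]) frame."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] < 3:
        raise InputError(f"{path}: BED needs at least 3 columns")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = raw.iloc[:, : min(6, raw.shape[1])].copy()
    df.columns = names[: df.shape[1]]
    for col in names[df.shape[1]:]:
        df[col] = np.nan
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except (ValueError, TypeError):
        raise InputError(f"{path}: unparseable interval") from None
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def read_mask(path: str | Path, genome: GenomeModel) -> GenomeModel:
    """Attach a heterochromatin mask (BED) to a genome model."""
    bed = read_bed_intervals(path)[["chrom", "start", "end"]]
    return genome.with_mask(bed)


def _parse_gff3_genes(path: str | Path) -> pd.DataFrame:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#", dtype={"seqid": str})
    df = df[df["type"] == "gene"].copy()
    if not len(df):
        raise InputError(f"{path}: no gene records")

    def _gene_id(attrs: str) -> str:
        for part in str(attrs).split(";"):
            key, _, val = part.strip().partition("=")
            if key == "ID":
                return val
        raise InputError(f"gene record without ID attribute: {attrs!r}")

    out = pd.DataFrame({
        "gene_id": df["attributes"].map(_gene_id),
        "chrom": df["seqid"],
        "strand": df["strand"],
        # GFF3 is 1-based inclusive; convert to 0-based half-open
        "start": df["start"].astype(np.int64) - 1,
        "end": df["end"].astype(np.int64),
    })
    return out


def _parse_gene_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    expected = {"gene_id", "chrom", "strand", "start", "end"}
    if not expected <= set(df.columns):
        # headerless 5-column variant
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["gene_id", "chrom", "strand", "start", "end"], dtype={"chrom": str},
        )
    return df[["gene_id", "chrom", "strand", "start", "end"]]


def read_genes(path: str | Path, genome: GenomeModel | None = None,
               format: str = "auto") -> list[GeneModel]:
    """Read gene models from GFF3 or a 5-column TSV (id, chrom, strand, start, end).

    TSV coordinates are 0-based half-open; GFF3 is converted from 1-based
    inclusive.  Both routes produce identical :class:`GeneModel` objects for
    equivalent inputs.
    """
    path = Path(path)
    if format == "auto":
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if format == "gff3":
        df = _parse_gff3_genes(path)
    elif format == "tsv":
        df = _parse_gene_tsv(path)
    else:
        raise ValueError(f"unknown gene format {format!r}")

    lengths = genome.lengths if genome is not None else None
    genes: list[GeneModel] = []
    for row in df.itertuples():
        strand = _STRAND_ALIASES.get(str(row.strand))
        if strand is None:
            raise InputError(f"gene {row.gene_id}: unknown strand {row.strand!r}")
        if lengths is not None and row.chrom not in lengths:
            raise InputError(f"gene {row.gene_id}: unknown chromosome {row.chrom!r}")
        genes.append(GeneModel(str(row.gene_id), str(row.chrom), strand,
                               int(row.start), int(row.end)))
    return genes


def read_tags(path: str | Path, genome: GenomeModel, sample_id: str | None = None,
              deduplicate: bool = True) -> TagSet:
    """Read mapped tags from BED; drop tags on undeclared chromosomes.

    Tags outside declared chromosome bounds are excluded with a logged count
    rather than an error (real tag files carry scaffold hits).
    """
    df = read_bed_intervals(path)
    df["strand"] = df["strand"].where(df["strand"].isin(STRANDS), "+")
    df = df[["chrom", "start", "end", "strand"]]
    lengths = genome.lengths
    bound = df["chrom"].map(lengths)
    ok = bound.notna() & (df["start"] >= 0) & (df["start"] < df["end"]) & (df["end"] <= bound.fillna(-1))
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.warning("%s: excluded %d tags outside declared chromosomes", path, n_excluded)
    df = df[ok].reset_index(drop=True)
    if deduplicate:
        df = df.drop_duplicates(ignore_index=True)
    return TagSet(sample_id or Path(path).stem, df, total_unique=len(df), n_excluded=n_excluded)


def make_tagset(sample_id: str, chrom: Sequence[str], start: Sequence[int],
                end: Sequence[int], strand: Sequence[str] | None = None,
                deduplicate: bool = False) -> TagSet:
    """Build a TagSet from in-memory arrays (used by the simulator and tests)."""
    df = pd.DataFrame({
        "chrom": np.asarray(chrom, dtype=object),
        "start": np.asarray(start, dtype=np.int64),
        "end": np.asarray(end, dtype=np.int64),
        "strand": np.asarray(strand, dtype=object) if strand is not None else "+",
    })
    if deduplicate:
        df = df.drop_duplicates(ignore_index=True)
    return TagSet(sample_id, df, total_unique=len(df))


def write_intervals(df: pd.DataFrame, path: str | Path, format: str = "bed",
                    header: Iterable[str] = ()) -> None:
    """Write sorted intervals as BED (chrom,start,end[,name,score,strand]) or
    bedGraph (chrom,start,end,value).  Input must already be sorted by
    (chrom, start); unsorted input is an error so round-trips are bit-exact.
    """
    if len(df):
        key = df[["chrom", "start"]]
        if not (key.sort_values(["chrom", "start"]).reset_index(drop=True).equals(
                key.reset_index(drop=True))):
            raise InputError("write_intervals: input not sorted by (chrom, start)")
    if format == "bed":
        cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    elif format == "bedgraph":
        cols = ["chrom", "start", "end", "value"]
    else:
        raise ValueError(f"unknown interval format {format!r}")
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        if len(df):
            df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression table: gene_id plus either precomputed ``fold_change``
    (mutant abundance relative to wild-type) and optional ``cv`` (percent), or
    per-replicate columns ``wt_*``/``mt_*`` from which fold and CV are derived.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise InputError(f"{path}: expression table needs a gene_id column")
    wt_cols = [c for c in df.columns if c.startswith("wt_")]
    mt_cols = [c for c in df.columns if c.startswith("mt_")]
    if "fold_change" not in df.columns:
        if not (wt_cols and mt_cols):
            raise InputError(f"{path}: need fold_change or wt_*/mt_* replicate columns")
        df = derive_fold_and_cv(df, wt_cols, mt_cols)
    if (df["fold_change"] <= 0).any():
        raise InputError(f"{path}: non-positive fold change")
    if "cv" in df.columns and (df["cv"].dropna() < 0).any():
        raise InputError(f"{path}: negative CV")
    return df


def derive_fold_and_cv(df: pd.DataFrame, wt_cols: list[str], mt_cols: list[str]) -> pd.DataFrame:
    """Per gene: fold = mean(mt)/mean(wt); CV (percent) of the per-replicate
    mt/wt ratios (replicates paired positionally)."""
    df = df.copy()
    wt = df[wt_cols].to_numpy(float)
    mt = df[mt_cols].to_numpy(float)
    df["fold_change"] = mt.mean(axis=1) / wt.mean(axis=1)
    k = min(len(wt_cols), len(mt_cols))
    ratios = mt[:, :k] / wt[:, :k]
    df["cv"] = 100.0 * ratios.std(axis=1, ddof=1) / ratios.mean(axis=1)
    return df


def read_gene_set(path: str | Path) -> set[str]:
    """Read a newline-delimited gene id list."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_gene_set(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(ids):
            fh.write(f"{gid}\n")
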