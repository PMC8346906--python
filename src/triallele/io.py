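"""Readers and writers for the tabular formats the pipeline consumes.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open (BED convention).  Text
formats that carry 1-based inclusive positions (the genotype TSV ``pos``
column, VCF ``POS``) are converted at the I/O boundary; BED files are
0-based half-open on disk and are passed through unchanged.

Missing allele frequencies are represented as ``numpy.nan``, never as 0:
a frequency of 0 is a legitimate observation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

ECOTYPES = ("marine", "freshwater", "unknown")
CROSSES = ("MarineXLong", "MarineXShort")
TISSUES = ("DS", "PS", "PF", "H")

#: columns of an ASE count table, in canonical order
ASE_COLUMNS = [
    "snp_id", "chrom", "pos", "gene_id", "exonic", "cross", "tissue",
    "library_id", "individual_id", "ref_count", "alt_count", "fw_allele",
]


class ParseError(ValueError):
    """A malformed row or header in an input file."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a table invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end {self.end} must exceed start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Distance in bp between two intervals on the same chromosome.

        0 if they touch or overlap; ``None`` for different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass
class GenotypeTable:
    """Alternate-allele frequencies at SNPs across populations/individuals.

    ``sites`` is a DataFrame with columns chrom, pos (0-based), ref, alt,
    sorted by (chrom, pos).  ``values`` is a |sites| x |samples| float
    matrix of alternate-allele frequency in [0, 1], NaN = missing.
    ``ecotypes`` labels each sample marine / freshwater / unknown.
    """

    sites: pd.DataFrame
    samples: list[str]
    values: np.ndarray
    ecotypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.ecotypes:
            self.ecotypes = ["unknown"] * len(self.samples)
        if self.values.shape != (len(self.sites), len(self.samples)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples")
        bad = set(self.ecotypes) - set(ECOTYPES)
        if bad:
            raise ValidationError(f"unknown ecotype labels: {sorted(bad)}")
        with np.errstate(invalid="ignore"):
            if np.any((self.values < 0) | (self.values > 1)):
                raise ValidationError("allele frequencies outside [0, 1]")
        order = self.sites.sort_values(["chrom", "pos"], kind="stable").index
        if not np.array_equal(order.to_numpy(), np.arange(len(self.sites))):
            self.sites = self.sites.loc[order].reset_index(drop=True)
            self.values = self.values[order.to_numpy()]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))


def _sample_header(name: str, ecotype: str) -> str:
    return f"{name}:{ecotype}" if ecotype != "unknown" else name

def _parse_sample_header(cell: str) -> tuple[str, str]:
    if ":" in cell:
        name, eco = cell.rsplit(":", 1)
        if eco in ECOTYPES:
            return name, eco
    return cell, "unknown"


def read_genotype_table(path, format: str = "tsv") -> GenotypeTable:
    """Read a genotype/allele-frequency table.

    ``tsv``: columns chrom, pos (1-based), ref, alt, then one column per
    sample named ``name`` or ``name:ecotype``; cell values are alternate
    allele frequencies in [0, 1], empty or ``NA`` for missing.

    ``vcf``: a minimal VCF subset; the per-sample alternate frequency is
    taken from FORMAT field ``AF`` if present, else derived from ``GT``
    (alt-allele dosage / ploidy).  Multi-allelic and non-SNP rows are
    skipped with a logged warning.
    """
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format in ("vcf", "vcf-like"):
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotype_tsv(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != required:
        raise ParseError(
            f"{path}: header must start with {required}, got "
            f"{list(df.columns[:4])}")
    sample_cells = list(df.columns[4:])
    if not sample_cells:
        raise ParseError(f"{path}: no sample columns")
    samples, ecotypes = zip(*(_parse_sample_header(c) for c in sample_cells))
    try:
        pos = df["pos"].astype(int) - 1  # 1-based on disk
    except ValueError as exc:
        bad = df.index[~df["pos"].str.fullmatch(r"\d+")][0]
        raise ParseError(f"{path}: line {bad + 2}: bad position") from exc
    vals = np.empty((len(df), len(samples)))
    for j, cell in enumerate(sample_cells):
        col = df[cell].where(~df[cell].isin(["", "NA", "."]), np.nan)
        try:
            vals[:, j] = col.astype(float)
        except ValueError as exc:
            bad = int(np.where(pd.to_numeric(col, errors="coerce").isna()
                               & col.notna())[0][0])
            raise ParseError(
                f"{path}: line {bad + 2}: non-numeric frequency in column "
                f"{cell!r}") from exc
    sites = pd.DataFrame({"chrom": df["chrom"], "pos": pos,
                          "ref": df["ref"], "alt": df["alt"]})
    return GenotypeTable(sites, list(samples), vals, list(ecotypes))


def _read_genotype_vcf(path) -> GenotypeTable:
    import pysam

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf = pysam.VariantFile(str(path))
        samples = list(vf.header.samples)
        rows, freqs = [], []
        for rec in vf:
            if len(rec.alts or ()) != 1:
                logger.warning("skipping multi-allelic row %s:%s",
                               rec.chrom, rec.pos)
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                logger.warning("skipping non-SNP row %s:%s", rec.chrom, rec.pos)
                continue
            row = []
            for s in samples:
                sm = rec.samples[s]
                if "AF" in sm and sm["AF"] is not None:
                    af = sm["AF"]
                    row.append(float(af[0] if isinstance(af, tuple) else af))
                else:
                    gt = sm.get("GT")
                    alleles = [a for a in (gt or ()) if a is not None]
                    row.append(np.nan if not alleles
                               else sum(alleles) / len(alleles))
            rows.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))
            freqs.append(row)
        vf.close()
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    vals = np.array(freqs, dtype=float).reshape(len(sites), len(samples))
    return GenotypeTable(sites, samples, vals)


def write_genotype_table(table: GenotypeTable, path) -> None:
    """Write the TSV form read back by :func:`read_genotype_table`."""
    out = table.sites.copy()
    out["pos"] = out["pos"] + 1  # back to 1-based on disk
    for name, eco, col in zip(table.samples, table.ecotypes, table.values.T):
        out[_sample_header(name, eco)] = [
            "" if np.isnan(v) else repr(float(v)) for v in col]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- BED

def write_bed(regions: Sequence, path) -> None:
    """Write intervals as sorted BED (0-based half-open).

    ``regions`` holds ``GenomicInterval`` or ``(interval, name)`` /
    ``(interval, name, score)`` tuples.  Input order is not required;
    overlapping intervals are written as-is.
    """
    rows = []
    for r in regions:
        extra = ()
        if isinstance(r, GenomicInterval):
            iv = r
        else:
            iv, *extra = r
        rows.append((iv.chrom, iv.start, iv.end, *extra))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {ln}: fewer than 3 BED fields")
            try:
                intervals.append(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from exc
    return intervals


# ---------------------------------------------------------------- ASE counts

def validate_ase_counts(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ASE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"ASE table missing columns {missing}")
    df = df[ASE_COLUMNS].copy()
    for col in ("ref_count", "alt_count"):
        counts = pd.to_numeric(df[col], errors="raise")
        if (counts < 0).any():
            raise ValidationError(f"negative values in {col}")
        df[col] = counts.astype(int)
    bad_cross = set(df["cross"]) - set(CROSSES)
    if bad_cross:
        raise ValidationError(f"unknown cross labels: {sorted(bad_cross)}")
    bad_tissue = set(df["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValidationError(f"unknown tissue labels: {sorted(bad_tissue)}")
    dup = df.duplicated(subset=["snp_id", "library_id"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["snp_id", "library_id"]].tolist()
        raise ValidationError(f"duplicated (snp, library) pair: {pair}")
    bad_fw = set(df["fw_allele"]) - {"ref", "alt"}
    if bad_fw:
        raise ValidationError(f"fw_allele must be 'ref' or 'alt', got {bad_fw}")
    return df


def read_ase_counts(path) -> pd.DataFrame:
    """Read a per-SNP x library allele count table (validated DataFrame)."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"snp_id": str, "gene_id": str, "library_id": str,
                            "individual_id": str})
    df["exonic"] = df["exonic"].astype(bool)
    return validate_ase_counts(df)


def write_ase_counts(df: pd.DataFrame, path) -> None:
    validate_ase_counts(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- genetic map

def read_genetic_map(path) -> pd.DataFrame:
    """Read a genetic map TSV: chrom, pos (bp, 0-based), cm.

    Within a chromosome physical positions must be strictly increasing and
    genetic positions non-decreasing.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "cm"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: genetic map needs columns {sorted(required)}")
    for chrom, grp in df.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["pos"]) > 0):
            raise ValidationError(
                f"{chrom}: physical positions not strictly increasing")
        if not np.all(np.diff(grp["cm"]) >= -1e-12):
            raise ValidationError(f"{chrom}: genetic positions decrease")
    return df[["chrom", "pos", "cm"]].copy()


def write_genetic_map(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "cm"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- annotation

def read_gene_annotation(path) -> pd.DataFrame:
    """Read a BED-derived gene/exon annotation.

    TSV with columns chrom, start, end, gene_id, feature where feature is
    ``gene`` or ``exon`` (0-based half-open, as BED).
    """
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "start", "end", "gene_id", "feature"],
                     header=None, comment="#")
    if df["feature"].iloc[0] == "feature":  # tolerate a header row
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = set(df["feature"]) - {"gene", "exon"}
    if bad:
        raise ValidationError(f"unknown annotation features: {sorted(bad)}")
    if (df["end"] <= df["start"]).any():
        raise ValidationError("annotation interval with end <= start")
    return df


def write_gene_annotation(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "gene_id", "feature"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_fasta(path) -> dict[str, str]:
    """Read FASTA records as {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
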