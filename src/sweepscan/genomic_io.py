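"""Readers/writers for the formats the scan touches, plus the sliding-window grid.

Internal coordinate convention: 0-based half-open intervals everywhere.
VCF positions (1-based) and GFF3 intervals (1-based inclusive) are converted
on ingest and converted back on write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .exceptions import FormatError, MissingSampleError, ParameterError

MISSING = -1  # sentinel for an uncalled genotype in GenotypeMatrix.geno

_BASES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes as alt-allele dosage, variants x samples.

    ``geno`` holds values in {0, 1, 2, MISSING}; positions are 1-based
    (as in VCF) and strictly increasing within each chromosome.
    """

    chrom: np.ndarray          # str per variant
    pos: np.ndarray            # int64, 1-based
    ref: np.ndarray            # single-base strings
    alt: np.ndarray
    samples: list[str]
    geno: np.ndarray           # int8, shape (n_variants, n_samples)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise MissingSampleError(f"sample {exc.args[0]!r} not in matrix") from exc

    def validate(self) -> None:
        if self.geno.shape != (self.n_variants, self.n_samples):
            raise FormatError("geno shape does not match variants x samples")
        bad = ~np.isin(self.geno, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("genotype values outside {0,1,2,missing}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise FormatError(f"positions not strictly increasing on {c}")

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome, in order of first appearance."""
        out: dict[str, slice] = {}
        if self.n_variants == 0:
            return out
        chroms = np.asarray(self.chrom)
        change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(chroms)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            c = chroms[lo]
            if c in out:
                raise FormatError(f"chromosome {c} appears in non-contiguous blocks")
            out[c] = slice(int(lo), int(hi))
        return out


@dataclass
class PopulationMap:
    """Assignment of sample ids to population group labels."""

    assignment: dict[str, str]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, group in self.assignment.items():
            out.setdefault(group, []).append(sample)
        return out

    def group_samples(self, group: str) -> list[str]:
        samples = [s for s, g in self.assignment.items() if g == group]
        if not samples:
            raise ParameterError(f"group {group!r} absent from population map")
        return samples

    def require_min_size(self, group: str, min_size: int = 2) -> list[str]:
        samples = self.group_samples(group)
        if len(samples) < min_size:
            raise ParameterError(
                f"group {group!r} has {len(samples)} samples; >= {min_size} required"
            )
        return samples


@dataclass
class WindowGrid:
    """Sliding windows, 0-based half-open, fully contained in their chromosome."""

    windows: list[tuple[str, int, int]]
    size_bp: int
    step_bp: int

    def __len__(self) -> int:
        return len(self.windows)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows, columns=["chrom", "start", "end"])


@dataclass
class GeneModel:
    """One gene interval after import (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )


def read_vcf(path, keep_samples=None) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF 4.x file (plain or bgzipped).

    Multiallelic records and indels are dropped. Genotypes are coded as
    alt-allele dosage; half-calls and ``./.`` become MISSING. Positions must
    be strictly increasing within each chromosome.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    if keep_samples is not None:
        absent = [s for s in keep_samples if s not in vcf.samples]
        if absent:
            raise MissingSampleError(f"samples not in VCF header: {absent}")
        vcf.set_samples(list(keep_samples))
    samples = list(vcf.samples)

    chroms, poss, refs, alts, rows = [], [], [], [], []
    last: dict[str, int] = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            continue
        prev = last.get(rec.CHROM)
        if prev is not None and rec.POS <= prev:
            raise FormatError(
                f"unsorted VCF: {rec.CHROM}:{rec.POS} after {rec.CHROM}:{prev}"
            )
        last[rec.CHROM] = rec.POS
        # gts012=True: 0/1/2 = alt dosage, 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(ref)
        alts.append(alt)
        rows.append(g)

    geno = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        samples=samples,
        geno=geno,
    )
    gm.validate()
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path, chrom_lengths: dict | None = None) -> None:
    """Write a GenotypeMatrix as minimal VCF 4.2 (GT field only)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        if chrom_lengths:
            for c, ln in chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_variants):
            gts = "\t".join(_GT_STR[int(v)] for v in matrix.geno[i])
            fh.write(
                f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_population_map(path) -> PopulationMap:
    """Read a two-column (sample, group) delimited table; header optional."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"population map {path} needs 2 columns")
    df = df.iloc[:, :2]
    df.columns = ["sample", "group"]
    first = [str(v).lower() for v in df.iloc[0]]
    if first[0] in ("sample", "sample_id", "id") or first[1] in ("group", "pop", "population"):
        df = df.iloc[1:]
    assignment: dict[str, str] = {}
    for sample, group in df.itertuples(index=False):
        if sample in assignment:
            if assignment[sample] != group:
                raise FormatError(
                    f"sample {sample!r} assigned to both "
                    f"{assignment[sample]!r} and {group!r}"
                )
            raise FormatError(f"sample {sample!r} listed twice in population map")
        assignment[sample] = group
    return PopulationMap(assignment)


def read_gff_genes(path, feature_type: str = "gene") -> list[GeneModel]:
    """Extract gene intervals from GFF3, converted to 0-based half-open.

    Non-gene features are ignored; an empty result triggers a warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            id_spec=["ID", "gene_id", "Name"],
        )
    except Exception as exc:
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc
    genes = []
    for feat in db.features_of_type(feature_type):
        if feat.end < feat.start:
            raise FormatError(
                f"feature {feat.id}: end {feat.end} < start {feat.start}"
            )
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF 1-based inclusive -> half-open
                end=feat.end,
                strand=feat.strand or ".",
            )
        )
    if not genes:
        warnings.warn(f"no {feature_type!r} features found in {path}", stacklevel=2)
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff_genes(genes: list[GeneModel], path) -> None:
    """Write gene models back to GFF3 (inverse of read_gff_genes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsweepscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def make_windows(chrom_lengths: dict[str, int], size_bp: int, step_bp: int) -> WindowGrid:
    """Tile each chromosome with [k*step, k*step + size) windows from 0.

    Only windows fully contained in the chromosome are emitted, so a
    chromosome of length G yields floor((G - size)/step) + 1 windows when
    G >= size and none otherwise.
    """
    if size_bp <= 0 or step_bp <= 0:
        raise ParameterError("window size and step must be positive")
    if step_bp > size_bp:
        raise ParameterError(
            f"step {step_bp} > size {size_bp}: gaps would break window merging"
        )
    windows: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        if length < size_bp:
            continue
        n = (length - size_bp) // step_bp + 1
        for k in range(n):
            start = k * step_bp
            windows.append((chrom, start, start + size_bp))
    return WindowGrid(windows=windows, size_bp=size_bp, step_bp=step_bp)


def read_vcf_chrom_lengths(path) -> dict[str, int]:
    """Chromosome lengths from VCF ##contig headers; empty dict if absent."""
    vcf = VCF(str(path))
    try:
        names, lens = vcf.seqnames, vcf.seqlens
    except Exception:
        return {}
    return dict(zip(names, lens))
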