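"""Candidate-gene trait linking.

Haplotype enumeration over a region (unphased genotype-dosage strings),
allele-class assignment at a designated variant (e.g. an exonic indel),
Welch location tests of phenotype by allele class, expression-phenotype
correlation, and overlap of association loci with called sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .genomic_io import MISSING, GenotypeMatrix, PopulationMap

WILD_TYPE = "wild-type"
HETEROZYGOUS = "heterozygous"
MUTANT = "mutant"
UNKNOWN = "unknown"

_CLASS_OF_DOSAGE = {0: WILD_TYPE, 1: HETEROZYGOUS, 2: MUTANT, MISSING: UNKNOWN}


@dataclass
class HaplotypeTable:
    """Unphased multilocus genotype strings and their per-group tallies."""

    haplotypes: pd.Series          # sample id -> string over {0,1,2,.}
    excluded: list[str]            # samples over the missingness cap
    group_counts: pd.DataFrame     # rows: haplotype string; cols: group counts

    @property
    def n_distinct(self) -> int:
        return self.haplotypes.nunique()

    def n_distinct_in(self, group: str) -> int:
        col = self.group_counts.get(group)
        return 0 if col is None else int((col > 0).sum())


def enumerate_haplotypes(
    matrix: GenotypeMatrix,
    region: tuple[str, int, int],
    popmap: PopulationMap | None = None,
    max_missing: float = 0.5,
) -> HaplotypeTable:
    """Haplotypes in ``region`` (chrom, start, end; 0-based half-open).

    A haplotype is the sample's dosage string across the region's variants
    ('.' = missing); samples whose missing fraction exceeds ``max_missing``
    are excluded.
    """
    chrom, start, end = region
    on_chrom = matrix.chrom == chrom
    in_region = on_chrom & (matrix.pos - 1 >= start) & (matrix.pos - 1 < end)
    if not in_region.any():
        raise ParameterError(f"no variants in region {chrom}:{start}-{end}")
    sub = matrix.geno[in_region]  # (k, n_samples)

    miss_frac = (sub == MISSING).mean(axis=0)
    keep = miss_frac <= max_missing
    excluded = [s for s, k in zip(matrix.samples, keep) if not k]
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} samples with missing fraction > {max_missing}",
            stacklevel=2,
        )

    def encode(col: np.ndarray) -> str:
        return "".join("." if v == MISSING else str(v) for v in col)

    haps = pd.Series(
        {s: encode(sub[:, i]) for i, s in enumerate(matrix.samples) if keep[i]}
    )
    if popmap is not None:
        groups = pd.Series({s: popmap.assignment.get(s) for s in haps.index})
        tab = pd.crosstab(haps, groups)
    else:
        tab = haps.value_counts().to_frame("all")
    tab.index.name = "haplotype"
    return HaplotypeTable(haplotypes=haps, excluded=excluded, group_counts=tab)


def assign_allele_classes(matrix: GenotypeMatrix, chrom: str, pos: int) -> pd.Series:
    """Allele class per sample at the designated variant (1-based pos).

    Dosage 0 -> wild-type, 1 -> heterozygous, 2 -> mutant, missing -> unknown.
    """
    hit = np.flatnonzero((matrix.chrom == chrom) & (matrix.pos == pos))
    if len(hit) == 0:
        raise ParameterError(f"designated variant {chrom}:{pos} absent from matrix")
    row = matrix.geno[hit[0]]
    return pd.Series(
        [_CLASS_OF_DOSAGE[int(v)] for v in row], index=matrix.samples, name="class"
    )


def class_phenotype_test(
    classes: pd.Series,
    phenotype: pd.Series,
    reference: str = WILD_TYPE,
    alternative: str = "two-sided",
    min_per_class: int = 3,
) -> pd.DataFrame:
    """Welch's t of each non-reference allele class against the reference.

    Returns one row per tested class: sample sizes, mean difference
    (class - reference), t statistic, raw p and a Bonferroni column.
    Classes with fewer than ``min_per_class`` phenotyped samples are
    skipped with a warning.
    """
    shared = classes.index.intersection(phenotype.dropna().index)
    cls = classes.loc[shared]
    phe = phenotype.loc[shared].astype(float)
    by_class = {
        c: phe[cls == c].to_numpy() for c in cls.unique() if c != UNKNOWN
    }
    sized = {c: v for c, v in by_class.items() if len(v) >= min_per_class}
    if reference not in sized:
        raise ParameterError(
            f"reference class {reference!r} has fewer than {min_per_class} phenotyped samples"
        )
    if len(sized) < 2:
        raise ParameterError("need >= 2 allele classes with enough phenotyped samples")

    ref_vals = sized[reference]
    rows = []
    for c, vals in by_class.items():
        if c == reference:
            continue
        if len(vals) < min_per_class:
            warnings.warn(
                f"class {c!r} has {len(vals)} phenotyped samples; pair skipped",
                stacklevel=2,
            )
            continue
        t, p = stats.ttest_ind(vals, ref_vals, equal_var=False, alternative=alternative)
        rows.append(
            {
                "class": c,
                "n": len(vals),
                "n_ref": len(ref_vals),
                "mean_diff": float(vals.mean() - ref_vals.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def expression_phenotype_correlation(
    expression: pd.Series,
    phenotype: pd.Series,
    method: str = "pearson",
):
    """Correlation between one gene's expression and a phenotype.

    Pairs observations by sample-id intersection after dropping missing
    values; needs >= 4 pairs. Returns (coefficient, two-sided p).
    """
    shared = expression.dropna().index.intersection(phenotype.dropna().index)
    if len(shared) < 4:
        raise ParameterError(f"only {len(shared)} paired observations; >= 4 required")
    x = expression.loc[shared].astype(float)
    y = phenotype.loc[shared].astype(float)
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def locus_sweep_overlap(loci: pd.DataFrame, sweeps: pd.DataFrame) -> pd.DataFrame:
    """Annotate association loci with the sweep containing them, if any.

    ``loci`` columns: chrom, pos (0-based point coordinate), plus anything
    else (p, trait). A locus is contained iff start <= pos < end.
    """
    out = loci.copy()
    starts, ends = [], []
    for row in loci.itertuples(index=False):
        hit = None
        if len(sweeps):
            sub = sweeps[
                (sweeps["chrom"] == row.chrom)
                & (sweeps["start"] <= row.pos)
                & (row.pos < sweeps["end"])
            ]
            if len(sub):
                hit = sub.iloc[0]
        starts.append(None if hit is None else int(hit["start"]))
        ends.append(None if hit is None else int(hit["end"]))
    out["sweep_start"] = starts
    out["sweep_end"] = ends
    out["in_sweep"] = [s is not None for s in starts]
    return out


def read_phenotypes(path) -> pd.Series:
    """Two-column TSV (sample, value) -> numeric Series indexed by sample."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParameterError(f"phenotype table {path} needs 2 columns")
    return pd.Series(df.iloc[:, 1].astype(float).to_numpy(), index=df.iloc[:, 0].astype(str))


def read_expression(path) -> pd.DataFrame:
    """Gene x sample TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_loci(path) -> pd.DataFrame:
    """Association-locus TSV (chrom, pos [1-based], p, trait) -> 0-based pos."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "chrom", df.columns[1]: "pos"})
    if ((df.get("p", pd.Series(dtype=float)) <= 0) | (df.get("p", pd.Series(dtype=float)) > 1)).any():
        raise ParameterError("association p-values must lie in (0, 1]")
    df["pos"] = df["pos"].astype(int) - 1
    return df
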