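"""Windowed diversity and differentiation statistics.

Per shared sliding window: nucleotide diversity (theta-pi) per group,
pairwise Weir & Cockerham (1984) F_ST with ratio-of-sums weighting, the
population branch statistic PBS, and the log2 pi-ratio. All statistics are
computed on one retained-window set: windows with fewer than ``min_snps``
SNPs segregating in the full matrix are dropped from everything at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .genomic_io import MISSING, GenotypeMatrix, PopulationMap, WindowGrid

FST_CAP = 1.0 - 1e-6  # keeps T = -ln(1 - F_ST) finite

POOLED = "pooled"  # sentinel group label: all assigned samples outside focal/baseline


@dataclass
class SiteAlleleCounts:
    """Per-group per-site allele counts over called chromosomes."""

    c_alt: np.ndarray     # alt-allele count
    n_called: np.ndarray  # called chromosomes (2 x called diploids)
    n_het: np.ndarray     # heterozygous individuals


def group_site_counts(matrix: GenotypeMatrix, sample_idx: np.ndarray) -> SiteAlleleCounts:
    """Allele counts at every site for the given sample columns."""
    g = matrix.geno[:, sample_idx]
    called = g != MISSING
    return SiteAlleleCounts(
        c_alt=np.where(called, g, 0).sum(axis=1).astype(np.int64),
        n_called=2 * called.sum(axis=1).astype(np.int64),
        n_het=(g == 1).sum(axis=1).astype(np.int64),
    )


def site_pi(c_alt, n_called):
    """Mean pairwise difference per site: 2c(n-c) / (n(n-1)).

    Sites with fewer than 2 called chromosomes contribute 0 (skipped).
    """
    c = np.asarray(c_alt, dtype=np.float64)
    n = np.asarray(n_called, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    return np.where(n >= 2, pi, 0.0)


def _window_bounds(pos: np.ndarray, start: int, end: int) -> tuple[int, int]:
    """Index range of 1-based positions falling in [start, end) 0-based."""
    lo = int(np.searchsorted(pos, start + 1, side="left"))
    hi = int(np.searchsorted(pos, end, side="right"))
    return lo, hi


def _window_sums(values: np.ndarray, pos: np.ndarray, starts, ends) -> np.ndarray:
    """Sum `values` (per site) over each [start, end) window via cumsum."""
    cs = np.concatenate([[0.0], np.cumsum(values, dtype=np.float64)])
    lo = np.searchsorted(pos, np.asarray(starts) + 1, side="left")
    hi = np.searchsorted(pos, np.asarray(ends), side="right")
    return cs[hi] - cs[lo]


def segregating_mask(matrix: GenotypeMatrix) -> np.ndarray:
    """Sites segregating across all samples in the matrix."""
    counts = group_site_counts(matrix, np.arange(matrix.n_samples))
    return (counts.c_alt > 0) & (counts.c_alt < counts.n_called)


def window_snp_counts(matrix: GenotypeMatrix, grid: WindowGrid) -> np.ndarray:
    """Per-window count of SNPs segregating in the full matrix."""
    seg = segregating_mask(matrix).astype(np.float64)
    out = np.zeros(len(grid))
    wf = grid.as_frame()
    for chrom, sl in matrix.chrom_slices().items():
        m = wf["chrom"] == chrom
        if not m.any():
            continue
        out[m.to_numpy()] = _window_sums(
            seg[sl], matrix.pos[sl], wf.loc[m, "start"].to_numpy(), wf.loc[m, "end"].to_numpy()
        )
    return out.astype(np.int64)


def window_pi(
    matrix: GenotypeMatrix,
    grid: WindowGrid,
    popmap: PopulationMap,
    min_snps: int = 5,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-window theta-pi (per bp) for each group.

    Windows with fewer than ``min_snps`` segregating SNPs (in the full
    matrix) are dropped. The denominator is the full window size in bp.
    """
    if min_snps < 0:
        raise ParameterError("min_snps must be >= 0")
    if groups is None:
        groups = sorted(popmap.groups())
    wf = grid.as_frame()
    wf["n_snps"] = window_snp_counts(matrix, grid)
    slices = matrix.chrom_slices()
    for group in groups:
        idx = matrix.sample_indices(popmap.require_min_size(group))
        counts = group_site_counts(matrix, idx)
        sp = site_pi(counts.c_alt, counts.n_called)
        col = np.zeros(len(grid))
        for chrom, sl in slices.items():
            m = (wf["chrom"] == chrom).to_numpy()
            if not m.any():
                continue
            col[m] = _window_sums(
                sp[sl], matrix.pos[sl], wf.loc[m, "start"].to_numpy(), wf.loc[m, "end"].to_numpy()
            )
        wf[f"pi_{group}"] = col / grid.size_bp
    return wf[wf["n_snps"] >= min_snps].reset_index(drop=True)


def wc_fst_site(counts1: SiteAlleleCounts, counts2: SiteAlleleCounts):
    """Weir & Cockerham (1984) two-population variance components per site.

    Returns ``(a, bc, informative)`` where ``a`` is the between-population
    component, ``bc`` the combined within-population components (b + c) and
    ``informative`` marks sites where both groups have >= 2 called
    chromosomes and the mean sample size exceeds one individual.
    """
    n1 = np.asarray(counts1.n_called, dtype=np.float64) / 2.0  # diploid counts
    n2 = np.asarray(counts2.n_called, dtype=np.float64) / 2.0
    informative = (counts1.n_called >= 2) & (counts2.n_called >= 2) & (n1 + n2 > 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.asarray(counts1.c_alt, dtype=np.float64) / np.asarray(counts1.n_called, dtype=np.float64)
        p2 = np.asarray(counts2.c_alt, dtype=np.float64) / np.asarray(counts2.n_called, dtype=np.float64)
        h1 = np.asarray(counts1.n_het, dtype=np.float64) / n1
        h2 = np.asarray(counts2.n_het, dtype=np.float64) / n2

        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0

    a = np.where(informative, a, 0.0)
    bc = np.where(informative, b + c, 0.0)
    return a, bc, informative


def window_fst(a: np.ndarray, bc: np.ndarray, pos: np.ndarray, starts, ends) -> np.ndarray:
    """Ratio-of-sums windowed F_ST: sum(a) / sum(a + b + c) over sites.

    Negative estimates are floored at 0 and values capped below 1 so the
    downstream branch-length transform stays finite. Windows with zero
    total variance are returned as NaN (uninformative).
    """
    num = _window_sums(a, pos, starts, ends)
    den = _window_sums(a + bc, pos, starts, ends)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = num / den
    fst = np.where(den == 0, np.nan, fst)
    return np.clip(fst, 0.0, FST_CAP)


def pbs(fst_ab, fst_ac, fst_bc, eps: float = 1e-6, tol: float = 1e-9):
    """Population branch statistic of focal group A.

    T_xy = -ln(1 - F_ST,xy); PBS_A = (T_AB + T_AC - T_BC) / 2.
    Inputs are clamped into [0, 1 - eps]; values outside [0, 1] beyond
    ``tol`` raise.
    """
    out = []
    for f in (fst_ab, fst_ac, fst_bc):
        f = np.asarray(f, dtype=np.float64)
        if np.any((f < -tol) | (f > 1.0 + tol) | ~np.isfinite(f)):
            raise ParameterError("F_ST outside [0, 1] passed to pbs")
        out.append(np.clip(f, 0.0, 1.0 - eps))
    t_ab, t_ac, t_bc = (-np.log1p(-f) for f in out)
    res = (t_ab + t_ac - t_bc) / 2.0
    return float(res) if np.isscalar(fst_ab) else res


def pi_ratio(pi_a, pi_b):
    """log2(pi_a / pi_b) with degenerate-case sentinels.

    pi_b == 0 with pi_a > 0 maps to +inf (rankable, sorts above all finite
    values); both zero maps to NaN (excluded from ranking).
    """
    a = np.asarray(pi_a, dtype=np.float64)
    b = np.asarray(pi_b, dtype=np.float64)
    if np.any(a < 0) or np.any(b < 0):
        raise ParameterError("negative diversity passed to pi_ratio")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = np.log2(a) - np.log2(b)
    res = np.where((a > 0) & (b == 0), np.inf, res)
    res = np.where((a == 0) & (b == 0), np.nan, res)
    res = np.where((a == 0) & (b > 0), -np.inf, res)
    return float(res) if np.isscalar(pi_a) else res


def _resolve_third(popmap: PopulationMap, focal: str, baseline: str, third: str):
    """Sample ids for the third PBS population (label or pooled complement)."""
    if third == POOLED:
        samples = [
            s for s, g in popmap.assignment.items() if g not in (focal, baseline)
        ]
        if len(samples) < 2:
            raise ParameterError("pooled third population has < 2 samples")
        return samples
    return popmap.require_min_size(third)


def compute_window_stats(
    matrix: GenotypeMatrix,
    grid: WindowGrid,
    popmap: PopulationMap,
    focal: str,
    baseline: str,
    third: str = POOLED,
    min_snps: int = 5,
) -> pd.DataFrame:
    """The WindowStatRow table for one focal-vs-baseline comparison.

    Columns: window coordinates, n_snps, per-group pi, the three pairwise
    F_ST values and their T transforms, PBS of the focal group, and
    log2(pi_baseline / pi_focal) (large positive = diversity loss in focal).
    """
    wf = grid.as_frame()
    wf["n_snps"] = window_snp_counts(matrix, grid)

    members = {
        focal: popmap.require_min_size(focal),
        baseline: popmap.require_min_size(baseline),
        "third": _resolve_third(popmap, focal, baseline, third),
    }
    counts = {
        name: group_site_counts(matrix, matrix.sample_indices(ids))
        for name, ids in members.items()
    }

    slices = matrix.chrom_slices()
    starts = wf["start"].to_numpy()
    chroms_arr = wf["chrom"].to_numpy()
    ends = wf["end"].to_numpy()

    def per_window(values: np.ndarray, reducer) -> np.ndarray:
        col = np.full(len(wf), np.nan)
        for chrom, sl in slices.items():
            m = chroms_arr == chrom
            if not m.any():
                continue
            col[m] = reducer(sl, starts[m], ends[m])
        return col

    # per-group pi
    pi_cols = {}
    for name, cnt in counts.items():
        sp = site_pi(cnt.c_alt, cnt.n_called)
        pi_cols[name] = per_window(
            sp, lambda sl, s, e, sp=sp: _window_sums(sp[sl], matrix.pos[sl], s, e) / grid.size_bp
        )
    wf[f"pi_{focal}"] = pi_cols[focal]
    wf[f"pi_{baseline}"] = pi_cols[baseline]
    wf["pi_third"] = pi_cols["third"]

    # pairwise windowed F_ST
    pair_keys = [(focal, baseline), (focal, "third"), (baseline, "third")]
    fst_cols = {}
    for g1, g2 in pair_keys:
        a, bc, _ = wc_fst_site(counts[g1], counts[g2])
        fst_cols[(g1, g2)] = per_window(
            a,
            lambda sl, s, e, a=a, bc=bc: window_fst(a[sl], bc[sl], matrix.pos[sl], s, e),
        )
    wf["fst_focal_baseline"] = fst_cols[(focal, baseline)]
    wf["fst_focal_third"] = fst_cols[(focal, "third")]
    wf["fst_baseline_third"] = fst_cols[(baseline, "third")]

    # PBS of the focal branch; NaN pairs propagate
    with np.errstate(invalid="ignore"):
        valid = (
            np.isfinite(wf["fst_focal_baseline"])
            & np.isfinite(wf["fst_focal_third"])
            & np.isfinite(wf["fst_baseline_third"])
        )
    pbs_col = np.full(len(wf), np.nan)
    if valid.any():
        pbs_col[valid] = pbs(
            wf.loc[valid, "fst_focal_baseline"].to_numpy(),
            wf.loc[valid, "fst_focal_third"].to_numpy(),
            wf.loc[valid, "fst_baseline_third"].to_numpy(),
        )
    wf["pbs"] = pbs_col
    wf["log2_pi_ratio"] = pi_ratio(wf[f"pi_{baseline}"].to_numpy(), wf[f"pi_{focal}"].to_numpy())

    return wf[wf["n_snps"] >= min_snps].reset_index(drop=True)
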