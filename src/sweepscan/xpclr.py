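"""Cross-population composite-likelihood-ratio (XP-CLR) sweep scan.

Model: under neutrality the object-population allele frequency q at a SNP
is Normal(p, omega * p(1-p)) around the reference frequency p, truncated to
[0, 1] with the escaped mass placed as atoms at the boundaries. Under a
sweep of strength s centred at a grid point, a lineage escapes the sweep by
recombination with probability c = 1 - exp(-(r/s) * ln(2*Ne)) (r = genetic
distance in Morgans), so the post-sweep frequency is (1-c) + c*q with
probability q and c*q otherwise. Observed alt-allele counts are binomial
given the latent frequency; the latent integral uses fixed-order
Gauss-Legendre quadrature plus the boundary atoms. The score at a grid
point is 2 * (sup_s loglik(s) - loglik(0)) over a selection grid containing
s = 0, with SNPs down-weighted by LD clique size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln, ndtr

from .exceptions import ParameterError
from .genomic_io import MISSING, GenotypeMatrix, PopulationMap, WindowGrid


def default_s_grid() -> np.ndarray:
    """{0} plus a 12-point logarithmic grid on [1e-4, 0.5]."""
    return np.concatenate([[0.0], np.geomspace(1e-4, 0.5, 12)])


@dataclass
class XpclrParams:
    """Run parameters for the scan.

    window_cM is a half-width: SNPs within this genetic distance of a grid
    point contribute. A uniform map (rec_rate_cM_per_Mb) converts bp to cM.
    """

    window_cM: float = 0.01
    grid_bp: int = 50_000
    max_snps: int = 100
    r2_max: float = 0.95
    rec_rate_cM_per_Mb: float = 1.0
    s_grid: np.ndarray = field(default_factory=default_s_grid)
    omega: float | None = None
    quad_order: int = 64
    effective_popsize: float = 10_000.0  # sets the sweep starting frequency 1/(2Ne)

    def __post_init__(self):
        self.s_grid = np.sort(np.asarray(self.s_grid, dtype=np.float64))
        if self.window_cM <= 0 or self.grid_bp <= 0:
            raise ParameterError("window_cM and grid_bp must be positive")
        if not (0 < self.r2_max <= 1):
            raise ParameterError("r2_max must be in (0, 1]")
        if 0.0 not in self.s_grid:
            raise ParameterError("s_grid must contain 0 (the neutral null)")
        if self.omega is not None and self.omega <= 0:
            raise ParameterError("omega must be positive once set")


OMEGA_FLOOR = 1e-6


def _group_freqs(matrix: GenotypeMatrix, popmap: PopulationMap, group: str):
    idx = matrix.sample_indices(popmap.require_min_size(group))
    g = matrix.geno[:, idx]
    called = g != MISSING
    n = 2 * called.sum(axis=1).astype(np.int64)
    c = np.where(called, g, 0).sum(axis=1).astype(np.int64)
    return c, n


def estimate_omega(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    reference: str,
    obj: str,
    min_snps: int = 1000,
) -> float:
    """Method-of-moments drift scale: Var(q - p) ~ omega * p(1 - p).

    Uses all SNPs polymorphic in the reference with both groups callable;
    subtracts binomial sampling variance from the squared frequency
    contrast and normalizes by the unbiased estimate of p(1 - p).
    """
    c_ref, n_ref = _group_freqs(matrix, popmap, reference)
    c_obj, n_obj = _group_freqs(matrix, popmap, obj)
    use = (n_ref >= 4) & (n_obj >= 4) & (c_ref > 0) & (c_ref < n_ref)
    if use.sum() < min_snps:
        raise ParameterError(
            f"only {int(use.sum())} usable SNPs for omega estimation; >= {min_snps} required"
        )
    p = c_ref[use] / n_ref[use]
    q = c_obj[use] / n_obj[use]
    num = (q - p) ** 2 - q * (1 - q) / (n_obj[use] - 1) - p * (1 - p) / (n_ref[use] - 1)
    den = p * (1 - p) * n_ref[use] / (n_ref[use] - 1)
    return max(float(num.sum() / den.sum()), OMEGA_FLOOR)


def ld_weights(genotypes: np.ndarray, r2_max: float) -> np.ndarray:
    """1/m weight for each SNP in a single-linkage clique of m SNPs with
    pairwise genotype r^2 above ``r2_max``.

    ``genotypes``: (n_snps, n_samples) dosages; missing values are
    mean-imputed per SNP for the correlation. Monomorphic SNPs are
    singletons (weight 1).
    """
    k = genotypes.shape[0]
    if k == 0:
        return np.empty(0)
    g = genotypes.astype(np.float64)
    g[g == MISSING] = np.nan
    mean = np.nanmean(g, axis=1, keepdims=True)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    g = np.where(np.isnan(g), mean, g)
    centred = g - g.mean(axis=1, keepdims=True)
    sd = centred.std(axis=1)
    ok = sd > 0
    r2 = np.zeros((k, k))
    if ok.sum() >= 2:
        cc = np.corrcoef(centred[ok])
        r2[np.ix_(ok, ok)] = cc**2
    adj = csr_matrix(r2 > r2_max)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return 1.0 / sizes[labels]


def _gauss_legendre_01(order: int):
    x, w = np.polynomial.legendre.leggauss(order)
    return (x + 1.0) / 2.0, w / 2.0


def _log_binom(m, n, q):
    """log Binomial(m; n, q), exact at q in {0, 1}; broadcasts over q."""
    m = np.asarray(m, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    logc = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = m * np.log(q)
        lq = (n - m) * np.log1p(-q)
    lp = np.where(m == 0, 0.0, lp)
    lq = np.where(n - m == 0, 0.0, lq)
    return logc + lp + lq


class _SiteModel:
    """Vectorized per-SNP likelihoods shared across grid points.

    Arrays are per SNP: reference frequency p (clamped off the boundary),
    object alt count m of n chromosomes, genetic distance r (cM) to the
    grid point being evaluated.
    """

    def __init__(self, params: XpclrParams, omega: float):
        self.params = params
        self.omega = omega
        self.nodes, self.qw = _gauss_legendre_01(params.quad_order)
        self.log_2ne = np.log(2.0 * params.effective_popsize)

    def _latent_density(self, p: np.ndarray):
        """Atoms and node masses of the truncated-normal latent q1 given p."""
        var = self.omega * p * (1 - p)
        sd = np.sqrt(np.maximum(var, 1e-12))
        atom0 = ndtr((0.0 - p) / sd)
        atom1 = 1.0 - ndtr((1.0 - p) / sd)
        z = (self.nodes[None, :] - p[:, None]) / sd[:, None]
        dens = np.exp(-0.5 * z**2) / (sd[:, None] * np.sqrt(2 * np.pi))
        mass = dens * self.qw[None, :]  # (k, Q)
        return atom0, atom1, mass

    def loglik(self, p, m, n, r_cM):
        """Log-likelihood per SNP for every s in the grid: shape (S, k)."""
        p = np.asarray(p, dtype=np.float64)
        m = np.asarray(m, dtype=np.float64)
        n = np.asarray(n, dtype=np.float64)
        r_cM = np.asarray(r_cM, dtype=np.float64)
        if not (np.isfinite(p).all() and np.isfinite(r_cM).all()):
            raise ParameterError("non-finite inputs to xpclr likelihood")

        atom0, atom1, mass = self._latent_density(p)  # (k,), (k,), (k,Q)
        x = self.nodes[None, :]  # latent q1 at nodes
        b_at_0 = np.exp(_log_binom(m, n, 0.0))
        b_at_1 = np.exp(_log_binom(m, n, 1.0))
        b_nodes = np.exp(_log_binom(m[:, None], n[:, None], x))  # (k,Q)

        s_grid = self.params.s_grid
        out = np.empty((len(s_grid), len(p)))
        r_m = r_cM / 100.0  # Morgans
        for i, s in enumerate(s_grid):
            if s == 0.0:
                lik = atom0 * b_at_0 + atom1 * b_at_1 + (mass * b_nodes).sum(axis=1)
            else:
                c = 1.0 - np.exp(-np.minimum(r_m / s * self.log_2ne, 700.0))  # (k,)
                q2_hit = (1.0 - c[:, None]) + c[:, None] * x
                q2_miss = c[:, None] * x
                b_hit = np.exp(_log_binom(m[:, None], n[:, None], q2_hit))
                b_miss = np.exp(_log_binom(m[:, None], n[:, None], q2_miss))
                inner = x * b_hit + (1.0 - x) * b_miss
                lik = atom0 * b_at_0 + atom1 * b_at_1 + (mass * inner).sum(axis=1)
            out[i] = np.log(np.maximum(lik, 1e-300))
        return out


def xpclr_site_loglik(p_ref, q_obs_count, n_obs, r_cM, s, params: XpclrParams):
    """Log-likelihood contribution of one SNP at one selection strength.

    Requires ``params.omega`` to be set.
    """
    if params.omega is None:
        raise ParameterError("omega must be estimated or supplied")
    if not np.all(np.isfinite([p_ref, q_obs_count, n_obs, r_cM, s])):
        raise ParameterError("non-finite inputs to xpclr_site_loglik")
    if s < 0 or r_cM < 0 or not (0 <= p_ref <= 1):
        raise ParameterError("invalid p_ref / r_cM / s")
    local = XpclrParams(**{**params.__dict__, "s_grid": np.array([0.0, s]) if s > 0 else np.array([0.0])})
    model = _SiteModel(local, params.omega)
    ll = model.loglik(
        np.array([p_ref]), np.array([q_obs_count]), np.array([n_obs]), np.array([r_cM])
    )
    return float(ll[-1, 0]) if s > 0 else float(ll[0, 0])


def xpclr_scan(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    chrom_lengths: dict[str, int],
    reference: str,
    obj: str,
    params: XpclrParams | None = None,
) -> pd.DataFrame:
    """Composite-likelihood scan over grid points every ``grid_bp``.

    Returns one row per grid point: chrom, pos (0-based), clr, s_hat,
    n_snps_used. Grid points with no usable SNP in the window get NaN clr
    (excluded from ranking).
    """
    params = params or XpclrParams()
    omega = params.omega
    if omega is None:
        omega = estimate_omega(matrix, popmap, reference, obj)
    model = _SiteModel(params, omega)

    c_ref, n_ref = _group_freqs(matrix, popmap, reference)
    c_obj, n_obj = _group_freqs(matrix, popmap, obj)
    obj_idx = matrix.sample_indices(popmap.require_min_size(obj))
    rate = params.rec_rate_cM_per_Mb

    rows = []
    slices = matrix.chrom_slices()
    for chrom, length in chrom_lengths.items():
        sl = slices.get(chrom)
        pos = matrix.pos[sl] if sl else np.empty(0, dtype=np.int64)
        if sl:
            usable = (n_ref[sl] >= 4) & (n_obj[sl] >= 4)
            pos_u = pos[usable]
            # clamp reference frequency off the boundary (degenerate variance)
            eps = 1.0 / (n_ref[sl][usable] + 1.0)
            p_u = np.clip(c_ref[sl][usable] / n_ref[sl][usable], eps, 1 - eps)
            m_u = c_obj[sl][usable].astype(np.float64)
            n_u = n_obj[sl][usable].astype(np.float64)
            gidx_u = np.flatnonzero(usable) + sl.start
        else:
            pos_u = np.empty(0, dtype=np.int64)
        cm_u = pos_u * rate / 1e6

        for gp in range(0, int(length), params.grid_bp):
            gp_cm = gp * rate / 1e6
            lo = np.searchsorted(cm_u, gp_cm - params.window_cM, side="left")
            hi = np.searchsorted(cm_u, gp_cm + params.window_cM, side="right")
            if hi == lo:
                rows.append((chrom, gp, np.nan, np.nan, 0))
                continue
            sel = np.arange(lo, hi)
            r = np.abs(cm_u[sel] - gp_cm)
            if len(sel) > params.max_snps:
                order = np.lexsort((pos_u[sel], r))[: params.max_snps]
                sel, r = sel[order], r[order]
            weights = ld_weights(matrix.geno[gidx_u[sel]][:, obj_idx], params.r2_max)
            ll = model.loglik(p_u[sel], m_u[sel], n_u[sel], r)  # (S, k)
            score = ll @ weights
            null = score[np.flatnonzero(params.s_grid == 0.0)[0]]
            best = int(np.argmax(score))
            clr = max(2.0 * (score[best] - null), 0.0)
            rows.append((chrom, gp, clr, params.s_grid[best], len(sel)))

    return pd.DataFrame(rows, columns=["chrom", "pos", "clr", "s_hat", "n_snps_used"])


def map_scores_to_windows(scores: pd.DataFrame, grid: WindowGrid) -> np.ndarray:
    """Per shared window, the max clr over grid points inside [start, end).

    Windows containing no scored grid point get NaN.
    """
    out = np.full(len(grid), np.nan)
    by_chrom = {c: df for c, df in scores.dropna(subset=["clr"]).groupby("chrom")}
    for i, (chrom, start, end) in enumerate(grid.windows):
        df = by_chrom.get(chrom)
        if df is None:
            continue
        p = df["pos"].to_numpy()
        lo = np.searchsorted(p, start, side="left")
        hi = np.searchsorted(p, end, side="left")
        if hi > lo:
            out[i] = df["clr"].to_numpy()[lo:hi].max()
    return out
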