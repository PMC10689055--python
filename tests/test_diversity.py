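import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.diversity import (
    SiteAlleleCounts,
    compute_window_stats,
    pbs,
    pi_ratio,
    site_pi,
    wc_fst_site,
    window_fst,
    window_pi,
)
from sweepscan.exceptions import ParameterError
from sweepscan.genomic_io import MISSING, PopulationMap, make_windows

from conftest import three_group_sim


def brute_force_site_pi(c_alt: int, n: int) -> float:
    """Exhaustive mean pairwise difference over all chromosome pairs."""
    alleles = [1] * c_alt + [0] * (n - c_alt)
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(n=st.integers(min_value=2, max_value=12), data=st.data())
def test_site_pi_equals_exhaustive_pair_counting(n, data):
    c = data.draw(st.integers(min_value=0, max_value=n))
    assert site_pi(c, n) == pytest.approx(brute_force_site_pi(c, n), abs=1e-12)


def test_site_pi_examples_and_skip_rule():
    assert site_pi(3, 10) == pytest.approx(21 / 45)  # 0.466667
    assert site_pi(0, 10) == 0.0
    assert site_pi(10, 10) == 0.0
    assert site_pi(np.array([1]), np.array([1]))[0] == 0.0  # n_called < 2 skipped


def _toy_matrix_one_group():
    """5 SNPs in a 1-Mb window, each with site_pi = 0.5 in the group."""
    from sweepscan.genomic_io import GenotypeMatrix

    # 2 diploids, dosage (1, 1): c=2, n=4 -> 2*2*2/(4*3) = 1/3... use (0,2): c=2 -> same.
    # dosage (1,1) gives c=2,n=4: pi = 2*2*2/12 = 1/3; for pi=0.5 need c=1,n=2? Use
    # one diploid called: dosage (1, missing): c=1, n=2 -> 2*1*1/(2*1) = 1.0.
    # Simplest exact target: 2 diploids (0/1 and 1/1 -> c=3,n=4): 2*3*1/12=0.5.
    geno = np.tile(np.array([[1, 2]], dtype=np.int8), (5, 1))
    return GenotypeMatrix(
        chrom=np.array(["chr1"] * 5, dtype=object),
        pos=np.array([10_000, 20_000, 30_000, 40_000, 50_000], dtype=np.int64),
        ref=np.array(["A"] * 5, dtype=object),
        alt=np.array(["C"] * 5, dtype=object),
        samples=["x1", "x2"],
        geno=geno,
    )


def test_window_pi_arithmetic_and_min_snps_filter():
    m = _toy_matrix_one_group()
    pm = PopulationMap({"x1": "G", "x2": "G"})
    grid = make_windows({"chr1": 1_000_000}, 500_000, 500_000)
    out = window_pi(m, grid, pm, min_snps=5)
    assert len(out) == 1  # second window has 0 SNPs -> dropped
    assert out["pi_G"].iloc[0] == pytest.approx(5 * 0.5 / 500_000)

    # with min_snps=6 the 5-SNP window is dropped from everything
    assert len(window_pi(m, grid, pm, min_snps=6)) == 0


def wc_oracle(counts):
    """Weir & Cockerham (1984) variance components, general-r textbook form
    with explicit scalar loops (independent of the vectorized code path)."""
    r = len(counts)
    n = [nc / 2 for _, nc, _ in counts]           # diploid sample sizes
    p = [ca / nc for ca, nc, _ in counts]
    h = [nh / (nc / 2) for _, nc, nh in counts]   # observed het proportion
    nbar = sum(n) / r
    nc_ = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc_) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def _counts(c_alt, n_called, n_het):
    return SiteAlleleCounts(
        c_alt=np.array([c_alt]), n_called=np.array([n_called]), n_het=np.array([n_het])
    )


def test_wc_fst_site_matches_textbook_oracle():
    a, bc, ok = wc_fst_site(_counts(18, 20, 2), _counts(2, 20, 2))
    oa, ob, oc = wc_oracle([(18, 20, 2), (2, 20, 2)])
    assert ok[0]
    assert a[0] == pytest.approx(oa, rel=1e-12)
    assert bc[0] == pytest.approx(ob + oc, rel=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n1=st.integers(2, 15), n2=st.integers(2, 15),
    c1=st.data(),
)
def test_wc_fst_site_matches_oracle_randomized(n1, n2, c1):
    ca1 = c1.draw(st.integers(0, 2 * n1))
    ca2 = c1.draw(st.integers(0, 2 * n2))
    h1 = c1.draw(st.integers(0, min(ca1, 2 * n1 - ca1)))
    h2 = c1.draw(st.integers(0, min(ca2, 2 * n2 - ca2)))
    a, bc, ok = wc_fst_site(_counts(ca1, 2 * n1, h1), _counts(ca2, 2 * n2, h2))
    oa, ob, oc = wc_oracle([(ca1, 2 * n1, h1), (ca2, 2 * n2, h2)])
    assert ok[0]
    assert a[0] == pytest.approx(oa, rel=1e-9, abs=1e-12)
    assert bc[0] == pytest.approx(ob + oc, rel=1e-9, abs=1e-12)


def test_wc_fst_edge_cases():
    # identical counts -> no between-group variance, a <= 0
    a, bc, _ = wc_fst_site(_counts(10, 20, 10), _counts(10, 20, 10))
    assert a[0] <= 1e-12
    # fixed difference without heterozygotes -> F_ST = 1
    a, bc, _ = wc_fst_site(_counts(20, 20, 0), _counts(0, 20, 0))
    assert a[0] / (a[0] + bc[0]) == pytest.approx(1.0)


def test_window_fst_is_ratio_of_sums_of_site_oracle():
    rng = np.random.default_rng(2)
    n1 = n2 = 20
    c1 = rng.integers(0, n1 + 1, size=10)
    c2 = rng.integers(0, n2 + 1, size=10)
    h1 = np.minimum(np.minimum(c1, n1 - c1), rng.integers(0, 8, size=10))
    h2 = np.minimum(np.minimum(c2, n2 - c2), rng.integers(0, 8, size=10))
    a, bc, _ = wc_fst_site(
        SiteAlleleCounts(c1, np.full(10, n1), h1),
        SiteAlleleCounts(c2, np.full(10, n2), h2),
    )
    pos = np.arange(1, 11) * 100
    got = window_fst(a, bc, pos, [0], [2000])[0]
    o = [wc_oracle([(c1[i], n1, h1[i]), (c2[i], n2, h2[i])]) for i in range(10)]
    expected = sum(x[0] for x in o) / sum(sum(x) for x in o)
    assert got == pytest.approx(max(expected, 0.0), rel=1e-9)

    # all sites with identical frequencies -> floored to 0
    a0, bc0, _ = wc_fst_site(_counts(10, 20, 4), _counts(10, 20, 4))
    assert window_fst(a0, bc0, np.array([100]), [0], [2000])[0] == 0.0


def test_pbs_closed_form_and_degenerate_cases():
    assert pbs(0.5, 0.5, 0.2) == pytest.approx(0.581575, abs=1e-6)
    assert pbs(0.0, 0.0, 0.0) == 0.0
    for x in np.arange(0.1, 0.95, 0.1):
        assert pbs(x, x, 0.0) == pytest.approx(-np.log1p(-x), rel=1e-9)
    with pytest.raises(ParameterError):
        pbs(1.2, 0.1, 0.1)


def test_pbs_symmetric_in_role_exchange():
    rng = np.random.default_rng(0)
    ab, ac, bc = rng.random(20) * 0.8, rng.random(20) * 0.8, rng.random(20) * 0.8
    np.testing.assert_allclose(pbs(ab, ac, bc), pbs(ac, ab, bc))


def test_pi_ratio_values_and_sentinels():
    # group diversities on the scale of a wild vs cultivated panel
    assert pi_ratio(0.00069, 0.00048) == pytest.approx(0.52356, abs=1e-5)
    assert pi_ratio(0.3, 0.3) == 0.0
    assert pi_ratio(0.5, 0.0) == np.inf
    assert np.isnan(pi_ratio(0.0, 0.0))
    with pytest.raises(ParameterError):
        pi_ratio(-0.1, 0.2)


def test_window_stats_invariant_to_sample_order_and_allele_relabeling():
    matrix, pm, lengths, _ = three_group_sim((0.2, 0.2, 0.2), genome_mb=3.0, seed=21)
    grid = make_windows(lengths, 500_000, 125_000)
    base = compute_window_stats(matrix, grid, pm, "A", "B", "C")

    # permute sample columns
    rng = np.random.default_rng(1)
    perm = rng.permutation(matrix.n_samples)
    import copy

    shuf = copy.copy(matrix)
    shuf.samples = [matrix.samples[i] for i in perm]
    shuf.geno = matrix.geno[:, perm]
    out = compute_window_stats(shuf, grid, pm, "A", "B", "C")
    np.testing.assert_allclose(out["pi_A"], base["pi_A"], rtol=1e-12)
    np.testing.assert_allclose(out["pbs"], base["pbs"], rtol=1e-10)

    # flip ref/alt coding at every site
    flip = copy.copy(matrix)
    flip.geno = np.where(matrix.geno == MISSING, MISSING, 2 - matrix.geno).astype(np.int8)
    out2 = compute_window_stats(flip, grid, pm, "A", "B", "C")
    np.testing.assert_allclose(out2["pi_A"], base["pi_A"], rtol=1e-12)
    np.testing.assert_allclose(out2["fst_focal_baseline"], base["fst_focal_baseline"], rtol=1e-10)


def test_low_snp_windows_dropped_from_every_statistic():
    matrix, pm, lengths, _ = three_group_sim((0.2, 0.2, 0.2), genome_mb=3.0, seed=23)
    grid = make_windows(lengths, 500_000, 125_000)
    out = compute_window_stats(matrix, grid, pm, "A", "B", "C", min_snps=10**9)
    assert len(out) == 0  # one shared retained-window set

    out2 = compute_window_stats(matrix, grid, pm, "A", "B", "C", min_snps=5)
    assert (out2["n_snps"] >= 5).all()
    for col in ("pi_A", "pbs", "log2_pi_ratio", "fst_focal_baseline"):
        assert col in out2.columns and len(out2[col]) == len(out2)


def test_unknown_group_raises():
    matrix, pm, lengths, _ = three_group_sim((0.2, 0.2, 0.2), genome_mb=3.0, seed=25)
    grid = make_windows(lengths, 500_000, 125_000)
    with pytest.raises(ParameterError):
        compute_window_stats(matrix, grid, pm, "A", "NOPE", "C")
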