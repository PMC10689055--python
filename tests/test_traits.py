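import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sweepscan.exceptions import ParameterError
from sweepscan.genomic_io import MISSING, GenotypeMatrix, PopulationMap
from sweepscan.traits import (
    HETEROZYGOUS,
    MUTANT,
    UNKNOWN,
    WILD_TYPE,
    assign_allele_classes,
    class_phenotype_test,
    enumerate_haplotypes,
    expression_phenotype_correlation,
    locus_sweep_overlap,
)


def _matrix(geno_rows, samples, chrom="chr1", start_pos=100):
    geno = np.array(geno_rows, dtype=np.int8)
    n = geno.shape[0]
    return GenotypeMatrix(
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.arange(start_pos, start_pos + n, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["C"] * n, dtype=object),
        samples=samples,
        geno=geno,
    )


class TestHaplotypes:
    def test_identical_and_distinct_strings(self):
        m = _matrix([[0, 0, 0, 0], [1, 1, 1, 1]], ["a", "b", "c", "d"])
        tab = enumerate_haplotypes(m, ("chr1", 0, 1000))
        assert tab.n_distinct == 1

        m2 = _matrix([[0, 1, 2, 0, 1], [0, 0, 0, 1, 2]], list("abcde"))
        tab2 = enumerate_haplotypes(m2, ("chr1", 0, 1000))
        assert tab2.n_distinct == 5

    def test_missingness_exclusion(self):
        m = _matrix(
            [[0, MISSING], [1, MISSING], [2, 0], [0, 1], [1, 2]], ["keep", "drop"]
        )
        with pytest.warns(UserWarning, match="excluded 1"):
            tab = enumerate_haplotypes(m, ("chr1", 0, 1000), max_missing=0.3)
        assert tab.excluded == ["drop"]
        assert list(tab.haplotypes.index) == ["keep"]

    def test_group_counts_and_subgroup_never_richer(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 3, size=(6, 20)).astype(np.int8)
        samples = [f"s{i}" for i in range(20)]
        m = _matrix(geno.tolist(), samples)
        pm = PopulationMap({s: ("X" if i < 10 else "Y") for i, s in enumerate(samples)})
        tab = enumerate_haplotypes(m, ("chr1", 0, 1000), popmap=pm)
        assert tab.n_distinct <= 20
        assert tab.n_distinct_in("X") <= tab.n_distinct
        assert tab.group_counts.sum().sum() == 20

        # order invariance
        perm = rng.permutation(20)
        m2 = _matrix(geno[:, perm].tolist(), [samples[i] for i in perm])
        assert enumerate_haplotypes(m2, ("chr1", 0, 1000)).n_distinct == tab.n_distinct

    def test_empty_region_raises(self):
        m = _matrix([[0, 1]], ["a", "b"])
        with pytest.raises(ParameterError, match="no variants"):
            enumerate_haplotypes(m, ("chr1", 5000, 6000))


class TestAlleleClasses:
    def test_dosage_to_class_mapping(self):
        m = _matrix([[0, 1, 2, MISSING]], list("abcd"))
        cls = assign_allele_classes(m, "chr1", 100)
        assert cls.tolist() == [WILD_TYPE, HETEROZYGOUS, MUTANT, UNKNOWN]

    def test_absent_variant_raises(self):
        m = _matrix([[0, 1]], ["a", "b"])
        with pytest.raises(ParameterError, match="absent"):
            assign_allele_classes(m, "chr1", 9999)

    def test_single_class_refused_downstream(self):
        m = _matrix([[0] * 8], [f"s{i}" for i in range(8)])
        cls = assign_allele_classes(m, "chr1", 100)
        pheno = pd.Series(np.arange(8.0), index=m.samples)
        with pytest.raises(ParameterError, match=">= 2 allele classes"):
            class_phenotype_test(cls, pheno)


def welch_oracle(x, y):
    """Closed-form Welch t and two-sided p (Satterthwaite df)."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx + vy / ny
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, 2 * stats.t.sf(abs(t), df)


class TestClassPhenotypeTest:
    def _classified(self, wt, mut, het=None):
        classes, values = [], []
        for v in wt:
            classes.append(WILD_TYPE); values.append(v)
        for v in mut:
            classes.append(MUTANT); values.append(v)
        for v in het or []:
            classes.append(HETEROZYGOUS); values.append(v)
        idx = [f"s{i}" for i in range(len(values))]
        return pd.Series(classes, index=idx), pd.Series(values, index=idx, dtype=float)

    def test_equals_closed_form_welch_on_balanced_data(self):
        rng = np.random.default_rng(8)
        wt, mut = rng.normal(10, 2, 15), rng.normal(12, 3, 15)
        classes, pheno = self._classified(wt, mut)
        out = class_phenotype_test(classes, pheno)
        t, p = welch_oracle(mut, wt)
        row = out[out["class"] == MUTANT].iloc[0]
        assert row["t"] == pytest.approx(t, rel=1e-12)
        assert row["p"] == pytest.approx(p, rel=1e-12)
        assert row["mean_diff"] == pytest.approx(mut.mean() - wt.mean(), rel=1e-12)

    def test_large_effect_tiny_variance_is_significant(self):
        rng = np.random.default_rng(9)
        wt = rng.normal(100, 0.5, 10)
        mut = wt + 10.0  # effect 10 with tiny variance
        classes, pheno = self._classified(wt, mut)
        out = class_phenotype_test(classes, pheno)
        assert out.iloc[0]["p"] < 1e-3

    def test_small_class_skipped_with_warning(self):
        rng = np.random.default_rng(10)
        classes, pheno = self._classified(
            rng.normal(0, 1, 10), rng.normal(1, 1, 10), het=[5.0, 6.0]
        )
        with pytest.warns(UserWarning, match="pair skipped"):
            out = class_phenotype_test(classes, pheno)
        assert set(out["class"]) == {MUTANT}

    def test_one_sided_alternative(self):
        rng = np.random.default_rng(11)
        wt = rng.normal(0, 1, 20)
        mut = rng.normal(2, 1, 20)
        classes, pheno = self._classified(wt, mut)
        two = class_phenotype_test(classes, pheno)
        one = class_phenotype_test(classes, pheno, alternative="greater")
        assert one.iloc[0]["p"] == pytest.approx(two.iloc[0]["p"] / 2, rel=1e-9)


class TestCorrelation:
    def test_exact_linear_relations(self):
        idx = [f"s{i}" for i in range(10)]
        x = pd.Series(np.arange(10.0), index=idx)
        r, _ = expression_phenotype_correlation(x, 2 * x)
        assert r == pytest.approx(1.0)
        r2, _ = expression_phenotype_correlation(x, -x + 1e-12 * np.arange(10))
        assert r2 == pytest.approx(-1.0, abs=1e-6)

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(12)
        idx = [f"s{i}" for i in range(30)]
        x = pd.Series(rng.normal(size=30), index=idx)
        y = pd.Series(rng.normal(size=30), index=idx)
        r_xy, _ = expression_phenotype_correlation(x, y)
        r_yx, _ = expression_phenotype_correlation(y, x)
        r_scaled, _ = expression_phenotype_correlation(x * 37.0, y)
        assert r_xy == pytest.approx(r_yx, rel=1e-12)
        assert r_scaled == pytest.approx(r_xy, rel=1e-12)

    def test_pairs_by_id_intersection_and_minimum(self):
        x = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        y = pd.Series([2.0, 4, 6, 8], index=list("abcf"))
        with pytest.raises(ParameterError, match=">= 4"):
            expression_phenotype_correlation(x, y)  # only 3 shared ids


class TestLocusOverlap:
    SWEEPS = pd.DataFrame(
        [{"chrom": "chr5", "start": 381_600_000, "end": 382_700_000}]
    )

    def test_contained_locus(self):
        loci = pd.DataFrame([{"chrom": "chr5", "pos": 381_700_000, "trait": "bolting"}])
        out = locus_sweep_overlap(loci, self.SWEEPS)
        assert out.iloc[0]["in_sweep"]

    def test_half_open_end_boundary(self):
        loci = pd.DataFrame([
            {"chrom": "chr5", "pos": 382_700_000},   # == end, excluded
            {"chrom": "chr5", "pos": 382_699_999},   # last contained point
            {"chrom": "chr5", "pos": 381_600_000},   # start contained
        ])
        out = locus_sweep_overlap(loci, self.SWEEPS)
        assert out["in_sweep"].tolist() == [False, True, True]

    def test_empty_sweep_list(self):
        loci = pd.DataFrame([{"chrom": "chr5", "pos": 1}])
        out = locus_sweep_overlap(loci, self.SWEEPS.iloc[:0])
        assert not out["in_sweep"].any()
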