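"""Synthetic multi-population genotype data with planted sweeps.

The engine is the Balding-Nichols model: each SNP gets an ancestral
frequency p from a neutral-shaped SFS (density proportional to 1/p on a
truncated range), and each group's frequency is drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F) with that group's drift parameter F.
E[F_ST] between two groups then equals the mean of their F values, and
heterozygosity within a group is (1-F) * E[2p(1-p)] -- exact expectations
the tests lean on. Planted sweeps are intervals where one group's drift is
replaced by a much larger F_sweep, producing the operative signal of a hard
sweep: locally collapsed diversity and extreme frequency differentiation.

Default parameters reproduce the diversity scale of a garlic-like
resequencing panel: SNP density 0.002/bp and drift values yielding group
theta-pi around 5e-4 to 7e-4 and pairwise F_ST between 0.2 and 0.45.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ParameterError
from .genomic_io import GeneModel, GenotypeMatrix, write_gff_genes, write_vcf

MISSING = -1


@dataclass
class GroupSpec:
    label: str
    n_diploids: int
    drift: float  # Balding-Nichols F in (0, 1)


@dataclass
class SweepSpec:
    group: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    f_sweep: float


@dataclass
class SimConfig:
    """Simulation parameters; the defaults emulate a five-group panel.

    mu and generation_years document the mutation-rate/time scaling of the
    emulated study (2.5e-9 per nt per year, one-year generations); the
    Balding-Nichols engine itself is parameterized directly by drift F.
    """

    groups: list[GroupSpec] = field(
        default_factory=lambda: [
            GroupSpec("BG", 28, 0.15),
            GroupSpec("CG1", 27, 0.45),
            GroupSpec("CG2", 46, 0.40),
            GroupSpec("G3", 16, 0.30),
            GroupSpec("G4", 17, 0.35),
        ]
    )
    genome: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 5_000_000)])
    snp_density: float = 0.002          # SNPs per bp
    sfs_min: float = 0.05               # ancestral frequency range for the 1/p SFS
    sfs_max: float = 0.95
    sweeps: list[SweepSpec] = field(default_factory=list)
    mu: float = 2.5e-9                  # mutations per nt per year (documentation)
    generation_years: float = 1.0
    missing_rate: float = 0.02
    seed: int = 1

    def __post_init__(self):
        for g in self.groups:
            if not (0 < g.drift < 1):
                raise ParameterError(f"group {g.label}: drift F must be in (0, 1)")
        labels = {g.label for g in self.groups}
        lengths = dict(self.genome)
        for s in self.sweeps:
            if not (0 < s.f_sweep < 1):
                raise ParameterError("F_sweep must be in (0, 1)")
            if s.group not in labels:
                raise ParameterError(f"sweep group {s.group!r} not among groups")
            base = next(g.drift for g in self.groups if g.label == s.group)
            if s.f_sweep <= base:
                raise ParameterError("F_sweep must exceed the group's background drift")
            if s.chrom not in lengths or not (0 <= s.start < s.end <= lengths[s.chrom]):
                raise ParameterError(f"sweep interval outside genome bounds: {s}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome"] = [[c, int(l)] for c, l in self.genome]
        return d


def _sample_positions(rng, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length]."""
    draw = rng.integers(1, length + 1, size=int(n * 1.2) + 16)
    uniq = np.unique(draw)
    while len(uniq) < n:
        extra = rng.integers(1, length + 1, size=n)
        uniq = np.unique(np.concatenate([uniq, extra]))
    return np.sort(rng.choice(uniq, size=n, replace=False))


def _ancestral_freqs(rng, n: int, lo: float, hi: float) -> np.ndarray:
    """Frequencies with density proportional to 1/p on [lo, hi]."""
    u = rng.random(n)
    return lo * (hi / lo) ** u


def simulate_genotypes(config: SimConfig):
    """Draw a GenotypeMatrix under the Balding-Nichols model.

    Returns (matrix, truth) where truth is a dict with the planted-sweep
    table and the seed. Fully reproducible from config.seed.
    """
    rng = np.random.default_rng(config.seed)
    chroms_all, pos_all = [], []
    for chrom, length in config.genome:
        n = int(round(length * config.snp_density))
        pos = _sample_positions(rng, length, n)
        chroms_all.append(np.full(n, chrom, dtype=object))
        pos_all.append(pos)
    chrom = np.concatenate(chroms_all)
    pos = np.concatenate(pos_all).astype(np.int64)
    n_sites = len(pos)

    p_anc = _ancestral_freqs(rng, n_sites, config.sfs_min, config.sfs_max)

    geno_cols = []
    samples = []
    for g in config.groups:
        f_site = np.full(n_sites, g.drift)
        for s in config.sweeps:
            if s.group == g.label:
                inside = (chrom == s.chrom) & (pos - 1 >= s.start) & (pos - 1 < s.end)
                f_site[inside] = s.f_sweep
        shape = (1.0 - f_site) / f_site
        q = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        gt = rng.binomial(2, q[:, None], size=(n_sites, g.n_diploids)).astype(np.int8)
        if config.missing_rate > 0:
            mask = rng.random(gt.shape) < config.missing_rate
            gt[mask] = MISSING
        geno_cols.append(gt)
        samples.extend(f"{g.label}_{i:03d}" for i in range(g.n_diploids))

    ref = np.array(rng.choice(list("ACGT"), size=n_sites), dtype=object)
    shift = rng.integers(1, 4, size=n_sites)
    bases = np.array(list("ACGT"), dtype=object)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    alt = bases[(np.array([base_idx[b] for b in ref]) + shift) % 4]

    matrix = GenotypeMatrix(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        samples=samples,
        geno=np.hstack(geno_cols),
    )
    truth = {
        "seed": config.seed,
        "sweeps": [asdict(s) for s in config.sweeps],
    }
    return matrix, truth


def simulate_phenotypes(
    matrix: GenotypeMatrix,
    causal: tuple[str, int],
    effect: float,
    noise_sd: float,
    seed: int,
    baseline: float = 100.0,
) -> tuple[pd.Series, dict]:
    """Phenotype = baseline + effect * dosage + N(0, noise_sd) per sample.

    Samples missing the causal genotype get NaN. ``causal`` is (chrom,
    1-based pos).
    """
    chrom, p = causal
    hit = np.flatnonzero((matrix.chrom == chrom) & (matrix.pos == p))
    if len(hit) == 0:
        raise ParameterError(f"causal variant {chrom}:{p} absent from matrix")
    dosage = matrix.geno[hit[0]].astype(float)
    dosage[dosage == MISSING] = np.nan
    rng = np.random.default_rng(seed)
    values = baseline + effect * dosage + rng.normal(0.0, noise_sd, size=len(dosage))
    pheno = pd.Series(values, index=matrix.samples, name="phenotype")
    truth = {"causal": {"chrom": chrom, "pos": int(p)}, "effect": effect, "noise_sd": noise_sd}
    return pheno, truth


def simulate_expression(
    phenotype: pd.Series,
    linked_gene: str,
    corr_target: float,
    seed: int,
    n_genes: int = 20,
    mean_fpkm: float = 50.0,
    sd_fpkm: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Gene x sample expression with one gene correlated to the phenotype.

    The linked gene's expression has Pearson correlation ~ corr_target to
    the phenotype; the other genes are independent noise.
    """
    if not (-1 < corr_target < 1):
        raise ParameterError("|corr_target| must be < 1")
    rng = np.random.default_rng(seed)
    phe = phenotype.dropna()
    z = (phe - phe.mean()) / (phe.std() or 1.0)
    n = len(phe)
    rows = {}
    e = corr_target * z.to_numpy() + np.sqrt(1 - corr_target**2) * rng.normal(size=n)
    rows[linked_gene] = mean_fpkm + sd_fpkm * e
    for i in range(n_genes - 1):
        rows[f"gene_{i:04d}"] = mean_fpkm + sd_fpkm * rng.normal(size=n)
    expr = pd.DataFrame(rows, index=phe.index).T
    truth = {"linked_gene": linked_gene, "corr_target": corr_target}
    return expr, truth


def tile_genes(genome, spacing: int = 400_000, length: int = 20_000) -> list[GeneModel]:
    """Regularly spaced gene models so some fall inside planted sweeps."""
    genes = []
    k = 0
    for chrom, size in genome:
        start = spacing // 2
        while start + length <= size:
            genes.append(GeneModel(f"gene{k:05d}", chrom, start, start + length, "+"))
            k += 1
            start += spacing
    return genes


def write_fixture_bundle(outdir, config: SimConfig, phenotype_spec=None, expression_spec=None) -> dict:
    """Write a self-contained scan fixture: VCF, popmap, GFF3, truth JSON,
    config YAML, and optional phenotype/expression tables.

    ``phenotype_spec``: (causal (chrom, pos) or None for a mid-genome SNP,
    effect, noise_sd); ``expression_spec``: (linked_gene, corr_target).
    Byte-identical on rerun with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_genotypes(config)

    write_vcf(matrix, outdir / "variants.vcf", chrom_lengths=dict(config.genome))
    with open(outdir / "popmap.tsv", "w") as fh:
        fh.write("sample\tgroup\n")
        for g in config.groups:
            for i in range(g.n_diploids):
                fh.write(f"{g.label}_{i:03d}\t{g.label}\n")
    genes = tile_genes(config.genome)
    write_gff_genes(genes, outdir / "genes.gff3")

    if phenotype_spec is not None:
        causal, effect, noise_sd = phenotype_spec
        if causal is None:
            mid = len(matrix.pos) // 2
            causal = (str(matrix.chrom[mid]), int(matrix.pos[mid]))
        pheno, ptruth = simulate_phenotypes(
            matrix, causal, effect, noise_sd, seed=config.seed + 1
        )
        pheno.rename_axis("sample").to_frame().to_csv(outdir / "phenotype.tsv", sep="\t")
        truth["phenotype"] = ptruth
        if expression_spec is not None:
            gene, corr = expression_spec
            expr, etruth = simulate_expression(pheno, gene, corr, seed=config.seed + 2)
            expr.rename_axis("gene_id").to_csv(outdir / "expression.tsv", sep="\t")
            truth["expression"] = etruth

    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return truth


def sweep_benchmark_config(seed: int = 1) -> SimConfig:
    """The planted-sweep benchmark: 10 hard sweeps (F_sweep = 0.95) in the
    focal group on an F = 0.1 three-group background, 1040 shared windows.

    Sweep intervals are 250 kb aligned to the 125-kb step so each overlaps
    exactly five 500-kb windows; the 4 x 32.875 Mb genome keeps the
    top-5% flag budget per method slightly above the 50 truth windows.
    """
    genome = [(f"chr{i}", 32_875_000) for i in range(1, 5)]
    starts_mb = {
        "chr1": [5.0, 15.0, 25.0],
        "chr2": [5.0, 15.0, 25.0],
        "chr3": [8.0, 20.0],
        "chr4": [8.0, 20.0],
    }
    sweeps = [
        SweepSpec("CG1", chrom, int(s * 1e6), int(s * 1e6) + 250_000, 0.95)
        for chrom, starts in starts_mb.items()
        for s in starts
    ]
    return SimConfig(
        groups=[
            GroupSpec("BG", 30, 0.1),
            GroupSpec("CG1", 30, 0.1),
            GroupSpec("G3", 30, 0.1),
        ],
        genome=genome,
        sweeps=sweeps,
        seed=seed,
    )


def truth_window_mask(windows: pd.DataFrame, sweeps: list[SweepSpec] | list[dict]) -> np.ndarray:
    """Boolean mask of windows overlapping any planted sweep by >= 1 bp."""
    mask = np.zeros(len(windows), dtype=bool)
    for s in sweeps:
        d = s if isinstance(s, dict) else asdict(s)
        mask |= (
            (windows["chrom"] == d["chrom"])
            & (windows["start"] < d["end"])
            & (windows["end"] > d["start"])
        ).to_numpy()
    return mask
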