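# Methods

## Problem and scope

`sweepscan` detects candidate selective sweeps in a structured resequencing
panel — the setting of crop-domestication genomics, where a diverse basal
population coexists with several derived, cultivated groups — and links
candidate regions to traits via haplotype structure, allele-class phenotype
contrasts, expression–phenotype correlation and association-locus overlap.
The scan combines three complementary statistics on one shared sliding-window
grid (500 kb windows, 125 kb steps by default):

* **θπ** — per-window nucleotide diversity per bp within each group, the sum
  over sites of the mean pairwise difference `2c(n−c)/(n(n−1))` (`c` alt
  alleles among `n` called chromosomes), divided by the full window length.
* **Weir–Cockerham F_ST** — the 1984 variance-components estimator,
  windowed as a ratio of sums `Σa / Σ(a+b+c)` over sites. Negative window
  estimates are floored at 0 and values capped at `1 − 1e-6` so the branch
  transform below stays finite.
* **PBS** — with `T_xy = −ln(1 − F_ST,xy)`, the focal branch length
  `PBS_A = (T_AB + T_AC − T_BC)/2`. Sensitive to incomplete sweeps because it
  isolates frequency change on the focal branch.
* **log₂ π-ratio** — `log2(θπ_baseline / θπ_focal)`; large positive values
  mean diversity loss in the focal group. A focal diversity of exactly 0
  with positive baseline diversity yields a +inf sentinel that ranks above
  every finite window; 0/0 is undefined and excluded from ranking.
* **XP-CLR** — a composite likelihood ratio contrasting a sweep model
  against neutral drift of object-population allele frequencies around
  reference-population frequencies (details below).

Windows in the top 5% of at least two of {PBS, π-ratio, XP-CLR} are
candidates; overlapping or book-ended candidates merge into sweep intervals,
which are annotated with genes at ≥1 bp overlap.

## Window and coordinate conventions

All internal intervals are 0-based half-open; VCF positions and GFF3
intervals are converted on ingest and back on write. Windows tile from
coordinate 0 and only fully contained windows are emitted, so every window
has identical length and no per-window renormalisation is needed. A window
enters the analysis only if it holds at least `min_snps` (default 5) SNPs
segregating across the *full* sample set; the filter is applied once, so all
three statistics and the evidence combination operate on the same
retained-window set. Multiallelic records and indels are dropped at ingest;
only biallelic SNPs are analysed. Strand is ignored in all interval overlap.

## Missing-data handling

Per-site counts use called chromosomes only. A site contributes to a pair's
F_ST only when both groups have ≥2 called chromosomes and the mean diploid
sample size exceeds one (the Weir–Cockerham small-sample corrections are
undefined below that). Groups used in any statistic must have ≥2 samples.

## XP-CLR model

Let `p` be the reference-group frequency at a SNP (clamped into
`[1/(n_ref+1), 1 − 1/(n_ref+1)]` to avoid a degenerate variance) and `q` the
latent object-group frequency. Neutrally, `q ~ Normal(p, ω·p(1−p))`
truncated to [0, 1], with the escaped tail mass placed as atoms at the
boundaries; ω is estimated genome-wide by method of moments
(`Var(q̂ − p̂) ≈ ω·p(1−p)` after subtracting binomial sampling variance),
floored at 1e-6. Under a sweep of strength `s` centred at a grid point, a
lineage at genetic distance `r` Morgans escapes by recombination with
probability `c = 1 − exp(−(r/s)·ln(2Ne))` (`Ne` default 10 000 sets the
sweep starting frequency); the post-sweep frequency is `(1−c) + c·q` with
probability `q` (the swept haplotype carried the allele) and `c·q`
otherwise. As `s → 0+`, `c → 1` and the sweep model reduces continuously to
the neutral model. Observed alt counts are binomial given the latent
frequency; the latent integral uses Gauss–Legendre quadrature of order 64 on
(0, 1) plus the boundary atoms — deterministic and reproducible.

Grid points are spaced 50 kb; SNPs within 0.01 cM (a half-width, under a
uniform map of 1 cM/Mb — all configurable) contribute, capped at the 100
nearest by genetic distance with ties broken by lower bp position. SNPs in
single-linkage cliques of pairwise genotype r² > 0.95 are weighted 1/clique
size. The score is `2(sup_s ℓ(s) − ℓ(0))` over a selection grid
{0} ∪ 12 log-spaced points on [1e-4, 0.5]; with 0 in the grid the score is
non-negative by construction. Per shared window the score is the max over
contained grid points; windows without a scored grid point are excluded from
the XP-CLR ranking.

## Outlier calling and merging

Each statistic is thresholded at its own top fraction `q` (default 0.05)
over the retained windows of the comparison: the `⌈q·N⌉` largest rankable
values are flagged and ties at the threshold are all included (so the
flagged count is never below `⌈q·N⌉`). π-ratio infinities rank above all
finite values — total diversity loss is the strongest possible signal for
that statistic. Candidates need flags from ≥2 methods; merging is
book-ended-inclusive because the 125-kb step makes neighbouring candidate
windows overlap by construction. Supporting methods are unioned and per-
statistic means/maxima reported per merged interval.

## Synthetic data generator

The generator is a Balding–Nichols engine: each SNP draws an ancestral
frequency from a neutral-shaped SFS (density ∝ 1/p, truncated to
[0.05, 0.95]); each group draws its frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with group-specific drift `F`; diploid
genotypes are binomial(2, q) with uniform missingness (default 2%). This
gives exact expectations the tests use: expected pairwise Weir–Cockerham
F_ST equals the mean of the two groups' F values, and within-group
heterozygosity equals `(1−F)·E[2p(1−p)]`. Sweeps are modelled as intervals
where the focal group's drift is replaced by a much larger `F_sweep`,
producing the operative hard-sweep signal — locally collapsed diversity and
near-fixed frequency differentiation — with exactly known truth intervals.
Default densities and drift values (SNP density 0.002/bp; F between 0.15
and 0.45 across the five default groups) reproduce the diversity scale of a
garlic-like panel: group θπ of roughly 5–7 × 10⁻⁴ and pairwise F_ST between
0.2 and 0.45. The mutation rate (2.5e-9 per nt per year) and one-year
generation time are carried in the configuration for documentation and
scaling parity; the engine is parameterised by F directly.

What the generator does *not* emulate: linkage disequilibrium and local
haplotype structure (sites are conditionally independent given the
ancestral frequency), realistic SFS shape at the rare end, variable
recombination or mutation rate, admixture, and genuine selection
trajectories. Passing tests therefore demonstrate correct estimator
behaviour and calling logic under a drift model with planted signal, not
performance on real LD-structured data; in particular the XP-CLR LD
down-weighting is exercised only lightly (simulated SNPs are nearly
uncorrelated).

## Benchmark sizing

The planted-sweep benchmark plants ten 250-kb sweeps (`F_sweep = 0.95` on an
`F = 0.1` three-group background, 30 diploids per group) aligned to the
125-kb step, so each sweep overlaps exactly five windows (50 truth windows).
The genome is 4 × 32.875 Mb = 1040 windows, making the per-method top-5%
flag budget (⌈52⌉) slightly exceed the truth count; with ~500 SNPs per
window the weakest truth window sits several standard deviations above the
background distribution of each statistic. Scoring: recall is the fraction
of truth windows (≥1 bp overlap with a planted interval) that are called;
the false fraction is the share of called windows outside truth; XP-CLR
coverage is the fraction of planted intervals containing at least one
top-5% grid point. These sizes were fixed from the analytic expectations
above, as the package's benchmark definition.

## Trait linking

Haplotypes are unphased multilocus genotype-dosage strings (the panels this
targets are unphased and no phasing step is modelled); heterozygous sites
are kept as '1', and samples above a missingness cap (default 50%) are
excluded. The allele-class phenotype contrast is Welch's t (unequal
variances), two-sided by default with a one-sided option for directional
hypotheses; classes need ≥3 phenotyped samples. Expression–phenotype
correlation is Pearson by default (Spearman available), paired by sample-id
intersection, ≥4 pairs. Association loci are consumed from a table — the
mixed-model association scan itself is out of scope — and a locus overlaps
a sweep iff its position lies in the half-open interval.

## Numerical choices and degenerate inputs

* F_ST: negative windowed estimates floored at 0; cap `1 − 1e-6` before the
  log transform; windows with zero total variance are NaN (uninformative).
* PBS inputs outside [0, 1] beyond 1e-9 raise; within tolerance they are
  clamped.
* Degenerate statistic distributions (all values tied) flag everything and
  emit a warning.
* All simulation and scan outputs are byte-deterministic given seed and
  config; logs carry a config hash instead of timestamps.

## Known limitations

* The merge rule (book-ended-inclusive over the sliding grid) is one of
  several defensible conventions; absolute sweep counts depend on it and
  should be compared only within a fixed configuration.
* The XP-CLR implementation is a clean-room model with a documented escape-
  probability parameterisation; scores are comparable within a run, not
  numerically interchangeable with other implementations.
* θπ uses the full window length as denominator, not accessible sites, so
  windows with poor callability understate diversity uniformly.
* The π-ratio of two *means* over a sweep is reported alongside the ratio of
  window sums; the two differ when window SNP counts vary strongly.
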