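# Methods

This note documents the models behind each module, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was open.

## Male mutation bias from intron divergence

Neutral divergence on a chromosome class is proportional to the
time-averaged germline mutation rate. With male rate αμ_f and female rate
μ_f, autosomes evolve at μ_f(α+1)/2 and the Z at μ_f(2α+1)/3, giving the
ratio map R(α) = (4α+2)/(3(α+1)) and its inverse α = (3R−2)/(4−3R). R is
confined to (2/3, 4/3): estimates at or past either bound are flagged
(+∞ "male-limit exceeded", or a negative value below the female limit)
rather than dropped, because a bootstrap replicate can legitimately cross a
bound when the point estimate is near it.

Per-locus distances are closed-form JC69 (default) or K2P. The published
analyses this re-implements used ML distances from genome-scale alignments;
closed forms are used here because they are deterministic and verifiable
against their defining formulas, and because the downstream quantity is a
ratio of medians, insensitive to the correction model at intron-scale
divergences. Gap/N columns are dropped pairwise. Class summaries are
medians (even counts average the central pair). Uncertainty comes from a
nonparametric bootstrap whose resampling unit is the locus — loci are the
independent units; sites within an intron are not — resampled with
replacement independently within the Z and autosome classes, 1000
replicates by default, percentile 2.5/97.5 interval over the finite
replicate α values with the non-finite count reported.

Calibration (recomputed by `scripts/acceptance.py` and the test suite):
median relative error of α̂ stays below 10% at α ∈ {1.6, 3.8} with 500
1-kb loci per class, and the 95% interval covers the truth in ~94–99% of
200 replicate experiments.

## Forward Wright–Fisher simulation with ZW inheritance

Discrete generations, constant sex numbers (default 50♂/50♀), random
mating, neutral infinite-sites mutation. Autosomal loci are diploid in both
sexes; Z-linked loci have two copies in males and one in females (the W is
not tracked — no Z locus resides on it). Each locus is transmitted
independently (free recombination), implemented as a boolean
mutation-by-copy matrix gathered by parent indices each generation.
Nucleotide diversity is the population heterozygosity Σ2p(1−p) with the
n/(n−1) correction, per site.

Defaults: 20N generations of burn-in (N = total population size; the
pre-condition enforces ≥10N), mutation rate 5×10⁻⁵ per site per generation
over 1-kb loci, 40 loci per class. At equal sex numbers Ne_Z/Ne_A = 3/4,
and the simulated π_Z/π_A lands within 0.05 of 0.75 pooled over 20
populations; with 4 males and 50 females the expected ratio drops to ~0.58,
reproducing the sexual-selection effect on the Z's effective size. These
population sizes are desk-scale stand-ins: real avian Ne is orders of
magnitude larger, but the diversity *ratio* is governed by the inheritance
system, not the absolute size.

## Strata demarcation

The Z/W divergence landscape is scanned in fixed windows (default 100 kb;
the benchmark uses 10-kb windows over 2-kb genes, preserving five genes per
window). Each window gets a JC69/K2P distance over its usable columns;
windows under `min_sites` comparable columns are excluded. At every
candidate breakpoint the `flank` (default 10) usable windows on each side
are compared by a two-sided Mann–Whitney test. Boundaries are local minima
of the p-value profile that remain below `p_cut` (default 0.01) after
Bonferroni correction over the number of tested breakpoints — `p_cut` is
therefore a per-chromosome family-wise level. Without that correction the
~n_windows overlapping tests produce spurious boundaries on ~10% of
constant-divergence chromosomes; with it the false-boundary rate is ≤5%
while a 0.30→0.10 step with per-gene noise SD 0.02 is still recovered
within ±3 windows in ≥95% of simulated chromosomes (the attainable
Mann–Whitney p with 10v10 flanks, ~1.1×10⁻⁵, stays below the corrected
threshold for chromosomes up to several hundred windows; use larger flanks
for longer chromosomes). Boundaries closer than `min_gap` (default 500 kb)
merge, keeping the smaller p. Segments are labeled S0, S1, … by descending
median divergence; a terminal near-zero segment is labeled PAR.

Stratum ages come from gametolog gene trees: neighbor-joining on K2P
distances, then a rooting-free bipartition test. An internal edge splitting
all Z copies from all W copies means recombination stopped before
speciation ("ancestral"); every species' own Z/W pair forming a cherry
means it stopped independently afterwards ("lineage-specific"); anything
else — including conflicting patterns across species — is "unknown". Genes
are assigned to the stratum containing their midpoint under 0-based
half-open coordinates (a midpoint exactly on a boundary belongs to the
right-hand stratum) — deterministic and stable under boundary jitter.

## Coding-sequence evolution

dN/dS uses the Nei–Gojobori (1986) counting method: per-codon fractional
synonymous/nonsynonymous sites (changes into stop codons excluded from the
opportunity), observed differences averaged over all substitution pathways
that avoid stops for codons differing at 2–3 positions, Jukes–Cantor
correction of the proportions, saturation flagged at p ≥ 3/4. The site and
difference counts are verified exactly against a brute-force pathway
enumeration in the test suite. Lineage-specific rates use the relative-rate
decomposition d_focal = (d_FO + d_FS − d_SO)/2 applied separately to the
synonymous and nonsynonymous components, truncating negative estimates to
zero with a flag; lineage acceleration is tested by Tajima's relative-rate
chi-square on lineage-unique sites. This whole block is a deliberate
methodological substitution for ML codon models (free-ratio / one-ratio vs
two-ratio branch tests): counting methods are self-contained and
oracle-verifiable, and the comparative conclusions rest on rate *contrasts*
between chromosome classes, which the counting estimates preserve
(neutral simulations recover ω̂ within [0.9, 1.1]; ω_true = 0.2 is
recovered within [0.15, 0.25] on average).

Codon-usage bias: FOP = optimal codons over codons-with-synonyms; CBI =
(N_opt − N_rand)/(N_tot − N_rand) with N_rand the optimal count expected
under uniform synonymous usage; GC3 over third positions of non-stop
codons; GCi over intron sequence. The optimal-codon set is an input table;
the bundled default is a chicken-like GC-ending set intended for testing
and exploration, not a curated species resource. Codons containing N are
excluded everywhere; standard genetic code only.

The gene-set enrichment helper is a plain hypergeometric upper tail over a
user-supplied gene→term map (P < 0.01 default); no ontology content ships
with the package. No multiple-testing correction is applied by default to
the rate scans, matching common practice for these chromosome-level
contrasts; a BH option exists on the enrichment output columns via the
reported p-values.

## Diversity, sexing, and fast-Z

SNP filters reproduce the stated rules exactly: depths outside [4, 100]
removed (bounds inclusive — "lower than 4 or higher than 100" spares 4 and
100), then sites closer than 5 bp to a surviving neighbor removed. Both
members of a close pair are removed by default; because "remove the
cluster" is ambiguous, `keep_one_of_pair=True` keeps the first site of each
run instead. Filtering is idempotent. Intron SNP density is per-kb per
region; the Z/A ratio of class medians proxies Ne_Z/Ne_A. The fast-Z test
is a Pearson correlation between that proxy and the Z/A dN/dS ratio across
species. Read-depth sexing thresholds the Z/autosome mean-depth ratio at
0.75 (midpoint of the expected 1.0 for ZZ males and 0.5 for ZW females),
flagging ratios in [0.65, 0.85] as low confidence; the threshold is a
package choice, stated rather than inherited. At 20× coverage sexing is
error-free across 200 simulated profiles. The Z-vs-autosome Wilcoxon
helper takes a `scale_a` multiplier so the "lower than three quarters"
null is `scale_a=0.75`.

## Expression and dosage compensation

FPKM = counts·10⁹/(length·total). The per-sample totals are an input:
they represent genome-wide mapped fragments, so callers analyzing a
simulated gene subset must pass fixed totals (the pipeline uses 10⁶) —
recomputing totals from the subset would let the sex-linked genes
renormalize themselves. M/F ratio = (mean male + ε)/(mean female + ε) with
ε = 0.1 FPKM; genes under 1 FPKM in both sexes are flagged out of
summaries. Both guards are standard protections against ratio blow-up at
low expression. Window scans use non-overlapping five-gene blocks along the
Z, dropping the trailing partial block; the window and stratum statistic is
the median of log2 ratios. Adjacent strata are compared young→old by
Mann–Whitney.

The generator scales a Z gene's female expectation by w + (1−w)c, where w
is the per-gene W-retention indicator (Bernoulli per the stratum fraction)
and c the compensation factor: 0.5 with no compensation, 1 under global
compensation, 1 only inside a designated gene-index window under regional
compensation (the chicken-like case). Counts are negative binomial with
dispersion 0.1 — typical bulk RNA-seq overdispersion. Under no
compensation a fully degenerate stratum shows a median M/F ratio in
[1.8, 2.2] (500 genes), and the global-compensation control sits at ~1.

## Phylogenetic regressions

Brownian covariance C comes from shared root-to-divergence path lengths;
Pagel's λ damps off-diagonals: V(λ) = λC + (1−λ)diag(C). The λ profile
likelihood is maximized on a 101-point grid refined by golden-section
search in the best cell; β and σ² are profiled analytically through a
Cholesky whitening. The λ=1 LRT uses the boundary-aware halved chi-square
p-value (50:50 mixture). The screen mirrors the two-step logic of the
original analysis: traits whose λ=1 hypothesis survives are tested by PGLS
(ML λ), others by ordinary regression — which is exactly the λ=0 fit, equal
to OLS to 1e-10 on ultrametric trees. Categorical traits (mating system)
are compared by Kruskal–Wallis. Missing data are dropped pairwise per
(response, trait). Star trees make λ unidentifiable; the fit is flagged
and reported at λ=0. Slope recovery bias on 45-tip Brownian simulations is
under 5% across 200 replicates.

The trait generator produces a Brownian predictor and a response
slope·x + noise with λ-scaled covariance on a random ultrametric tree; it
does not emulate measurement error, trait transformations (log mass etc.),
or the fossil-calibrated branch lengths of real bird phylogenies.

## What the synthetic data do not show

The generators exercise the estimators under their own assumptions:
independent loci, Jukes–Cantor substitution, free recombination, no
selection in the population simulation, no indels or alignment error, no
read-level noise. Passing tests therefore demonstrate correctness of the
estimators and their calibration under the assumed models — not robustness
to alignment artifacts, reference bias, GC-biased gene conversion, or
substitution-model misspecification, all of which affect real genome
analyses. The benchmark problem sizes (500 loci/class, 100-member
populations, 100 chromosomes, 45 tips, 200 replicates) were chosen once as
the package's desk-scale study conditions.

## Pipeline

`zstrata run` executes simulate → α → strata → codon/rates → popgen →
expression → traits on generated data, writing per-stage TSVs and a
manifest (tool version, seed, parameters, stage summaries, output list).
All randomness derives from the single configured seed with fixed
per-stage offsets; identical configuration reproduces byte-identical
outputs. Stage failures halt the run naming the stage, preserving completed
outputs. Coordinates are 0-based half-open everywhere; TSV missing values
are `.`.
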