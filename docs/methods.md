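# Methods

`sweepscan` implements a selection-signature scan for phased SNP-chip panels:
three extended-haplotype-homozygosity (EHH) statistics with a sliding-window
region caller and multi-method consensus, a Bayesian F_ST outlier test, and
the preprocessing that precedes them. A forward Wright-Fisher simulator
generates panels with known sweeps so that every stage can be validated
end-to-end without any external data.

## EHH statistics

For a core marker and a set of n_a haplotypes carrying a chosen core allele,
EHH at a marker x is the probability that two randomly drawn carriers are
identical at every marker between the core and x:

    EHH(x) = sum_h C(n_h, 2) / C(n_a, 2),

summing over the distinct extended haplotypes h among the carriers (the
unbiased pairwise form, matching the identity-by-descent definition of the
statistic). Extension proceeds marker by marker in both directions and stops
at the chromosome end, when EHH falls below a cutoff, or when the gap to the
next marker exceeds a maximum (profile truncated before the gap).

* **Max gap**: 500 kb. Chip panels have occasional sparse stretches;
  haplotype identity across a long unobserved gap is uninformative.
* **EHH cutoff**: 0.05. The dominant convention; bounds the integral below.
* **Integration**: trapezoidal, over physical distance (bp), both flanks
  summed. No genetic map is assumed — chip data rarely come with one, and
  the gap rule is physical; a genetic-map variant would only rescale the
  x-axis.

iHH integrates EHH separately for carriers of the ancestral and the derived
core allele; iES integrates EHH over all haplotypes of a population pooled
regardless of core allele. The scan statistics are

* **iHS** = ln(iHH_ancestral / iHH_derived), standardized to mean 0, sd 1
  within derived-allele-frequency bins (default 20 equal-width bins; bins
  with fewer than 10 markers are merged into their right neighbour). Binning
  removes the strong frequency dependence of the unstandardized ratio. Both
  knobs are arguments.
* **Rsb** = ln(iES_pop1 / iES_pop2), centred on the genome-wide median and
  scaled by the sd (median-centring follows the statistic's original
  description and is robust to the sweep's own tail).
* **XP-EHH** = the same log-ratio, mean/sd standardized.

Standardized scores are mapped to two-sided tail probabilities under a
standard normal, reported as −log10(1 − 2|Φ(score) − ½|) and computed via
`log_ndtr` so that extreme scores stay finite. A score of 0 maps to exactly
0; the transform is symmetric; a score of ±3.29053 maps to exactly 3.0.
Normality of the standardized scores is an approximation: on desk-scale
panels (tens of haplotypes, a few Mb) the null log-ratio distribution has
slightly heavy tails, so the empirical fraction of markers at −log10 p ≥ 3
on neutral simulations scatters around the nominal 0.001 with replicate-level
bursts (markers in LD exceed together). The calibration test therefore
checks the transform exactly on normal deviates and checks the simulation
rate with a replicate-clustered standard error.

## Window caller and consensus

Per-marker −log10 p tracks are summarized over 1-Mb windows advancing on a
10-kb grid; a window is called when it contains at least 3 (iHS) or 4
(Rsb, XP-EHH) markers with −log10 p ≥ 3.0 (threshold inclusive). Overlapping
called windows merge into regions, so region bounds lie on the 10-kb grid
and lengths are 1 Mb + k·10 kb — exactly the granularity of the published
region table the package ships as a fixture, which is how the 10-kb step
interpretation was fixed (a 990-kb step cannot produce those lengths).
Consensus across methods merges regions transitively on ≥ 1 bp overlap and
keeps those supported by at least `min_methods` *distinct tests* (the same
test under two contrasts does not count twice). This minimal-overlap rule
reproduces the published consensus counts (36 regions; 10 two-test; 1
three-test; 13 including the two F_ST-supported regions) from the fixture's
48 intervals.

Region annotation joins gene/QTL/SV intervals on ≥ 1 bp overlap (half-open
coordinates; an abutting feature does not overlap). Structural variants of
8 Mb or longer are dropped first — intervals that size exceed what
short-read SV callers resolve and would blanket every region.

## Preprocessing

* **MAF filter**: markers with minor-allele frequency strictly below 0.05
  are removed (a marker at exactly 0.05 is kept).
* **LD pruning**: windows of 50 consecutive kept markers advancing 5 markers
  at a time; in a violating pair (dosage r² > 0.5) the lower-MAF member is
  dropped (tie: later position), iterated to a fixpoint, so the final panel
  contains no violating pair in any window. PLINK's exact internal order is
  version-dependent; this rule is deterministic and documented.
* **Relatedness**: method-of-moments IBD from IBS counts (PI-HAT =
  P(IBD=1)/2 + P(IBD=2), probabilities truncated to the simplex). Pairs over
  their class threshold — 0.25 for commercial breeds, 0.1 for local
  populations bred by natural service — lose one member; the member with
  the most over-threshold partners goes first (tie: later sample id), which
  maximizes retained samples.
* **Polarization**: the ancestral allele is the strict majority among up to
  three outgroup calls, requiring at least two concordant non-missing calls;
  ties and under-called markers are removed. Calls matching neither allele
  are logged and treated as missing. After polarization haplotype code 0 is
  ancestral everywhere.
* **Weir–Cockerham θ** is computed from the published variance components
  (a, b, c) per biallelic locus — the diploid form with the heterozygosity
  term from genotypes, the haploid form (c = 0) from chromosome counts —
  with the multi-locus estimate as the ratio of sums. It validates the
  synthetic allele-count generator; it is not part of the scan itself.

## Wright–Fisher simulator

Discrete non-overlapping generations; each offspring haplotype is a
recombinant copy of one parent's two haplotypes with Poisson(r·L)
crossovers; additive viability selection (weights 1, 1+s, 1+2s) at one
focal site; populations split by copying the parent deme, with optional
symmetric migration thereafter. Initial variation comes from a
mutation-drift burn-in of 10·N_e generations (recurrent 0↔1 flips at rate
mu per site per gamete). After the burn-in, mutation is off by default: on
the tens-of-generations timescale of the divergence phase new mutations
contribute nothing to common chip variation, while any rate high enough to
matter would artificially erode the long-range haplotype identity the scans
measure. The simulator knows the truth: allele 0 is ancestral by
construction, and for sweep runs it records the selected site, s, the final
frequencies, and the maximal interval around the selected site where the
modal extended haplotype exceeds 80% — the recovery target for the region
caller.

Desk-scale parameters are deliberately rescaled, as is standard for forward
simulation: N_e = 100 diploids with r = 10⁻⁶ per bp (so that recombination
during a sweep of ~15 generations localizes the swept haplotype within a
4-Mb chromosome) and θ = 4·N_e·mu ≈ 0.4 per marker site (so that most of
the 1,300 marker sites segregate at chip-like frequencies after the
burn-in). The standard study condition (`two_population_study_config`) is a
focal and a reference population splitting at the start of a 28-generation
phase with migration m = 0.01, 50 diploids sampled from each; sweep runs
place a hard sweep (single new copy, s = 1, N_e·s = 100) in the focal
population only and are redrawn until the derived allele reaches frequency
0.8, so that sampling happens shortly after fixation — the regime Rsb and
XP-EHH are designed for. Against these conditions the validation suite
measures sweep recovery of the full pipeline against matched neutral runs
(12 replicates per arm; one-sided Fisher test), the localization of the
extreme standardized score, neutral p-value calibration, and the classical
diffusion checks (neutral drift is a martingale; heterozygosity decays by
1 − 1/(2N_e) per generation; fixation probabilities match Kimura's
(1 − e^(−4N_e s p₀))/(1 − e^(−4N_e s)) within a binomial 99% CI).

What the generator does *not* emulate: ascertainment bias of real chips
beyond a MAF cutoff, variable recombination maps, genotyping error, phasing
error (input is phased by construction), and deep multi-population
histories. Passing tests demonstrate the statistics and the caller behave
correctly on data whose generating process is known — not that power on any
real panel equals the measured desk-scale power.

## F_ST outlier test

Differentiation decomposes on the logit scale, logit F_ST(i,j) = α_i + β_j,
with the locus effect α_i present only when locus i is selected. Population
allele frequencies are Beta-distributed around an ancestral frequency p_i
with precision θ_ij = (1 − F_ST)/F_ST, and observed derived counts are
binomial; the frequency integrates out to a beta-binomial cell likelihood
(the biallelic reduction of the multinomial-Dirichlet model — SNP-chip loci
are biallelic, which also keeps the reversible-jump moves simple).

The sampler updates p_i (reflected random walk on (0.01, 0.99)), α_i
(random walk, included loci only), β_j (random walk, Normal(−1, 1) prior),
and toggles α_i ∈ {0, free} by a reversible-jump move whose proposal is the
α prior (Normal(0, 1)), so proposal and prior densities cancel and the
acceptance ratio is the likelihood ratio times the prior odds for
neutrality (10, the conventional default; the α/β/p priors are arguments).
Twenty pilot runs of 5,000 iterations adapt all proposal widths toward
acceptance rates in [0.25, 0.45]; then 50,000 burn-in iterations and
100,000 sampling iterations thinned by 10 (5,000 kept) — the full-length
settings. A reduced preset (`McmcSettings.reduced`: 20,000 total
iterations) serves the validation suites. Loci are exchangeable by
construction: every locus draws its randomness from a counter-based stream
keyed by a hash of its identifier, and cross-locus likelihood sums are
accumulated in sorted order, so permuting locus order permutes the output
exactly.

Outliers are ranked by posterior inclusion probability; q-values are the
Bayesian FDR (running mean of 1 − P down the ranking, ties sharing the last
member's value) and loci with q ≤ 0.05 are called.

Two calibration facts, established while designing the validation suite and
worth knowing when interpreting results at few populations:

* With 3 populations a locus's realized dispersion carries two degrees of
  freedom, so even a strongly selected locus (α = 2.5) produces a
  nearly-null-looking draw in a sizeable fraction of datasets, and the
  *maximum* realized dispersion among hundreds of null loci is several
  times the null mean. A planted α = 2.5 locus among 499 null loci
  therefore attains the top inclusion probability in only ~55–70% of
  datasets — a ceiling shared by an ideal likelihood-ratio ranker with the
  true β known, i.e. a property of the data, not of the sampler. The
  validation suite measures this recovery rate; interpretation of
  single-locus outliers at 3 populations should bear it in mind.
* Planted-locus recovery studies pin the planted locus's ancestral
  frequency at 0.5 and redraw datasets until it passes the pooled MAF ≥
  0.05 filter (a near-monomorphic locus would never reach the test in a
  real pipeline, and an extreme ancestral frequency leaves no
  locus-specific information at all).

The generator's default population effect is β = −2 (background F_ST
≈ 0.12, the scale of differentiation between cattle breed groups). At only
3 populations the model's posterior mean F_ST sits slightly below the
generating value (the dispersion is estimated from 2 df per locus; a
profile-likelihood check shows the same for the likelihood itself), so the
posterior-recovery test runs at 8 populations, where the estimate is clean.

## Degenerate inputs and numerical conventions

Markers where either allele has fewer than two carriers yield undefined
EHH profiles (flagged, not raised) and are skipped by the scans, as are
markers with zero iHH/iES. Monomorphic loci are excluded from Weir-
Cockerham sums. Region/feature coordinates are 0-based half-open
internally; VCF and GFF3 are converted on read, BED passes through; marker
positions stay 1-based physical bp. The packaged region-table fixture is
checksummed (sha256) at load. All simulations and the MCMC are exactly
reproducible from their seed; the suite's problem sizes (12 replicates per
simulation arm, 10 MCMC recovery runs, 500-locus count matrices, 2,000
fixation replicates) were chosen so the whole validation runs on one CPU at
desk scale.
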