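# Methods

This note documents the statistical models, the defaults that matter, and
the design decisions behind `finemapkit`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Association testing and QC

Single-variant association uses the score-test form of the Cochran–Armitage
trend test, `χ² = U²/V` with `U = Σᵢ gᵢ(yᵢ − ȳ)` and
`V = ȳ(1−ȳ) Σᵢ (gᵢ − ḡ)²`, which on hard 0/1/2 calls equals the classical
2×3-table statistic (equivalently, `N·corr(g, y)²`) and extends naturally
to fractional imputed dosages. Effect sizes come from Newton–Raphson
maximum likelihood on the Bernoulli log-likelihood with an intercept;
convergence is declared when the largest score component falls below 1e-8
(cap 25 iterations). Quasi-complete separation makes the score vanish while
the MLE diverges, so any coefficient beyond ±15 log-odds flags the fit as
non-converged; nothing is reported silently. "Conditional logistic
regression" is ordinary (unconditional-likelihood) logistic regression with
the lead SNP's dosage as covariate — the design is population-based
case-control with no matched strata. A variant whose dosage is
near-collinear with the lead (1 − r² < 1e-8) cannot be conditioned and is
flagged rather than fitted.

Imputation certainty uses the ratio-of-variances information measure on
genotype-probability triples: `eᵢ = pᵢ₁ + 2pᵢ₂`, `fᵢ = pᵢ₁ + 4pᵢ₂`,
`Is = 1 − Σᵢ(fᵢ − eᵢ²)/(2N θ̂(1−θ̂))`, clamped to [0, 1]; a flat
HWE-prior posterior scores 0 and hard calls score 1. The risk-SNP filters
are applied exactly as printed in the source analysis: MAF strictly
greater than 0.01 (pooled cases+controls — the pooling is a package choice,
the source does not specify), Is ≥ 0.80 retained, trend p strictly below
5×10⁻⁷.

## LD estimation

From phased haplotypes, `D = f_AB − p_A p_B`, `r² = D²/(p_A q_A p_B q_B)`,
`D′ = |D|/D_max`. From unphased genotypes, haplotype frequencies come from
the Excoffier–Slatkin EM: all genotype pairs except double heterozygotes
determine their haplotypes; the 1/1 cell is split between cis and trans
resolutions in proportion to current frequency products. The EM is
initialised at linkage equilibrium with a single start (the two-locus
likelihood is well behaved) and stops when frequencies move less than 1e-8;
the observed-data log-likelihood is non-decreasing by construction and is
recorded per iteration. Proxy selection keeps variants with strict
r² > 0.2, sorted by descending r², position-ascending on ties.

## Regulatory annotation and prioritization

Variant positions are 1-based (VCF convention); interval tracks are 0-based
half-open (BED convention). A variant at position P overlaps [s, e) iff
s ≤ P−1 < e. bedGraph conservation tracks must be non-overlapping; a
position not covered by any interval yields a missing score, never 0.
Prioritization counts three binary criteria per variant — conserved
(phastCons ≥ 0.9 **or** GERP ≥ 2; the source argues conservation
qualitatively, so the cutoffs are package defaults exposed in config),
active enhancer (DNase **and** H3K27ac **and** H3K4me1), and motif
disruption (|allele delta| ≥ 3 log₂-odds units) — and ranks by evidence
count, then association p, then position. Super-enhancer and
contact-domain calls are consumed as published BED intervals; calling them
is out of scope.

## Motif disruption

JASPAR count matrices become probability matrices with
`(count + 0.25)/(colsum + 1)` (pseudocount 0.25, configurable) and
log₂-odds against a uniform 0.25 background. Scanning scores every window
on both strands (minus strand via reverse complement); windows containing N
are skipped; ties prefer the plus strand, then the leftmost window. The
allele delta considers **only** windows covering the variant — disruption
semantics: a strong intact match elsewhere in the context must not mask the
allele effect — and is positive when the alternate allele weakens the best
match.

## 4C-seq profiling

Fragments are defined by splitting at the first base of every primary-site
occurrence (DpnII cuts 5′ of GATC, so the cut-at-site-start blunt model
matches the enzyme); a fragment is blind iff it fully contains no
secondary site (HindIII, AAGCTT). Classification is at whole-fragment
level; no fragment-end sub-model. Reads (BED6, score = mapping quality) are
filtered at MAPQ ≥ 30, deduplicated on their 5′ position, and dropped
inside masked intervals or within 1.5 kb of the viewpoint (both
configurable; the masked region defaults to 10 kb around the viewpoint in
the fixture). Each surviving read is assigned to the fragment containing
its 5′ position; reads outside the map are counted and reported, never
fatal. Binned profiles (default 100 bp) spread each fragment's count over
the bins it overlaps in proportion to overlap length, preserving total
signal, with blind/non-blind/combined channels kept separate; no
cross-class normalization is applied (none is specified by the upstream
protocol, and the channels are reported side by side). Smoothing is a
centered running mean over `window/resolution` bins (default 5 kb / 100 bp
= 50 bins, covering `[i − 25, i + 25)`); masked bins contribute neither
numerator nor denominator, and a bin whose entire window is masked is
absent (NaN, omitted from bedGraph output, which rounds to 6 decimals).

## cis-eQTL, correlation and splicing

The eQTL scan regresses each gene's expression on risk-allele dosage by
OLS for genes whose TSS lies within 1 Mb of the SNP, with two-sided t
p-values and Benjamini–Hochberg q across the tested genes only. Samples
are joined on ids, so sample order is irrelevant; an id-based exclusion
list supports dropping samples with copy-number loss over the locus. No
expression normalization is performed — the package consumes
pre-normalized matrices, as the upstream arrays were. Spearman correlation
uses average ranks for ties with the large-sample t approximation.
Splicing support counts reads containing k-mers (default k = 31, an
implementer choice; the source does not state k) unique to each junction
sequence, including reverse complements (reads are strand-unaware), with
k-mers shared between events excluded from all of them; per-sample counts
between the two homozygote classes are compared by Student's t test.

## The synthetic locus

`LocusDesign` defaults define the study conditions: locus
chr15:40,379,030–40,532,514 (1-based inclusive, ~153 kb), causal per-allele
OR 1.35, pooled sample sizes 1,920 cases / 5,199 controls (517 + 1,403 and
2,698 + 2,501 from the two contributing scans), three proxies at
r² = 0.91/0.87/0.83 (the first standing in for the previously published
SNP at the reported r² = 0.91), ~30 independent background SNPs of which
two are rare (risk-allele frequency 0.003) to exercise the MAF filter, and
genome-wide filters exactly as above. The causal risk-allele frequency
defaults to 0.35 — the source never prints it, so this is an explicit
modelling choice.

Haplotypes are built pairwise against the causal SNP: given both allele
frequencies and a target r², the two-locus haplotype frequencies solve
analytically with D > 0, and each proxy is drawn conditionally on the
causal allele (proxies correlate with each other only through the causal
column — a single-underlying-variant architecture; no recombination maps
or coalescent realism). Infeasible targets (r² above
`D²_max/(p_A q_A p_B q_B)`) raise an error naming the maximum achievable
value. Disease status follows `logit P = logit(0.001) + log(OR)·dose`; the
baseline risk of 0.001 keeps the rare-disease regime where the sampled
per-allele OR approximates the generating OR, and sampling repeats in
vectorized chunks until the case/control quotas are met exactly.
Imputation uncertainty places probability mass `certainty` (default 0.99)
on the true genotype with the remainder split equally; dosages then become
posterior-expected doses, exactly as imputation software reports them. The
0.99 default keeps the two rare background SNPs below the 0.01 MAF cutoff
despite the uncertainty-induced upward bias of dosage-based allele
frequencies (floor `(1−c)/2` per haploid dose).

The genome is a seeded random sequence with the 23-bp probe context
`GAGGGGACTTT[C]CCTCCCCAAAC` planted around the causal position (non-risk C
allele in the reference); the 10-bp RELA-like motif `GGGACTTTCC` inside it
carries phastCons 1.00 over its footprint and GERP 4.81 at the causal
base. The bundled count matrix is a synthetic NF-κB p65-style PFM whose
consensus is the motif and whose variant column strongly prefers C, so the
risk allele's delta is positive by construction of the matrix, not of the
scorer. Primary/secondary restriction sites occur naturally in the random
sequence (~1 GATC per 256 bp).

4C reads follow per-fragment expected counts proportional to
`distance^(−1)` times a fold-enrichment over the distal end of the
super-enhancer, zero in masked intervals, realised as a multinomial draw
with read starts near a randomly chosen fragment end; ~3% of reads carry
sub-threshold mapping quality to exercise the filter. Two constraints tie
the generator's defaults to its own generative law: the fold-enrichment
(default 12) must exceed `(d_enriched/d_nearest_unmasked)^decay ≈ 7.2`, or
distance decay drowns the enrichment in expectation; and the read depth
(default 20,000) must keep the hottest non-viewpoint fragment's expected
count below about half the unique-position cap (~2 × read length), or
deduplication saturates counts and decouples them from contact weights.

Expression values for 426 samples (the expression-cohort size) are
`8 + β·dose + N(0, 1)` for the target gene (β = −0.5: risk allele lowers
expression) and intercept-plus-noise for 14 null genes, two of them placed
beyond the 1-Mb window to exercise the cis filter.

What passing tests on this fixture do **not** show: robustness to
population structure, genotyping batch effects, multi-locus LD beyond
pairwise structure, expression confounders, 4C re-ligation artefacts, or
trans contacts. The fixture demonstrates correctness of the statistical
machinery under its stated generative model, nothing more.

## Numerical choices and degenerate inputs

Monomorphic variants give a degenerate trend result (χ² = 0, p = 1) rather
than an error inside scans; the info score of a monomorphic posterior
(θ̂ ∈ {0,1}) is defined as 0 with a degeneracy flag; negative info values
are clamped to 0. BH q-values enforce monotonicity via the cumulative
minimum and preserve input order. Proxy and ranking ties break by genomic
position for determinism, and all simulation entry points take explicit
seeds: identical design ⇒ byte-identical fixture files (verified by
SHA-256 in the manifest).

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute of
simulation-heavy work: 200 replicates for odds-ratio recovery, 100 for LD
recovery and conditional-scan behaviour, 500 light replicates for the
empirical-FDR check, and the single full-size seed-42 locus shared across
tests.
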