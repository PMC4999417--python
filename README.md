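# finemapkit

Post-GWAS fine-mapping and regulatory-mechanism analysis for a single
disease risk locus, written for statistical geneticists who want to go from
"this region is associated" to "this base, in this enhancer, through this
transcription factor, on this gene".

The package implements the analysis chain used to dissect a B-cell
malignancy risk locus where the candidate causal SNP sits in a B
cell super-enhancer inside an intron of a BH3-only apoptosis gene, alters a
conserved NF-κB (RELA) binding motif, and is associated with reduced
expression of that gene:

1. **Association & QC** — Cochran–Armitage trend test (1 df, additive
   scores), Newton–Raphson logistic regression for per-allele odds ratios
   and covariate-adjusted conditional scans, the IMPUTE-style information
   measure `Is = 1 − Σᵢ(fᵢ − eᵢ²) / (2N·θ̂(1−θ̂))` for imputed genotype
   posteriors, and the risk-SNP filters (MAF > 0.01, Is ≥ 0.80,
   p < 5×10⁻⁷).
2. **LD** — haplotype r²/D′ by direct counting, and from unphased
   genotypes by the Excoffier–Slatkin EM; proxy selection at r² > 0.2.
3. **Regulatory annotation** — overlap of 1-based variant positions with
   0-based half-open BED tracks (DNase, H3K4me1/H3K27ac, TF binding,
   super-enhancer, contact domain) and conservation bedGraphs
   (phastCons, GERP); evidence-count ranking of candidates.
4. **Motif disruption** — JASPAR PFM → probability matrix (pseudocount
   0.25) → log₂-odds vs uniform background; bidirectional scanning; allele
   delta = best reference-allele window score minus best alternate-allele
   window score over variant-covering windows.
5. **4C-seq profiling** — in-silico DpnII/HindIII digestion, blind vs
   non-blind fragment classification, MAPQ ≥ 30 and unique-position read
   filtering, 100-bp binned profiles and a 5-kb running-window mean.
6. **cis-eQTL** — OLS of expression on risk-allele dosage for genes within
   1 Mb, Benjamini–Hochberg FDR, Spearman transcript correlation, and
   junction-k-mer splicing counts compared between homozygote classes.
7. **Synthetic locus** — a generator producing every input above (a
   ~150-kb locus, one causal SNP with per-allele OR 1.35 plus three
   high-LD proxies, genotype posteriors, tracks, a planted RELA motif,
   distance-decay 4C reads, an expression dose effect), so the whole
   pipeline runs and is tested without any external data.

## Worked example

```sh
finemapkit simulate --seed 42 --out locus/
finemapkit run --config locus/config.json
```

The second command logs one line per stage and finishes with:

```
{"stage": "associate", "n_in": 34, "n_out": 34, "seconds": 1.9}
{"stage": "filter", "n_in": 34, "n_out": 4, "seconds": 0.001}
...
top candidate: rs539846 (evidence 3/3, p=3.97e-12); report: locus/results/candidate_report.tsv
```

Of 34 simulated variants, exactly 4 survive the MAF/info/significance
filters (the causal SNP and its three r² > 0.8 proxies). In
`candidate_report.tsv` the causal SNP ranks first with OR ≈ 1.31
(generating value 1.35), trend p ≈ 4×10⁻¹², phastCons 1.00 / GERP 4.81, all
three enhancer marks, a motif delta of +3.7 log₂-odds units (the risk
allele weakens the RELA motif), and the target gene as its only
FDR-significant eQTL (q ≈ 1×10⁻⁷); the proxies' conditional p-values
(conditioning on the causal SNP) are all > 0.01, consistent with a single
underlying variant. The 4C stage writes raw and smoothed bedGraph tracks
per fragment class; the smoothed contact maximum outside the viewpoint
region falls in the simulated enriched interval at the distal end of the
super-enhancer.

Every subcommand (`assoc`, `ld`, `annotate`, `motif`, `fourc`, `eqtl`) is
also usable on its own files; `--help` documents the flags.

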