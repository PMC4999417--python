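"""Synthetic replica of a single disease risk locus, end to end.

Generates every input the analysis pipeline consumes, with the statistical
structure the downstream methods assume: a ~150-kb locus carrying one causal
SNP (per-allele odds ratio 1.35 by default) plus three high-LD proxies and
independent background SNPs; case-control genotypes sampled from a logistic
disease model; genotype-probability triples with controllable certainty
(emulating imputation); enhancer / super-enhancer / contact-domain BED
tracks; conservation bedGraphs pinning a perfectly conserved 10-bp motif on
the causal allele; a genome FASTA containing an NF-kB (RELA-like) motif
context centered on the causal SNP; a two-enzyme restriction-fragment
landscape with distance-decay 4C reads enriched at the distal end of the
super-enhancer; and an expression matrix with an allelic dose effect on one
target gene.

LD structure is pairwise against the causal SNP only (proxies are mutually
correlated through the causal column), matching a single-underlying-variant
architecture.  Coordinates: variant positions are 1-based (VCF convention);
all BED/bedGraph outputs are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotation import GenomicInterval, write_bed, write_bedgraph
from .eqtl import ExpressionMatrix, write_expression
from .fourc import FragmentMap, build_fragment_map
from .genotypes import GenotypeTable, write_genotype_table, write_phenotypes
from .motif import PWM, write_jaspar

__all__ = [
    "LocusDesign",
    "simulate_haplotypes",
    "simulate_case_control",
    "add_genotype_uncertainty",
    "table_with_uncertainty",
    "simulate_expression",
    "simulate_4c_reads",
    "expected_fragment_weights",
    "write_fixture_locus",
    "EMSA_CONTEXT",
    "RELA_CONSENSUS",
]

# Probe context around the causal SNP (non-risk allele C at offset 11); the
# 10-bp motif GGGACTTTCC occupies context offsets 3..12.
EMSA_CONTEXT = "GAGGGGACTTTCCCTCCCCAAAC"
EMSA_VARIANT_OFFSET = 11
RELA_CONSENSUS = "GGGACTTTCC"

# NF-kB p65 style count matrix (rows A, C, G, T), consensus GGGACTTTCC with
# a strongly preferred C at the variant-bearing position.
RELA_COUNTS = np.array(
    [
        #  G   G   G   A   C   T   T   T   C   C
        [ 1,  0,  1, 17,  0,  1,  0,  1,  1,  2],  # A
        [ 1,  1,  0,  1, 16,  1,  2,  1, 16, 14],  # C
        [16, 18, 17,  1,  1,  0,  1,  0,  1,  2],  # G
        [ 1,  0,  1,  0,  2, 17, 16, 17,  1,  1],  # T
    ],
    dtype=float,
)


@dataclass
class LocusDesign:
    """Design of the synthetic locus replica.

    Sample counts default to the pooled counts of the two contributing
    case-control scans (517 + 1,403 cases; 2,698 + 2,501 controls); the
    causal per-allele odds ratio defaults to 1.35 and the locus to the
    fine-mapped interval chr15:40,379,030-40,532,514 (1-based inclusive).
    The causal risk-allele frequency (0.35) is a modelling choice: the
    source association data never state it.
    """

    chrom: str = "chr15"
    locus_start: int = 40_379_030
    locus_end: int = 40_532_514
    causal_pos: int = 40_398_000
    causal_raf: float = 0.35
    causal_or: float = 1.35
    n_proxy_high: int = 3
    n_background: int = 30
    n_cases: int = 1_920
    n_controls: int = 5_199
    seed: int = 42
    baseline_risk: float = 0.001
    certainty: float = 0.99
    proxy_r2: tuple[float, ...] = (0.91, 0.87, 0.83)
    proxy_raf: tuple[float, ...] = (0.35, 0.36, 0.33)
    proxy_pos: tuple[int, ...] = (40_385_500, 40_410_250, 40_441_000)
    n_rare_background: int = 2
    rare_raf: float = 0.003
    n_haplotype_pool: int = 20_000
    n_expression_samples: int = 426
    expr_beta: float = -0.5
    expr_noise_sd: float = 1.0
    n_null_genes: int = 14
    target_gene: str = "BMF"
    # Unique-position deduplication caps a fragment at ~2 x read_length
    # distinct 5' positions; depth is chosen so the hottest non-viewpoint
    # fragment expects ~half that cap, keeping counts proportional to the
    # underlying contact weights after dedup.
    fourc_n_reads: int = 20_000
    fourc_decay: float = 1.0
    # The enrichment must exceed the decay ratio between the closest unmasked
    # distance (~10 kb) and the enriched interval's distance (~72 kb) from the
    # viewpoint, else the distance decay drowns it: fold > (72/10)^decay.
    fourc_fold: float = 12.0
    read_length: int = 150

    def __post_init__(self) -> None:
        if not 0.0 < self.causal_raf < 1.0:
            raise ValueError("causal_raf must lie in (0, 1)")
        if self.causal_or <= 0:
            raise ValueError("causal_or must be positive")
        for name in ("n_proxy_high", "n_background", "n_cases", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.locus_start >= self.locus_end:
            raise ValueError("locus_start must precede locus_end")
        if not self.locus_start <= self.causal_pos <= self.locus_end:
            raise ValueError("causal_pos outside locus")
        if len(self.proxy_r2) != self.n_proxy_high or len(self.proxy_raf) != self.n_proxy_high:
            raise ValueError("proxy_r2/proxy_raf must have length n_proxy_high")

    @property
    def offset(self) -> int:
        """0-based genomic coordinate of the first base of the locus."""
        return self.locus_start - 1

    @property
    def locus_length(self) -> int:
        return self.locus_end - self.locus_start + 1


def _max_r2(p_a: float, p_b: float) -> float:
    """Maximum achievable r^2 for two loci with D > 0."""
    dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    return dmax**2 / (p_a * (1 - p_a) * p_b * (1 - p_b))


def simulate_haplotypes(
    raf_per_snp,
    target_r2,
    n_haplotypes: int,
    seed: int,
    causal_index: int = 0,
) -> np.ndarray:
    """Binary haplotypes with prescribed pairwise r^2 against a causal SNP.

    Each non-causal SNP is generated conditionally on the causal allele so
    that the two-locus haplotype frequencies solve ``(p_A, p_B, r^2)``
    analytically with D > 0; SNPs with ``target_r2 = 0`` are independent.
    Empirical allele frequencies and r^2 converge to the targets as
    ``n_haplotypes`` grows.
    """
    raf = np.asarray(raf_per_snp, dtype=float)
    r2 = np.asarray(target_r2, dtype=float)
    if raf.shape != r2.shape or raf.ndim != 1:
        raise ValueError("raf_per_snp and target_r2 must be equal-length 1-D")
    if np.any(raf <= 0) or np.any(raf >= 1):
        raise ValueError("allele frequencies must lie in (0, 1)")
    if np.any(r2 < 0) or np.any(r2 > 1):
        raise ValueError("target r2 must lie in [0, 1]")
    if not 0 <= causal_index < len(raf):
        raise ValueError("causal_index out of range")
    rng = np.random.default_rng(seed)
    p_a = raf[causal_index]
    n_snps = len(raf)
    haps = np.empty((n_haplotypes, n_snps), dtype=np.int8)
    anchor = (rng.random(n_haplotypes) < p_a).astype(np.int8)
    haps[:, causal_index] = anchor
    for j in range(n_snps):
        if j == causal_index:
            continue
        p_b = raf[j]
        if r2[j] == 0.0:
            haps[:, j] = rng.random(n_haplotypes) < p_b
            continue
        r2max = _max_r2(p_a, p_b)
        if r2[j] > r2max + 1e-12:
            raise ValueError(
                f"target r2={r2[j]:.4g} infeasible for allele frequencies "
                f"({p_a:.4g}, {p_b:.4g}); maximum achievable r2 is {r2max:.4g}"
            )
        d = np.sqrt(r2[j] * p_a * (1 - p_a) * p_b * (1 - p_b))
        prob_given_1 = (p_a * p_b + d) / p_a
        prob_given_0 = ((1 - p_a) * p_b - d) / (1 - p_a)
        u = rng.random(n_haplotypes)
        haps[:, j] = np.where(anchor == 1, u < prob_given_1, u < prob_given_0)
    return haps


def simulate_case_control(
    haplotypes: np.ndarray,
    causal_column: int,
    or_per_allele: float,
    n_cases: int,
    n_controls: int,
    baseline_risk: float = 0.001,
    seed: int = 0,
    variants: pd.DataFrame | None = None,
    max_draws: int = 50_000_000,
) -> tuple[GenotypeTable, np.ndarray]:
    """Case-control genotypes under a logistic disease model.

    Diploid genotypes are formed by random pairing (with replacement) of
    pool haplotypes; disease status follows
    ``logit P(case) = logit(baseline_risk) + log(OR) * dose`` where dose is
    the causal-allele count.  Sampling repeats until both quotas are met.
    In the rare-disease regime (small ``baseline_risk``) the per-allele OR
    of the sampled data approximates the generating OR.
    """
    haps = np.asarray(haplotypes)
    if haps.ndim != 2 or haps.shape[0] < 2:
        raise ValueError("need a 2-D haplotype pool")
    if or_per_allele <= 0:
        raise ValueError("or_per_allele must be positive")
    if not 0 < baseline_risk < 1:
        raise ValueError("baseline_risk must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_pool = haps.shape[0]
    alpha = logit(baseline_risk)
    log_or = np.log(or_per_allele)
    causal = haps[:, causal_column].astype(np.int16)
    case_pairs: list[np.ndarray] = []
    ctrl_pairs: list[np.ndarray] = []
    need_cases, need_controls = n_cases, n_controls
    drawn = 0
    chunk = max(50_000, min(500_000, 20 * (n_cases + n_controls)))
    while (need_cases > 0 or need_controls > 0) and drawn < max_draws:
        m = min(chunk, max_draws - drawn)
        drawn += m
        i1 = rng.integers(n_pool, size=m)
        i2 = rng.integers(n_pool, size=m)
        dose = causal[i1] + causal[i2]
        y = rng.random(m) < expit(alpha + log_or * dose)
        if need_cases > 0:
            sel = np.flatnonzero(y)[:need_cases]
            case_pairs.append(np.column_stack([i1[sel], i2[sel]]))
            need_cases -= len(sel)
        if need_controls > 0:
            sel = np.flatnonzero(~y)[:need_controls]
            ctrl_pairs.append(np.column_stack([i1[sel], i2[sel]]))
            need_controls -= len(sel)
    if need_cases > 0 or need_controls > 0:
        raise RuntimeError(
            f"sampling quota unreachable within {max_draws} draws: attained "
            f"{n_cases - need_cases}/{n_cases} cases, "
            f"{n_controls - need_controls}/{n_controls} controls"
        )
    pairs = np.vstack(case_pairs + ctrl_pairs)
    genotypes = haps[pairs[:, 0]].astype(np.int16) + haps[pairs[:, 1]].astype(np.int16)
    phenotype = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    sample_ids = [f"case{i:05d}" for i in range(n_cases)] + [
        f"control{i:05d}" for i in range(n_controls)
    ]
    if variants is None:
        variants = pd.DataFrame(
            {
                "variant_id": [f"snp{j:04d}" for j in range(haps.shape[1])],
                "chrom": "chrS",
                "pos": np.arange(1, haps.shape[1] + 1) * 1000,
                "ref": "C",
                "alt": "A",
            }
        )
    table = GenotypeTable(variants, genotypes.astype(float), sample_ids)
    return table, phenotype


def add_genotype_uncertainty(genotypes, certainty: float, seed: int | None = None) -> np.ndarray:
    """Genotype-probability triples with mass ``certainty`` on the truth.

    The remaining ``1 - certainty`` is split equally over the other two
    genotypes (a fixed, deterministic rule; ``seed`` is accepted for
    interface uniformity but unused).  ``certainty = 1`` reproduces hard
    calls; values at or below 1/3 are rejected because the true genotype
    would no longer be the posterior mode.
    """
    if not (1.0 / 3.0) < certainty <= 1.0:
        raise ValueError("certainty must lie in (1/3, 1]")
    g = np.asarray(genotypes)
    if set(np.unique(g)) - {0, 1, 2}:
        raise ValueError("genotypes must be hard 0/1/2 calls")
    rest = (1.0 - certainty) / 2.0
    probs = np.full(g.shape + (3,), rest)
    for k in range(3):
        probs[..., k] = np.where(g == k, certainty, rest)
    return probs


def table_with_uncertainty(table: GenotypeTable, certainty: float) -> GenotypeTable:
    """Attach uncertainty triples to a hard-call table; dosages become the
    posterior-expected dose, as imputation software reports."""
    probs = add_genotype_uncertainty(np.round(table.dosages).astype(int), certainty)
    dosages = probs[..., 1] + 2.0 * probs[..., 2]
    return GenotypeTable(table.variants.copy(), dosages, list(table.sample_ids), probs)


def simulate_expression(
    dosage,
    target_gene: str = "BMF",
    beta_per_allele: float = -0.5,
    noise_sd: float = 1.0,
    n_null_genes: int = 14,
    n_samples: int | None = None,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    genes: pd.DataFrame | None = None,
    intercept: float = 8.0,
) -> ExpressionMatrix:
    """Expression matrix with an allelic dose effect on one target gene.

    Target gene: ``intercept + beta * dose + N(0, noise_sd)``; null genes
    are intercept plus noise.  A negative beta means the risk allele lowers
    expression.  Default gene metadata places the target near the causal
    SNP, most null genes inside the 1-Mb cis window and two beyond it.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    dose = np.asarray(dosage, dtype=float)
    if n_samples is None:
        n_samples = len(dose)
    if n_samples > len(dose):
        raise ValueError("n_samples exceeds available dosages")
    dose = dose[:n_samples]
    rng = np.random.default_rng(seed)
    if genes is None:
        rows = [{"gene_id": target_gene, "chrom": "chr15", "tss": 40_401_000}]
        inside = [39_500_000 + 120_000 * k for k in range(max(n_null_genes - 2, 0))]
        outside = [39_200_000, 41_600_000][: min(2, n_null_genes)]
        for k, tss in enumerate(inside + outside):
            rows.append({"gene_id": f"GENE{k + 1:02d}", "chrom": "chr15", "tss": tss})
        genes = pd.DataFrame(rows)
    if target_gene not in set(genes["gene_id"]):
        raise ValueError(f"target gene {target_gene!r} not in gene metadata")
    values = intercept + rng.normal(scale=noise_sd, size=(len(genes), n_samples))
    tgt = genes.index[genes["gene_id"] == target_gene][0]
    values[tgt] += beta_per_allele * dose
    if sample_ids is None:
        sample_ids = [f"sample{i:05d}" for i in range(n_samples)]
    return ExpressionMatrix(genes, values, list(sample_ids[:n_samples]))


def expected_fragment_weights(
    fmap: FragmentMap,
    viewpoint_fragment: int,
    decay_exponent: float = 1.0,
    enriched_intervals: list[tuple[int, int, float]] | None = None,
    masked_interval: tuple[int, int] | None = None,
) -> np.ndarray:
    """Unnormalised expected 4C read weight per fragment.

    Weight is ``distance^(-decay)`` from the fragment midpoint to the
    viewpoint midpoint, times any fold-enrichment whose interval contains
    the midpoint; fragments overlapping the masked interval and the
    viewpoint fragment itself get zero.
    """
    frags = fmap.fragments
    if len(frags) == 0:
        raise ValueError("empty fragment map")
    if not 0 <= viewpoint_fragment < len(frags):
        raise ValueError("viewpoint fragment outside fragment map")
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be positive")
    mids = (frags["start"].to_numpy() + frags["end"].to_numpy()) / 2.0
    vp_mid = mids[viewpoint_fragment]
    dist = np.maximum(np.abs(mids - vp_mid), 1.0)
    w = dist**-decay_exponent
    w[viewpoint_fragment] = 0.0
    for s, e, fold in enriched_intervals or []:
        w[(mids >= s) & (mids < e)] *= fold
    if masked_interval is not None:
        ms, me = masked_interval
        overlap = (frags["start"].to_numpy() < me) & (frags["end"].to_numpy() > ms)
        w[overlap] = 0.0
    return w


def simulate_4c_reads(
    fragment_map: FragmentMap,
    viewpoint_fragment: int,
    decay_exponent: float = 1.0,
    enriched_intervals: list[tuple[int, int, float]] | None = None,
    masked_interval: tuple[int, int] | None = None,
    n_reads: int = 120_000,
    seed: int = 0,
    read_length: int = 150,
    low_mapq_fraction: float = 0.03,
) -> pd.DataFrame:
    """Mapped single-end 4C reads as BED6 records (score = mapping quality).

    Per-fragment expected counts follow the distance-decay law of
    :func:`expected_fragment_weights`; realised counts are multinomial.
    Reads start near a randomly chosen fragment end (within one read length)
    on the plus strand; a small fraction carry sub-threshold mapping
    quality to exercise downstream filtering.
    """
    w = expected_fragment_weights(
        fragment_map, viewpoint_fragment, decay_exponent, enriched_intervals, masked_interval
    )
    total = w.sum()
    if total <= 0:
        raise ValueError("all fragment weights are zero")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, w / total)
    frags = fragment_map.fragments
    rows = []
    read_no = 0
    for (chrom, s, e), c in zip(
        frags[["chrom", "start", "end"]].itertuples(index=False, name=None), counts
    ):
        if c == 0:
            continue
        flen = e - s
        span = min(read_length, flen)
        side = rng.random(c) < 0.5
        offs = rng.integers(0, span, size=c)
        pos = np.where(side, s + offs, e - 1 - offs)
        for p in pos:
            start = int(p)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + read_length, e),
                    "name": f"read{read_no:07d}",
                    "mapq": 60,
                    "strand": "+",
                }
            )
            read_no += 1
    reads = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "mapq", "strand"])
    low = rng.random(len(reads)) < low_mapq_fraction
    reads.loc[low, "mapq"] = rng.integers(0, 30, size=int(low.sum()))
    return reads


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.array(list("ACGT"))


def _plant(genome: np.ndarray, local_start: int, seq: str) -> None:
    idx = {b: i for i, b in enumerate("ACGT")}
    genome[local_start : local_start + len(seq)] = [idx[c] for c in seq]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_locus(design: LocusDesign, outdir, overwrite: bool = False) -> dict:
    """Write the complete synthetic locus fixture and return its manifest.

    Identical designs produce byte-identical file sets.  See the module
    docstring for what is generated; a pipeline-ready ``config.json`` and a
    ``manifest.json`` with per-file SHA-256 checksums are included.
    """
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    off = design.offset
    length = design.locus_length
    causal0 = design.causal_pos - 1  # 0-based genomic

    # --- genome with planted motif context -------------------------------
    genome = _random_genome(rng, length)
    ctx_local = causal0 - off - EMSA_VARIANT_OFFSET
    _plant(genome, ctx_local, EMSA_CONTEXT)
    seq = "".join(_BASES[genome])
    fasta_path = out / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{design.chrom}\n")
        for i in range(0, length, 70):
            fh.write(seq[i : i + 70] + "\n")

    # --- variant panel ---------------------------------------------------
    taken = {design.causal_pos, *design.proxy_pos}
    n_bg = design.n_background
    positions = []
    while len(positions) < n_bg:
        p = int(rng.integers(design.locus_start, design.locus_end + 1))
        if p in taken or abs(p - design.causal_pos) <= len(EMSA_CONTEXT):
            continue
        taken.add(p)
        positions.append(p)
    bg_raf = rng.uniform(0.05, 0.5, size=n_bg)
    bg_raf[: design.n_rare_background] = design.rare_raf
    records = [
        {"pos": design.causal_pos, "raf": design.causal_raf, "r2": 1.0, "kind": "causal"}
    ]
    for p, r2, raf in zip(design.proxy_pos, design.proxy_r2, design.proxy_raf):
        records.append({"pos": p, "raf": raf, "r2": r2, "kind": "proxy"})
    for p, raf in zip(positions, bg_raf):
        records.append({"pos": p, "raf": raf, "r2": 0.0, "kind": "background"})
    panel = pd.DataFrame(records).sort_values("pos").reset_index(drop=True)
    refs, alts = [], []
    for p, kind in zip(panel["pos"], panel["kind"]):
        base = seq[p - 1 - off]
        if kind == "causal":
            refs.append("C")
            alts.append("A")
        else:
            refs.append(base)
            alts.append(rng.choice([b for b in "ACGT" if b != base]))
    panel["ref"], panel["alt"] = refs, alts
    panel["variant_id"] = [
        "rs539846" if k == "causal" else f"rsS{i:04d}"
        for i, k in enumerate(panel["kind"])
    ]
    variants = pd.DataFrame(
        {
            "variant_id": panel["variant_id"],
            "chrom": design.chrom,
            "pos": panel["pos"],
            "ref": panel["ref"],
            "alt": panel["alt"],
        }
    )
    causal_idx = int(panel.index[panel["kind"] == "causal"][0])

    # --- genotypes and phenotypes ---------------------------------------
    haps = simulate_haplotypes(
        panel["raf"].to_numpy(),
        panel["r2"].to_numpy(),
        design.n_haplotype_pool,
        seed=int(rng.integers(2**31 - 1)),
        causal_index=causal_idx,
    )
    table, phenotype = simulate_case_control(
        haps,
        causal_idx,
        design.causal_or,
        design.n_cases,
        design.n_controls,
        design.baseline_risk,
        seed=int(rng.integers(2**31 - 1)),
        variants=variants,
    )
    table = table_with_uncertainty(table, design.certainty)
    write_genotype_table(table, out / "genotypes.tsv", out / "genotype_probs.tsv")
    write_phenotypes(table.sample_ids, phenotype, out / "phenotypes.tsv")

    # --- annotation tracks (0-based half-open) ---------------------------
    chrom = design.chrom
    se_start, se_end = 40_390_000, 40_470_000  # ~80 kb, contains the causal SNP
    proxy1 = design.proxy_pos[0]
    tracks = {
        "dnase": [
            GenomicInterval(chrom, causal0 - 700, causal0 + 700, "DNase_pk1"),
            GenomicInterval(chrom, 40_430_000, 40_431_500, "DNase_pk2"),
        ],
        "h3k4me1": [
            GenomicInterval(chrom, causal0 - 1_200, causal0 + 900, "H3K4me1_pk1"),
            GenomicInterval(chrom, 40_452_000, 40_454_000, "H3K4me1_pk2"),
        ],
        "h3k27ac": [
            GenomicInterval(chrom, causal0 - 900, causal0 + 1_100, "H3K27ac_pk1"),
            GenomicInterval(chrom, proxy1 - 500, proxy1 + 700, "H3K27ac_pk2"),
            GenomicInterval(chrom, 40_462_000, 40_470_000, "H3K27ac_pk3"),
        ],
        "tf_rela": [
            GenomicInterval(chrom, causal0 - 250, causal0 + 250, "RELA_pk1"),
            GenomicInterval(chrom, 40_463_500, 40_465_000, "RELA_pk2"),
        ],
        "super_enhancer": [GenomicInterval(chrom, se_start, se_end, "SE_Bcell")],
        "contact_domain": [GenomicInterval(chrom, 40_384_000, 40_478_000, "domain1")],
    }
    track_paths = {}
    for name, ivs in tracks.items():
        path = out / f"{name}.bed"
        write_bed(ivs, path)
        track_paths[name] = path.name

    phastcons = [
        GenomicInterval(chrom, design.proxy_pos[0] - 50, design.proxy_pos[0] + 50, value=0.12),
        GenomicInterval(chrom, causal0 - 8, causal0 + 2, value=1.00),
        GenomicInterval(chrom, design.proxy_pos[1] - 30, design.proxy_pos[1] + 30, value=0.20),
        GenomicInterval(chrom, design.proxy_pos[2] - 30, design.proxy_pos[2] + 30, value=0.31),
    ]
    gerp = [
        GenomicInterval(chrom, design.proxy_pos[0] - 20, design.proxy_pos[0] + 20, value=0.52),
        GenomicInterval(chrom, causal0, causal0 + 1, value=4.81),
        GenomicInterval(chrom, design.proxy_pos[1] - 20, design.proxy_pos[1] + 20, value=-1.20),
        GenomicInterval(chrom, design.proxy_pos[2] - 20, design.proxy_pos[2] + 20, value=0.80),
    ]
    write_bedgraph(sorted(phastcons, key=lambda iv: iv.start), out / "phastcons.bedgraph")
    write_bedgraph(sorted(gerp, key=lambda iv: iv.start), out / "gerp.bedgraph")

    # --- motif model -----------------------------------------------------
    pwm = PWM(id="SYN0001", name="RELA_synthetic", counts=RELA_COUNTS)
    write_jaspar([pwm], out / "rela_pfm.jaspar")

    # --- 4C design and reads --------------------------------------------
    fmap = build_fragment_map(
        {chrom: seq}, offsets={chrom: off}
    )
    vp_idx = fmap.fragment_at(chrom, causal0 + 200)
    if vp_idx < 0:
        vp_idx = fmap.fragment_at(chrom, causal0)
    vp = fmap.fragments.iloc[vp_idx]
    vp_mid = int((vp["start"] + vp["end"]) // 2)
    enriched = [(40_462_000, 40_470_000, design.fourc_fold)]
    masked = (vp_mid - 5_000, vp_mid + 5_000)
    reads = simulate_4c_reads(
        fmap,
        vp_idx,
        design.fourc_decay,
        enriched,
        masked_interval=masked,
        n_reads=design.fourc_n_reads,
        seed=int(rng.integers(2**31 - 1)),
        read_length=design.read_length,
    )
    reads_path = out / "fourc_reads.bed"
    reads.to_csv(reads_path, sep="\t", header=False, index=False)

    # --- expression ------------------------------------------------------
    case_ids = table.sample_ids[: design.n_expression_samples]
    dose = np.round(table.dosages[: design.n_expression_samples, causal_idx])
    expr = simulate_expression(
        dose,
        target_gene=design.target_gene,
        beta_per_allele=design.expr_beta,
        noise_sd=design.expr_noise_sd,
        n_null_genes=design.n_null_genes,
        seed=int(rng.integers(2**31 - 1)),
        sample_ids=case_ids,
    )
    write_expression(expr, out / "expression.tsv")

    # --- pipeline config and manifest ------------------------------------
    config = {
        "genotypes": "genotypes.tsv",
        "probabilities": "genotype_probs.tsv",
        "phenotypes": "phenotypes.tsv",
        "expression": "expression.tsv",
        "genome_fasta": "genome.fa",
        "genome_offset": off,
        "pfm": "rela_pfm.jaspar",
        "fourc_reads": "fourc_reads.bed",
        "outdir": "results",
        "region_chrom": design.chrom,
        "region_start": design.locus_start,
        "region_end": design.locus_end,
        "viewpoint": [design.chrom, int(vp["start"]), int(vp["end"])],
        "fourc_masked": [list(masked)],
        "maf_min": 0.01,
        "info_min": 0.80,
        "p_max": 5.0e-7,
        "r2_min": 0.2,
        "fdr": 0.05,
        "motif_delta_min": 3.0,
        "phastcons_min": 0.9,
        "gerp_min": 2.0,
        "fourc_resolution": 100,
        "fourc_window": 5000,
        "min_mapq": 30,
        "exclusion_radius": 1500,
        "eqtl_window_bp": 1_000_000,
        "seed": design.seed,
    }
    for name, fname in track_paths.items():
        config[f"track_{name}"] = fname
    config["cons_phastcons"] = "phastcons.bedgraph"
    config["cons_gerp"] = "gerp.bedgraph"
    with open(out / "config.json", "w") as fh:
        json.dump(config, fh, indent=1, sort_keys=True)

    files = sorted(
        p.name
        for p in out.iterdir()
        if p.is_file() and p.name != "manifest.json" and not p.name.endswith(".fai")
    )
    manifest = {
        "design": asdict(design),
        "causal_variant": "rs539846",
        "viewpoint_fragment": [design.chrom, int(vp["start"]), int(vp["end"])],
        "enriched_interval": list(enriched[0][:2]),
        "files": {name: {"sha256": _sha256(out / name), "bytes": (out / name).stat().st_size}
                  for name in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
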