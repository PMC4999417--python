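"""cis-eQTL dose testing, FDR control, expression correlation, splicing k-mers.

The eQTL scan regresses each gene's expression on the risk-allele dosage of
one SNP for all genes whose TSS lies within a window (default 1 Mb) of the
SNP, and controls the false discovery rate across the tested genes with the
Benjamini-Hochberg step-up procedure.  Spearman rank correlation relates two
transcripts' expression.  Splicing support is quantified by counting reads
carrying k-mers unique to each splice-junction sequence and comparing the
per-sample counts between homozygote genotype classes with a Student t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "eqtl_scan",
    "bh_fdr",
    "spearman_corr",
    "count_junction_kmers",
    "splice_ttest",
]

GENE_COLUMNS = ["gene_id", "chrom", "tss"]


@dataclass
class ExpressionMatrix:
    """Genes x samples continuous expression values with TSS metadata."""

    genes: pd.DataFrame  # gene_id, chrom, tss (1-based)
    values: np.ndarray  # genes x samples
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene metadata missing columns: {missing}")
        self.genes = self.genes.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.genes):
            raise ValueError("value rows must match genes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if not self.sample_ids:
            self.sample_ids = [f"sample{i:05d}" for i in range(self.values.shape[1])]
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length must match value columns")

    def expression_of(self, gene_id: str) -> np.ndarray:
        idx = self.genes.index[self.genes["gene_id"] == gene_id]
        if len(idx) == 0:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self.values[int(idx[0])]


def write_expression(expr: ExpressionMatrix, path) -> None:
    vals = pd.DataFrame(np.round(expr.values, 6), columns=expr.sample_ids, copy=False)
    df = pd.concat([expr.genes[GENE_COLUMNS].reset_index(drop=True), vals], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_ids = [c for c in df.columns if c not in GENE_COLUMNS]
    return ExpressionMatrix(df[GENE_COLUMNS], df[sample_ids].to_numpy(dtype=float), sample_ids)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a nonempty 1-D array")
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def eqtl_scan(
    expr: ExpressionMatrix,
    genotypes: GenotypeTable,
    snp_id: str,
    window_bp: int = 1_000_000,
    exclude_samples: tuple[str, ...] = (),
) -> pd.DataFrame:
    """cis-eQTL scan: OLS of each nearby gene's expression on SNP dosage.

    Samples are joined on ids (order-independent); ``exclude_samples``
    supports dropping e.g. cases with copy-number loss over the locus.
    Genes on the SNP's chromosome with ``|tss - pos| <= window_bp`` are
    tested; q is the BH-adjusted p across tested genes only.
    """
    j = genotypes.index_of(snp_id)
    snp = genotypes.variants.iloc[j]
    excl = set(exclude_samples)
    geno_order = {s: i for i, s in enumerate(genotypes.sample_ids)}
    shared = [s for s in expr.sample_ids if s in geno_order and s not in excl]
    if len(shared) < 3:
        raise ValueError("fewer than 3 samples after join")
    expr_order = {s: i for i, s in enumerate(expr.sample_ids)}
    dose = genotypes.dosages[[geno_order[s] for s in shared], j]
    if np.var(dose) == 0:
        raise ValueError(f"SNP {snp_id!r} has zero dosage variance in joined samples")
    cols = [expr_order[s] for s in shared]
    near = (expr.genes["chrom"] == snp["chrom"]) & (
        (expr.genes["tss"] - int(snp["pos"])).abs() <= window_bp
    )
    rows = []
    for gi in np.flatnonzero(near.to_numpy()):
        y = expr.values[gi, cols]
        fit = stats.linregress(dose, y)
        rows.append(
            {
                "gene_id": expr.genes.iloc[gi]["gene_id"],
                "beta": fit.slope,
                "se": fit.stderr,
                "p": fit.pvalue,
                "n": len(shared),
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "beta", "se", "p", "n"])
    if len(df):
        df["q"] = bh_fdr(np.clip(df["p"].to_numpy(), 1e-300, 1.0))
    else:
        df["q"] = []
    return df


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 5:
        raise ValueError("x and y must be equal-length 1-D with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _kmers(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def count_junction_kmers(
    reads: list[str],
    event_junction_seqs: dict[str, str],
    k: int = 31,
) -> dict[str, int]:
    """Count reads supporting each splicing event via junction-unique k-mers.

    An event's k-mer set is built from its junction sequence and the reverse
    complement (reads are strand-unaware); k-mers shared between events are
    excluded from all sets, so counts are event-specific.  A read counts for
    an event if it contains at least one of that event's unique k-mers.
    """
    if not event_junction_seqs:
        raise ValueError("no events given")
    for name, seq in event_junction_seqs.items():
        if len(seq) < k:
            raise ValueError(f"junction sequence for {name!r} shorter than k={k}")
    raw = {
        name: _kmers(seq, k) | _kmers(_revcomp(seq.upper()), k)
        for name, seq in event_junction_seqs.items()
    }
    counts_of: dict[str, int] = {}
    all_kmers: dict[str, int] = {}
    for s in raw.values():
        for km in s:
            all_kmers[km] = all_kmers.get(km, 0) + 1
    unique = {name: {km for km in s if all_kmers[km] == 1} for name, s in raw.items()}
    counts = {name: 0 for name in event_junction_seqs}
    for read in reads:
        read = read.upper()
        if len(read) < k:
            continue
        rk = _kmers(read, k)
        for name, uset in unique.items():
            if rk & uset:
                counts[name] += 1
    return counts


def splice_ttest(counts_group_a, counts_group_b) -> tuple[float, float]:
    """Student t test (equal variances) on per-sample junction counts
    between two genotype classes (e.g. risk vs non-risk homozygotes)."""
    a = np.asarray(counts_group_a, dtype=float)
    b = np.asarray(counts_group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
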