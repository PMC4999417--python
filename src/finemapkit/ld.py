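"""Two-locus linkage disequilibrium estimation and proxy selection.

Haplotype-based r2/D' come from the closed form on observed haplotype
counts.  For unphased diploid genotypes, haplotype frequencies are estimated
with the Excoffier-Slatkin EM algorithm, which resolves the phase ambiguity
of double heterozygotes under Hardy-Weinberg equilibrium; its expected
complete-data log-likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = [
    "HaplotypeFreqs",
    "EMEstimate",
    "r2_from_haplotypes",
    "em_haplotype_freqs",
    "ld_proxies",
]


@dataclass
class HaplotypeFreqs:
    """Two-locus haplotype frequencies and derived LD measures.

    Allele coding: "A"/"B" denote the counted (alternate) allele at the
    first/second locus, lower case the other allele, so ``f_AB`` is the
    frequency of the haplotype carrying both counted alleles.
    """

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    D: float = field(init=False)
    r2: float = field(init=False)
    dprime: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.f_AB + self.f_Ab + self.f_aB + self.f_ab
        if abs(total - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        p_a, p_b = self.p_A, self.p_B
        self.D = self.f_AB - p_a * p_b
        denom = p_a * (1 - p_a) * p_b * (1 - p_b)
        if denom <= 0:
            raise ValueError("r2 undefined for a monomorphic locus")
        self.r2 = float(min(self.D**2 / denom, 1.0))
        if self.D >= 0:
            dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
        else:
            dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
        self.dprime = float(min(abs(self.D) / dmax, 1.0)) if dmax > 0 else 0.0

    @property
    def p_A(self) -> float:
        return self.f_AB + self.f_Ab

    @property
    def p_B(self) -> float:
        return self.f_AB + self.f_aB


@dataclass
class EMEstimate:
    freqs: HaplotypeFreqs
    converged: bool
    n_iter: int
    logliks: list[float]


def r2_from_haplotypes(hapA, hapB) -> HaplotypeFreqs:
    """LD from phased binary haplotype vectors by direct counting."""
    a = np.asarray(hapA, dtype=int)
    b = np.asarray(hapB, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("haplotype vectors must be equal-length 1-D, n >= 2")
    if set(np.unique(a)) - {0, 1} or set(np.unique(b)) - {0, 1}:
        raise ValueError("haplotypes must be binary 0/1")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("monomorphic locus: r2 undefined")
    n = len(a)
    f_ab_11 = np.sum((a == 1) & (b == 1)) / n
    f_10 = np.sum((a == 1) & (b == 0)) / n
    f_01 = np.sum((a == 0) & (b == 1)) / n
    f_00 = np.sum((a == 0) & (b == 0)) / n
    return HaplotypeFreqs(f_ab_11, f_10, f_01, f_00)


def _genotype_counts(genoA, genoB) -> np.ndarray:
    a = np.asarray(genoA)
    b = np.asarray(genoB)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("genotype vectors must be equal-length 1-D")
    if set(np.unique(a)) - {0, 1, 2} or set(np.unique(b)) - {0, 1, 2}:
        raise ValueError("genotypes must be 0/1/2")
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((a == i) & (b == j))
    return counts


def em_haplotype_freqs(genoA, genoB, tol: float = 1e-8, max_iter: int = 1000) -> EMEstimate:
    """Excoffier-Slatkin EM for two-locus haplotype frequencies.

    Genotypes are counts of the alternate allele (0/1/2) at each locus.
    Apart from double heterozygotes every genotype pair determines its two
    haplotypes; the 1/1 cell is split between cis (AB/ab) and trans (Ab/aB)
    resolutions in proportion to the current frequency products.  Initialised
    at linkage equilibrium (a single start: the 2-locus likelihood is
    well-behaved).
    """
    counts = _genotype_counts(genoA, genoB)
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes")
    p_a = (counts * np.arange(3)[:, None]).sum() / (2 * n)
    p_b = (counts * np.arange(3)[None, :]).sum() / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic locus: r2 undefined")

    # Fixed haplotype contributions from unambiguous cells: for genotype
    # (i, j) != (1, 1), each sample contributes known counts of the four
    # haplotypes.  hap order: AB, Ab, aB, ab.
    base = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if (i, j) == (1, 1):
                continue
            c = counts[i, j]
            if c == 0:
                continue
            # haplotypes: locus A alleles (i copies of A), locus B (j of B)
            n_A, n_a = i, 2 - i
            n_B, n_b = j, 2 - j
            # For non double-het cells the pairing is forced.
            ab_pairs = {
                (0, 0): (0, 0, 0, 2),
                (0, 1): (0, 0, 1, 1),
                (0, 2): (0, 0, 2, 0),
                (1, 0): (0, 1, 0, 1),
                (1, 2): (1, 0, 1, 0),
                (2, 0): (0, 2, 0, 0),
                (2, 1): (1, 1, 0, 0),
                (2, 2): (2, 0, 0, 0),
            }[(i, j)]
            base += c * np.array(ab_pairs, dtype=float)
    n_dh = counts[1, 1]

    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    logliks: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split double heterozygotes between cis and trans phase.
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        tot = cis + trans
        w_cis = 0.5 if tot == 0 else cis / tot
        hap_counts = base.copy()
        hap_counts += n_dh * np.array([w_cis, 1 - w_cis, 1 - w_cis, w_cis])
        new_f = hap_counts / (2 * n)
        logliks.append(_obs_loglik(counts, new_f))
        if np.max(np.abs(new_f - f)) < tol:
            f = new_f
            converged = True
            break
        f = new_f
    freqs = HaplotypeFreqs(*f)
    return EMEstimate(freqs, converged, it, logliks)


def _obs_loglik(counts: np.ndarray, f: np.ndarray) -> float:
    """Observed-data multinomial log-likelihood of the 3x3 genotype table
    under HWE with haplotype frequencies ``f`` (AB, Ab, aB, ab)."""
    f_AB, f_Ab, f_aB, f_ab = f
    prob = np.zeros((3, 3))
    prob[0, 0] = f_ab**2
    prob[0, 1] = 2 * f_ab * f_aB
    prob[0, 2] = f_aB**2
    prob[1, 0] = 2 * f_ab * f_Ab
    prob[1, 1] = 2 * (f_AB * f_ab + f_Ab * f_aB)
    prob[1, 2] = 2 * f_AB * f_aB
    prob[2, 0] = f_Ab**2
    prob[2, 1] = 2 * f_AB * f_Ab
    prob[2, 2] = f_AB**2
    with np.errstate(divide="ignore"):
        ll = np.where(counts > 0, counts * np.log(np.clip(prob, 1e-300, None)), 0.0)
    return float(ll.sum())


def ld_proxies(table: GenotypeTable, lead_id: str, r2_min: float = 0.2) -> pd.DataFrame:
    """Variants in LD with the lead SNP (strict ``r2 > r2_min``).

    Dosages are rounded to hard calls for the EM.  Result is sorted by
    descending r2, ties broken by ascending genomic position; the lead
    itself and monomorphic variants are excluded.
    """
    lead = np.round(table.dosage_of(lead_id)).astype(int)
    if len(np.unique(lead)) < 2:
        raise ValueError(f"lead variant {lead_id!r} is monomorphic")
    rows = []
    for j in range(table.n_variants):
        var = table.variants.iloc[j]
        if var["variant_id"] == lead_id:
            continue
        g = np.round(table.dosages[:, j]).astype(int)
        if len(np.unique(g)) < 2:
            continue
        est = em_haplotype_freqs(g, lead)
        if est.freqs.r2 > r2_min:
            rows.append(
                {
                    "variant_id": var["variant_id"],
                    "pos": int(var["pos"]),
                    "r2": est.freqs.r2,
                    "dprime": est.freqs.dprime,
                }
            )
    df = pd.DataFrame(rows, columns=["variant_id", "pos", "r2", "dprime"])
    return df.sort_values(["r2", "pos"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )
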