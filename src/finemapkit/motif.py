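"""PWM construction, bidirectional motif scanning, allele-specific disruption.

Count matrices in JASPAR PFM text format are turned into probability
matrices with a pseudocount and into log2-odds scores against a uniform
background (0.25 per base).  A window's score is the sum of per-position
log-odds; the minus strand is scored on the reverse complement.  The
disruption score of a variant is the difference between the best
variant-covering window score under the reference and alternate alleles:
positive delta means the alternate allele weakens the motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from Bio import motifs as bio_motifs

__all__ = [
    "PWM",
    "Hit",
    "ScanResult",
    "DeltaResult",
    "load_jaspar",
    "write_jaspar",
    "scan_sequence",
    "allele_delta",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix (rows A, C, G, T)."""

    id: str
    name: str
    counts: np.ndarray
    pseudocount: float = 0.25
    background: float = 0.25
    probs: np.ndarray = field(init=False)
    logodds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A, C, G, T)")
        if self.counts.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        colsums = self.counts.sum(axis=0)
        if np.any(colsums + 4 * self.pseudocount <= 0):
            raise ValueError("empty column with zero pseudocount")
        self.probs = (self.counts + self.pseudocount) / (colsums + 4 * self.pseudocount)
        with np.errstate(divide="ignore"):  # zero prob -> -inf log-odds
            self.logodds = np.log2(self.probs / self.background)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())


def load_jaspar(path, pseudocount: float = 0.25) -> list[PWM]:
    """Load PWMs from a JASPAR PFM text file (``>ID name`` + 4 base rows)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        out.append(
            PWM(
                id=m.matrix_id or m.name or "motif",
                name=m.name or "",
                counts=counts,
                pseudocount=pseudocount,
            )
        )
    if not out:
        raise ValueError(f"{path}: no motifs found")
    return out


def write_jaspar(pwms, path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{int(c):>4d}" if float(c).is_integer() else f"{c:g}"
                               for c in pwm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


class Hit(NamedTuple):
    position: int  # 0-based window start on the given sequence
    strand: str  # '+' or '-'
    score: float


class ScanResult(NamedTuple):
    best: Hit | None
    hits: list[Hit]


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, -1) for c in seq.upper()], dtype=int)


def _window_scores(enc: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Scores of all plus-strand windows; NaN where a window contains N."""
    L = logodds.shape[1]
    n_win = len(enc) - L + 1
    scores = np.full(max(n_win, 0), np.nan)
    for s in range(n_win):
        window = enc[s : s + L]
        if np.any(window < 0):
            continue
        scores[s] = logodds[window, np.arange(L)].sum()
    return scores


def scan_sequence(
    seq: str,
    pwm: PWM,
    both_strands: bool = True,
    threshold: float = 0.0,
) -> ScanResult:
    """Scan a sequence with a PWM on one or both strands.

    Returns the best hit (ties: plus strand first, then leftmost) and all
    hits with score >= ``threshold``.  Windows containing N are skipped; a
    sequence shorter than the motif yields an empty result.
    """
    seq = seq.upper()
    L = pwm.length
    if any(c not in "ACGTN" for c in seq):
        raise ValueError("sequence must be over A, C, G, T, N")
    if len(seq) < L:
        return ScanResult(None, [])
    plus = _window_scores(_encode(seq), pwm.logodds)
    candidates: list[Hit] = []
    for s, sc in enumerate(plus):
        if np.isfinite(sc):
            candidates.append(Hit(s, "+", float(sc)))
    if both_strands:
        minus = _window_scores(_encode(reverse_complement(seq)), pwm.logodds)
        # window starting at s' on the RC corresponds to window starting at
        # len(seq) - L - s' on the forward sequence
        for sp, sc in enumerate(minus):
            if np.isfinite(sc):
                candidates.append(Hit(len(seq) - L - sp, "-", float(sc)))
    if not candidates:
        return ScanResult(None, [])
    best = max(candidates, key=lambda h: (h.score, h.strand == "+", -h.position))
    hits = sorted(
        (h for h in candidates if h.score >= threshold),
        key=lambda h: (-h.score, h.strand != "+", h.position),
    )
    return ScanResult(best, hits)


class DeltaResult(NamedTuple):
    best_ref: float
    best_alt: float
    delta: float


def allele_delta(
    context_seq: str,
    variant_offset: int,
    ref_allele: str,
    alt_allele: str,
    pwm: PWM,
    both_strands: bool = True,
) -> DeltaResult:
    """Allele-specific motif disruption over variant-covering windows.

    ``delta = best_ref - best_alt``; positive when the alternate allele
    weakens the best motif match.  Only windows overlapping the variant
    position are considered (disruption semantics: a distal intact match
    should not mask an allele effect at the variant).
    """
    context_seq = context_seq.upper()
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        raise ValueError("both alleles must be single bases")
    if not (0 <= variant_offset < len(context_seq)):
        raise ValueError("variant_offset outside context")
    if context_seq[variant_offset] != ref_allele.upper():
        raise ValueError(
            f"reference allele mismatch at offset {variant_offset}: "
            f"context has {context_seq[variant_offset]!r}, expected {ref_allele!r}"
        )
    L = pwm.length
    lo = max(0, variant_offset - L + 1)
    hi = min(len(context_seq), variant_offset + L)
    if hi - lo < L:
        raise ValueError("context too short: no window covers the variant")
    alt_context = (
        context_seq[:variant_offset] + alt_allele.upper() + context_seq[variant_offset + 1 :]
    )
    sub_ref = context_seq[lo:hi]
    sub_alt = alt_context[lo:hi]
    best_ref = scan_sequence(sub_ref, pwm, both_strands).best
    best_alt = scan_sequence(sub_alt, pwm, both_strands).best
    if best_ref is None or best_alt is None:
        raise ValueError("no scorable window covers the variant")
    return DeltaResult(best_ref.score, best_alt.score, best_ref.score - best_alt.score)
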