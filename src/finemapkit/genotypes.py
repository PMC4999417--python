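"""Genotype containers and tab-delimited I/O.

The on-disk genotype table is a plain tab-delimited file with one row per
variant: ``variant_id  chrom  pos  ref  alt`` followed by one dosage column
per sample (expected count of the alternate allele, in [0, 2]).  An optional
companion file with the same layout carries per-sample genotype-probability
triples ``p0,p1,p2`` (comma separated) as produced by imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]

__all__ = [
    "GenotypeTable",
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotypes",
    "write_phenotypes",
]


@dataclass
class GenotypeTable:
    """Samples x variants dosage matrix with variant metadata.

    Parameters
    ----------
    variants
        DataFrame with columns ``variant_id, chrom, pos, ref, alt``; ``pos``
        is 1-based (VCF convention) and strictly increasing per chromosome.
    dosages
        ``(n_samples, n_variants)`` float array of alt-allele dosages in
        [0, 2].
    sample_ids
        Sample identifiers, one per dosage row.
    probabilities
        Optional ``(n_samples, n_variants, 3)`` array of genotype
        probabilities (hom-ref, het, hom-alt); each triple sums to 1 and is
        consistent with the dosage (``dose = p1 + 2 p2``).
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata missing columns: {missing}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        n_samples, n_variants = self.dosages.shape
        if n_variants != len(self.variants):
            raise ValueError(
                f"{n_variants} dosage columns but {len(self.variants)} variants"
            )
        if not self.sample_ids:
            self.sample_ids = [f"sample{i:05d}" for i in range(n_samples)]
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match dosage rows")
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9
        ):
            raise ValueError("dosages must lie in [0, 2]")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")
        if self.probabilities is not None:
            self.probabilities = np.asarray(self.probabilities, dtype=float)
            if self.probabilities.shape != (n_samples, n_variants, 3):
                raise ValueError("probabilities must have shape (n_samples, n_variants, 3)")
            sums = self.probabilities.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("probability triples must sum to 1")
            expected = self.probabilities[:, :, 1] + 2.0 * self.probabilities[:, :, 2]
            if not np.allclose(expected, self.dosages, atol=1e-6):
                raise ValueError("dosage inconsistent with probability triples")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in table")
        return int(idx[0])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(variant_id)]

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeTable":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [order[s] for s in sample_ids]
        probs = None if self.probabilities is None else self.probabilities[rows]
        return GenotypeTable(self.variants.copy(), self.dosages[rows], list(sample_ids), probs)


def write_genotype_table(table: GenotypeTable, path, probs_path=None) -> None:
    """Write dosages (and optionally probability triples) as tab-delimited text."""
    dose = pd.DataFrame(
        np.round(table.dosages.T, 6), columns=table.sample_ids, copy=False
    )
    df = pd.concat([table.variants[VARIANT_COLUMNS].reset_index(drop=True), dose], axis=1)
    df.to_csv(path, sep="\t", index=False)
    if probs_path is not None:
        if table.probabilities is None:
            raise ValueError("table carries no probabilities")
        probs = np.round(table.probabilities, 6)
        cells = {
            sid: [",".join(f"{v:g}" for v in probs[j, i]) for i in range(table.n_variants)]
            for j, sid in enumerate(table.sample_ids)
        }
        pdf = pd.concat(
            [table.variants[VARIANT_COLUMNS].reset_index(drop=True), pd.DataFrame(cells)], axis=1
        )
        pdf.to_csv(probs_path, sep="\t", index=False)


def read_genotype_table(path, probs_path=None) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_ids = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[sample_ids].to_numpy(dtype=float).T
    probabilities = None
    if probs_path is not None:
        pdf = pd.read_csv(probs_path, sep="\t", dtype={"chrom": str})
        if list(pdf["variant_id"]) != list(df["variant_id"]):
            raise ValueError("probability file variants do not match genotype file")
        probabilities = np.empty((len(sample_ids), len(df), 3))
        for j, sid in enumerate(sample_ids):
            col = pdf[sid].str.split(",", expand=True).to_numpy(dtype=float)
            probabilities[j] = col
    return GenotypeTable(df[VARIANT_COLUMNS], dosages, sample_ids, probabilities)


def write_phenotypes(sample_ids, status, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "status": np.asarray(status, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if set(df["status"]) - {0, 1}:
        raise ValueError("phenotype status must be 0/1")
    return df
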