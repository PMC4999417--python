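"""Interval-track annotation of candidate variants and evidence ranking.

Variants (1-based positions, VCF convention) are overlaid on 0-based
half-open interval tracks (BED: DNase, histone marks, chromatin state,
super-enhancer, contact domain, TF binding) and on conservation tracks
(bedGraph: phastCons, GERP).  Evidence across association, conservation,
enhancer activity and motif disruption is combined into a ranked candidate
report.  A variant at 1-based position P overlaps [s, e) iff s <= P-1 < e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "annotate_variants",
    "prioritize",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end), 0-based."""

    chrom: str
    start: int
    end: int
    name: str = ""
    value: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start >= self.end:
            raise ValueError(f"start >= end: {self.chrom}:{self.start}-{self.end}")


def _sorted(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def read_bed(path) -> list[GenomicInterval]:
    """Read BED (3+ columns); returns intervals sorted per chromosome.

    Column 4 is kept as ``name`` and column 5 (score) as ``value`` when
    present.  Malformed lines raise with their line number.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else ""
            value = None
            if len(fields) > 4:
                try:
                    value = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            out.append(GenomicInterval(fields[0], start, end, name, value))
    return _sorted(out)


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name or iv.value is not None:
                fields.append(iv.name or ".")
            if iv.value is not None:
                fields.append(f"{iv.value:g}")
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path) -> list[GenomicInterval]:
    """Read a 4-column bedGraph; overlapping intervals are rejected."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs exactly 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            out.append(GenomicInterval(fields[0], start, end, value=value))
    out = _sorted(out)
    for prev, cur in zip(out, out[1:]):
        if cur.chrom == prev.chrom and cur.start < prev.end:
            raise ValueError(
                f"{path}: overlapping bedGraph intervals "
                f"{prev.chrom}:{prev.start}-{prev.end} and {cur.chrom}:{cur.start}-{cur.end}"
            )
    return out


def write_bedgraph(intervals, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.value:.6f}\n")


def _trees(intervals: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def annotate_variants(
    variants: pd.DataFrame,
    tracks: dict[str, list[GenomicInterval]],
    conservation: dict[str, list[GenomicInterval]] | None = None,
) -> pd.DataFrame:
    """Overlap flags and conservation scores per variant.

    Parameters
    ----------
    variants
        DataFrame with at least ``variant_id, chrom, pos`` (pos 1-based).
    tracks
        Named interval tracks; each yields a boolean column.
    conservation
        Named bedGraph tracks; each yields a float column (NaN where the
        position is uncovered).  Track names must not collide.
    """
    conservation = conservation or {}
    dup = set(tracks) & set(conservation)
    if dup:
        raise ValueError(f"duplicated track names: {sorted(dup)}")
    track_trees = {name: _trees(ivs) for name, ivs in tracks.items()}
    cons_trees = {name: _trees(ivs) for name, ivs in conservation.items()}
    out = variants[["variant_id", "chrom", "pos"]].copy()
    for name, trees in track_trees.items():
        flags = []
        for chrom, pos in zip(out["chrom"], out["pos"]):
            tree = trees.get(str(chrom))
            flags.append(bool(tree is not None and tree.overlaps_point(int(pos) - 1)))
        out[name] = flags
    for name, trees in cons_trees.items():
        vals = []
        for chrom, pos in zip(out["chrom"], out["pos"]):
            tree = trees.get(str(chrom))
            hits = tree[int(pos) - 1] if tree is not None else set()
            vals.append(next(iter(hits)).data.value if hits else np.nan)
        out[name] = vals
    return out


def prioritize(
    assoc_results: pd.DataFrame,
    annotations: pd.DataFrame,
    motif_deltas: dict[str, float] | pd.Series | None = None,
    *,
    phastcons_min: float = 0.9,
    gerp_min: float = 2.0,
    motif_delta_min: float = 3.0,
    p_column: str = "p_trend",
) -> pd.DataFrame:
    """Rank candidate variants by combined regulatory evidence.

    Three binary criteria are counted per variant:

    1. conserved: ``phastcons >= phastcons_min`` or ``gerp >= gerp_min``;
    2. active enhancer: DNase accessibility AND H3K27ac AND H3K4me1;
    3. motif disruption: ``|motif_delta| >= motif_delta_min`` (log2-odds).

    Ranking: evidence count descending, association p ascending, position
    ascending.  Missing annotation columns simply contribute ``False``.
    """
    motif_deltas = dict(motif_deltas or {})
    df = assoc_results.merge(annotations.drop(columns=["chrom", "pos"], errors="ignore"),
                             on="variant_id", how="left")
    phast = df.get("phastcons", pd.Series(np.nan, index=df.index)).astype(float)
    gerp = df.get("gerp", pd.Series(np.nan, index=df.index)).astype(float)
    conserved = (phast >= phastcons_min) | (gerp >= gerp_min)

    def flag(col: str) -> pd.Series:
        if col in df.columns:
            return df[col].fillna(False).astype(bool)
        return pd.Series(False, index=df.index)

    active = flag("dnase") & flag("h3k27ac") & flag("h3k4me1")
    delta = df["variant_id"].map(motif_deltas).astype(float)
    disrupts = delta.abs() >= motif_delta_min
    disrupts = disrupts.fillna(False)

    df["conserved"] = conserved.fillna(False)
    df["active_enhancer"] = active
    df["motif_delta"] = delta
    df["motif_disrupting"] = disrupts
    df["evidence_count"] = (
        df["conserved"].astype(int)
        + df["active_enhancer"].astype(int)
        + df["motif_disrupting"].astype(int)
    )
    df = df.sort_values(
        ["evidence_count", p_column, "pos"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
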