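"""4C-seq contact profiling on a restriction-fragment landscape.

A two-enzyme circular chromosome conformation capture design digests the
genome with a primary enzyme (default DpnII, site GATC) defining the
fragments, and a secondary enzyme (default HindIII, site AAGCTT) trimming
the circles.  Fragments lacking a secondary site ("blind" fragments) are
conventionally profiled separately from non-blind ones.  The pipeline here:

1. build the primary fragment map from the genome sequence (fragments split
   at the first base of every primary site — DpnII cuts 5' of GATC);
2. allocate mapped reads to fragments: mapping quality >= 30, duplicate
   positions collapsed to unique, viewpoint-proximal and masked regions
   dropped, assignment by the read's 5' position;
3. bin per-fragment counts at fixed resolution (default 100 bp), fragments
   spread over bins in proportion to overlap;
4. smooth with a centered running-window mean (default 5 kb), masked bins
   excluded from both numerator and denominator.

No cross-class normalization is applied between blind and non-blind
channels; they are reported separately alongside their sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, write_bedgraph

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentMap",
    "ContactProfile",
    "build_fragment_map",
    "read_reads_bed",
    "assign_reads",
    "binned_profile",
    "smooth_profile",
    "write_profile_bedgraph",
]

CHANNELS = ("blind", "nonblind", "combined")


@dataclass
class FragmentMap:
    """Ordered primary restriction fragments tiling one or more sequences."""

    fragments: pd.DataFrame  # chrom, start, end, blind
    primary_site: str
    secondary_site: str

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "blind"}
        if not req <= set(self.fragments.columns):
            raise ValueError(f"fragment table needs columns {sorted(req)}")
        self.fragments = self.fragments.reset_index(drop=True)
        for chrom, grp in self.fragments.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not np.all(starts[1:] == ends[:-1]):
                raise ValueError(f"fragments do not tile {chrom} without gaps/overlaps")

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.fragments["chrom"]))

    def fragment_at(self, chrom: str, pos: int) -> int:
        """Row index of the fragment containing 0-based ``pos``; -1 if outside."""
        grp = self.fragments[self.fragments["chrom"] == chrom]
        if grp.empty:
            return -1
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            return -1
        return int(grp.index[i])


def _find_all(seq: str, site: str) -> list[int]:
    out, i = [], seq.find(site)
    while i != -1:
        out.append(i)
        i = seq.find(site, i + 1)
    return out


def build_fragment_map(
    genome,
    primary: str = "GATC",
    secondary: str = "AAGCTT",
    offsets: dict[str, int] | None = None,
) -> FragmentMap:
    """Digest sequences in silico into a primary fragment map.

    Parameters
    ----------
    genome
        Mapping of sequence name to sequence, or a path to a FASTA file
        (read via pyfaidx).
    primary, secondary
        Recognition sequences of the fragment-defining and trimming enzymes.
    offsets
        Optional per-sequence genomic offset added to all coordinates, for
        FASTA records that represent a sub-locus of a chromosome.

    Fragment boundaries sit at the first base of each primary-site
    occurrence (blunt cut-at-site-start model).  A fragment is blind iff it
    fully contains no secondary-site occurrence.
    """
    for site in (primary, secondary):
        if not site or set(site.upper()) - set("ACGT"):
            raise ValueError(f"invalid recognition sequence {site!r}")
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        from pyfaidx import Fasta

        fa = Fasta(str(genome))
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        seqs = dict(genome)
    offsets = offsets or {}
    rows = []
    for name, seq in seqs.items():
        seq = seq.upper()
        off = offsets.get(name, 0)
        cuts = _find_all(seq, primary.upper())
        if not cuts:
            logger.warning("no %s site in sequence %s: single fragment", primary, name)
        bounds = [0] + [c for c in cuts if c > 0] + [len(seq)]
        sec = _find_all(seq, secondary.upper())
        sec_starts = np.array(sec, dtype=int)
        slen = len(secondary)
        for s, e in zip(bounds[:-1], bounds[1:]):
            inside = np.sum((sec_starts >= s) & (sec_starts + slen <= e))
            rows.append({"chrom": name, "start": s + off, "end": e + off, "blind": inside == 0})
    return FragmentMap(pd.DataFrame(rows), primary.upper(), secondary.upper())


def read_reads_bed(path) -> pd.DataFrame:
    """Read mapped reads from BED6 (score column = mapping quality)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "mapq", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: read with start >= end")
    return df


def assign_reads(
    reads: pd.DataFrame,
    fmap: FragmentMap,
    min_mapq: int = 30,
    viewpoint: tuple[str, int, int] | None = None,
    exclusion_radius: int = 1500,
    masked: list[tuple[str, int, int]] | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Allocate unique, quality-filtered reads to restriction fragments.

    Returns per-fragment counts (aligned to ``fmap.fragments`` rows) and a
    summary of how many reads each filter removed.  Reads falling outside
    the fragment map are counted in the summary, never fatal.
    """
    report = {"n_input": len(reads)}
    df = reads.copy()
    lowq = df["mapq"] < min_mapq
    report["n_low_mapq"] = int(lowq.sum())
    df = df[~lowq]
    pos5 = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    df = df.assign(pos5=pos5)
    before = len(df)
    df = df.drop_duplicates(subset=["chrom", "pos5", "strand"])
    report["n_duplicate"] = before - len(df)

    drop = np.zeros(len(df), dtype=bool)
    regions = list(masked or [])
    if viewpoint is not None:
        vchrom, vstart, vend = viewpoint
        regions.append((vchrom, vstart - exclusion_radius, vend + exclusion_radius))
    n_masked = 0
    for chrom, start, end in regions:
        inside = (df["chrom"] == chrom) & (df["pos5"] >= start) & (df["pos5"] < end)
        drop |= inside.to_numpy()
    report["n_masked_or_excluded"] = int(drop.sum())
    df = df[~drop]

    counts = np.zeros(len(fmap.fragments), dtype=float)
    n_outside = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        frag = fmap.fragments[fmap.fragments["chrom"] == chrom]
        if frag.empty:
            n_outside += len(grp)
            continue
        starts = frag["start"].to_numpy()
        ends = frag["end"].to_numpy()
        pos = grp["pos5"].to_numpy()
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = (i >= 0) & (pos < ends[np.clip(i, 0, len(ends) - 1)])
        n_outside += int((~ok).sum())
        np.add.at(counts, frag.index.to_numpy()[i[ok]], 1.0)
    report["n_outside_map"] = n_outside
    report["n_assigned"] = int(counts.sum())
    return counts, report


@dataclass
class ContactProfile:
    """Fixed-resolution binned 4C signal with optional smoothed channels."""

    chrom: str
    start: int  # genomic coordinate of the left edge of bin 0
    resolution: int
    bins: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray] | None = None
    window: int | None = None
    masked: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(next(iter(self.bins.values())))

    def bin_edges(self) -> np.ndarray:
        return self.start + self.resolution * np.arange(self.n_bins + 1)


def binned_profile(
    fragment_counts: np.ndarray,
    fmap: FragmentMap,
    resolution: int = 100,
) -> ContactProfile:
    """Spread per-fragment counts onto fixed-width bins.

    Each fragment's count is distributed over the bins it overlaps in
    proportion to the overlap fraction, separately for blind and non-blind
    fragments; total signal is conserved.  The fragment map must cover a
    single sequence.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    chroms = fmap.chroms
    if len(chroms) != 1:
        raise ValueError("profiling requires a single-sequence fragment map")
    chrom = chroms[0]
    frags = fmap.fragments
    counts = np.asarray(fragment_counts, dtype=float)
    if counts.shape != (len(frags),):
        raise ValueError("fragment_counts length must match fragment map")
    gstart = int(frags["start"].min())
    gend = int(frags["end"].max())
    start0 = (gstart // resolution) * resolution
    n_bins = int(np.ceil((gend - start0) / resolution))
    bins = {ch: np.zeros(n_bins) for ch in CHANNELS}
    for (s, e, blind), c in zip(
        frags[["start", "end", "blind"]].itertuples(index=False, name=None), counts
    ):
        if c == 0:
            continue
        flen = e - s
        b0 = (s - start0) // resolution
        b1 = (e - 1 - start0) // resolution
        channel = "blind" if blind else "nonblind"
        for b in range(b0, b1 + 1):
            lo = max(s, start0 + b * resolution)
            hi = min(e, start0 + (b + 1) * resolution)
            share = c * (hi - lo) / flen
            bins[channel][b] += share
            bins["combined"][b] += share
    return ContactProfile(chrom, start0, resolution, bins)


def smooth_profile(
    profile: ContactProfile,
    window: int = 5000,
    masked: list[tuple[int, int]] | None = None,
) -> ContactProfile:
    """Centered running-window mean of each channel.

    ``window`` must be a positive multiple of the resolution; the mean runs
    over the ``window/resolution`` bins centered on each bin.  Bins
    overlapping a masked genomic interval contribute neither signal nor
    denominator; a bin whose whole window is masked gets NaN (absent).
    """
    res = profile.resolution
    if window < res:
        raise ValueError("window must be >= resolution")
    if window % res != 0:
        raise ValueError("window must be a positive multiple of the resolution")
    w = window // res
    n = profile.n_bins
    unmasked = np.ones(n, dtype=bool)
    for mstart, mend in masked or []:
        b0 = max(0, (mstart - profile.start) // res)
        b1 = min(n, int(np.ceil((mend - profile.start) / res)))
        if b1 > b0:
            unmasked[b0:b1] = False
    # centered window: bin i averages bins [i - w//2, i - w//2 + w)
    off = w - 1 - w // 2
    kernel = np.ones(w)
    denom = np.convolve(unmasked.astype(float), kernel, mode="full")[off : off + n]
    smoothed = {}
    for ch, vals in profile.bins.items():
        num = np.convolve(np.where(unmasked, vals, 0.0), kernel, mode="full")[off : off + n]
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed[ch] = np.where(denom > 0, num / denom, np.nan)
    return ContactProfile(
        profile.chrom,
        profile.start,
        res,
        profile.bins,
        smoothed=smoothed,
        window=window,
        masked=list(masked or []),
    )


def write_profile_bedgraph(profile: ContactProfile, channel: str, path, smoothed: bool = False,
                           header: str | None = None) -> None:
    """Write one channel as bedGraph, values rounded to 6 decimals; NaN bins
    (fully-masked smoothing windows) are omitted."""
    source = profile.smoothed if smoothed else profile.bins
    if source is None or channel not in source:
        raise ValueError(f"channel {channel!r} not present")
    vals = source[channel]
    ivs = []
    for b, v in enumerate(vals):
        if np.isnan(v):
            continue
        s = profile.start + b * profile.resolution
        ivs.append(GenomicInterval(profile.chrom, s, s + profile.resolution, value=float(v)))
    write_bedgraph(ivs, path, header=header)
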