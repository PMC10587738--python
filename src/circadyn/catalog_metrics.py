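"""Catalog-level characterization.

EPM (eccDNA per million mapped reads, mitochondrial reads excluded from
the denominator), the multi-modal length distribution with its
nucleosome-ladder peak structure, length bands, GC content of records vs
equivalent-length flanks, and per-chromosome density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .io_formats import Catalog

log = logging.getLogger(__name__)

LENGTH_BANDS = ((0, 500), (500, 2000), (2000, 10_000), (10_000, np.inf))
BAND_NAMES = ("<500bp", "500bp-2kb", "2-10kb", ">10kb")


@dataclass
class LengthPeaks:
    """Called peak structure of a 1-bp length histogram."""

    bin_edges: np.ndarray
    histogram: np.ndarray
    smoothed: np.ndarray
    #: (center_bp, height) per cluster, centers ascending
    clusters: list[tuple[int, float]]
    #: sub-peak positions (bp) per cluster, parallel to ``clusters``
    sub_peaks: list[list[int]]
    mean_spacing: float | None

    @property
    def centers(self) -> list[int]:
        return [c for c, _ in self.clusters]


@dataclass
class GcProfile:
    """Per-record GC and equivalent-length flank GC."""

    record_gc: np.ndarray
    flank_gc: np.ndarray      # mean of up+downstream flanks; NaN if excluded
    n_flank_excluded: int     # records whose flanks left the contig
    mode: float               # smoothed-histogram mode of record GC
    median: float
    flank_mode: float
    flank_median: float


def epm(catalog: Catalog, unique: bool = True) -> float:
    """eccDNA count per million mapped reads.

    ``unique`` collapses duplicate (chrom, start, end) coordinates before
    counting, matching the unique-eccDNA counting unit used elsewhere.
    """
    if catalog.total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    df = catalog.df
    n = len(df.drop_duplicates(subset=["chrom", "start", "end"])) if unique \
        else len(df)
    return n / catalog.total_mapped_reads * 1e6


def histogram_mode(values, bin_width: float, lo: float = 0.0,
                   hi: float = 1.0, smooth_sd_bins: float = 3.0) -> float:
    """Mode of a distribution via the argmax of a smoothed histogram.

    Returns the center of the maximal bin after Gaussian smoothing.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values for mode estimation")
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist, _ = np.histogram(values, bins=edges)
    sm = gaussian_filter1d(hist.astype(float), smooth_sd_bins)
    i = int(np.argmax(sm))
    return float((edges[i] + edges[i + 1]) / 2)


def length_peaks(lengths, smoothing_sd: float = 2.0, max_len: int = 800,
                 min_len: int = 50, prominence_frac: float = 0.05,
                 cluster_gap: int = 30) -> LengthPeaks:
    """Call sub-peaks and peak clusters from a 1-bp length histogram.

    The histogram over [``min_len``, ``max_len``] is smoothed with a
    Gaussian of ``smoothing_sd`` bp; local maxima with prominence at least
    ``prominence_frac`` of the global maximum are sub-peaks; sub-peaks
    closer than ``cluster_gap`` bp are grouped into one cluster whose
    center is its highest sub-peak.  The mean spacing pools adjacent
    sub-peak differences within clusters.
    """
    if isinstance(lengths, Catalog):
        lengths = lengths.lengths
    lengths = np.asarray(lengths)
    if lengths.size == 0:
        raise ValueError("empty catalog: no lengths to analyze")
    if lengths.size < 1000:
        warnings.warn(f"only {lengths.size} records; peak calls may be "
                      "unstable below 1000", stacklevel=2)
    edges = np.arange(min_len, max_len + 2) - 0.5  # integer-centered bins
    hist, _ = np.histogram(lengths, bins=edges)
    sm = gaussian_filter1d(hist.astype(float), smoothing_sd)
    if sm.max() <= 0:
        return LengthPeaks(edges, hist, sm, [], [], None)
    idx, _props = find_peaks(sm, prominence=prominence_frac * sm.max())
    positions = idx + min_len
    # group sub-peaks into clusters by the gap rule
    clusters_pos: list[list[int]] = []
    for p in positions:
        if clusters_pos and p - clusters_pos[-1][-1] <= cluster_gap:
            clusters_pos[-1].append(int(p))
        else:
            clusters_pos.append([int(p)])
    clusters = []
    spacings: list[float] = []
    for grp in clusters_pos:
        heights = sm[np.asarray(grp) - min_len]
        best = grp[int(np.argmax(heights))]
        clusters.append((best, float(heights.max())))
        if len(grp) >= 2:
            spacings.extend(np.diff(grp).tolist())
    mean_spacing = float(np.mean(spacings)) if spacings else None
    return LengthPeaks(edges, hist, sm, clusters,
                       clusters_pos, mean_spacing)


def length_bands(catalog) -> dict[str, float]:
    """Fractions of records in the bands <500 bp, 500 bp-2 kb, 2-10 kb, >10 kb.

    Bands are half-open [lo, hi); fractions sum to 1 exactly.
    """
    lengths = catalog.lengths if isinstance(catalog, Catalog) \
        else np.asarray(catalog)
    if lengths.size == 0:
        raise ValueError("empty catalog")
    out = {}
    for name, (lo, hi) in zip(BAND_NAMES, LENGTH_BANDS):
        out[name] = float(((lengths >= lo) & (lengths < hi)).sum()) / lengths.size
    return out


def _gc_cumsum(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C")) \
        | (arr == ord("g")) | (arr == ord("c"))
    cum = np.zeros(arr.size + 1, dtype=np.int64)
    np.cumsum(is_gc, out=cum[1:])
    return cum


def gc_profile(catalog: Catalog, genome, gc_bin: float = 0.005) -> GcProfile:
    """GC of each record and of its equivalent-length flanks.

    The upstream flank is [start-L, start), the downstream flank is
    [end, end+L) with L the record length; flank GC is the mean of the
    two.  Records whose flanks would leave the contig are excluded from
    flank statistics (counted, not clipped).  Modes come from a smoothed
    histogram with ``gc_bin``-wide bins.
    """
    contigs = genome.contigs if hasattr(genome, "contigs") else genome
    cums = {name: _gc_cumsum(seq) for name, seq in contigs.items()}
    lens = {name: len(seq) for name, seq in contigs.items()}

    df = catalog.df
    rec_gc = np.full(len(df), np.nan)
    fl_gc = np.full(len(df), np.nan)
    n_excl = 0
    for chrom, sub in df.groupby("chrom"):
        if chrom not in cums:
            raise ValueError(f"record on unknown contig {chrom!r}")
        cum = cums[chrom]
        L = lens[chrom]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if (s < 0).any() or (e > L).any():
            raise ValueError(f"record outside contig {chrom!r} bounds")
        n = e - s
        rec_gc[sub.index] = (cum[e] - cum[s]) / n
        ok = (s - n >= 0) & (e + n <= L)
        n_excl += int((~ok).sum())
        up = np.where(ok, cum[s] - cum[np.maximum(s - n, 0)], 0)
        dn = np.where(ok, cum[np.minimum(e + n, L)] - cum[e], 0)
        fl = np.where(ok, (up + dn) / (2 * n), np.nan)
        fl_gc[sub.index] = fl
    finite_fl = fl_gc[np.isfinite(fl_gc)]
    return GcProfile(
        record_gc=rec_gc,
        flank_gc=fl_gc,
        n_flank_excluded=n_excl,
        mode=histogram_mode(rec_gc, gc_bin),
        median=float(np.nanmedian(rec_gc)),
        flank_mode=histogram_mode(finite_fl, gc_bin) if finite_fl.size
        else float("nan"),
        flank_median=float(np.median(finite_fl)) if finite_fl.size
        else float("nan"),
    )


def chromosome_density(catalog: Catalog, genome, window: int = 100_000
                       ) -> pd.DataFrame:
    """Record-start counts per window, normalized to a per-Mb rate."""
    if window < 1000:
        raise ValueError("window must be at least 1 kb")
    contigs = genome.contigs if hasattr(genome, "contigs") else genome
    rows = []
    for chrom, seq in contigs.items():
        L = len(seq)
        edges = np.arange(0, L + window, window)
        edges[-1] = max(edges[-1], L)
        starts = catalog.df.loc[catalog.df["chrom"] == chrom, "start"].to_numpy()
        counts, _ = np.histogram(starts, bins=edges)
        for i, c in enumerate(counts):
            w = min(edges[i + 1], L) - edges[i]
            rows.append((chrom, int(edges[i]), int(min(edges[i + 1], L)),
                         int(c), c / w * 1e6))
    return pd.DataFrame(rows, columns=["chrom", "win_start", "win_end",
                                       "count", "per_mb"])
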