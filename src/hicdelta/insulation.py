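"""Insulation scores, TAD-boundary calling as profile minima, aggregated
boundary profiles, and between-condition insulation differences.

The insulation score at a bin is the mean balanced signal inside a square
sliding along the matrix diagonal — the off-diagonal window linking the
``w`` bins upstream to the ``w`` bins downstream, where
``w = square_size / bin_size`` (e.g. 8 at a 20 kb bin size with a 160 kb
square). Scores are reported as the log2 ratio to the chromosome mean, so
dips mark contact insulation and their prominence measures boundary
strength.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .genome import BinTable, IntervalSet, ProfileTrack
from .matrix import ContactMap

__all__ = [
    "InsulationProfile",
    "BoundarySet",
    "insulation_score",
    "call_boundaries",
    "aggregate_boundary_profile",
    "delta_insulation",
    "average_to_bins",
]


@dataclasses.dataclass
class InsulationProfile:
    track: ProfileTrack
    bin_size: int
    square_size: int
    normalization: str  # "log2_mean" or "raw"

    @property
    def values(self) -> np.ndarray:
        return self.track.values

    @property
    def bins(self) -> BinTable:
        return self.track.bins


@dataclasses.dataclass
class BoundarySet:
    """One-bin boundary intervals with a per-boundary strength (prominence
    of the insulation minimum)."""

    bin_indices: np.ndarray  # global
    strength: np.ndarray
    bins: BinTable

    def __len__(self) -> int:
        return len(self.bin_indices)

    def to_intervals(self) -> IntervalSet:
        b = self.bins
        df = pd.DataFrame(
            {
                "chrom": b.chroms[self.bin_indices],
                "start": b.starts[self.bin_indices],
                "end": b.ends[self.bin_indices],
                "name": [f"boundary_{i}" for i in range(len(self))],
            }
        )
        return IntervalSet(df, b.genome)


def insulation_score(
    cmap: ContactMap,
    square_size: int,
    normalization: str = "log2_mean",
    max_masked_fraction: float = 0.5,
) -> InsulationProfile:
    """Sliding-square insulation profile of a balanced map.

    The raw score at bin i averages the unmasked entries of the square
    rows (i-w..i-1) x columns (i+1..i+w); windows within ``w`` bins of a
    chromosome end, at masked bins, or with more than
    ``max_masked_fraction`` of their entries masked are missing. With
    ``normalization="log2_mean"`` the score is log2(raw / chromosome mean
    of raw), giving a profile with chromosome mean ~0 in log space.
    """
    bins = cmap.bins
    if square_size % bins.bin_size != 0:
        raise ValueError("square_size must be a multiple of bin_size")
    w = square_size // bins.bin_size
    if w < 1:
        raise ValueError("square smaller than one bin")
    values = np.full(len(bins), np.nan)
    for chrom in bins.genome.names:
        s = bins.chrom_slice(chrom)
        M = cmap.cis(chrom).astype(float).copy()
        cm = cmap.cis_mask(chrom)
        M[cm, :] = np.nan
        M[:, cm] = np.nan
        nb = M.shape[0]
        raw = np.full(nb, np.nan)
        for i in range(w, nb - w):
            if cm[i]:
                continue
            win = M[i - w : i, i + 1 : i + w + 1]
            ok = ~np.isnan(win)
            if ok.sum() < (1 - max_masked_fraction) * win.size or ok.sum() == 0:
                continue
            raw[i] = win[ok].mean()
        if normalization == "log2_mean":
            mu = np.nanmean(raw) if np.isfinite(raw).any() else np.nan
            with np.errstate(invalid="ignore", divide="ignore"):
                norm = np.log2(raw / mu)
            norm[~np.isfinite(norm)] = np.nan
            values[s] = norm
        else:
            values[s] = raw
    return InsulationProfile(
        ProfileTrack(bins, values), bins.bin_size, square_size, normalization
    )


def _bridge_gaps(v: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap so that
    minima adjacent to isolated masked bins remain detectable."""
    v = v.copy()
    finite = np.isfinite(v)
    if finite.sum() < 2:
        return v
    i = 0
    n = len(v)
    while i < n:
        if finite[i]:
            i += 1
            continue
        j = i
        while j < n and not finite[j]:
            j += 1
        if 0 < i and j < n and (j - i) <= max_gap:
            x0, x1 = v[i - 1], v[j]
            for k in range(i, j):
                t = (k - i + 1) / (j - i + 1)
                v[k] = x0 * (1 - t) + x1 * t
        i = j
    return v


def call_boundaries(
    profile: InsulationProfile, min_strength: float = 0.1, max_gap: int = 2
) -> BoundarySet:
    """TAD boundaries as local minima of the insulation profile.

    A boundary is a minimum whose prominence (depth below the lower of its
    flanking maxima) is at least ``min_strength``. Interior masked gaps of
    up to ``max_gap`` bins are bridged by linear interpolation first, so a
    single masked bin at a junction does not hide the dip. Plateaus of
    equal minima report their leftmost bin. Calls are invariant to a global
    rescaling of the contact matrix (the profile is a log ratio).
    """
    bins = profile.bins
    idx_all, strength_all = [], []
    for chrom in bins.genome.names:
        s = bins.chrom_slice(chrom)
        v = _bridge_gaps(profile.values[s], max_gap)
        # split into contiguous runs of finite values
        finite = np.isfinite(v)
        starts = np.where(finite & ~np.roll(finite, 1))[0]
        if finite[0]:
            starts = np.unique(np.concatenate([[0], starts]))
        for st in starts:
            en = st
            while en < len(v) and finite[en]:
                en += 1
            seg = v[st:en]
            if len(seg) < 3:
                continue
            peaks, props = find_peaks(-seg, prominence=min_strength, plateau_size=1)
            lefts = props.get("left_edges", peaks)
            for p, left, prom in zip(peaks, lefts, props["prominences"]):
                pos = int(left) if seg[int(left)] == seg[p] else int(p)
                idx_all.append(s.start + st + pos)
                strength_all.append(float(prom))
    order = np.argsort(idx_all, kind="stable")
    return BoundarySet(
        np.array(idx_all, dtype=int)[order],
        np.array(strength_all)[order],
        bins,
    )


def aggregate_boundary_profile(
    profile: InsulationProfile, boundaries: BoundarySet, flank_bp: int
):
    """Stack the profile around each boundary and average per offset.

    Returns ``(matrix, mean, offsets_bp)`` where matrix is boundary x
    offset over [-flank, +flank]; boundaries whose flank leaves the
    chromosome (or hits missing profile edges) are dropped.
    """
    if len(boundaries) == 0:
        raise ValueError("empty boundary set")
    bins = profile.bins
    f = flank_bp // bins.bin_size
    rows = []
    for b in boundaries.bin_indices:
        chrom = bins.chroms[b]
        s = bins.chrom_slice(chrom)
        if b - f < s.start or b + f >= s.stop:
            continue
        rows.append(profile.values[b - f : b + f + 1])
    if not rows:
        raise ValueError("no boundary has complete flanks")
    M = np.array(rows)
    offsets = (np.arange(-f, f + 1)) * bins.bin_size
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(M, axis=0)
    return M, mean, offsets


def delta_insulation(
    profile_a: InsulationProfile, profile_b: InsulationProfile
) -> ProfileTrack:
    """Per-bin insulation difference (B - A) on a shared grid."""
    if profile_a.bins != profile_b.bins or profile_a.square_size != profile_b.square_size:
        raise ValueError("profiles must share bins and parameters")
    return ProfileTrack(profile_a.bins, profile_b.values - profile_a.values)


def average_to_bins(track: ProfileTrack, coarse: BinTable) -> ProfileTrack:
    """Average a fine per-bin track within each coarse bin (e.g. 20 kb
    insulation differences averaged across each 100 kb bin); coarse bins
    with no finite fine values are missing."""
    fine = track.bins
    if coarse.bin_size % fine.bin_size != 0:
        raise ValueError("coarse bin size must be a multiple of the fine size")
    if coarse.genome != fine.genome:
        raise ValueError("bin tables must share a genome")
    out = np.full(len(coarse), np.nan)
    for chrom in fine.genome.names:
        sf = fine.chrom_slice(chrom)
        sc = coarse.chrom_slice(chrom)
        v = track.values[sf]
        assign = np.arange(len(v)) * fine.bin_size // coarse.bin_size
        for ci in range(sc.stop - sc.start):
            sub = v[assign == ci]
            sub = sub[np.isfinite(sub)]
            if sub.size:
                out[sc.start + ci] = sub.mean()
    return ProfileTrack(coarse, out)
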