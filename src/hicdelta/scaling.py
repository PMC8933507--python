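"""Contact-frequency scaling with genomic distance, distal-to-local ratios
(DLR), interchromosomal fractions (ICF), their between-condition deltas, and
class-stratified summaries.

DLR is, per bin, ``log2(distal cis contacts / local cis contacts)`` with the
distal/local split at 3 Mb; ICF is ``trans / (trans + cis)``. Both are the
standard per-locus readouts of large-scale chromosome reorganization: DLR
rises where a locus trades local for distal contacts, ICF rises where a
chromosome mixes more with the rest of the genome.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import AnnotationLabels, ProfileTrack, UNLABELED
from .matrix import ContactMap

__all__ = [
    "ScalingCurve",
    "contact_scaling_curve",
    "dlr_profile",
    "delta_dlr",
    "icf_profile",
    "delta_icf",
    "stratify_by_class",
]


@dataclasses.dataclass
class ScalingCurve:
    """Smoothed interaction frequency vs genomic distance, normalized so the
    fitted value at the minimum distance is 1."""

    distances_bp: np.ndarray
    values: np.ndarray  # normalized loess fit
    raw_means: np.ndarray  # per-distance mean before smoothing/normalization

    def log_slope(self, d_min_bp: float, d_max_bp: float, on: str = "fit") -> float:
        """Least-squares log10-log10 slope over a distance range.

        ``on="fit"`` uses the loess curve; ``on="raw"`` uses the unsmoothed
        per-distance means, appropriate when the range abuts a slope break
        that smoothing would blur across.
        """
        y_src = self.values if on == "fit" else self.raw_means
        sel = (
            (self.distances_bp >= d_min_bp)
            & (self.distances_bp <= d_max_bp)
            & np.isfinite(y_src)
            & (y_src > 0)
        )
        if sel.sum() < 2:
            raise ValueError("fewer than two curve points in range")
        x = np.log10(self.distances_bp[sel])
        y = np.log10(y_src[sel])
        return float(np.polyfit(x, y, 1)[0])


def contact_scaling_curve(
    cmap: ContactMap,
    max_distance_bp: int | None = None,
    loess_frac: float = 0.3,
) -> ScalingCurve:
    """Genome-pooled contact frequency vs distance with a loess fit.

    All intrachromosomal pairs across all chromosomes are pooled at each
    separation (diagonal excluded); the per-distance mean is loess-smoothed
    in log10-log10 coordinates and normalized so the fitted value at the
    minimum distance is 1. At 10 kb resolution the distance range is
    conventionally capped at 1 Mb via ``max_distance_bp``.
    """
    bins = cmap.bins
    max_nb = max(bins.n_bins_of(c) for c in bins.genome.names)
    sums = np.zeros(max_nb)
    ns = np.zeros(max_nb)
    for chrom in bins.genome.names:
        M = cmap.cis(chrom).astype(float).copy()
        cm = cmap.cis_mask(chrom)
        M[cm, :] = np.nan
        M[:, cm] = np.nan
        nb = M.shape[0]
        for d in range(1, nb):
            diag = np.diagonal(M, d)
            ok = np.isfinite(diag)
            sums[d] += diag[ok].sum()
            ns[d] += ok.sum()
    d_bins = np.arange(1, max_nb)
    dist_bp = d_bins * bins.bin_size
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(ns[1:] > 0, sums[1:] / np.maximum(ns[1:], 1), np.nan)
    if max_distance_bp is not None:
        keep = dist_bp <= max_distance_bp
        dist_bp, means = dist_bp[keep], means[keep]
    ok = np.isfinite(means) & (means > 0)
    if ok.sum() < 2:
        raise ValueError("empty distance range")
    x = np.log10(dist_bp[ok].astype(float))
    y = np.log10(means[ok])
    fit = lowess(y, x, frac=loess_frac, return_sorted=False)
    values = np.full(len(dist_bp), np.nan)
    values[ok] = 10.0**fit
    values = values / values[np.flatnonzero(ok)[0]]  # max = value at min distance
    return ScalingCurve(dist_bp, values, means)


def dlr_profile(cmap: ContactMap, cutoff_bp: int = 3_000_000) -> ProfileTrack:
    """Per-bin distal-to-local ratio: log2 of cis contacts at distances
    greater than ``cutoff_bp`` over cis contacts at distances up to and
    including the cutoff. The diagonal is excluded; bins with an empty
    distal or local sum (or masked bins) are missing."""
    bins = cmap.bins
    if cutoff_bp < bins.bin_size:
        raise ValueError("cutoff must be at least one bin")
    out = np.full(len(bins), np.nan)
    for chrom in bins.genome.names:
        s = bins.chrom_slice(chrom)
        M = cmap.cis(chrom).astype(float).copy()
        cm = cmap.cis_mask(chrom)
        M[cm, :] = np.nan
        M[:, cm] = np.nan
        np.fill_diagonal(M, np.nan)
        nb = M.shape[0]
        idx = np.arange(nb)
        dist = np.abs(np.subtract.outer(idx, idx)) * bins.bin_size
        distal = np.where(dist > cutoff_bp, M, np.nan)
        local = np.where((dist <= cutoff_bp) & (dist > 0), M, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ds = np.nansum(distal, axis=1)
            ls = np.nansum(local, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.log2(ds / ls)
        v[(ds <= 0) | (ls <= 0) | cm] = np.nan
        out[s] = v
    return ProfileTrack(bins, out)


def delta_dlr(
    profile_a: ProfileTrack, profile_b: ProfileTrack, median_center: bool = False
) -> ProfileTrack:
    """Per-bin DLR difference (B - A), optionally centred on its genome-wide
    median so the reported changes are relative shifts."""
    if profile_a.bins != profile_b.bins:
        raise ValueError("profiles must share bins")
    d = profile_b.values - profile_a.values
    if median_center:
        d = d - np.nanmedian(d)
    return ProfileTrack(profile_a.bins, d)


def icf_profile(cmap: ContactMap, level: str = "bin") -> ProfileTrack | pd.Series:
    """Interchromosomal fraction: trans / (trans + cis), in [0, 1].

    ``level="bin"`` returns a per-bin track (cis sums exclude the
    diagonal); ``level="chrom"`` aggregates whole chromosomes and returns a
    Series. Units with zero total signal are missing. A "trans/cis" odds
    variant is available downstream as icf/(1-icf).
    """
    bins = cmap.bins
    counts = cmap.counts.astype(float).copy()
    counts[cmap.mask, :] = np.nan
    counts[:, cmap.mask] = np.nan
    cis_tot = np.zeros(len(bins))
    all_tot = np.zeros(len(bins))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_tot = np.nansum(counts, axis=1) - np.nan_to_num(np.diag(counts))
        for chrom in bins.genome.names:
            s = bins.chrom_slice(chrom)
            block = counts[s, s].copy()
            np.fill_diagonal(block, np.nan)
            cis_tot[s] = np.nansum(block, axis=1)
        all_tot = row_tot
    trans_tot = all_tot - cis_tot
    if level == "chrom":
        out = {}
        for chrom in bins.genome.names:
            s = bins.chrom_slice(chrom)
            tr, tot = trans_tot[s].sum(), all_tot[s].sum()
            out[chrom] = tr / tot if tot > 0 else np.nan
        return pd.Series(out, name="icf")
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(all_tot > 0, trans_tot / all_tot, np.nan)
    v[cmap.mask] = np.nan
    return ProfileTrack(bins, v)


def delta_icf(a, b):
    """Per-unit ICF difference (B - A); works on tracks or chromosome
    Series. Bounded in [-1, 1]."""
    if isinstance(a, ProfileTrack):
        if a.bins != b.bins:
            raise ValueError("tracks must share bins")
        return ProfileTrack(a.bins, b.values - a.values)
    if not a.index.equals(b.index):
        raise ValueError("series must share units")
    return b - a


def stratify_by_class(track: ProfileTrack, labels: AnnotationLabels) -> pd.DataFrame:
    """Distribution summary (count, quartiles) of a track per label class;
    unlabeled bins are excluded, empty classes are absent."""
    if len(track) != len(labels):
        raise ValueError("track and labels must share bins")
    rows = []
    for lab in labels.vocabulary:
        v = track.values[labels.mask_of(lab)]
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        rows.append(
            {
                "class": lab,
                "n": int(v.size),
                "median": float(np.median(v)),
                "q25": float(np.quantile(v, 0.25)),
                "q75": float(np.quantile(v, 0.75)),
                "mean": float(v.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("class") if rows else pd.DataFrame(
        columns=["n", "median", "q25", "q75", "mean"]
    )
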