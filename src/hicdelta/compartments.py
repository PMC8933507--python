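"""A/B compartment analysis: PC1 eigenvector calling with gene-density sign
assignment, between-condition concordance, saddle-difference matrices, and
per-chromosome compartment-strength statistics.

The compartment signal is the first principal component of the correlation
matrix of the distance-normalized (observed/expected) cis map, computed per
chromosome. The eigenvector's sign is arbitrary, so the positive pole is
assigned to whichever sign group has the higher mean gene density (the A
compartment is gene rich).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .genome import BinTable, ProfileTrack
from .matrix import ContactMap, distance_zscore, observed_over_expected

__all__ = [
    "CompartmentProfile",
    "SaddleMatrix",
    "compartment_pc1",
    "pc1_concordance",
    "saddle_difference",
    "saddle_corner_means",
    "compartment_strength",
]


@dataclasses.dataclass
class CompartmentProfile:
    """Per-bin PC1 values (NaN at masked/skipped bins) with per-chromosome
    explained-variance fractions and degeneracy flags."""

    track: ProfileTrack
    explained_variance: dict
    degenerate: dict  # chrom -> bool ("no compartment signal")

    @property
    def values(self) -> np.ndarray:
        return self.track.values


def _masked_correlation(oe: np.ndarray, min_frac: float = 0.5) -> np.ndarray:
    """Pairwise-complete Pearson correlation of O/E rows.

    Row pairs sharing fewer than ``min_frac`` of the maximum observed
    overlap give missing entries, imputed as 0 for the eigendecomposition.
    """
    oe = oe.copy()
    # rows with no real variation (flat O/E up to floating noise) carry no
    # compartment signal; mark them missing so noise cannot masquerade
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(oe, axis=1)
        sd = np.nanstd(oe, axis=1)
    flat = sd <= 1e-10 * np.maximum(np.abs(mu), 1e-300)
    oe[flat, :] = np.nan
    df = pd.DataFrame(oe.T)  # columns = rows of the O/E matrix
    valid = (~np.isnan(oe)).sum(axis=1)
    min_periods = max(3, int(min_frac * max(valid.max(initial=0), 1)))
    C = df.corr(min_periods=min_periods).to_numpy()
    imputed = np.isnan(C)
    if imputed.any():
        C = np.where(imputed, 0.0, C)
    return C


def compartment_pc1(
    cmap: ContactMap,
    gene_density: ProfileTrack,
    min_bins: int = 10,
) -> CompartmentProfile:
    """Call per-chromosome compartment PC1 from a balanced map.

    Pipeline per chromosome: O/E matrix -> missing-tolerant correlation
    matrix -> leading eigenvector, scaled by sqrt(eigenvalue). Sign is
    flipped so the positive group has the higher mean gene density.
    Chromosomes with fewer than ``min_bins`` unmasked bins are skipped;
    a non-positive leading eigenvalue flags "no compartment signal".
    """
    bins = cmap.bins
    oe_full = observed_over_expected(cmap)
    values = np.full(len(bins), np.nan)
    evr, degen = {}, {}
    for chrom in bins.genome.names:
        s = bins.chrom_slice(chrom)
        good = ~cmap.mask[s]
        if good.sum() < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} unmasked bins; skipped",
                          RuntimeWarning)
            continue
        oe = oe_full[s, s][np.ix_(good, good)]
        C = _masked_correlation(oe)
        # guard rows that were entirely missing
        C[np.isnan(C)] = 0.0
        w, V = np.linalg.eigh(C)
        lead = w[-1]
        total = np.abs(w).sum()
        evr[chrom] = float(lead / total) if total > 0 else 0.0
        if lead <= 1e-10 or not np.isfinite(lead):
            degen[chrom] = True
            warnings.warn(f"{chrom}: degenerate spectrum, no compartment signal",
                          RuntimeWarning)
            continue
        degen[chrom] = False
        pc1 = V[:, -1] * np.sqrt(lead)
        gd = gene_density.values[s][good]
        pos, neg = pc1 > 0, pc1 < 0
        if pos.any() and neg.any():
            if np.nanmean(gd[pos]) < np.nanmean(gd[neg]):
                pc1 = -pc1
        v = np.full(s.stop - s.start, np.nan)
        v[good] = pc1
        values[s] = v
    return CompartmentProfile(ProfileTrack(bins, values), evr, degen)


def pc1_concordance(profile1: CompartmentProfile, profile2: CompartmentProfile) -> dict:
    """Genome-wide correlation and sign agreement over mutually called bins."""
    a, b = profile1.values, profile2.values
    if len(a) != len(b):
        raise ValueError("profiles must share bins")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("too few mutually called bins")
    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    agree = float(np.mean(np.sign(a[ok]) == np.sign(b[ok])))
    return {"n": int(ok.sum()), "correlation": r, "sign_agreement": agree,
            "values1": a[ok], "values2": b[ok]}


@dataclasses.dataclass
class SaddleMatrix:
    """Compartment-ordered matrix; ``order`` holds the global bin indices of
    its rows (ascending PC1: strongest B first, strongest A last)."""

    matrix: np.ndarray
    order: np.ndarray
    chrom: str
    units: str


def _block_smooth(M: np.ndarray, f: int) -> np.ndarray:
    """f x f block-mean smoothing (NaN tolerant); trims a ragged edge."""
    n = (M.shape[0] // f) * f
    T = M[:n, :n].reshape(n // f, f, n // f, f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(T, axis=(1, 3))


def saddle_difference(
    map_a: ContactMap,
    map_b: ContactMap,
    profile: CompartmentProfile,
    smooth_factor: int = 2,
) -> dict:
    """Per-chromosome saddle matrices of (z_B - z_A) in one reference order.

    Distance z-scores are computed per map, rows/columns permuted by the
    reference profile's ascending PC1 (strongest B to strongest A), the
    control subtracted from the perturbed condition, and the result smoothed
    by ``smooth_factor`` x ``smooth_factor`` block means (250 kb -> 500 kb at
    the default). Antisymmetric in its two map arguments.
    """
    if map_a.bins != map_b.bins:
        raise ValueError("maps must share a bin table")
    za = distance_zscore(map_a)
    zb = distance_zscore(map_b)
    out = {}
    bins = map_a.bins
    for chrom in bins.genome.names:
        s = bins.chrom_slice(chrom)
        pc1 = profile.values[s]
        called = ~np.isnan(pc1)
        if called.sum() < 4:
            continue
        order_local = np.where(called)[0][np.argsort(pc1[called], kind="stable")]
        D = (zb[s, s] - za[s, s])[np.ix_(order_local, order_local)]
        out[chrom] = SaddleMatrix(
            matrix=_block_smooth(D, smooth_factor),
            order=order_local + s.start,
            chrom=chrom,
            units="delta-zscore",
        )
    return out


def saddle_corner_means(saddle: SaddleMatrix, frac: float = 0.2) -> dict:
    """Mean of the B-B, A-A, and A-B corner blocks of a saddle matrix."""
    n = saddle.matrix.shape[0]
    k = max(1, int(round(frac * n)))
    M = saddle.matrix
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "BB": float(np.nanmean(M[:k, :k])),
            "AA": float(np.nanmean(M[-k:, -k:])),
            "AB": float(np.nanmean(np.concatenate([M[:k, -k:].ravel(),
                                                   M[-k:, :k].ravel()]))),
        }


def compartment_strength(
    cmap: ContactMap,
    profile: CompartmentProfile,
    smooth_factor: int = 2,
    top_fraction: float = 0.2,
    threshold_mode: str = "per_class",
) -> pd.DataFrame:
    """Per-chromosome A-A and B-B interaction strengths.

    Per chromosome: the distance-corrected (O/E) cis matrix is reordered by
    ascending PC1, block-smoothed, and each off-diagonal pair classified as
    A-A, B-B, or A-B by the signs of the merged bins' mean PC1. Only the top
    ``top_fraction`` of smoothed values is kept — within each class by
    default ("per_class"), or across all classified pairs ("pooled") — and
    strengths are median(A-A) - median(A-B) and median(B-B) - median(A-B).
    Invariant to a global rescaling of counts. Chromosomes lacking both PC1
    signs are reported as NaN.
    """
    if threshold_mode not in ("per_class", "pooled"):
        raise ValueError("threshold_mode must be 'per_class' or 'pooled'")
    oe_full = observed_over_expected(cmap)
    bins = cmap.bins
    rows = []
    for chrom in bins.genome.names:
        s = bins.chrom_slice(chrom)
        pc1 = profile.values[s]
        called = ~np.isnan(pc1)
        if called.sum() < 4 or not ((pc1[called] > 0).any() and (pc1[called] < 0).any()):
            rows.append({"chrom": chrom, "A_strength": np.nan, "B_strength": np.nan})
            continue
        order = np.where(called)[0][np.argsort(pc1[called], kind="stable")]
        OE = oe_full[s, s][np.ix_(order, order)]
        S = _block_smooth(OE, smooth_factor)
        pc_ord = pc1[order]
        m = S.shape[0]
        pc_s = np.array(
            [np.nanmean(pc_ord[i * smooth_factor : (i + 1) * smooth_factor])
             for i in range(m)]
        )
        sign = np.sign(pc_s)
        iu, ju = np.triu_indices(m, k=1)
        vals = S[iu, ju]
        cls = np.where(
            (sign[iu] > 0) & (sign[ju] > 0), "AA",
            np.where((sign[iu] < 0) & (sign[ju] < 0), "BB", "AB"),
        )
        ok = ~np.isnan(vals) & (sign[iu] != 0) & (sign[ju] != 0)
        vals, cls = vals[ok], cls[ok]
        med = {}
        if threshold_mode == "pooled":
            if vals.size == 0:
                rows.append({"chrom": chrom, "A_strength": np.nan, "B_strength": np.nan})
                continue
            thr = np.quantile(vals, 1 - top_fraction)
            keep = vals >= thr
            for c in ("AA", "BB", "AB"):
                sub = vals[keep & (cls == c)]
                med[c] = float(np.median(sub)) if sub.size else np.nan
        else:
            for c in ("AA", "BB", "AB"):
                sub = vals[cls == c]
                if sub.size == 0:
                    med[c] = np.nan
                    continue
                thr = np.quantile(sub, 1 - top_fraction)
                med[c] = float(np.median(sub[sub >= thr]))
        rows.append(
            {
                "chrom": chrom,
                "A_strength": med.get("AA", np.nan) - med.get("AB", np.nan),
                "B_strength": med.get("BB", np.nan) - med.get("AB", np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("chrom")
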