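"""Loop-set classification, pileup aggregation (APA), donut loop strength,
site pairing, and anchor-factor enrichment.

Loops are anchor pairs on one chromosome (anchor1 upstream of anchor2),
carried as a BEDPE-style DataFrame with per-anchor CTCF motif/peak flags.
Classification follows the two-sided motif rule: loops with motifs at both
anchors are "CTCF"; loops with no motif at either anchor AND no overlap with
any supplied CTCF peak set at either anchor are "nonCTCF"; everything else
is "other".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome import GenomeSpec, IntervalSet
from .matrix import ContactMap, ExpectedProfile, expected_by_distance, observed_over_expected

__all__ = [
    "classify_loops",
    "pair_sites",
    "pileup_sum",
    "pileup_obs_exp",
    "loop_strength",
    "anchor_factor_enrichment",
]

_ANCHOR_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def _check_loops(loops: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _ANCHOR_COLS if c not in loops.columns]
    if missing:
        raise ValueError(f"loop table lacks columns {missing}")
    bad = loops["chrom1"] != loops["chrom2"]
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} loops with anchors on different chromosomes rejected",
            RuntimeWarning,
        )
        loops = loops[~bad]
    return loops.reset_index(drop=True)


def _anchor_overlaps(loops: pd.DataFrame, peaks: IntervalSet) -> tuple:
    trees = peaks.trees()

    def hit(chrom, start, end):
        t = trees.get(chrom)
        return bool(t and t.overlap(start, end))

    a1 = loops.apply(lambda r: hit(r["chrom1"], r["start1"], r["end1"]), axis=1)
    a2 = loops.apply(lambda r: hit(r["chrom2"], r["start2"], r["end2"]), axis=1)
    return np.asarray(a1, dtype=bool), np.asarray(a2, dtype=bool)


def classify_loops(loops: pd.DataFrame, ctcf_peak_sets: list | None = None) -> pd.DataFrame:
    """Partition loops into CTCF / nonCTCF / other classes.

    Requires boolean columns ``ctcf_motif1``/``ctcf_motif2``. A loop is
    "CTCF" when both anchors carry a motif. It is "nonCTCF" only when
    neither anchor has a motif and neither anchor overlaps any interval of
    any peak set in ``ctcf_peak_sets`` (the peak screen removes loops whose
    anchors are CTCF-bound without an annotated motif). The rest are
    "other". Every loop gets exactly one class.
    """
    loops = _check_loops(loops.copy())
    for c in ("ctcf_motif1", "ctcf_motif2"):
        if c not in loops.columns:
            raise ValueError(f"loop table lacks motif flag column {c!r}")
    m1 = loops["ctcf_motif1"].astype(bool).to_numpy()
    m2 = loops["ctcf_motif2"].astype(bool).to_numpy()
    peak_hit = np.zeros(len(loops), dtype=bool)
    for peaks in ctcf_peak_sets or []:
        a1, a2 = _anchor_overlaps(loops, peaks)
        peak_hit |= a1 | a2
    cls = np.where(
        m1 & m2, "CTCF", np.where(~m1 & ~m2 & ~peak_hit, "nonCTCF", "other")
    )
    loops["loop_class"] = cls
    return loops


def pair_sites(
    sites: IntervalSet,
    min_separation_bp: int = 50_000,
    max_separation_bp: int | None = None,
) -> pd.DataFrame:
    """All same-chromosome site pairs with midpoint separation above
    ``min_separation_bp`` (and at most ``max_separation_bp`` if given) —
    the candidate-interaction construction used for factor-site pileups."""
    rows = []
    df = sites.df
    for chrom, grp in df.groupby("chrom", sort=False):
        g = grp.sort_values(["start", "end"]).reset_index(drop=True)
        mids = ((g["start"] + g["end"]) // 2).to_numpy()
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                sep = abs(int(mids[j]) - int(mids[i]))
                if sep <= min_separation_bp:
                    continue
                if max_separation_bp is not None and sep > max_separation_bp:
                    continue
                rows.append(
                    (
                        chrom, int(g.at[i, "start"]), int(g.at[i, "end"]),
                        chrom, int(g.at[j, "start"]), int(g.at[j, "end"]),
                    )
                )
    return pd.DataFrame(rows, columns=_ANCHOR_COLS)


def _pair_pixels(cmap: ContactMap, pairs: pd.DataFrame):
    """Snap anchor midpoints to bins; yield (bin_i, bin_j, chrom_slice)."""
    bins = cmap.bins
    for _, row in pairs.iterrows():
        chrom = row["chrom1"]
        mid1 = (int(row["start1"]) + int(row["end1"])) // 2
        mid2 = (int(row["start2"]) + int(row["end2"])) // 2
        bi = bins.bin_index(chrom, mid1)
        bj = bins.bin_index(chrom, mid2)
        if bi > bj:
            bi, bj = bj, bi
        yield bi, bj, bins.chrom_slice(chrom)


def pileup_sum(cmap: ContactMap, pairs: pd.DataFrame, flank_bp: int = 100_000):
    """Summed aggregate sub-matrix around a list of anchor pairs.

    Extracts the window ``flank_bp`` up/downstream of each anchor (21x21 at
    10 kb bins with a 100 kb flank) and sums balanced signal over all pairs
    and chromosomes. Pairs whose window crosses a chromosome end are
    dropped; returns ``(matrix, n_used, n_dropped)``.
    """
    pairs = _check_loops(pairs)
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    f = flank_bp // cmap.bins.bin_size
    size = 2 * f + 1
    agg = np.zeros((size, size))
    used = dropped = 0
    for bi, bj, s in _pair_pixels(cmap, pairs):
        if bi - f < s.start or bi + f >= s.stop or bj - f < s.start or bj + f >= s.stop:
            dropped += 1
            continue
        agg += cmap.counts[bi - f : bi + f + 1, bj - f : bj + f + 1]
        used += 1
    return agg, used, dropped


def pileup_obs_exp(
    cmap: ContactMap,
    pairs: pd.DataFrame,
    flank_bp: int = 100_000,
    expected: ExpectedProfile | None = None,
):
    """Aggregate log2(observed/expected) pileup: per-offset missing-tolerant
    mean of log2 O/E over all pairs. Returns ``(matrix, n_used, n_dropped)``."""
    pairs = _check_loops(pairs)
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    oe = observed_over_expected(cmap, expected)
    with np.errstate(invalid="ignore", divide="ignore"):
        log_oe = np.log2(oe)
    log_oe[~np.isfinite(log_oe)] = np.nan
    f = flank_bp // cmap.bins.bin_size
    size = 2 * f + 1
    total = np.zeros((size, size))
    n = np.zeros((size, size))
    used = dropped = 0
    for bi, bj, s in _pair_pixels(cmap, pairs):
        if bi - f < s.start or bi + f >= s.stop or bj - f < s.start or bj + f >= s.stop:
            dropped += 1
            continue
        win = log_oe[bi - f : bi + f + 1, bj - f : bj + f + 1]
        ok = np.isfinite(win)
        total[ok] += win[ok]
        n += ok
        used += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return mean, used, dropped


def loop_strength(
    cmap: ContactMap,
    loops: pd.DataFrame,
    loop_bin_bp: int = 30_000,
    donut_inner: int = 1,
    donut_outer: int = 5,
    max_missing_fraction: float = 0.5,
    use_obs_exp: bool = True,
) -> pd.DataFrame:
    """Per-loop donut strength: log2 of the mean signal in the loop bin over
    the mean signal in a surrounding donut.

    The loop bin is a ``loop_bin_bp`` square (3x3 at 10 kb) centred on the
    anchor-midpoint pixel; the donut is the ring beyond ``donut_inner``
    bins around that square out to ``donut_outer`` bins, excluding the
    row/column stripes through the centre. Loops whose donut leaves the
    chromosome or is more than half missing are reported with a reason.
    Signal is distance-normalized (O/E) by default, making the statistic
    invariant to global scaling and decay.
    """
    loops = _check_loops(loops)
    if len(loops) == 0:
        raise ValueError("empty loop set")
    bins = cmap.bins
    half = (loop_bin_bp // bins.bin_size) // 2  # 3x3 core at defaults
    if use_obs_exp:
        sig = observed_over_expected(cmap)
    else:
        sig = cmap.counts.astype(float).copy()
        sig[cmap.mask, :] = np.nan
        sig[:, cmap.mask] = np.nan
    r = half + donut_inner + donut_outer
    size = 2 * r + 1
    c = r
    yy, xx = np.mgrid[0:size, 0:size]
    cheb = np.maximum(np.abs(yy - c), np.abs(xx - c))
    donut_mask = (cheb > half + donut_inner) & (cheb <= r)
    donut_mask &= (yy != c) & (xx != c)  # drop centre stripes
    core_mask = cheb <= half
    out = []
    for li, (bi, bj, s) in enumerate(_pair_pixels(cmap, loops)):
        if bi - r < s.start or bi + r >= s.stop or bj - r < s.start or bj + r >= s.stop:
            out.append((np.nan, "incomplete donut"))
            continue
        win = sig[bi - r : bi + r + 1, bj - r : bj + r + 1]
        core = win[core_mask]
        ring = win[donut_mask]
        if np.isnan(ring).mean() > max_missing_fraction or np.isnan(core).all():
            out.append((np.nan, "masked donut"))
            continue
        core_m = np.nanmean(core)
        ring_m = np.nanmean(ring)
        if not (core_m > 0 and ring_m > 0):
            out.append((np.nan, "non-positive signal"))
            continue
        out.append((float(np.log2(core_m / ring_m)), ""))
    res = loops.copy()
    res["strength"] = [v for v, _ in out]
    res["strength_note"] = [note for _, note in out]
    return res


def anchor_factor_enrichment(
    loops: pd.DataFrame,
    factor_peaks: IntervalSet,
    genome: GenomeSpec,
    n_random: int = 100,
    seed: int = 0,
) -> dict:
    """Observed anchor-overlap fraction for a factor vs size-matched random
    region sets.

    Each loop contributes two anchors. Random sets match the anchor count
    and length distribution, placed uniformly per chromosome (weighted by
    length), seeded. Returns the observed fraction, the mean random
    fraction, their ratio, the empirical percentile of the observed value,
    and the central 95% interval of the null fractions.
    """
    if len(factor_peaks) == 0:
        raise ValueError("factor peak set is empty")
    loops = _check_loops(loops)
    anchors = pd.concat(
        [
            loops[["chrom1", "start1", "end1"]].rename(
                columns={"chrom1": "chrom", "start1": "start", "end1": "end"}
            ),
            loops[["chrom2", "start2", "end2"]].rename(
                columns={"chrom2": "chrom", "start2": "start", "end2": "end"}
            ),
        ],
        ignore_index=True,
    )
    trees = factor_peaks.trees()

    def frac(df: pd.DataFrame) -> float:
        hits = 0
        for _, row in df.iterrows():
            t = trees.get(row["chrom"])
            if t and t.overlap(row["start"], row["end"]):
                hits += 1
        return hits / len(df)

    obs = frac(anchors)
    lengths = (anchors["end"] - anchors["start"]).to_numpy()
    rng = np.random.default_rng(int(seed) % 2**31)
    weights = np.array(genome.lengths, dtype=float)
    weights /= weights.sum()
    null = []
    for _ in range(n_random):
        ch_idx = rng.choice(len(genome), size=len(anchors), p=weights)
        rows = []
        for k, ci in enumerate(ch_idx):
            L = genome.lengths[ci]
            w = int(min(lengths[k], L - 1))
            start = int(rng.integers(0, max(1, L - w)))
            rows.append((genome.names[ci], start, start + max(w, 1)))
        null.append(frac(pd.DataFrame(rows, columns=["chrom", "start", "end"])))
    null = np.array(null)
    mean_null = float(null.mean())
    return {
        "observed_fraction": float(obs),
        "random_mean_fraction": mean_null,
        "enrichment_ratio": float(obs / mean_null) if mean_null > 0 else np.inf,
        "percentile": float((null < obs).mean() * 100),
        "null_interval_95": (float(np.quantile(null, 0.025)),
                             float(np.quantile(null, 0.975))),
    }
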