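"""Contact-map container, on-disk formats, coarsening, iterative correction,
distance normalization (expected, O/E, z-scores), chromosome-pair O/E, and
the two-step correlation reproducibility metric.

A ContactMap stores the genome-wide symmetric matrix densely; the canonical
on-disk format is sparse upper-triangle triplet text. The main diagonal
(zero genomic distance) is excluded from balancing and from every
distance-normalized statistic.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .genome import BinTable, FileFormatError

__all__ = [
    "ContactMap",
    "ExpectedProfile",
    "read_matrix",
    "write_matrix",
    "read_dense",
    "write_dense",
    "coarsen",
    "ice_balance",
    "expected_by_distance",
    "observed_over_expected",
    "distance_zscore",
    "trans_observed_expected",
    "reproducibility_correlation",
]


class ContactMap:
    """Genome-wide symmetric binned contact matrix.

    Parameters
    ----------
    bins : BinTable
        Bin grid indexing both matrix axes.
    counts : (n, n) array
        Symmetric, non-negative. Raw counts or balanced signal.
    mask : (n,) bool array, optional
        True marks excluded bins; their rows/columns are unusable.
    balanced : bool
        Whether ``counts`` has been iteratively corrected.
    bias : (n,) array, optional
        Per-bin balancing bias (NaN at masked bins) with
        ``corrected_ij = raw_ij / (bias_i * bias_j)``.
    """

    def __init__(self, bins: BinTable, counts, mask=None, balanced=False, bias=None):
        counts = np.asarray(counts, dtype=float)
        n = len(bins)
        if counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}")
        if not np.allclose(counts, counts.T, equal_nan=True):
            raise ValueError("counts must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmin(counts) < 0:
                raise ValueError("counts must be non-negative")
        self.bins = bins
        self.counts = counts
        self.mask = (
            np.zeros(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        )
        self.balanced = bool(balanced)
        self.bias = None if bias is None else np.asarray(bias, dtype=float)
        if balanced and self.bias is None:
            raise ValueError("balanced map must record its bias vector")

    def __len__(self) -> int:
        return len(self.bins)

    def cis(self, chrom: str) -> np.ndarray:
        """View of the intrachromosomal block for one chromosome."""
        s = self.bins.chrom_slice(chrom)
        return self.counts[s, s]

    def cis_mask(self, chrom: str) -> np.ndarray:
        return self.mask[self.bins.chrom_slice(chrom)]

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.bins,
            self.counts.copy(),
            self.mask.copy(),
            self.balanced,
            None if self.bias is None else self.bias.copy(),
        )

    @property
    def total(self) -> float:
        """Total signal over unordered bin pairs (diagonal counted once)."""
        return (self.counts.sum() + np.trace(self.counts)) / 2.0

    def trans_matrix(self) -> np.ndarray:
        """Copy of counts with all cis blocks set to NaN."""
        out = self.counts.copy()
        for chrom in self.bins.genome.names:
            s = self.bins.chrom_slice(chrom)
            out[s, s] = np.nan
        return out


# -- I/O ---------------------------------------------------------------------


def write_matrix(cmap: ContactMap, path) -> None:
    """Write nonzero upper-triangle entries as 'bin1 bin2 value' triplets."""
    iu, ju = np.triu_indices(len(cmap))
    vals = cmap.counts[iu, ju]
    keep = vals != 0
    with open(path, "w") as fh:
        for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")


def read_matrix(path, bins: BinTable) -> ContactMap:
    """Read triplet text into a symmetric ContactMap.

    Mirror entries (i,j) and (j,i) must agree when both are present.
    """
    n = len(bins)
    counts = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FileFormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                raise FileFormatError(f"{path}:{lineno}: bad triplet")
            if not (0 <= i < n and 0 <= j < n):
                raise FileFormatError(f"{path}:{lineno}: bin index out of range")
            if v < 0:
                raise FileFormatError(f"{path}:{lineno}: negative count")
            a, b = min(i, j), max(i, j)
            if seen[a, b] and counts[a, b] != v:
                raise FileFormatError(
                    f"{path}:{lineno}: conflicting mirror entries at ({i},{j})"
                )
            seen[a, b] = True
            counts[a, b] = v
            counts[b, a] = v
    return ContactMap(bins, counts)


def write_dense(cmap: ContactMap, path) -> None:
    np.savetxt(path, cmap.counts, delimiter="\t", fmt="%.10g")


def read_dense(path, bins: BinTable) -> ContactMap:
    counts = np.loadtxt(path, delimiter="\t", ndmin=2)
    return ContactMap(bins, counts)


# -- coarsening --------------------------------------------------------------


def coarsen(cmap: ContactMap, new_bin_size: int) -> ContactMap:
    """Sum counts into larger bins. ``new_bin_size`` must be a multiple of
    the current size. A merged bin is masked only if all its parts are."""
    old = cmap.bins.bin_size
    if new_bin_size % old != 0 or new_bin_size <= 0:
        raise ValueError("new bin size must be a positive multiple of the old")
    if new_bin_size == old:
        return cmap.copy()
    new_bins = BinTable(cmap.bins.genome, new_bin_size)
    # per-bin aggregation map: old global index -> new global index
    agg = np.empty(len(cmap.bins), dtype=np.int64)
    for chrom in cmap.bins.genome.names:
        s_old = cmap.bins.chrom_slice(chrom)
        s_new = new_bins.chrom_slice(chrom)
        local = np.arange(s_old.stop - s_old.start) * old // new_bin_size
        agg[s_old] = s_new.start + local
    n_new = len(new_bins)
    # two-sided one-hot aggregation
    P = np.zeros((n_new, len(cmap.bins)))
    P[agg, np.arange(len(cmap.bins))] = 1.0
    counts = P @ cmap.counts @ P.T
    # the dense product double-counts old off-diagonal pairs that fall on
    # the new diagonal; restore unordered-pair semantics there
    old_diag_sums = np.zeros(n_new)
    np.add.at(old_diag_sums, agg, np.diag(cmap.counts))
    di = np.arange(n_new)
    counts[di, di] = (counts[di, di] + old_diag_sums) / 2.0
    mask = np.ones(n_new, dtype=bool)
    np.minimum.at(mask, agg, cmap.mask)
    return ContactMap(new_bins, counts, mask)


# -- iterative correction (ICE) ----------------------------------------------


@dataclasses.dataclass
class IceResult:
    map: ContactMap
    bias: np.ndarray
    converged: bool
    n_iter: int
    final_cv: float


def ice_balance(
    cmap: ContactMap,
    mask_low_coverage_percent: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    include_diagonal: bool = False,
) -> IceResult:
    """Iterative correction: remove multiplicative per-bin biases so every
    unmasked row of the corrected matrix has the same marginal sum.

    Bins with zero coverage, plus the lowest ``mask_low_coverage_percent``
    percent of positive-coverage bins, are masked before iteration. The
    main diagonal is excluded from the balancing sums unless
    ``include_diagonal``. Convergence: coefficient of variation of unmasked
    marginals < ``tol``. The bias vector is normalized to mean 1 over
    unmasked bins; ``corrected_ij = counts_ij / (bias_i * bias_j)`` up to
    a global scale that sets the mean unmasked marginal to its raw value.
    """
    n = len(cmap)
    W = cmap.counts.astype(float).copy()
    if not include_diagonal:
        np.fill_diagonal(W, 0.0)
    mask = cmap.mask.copy()
    coverage = W.sum(axis=1)
    mask |= coverage <= 0
    pos = coverage[~mask]
    if mask_low_coverage_percent > 0 and pos.size:
        thr = np.percentile(pos, mask_low_coverage_percent)
        mask |= coverage < thr  # bottom percentile of positive-coverage bins
    W[mask, :] = 0.0
    W[:, mask] = 0.0

    bias = np.ones(n)
    converged = False
    cv = np.inf
    it = 0
    unmasked = ~mask
    if unmasked.sum() == 0:
        raise ValueError("all bins masked; nothing to balance")
    for it in range(1, max_iter + 1):
        marg = W.sum(axis=1)
        m = marg[unmasked]
        mean = m.mean()
        cv = m.std() / mean if mean > 0 else np.inf
        if cv < tol:
            converged = True
            break
        adj = np.ones(n)
        adj[unmasked] = marg[unmasked] / mean
        W /= np.outer(adj, adj)
        bias *= adj
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations (CV={cv:.3g}); "
            "returning partial result",
            RuntimeWarning,
        )
    # normalize bias to mean 1 over unmasked bins; fold the scale into W
    bmean = bias[unmasked].mean()
    bias /= bmean
    W *= bmean**2
    # restore the diagonal, corrected with the final biases
    if not include_diagonal:
        d = np.diag(cmap.counts).copy().astype(float)
        d[unmasked] = d[unmasked] / bias[unmasked] ** 2
        d[mask] = 0.0
        np.fill_diagonal(W, d)
    bias_out = bias.copy()
    bias_out[mask] = np.nan
    out = ContactMap(cmap.bins, W, mask, balanced=True, bias=bias_out)
    return IceResult(out, bias_out, converged, it, cv)


# -- distance normalization --------------------------------------------------


@dataclasses.dataclass
class ExpectedProfile:
    """Mean balanced signal per genomic separation (in bins), cis only.

    ``by_chrom[chrom][d]`` for d = 0..n_chrom-1; index 0 (the diagonal) is
    NaN by construction. ``pooled`` is the genome-wide average over all
    intrachromosomal pairs at each separation.
    """

    bins: BinTable
    by_chrom: dict
    pooled: np.ndarray

    def expected_cis(self, chrom: str) -> np.ndarray:
        """Dense expected matrix for one chromosome's cis block."""
        prof = self.by_chrom[chrom]
        nb = len(prof)
        d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        return prof[d]


def expected_by_distance(cmap: ContactMap) -> ExpectedProfile:
    """Average unmasked signal at each separation, per chromosome and pooled.

    Separations with no unmasked pairs get NaN.
    """
    by_chrom = {}
    genome = cmap.bins.genome
    max_nb = max(cmap.bins.n_bins_of(c) for c in genome.names)
    pooled_sum = np.zeros(max_nb)
    pooled_n = np.zeros(max_nb)
    for chrom in genome.names:
        M = cmap.cis(chrom).copy()
        cm = cmap.cis_mask(chrom)
        M[cm, :] = np.nan
        M[:, cm] = np.nan
        nb = M.shape[0]
        prof = np.full(nb, np.nan)
        for d in range(1, nb):
            diag = np.diagonal(M, d)
            ok = ~np.isnan(diag)
            if ok.any():
                prof[d] = diag[ok].mean()
                pooled_sum[d] += diag[ok].sum()
                pooled_n[d] += ok.sum()
        by_chrom[chrom] = prof
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(pooled_n > 0, pooled_sum / np.maximum(pooled_n, 1), np.nan)
    pooled[0] = np.nan
    return ExpectedProfile(cmap.bins, by_chrom, pooled)


def observed_over_expected(
    cmap: ContactMap, expected: ExpectedProfile | None = None
) -> np.ndarray:
    """Genome-wide matrix of cis observed/expected ratios.

    Trans entries, the diagonal, and masked bins are NaN. Expected is
    per-chromosome.
    """
    if expected is None:
        expected = expected_by_distance(cmap)
    n = len(cmap)
    out = np.full((n, n), np.nan)
    for chrom in cmap.bins.genome.names:
        s = cmap.bins.chrom_slice(chrom)
        M = cmap.cis(chrom)
        E = expected.expected_cis(chrom)
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = M / E
        cm = cmap.cis_mask(chrom)
        oe[cm, :] = np.nan
        oe[:, cm] = np.nan
        np.fill_diagonal(oe, np.nan)
        out[s, s] = oe
    return out


def distance_zscore(cmap: ContactMap) -> np.ndarray:
    """Per-pair z-scores within each separation, per chromosome.

    Normalizes for distance decay: z_ij = (x_ij - mean_d) / sd_d over the
    unmasked pairs of that chromosome at separation d. Separations whose
    sd is 0 (or with a single pair) give NaN. Trans and diagonal are NaN.
    """
    n = len(cmap)
    out = np.full((n, n), np.nan)
    for chrom in cmap.bins.genome.names:
        s = cmap.bins.chrom_slice(chrom)
        M = cmap.cis(chrom).astype(float).copy()
        cm = cmap.cis_mask(chrom)
        M[cm, :] = np.nan
        M[:, cm] = np.nan
        nb = M.shape[0]
        Z = np.full((nb, nb), np.nan)
        for d in range(1, nb):
            diag = np.diagonal(M, d)
            ok = ~np.isnan(diag)
            if ok.sum() < 2:
                continue
            mu = diag[ok].mean()
            sd = diag[ok].std()
            if sd <= 1e-12 * max(abs(mu), 1e-300):  # numerically constant
                z = np.where(ok, 0.0, np.nan)
            else:
                z = (diag - mu) / sd
            idx = np.arange(nb - d)
            Z[idx, idx + d] = z
            Z[idx + d, idx] = z
        out[s, s] = Z
    return out


def trans_observed_expected(cmap: ContactMap) -> pd.DataFrame:
    """Chromosome-pair observed/expected contact matrix.

    Expected counts between chromosomes A and B are proportional to the
    product of the total trans reads involving each chromosome,
    renormalized so that the expected total over all chromosome pairs
    equals the observed total. Diagonal (cis) entries are NaN. Invariant
    to a global rescaling of counts.
    """
    names = list(cmap.bins.genome.names)
    k = len(names)
    obs = np.zeros((k, k))
    for a in range(k):
        sa = cmap.bins.chrom_slice(names[a])
        for b in range(a + 1, k):
            sb = cmap.bins.chrom_slice(names[b])
            obs[a, b] = obs[b, a] = cmap.counts[sa, sb].sum()
    totals = obs.sum(axis=1)  # trans reads involving each chromosome
    if (totals == 0).any():
        missing = [names[i] for i in np.where(totals == 0)[0]]
        warnings.warn(f"chromosomes with zero trans reads: {missing}", RuntimeWarning)
    raw_exp = np.outer(totals, totals)
    np.fill_diagonal(raw_exp, 0.0)
    scale = obs.sum() / raw_exp.sum() if raw_exp.sum() > 0 else np.nan
    exp = raw_exp * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp > 0, obs / exp, np.nan)
    np.fill_diagonal(oe, np.nan)
    oe[totals == 0, :] = np.nan
    oe[:, totals == 0] = np.nan
    return pd.DataFrame(oe, index=names, columns=names)


# -- reproducibility ---------------------------------------------------------


def _correlation_map(cmap: ContactMap, method: str = "spearman") -> np.ndarray:
    """Per-map correlation matrix: entry (i,j) is the correlation of row i
    with row j of the log-transformed matrix across the genome, diagonal
    contribution removed. Zeros and masked bins enter as missing."""
    M = cmap.counts.astype(float).copy()
    M[cmap.mask, :] = np.nan
    M[:, cmap.mask] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        L = np.where(M > 0, np.log(M), np.nan)
    np.fill_diagonal(L, np.nan)
    df = pd.DataFrame(L.T)  # columns = matrix rows
    return df.corr(method=method, min_periods=3).to_numpy()


def reproducibility_correlation(maps: list, method: str = "spearman") -> np.ndarray:
    """Pairwise reproducibility scores between balanced 1 Mb maps.

    Two steps, both rank correlations by default: a per-map correlation
    map, then the correlation between vectorized correlation maps of each
    pair of datasets. Returns a symmetric score matrix with unit diagonal.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    bins0 = maps[0].bins
    for m in maps[1:]:
        if m.bins != bins0:
            raise ValueError("maps must share a bin table")
    cms = [_correlation_map(m, method) for m in maps]
    n = len(maps)
    iu = np.triu_indices(len(bins0), k=1)
    scores = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            x, y = cms[a][iu], cms[b][iu]
            ok = ~(np.isnan(x) | np.isnan(y))
            if method == "spearman":
                r = spearmanr(x[ok], y[ok]).statistic
            else:
                r = np.corrcoef(x[ok], y[ok])[0, 1]
            scores[a, b] = scores[b, a] = r
    return scores
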