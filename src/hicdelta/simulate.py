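"""Synthetic paired-condition Hi-C contact maps with planted ground truth.

The generative model composes, per cis bin pair, a power-law distance decay,
an A/B plaid, TAD blocks, loop dots, and multiplicative per-bin biases; trans
pairs get a uniform background scaled by chromosome-pair preferences. Counts
are sampled independently Poisson on the upper triangle at a rate scaled to a
target sequencing depth. An "expansion" perturbation derives a second
condition: steeper short-range decay (continuous at the cutoff), attenuated
compartmentalization, class-dependent distal-contact shifts, per-loop
strength modulation, and per-chromosome trans modifiers — the structural
signature of chromatin decompaction under divalent-cation depletion.

Ground truth (compartment labels, gene density, TAD boundaries, loops, class
labels, biases) is returned alongside the maps and can be serialized through
the standard BED/bedGraph writers, so downstream tests never reach into
simulator internals.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    AnnotationLabels,
    BinTable,
    GenomeSpec,
    IntervalSet,
    ProfileTrack,
)
from .matrix import ContactMap

__all__ = [
    "SimulationConfig",
    "PerturbationConfig",
    "GroundTruth",
    "build_expected_model",
    "sample_contact_map",
    "apply_perturbation",
    "generate_condition_pair",
    "make_tiling_tads",
    "place_loops",
    "LAD_CLASSES",
]

LAD_CLASSES = ("cLAD", "fLAD", "fiLAD", "ciLAD")


@dataclasses.dataclass(frozen=True)
class PerturbationConfig:
    """Expansion-like transform of a simulation's expected model.

    ``decay_exponent_delta`` steepens the cis decay below
    ``short_range_cutoff_bp`` (continuously matched at the cutoff);
    ``compartment_attenuation`` multiplies the plaid amplitude delta;
    ``class_distal_multipliers`` scale contacts beyond ``distal_cutoff_bp``
    by m_i * m_j for bins of each class; ``loop_modulation`` rescales dot
    amplitudes per loop index ("*" applies to all); ``trans_modifiers``
    scale trans rows per chromosome.
    """

    short_range_cutoff_bp: int = 500_000
    decay_exponent_delta: float = 0.0
    compartment_attenuation: float = 1.0
    class_distal_multipliers: Mapping[str, float] = dataclasses.field(
        default_factory=dict
    )
    distal_cutoff_bp: int = 3_000_000
    loop_modulation: Mapping = dataclasses.field(default_factory=dict)
    trans_modifiers: Mapping[str, float] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.decay_exponent_delta < 0:
            raise ValueError("decay_exponent_delta must be >= 0")
        if not (0 < self.compartment_attenuation <= 1):
            raise ValueError("compartment_attenuation must be in (0, 1]")
        for m in (*self.class_distal_multipliers.values(),
                  *self.loop_modulation.values(),
                  *self.trans_modifiers.values()):
            if m <= 0:
                raise ValueError("all perturbation multipliers must be > 0")

    @classmethod
    def identity(cls) -> "PerturbationConfig":
        return cls()


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic Hi-C condition.

    The expected cis intensity at separation s (in bins) is
    ``bias_i * bias_j * max(s**-alpha, floor) * plaid * tad * loop`` with
    plaid = 1+delta for same-compartment pairs and 1-delta otherwise; trans
    intensity is ``bias_i * bias_j * trans_level * chrom_pref``.
    """

    genome: GenomeSpec
    bin_size: int = 100_000
    decay_exponent: float = 1.0
    decay_floor: float = 1e-5
    compartment_strength: float = 0.2
    compartment_segment_length: int = 2_500_000
    tad_spec: Mapping[str, Sequence[tuple]] = dataclasses.field(default_factory=dict)
    loop_spec: Sequence[tuple] = ()
    bias_sd: float = 0.3
    trans_level: float = 0.01
    chrom_pref: Optional[np.ndarray] = None
    class_segment_length: int = 4_000_000
    depth: int = 5_000_000
    seed: int = 0
    perturbation: Optional[PerturbationConfig] = None

    def __post_init__(self):
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not (0 <= self.compartment_strength < 1):
            raise ValueError("compartment_strength must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for chrom, blocks in self.tad_spec.items():
            for start, end, enr in blocks:
                if enr <= 1:
                    raise ValueError("TAD enrichment must be > 1")
        for loop in self.loop_spec:
            if loop[3] <= 1:
                raise ValueError("loop intensity must be > 1")
        if self.chrom_pref is not None:
            p = np.asarray(self.chrom_pref)
            if p.shape != (len(self.genome), len(self.genome)):
                raise ValueError("chrom_pref must be square over the genome")
            if not np.allclose(p, p.T) or (p <= 0).any():
                raise ValueError("chrom_pref must be symmetric positive")

    @property
    def bins(self) -> BinTable:
        return BinTable(self.genome, self.bin_size)


# -- planted structure (deterministic in config.seed) ------------------------


def _segment_labels(bins: BinTable, seg_len_bp: int, labels: Sequence, rng) -> np.ndarray:
    """Tile each chromosome with segments of exponential length, cycling a
    shuffled label choice per segment."""
    out = np.empty(len(bins), dtype=object)
    mean_bins = max(1.0, seg_len_bp / bins.bin_size)
    for chrom in bins.genome.names:
        s = bins.chrom_slice(chrom)
        nb = s.stop - s.start
        pos = 0
        prev = None
        while pos < nb:
            L = max(1, int(np.ceil(rng.exponential(mean_bins))))
            choices = [l for l in labels if l != prev] or list(labels)
            lab = choices[rng.integers(len(choices))]
            out[s.start + pos : s.start + min(nb, pos + L)] = lab
            prev = lab
            pos += L
    return out


def planted_compartments(config: SimulationConfig) -> np.ndarray:
    """Per-bin planted compartment sign (+1 = A, -1 = B)."""
    rng = np.random.default_rng([int(config.seed) % 2**31, 11])
    labels = _segment_labels(
        config.bins, config.compartment_segment_length, ("A", "B"), rng
    )
    return np.where(labels == "A", 1, -1)


def planted_classes(config: SimulationConfig) -> np.ndarray:
    """Per-bin planted LAD-style class labels."""
    rng = np.random.default_rng([int(config.seed) % 2**31, 13])
    return _segment_labels(config.bins, config.class_segment_length, LAD_CLASSES, rng)


def planted_biases(config: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng([int(config.seed) % 2**31, 17])
    return np.exp(rng.normal(0.0, config.bias_sd, len(config.bins)))


def planted_gene_density(config: SimulationConfig) -> np.ndarray:
    """Gene-density track consistent with the planted A labels (A-rich)."""
    rng = np.random.default_rng([int(config.seed) % 2**31, 19])
    comp = planted_compartments(config)
    base = np.where(comp > 0, 8.0, 2.0)
    return base + rng.gamma(2.0, 0.5, len(comp))


# -- expected model ----------------------------------------------------------


def _cis_decay(d: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Distance-decay factor over separations d (bins); d=0 treated as d=1."""
    alpha = config.decay_exponent
    de = np.maximum(d, 1).astype(float)
    decay = de**-alpha
    pert = config.perturbation
    if pert is not None and pert.decay_exponent_delta > 0:
        cut = max(1.0, pert.short_range_cutoff_bp / config.bin_size)
        dalpha = pert.decay_exponent_delta
        short = de <= cut
        # continuous at the cutoff: cut^dalpha * d^-(alpha+dalpha) == d^-alpha at d=cut
        decay = np.where(short, cut**dalpha * de ** -(alpha + dalpha), decay)
    return np.maximum(decay, config.decay_floor)


def build_expected_model(config: SimulationConfig) -> np.ndarray:
    """Dense symmetric expected-intensity matrix over all bin pairs."""
    bins = config.bins
    n = len(bins)
    genome = config.genome
    pert = config.perturbation
    comp = planted_compartments(config)
    cls = planted_classes(config)
    bias = planted_biases(config)

    delta = config.compartment_strength
    if pert is not None:
        delta *= pert.compartment_attenuation

    lam = np.zeros((n, n))

    # trans background
    pref = (
        np.ones((len(genome), len(genome)))
        if config.chrom_pref is None
        else np.asarray(config.chrom_pref, dtype=float)
    )
    tmod = np.ones(len(genome))
    if pert is not None:
        for ci, name in enumerate(genome.names):
            tmod[ci] = pert.trans_modifiers.get(name, 1.0)
    for a, ca in enumerate(genome.names):
        sa = bins.chrom_slice(ca)
        for b in range(a + 1, len(genome)):
            sb = bins.chrom_slice(genome.names[b])
            level = config.trans_level * pref[a, b] * tmod[a] * tmod[b]
            lam[sa, sb] = level
            lam[sb, sa] = level

    # cis blocks
    for ci, chrom in enumerate(genome.names):
        s = bins.chrom_slice(chrom)
        nb = s.stop - s.start
        idx = np.arange(nb)
        d = np.abs(np.subtract.outer(idx, idx))
        block = _cis_decay(d, config)

        c = comp[s]
        same = np.equal.outer(c, c)
        block = block * np.where(same, 1.0 + delta, 1.0 - delta)

        for start, end, enr in config.tad_spec.get(chrom, ()):
            b0 = start // config.bin_size
            b1 = -(-end // config.bin_size)
            inside = (idx >= b0) & (idx < b1)
            block[np.ix_(inside, inside)] *= enr

        if pert is not None and pert.class_distal_multipliers:
            m = np.array(
                [pert.class_distal_multipliers.get(lab, 1.0) for lab in cls[s]]
            )
            distal = d * config.bin_size > pert.distal_cutoff_bp
            block = np.where(distal, block * np.outer(m, m), block)

        lam[s, s] = block

    # loop dots
    for li, (chrom, a_bp, b_bp, k, width) in enumerate(_norm_loops(config.loop_spec)):
        if pert is not None:
            mult = pert.loop_modulation.get(li, pert.loop_modulation.get("*", 1.0))
            k = 1.0 + (k - 1.0) * mult
        s = bins.chrom_slice(chrom)
        bi = bins.bin_index(chrom, a_bp)
        bj = bins.bin_index(chrom, b_bp)
        h = (int(width) - 1) // 2
        # slightly peaked dot: full amplitude k at the centre pixel, tapering
        # by 10% per Chebyshev ring, so the centre is the unique maximum
        for di in range(-h, h + 1):
            for dj in range(-h, h + 1):
                i, j = bi + di, bj + dj
                if not (s.start <= i < s.stop and s.start <= j < s.stop):
                    continue
                r = max(abs(di), abs(dj))
                factor = 1.0 + (k - 1.0) * 0.9**r
                lam[i, j] *= factor
                lam[j, i] = lam[i, j]

    lam *= np.outer(bias, bias)
    if not np.isfinite(lam).all() or (lam <= 0).any():
        raise AssertionError("expected model must be strictly positive and finite")
    return lam


def _norm_loops(loop_spec):
    out = []
    for loop in loop_spec:
        chrom, a, b, k = loop[:4]
        width = loop[4] if len(loop) > 4 else 1
        if a > b:
            a, b = b, a
        out.append((chrom, int(a), int(b), float(k), int(width)))
    return out


# -- sampling ----------------------------------------------------------------


def sample_contact_map(
    lam: np.ndarray, bins: BinTable, depth: int, seed: int
) -> ContactMap:
    """Poisson-sample a ContactMap from an expected model.

    Upper-triangle rates are scaled so the expected total count equals
    ``depth``; the sampled matrix is symmetrized. Reproducible in ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    n = lam.shape[0]
    iu, ju = np.triu_indices(n)
    rates = lam[iu, ju]
    scale = depth / rates.sum()
    rng = np.random.default_rng(int(seed) % 2**31)
    draws = rng.poisson(rates * scale)
    counts = np.zeros((n, n))
    counts[iu, ju] = draws
    counts[ju, iu] = draws
    return ContactMap(bins, counts)


# -- perturbation and paired generation --------------------------------------


def apply_perturbation(
    config: SimulationConfig, pert: PerturbationConfig
) -> SimulationConfig:
    """Derive the perturbed condition's config; planted structure (seeded
    from ``config.seed``) is shared with the control so only the expected
    model changes."""
    return dataclasses.replace(config, perturbation=pert)


@dataclasses.dataclass
class GroundTruth:
    """Planted truth serialized next to every simulated pair."""

    compartment_sign: np.ndarray  # +1 A / -1 B per bin
    compartment_labels: AnnotationLabels
    gene_density: ProfileTrack
    class_labels: AnnotationLabels
    boundaries: np.ndarray  # global bin indices of planted TAD junctions
    loops: pd.DataFrame  # BEDPE-compatible anchor table
    bias: np.ndarray

    def boundary_intervals(self, bins: BinTable) -> IntervalSet:
        df = pd.DataFrame(
            {
                "chrom": bins.chroms[self.boundaries],
                "start": bins.starts[self.boundaries],
                "end": bins.ends[self.boundaries],
                "name": "boundary",
            }
        )
        return IntervalSet(df, bins.genome)

    def compartment_intervals(self, bins: BinTable) -> IntervalSet:
        labs = self.compartment_labels.labels
        rows = []
        i = 0
        while i < len(bins):
            j = i
            while (
                j + 1 < len(bins)
                and bins.chroms[j + 1] == bins.chroms[i]
                and labs[j + 1] == labs[i]
            ):
                j += 1
            rows.append((bins.chroms[i], bins.starts[i], bins.ends[j], labs[i]))
            i = j + 1
        return IntervalSet(pd.DataFrame(rows, columns=IntervalSet.COLUMNS), bins.genome)


def truth_boundaries(config: SimulationConfig) -> np.ndarray:
    """Global bin indices of planted TAD block edges (interior junctions)."""
    bins = config.bins
    out = []
    for chrom, blocks in config.tad_spec.items():
        s = bins.chrom_slice(chrom)
        nb = s.stop - s.start
        edges = set()
        for start, end, _ in blocks:
            edges.add(start // config.bin_size)
            edges.add(-(-end // config.bin_size))
        for e in sorted(edges):
            if 0 < e < nb:  # chromosome ends are not boundaries
                out.append(s.start + e)
    return np.array(sorted(set(out)), dtype=int)


def generate_condition_pair(
    config: SimulationConfig,
    pert: PerturbationConfig,
    seed: int,
):
    """Simulate (control, perturbed) maps sharing planted structure.

    Returns ``(map_control, map_perturbed, truth)``. Sampling seeds are
    derived from ``seed`` so the two conditions' Poisson noise is
    independent but jointly reproducible.
    """
    bins = config.bins
    lam_c = build_expected_model(config)
    lam_p = build_expected_model(apply_perturbation(config, pert))
    map_c = sample_contact_map(lam_c, bins, config.depth, np.random.default_rng([int(seed) % 2**31, 1]).integers(2**31))
    map_p = sample_contact_map(lam_p, bins, config.depth, np.random.default_rng([int(seed) % 2**31, 2]).integers(2**31))

    comp = planted_compartments(config)
    comp_labels = AnnotationLabels(
        bins, np.where(comp > 0, "A", "B"), vocabulary=("A", "B")
    )
    cls = AnnotationLabels(bins, planted_classes(config), vocabulary=LAD_CLASSES)
    loops = pd.DataFrame(
        [
            {
                "chrom1": c, "start1": a, "end1": a + config.bin_size,
                "chrom2": c, "start2": b, "end2": b + config.bin_size,
                "name": f"loop{i}", "intensity": k, "width": w,
            }
            for i, (c, a, b, k, w) in enumerate(_norm_loops(config.loop_spec))
        ]
    )
    truth = GroundTruth(
        compartment_sign=comp,
        compartment_labels=comp_labels,
        gene_density=ProfileTrack(bins, planted_gene_density(config)),
        class_labels=cls,
        boundaries=truth_boundaries(config),
        loops=loops,
        bias=planted_biases(config),
    )
    return map_c, map_p, truth


# -- convenience builders ----------------------------------------------------


def make_tiling_tads(
    genome: GenomeSpec, bin_size: int, tad_size_bp: int, enrichment: float
) -> dict:
    """Adjacent TAD blocks tiling each chromosome; junctions are the planted
    boundaries."""
    spec = {}
    for name, length in zip(genome.names, genome.lengths):
        blocks = []
        pos = 0
        while pos < length:
            end = min(pos + tad_size_bp, length)
            blocks.append((pos, end, enrichment))
            pos = end
        spec[name] = blocks
    return spec


def place_loops(
    genome: GenomeSpec,
    bin_size: int,
    n_per_chrom: int,
    intensity: float,
    seed: int,
    min_sep_bp: int = 500_000,
    max_sep_bp: int = 3_000_000,
    width: int = 1,
) -> list:
    """Randomly place same-chromosome loop anchor pairs, edge-avoiding."""
    rng = np.random.default_rng(int(seed) % 2**31)
    loops = []
    margin = 10 * bin_size
    for name, length in zip(genome.names, genome.lengths):
        for _ in range(n_per_chrom):
            for _attempt in range(100):
                a = int(rng.integers(margin, length - margin - max_sep_bp))
                sep = int(rng.integers(min_sep_bp, max_sep_bp))
                b = a + sep
                a = (a // bin_size) * bin_size
                b = (b // bin_size) * bin_size
                if b - a >= min_sep_bp:
                    loops.append((name, a, b, intensity, width))
                    break
    return loops
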