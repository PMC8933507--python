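"""Config-driven orchestration of the paired-condition comparison.

A run takes two or more conditions — contact matrices on disk, or a
simulated pair/triplet — and produces, per condition and per contrast
against the first (reference) condition: balancing, the reproducibility
score matrix, compartment PC1 and concordance, saddle differences and
compartment strengths, insulation profiles with boundary calls and
aggregate profiles, scaling curves, DLR/ICF and their deltas, loop pileups
and donut strengths, and (when tracks are available) the ridge/forest
regression of metric changes. Every figure-level quantity is emitted as a
TSV table; a JSON manifest records parameters and derived seeds so any
table can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import (
    AnnotationLabels,
    BinTable,
    GenomeSpec,
    ProfileTrack,
    read_chromsizes,
    write_bed,
    write_bedgraph,
)
from .matrix import (
    ContactMap,
    coarsen,
    ice_balance,
    read_matrix,
    reproducibility_correlation,
    trans_observed_expected,
)
from .compartments import (
    compartment_pc1,
    compartment_strength,
    pc1_concordance,
    saddle_corner_means,
    saddle_difference,
)
from .insulation import (
    aggregate_boundary_profile,
    average_to_bins,
    call_boundaries,
    delta_insulation,
    insulation_score,
)
from .scaling import (
    contact_scaling_curve,
    delta_dlr,
    delta_icf,
    dlr_profile,
    icf_profile,
    stratify_by_class,
)
from .loops import loop_strength, pileup_obs_exp, pileup_sum
from .regression import build_feature_table, forest_importance, ridge_fit
from .simulate import (
    PerturbationConfig,
    SimulationConfig,
    apply_perturbation,
    build_expected_model,
    generate_condition_pair,
    make_tiling_tads,
    place_loops,
    planted_classes,
    planted_gene_density,
    sample_contact_map,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("hicdelta")


@dataclasses.dataclass
class RunConfig:
    """Validated run description (see ``load_config`` for the file schema)."""

    conditions: list
    outdir: Path
    seed: int = 0
    simulate: dict | None = None
    perturbations: dict | None = None  # condition name -> perturbation params
    matrices: dict | None = None  # condition name -> triplet path
    chromsizes: str | None = None
    bin_size: int | None = None
    stages: tuple = (
        "balance",
        "reproducibility",
        "compartments",
        "insulation",
        "scaling",
        "loops",
        "regression",
    )

    def __post_init__(self):
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")
        if self.simulate is None and self.matrices is None:
            raise ValueError("either 'simulate' or 'matrices' must be given")


def load_config(path) -> RunConfig:
    """Load a YAML run config.

    Keys: ``conditions`` (list of names), ``outdir``, ``seed``,
    ``stages`` (optional subset), and either ``simulate`` (simulation
    parameters: chrom_lengths mapping, bin_size, depth, decay_exponent,
    compartment_strength, tad_size_bp, tad_enrichment, loops_per_chrom,
    loop_intensity, trans_level, bias_sd) plus optional ``perturbations``
    (per non-reference condition: decay_exponent_delta,
    short_range_cutoff_bp, compartment_attenuation,
    class_distal_multipliers, loop_modulation, trans_modifiers), or
    ``matrices`` (condition -> triplet path) with ``chromsizes`` and
    ``bin_size``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw["outdir"] = Path(raw.get("outdir", "hicdelta_out"))
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


def _derived_seed(seed: int, stage: str) -> int:
    """Stage-specific seed derived from the global seed, stable across
    stage toggling."""
    h = np.uint32(2166136261)
    for ch in stage:
        h = np.uint32((int(h) ^ ord(ch)) * 16777619 % 2**32)
    return int((int(h) ^ (int(seed) * 2654435761)) % 2**31)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format="%.8g", index=index)


def _write_matrix_tsv(M: np.ndarray, path: Path) -> None:
    np.savetxt(path, M, delimiter="\t", fmt="%.8g")


def _build_inputs(config: RunConfig):
    """Return (raw maps by condition, bins, truth or None)."""
    if config.simulate is not None:
        sim = dict(config.simulate)
        genome = GenomeSpec(
            list(sim["chrom_lengths"].keys()),
            list(sim["chrom_lengths"].values()),
        )
        bin_size = int(sim.get("bin_size", 100_000))
        tad_spec = make_tiling_tads(
            genome,
            bin_size,
            int(sim.get("tad_size_bp", 2_000_000)),
            float(sim.get("tad_enrichment", 3.0)),
        )
        loop_spec = place_loops(
            genome,
            bin_size,
            int(sim.get("loops_per_chrom", 3)),
            float(sim.get("loop_intensity", 4.0)),
            _derived_seed(config.seed, "loop-placement"),
        )
        base = SimulationConfig(
            genome=genome,
            bin_size=bin_size,
            decay_exponent=float(sim.get("decay_exponent", 1.0)),
            compartment_strength=float(sim.get("compartment_strength", 0.2)),
            compartment_segment_length=int(sim.get("compartment_segment_length", 2_500_000)),
            tad_spec=tad_spec,
            loop_spec=loop_spec,
            bias_sd=float(sim.get("bias_sd", 0.3)),
            trans_level=float(sim.get("trans_level", 0.01)),
            depth=int(sim.get("depth", 5_000_000)),
            seed=_derived_seed(config.seed, "planted-structure"),
        )
        bins = base.bins
        perts = config.perturbations or {}
        maps = {}
        truth = None
        for ci, name in enumerate(config.conditions):
            if ci == 0:
                cfg = base
            else:
                p = perts.get(name, {})
                cfg = apply_perturbation(base, PerturbationConfig(**p))
            lam = build_expected_model(cfg)
            maps[name] = sample_contact_map(
                lam, bins, base.depth, _derived_seed(config.seed, f"sample-{name}")
            )
            if ci == 0:
                # planted truth is shared by construction
                _, _, truth = generate_condition_pair(
                    base, PerturbationConfig.identity(), _derived_seed(config.seed, "truth")
                )
        return maps, bins, base, truth
    genome = read_chromsizes(config.chromsizes)
    bins = BinTable(genome, int(config.bin_size))
    maps = {name: read_matrix(path, bins) for name, path in config.matrices.items()}
    return maps, bins, None, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; independent stage failures are recorded
    in the manifest and do not halt the run. Returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(fh)
    manifest = {
        "version": __version__,
        "seed": int(config.seed),
        "conditions": list(config.conditions),
        "stages": list(config.stages),
        "errors": {},
        "tables": [],
    }

    def emit(name, writer):
        try:
            writer()
            manifest["tables"].append(name)
            log.info("wrote %s", name)
        except Exception as exc:  # stage isolation: record and continue
            manifest["errors"][name] = f"{type(exc).__name__}: {exc}"
            log.error("stage output %s failed: %s", name, exc)

    raw_maps, bins, sim_cfg, truth = _build_inputs(config)
    ref = config.conditions[0]

    balanced = {}
    if "balance" in config.stages:
        for name, m in raw_maps.items():
            res = ice_balance(m)
            balanced[name] = res.map
            emit(
                f"bias_{name}.bedgraph",
                lambda res=res, name=name: write_bedgraph(
                    ProfileTrack(bins, res.bias), out / f"bias_{name}.bedgraph"
                ),
            )
    else:
        balanced = raw_maps

    if "reproducibility" in config.stages:
        def _repro():
            coarse = []
            target = max(bins.bin_size, 1_000_000)
            target = (target // bins.bin_size) * bins.bin_size
            for name in config.conditions:
                cm = coarsen(raw_maps[name], target)
                coarse.append(ice_balance(cm).map)
            scores = reproducibility_correlation(coarse)
            _write_tsv(
                pd.DataFrame(scores, index=config.conditions, columns=config.conditions),
                out / "reproducibility_scores.tsv",
            )
        emit("reproducibility_scores.tsv", _repro)
        for name in config.conditions:
            emit(
                f"trans_obs_exp_{name}.tsv",
                lambda name=name: _write_tsv(
                    trans_observed_expected(raw_maps[name]),
                    out / f"trans_obs_exp_{name}.tsv",
                ),
            )

    profiles = {}
    if "compartments" in config.stages:
        gd = (
            ProfileTrack(bins, planted_gene_density(sim_cfg))
            if sim_cfg is not None
            else ProfileTrack(bins, np.ones(len(bins)))
        )
        for name in config.conditions:
            profiles[name] = compartment_pc1(balanced[name], gd)
            emit(
                f"pc1_{name}.bedgraph",
                lambda name=name: write_bedgraph(
                    profiles[name].track, out / f"pc1_{name}.bedgraph"
                ),
            )
            emit(
                f"compartment_strength_{name}.tsv",
                lambda name=name: _write_tsv(
                    compartment_strength(balanced[name], profiles[ref]),
                    out / f"compartment_strength_{name}.tsv",
                ),
            )
        for name in config.conditions[1:]:
            def _concord(name=name):
                c = pc1_concordance(profiles[ref], profiles[name])
                _write_tsv(
                    pd.DataFrame(
                        {
                            "metric": ["n", "correlation", "sign_agreement"],
                            "value": [c["n"], c["correlation"], c["sign_agreement"]],
                        }
                    ),
                    out / f"pc1_concordance_{name}_vs_{ref}.tsv",
                    index=False,
                )
            emit(f"pc1_concordance_{name}_vs_{ref}.tsv", _concord)

            def _saddle(name=name):
                saddles = saddle_difference(balanced[ref], balanced[name], profiles[ref])
                rows = []
                for chrom, sd in saddles.items():
                    _write_matrix_tsv(sd.matrix, out / f"saddle_{name}_vs_{ref}_{chrom}.tsv")
                    corners = saddle_corner_means(sd)
                    rows.append({"chrom": chrom, **corners})
                _write_tsv(
                    pd.DataFrame(rows).set_index("chrom"),
                    out / f"saddle_corners_{name}_vs_{ref}.tsv",
                )
            emit(f"saddle_{name}_vs_{ref}", _saddle)

    insul = {}
    if "insulation" in config.stages:
        square = 8 * bins.bin_size
        for name in config.conditions:
            insul[name] = insulation_score(balanced[name], square)
            emit(
                f"insulation_{name}.bedgraph",
                lambda name=name: write_bedgraph(
                    insul[name].track, out / f"insulation_{name}.bedgraph"
                ),
            )
        bset = call_boundaries(insul[ref])
        emit(
            "boundaries.bed",
            lambda: write_bed(bset.to_intervals(), out / "boundaries.bed", score=bset.strength),
        )
        if len(bset):
            for name in config.conditions:
                def _agg(name=name):
                    _, mean, offs = aggregate_boundary_profile(
                        insul[name], bset, 5 * bins.bin_size
                    )
                    _write_tsv(
                        pd.DataFrame({"offset_bp": offs, "mean_insulation": mean}),
                        out / f"boundary_profile_{name}.tsv",
                        index=False,
                    )
                emit(f"boundary_profile_{name}.tsv", _agg)
        for name in config.conditions[1:]:
            emit(
                f"delta_insulation_{name}_vs_{ref}.bedgraph",
                lambda name=name: write_bedgraph(
                    delta_insulation(insul[ref], insul[name]),
                    out / f"delta_insulation_{name}_vs_{ref}.bedgraph",
                ),
            )

    dlr = {}
    if "scaling" in config.stages:
        for name in config.conditions:
            def _curve(name=name):
                c = contact_scaling_curve(balanced[name])
                _write_tsv(
                    pd.DataFrame({"distance_bp": c.distances_bp, "value": c.values}),
                    out / f"scaling_curve_{name}.tsv",
                    index=False,
                )
            emit(f"scaling_curve_{name}.tsv", _curve)
            dlr[name] = dlr_profile(balanced[name])
            emit(
                f"dlr_{name}.bedgraph",
                lambda name=name: write_bedgraph(dlr[name], out / f"dlr_{name}.bedgraph"),
            )
            emit(
                f"icf_{name}.tsv",
                lambda name=name: _write_tsv(
                    icf_profile(raw_maps[name], level="chrom").to_frame(),
                    out / f"icf_{name}.tsv",
                ),
            )
        for name in config.conditions[1:]:
            ddlr = delta_dlr(dlr[ref], dlr[name], median_center=True)
            emit(
                f"delta_dlr_{name}_vs_{ref}.bedgraph",
                lambda ddlr=ddlr, name=name: write_bedgraph(
                    ddlr, out / f"delta_dlr_{name}_vs_{ref}.bedgraph"
                ),
            )
            emit(
                f"delta_icf_{name}_vs_{ref}.tsv",
                lambda name=name: _write_tsv(
                    delta_icf(
                        icf_profile(raw_maps[ref], level="chrom"),
                        icf_profile(raw_maps[name], level="chrom"),
                    ).to_frame("delta_icf"),
                    out / f"delta_icf_{name}_vs_{ref}.tsv",
                ),
            )
            if truth is not None:
                emit(
                    f"delta_dlr_by_class_{name}_vs_{ref}.tsv",
                    lambda ddlr=ddlr, name=name: _write_tsv(
                        stratify_by_class(ddlr, truth.class_labels),
                        out / f"delta_dlr_by_class_{name}_vs_{ref}.tsv",
                    ),
                )

    if "loops" in config.stages and truth is not None and len(truth.loops):
        for name in config.conditions:
            def _pile(name=name):
                agg, used, dropped = pileup_obs_exp(
                    balanced[name], truth.loops, flank_bp=5 * bins.bin_size
                )
                _write_matrix_tsv(agg, out / f"loop_pileup_{name}.tsv")
            emit(f"loop_pileup_{name}.tsv", _pile)

            def _strength(name=name):
                res = loop_strength(
                    balanced[name], truth.loops, loop_bin_bp=3 * bins.bin_size
                )
                _write_tsv(res, out / f"loop_strength_{name}.tsv", index=False)
            emit(f"loop_strength_{name}.tsv", _strength)

    if "regression" in config.stages and truth is not None and dlr:
        for name in config.conditions[1:]:
            def _regress(name=name):
                resp = delta_dlr(dlr[ref], dlr[name])
                table = build_feature_table(
                    {"gene_density": truth.gene_density}, truth.class_labels, resp
                )
                _write_tsv(ridge_fit(table), out / f"ridge_delta_dlr_{name}.tsv", index=False)
                _write_tsv(
                    forest_importance(
                        table, seed=_derived_seed(config.seed, f"forest-{name}")
                    ),
                    out / f"forest_delta_dlr_{name}.tsv",
                    index=False,
                )
            emit(f"regression_{name}", _regress)

    with open(out / "manifest.json", "w") as mh:
        json.dump(manifest, mh, indent=2, sort_keys=True)
    log.removeHandler(fh)
    fh.close()
    return manifest
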