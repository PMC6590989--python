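"""Pipeline orchestration: shared config, seeding, and stage reports.

Each stage runs a simulate-then-analyze round trip: the synthetic generator
for that stage produces ground-truthed input and the corresponding analysis
recovers the planted quantity.  Reports are plain dicts serialized as JSON,
each embedding the config hash, the seed and the package version so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .conservation import Alignment, anchor_conservation
from .confocal import ConfocalImage, membrane_fraction
from .gradient import fraction_shift, partition_stats
from .hill import compare_conditions, classify_mcd_sensitivity, fit_hill
from .motifs import PATTERN_PRESETS, TM_PRESETS, ProteinRecord, scan_tm
from .synthetic import (
    CellImageSpec,
    DoseResponseSpec,
    GradientSpec,
    MovieSpec,
    OrthologSetSpec,
    gen_confocal_cell,
    gen_dose_response,
    gen_gradient_profile,
    gen_ortholog_set,
    gen_tirf_movie,
)
from .tirf import detect_spots, link_tracks, score_comovement

logger = logging.getLogger("raftcrac")

STAGES = ("scan", "conserve", "gradient", "tirf", "confocal", "dose")

_KNOWN_KEYS = {
    "seed", "stages", "outdir",
    "scan", "conserve", "gradient", "tirf", "confocal", "dose",
}
_KNOWN_STAGE_KEYS = {
    "scan": {"pattern", "flank", "tm_preset"},
    "conserve": {"n_species", "substitution_rate", "anchor_fidelity"},
    "gradient": {"raft_fractions", "control_raft_weight", "treated_raft_weight",
                 "noise_sd"},
    "tirf": {"sigma", "k_threshold", "r_link", "r_pair", "min_consecutive",
             "n_coloc_pairs", "n_red_only", "n_green_only"},
    "confocal": {"f_membrane", "noise_sd"},
    "dose": {"bootstrap_b", "noise_sd", "n_cells_per_conc",
             "treated_ec50_fold", "treated_max_ratio"},
}

#: TM2/TM4 demonstration template used by the scan and conserve stages: a
#: synthetic stand-in sequence spanning residues 761-863 that carries the
#: study's printed anchor residues (L768/F771 with a basic partner, the
#: 780-790 fragment, and the 850-855 fragment) on an inert backbone.
DEMO_TEMPLATE_OFFSET = 761


def _build_demo_template() -> str:
    # fragments at their native residue numbers; filler drawn cyclically from
    # residues outside every anchor class so no spurious motifs can arise
    fragments = {
        768: "L",            # CRAC1 apolar anchor
        771: "F",            # CRAC1 aromatic anchor
        775: "K",            # CRAC1 basic partner (within the allowed gap)
        780: "VFLSSIFGYCK",  # printed TM2 fragment (CRACs 2/3/4)
        850: "LLYLQR",       # printed TM4 fragment (CRAC 5)
    }
    start, end = DEMO_TEMPLATE_OFFSET, 863
    filler = "SGTNHA"
    chars = [filler[(p - start) % len(filler)] for p in range(start, end + 1)]
    for pos, frag in fragments.items():
        chars[pos - start : pos - start + len(frag)] = list(frag)
    return "".join(chars)


DEMO_TEMPLATE = _build_demo_template()


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    outdir: str = "."
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params = {}
        for stage in STAGES:
            block = data.get(stage, {})
            bad = set(block) - _KNOWN_STAGE_KEYS[stage]
            if bad:
                raise ValueError(
                    f"unknown keys in {stage!r} block: {sorted(bad)}"
                )
            params[stage] = dict(block)
        stages = tuple(data.get("stages", STAGES))
        for s in stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        return cls(
            seed=int(data.get("seed", 0)),
            stages=stages,
            outdir=str(data.get("outdir", ".")),
            params=params,
        )

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "stages": list(self.stages), "outdir": self.outdir}
        for stage in STAGES:
            if self.params.get(stage):
                d[stage] = self.params[stage]
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        # independent per-stage streams derived from the global seed
        return (self.seed * len(STAGES) + STAGES.index(stage)) % (2**31)


def _demo_record() -> ProteinRecord:
    return ProteinRecord("demo", "synthetic", DEMO_TEMPLATE,
                        offset=DEMO_TEMPLATE_OFFSET)


def run_stage(config: PipelineConfig, stage: str) -> dict:
    """Run one simulate-then-analyze stage and return its report dict."""
    p = config.params.get(stage, {})
    seed = config.stage_seed(stage)
    logger.info("stage %s (seed %d)", stage, seed)

    if stage == "scan":
        pattern = PATTERN_PRESETS[p.get("pattern", "crac-extended")]
        topo = TM_PRESETS[p.get("tm_preset", "mTRPA1-fig")]
        record = _demo_record()
        per_segment = scan_tm(record, topo, pattern, flank=p.get("flank", 5))
        return {
            "counts": {sid: len(ms) for sid, ms in per_segment.items()},
            "motifs": {
                sid: [list(m.anchors) for m in ms]
                for sid, ms in per_segment.items()
            },
        }

    if stage == "conserve":
        pattern = PATTERN_PRESETS["crac-extended"]
        spec = OrthologSetSpec(
            template_sequence=DEMO_TEMPLATE,
            template_offset=DEMO_TEMPLATE_OFFSET,
            topology=TM_PRESETS["mTRPA1-fig"],
            n_species=p.get("n_species", 24),
            substitution_rate=p.get("substitution_rate", 0.1),
            anchor_fidelity=p.get("anchor_fidelity", 0.9),
            seed=seed,
        )
        panel = gen_ortholog_set(spec)
        aln = Alignment(panel.ids, panel.sequences, panel.reference_id,
                        reference_offset=panel.reference_offset)
        cons = anchor_conservation(aln, list(panel.matches), pattern)
        mean_frac = float(np.mean([c.mean_fraction for c in cons])) if cons else None
        return {
            "n_motifs": len(cons),
            "anchor_fidelity_planted": spec.anchor_fidelity,
            "mean_anchor_conservation": mean_frac,
            "per_motif": [
                {"anchors": list(c.match.anchors),
                 "apolar": c.apolar_fraction,
                 "aromatic": c.aromatic_fraction,
                 "basic": c.basic_fraction}
                for c in cons
            ],
        }

    if stage == "gradient":
        raft = set(p.get("raft_fractions", [3, 4]))
        noise = p.get("noise_sd", 10.0)
        ctrl = gen_gradient_profile(
            GradientSpec(raft_weight=p.get("control_raft_weight", 0.7),
                         noise_sd=noise, seed=seed),
            condition="control",
        )
        trt = gen_gradient_profile(
            GradientSpec(raft_weight=p.get("treated_raft_weight", 0.2),
                         noise_sd=noise, seed=seed + 1),
            condition="MCD",
        )
        sc, st = partition_stats(ctrl, raft), partition_stats(trt, raft)
        return {
            "control": {"centroid": sc.centroid_index, "peak": sc.peak_fraction,
                        "raft_share": sc.raft_share},
            "treated": {"centroid": st.centroid_index, "peak": st.peak_fraction,
                        "raft_share": st.raft_share},
            "shift": fraction_shift(ctrl, trt, raft),
        }

    if stage == "tirf":
        spec = MovieSpec(
            n_coloc_pairs=p.get("n_coloc_pairs", 5),
            n_red_only=p.get("n_red_only", 5),
            n_green_only=p.get("n_green_only", 3),
            seed=seed,
        )
        movie = gen_tirf_movie(spec)
        tracks = {}
        for channel in ("red", "green"):
            spots = detect_spots(
                movie.stack.channel(channel),
                sigma=p.get("sigma", 1.5),
                k_threshold=p.get("k_threshold", 6.0),
                channel=channel,
            )
            tracks[channel] = link_tracks(spots, r_link=p.get("r_link", 3.0))
        result = score_comovement(
            tracks["red"], tracks["green"],
            r_pair=p.get("r_pair", 3.0),
            min_consecutive=p.get("min_consecutive", 3),
        )
        return {
            "planted_coloc_percentage": 100 * movie.planted_coloc_fraction,
            "measured_percentage": result.percentage,
            "n_red_tracks": result.n_red_tracks,
            "n_coloc_red_tracks": result.n_coloc_red_tracks,
        }

    if stage == "confocal":
        spec = CellImageSpec(
            f_membrane=p.get("f_membrane", 0.6),
            noise_sd=p.get("noise_sd", 2.0),
            seed=seed,
        )
        cell = gen_confocal_cell(spec)
        quant = membrane_fraction(
            ConfocalImage(cell.membrane_channel, cell.reporter_channel,
                          cell.nuclear_channel)
        )
        return {
            "planted_f_membrane": spec.f_membrane,
            "measured_membrane_fraction": quant.membrane_fraction,
            "membrane_cv": quant.membrane_cv,
        }

    if stage == "dose":
        noise = p.get("noise_sd", 0.1)
        n = p.get("n_cells_per_conc", 50)
        ctrl_spec = DoseResponseSpec(noise_sd=noise, n_cells_per_conc=n,
                                     seed=seed)
        fold = p.get("treated_ec50_fold", 5.0)
        ratio = p.get("treated_max_ratio", 0.4)
        trt_spec = DoseResponseSpec(
            ec50=ctrl_spec.ec50 * fold, max_response=ctrl_spec.max_response * ratio,
            noise_sd=noise, n_cells_per_conc=n, condition="MCD", seed=seed + 1,
        )
        ctrl = gen_dose_response(ctrl_spec)
        trt = gen_dose_response(trt_spec)
        fit_c = fit_hill(ctrl)
        comparison = compare_conditions(
            ctrl, trt, bootstrap_b=p.get("bootstrap_b", 100), seed=seed,
        )
        return {
            "control_fit": {"Max": fit_c.max_response, "EC50": fit_c.ec50,
                            "H_S": fit_c.hill_coefficient},
            "planted": {"EC50_fold": fold, "Max_ratio": ratio},
            "ec50_fold_change": comparison.ec50_fold_change,
            "max_ratio": comparison.max_ratio,
            "ec50_fold_interval": comparison.ec50_fold_interval,
            "max_ratio_interval": comparison.max_ratio_interval,
            "mcd_sensitivity": classify_mcd_sensitivity(comparison)
            if comparison.ec50_fold_interval else None,
        }

    raise ValueError(f"unknown stage {stage!r}")


def run(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and write per-stage + combined reports.

    Returns the combined summary dict.  Any stage failure propagates (the CLI
    converts it to a non-zero exit code).
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }
    summary = {"meta": meta, "stages": {}}
    for stage in config.stages:
        report = run_stage(config, stage)
        summary["stages"][stage] = report
        with open(outdir / f"{stage}.json", "w") as fh:
            json.dump({"meta": meta, **report}, fh, indent=2, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
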