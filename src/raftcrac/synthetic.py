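"""Ground-truthed synthetic inputs for every stage of the pipeline.

Each generator emulates the statistical structure one analysis stage assumes
and returns its ground truth alongside the data, so recovery tests compare
pipeline output against planted truth rather than re-deriving it:

* ortholog panels — equal-length (pre-aligned, no indels) sequence sets with
  planted CRAC anchors preserved at a controlled per-site fidelity and
  background point substitutions elsewhere;
* two-channel TIRF movies — Gaussian spots on Brownian trajectories, a
  controlled fraction of red structures co-moving with a green partner;
* confocal cell images — membrane-dye annulus, nuclear disk, and a reporter
  whose photon budget is split between membrane and interior at an exact
  planted fraction, with optional angular clustering;
* six-fraction gradient profiles — a raft/non-raft two-component mixture;
* per-cell dose-response tables — Hill-equation responses plus Gaussian noise.

All generators draw from a single ``numpy.random.default_rng(seed)`` stream
and are bit-reproducible for a fixed spec.  Noise is additive Gaussian read
noise on ideal (Poisson-free) images, keeping recovery expectations
analytically tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gradient import FractionProfile
from .hill import predict_hill
from .motifs import (
    AMINO_ACIDS,
    CracMatch,
    MotifPattern,
    CRAC_EXTENDED,
    ProteinRecord,
    TMTopology,
    scan_tm,
)
from .tirf import FrameStack

__all__ = [
    "OrthologSetSpec",
    "MovieSpec",
    "CellImageSpec",
    "GradientSpec",
    "DoseResponseSpec",
    "gen_ortholog_set",
    "gen_tirf_movie",
    "gen_confocal_cell",
    "gen_gradient_profile",
    "gen_dose_response",
    "gradient_expected_centroid",
]


# ---------------------------------------------------------------------------
# ortholog panels

@dataclass(frozen=True)
class OrthologSetSpec:
    """Parameters of a planted-anchor ortholog panel.

    ``substitution_rate`` is the per-site substitution probability at
    non-anchor sites; ``anchor_fidelity`` is the probability that an anchor
    site keeps a residue of its own class (when perturbed it moves *outside*
    the class, so class membership is informative).
    """

    template_sequence: str
    topology: TMTopology
    template_offset: int = 1
    n_species: int = 24
    substitution_rate: float = 0.1
    anchor_fidelity: float = 0.9
    flank: int = 5
    pattern: MotifPattern = CRAC_EXTENDED
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must lie in [0, 1]")
        if not 0 <= self.anchor_fidelity <= 1:
            raise ValueError("anchor_fidelity must lie in [0, 1]")


@dataclass(frozen=True)
class OrthologSet:
    """Generated panel plus planted-anchor truth."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    reference_id: str
    reference_offset: int
    truth: pd.DataFrame  # columns: position, role, class_residues, motif anchors
    matches: tuple[CracMatch, ...]


def gen_ortholog_set(spec: OrthologSetSpec) -> OrthologSet:
    """Generate ``n_species`` equal-length orthologs of the template.

    The template itself is returned unchanged as the reference row.  Anchor
    positions are those of the template's own CRAC matches inside the flanked
    transmembrane windows.  No indels are introduced, so the panel is its own
    alignment.
    """
    record = ProteinRecord("ref", "reference", spec.template_sequence,
                          offset=spec.template_offset)
    for sid, a, b in spec.topology.segments:
        if b - a + 1 > len(record.sequence):
            raise ValueError(
                f"template shorter than topology segment {sid} ({a}-{b})"
            )
    per_segment = scan_tm(record, spec.topology, spec.pattern, flank=spec.flank)
    matches = tuple(m for ms in per_segment.values() for m in ms)

    anchor_class: dict[int, tuple[str, frozenset[str]]] = {}
    for m in matches:
        anchor_class[m.apolar_pos] = ("apolar", spec.pattern.apolar_set)
        anchor_class[m.aromatic_pos] = ("aromatic", spec.pattern.aromatic_set)
        anchor_class[m.basic_pos] = ("basic", spec.pattern.basic_set)

    rng = np.random.default_rng(spec.seed)
    template = record.sequence
    off = spec.template_offset
    alphabet = sorted(AMINO_ACIDS)
    ids = ["ref"] + [f"sp{i:02d}" for i in range(1, spec.n_species)]
    seqs = [template]
    for _ in range(spec.n_species - 1):
        chars = list(template)
        for i, c in enumerate(chars):
            pos = i + off
            if pos in anchor_class:
                _, members = anchor_class[pos]
                if rng.random() >= spec.anchor_fidelity:
                    outside = [a for a in alphabet if a not in members]
                    chars[i] = outside[rng.integers(len(outside))]
                # else: anchor kept verbatim (still in class by identity)
            else:
                if rng.random() < spec.substitution_rate:
                    others = [a for a in alphabet if a != c]
                    chars[i] = others[rng.integers(len(others))]
        seqs.append("".join(chars))

    truth = pd.DataFrame(
        [
            {"position": pos, "role": role,
             "class_residues": "".join(sorted(members))}
            for pos, (role, members) in sorted(anchor_class.items())
        ]
    )
    return OrthologSet(
        ids=tuple(ids),
        sequences=tuple(seqs),
        reference_id="ref",
        reference_offset=off,
        truth=truth,
        matches=matches,
    )


# ---------------------------------------------------------------------------
# TIRF movies

@dataclass(frozen=True)
class MovieSpec:
    """Parameters of a two-channel spot movie with a planted co-moving set."""

    n_frames: int = 20
    frame_interval: float = 0.5
    image_size: tuple[int, int] = (128, 128)
    n_coloc_pairs: int = 5
    n_red_only: int = 5
    n_green_only: int = 3
    diffusion_sigma: float = 0.5  # px / frame
    pair_jitter: float = 0.3  # px
    spot_sigma: float = 1.5  # px, point-spread width
    spot_amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("need >= 3 frames for the co-movement rule")
        if min(self.image_size) < 8:
            raise ValueError("image too small")


@dataclass(frozen=True)
class SyntheticMovie:
    stack: FrameStack
    truth_tracks: pd.DataFrame  # structure_id, channel, frame, x, y, coloc (bool)
    planted_coloc_fraction: float  # among red structures


def _brownian_path(rng, n, size, sigma) -> np.ndarray:
    h, w = size
    margin = 4.0
    pos = np.empty((n, 2))
    pos[0] = rng.uniform([margin, margin], [w - margin, h - margin])
    for t in range(1, n):
        step = rng.normal(0.0, sigma, size=2)
        nxt = pos[t - 1] + step
        # reflect at the margins so truth stays in bounds
        nxt[0] = np.clip(nxt[0], margin, w - margin)
        nxt[1] = np.clip(nxt[1], margin, h - margin)
        pos[t] = nxt
    return pos  # columns (x, y)


def gen_tirf_movie(spec: MovieSpec) -> SyntheticMovie:
    """Render a two-channel movie with a controlled co-moving red fraction.

    Co-moving pairs share one Brownian trajectory; each partner adds
    independent Gaussian jitter of ``pair_jitter`` pixels.  Spots are
    isotropic Gaussians of width ``spot_sigma`` on a constant background with
    additive Gaussian read noise.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    n_spots = spec.n_coloc_pairs * 2 + spec.n_red_only + spec.n_green_only
    if n_spots > 0:
        area_per = (h * w) / max(1, spec.n_coloc_pairs + spec.n_red_only
                                 + spec.n_green_only)
        mean_nn = 0.5 * np.sqrt(area_per)
        if mean_nn < 2 * 3.0:  # 2 × default pairing radius
            warnings.warn(
                "spot density so high that tracking is ill-posed "
                f"(mean nearest-neighbour spacing ~{mean_nn:.1f} px)"
            )

    rows = []
    structure_id = 0
    for _ in range(spec.n_coloc_pairs):
        base = _brownian_path(rng, spec.n_frames, spec.image_size,
                              spec.diffusion_sigma)
        for channel in ("red", "green"):
            jitter = rng.normal(0.0, spec.pair_jitter, size=base.shape)
            path = base + jitter
            for t, (x, y) in enumerate(path):
                rows.append((structure_id, channel, t, x, y, True))
            structure_id += 1
    for channel, count in (("red", spec.n_red_only), ("green", spec.n_green_only)):
        for _ in range(count):
            path = _brownian_path(rng, spec.n_frames, spec.image_size,
                                  spec.diffusion_sigma)
            for t, (x, y) in enumerate(path):
                rows.append((structure_id, channel, t, x, y, False))
            structure_id += 1
    truth = pd.DataFrame(
        rows, columns=["structure_id", "channel", "frame", "x", "y", "coloc"]
    )

    yy, xx = np.mgrid[0:h, 0:w]
    stacks = {}
    for channel in ("red", "green"):
        frames = np.full((spec.n_frames, h, w), float(spec.background))
        ch = truth[truth.channel == channel]
        for t in range(spec.n_frames):
            for _, r in ch[ch.frame == t].iterrows():
                frames[t] += spec.spot_amplitude * np.exp(
                    -((xx - r.x) ** 2 + (yy - r.y) ** 2) / (2 * spec.spot_sigma**2)
                )
        if spec.noise_sd > 0:
            frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)
        stacks[channel] = frames

    n_red = spec.n_coloc_pairs + spec.n_red_only
    frac = spec.n_coloc_pairs / n_red if n_red else float("nan")
    return SyntheticMovie(
        stack=FrameStack(stacks["red"], stacks["green"],
                         frame_interval=spec.frame_interval),
        truth_tracks=truth,
        planted_coloc_fraction=frac,
    )


# ---------------------------------------------------------------------------
# confocal cells

@dataclass(frozen=True)
class CellImageSpec:
    """Parameters of a ring-membrane cell image with a planted membrane fraction."""

    image_size: tuple[int, int] = (128, 128)
    cell_radius: float = 45.0
    membrane_thickness: float = 4.0
    nucleus_radius: float = 15.0
    f_membrane: float = 0.6
    clustering_concentration: float = 0.0  # von Mises kappa; 0 = uniform
    photon_budget: float = 1e5
    dye_amplitude: float = 150.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.f_membrane <= 1:
            raise ValueError("f_membrane must lie in [0, 1]")
        if self.membrane_thickness < 1:
            raise ValueError("membrane_thickness must be >= 1 pixel")
        h, w = self.image_size
        if self.cell_radius + 2 > min(h, w) / 2:
            raise ValueError("cell does not fit in the image")


@dataclass(frozen=True)
class SyntheticCell:
    membrane_channel: np.ndarray
    reporter_channel: np.ndarray
    nuclear_channel: np.ndarray
    true_f_membrane: float
    ring_mask: np.ndarray
    interior_mask: np.ndarray


def gen_confocal_cell(spec: CellImageSpec) -> SyntheticCell:
    """Render a single cell: dye annulus, reporter, nuclear disk.

    The reporter photon budget is split membrane/interior at exactly
    ``f_membrane`` before noise; membrane reporter is spread along the annulus
    either uniformly or concentrated in angle by a von Mises profile
    (``clustering_concentration`` > 0) to emulate clustered expression.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cy, cx = (h - 1) / 2, (w - 1) / 2
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)

    r_out = spec.cell_radius
    r_in = spec.cell_radius - spec.membrane_thickness
    ring = (rr <= r_out) & (rr >= r_in)
    interior = rr < r_in
    nucleus = rr <= spec.nucleus_radius

    membrane_dye = np.where(ring, spec.dye_amplitude, 0.0)
    nuclear = np.where(nucleus, spec.dye_amplitude, 0.0)

    reporter = np.zeros((h, w))
    mem_budget = spec.photon_budget * spec.f_membrane
    int_budget = spec.photon_budget * (1.0 - spec.f_membrane)
    if ring.any() and mem_budget > 0:
        if spec.clustering_concentration > 0:
            mu = rng.uniform(-np.pi, np.pi)
            weights = np.exp(
                spec.clustering_concentration * np.cos(theta[ring] - mu)
            )
        else:
            weights = np.ones(int(ring.sum()))
        weights = weights / weights.sum()
        reporter[ring] += mem_budget * weights
    if interior.any() and int_budget > 0:
        reporter[interior] += int_budget / interior.sum()

    channels = []
    for ch in (membrane_dye, reporter, nuclear):
        noisy = ch + (rng.normal(0.0, spec.noise_sd, size=ch.shape)
                      if spec.noise_sd > 0 else 0.0)
        channels.append(noisy)
    return SyntheticCell(
        membrane_channel=channels[0],
        reporter_channel=channels[1],
        nuclear_channel=channels[2],
        true_f_membrane=spec.f_membrane,
        ring_mask=ring,
        interior_mask=interior,
    )


# ---------------------------------------------------------------------------
# gradient profiles

@dataclass(frozen=True)
class GradientSpec:
    """Two-component (raft/non-raft) mixture over gradient fractions."""

    n_fractions: int = 6
    raft_weight: float = 0.7
    raft_center: float = 3.0
    nonraft_center: float = 5.5
    component_width: float = 0.7  # fractions (Gaussian sigma)
    total_intensity: float = 1000.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("need >= 2 fractions")
        if not 0 <= self.raft_weight <= 1:
            raise ValueError("raft_weight must lie in [0, 1]")
        for name, c in (("raft_center", self.raft_center),
                        ("nonraft_center", self.nonraft_center)):
            if not 1 <= c <= self.n_fractions:
                raise ValueError(
                    f"{name}={c} outside fractions 1..{self.n_fractions}"
                )


def _mixture_profile(spec: GradientSpec) -> np.ndarray:
    idx = np.arange(1, spec.n_fractions + 1, dtype=float)
    width = max(spec.component_width, 1e-9)

    def comp(center):
        v = np.exp(-((idx - center) ** 2) / (2 * width**2))
        s = v.sum()
        if s == 0:  # width → 0 with off-grid center: all mass to nearest fraction
            v = np.zeros_like(idx)
            v[int(np.clip(round(center), 1, spec.n_fractions)) - 1] = 1.0
            return v
        return v / s

    mix = (spec.raft_weight * comp(spec.raft_center)
           + (1 - spec.raft_weight) * comp(spec.nonraft_center))
    return spec.total_intensity * mix


def gradient_expected_centroid(spec: GradientSpec) -> float:
    """Noise-free centroid of the discretized mixture (analytic expectation)."""
    ideal = _mixture_profile(spec)
    idx = np.arange(1, spec.n_fractions + 1)
    return float((idx * ideal).sum() / ideal.sum())


def gen_gradient_profile(
    spec: GradientSpec, label: str = "marker", condition: str = "control"
) -> FractionProfile:
    """Draw one noisy profile from the raft/non-raft mixture (clipped at 0)."""
    rng = np.random.default_rng(spec.seed)
    ideal = _mixture_profile(spec)
    noisy = ideal + (rng.normal(0.0, spec.noise_sd, size=ideal.shape)
                     if spec.noise_sd > 0 else 0.0)
    noisy = np.clip(noisy, 0.0, None)
    if not noisy.any():
        noisy[int(round(spec.raft_center)) - 1] = spec.total_intensity
    return FractionProfile(label, condition, noisy.tolist(), source="synthetic")


# ---------------------------------------------------------------------------
# dose-response tables

@dataclass(frozen=True)
class DoseResponseSpec:
    """Per-cell Hill responses with Gaussian noise.

    Defaults carry the wild-type control condition: EC50 11.8 µM agonist,
    saturating ΔCa²⁺ of 0.79 µM.  The Hill coefficient is a free parameter
    (default 2).
    """

    concentrations: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0)
    n_cells_per_conc: int = 50
    max_response: float = 0.79  # µM Ca²⁺
    ec50: float = 11.8  # µM agonist
    hill_coefficient: float = 2.0
    noise_sd: float = 0.1  # µM Ca²⁺
    condition: str = "control"
    genotype: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if self.n_cells_per_conc < 1:
            raise ValueError("n_cells_per_conc must be >= 1")
        object.__setattr__(
            self, "concentrations", tuple(float(c) for c in self.concentrations)
        )


def gen_dose_response(spec: DoseResponseSpec) -> pd.DataFrame:
    """One row per cell: (concentration, delta_ca, condition, genotype)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for c in spec.concentrations:
        ideal = predict_hill(spec.max_response, spec.ec50,
                             spec.hill_coefficient, c)
        noise = (rng.normal(0.0, spec.noise_sd, size=spec.n_cells_per_conc)
                 if spec.noise_sd > 0 else np.zeros(spec.n_cells_per_conc))
        for eps in noise:
            rows.append(
                {"concentration": c, "delta_ca": float(ideal + eps),
                 "condition": spec.condition, "genotype": spec.genotype}
            )
    return pd.DataFrame(rows)
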