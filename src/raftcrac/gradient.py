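"""Density-gradient partition statistics for membrane-raft flotation assays.

In a detergent-free flotation gradient, lipid-raft material floats into the
low-density fractions (here fractions 3–4 of a six-fraction OptiPrep
gradient, anchored by the raft marker flotillin-2), while non-raft membrane
stays denser.  Cholesterol depletion displaces raft-resident proteins toward
denser fractions.  This module reduces per-fraction densitometry profiles to
partition summaries (normalized profile, peak fraction, intensity centroid,
raft share) and to the control-vs-treated "fraction shift" statistic, whose
headline form is the peak shift with the centroid shift reported as the
continuous counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FractionProfile",
    "PartitionStats",
    "DEFAULT_RAFT_FRACTIONS",
    "partition_stats",
    "fraction_shift",
    "summarize_conditions",
    "read_profiles",
]

DEFAULT_RAFT_FRACTIONS = frozenset({3, 4})


@dataclass(frozen=True)
class FractionProfile:
    """Per-fraction intensities for one marker under one condition.

    ``intensities[i]`` is the signal in fraction ``i + 1``; fraction 1 is the
    top (lightest) of the gradient.
    """

    label: str
    condition: str
    intensities: tuple[float, ...]
    source: str = ""

    def __init__(self, label, condition, intensities, source=""):
        vals = tuple(float(v) for v in intensities)
        if len(vals) < 2:
            raise ValueError("need at least 2 fractions")
        if any(v < 0 for v in vals):
            raise ValueError("intensities must be non-negative")
        if not any(v > 0 for v in vals):
            raise ValueError("profile must contain at least one positive intensity")
        object.__setattr__(self, "label", str(label))
        object.__setattr__(self, "condition", str(condition))
        object.__setattr__(self, "intensities", vals)
        object.__setattr__(self, "source", str(source))

    @property
    def n_fractions(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class PartitionStats:
    normalized_profile: tuple[float, ...]
    peak_fraction: int
    peak_tied: bool
    centroid_index: float
    raft_share: float


def partition_stats(
    profile: FractionProfile,
    raft_fractions=DEFAULT_RAFT_FRACTIONS,
) -> PartitionStats:
    """Summarize where a profile's mass sits on the gradient.

    centroid_index = Σ i·I_i / Σ I_i over fractions i = 1..N; peak ties
    resolve to the lowest index and are flagged; raft_share is the normalized
    mass over ``raft_fractions``.
    """
    I = np.asarray(profile.intensities, dtype=float)
    total = I.sum()
    norm = I / total
    idx = np.arange(1, len(I) + 1)
    centroid = float((idx * norm).sum())
    peak = int(np.argmax(I)) + 1  # argmax takes the first (lowest) of ties
    tied = int((I == I.max()).sum()) > 1
    raft = frozenset(int(f) for f in raft_fractions)
    if not raft <= set(idx.tolist()):
        raise ValueError(
            f"raft fractions {sorted(raft)} outside 1..{len(I)}"
        )
    share = float(norm[[f - 1 for f in sorted(raft)]].sum())
    return PartitionStats(
        normalized_profile=tuple(norm.tolist()),
        peak_fraction=peak,
        peak_tied=tied,
        centroid_index=centroid,
        raft_share=share,
    )


def fraction_shift(
    control: FractionProfile,
    treated: FractionProfile,
    raft_fractions=DEFAULT_RAFT_FRACTIONS,
) -> dict[str, float]:
    """Displacement of a marker down the gradient after treatment.

    Positive values mean movement toward denser (higher-index) fractions.
    Returns both the integer ``peak_shift`` (headline statistic) and the
    continuous ``centroid_shift``, plus the change in raft share.
    """
    if control.n_fractions != treated.n_fractions:
        raise ValueError(
            f"fraction count mismatch: control {control.n_fractions} "
            f"vs treated {treated.n_fractions}"
        )
    if control.label != treated.label:
        raise ValueError(
            f"label mismatch: {control.label!r} vs {treated.label!r}"
        )
    sc = partition_stats(control, raft_fractions)
    st = partition_stats(treated, raft_fractions)
    return {
        "centroid_shift": st.centroid_index - sc.centroid_index,
        "peak_shift": st.peak_fraction - sc.peak_fraction,
        "raft_share_change": st.raft_share - sc.raft_share,
    }


def summarize_conditions(
    profiles: list[FractionProfile],
    control_condition: str = "control",
    treated_condition: str = "MCD",
    raft_fractions=DEFAULT_RAFT_FRACTIONS,
    shift_statistic: str = "peak_shift",
) -> pd.DataFrame:
    """Pair replicate control/treated profiles per label and average shifts.

    Profiles are grouped by ``label``; within a label, the i-th control
    replicate is paired with the i-th treated replicate (by input order).
    Labels missing either condition are skipped with a warning.  The mean and
    s.e.m. of ``shift_statistic`` over replicate pairs are reported; with a
    single pair the s.e.m. is NaN.
    """
    if shift_statistic not in ("peak_shift", "centroid_shift"):
        raise ValueError(f"unknown shift statistic {shift_statistic!r}")
    rows = []
    labels = list(dict.fromkeys(p.label for p in profiles))
    for label in labels:
        ctrl = [p for p in profiles if p.label == label and p.condition == control_condition]
        trt = [p for p in profiles if p.label == label and p.condition == treated_condition]
        if not ctrl or not trt:
            warnings.warn(
                f"label {label!r}: missing {'control' if not ctrl else 'treated'} "
                f"profiles; skipped"
            )
            continue
        if len(ctrl) != len(trt):
            warnings.warn(
                f"label {label!r}: {len(ctrl)} control vs {len(trt)} treated "
                f"replicates; pairing the first {min(len(ctrl), len(trt))}"
            )
        shifts = []
        for c, t in zip(ctrl, trt):
            sh = fraction_shift(c, t, raft_fractions)
            shifts.append(sh)
        vals = np.array([s[shift_statistic] for s in shifts], dtype=float)
        cents = np.array([s["centroid_shift"] for s in shifts], dtype=float)
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append(
            {
                "label": label,
                "n_pairs": len(vals),
                "mean_shift": float(vals.mean()),
                "sem_shift": sem,
                "mean_centroid_shift": float(cents.mean()),
                "mean_control_raft_share": float(
                    np.mean([partition_stats(c, raft_fractions).raft_share for c in ctrl])
                ),
                "mean_treated_raft_share": float(
                    np.mean([partition_stats(t, raft_fractions).raft_share for t in trt])
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "n_pairs", "mean_shift", "sem_shift", "mean_centroid_shift",
            "mean_control_raft_share", "mean_treated_raft_share",
        ],
    )


def read_profiles(path) -> list[FractionProfile]:
    """Read a tidy CSV (label, condition, fraction, intensity[, source]).

    Fractions must be numbered 1..N per (label, condition, source) group.
    """
    df = pd.read_csv(path)
    required = {"label", "condition", "fraction", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    if "source" not in df.columns:
        df = df.assign(source="")
    out = []
    for (label, condition, source), g in df.groupby(
        ["label", "condition", "source"], sort=False
    ):
        g = g.sort_values("fraction")
        fr = g["fraction"].to_numpy()
        if not np.array_equal(fr, np.arange(1, len(fr) + 1)):
            raise ValueError(
                f"{label}/{condition}: fractions must be 1..N without gaps"
            )
        out.append(
            FractionProfile(label, condition, g["intensity"].tolist(), source)
        )
    return out
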