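"""Variable-gap CRAC motif scanning in transmembrane windows.

The CRAC (Cholesterol Recognition/interaction Amino acid Consensus) motif is a
short linear pattern read N→C along a protein sequence: a branched apolar
residue (L/V), a gap of 1–5 arbitrary residues, an aromatic residue (Y in the
canonical definition; Y/F/W in the extended one), another 1–5 residue gap, and
a basic residue (K/R).  Because the gaps are variable, a single stretch of
sequence can host several distinct anchor triples that share residues; each
triple is reported as a separate motif.

Residue coordinates are 1-based and inclusive throughout, following the
convention of structural annotations (e.g. "V780" names the valine at residue
780).  Sequences may start at an arbitrary residue number via
:attr:`ProteinRecord.offset`, so sub-sequences keep their native numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}

__all__ = [
    "ProteinRecord",
    "TMTopology",
    "MotifPattern",
    "CracMatch",
    "CRAC_CANONICAL",
    "CRAC_EXTENDED",
    "PATTERN_PRESETS",
    "TM_PRESETS",
    "scan_sequence",
    "tm_windows",
    "scan_tm",
    "report_matches",
    "read_matches",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an explicit first-residue number.

    Parameters
    ----------
    id : str
        Record identifier (e.g. a UniProt accession).
    species : str
        Species label; free text.
    sequence : str
        One-letter amino-acid codes; the 20 standard codes plus ``X``.
    offset : int
        Residue number of the first sequence character (1-based, default 1).
    """

    id: str
    species: str = ""
    sequence: str = ""
    offset: int = 1

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ValueError(f"offset must be >= 1, got {self.offset}")
        bad = [
            (i, c)
            for i, c in enumerate(self.sequence.upper())
            if c not in VALID_RESIDUES
        ]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"invalid residue code {c!r} at residue {self.offset + i} "
                f"of record {self.id!r}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def first_residue(self) -> int:
        return self.offset

    @property
    def last_residue(self) -> int:
        return self.offset + len(self.sequence) - 1

    def residue(self, number: int) -> str:
        """Return the one-letter code at residue ``number`` (1-based numbering)."""
        if not self.first_residue <= number <= self.last_residue:
            raise IndexError(
                f"residue {number} outside record range "
                f"[{self.first_residue}, {self.last_residue}]"
            )
        return self.sequence[number - self.offset]


@dataclass(frozen=True)
class TMTopology:
    """Transmembrane segment coordinates: (segment_id, start, end), 1-based inclusive."""

    segments: tuple[tuple[str, int, int], ...]

    def __init__(self, segments: Iterable[tuple[str, int, int]]):
        segs = tuple((str(sid), int(a), int(b)) for sid, a, b in segments)
        for sid, a, b in segs:
            if a > b:
                raise ValueError(f"segment {sid}: start {a} > end {b}")
        for (s1, a1, b1), (s2, a2, b2) in zip(segs, segs[1:]):
            if a2 <= b1:
                raise ValueError(
                    f"segments must be sorted and non-overlapping: "
                    f"{s1}=({a1},{b1}) then {s2}=({a2},{b2})"
                )
        object.__setattr__(self, "segments", segs)


@dataclass(frozen=True)
class MotifPattern:
    """A three-anchor variable-gap motif: apolar — gap — aromatic — gap — basic.

    ``gap_min``/``gap_max`` bound the number of residues strictly *between*
    consecutive anchors (the "X_1-5" of the pattern notation).
    """

    name: str
    apolar_set: frozenset[str] = frozenset("LV")
    aromatic_set: frozenset[str] = frozenset("YFW")
    basic_set: frozenset[str] = frozenset("KR")
    gap_min: int = 1
    gap_max: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "apolar_set", frozenset(self.apolar_set))
        object.__setattr__(self, "aromatic_set", frozenset(self.aromatic_set))
        object.__setattr__(self, "basic_set", frozenset(self.basic_set))
        if not (1 <= self.gap_min <= self.gap_max):
            raise ValueError(
                f"require 1 <= gap_min <= gap_max, got ({self.gap_min}, {self.gap_max})"
            )
        if not (self.apolar_set and self.aromatic_set and self.basic_set):
            raise ValueError("anchor residue sets must be non-empty")

    def anchor_set(self, role: str) -> frozenset[str]:
        return {"apolar": self.apolar_set,
                "aromatic": self.aromatic_set,
                "basic": self.basic_set}[role]


#: Canonical CRAC: (L/V)-X1-5-(Y)-X1-5-(K/R)
CRAC_CANONICAL = MotifPattern("crac-canonical", aromatic_set=frozenset("Y"))
#: Extended CRAC: (L/V)-X1-5-(Y/F/W)-X1-5-(K/R)
CRAC_EXTENDED = MotifPattern("crac-extended")

PATTERN_PRESETS = {p.name: p for p in (CRAC_CANONICAL, CRAC_EXTENDED)}

#: Mouse TRPA1 TM2/TM4 boundary presets.  The figure annotation and the
#: modeling methods of the source study disagree by one residue on the TM2
#: start; both are kept selectable rather than silently choosing one.
TM_PRESETS = {
    "mTRPA1-fig": TMTopology([("TM2", 766, 793), ("TM4", 828, 858)]),
    "mTRPA1-model": TMTopology([("TM2", 765, 793), ("TM4", 830, 857)]),
}


@dataclass(frozen=True)
class CracMatch:
    """One anchor triple matching a CRAC-family pattern.

    All positions are residue numbers in the record's own numbering.  The
    matched span runs from the apolar to the basic anchor inclusive.
    """

    apolar_pos: int
    aromatic_pos: int
    basic_pos: int
    matched_subsequence: str
    segment_id: str | None = None

    def __post_init__(self) -> None:
        if not self.apolar_pos < self.aromatic_pos < self.basic_pos:
            raise ValueError("anchor positions must be strictly increasing N→C")

    @property
    def start(self) -> int:
        return self.apolar_pos

    @property
    def end(self) -> int:
        return self.basic_pos

    @property
    def anchors(self) -> tuple[int, int, int]:
        return (self.apolar_pos, self.aromatic_pos, self.basic_pos)


def scan_sequence(
    record: ProteinRecord,
    pattern: MotifPattern = CRAC_EXTENDED,
    region: tuple[int, int] | None = None,
) -> list[CracMatch]:
    """Enumerate all anchor triples of ``pattern`` within ``record``.

    Every distinct (apolar, aromatic, basic) position triple satisfying the
    residue-class and gap constraints is returned, including overlapping
    triples that share residues.  If ``region`` (a 1-based inclusive residue
    interval) is given, a triple counts only when all three anchors lie inside
    it.  ``X`` residues match no anchor class but may occupy gap positions.

    Returns matches sorted by (apolar_pos, aromatic_pos, basic_pos).
    """
    seq = record.sequence
    if not seq:
        return []
    lo, hi = record.first_residue, record.last_residue
    if region is not None:
        rlo, rhi = region
        if rlo > rhi:
            raise ValueError(f"empty region ({rlo}, {rhi})")
        if rlo < lo or rhi > hi:
            raise ValueError(
                f"region ({rlo}, {rhi}) outside record range ({lo}, {hi})"
            )
        lo, hi = rlo, rhi

    off = record.offset
    # 0-based index range of the searchable region
    i0, i1 = lo - off, hi - off
    apolar = [i for i in range(i0, i1 + 1) if seq[i] in pattern.apolar_set]
    matches: list[CracMatch] = []
    for i in apolar:
        j_lo = i + pattern.gap_min + 1
        j_hi = min(i + pattern.gap_max + 1, i1)
        for j in range(j_lo, j_hi + 1):
            if seq[j] not in pattern.aromatic_set:
                continue
            k_lo = j + pattern.gap_min + 1
            k_hi = min(j + pattern.gap_max + 1, i1)
            for k in range(k_lo, k_hi + 1):
                if seq[k] not in pattern.basic_set:
                    continue
                matches.append(
                    CracMatch(
                        apolar_pos=i + off,
                        aromatic_pos=j + off,
                        basic_pos=k + off,
                        matched_subsequence=seq[i : k + 1],
                    )
                )
    matches.sort(key=lambda m: m.anchors)
    return matches


def tm_windows(
    topology: TMTopology,
    flank: int = 5,
    sequence_range: tuple[int, int] | None = None,
) -> list[tuple[str, int, int]]:
    """Expand each transmembrane segment by ``flank`` residues on both sides.

    The flank admits motif anchors sitting at the lipid–water interface just
    outside the hydrophobic core.  Windows are clipped to ``sequence_range``
    but never merged: overlapping windows each keep their segment identity.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    windows = []
    for sid, a, b in topology.segments:
        lo, hi = a - flank, b + flank
        if sequence_range is not None:
            lo = max(lo, sequence_range[0])
            hi = min(hi, sequence_range[1])
        if lo <= hi:
            windows.append((sid, lo, hi))
    return windows


def scan_tm(
    record: ProteinRecord,
    topology: TMTopology,
    pattern: MotifPattern = CRAC_EXTENDED,
    flank: int = 5,
) -> dict[str, list[CracMatch]]:
    """Scan each flanked transmembrane window and group matches per segment.

    A match is attributed to a segment when its full anchor span lies inside
    that segment's flanked window; a motif falling into two overlapping
    windows is reported under each.
    """
    for sid, a, b in topology.segments:
        if a < record.first_residue or b > record.last_residue:
            raise ValueError(
                f"segment {sid}=({a},{b}) outside record range "
                f"[{record.first_residue}, {record.last_residue}]"
            )
    out: dict[str, list[CracMatch]] = {}
    rng = (record.first_residue, record.last_residue)
    for sid, lo, hi in tm_windows(topology, flank=flank, sequence_range=rng):
        hits = scan_sequence(record, pattern, region=(lo, hi))
        out[sid] = [
            CracMatch(
                m.apolar_pos, m.aromatic_pos, m.basic_pos,
                m.matched_subsequence, segment_id=sid,
            )
            for m in hits
        ]
    return out


_REPORT_COLUMNS = [
    "segment_id", "apolar_pos", "aromatic_pos", "basic_pos",
    "start", "end", "matched_subsequence",
]


def report_matches(
    matches: Sequence[CracMatch] | dict[str, list[CracMatch]],
    path=None,
) -> pd.DataFrame:
    """Tabulate matches as a tidy frame (optionally written as TSV).

    Rows are ordered by (segment_id, anchors) so output is stable across runs.
    """
    if isinstance(matches, dict):
        flat = [m for ms in matches.values() for m in ms]
    else:
        flat = list(matches)
    rows = [
        {
            "segment_id": m.segment_id if m.segment_id is not None else "",
            "apolar_pos": m.apolar_pos,
            "aromatic_pos": m.aromatic_pos,
            "basic_pos": m.basic_pos,
            "start": m.start,
            "end": m.end,
            "matched_subsequence": m.matched_subsequence,
        }
        for m in flat
    ]
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df = df.sort_values(
        ["segment_id", "apolar_pos", "aromatic_pos", "basic_pos"]
    ).reset_index(drop=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def read_matches(path) -> list[CracMatch]:
    """Read a TSV written by :func:`report_matches` back into match objects."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        CracMatch(
            int(r.apolar_pos), int(r.aromatic_pos), int(r.basic_pos),
            str(r.matched_subsequence),
            segment_id=str(r.segment_id) or None,
        )
        for r in df.itertuples()
    ]
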