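"""Per-column conservation and consensus scoring of ortholog alignments.

Quantifies how well residues — in particular CRAC anchor residues — are
preserved across a panel of orthologs.  Scoring is a transparent
property-class scheme: each column's conservation is the number of
physico-chemical classes shared by *all* of its residues, divided by the
total number of classes, with 1.0 reserved for strict identity.  The familiar
alignment-viewer flags are reproduced exactly: ``*`` (identity) marks columns
where all rows carry the same residue and no gaps, ``+`` (property) marks
columns where every residue shares at least one class and no gaps.

Gaps are conservative throughout: they break both flags, are excluded from
consensus denominators, and count as non-conserving when scoring anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .motifs import CracMatch, MotifPattern

__all__ = [
    "Alignment",
    "ColumnStats",
    "AnchorConservation",
    "DEFAULT_PROPERTY_TABLE",
    "column_stats",
    "consensus_sequence",
    "anchor_conservation",
]

#: Physico-chemical residue classes used for the '+' flag and the
#: conservation score.  A residue may belong to several classes.
DEFAULT_PROPERTY_TABLE: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("AVLIMFWC"),
    "aromatic": frozenset("FWYH"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQYCH"),
    "small": frozenset("AGSCT"),
    "special": frozenset("PG"),
}


def _classes_of(residue: str, table: Mapping[str, frozenset[str]]) -> set[str]:
    return {name for name, members in table.items() if residue in members}


@dataclass(frozen=True)
class Alignment:
    """An in-memory multiple alignment with a designated reference row.

    Rows are equal-length aligned sequences with ``-`` gaps.  The reference
    row carries the residue numbering used by motif matches; its ungapped
    positions map one-to-one onto reference residue numbers starting at
    ``reference_offset``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    reference_id: str
    reference_offset: int = 1

    def __init__(self, ids, rows, reference_id, reference_offset=1):
        ids = tuple(str(i) for i in ids)
        rows = tuple(str(r).upper() for r in rows)
        if len(ids) != len(rows):
            raise ValueError("ids and rows must have equal length")
        if not rows:
            raise ValueError("empty alignment")
        if len({len(r) for r in rows}) != 1:
            raise ValueError("all aligned rows must have the same length")
        if reference_id not in ids:
            raise ValueError(f"reference row {reference_id!r} not in alignment")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "reference_id", str(reference_id))
        object.__setattr__(self, "reference_offset", int(reference_offset))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    def column(self, index: int) -> list[str]:
        """Residues (including gaps) of 0-based column ``index``."""
        return [r[index] for r in self.rows]

    def reference_column_of(self, residue_number: int) -> int:
        """0-based alignment column holding the given reference residue."""
        ref = self.reference_row
        n = self.reference_offset - 1
        for col, c in enumerate(ref):
            if c != "-":
                n += 1
                if n == residue_number:
                    return col
        raise IndexError(
            f"residue {residue_number} beyond reference row "
            f"(last residue {n})"
        )

    @classmethod
    def from_biopython(cls, aln, reference_id: str, reference_offset: int = 1):
        """Build from a ``Bio.Align.MultipleSeqAlignment``."""
        return cls(
            ids=[rec.id for rec in aln],
            rows=[str(rec.seq) for rec in aln],
            reference_id=reference_id,
            reference_offset=reference_offset,
        )


@dataclass(frozen=True)
class ColumnStats:
    column_index: int
    consensus_residue: str
    consensus_fraction: float
    ambiguous: bool
    identity_flag: bool
    property_flag: bool
    conservation_score: float


def column_stats(
    alignment: Alignment,
    property_table: Mapping[str, frozenset[str]] | None = None,
) -> list[ColumnStats]:
    """Score every alignment column.

    ``identity_flag`` — all residues identical, no gaps.  ``property_flag`` —
    all residues share at least one property class, no gaps.
    ``conservation_score`` — fraction of property classes shared by all
    residues in the column, promoted to 1.0 for identity columns.
    """
    table = dict(property_table) if property_table is not None else DEFAULT_PROPERTY_TABLE
    n_classes = len(table)
    if n_classes == 0:
        raise ValueError("property table must define at least one class")
    out = []
    for col in range(alignment.n_columns):
        residues = alignment.column(col)
        has_gap = "-" in residues
        nongap = [r for r in residues if r != "-"]
        cons, frac, amb = _consensus_of_column(nongap)
        if not nongap:
            out.append(ColumnStats(col, "-", 0.0, False, False, False, 0.0))
            continue
        identical = len(set(nongap)) == 1
        shared = _classes_of(nongap[0], table)
        for r in nongap[1:]:
            shared &= _classes_of(r, table)
        identity = identical and not has_gap
        prop = bool(shared) and not has_gap
        if identity:
            score = 1.0
        elif has_gap:
            score = 0.0
        else:
            score = len(shared) / n_classes
        out.append(ColumnStats(col, cons, frac, amb, identity, prop, score))
    return out


def _consensus_of_column(nongap: Sequence[str]) -> tuple[str, float, bool]:
    if not nongap:
        return "-", 0.0, False
    counts: dict[str, int] = {}
    for r in nongap:
        counts[r] = counts.get(r, 0) + 1
    top = max(counts.values())
    winners = sorted(r for r, c in counts.items() if c == top)
    return winners[0], top / len(nongap), len(winners) > 1


def consensus_sequence(alignment: Alignment) -> pd.DataFrame:
    """Per-column modal residue and its frequency among non-gap rows.

    Ties are broken alphabetically and flagged ``ambiguous``; all-gap columns
    yield ``-`` with fraction 0.
    """
    rows = []
    for col in range(alignment.n_columns):
        nongap = [r for r in alignment.column(col) if r != "-"]
        cons, frac, amb = _consensus_of_column(nongap)
        rows.append(
            {"column_index": col, "consensus_residue": cons,
             "consensus_fraction": frac, "ambiguous": amb}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnchorConservation:
    """Per-class conservation of one motif's three anchors across species."""

    match: CracMatch
    apolar_fraction: float
    aromatic_fraction: float
    basic_fraction: float

    @property
    def mean_fraction(self) -> float:
        return (self.apolar_fraction + self.aromatic_fraction + self.basic_fraction) / 3


def anchor_conservation(
    alignment: Alignment,
    matches: Sequence[CracMatch],
    pattern: MotifPattern,
) -> list[AnchorConservation]:
    """Fraction of rows whose residue at each anchor column stays in-class.

    Anchor positions are reference-row residue numbers; each is mapped through
    the alignment and every row's residue at that column is tested against the
    pattern's class set for that anchor role.  Gap characters never conserve.
    The reference row must be ungapped at every anchor.
    """
    out = []
    for m in matches:
        fracs = {}
        for role, pos in (
            ("apolar", m.apolar_pos),
            ("aromatic", m.aromatic_pos),
            ("basic", m.basic_pos),
        ):
            col = alignment.reference_column_of(pos)
            ref_res = alignment.reference_row[col]
            if ref_res == "-":  # unreachable by construction, kept defensive
                raise ValueError(f"reference gapped at anchor {pos}")
            if ref_res not in pattern.anchor_set(role):
                raise ValueError(
                    f"reference residue {ref_res} at {pos} is not in the "
                    f"{role} anchor class"
                )
            members = pattern.anchor_set(role)
            hits = sum(1 for r in alignment.column(col) if r in members)
            fracs[role] = hits / alignment.n_rows
        out.append(
            AnchorConservation(m, fracs["apolar"], fracs["aromatic"], fracs["basic"])
        )
    return out
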