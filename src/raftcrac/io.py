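"""File-format front ends: FASTA / Clustal alignments, topology tables.

Sequence parsing delegates to Biopython; this module only adapts records to
the package's own containers (ProteinRecord, Alignment, TMTopology).
"""

from __future__ import annotations

import json

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import Alignment
from .motifs import ProteinRecord, TMTopology

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_topology",
    "write_topology",
]


def read_fasta(path, offset: int = 1) -> list[ProteinRecord]:
    """Read (possibly multi-record) protein FASTA into ProteinRecords.

    ``offset`` applies to every record; per-record offsets can be encoded in
    the description as ``offset=<n>`` and take precedence.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        off = offset
        for token in rec.description.split():
            if token.startswith("offset="):
                off = int(token.split("=", 1)[1])
        out.append(ProteinRecord(rec.id, "", str(rec.seq), offset=off))
    return out


def write_fasta(path, records: list[ProteinRecord]) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=f"offset={r.offset}" if r.offset != 1 else "")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_alignment(
    path, reference_id: str, fmt: str = "fasta", reference_offset: int = 1
) -> Alignment:
    """Read an aligned FASTA (``fmt="fasta"``) or Clustal (``fmt="clustal"``) file."""
    aln = AlignIO.read(str(path), fmt)
    return Alignment.from_biopython(aln, reference_id, reference_offset)


def write_alignment(path, alignment: Alignment, fmt: str = "fasta") -> None:
    from Bio.Align import MultipleSeqAlignment

    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(alignment.ids, alignment.rows)
    )
    AlignIO.write(msa, str(path), fmt)


def read_topology(path) -> TMTopology:
    """Read transmembrane segments from TSV (segment_id, start, end) or JSON.

    JSON form: ``{"segments": [["TM2", 766, 793], ...]}``.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        return TMTopology([tuple(s) for s in data["segments"]])
    df = pd.read_csv(path, sep="\t")
    required = {"segment_id", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"topology TSV needs columns {sorted(required)}")
    return TMTopology(
        [(r.segment_id, int(r.start), int(r.end)) for r in df.itertuples()]
    )


def write_topology(path, topology: TMTopology) -> None:
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump({"segments": [list(s) for s in topology.segments]}, fh)
    else:
        pd.DataFrame(
            topology.segments, columns=["segment_id", "start", "end"]
        ).to_csv(path, sep="\t", index=False)
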