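"""Format adapters: FASTA and GenBank round-trips, atomic file writes.

GenBank records carry circular topology in the LOCUS line (Biopython's
``annotations["topology"]``) and features in 1-based inclusive convention;
FASTA has no topology slot, so circular sequences carry a ``[circular]``
token in the description.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .seqcore import DnaSequence, Feature

__all__ = [
    "to_seqrecord",
    "from_seqrecord",
    "write_genbank",
    "read_genbank",
    "write_fasta",
    "read_fasta",
    "atomic_write_text",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def to_seqrecord(seq: DnaSequence, name: str, description: str = "") -> SeqRecord:
    rec = SeqRecord(Seq(seq.bases), id=name, name=name[:16], description=description)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = seq.topology
    for f in seq.features:
        if seq.circular and f.end < f.start:
            # wrap-around feature: split at the origin for GenBank
            loc = FeatureLocation(f.start, len(seq), strand=f.strand) + \
                FeatureLocation(0, f.end, strand=f.strand)
        else:
            loc = FeatureLocation(f.start, f.end, strand=f.strand)
        rec.features.append(
            SeqFeature(loc, type="misc_feature", qualifiers={"label": [f.label]})
        )
    return rec


def from_seqrecord(rec: SeqRecord) -> DnaSequence:
    circular = rec.annotations.get("topology", "linear") == "circular"
    feats = []
    for sf in rec.features:
        if sf.type == "source":
            continue
        label = sf.qualifiers.get("label", [sf.type])[0]
        feats.append(
            Feature(
                label,
                int(sf.location.start),
                int(sf.location.end),
                sf.location.strand or 1,
            )
        )
    return DnaSequence(str(rec.seq), circular, tuple(feats))


def write_genbank(path: str | Path, seqs: dict[str, DnaSequence]) -> None:
    records = [to_seqrecord(s, name) for name, s in seqs.items()]
    from io import StringIO

    buf = StringIO()
    SeqIO.write(records, buf, "genbank")
    atomic_write_text(path, buf.getvalue())


def read_genbank(path: str | Path) -> dict[str, DnaSequence]:
    return {rec.id: from_seqrecord(rec) for rec in SeqIO.parse(str(path), "genbank")}


def write_fasta(path: str | Path, seqs: dict[str, DnaSequence]) -> None:
    lines = []
    for name, s in seqs.items():
        topo = " [circular]" if s.circular else ""
        lines.append(f">{name}{topo}")
        for i in range(0, len(s), 70):
            lines.append(s.bases[i : i + 70])
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, DnaSequence]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = "[circular]" in rec.description
        out[rec.id] = DnaSequence(str(rec.seq), circular)
    return out
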