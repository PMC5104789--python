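"""Sequence I/O, translation and identity clustering.

Nucleotide records are plain uppercase DNA strings over ``{A,C,G,T,N}``.
Translation uses the standard genetic code (table 1); any codon containing
an ``N`` is emitted as ``X`` so that downstream motif matching never fires
on ambiguous positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "NucleotideRecord",
    "ProteinRecord",
    "IdentityClusterSet",
    "read_fasta",
    "write_fasta",
    "translate",
    "cluster_identical",
    "clusters_to_rows",
]

_VALID_NT = set("ACGTN")
_ACCESSION_KEY_RE = re.compile(r"\b(?:cultivar|accession)=(\S+)")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"


@dataclass(frozen=True)
class NucleotideRecord:
    """One cloned transcript."""

    id: str
    seq: str
    accession_label: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")


@dataclass(frozen=True)
class ProteinRecord:
    """A translated sequence; ``*`` marks stop codons, ``X`` ambiguity."""

    id: str
    aa_seq: str
    source_id: str

    @property
    def stop_positions(self) -> list[int]:
        """1-based positions of every '*' in the protein."""
        return [i + 1 for i, aa in enumerate(self.aa_seq) if aa == "*"]


@dataclass
class IdentityClusterSet:
    """Partition of record ids into groups of identical sequences."""

    level: Literal["nucleotide", "protein"]
    clusters: list[list[str]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def read_fasta(path) -> list[NucleotideRecord]:
    """Read a nucleotide FASTA into records.

    The first header token is the id; a ``cultivar=`` or ``accession=``
    key=value anywhere in the description populates ``accession_label``.

    Raises
    ------
    ValueError
        On an empty file, duplicate ids, or characters outside
        ``{A,C,G,T,N}`` (case-insensitive).
    """
    records: list[NucleotideRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate id in FASTA: {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in _VALID_NT:
                raise ValueError(
                    f"record {entry.id!r}: invalid character {ch!r} at position {pos}"
                )
        match = _ACCESSION_KEY_RE.search(entry.description)
        label = match.group(1) if match else ""
        records.append(NucleotideRecord(id=entry.id, seq=seq, accession_label=label))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[NucleotideRecord], path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.accession_label:
                header += f" accession={rec.accession_label}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")


def translate(rec: NucleotideRecord, frame: int = 1) -> ProteinRecord:
    """Translate in a fixed frame with the standard genetic code.

    Trailing 1-2 nt are discarded; stop codons are emitted as ``*`` and
    any codon containing ``N`` as ``X``.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    sub = rec.seq[frame - 1 :]
    if len(sub) < 3:
        raise ValueError(f"record {rec.id!r}: fewer than one codon in frame {frame}")
    aas = []
    for i in range(0, len(sub) - len(sub) % 3, 3):
        codon = sub[i : i + 3]
        aas.append("X" if "N" in codon else CODON_TO_AA[codon])
    return ProteinRecord(id=rec.id, aa_seq="".join(aas), source_id=rec.id)


def cluster_identical(
    records: Sequence[NucleotideRecord] | Sequence[ProteinRecord],
    level: Literal["nucleotide", "protein"],
) -> IdentityClusterSet:
    """Group records whose sequences are exactly identical.

    Cluster order is by first-seen member, so the result is deterministic
    for a given input order.
    """
    if not records:
        raise ValueError("cannot cluster an empty record list")
    by_seq: dict[str, list[str]] = {}
    for rec in records:
        seq = rec.aa_seq if level == "protein" else rec.seq  # type: ignore[union-attr]
        by_seq.setdefault(seq, []).append(rec.id)
    return IdentityClusterSet(level=level, clusters=list(by_seq.values()))


def clusters_to_rows(cs: IdentityClusterSet) -> list[dict]:
    """Flatten a cluster set for TSV export."""
    return [
        {
            "cluster_id": f"{cs.level[:3]}_{i + 1}",
            "level": cs.level,
            "size": len(members),
            "member_ids": ",".join(members),
        }
        for i, members in enumerate(cs.clusters)
    ]
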