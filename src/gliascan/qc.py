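"""Transcript quality control.

Full-ORF vs. pseudogene classification, the nucleotide spectrum of
premature-stop-creating substitutions, and a two-half genome-concordance
check for PCR chimeras.

A premature stop codon (PSC) is any in-frame internal stop; a stop at
the final codon only is a natural terminator, not a PSC (the amplicon
ends inside the coding sequence, so most clones have no terminator at
all).  The chimera heuristic splits the protein at the midpoint of
unique domain I and scores each half independently against the genome
motif table: two confident but conflicting half-calls flag a chimera.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from gliascan.annotate import DomainAnnotation
from gliascan.epitopes import build_report
from gliascan.genomes import DEFAULT_MARGIN, GENOMES, MotifTable, score_genomes
from gliascan.seq_core import CODON_TO_AA, NucleotideRecord, ProteinRecord

__all__ = [
    "OrfStatus",
    "PscEvent",
    "ChimeraFlag",
    "classify_orf",
    "nearest_full_orf",
    "psc_spectrum",
    "flag_chimera",
]

STOP_CODONS = frozenset(c for c, aa in CODON_TO_AA.items() if aa == "*")


@dataclass
class OrfStatus:
    status: str  # "full_orf" | "pseudogene"
    psc_positions: list[int] = field(default_factory=list)
    starts_with_met: bool = False

    @property
    def is_pseudogene(self) -> bool:
        return self.status == "pseudogene"


@dataclass(frozen=True)
class PscEvent:
    """A single-nucleotide substitution creating a premature stop."""

    codon_index: int  # 1-based
    ref_codon: str
    obs_codon: str
    substitution: tuple[str, str]  # (ref nt, obs nt), e.g. ("C", "T")

    def __post_init__(self) -> None:
        if self.obs_codon not in STOP_CODONS:
            raise ValueError(f"observed codon {self.obs_codon} is not a stop")
        if self.ref_codon in STOP_CODONS:
            raise ValueError(f"reference codon {self.ref_codon} is a stop")
        if sum(a != b for a, b in zip(self.ref_codon, self.obs_codon)) != 1:
            raise ValueError("codons must differ at exactly one position")

    @property
    def is_c_to_t(self) -> bool:
        return self.substitution == ("C", "T")


@dataclass
class ChimeraFlag:
    is_chimeric: bool
    front_call: str = "unassigned"
    back_call: str = "unassigned"
    breakpoint_region: str = "unique_I"


def classify_orf(prot: ProteinRecord) -> OrfStatus:
    """Pseudogene iff any internal stop; a terminal stop alone is fine."""
    if not prot.aa_seq:
        raise ValueError(f"record {prot.id!r}: empty protein")
    internal = [p for p in prot.stop_positions if p < len(prot.aa_seq)]
    return OrfStatus(
        status="pseudogene" if internal else "full_orf",
        psc_positions=internal,
        starts_with_met=prot.aa_seq.startswith("M"),
    )


def nearest_full_orf(
    pseudo: NucleotideRecord, fulls: Sequence[NucleotideRecord]
) -> NucleotideRecord:
    """Closest full-ORF sequence by Hamming distance (same length only).

    Ties break to the lexicographically first id.
    """
    candidates = [f for f in fulls if len(f.seq) == len(pseudo.seq)]
    if not candidates:
        raise ValueError(
            f"no full-ORF sequence of length {len(pseudo.seq)} for {pseudo.id!r}"
        )
    def key(rec: NucleotideRecord) -> tuple[int, str]:
        dist = sum(a != b for a, b in zip(pseudo.seq, rec.seq))
        return dist, rec.id
    return min(candidates, key=key)


def psc_spectrum(
    pseudo: NucleotideRecord, nearest_full: NucleotideRecord
) -> list[PscEvent]:
    """Directed substitutions (full -> pseudo) behind each premature stop.

    Only in-frame stops whose aligned reference codon is a non-stop codon
    one substitution away are reported; anything else is left out.
    """
    if len(pseudo.seq) != len(nearest_full.seq):
        raise ValueError(
            f"length mismatch: {pseudo.id!r} ({len(pseudo.seq)} nt) vs "
            f"{nearest_full.id!r} ({len(nearest_full.seq)} nt); align first"
        )
    events: list[PscEvent] = []
    n_codons = len(pseudo.seq) // 3
    for ci in range(n_codons - 1):  # internal codons only
        obs = pseudo.seq[ci * 3 : ci * 3 + 3]
        if obs not in STOP_CODONS:
            continue
        ref = nearest_full.seq[ci * 3 : ci * 3 + 3]
        if ref in STOP_CODONS:
            continue
        diffs = [k for k in range(3) if ref[k] != obs[k]]
        if len(diffs) != 1:
            continue
        k = diffs[0]
        events.append(
            PscEvent(
                codon_index=ci + 1,
                ref_codon=ref,
                obs_codon=obs,
                substitution=(ref[k], obs[k]),
            )
        )
    return events


def flag_chimera(
    prot: ProteinRecord,
    motifs: MotifTable,
    ann: DomainAnnotation,
    margin_threshold: int = DEFAULT_MARGIN,
) -> ChimeraFlag:
    """Two-half genome concordance check.

    Each half of the protein (split at the unique-domain-I midpoint) is
    scored against the motif table on its own epitope scan.  Confident
    (margin >= threshold) but conflicting calls flag a chimera.
    """
    lo, hi = ann.boundaries["unique_I"]
    mid = (lo + hi) // 2
    halves = (prot.aa_seq[: mid - 1], prot.aa_seq[mid - 1 :])
    calls = []
    for part, aa in zip(("front", "back"), halves):
        report = build_report(f"{prot.id}:{part}", aa)
        scores = score_genomes(aa, report, motifs)
        ranked = sorted(GENOMES, key=lambda g: (-scores[g], g))
        margin = scores[ranked[0]] - scores[ranked[1]]
        if scores[ranked[0]] > 0 and margin >= margin_threshold:
            calls.append(ranked[0])
        else:
            calls.append("unassigned")
    front, back = calls
    is_chimeric = (
        front != back and front != "unassigned" and back != "unassigned"
    )
    return ChimeraFlag(
        is_chimeric=is_chimeric,
        front_call=front,
        back_call=back,
        breakpoint_region="unique_I",
    )
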