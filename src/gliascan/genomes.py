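"""Motif-based assignment of transcripts to the A, B or D subgenome.

Assignment is additive evidence scoring over a user-editable rule table.
Rule kinds:

``substring``
    A genome-diagnostic amino-acid string present anywhere in the protein.
``canonical_epitope``
    A named epitope group present in canonical form (e.g. canonical
    DQ2.5-glia-a2 is diagnostic for the D genome).
``profile_a``
    Canonical DQ2.5-glia-a1 and/or -a3 present, no canonical
    DQ2.5-glia-a2, and a substitution variant of -a2 present.
``profile_b``
    No canonical DQ2.5 epitope at all, plus a single-residue deletion
    variant of DQ2.5-glia-a1 or -a2.

The best-scoring genome is called only when it leads the runner-up by a
configurable margin (default 2); otherwise the sequence stays unassigned.
B-genome sequences are further subtyped as YG (tyrosine/leucine eleven
residues before the DQ8 locus) or FV (valine at the second position of
the DQ8 window); sequences showing both signatures, or neither, type as
"other".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from gliascan.annotate import DomainAnnotation
from gliascan.epitopes import DQ8, EpitopeReport, _hamming

__all__ = [
    "MotifRule",
    "MotifTable",
    "GenomeCall",
    "load_motif_table",
    "score_genomes",
    "assign_genome",
    "locate_dq8_window",
    "classify_b_type",
    "type_pq2_association",
]

GENOMES = ("A", "B", "D")
RULE_KINDS = ("substring", "canonical_epitope", "profile_a", "profile_b")
DEFAULT_MARGIN = 2


@dataclass(frozen=True)
class MotifRule:
    id: str
    genome: str
    kind: str
    weight: int
    pattern: str = ""
    provenance: str = "thisPaper"

    def __post_init__(self) -> None:
        if self.genome not in GENOMES:
            raise ValueError(f"rule {self.id!r}: unknown genome code {self.genome!r}")
        if self.kind not in RULE_KINDS:
            raise ValueError(f"rule {self.id!r}: unknown kind {self.kind!r}")
        if not isinstance(self.weight, int) or self.weight <= 0:
            raise ValueError(f"rule {self.id!r}: weight must be a positive integer")
        if self.kind in ("substring", "canonical_epitope") and not self.pattern:
            raise ValueError(f"rule {self.id!r}: pattern required for kind {self.kind}")


@dataclass
class MotifTable:
    rules: list[MotifRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rule in self.rules:
            if rule.id in seen:
                raise ValueError(f"duplicate rule id {rule.id!r}")
            seen.add(rule.id)

    def for_genome(self, genome: str) -> list[MotifRule]:
        return [r for r in self.rules if r.genome == genome]


@dataclass
class GenomeCall:
    seq_id: str
    genome: str  # A | B | D | unassigned
    scores: dict[str, int]
    margin: int
    b_type: str = "n/a"  # YG | FV | other | n/a
    phylo_concordant: Optional[bool] = None


def load_motif_table(path=None, merge_defaults: bool = True) -> MotifTable:
    """Load the motif rule table; user rules override same-id defaults."""
    default_text = resources.files("gliascan.data").joinpath("motifs.yaml").read_text()
    rules: dict[str, MotifRule] = {}
    sources = [default_text] if path is None else (
        [default_text] if merge_defaults else []
    )
    if path is not None:
        with open(path) as fh:
            sources.append(fh.read())
    for text in sources:
        raw = yaml.safe_load(text)
        batch_seen: set[str] = set()
        for entry in raw["rules"]:
            rule = MotifRule(
                id=entry["id"],
                genome=entry["genome"],
                kind=entry["kind"],
                weight=entry["weight"],
                pattern=entry.get("pattern", ""),
                provenance=entry.get("provenance", "thisPaper"),
            )
            if rule.id in batch_seen:
                raise ValueError(f"duplicate rule id {rule.id!r}")
            batch_seen.add(rule.id)
            rules[rule.id] = rule  # later source overrides
    return MotifTable(rules=list(rules.values()))


def _rule_matches(rule: MotifRule, aa_seq: str, report: EpitopeReport) -> bool:
    if rule.kind == "substring":
        return rule.pattern in aa_seq
    if rule.kind == "canonical_epitope":
        return report.canonical_counts.get(rule.pattern, 0) > 0
    counts = report.canonical_counts
    if rule.kind == "profile_a":
        has_a1_or_a3 = counts["DQ2.5-glia-a1"] > 0 or counts["DQ2.5-glia-a3"] > 0
        a2_variant = any(
            h.epitope == "DQ2.5-glia-a2" and h.kind == "substitution"
            for h in report.variant_hits
        )
        return has_a1_or_a3 and counts["DQ2.5-glia-a2"] == 0 and a2_variant
    if rule.kind == "profile_b":
        no_dq25 = (
            counts["DQ2.5-glia-a1"] == 0
            and counts["DQ2.5-glia-a2"] == 0
            and counts["DQ2.5-glia-a3"] == 0
        )
        deletion = any(
            h.epitope in ("DQ2.5-glia-a1", "DQ2.5-glia-a2") and h.kind == "deletion"
            for h in report.variant_hits
        )
        return no_dq25 and deletion
    raise AssertionError(rule.kind)


def score_genomes(
    aa_seq: str, report: EpitopeReport, motifs: MotifTable
) -> dict[str, int]:
    """Additive, order-independent evidence score per genome."""
    scores = {g: 0 for g in GENOMES}
    for rule in motifs.rules:
        if _rule_matches(rule, aa_seq, report):
            scores[rule.genome] += rule.weight
    return scores


def assign_genome(
    aa_seq: str,
    report: EpitopeReport,
    motifs: MotifTable,
    ann: DomainAnnotation | None = None,
    margin_threshold: int = DEFAULT_MARGIN,
) -> GenomeCall:
    """Call the genome of origin; low-margin evidence stays unassigned."""
    scores = score_genomes(aa_seq, report, motifs)
    ranked = sorted(GENOMES, key=lambda g: (-scores[g], g))
    best, second = ranked[0], ranked[1]
    margin = scores[best] - scores[second]
    if scores[best] > 0 and margin >= margin_threshold:
        genome = best
    else:
        genome = "unassigned"
    call = GenomeCall(
        seq_id=report.seq_id, genome=genome, scores=scores, margin=margin
    )
    if genome == "B":
        call.b_type = classify_b_type(aa_seq, ann)
    return call


def locate_dq8_window(
    aa_seq: str, ann: DomainAnnotation | None = None, max_sub: int = 2
) -> Optional[tuple[int, str, int]]:
    """Best-matching DQ8 9-mer window: (1-based start, window, edits).

    Restricted to unique domain II when an annotation is available;
    ties broken by the leftmost window.
    """
    if ann is not None:
        lo, hi = ann.boundaries["unique_II"]
        region = aa_seq[lo - 1 : hi - 1]
        offset = lo - 1
    else:
        region, offset = aa_seq, 0
    best: Optional[tuple[int, str, int]] = None
    for i in range(len(region) - 8):
        window = region[i : i + 9]
        d = _hamming(window, DQ8)
        if d <= max_sub and (best is None or d < best[2]):
            best = (offset + i + 1, window, d)
            if d == 0:
                break
    return best


def classify_b_type(aa_seq: str, ann: DomainAnnotation | None = None) -> str:
    """YG/FV subtype of a B-genome sequence from its DQ8 locus context."""
    located = locate_dq8_window(aa_seq, ann)
    if located is None:
        return "other"
    start, window, _ = located
    yg = start - 11 >= 1 and aa_seq[start - 12] in ("Y", "L")
    fv = window[1] == "V"
    if yg and not fv:
        return "YG"
    if fv and not yg:
        return "FV"
    return "other"


def type_pq2_association(
    calls: Sequence[GenomeCall],
    anns: Mapping[str, DomainAnnotation],
    short_max: int = 7,
    long_min: int = 13,
) -> tuple[dict[tuple[str, str], int], float, list[str]]:
    """Association between B-genome YG/FV subtype and PQII length.

    Returns the {YG,FV} x {short,long,intermediate} contingency counts,
    the concordance fraction (YG with short PQII or FV with long PQII,
    intermediates counted discordant) and the discordant sequence ids.
    """
    b_calls = [c for c in calls if c.genome == "B"]
    if not b_calls:
        raise ValueError("no B-genome sequences to test")
    table: dict[tuple[str, str], int] = {}
    concordant = 0
    total = 0
    discordant_ids: list[str] = []
    for call in b_calls:
        if call.b_type not in ("YG", "FV") or call.seq_id not in anns:
            continue
        q = anns[call.seq_id].q_count_pq2
        if q <= short_max:
            length_class = "short"
        elif q >= long_min:
            length_class = "long"
        else:
            length_class = "intermediate"
        table[(call.b_type, length_class)] = table.get((call.b_type, length_class), 0) + 1
        total += 1
        if (call.b_type, length_class) in (("YG", "short"), ("FV", "long")):
            concordant += 1
        else:
            discordant_ids.append(call.seq_id)
    if total == 0:
        raise ValueError("no typed B-genome sequences with PQII annotation")
    return table, concordant / total, discordant_ids
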