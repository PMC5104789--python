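"""Celiac-disease T-cell epitope scanning.

Four 9-mer epitopes are screened in canonical and variant form:

* ``DQ2.5-glia-a1`` with two canonical sub-forms ``a1a`` (PFPQPQLPY) and
  ``a1b`` (PYPQPQLPY),
* ``DQ2.5-glia-a2`` (PQPQLPYPQ), which can occur in tandem; three
  overlapping copies constitute the highly immunogenic 33-mer fragment,
* ``DQ2.5-glia-a3`` (FRPQQPYPQ),
* ``DQ8-glia-a1`` (QGSFQPSQQ).

Canonical scanning counts every overlapping occurrence.  Variant scanning
reports windows within a small edit distance of a canonical form
(substitutions up to ``max_sub``, optionally one single-residue deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ALPHA1A",
    "ALPHA1B",
    "ALPHA2",
    "ALPHA3",
    "DQ8",
    "EPITOPE_GROUPS",
    "EpitopeDefinition",
    "EpitopeHit",
    "EpitopeReport",
    "AccessionSummary",
    "load_epitope_definitions",
    "find_all",
    "scan_canonical",
    "count_duplications",
    "scan_variants",
    "build_report",
    "summarize_accession",
]

ALPHA1A = "PFPQPQLPY"
ALPHA1B = "PYPQPQLPY"
ALPHA2 = "PQPQLPYPQ"
ALPHA3 = "FRPQQPYPQ"
DQ8 = "QGSFQPSQQ"

#: epitope group -> canonical 9-mer forms
EPITOPE_GROUPS: dict[str, tuple[str, ...]] = {
    "DQ2.5-glia-a1": (ALPHA1A, ALPHA1B),
    "DQ2.5-glia-a2": (ALPHA2,),
    "DQ2.5-glia-a3": (ALPHA3,),
    "DQ8-glia-a1": (DQ8,),
}

#: domain a variant window must fall in, when an annotation is available
DOMAIN_ANCHORS: dict[str, str] = {
    "DQ2.5-glia-a1": "repetitive",
    "DQ2.5-glia-a2": "repetitive",
    "DQ2.5-glia-a3": "repetitive",
    "DQ8-glia-a1": "unique_II",
}


@dataclass(frozen=True)
class EpitopeDefinition:
    name: str
    canonical: tuple[str, ...]
    anchor: str = ""

    def __post_init__(self) -> None:
        for form in self.canonical:
            if len(form) != 9:
                raise ValueError(f"{self.name}: canonical form {form!r} is not a 9-mer")


@dataclass(frozen=True)
class EpitopeHit:
    """One epitope occurrence: canonical (edits=0) or variant."""

    epitope: str
    observed: str
    start: int  # 1-based
    edits: int
    kind: str  # "canonical" | "substitution" | "deletion"
    ambiguous: bool = False

    @property
    def is_canonical(self) -> bool:
        return self.edits == 0


@dataclass
class EpitopeReport:
    seq_id: str
    canonical_counts: dict[str, int]
    canonical_hits: list[EpitopeHit]
    alpha1a_count: int
    alpha1b_count: int
    alpha2_duplications: int
    has_33mer: bool
    variant_hits: list[EpitopeHit] = field(default_factory=list)
    variant_inventory: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total_canonical(self) -> int:
        return sum(self.canonical_counts.values())


@dataclass
class AccessionSummary:
    accession_label: str
    n_sequences: int
    mean_canonical_per_seq: float
    decomposition: dict[str, float]
    genome_proportions: dict[str, float] = field(default_factory=dict)


def load_epitope_definitions(path=None) -> list[EpitopeDefinition]:
    """Load epitope definitions from YAML; defaults ship with the package."""
    if path is None:
        text = resources.files("gliascan.data").joinpath("epitopes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    defs = []
    for entry in raw["epitopes"]:
        forms = entry["canonical"]
        if isinstance(forms, str):
            forms = [forms]
        defs.append(
            EpitopeDefinition(
                name=entry["name"],
                canonical=tuple(forms),
                anchor=entry.get("anchor", ""),
            )
        )
    return defs


def find_all(haystack: str, needle: str) -> list[int]:
    """1-based start positions of every (overlapping) occurrence."""
    hits = []
    start = haystack.find(needle)
    while start != -1:
        hits.append(start + 1)
        start = haystack.find(needle, start + 1)
    return hits


def scan_canonical(aa_seq: str) -> list[EpitopeHit]:
    """All overlapping canonical occurrences of the four epitopes."""
    hits: list[EpitopeHit] = []
    for group, forms in EPITOPE_GROUPS.items():
        for form in forms:
            for pos in find_all(aa_seq, form):
                hits.append(
                    EpitopeHit(
                        epitope=group, observed=form, start=pos, edits=0,
                        kind="canonical",
                    )
                )
    hits.sort(key=lambda h: (h.start, h.epitope, h.observed))
    return hits


def count_duplications(alpha2_canonical_count: int) -> tuple[int, bool]:
    """Duplications = occurrences − 1 (floor 0); 33-mer iff ≥ 3 copies."""
    return max(0, alpha2_canonical_count - 1), alpha2_canonical_count >= 3


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _is_single_deletion(window8: str, canonical9: str) -> bool:
    return any(
        canonical9[:i] + canonical9[i + 1 :] == window8 for i in range(9)
    )


def _canonical_forms() -> set[str]:
    return {form for forms in EPITOPE_GROUPS.values() for form in forms}


def scan_variants(
    aa_seq: str,
    defs: Sequence[EpitopeDefinition] | None = None,
    max_sub: int = 2,
    allow_single_deletion: bool = True,
    domain_of: Mapping[str, tuple[int, int]] | None = None,
) -> list[EpitopeHit]:
    """Near-canonical epitope windows.

    Every 9-mer window within ``max_sub`` substitutions of a canonical form
    (and, if enabled, every 8-mer window equal to a canonical form minus one
    residue) is reported.  Exactly-canonical windows are excluded.  A window
    is assigned to the epitope group with the smallest edit count; ties are
    reported under every tied group with ``ambiguous=True``.

    ``domain_of`` maps domain name to a 1-based half-open interval; when
    given, DQ2.5 variants are kept only inside the repetitive domain and
    DQ8 variants only inside unique domain II.
    """
    groups: dict[str, tuple[str, ...]]
    if defs is None:
        groups = EPITOPE_GROUPS
    else:
        groups = {d.name: d.canonical for d in defs}
    canonical_set = {form for forms in groups.values() for form in forms}

    hits: list[EpitopeHit] = []
    lengths = [9, 8] if allow_single_deletion else [9]
    for wlen in lengths:
        for i in range(len(aa_seq) - wlen + 1):
            window = aa_seq[i : i + wlen]
            if wlen == 9 and window in canonical_set:
                continue
            best: dict[str, tuple[int, str]] = {}
            for group, forms in groups.items():
                for form in forms:
                    if wlen == 9:
                        d = _hamming(window, form)
                        if 1 <= d <= max_sub:
                            if group not in best or d < best[group][0]:
                                best[group] = (d, "substitution")
                    else:
                        if _is_single_deletion(window, form):
                            if group not in best or 1 < best[group][0]:
                                best[group] = (1, "deletion")
            if not best:
                continue
            min_d = min(d for d, _ in best.values())
            winners = [g for g, (d, _) in best.items() if d == min_d]
            for group in winners:
                hits.append(
                    EpitopeHit(
                        epitope=group,
                        observed=window,
                        start=i + 1,
                        edits=min_d,
                        kind=best[group][1],
                        ambiguous=len(winners) > 1,
                    )
                )

    if domain_of is not None:
        kept = []
        for hit in hits:
            anchor = DOMAIN_ANCHORS.get(hit.epitope)
            interval = domain_of.get(anchor) if anchor else None
            if interval is None:
                kept.append(hit)
                continue
            lo, hi = interval
            if lo <= hit.start < hi:
                kept.append(hit)
        hits = kept

    hits.sort(key=lambda h: (h.start, h.epitope))
    return hits


def build_report(
    seq_id: str,
    aa_seq: str,
    defs: Sequence[EpitopeDefinition] | None = None,
    max_sub: int = 2,
    allow_single_deletion: bool = True,
    domain_of: Mapping[str, tuple[int, int]] | None = None,
) -> EpitopeReport:
    """Full canonical + variant scan for one protein."""
    canonical_hits = scan_canonical(aa_seq)
    counts = {group: 0 for group in EPITOPE_GROUPS}
    a1a = a1b = 0
    for hit in canonical_hits:
        counts[hit.epitope] += 1
        if hit.observed == ALPHA1A:
            a1a += 1
        elif hit.observed == ALPHA1B:
            a1b += 1
    dups, has_33mer = count_duplications(counts["DQ2.5-glia-a2"])
    variant_hits = scan_variants(
        aa_seq,
        defs=defs,
        max_sub=max_sub,
        allow_single_deletion=allow_single_deletion,
        domain_of=domain_of,
    )
    inventory: dict[tuple[str, str], int] = {}
    for hit in variant_hits:
        key = (hit.epitope, hit.observed)
        inventory[key] = inventory.get(key, 0) + 1
    return EpitopeReport(
        seq_id=seq_id,
        canonical_counts=counts,
        canonical_hits=canonical_hits,
        alpha1a_count=a1a,
        alpha1b_count=a1b,
        alpha2_duplications=dups,
        has_33mer=has_33mer,
        variant_hits=variant_hits,
        variant_inventory=inventory,
    )


def summarize_accession(
    accession_label: str,
    reports: Sequence[EpitopeReport],
    genome_calls: Mapping[str, str] | None = None,
) -> AccessionSummary:
    """Per-accession mean canonical epitope load and genome proportions.

    The mean counts every canonical occurrence (duplications included);
    the per-epitope decomposition sums to the mean.
    """
    if not reports:
        raise ValueError(f"accession {accession_label!r}: no reports")
    n = len(reports)
    decomposition = {
        group: sum(r.canonical_counts[group] for r in reports) / n
        for group in EPITOPE_GROUPS
    }
    mean = sum(decomposition.values())
    proportions: dict[str, float] = {}
    if genome_calls is not None:
        assigned = [
            genome_calls[r.seq_id]
            for r in reports
            if genome_calls.get(r.seq_id) in ("A", "B", "D")
        ]
        if assigned:
            for g in ("A", "B", "D"):
                proportions[g] = assigned.count(g) / len(assigned)
    return AccessionSummary(
        accession_label=accession_label,
        n_sequences=n,
        mean_canonical_per_seq=mean,
        decomposition=decomposition,
        genome_proportions=proportions,
    )
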