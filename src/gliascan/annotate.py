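"""Domain segmentation of the canonical alpha-gliadin architecture.

A mature alpha-gliadin reads, N- to C-terminal: signal peptide,
repetitive domain, first polyglutamine region (PQI), unique domain I,
second polyglutamine region (PQII), unique domain II.  Segmentation is
driven by the two dominant glutamine runs; everything else follows from
their positions.  Cysteines are counted on the mature protein (signal
peptide excluded): the typical complement is six, four in unique domain I
and two in unique domain II.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "DOMAIN_ORDER",
    "SegmentationConfig",
    "DomainAnnotation",
    "PolyQGroupStats",
    "AtypicalArchitectureError",
    "find_q_runs",
    "segment_domains",
    "count_cysteines",
    "polyq_group_stats",
]

DOMAIN_ORDER = (
    "signal_peptide",
    "repetitive",
    "polyQ_I",
    "unique_I",
    "polyQ_II",
    "unique_II",
)


class AtypicalArchitectureError(ValueError):
    """Raised when the two polyglutamine regions cannot be located."""


@dataclass(frozen=True)
class SegmentationConfig:
    signal_len: int = 20
    min_run: int = 6         # minimum residues in a qualifying Q-run
    q_frac: float = 0.8      # minimum fraction of Q inside the run
    indel_sigma: float = 15.0  # flag domains deviating this much from template
    template_lengths: Mapping[str, float] | None = None


@dataclass
class DomainAnnotation:
    """Half-open 1-based intervals covering the protein end-to-end."""

    boundaries: dict[str, tuple[int, int]]
    cys_positions: list[int]
    q_count_pq1: int
    q_count_pq2: int
    indel_note: str = ""

    def domain_of(self, pos: int) -> str:
        for name, (lo, hi) in self.boundaries.items():
            if lo <= pos < hi:
                return name
        raise ValueError(f"position {pos} outside annotated intervals")


@dataclass
class PolyQGroupStats:
    genome: str
    region: str
    n: int
    mean_q: float
    sd_q: float
    degenerate: bool = False  # n == 1, sd reported as 0


def find_q_runs(aa_seq: str, min_run: int = 6, q_frac: float = 0.8) -> list[tuple[int, int]]:
    """Maximal glutamine-rich windows as 1-based half-open intervals.

    A run starts and ends on a Q, spans at least ``min_run`` residues and
    keeps a Q fraction of at least ``q_frac``; each run is extended
    greedily to the farthest end position that maintains the fraction.
    """
    n = len(aa_seq)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if aa_seq[i] != "Q":
            i += 1
            continue
        best_end = -1
        q_count = 0
        for j in range(i, n):
            if aa_seq[j] == "Q":
                q_count += 1
                length = j - i + 1
                if length >= min_run and q_count / length >= q_frac:
                    best_end = j
        if best_end >= 0:
            runs.append((i + 1, best_end + 2))
            i = best_end + 1
        else:
            i += 1
    return runs


def segment_domains(aa_seq: str, cfg: SegmentationConfig | None = None) -> DomainAnnotation:
    """Segment a full-ORF protein into the six canonical domains.

    The two longest qualifying Q-runs after the signal peptide become PQI
    and PQII (positional order); the repetitive domain runs from the end
    of the signal peptide to PQI, unique domain I sits between the runs
    and unique domain II extends from PQII to the terminus.
    """
    cfg = cfg or SegmentationConfig()
    if len(aa_seq) < 120:
        raise ValueError(f"protein too short to segment ({len(aa_seq)} aa)")
    sig_end = cfg.signal_len + 1  # half-open
    runs = [r for r in find_q_runs(aa_seq, cfg.min_run, cfg.q_frac) if r[0] >= sig_end]
    if len(runs) < 2:
        raise AtypicalArchitectureError(
            f"atypical architecture: found {len(runs)} qualifying Q-run(s), need 2"
        )
    # keep the two longest; tie-break by leftmost start
    ranked = sorted(runs, key=lambda r: (-(r[1] - r[0]), r[0]))[:2]
    pq1, pq2 = sorted(ranked)
    if pq2[1] > len(aa_seq):
        raise AtypicalArchitectureError("polyQ run extends to the terminus")
    boundaries = {
        "signal_peptide": (1, sig_end),
        "repetitive": (sig_end, pq1[0]),
        "polyQ_I": pq1,
        "unique_I": (pq1[1], pq2[0]),
        "polyQ_II": pq2,
        "unique_II": (pq2[1], len(aa_seq) + 1),
    }
    if boundaries["repetitive"][1] <= boundaries["repetitive"][0]:
        raise AtypicalArchitectureError("no repetitive domain before first polyQ run")
    if boundaries["unique_I"][1] <= boundaries["unique_I"][0]:
        raise AtypicalArchitectureError("polyQ runs are adjacent; no unique domain I")

    q1 = sum(1 for i in range(pq1[0] - 1, pq1[1] - 1) if aa_seq[i] == "Q")
    q2 = sum(1 for i in range(pq2[0] - 1, pq2[1] - 1) if aa_seq[i] == "Q")
    cys = [i + 1 for i, aa in enumerate(aa_seq) if aa == "C"]

    note = ""
    if cfg.template_lengths:
        devs = []
        for name, (lo, hi) in boundaries.items():
            expected = cfg.template_lengths.get(name)
            if expected is not None and abs((hi - lo) - expected) > cfg.indel_sigma:
                devs.append(f"{name}:{hi - lo}aa(expected~{expected:.0f})")
        if devs:
            note = "possible indel in " + ",".join(devs)

    return DomainAnnotation(
        boundaries=boundaries,
        cys_positions=cys,
        q_count_pq1=q1,
        q_count_pq2=q2,
        indel_note=note,
    )


def count_cysteines(
    aa_seq: str, ann: DomainAnnotation | None = None, signal_len: int = 20
) -> tuple[int, dict[str, int]]:
    """Cysteine census on the mature protein (signal peptide excluded)."""
    if ann is not None:
        sig_hi = ann.boundaries["signal_peptide"][1]
        total = sum(1 for p in ann.cys_positions if p >= sig_hi)
        per_domain: dict[str, int] = {}
        for p in ann.cys_positions:
            dom = ann.domain_of(p)
            per_domain[dom] = per_domain.get(dom, 0) + 1
        return total, per_domain
    mature = aa_seq[signal_len:]
    return mature.count("C"), {}


def polyq_group_stats(
    labeled: Sequence[tuple[str, DomainAnnotation]],
) -> list[PolyQGroupStats]:
    """Mean/SD of glutamine counts per genome x polyQ region.

    ``labeled`` pairs a genome label in {A,B,D} with an annotation.
    Sample SD uses the n−1 denominator; single-member groups report 0
    with a degenerate flag.  Empty groups are omitted.
    """
    out: list[PolyQGroupStats] = []
    for genome in ("A", "B", "D"):
        for region, attr in (("PQI", "q_count_pq1"), ("PQII", "q_count_pq2")):
            values = [getattr(a, attr) for g, a in labeled if g == genome]
            if not values:
                continue
            n = len(values)
            mean = sum(values) / n
            if n == 1:
                out.append(PolyQGroupStats(genome, region, 1, mean, 0.0, degenerate=True))
            else:
                var = sum((v - mean) ** 2 for v in values) / (n - 1)
                out.append(PolyQGroupStats(genome, region, n, mean, math.sqrt(var)))
    return out
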