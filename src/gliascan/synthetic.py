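"""Synthetic alpha-gliadin transcript cohorts with known truth labels.

Proteins are assembled piecewise — signal peptide, repetitive domain
carrying per-genome epitope cassettes, PQI, unique domain I (four
cysteines), PQII, unique domain II (two cysteines plus the DQ8 locus) —
then back-translated with random synonymous codons.  Premature stop
codons are injected at the nucleotide level with a configurable C-to-T
bias, and chimeras are spliced from two parent templates at the
unique-domain-I midpoint.  Every emitted sequence carries a truth record
consistent with the sequence by construction.

Genome cassettes (defaults):

* D — canonical DQ2.5-glia-a1/-a3, one to three tandem canonical copies
  of DQ2.5-glia-a2, and the QGFFQPSQQ DQ8 variant in about half of the
  sequences;
* A — canonical a1/a3 with a substitution-mutated a2 (PQPQLPYSQ, or
  PQPQLPYSH in a minority), DQ8 mostly mutated;
* B — no canonical DQ2.5 epitope: single-deletion variants of a1 and a2,
  a threonine directly after the a2 locus, a substituted a3, and a
  YG- or FV-type DQ8 context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from gliascan.seq_core import CODON_TO_AA, NucleotideRecord

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "TruthTable",
    "back_translate",
    "generate_cohort",
]

# ---------------------------------------------------------------------------
# building blocks (all verified epitope/motif-clean by the test suite)

SIGNAL = "MKTFLILALLAIVATTATTA"  # 20 aa, starts at the forward-primer ATG

REP_MID = "QPQPFPPQ"
# trailing 8 residues Q-free so the polyQ_I run cannot extend backwards
REP_END = "QPQQPFPQSAVLPMSF"

# filler segments carry fixed genome-diagnostic substitutions so that the
# three homeolog groups separate phylogenetically, as real ones do
REP_PREFIX = {
    "A": "VRVPVPQLQPQNPSQQQPQEQVPL",
    "B": "VRVPIPQLEPQNPSQQHPQEQVPL",
    "D": "VRVPVPQLQPHNPSQEQPQEQIPL",
}
UNIQUE_I = {  # 4 cysteines, Q-free
    "A": "LRTLPAMCNVYIPPHCSTTIAPFGCFGTNCA",
    "B": "LRSLPAMCNVYVPPHCSSTIAPFGCFGTNCA",
    "D": "LRTLAAMCNVFIPPHCSTTISPFGCFGTNCA",
}
UII_PRE = "SRHESIRAMCNIYVPRDCSTINV"  # 2 cysteines, Q-free
UII_SPACER = "PEHSMVAHAI"  # 10 residues between -11 context and DQ8 window
UII_SPACER_FV = "PEHSMVAHAS"  # FV carries S one position before the window
UII_POST = {
    "A": "VPHSVMHSIIMASGEGV",
    "B": "VPYSVMHSLIMASGEGV",
    "D": "VPHSVMYSIIMTSGEGV",
}

DQ8_CANONICAL = "QGSFQPSQQ"
DQ8_YG = "QGSFQSSQQ"
DQ8_FV = "QVSFQPSQL"
DQ8_D_FF = "QGFFQPSQQ"
DQ8_A_VAR = "QGSFQPSQL"

ALPHA3_CANONICAL = "FRPQQPYPQ"
ALPHA3_D_SER = "FRPQQSYPQ"
ALPHA3_B_VAR = "FRPQQPFPQ"

NOISE_ALPHABET = "ASTVILNEGH"  # no C, no Q, no stop

DEFAULT_PQ_MODELS: dict[tuple[str, str], tuple[int, int]] = {
    ("A", "PQI"): (18, 25),
    ("B", "PQI"): (8, 16),
    ("D", "PQI"): (8, 16),
    ("A", "PQII"): (6, 10),
    ("D", "PQII"): (8, 12),
    # B PQII is bimodal, conditioned on the YG/FV subtype:
    ("B_YG", "PQII"): (6, 7),
    ("B_FV", "PQII"): (13, 25),
    ("B_other", "PQII"): (6, 25),
}

# inverse codon table for back-translation
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class GeneratorConfig:
    """Cohort generator parameters; frequencies default to the reference
    spelt dataset statistics."""

    seed: int
    n_accessions: int = 4
    n_seqs_per_accession: int = 25
    genome_mix: tuple[float, float, float] = (0.42, 0.34, 0.24)  # A, B, D
    d_dup_probs: tuple[float, float] = (0.275, 0.138)  # P(2 copies), P(3 copies)
    b_type_mix: tuple[float, float, float] = (0.737, 0.25, 0.013)  # YG, FV, other
    psc_rate: float = 0.039
    psc_ct_bias: float = 18 / 19
    chimera_rate: float = 0.0
    noise_rate: float = 0.0
    pq_length_models: Optional[dict] = None
    d_a3_ser_rate: float = 0.119
    d_dq8_ff_rate: float = 0.523
    a_sh_rate: float = 0.146
    a_dq8_canonical_rate: float = 6 / 185
    yg_dq8_mut_rate: float = 0.894
    extra_cys_rate: float = 17 / 446
    cys_loss_rate: float = 1 / 446

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        probs = [
            *self.genome_mix, *self.d_dup_probs, *self.b_type_mix,
            self.psc_rate, self.psc_ct_bias, self.chimera_rate,
            self.noise_rate, self.d_a3_ser_rate, self.d_dq8_ff_rate,
            self.a_sh_rate, self.a_dq8_canonical_rate, self.yg_dq8_mut_rate,
            self.extra_cys_rate, self.cys_loss_rate,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for mix, name in ((self.genome_mix, "genome_mix"),
                          (self.b_type_mix, "b_type_mix"),
                          (self.d_dup_probs, "d_dup_probs")):
            if sum(mix) > 1 + 1e-9:
                raise ValueError(f"{name} sums above 1")

    def pq_range(self, genome: str, region: str, b_type: str = "") -> tuple[int, int]:
        models = dict(DEFAULT_PQ_MODELS)
        if self.pq_length_models:
            models.update(self.pq_length_models)
        if genome == "B" and region == "PQII":
            return models[(f"B_{b_type}", "PQII")]
        return models[(genome, region)]


@dataclass
class TruthRecord:
    seq_id: str
    accession: str
    genome: str
    b_type: str  # YG | FV | other | n/a
    n_alpha2_copies: int
    canonical_counts: dict[str, int]
    pq1_len: int
    pq2_len: int
    n_cys: int
    boundaries: dict[str, tuple[int, int]]
    is_pseudogene: bool = False
    psc_codon_positions: list[int] = field(default_factory=list)
    psc_substitutions: list[str] = field(default_factory=list)  # e.g. "C>T"
    is_chimera: bool = False
    back_genome: str = ""


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def by_id(self) -> dict[str, TruthRecord]:
        return {r.seq_id: r for r in self.records}

    def to_rows(self) -> list[dict]:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "seq_id": r.seq_id,
                    "accession": r.accession,
                    "genome": r.genome,
                    "b_type": r.b_type,
                    "n_alpha2_copies": r.n_alpha2_copies,
                    "pq1_len": r.pq1_len,
                    "pq2_len": r.pq2_len,
                    "n_cys": r.n_cys,
                    "is_pseudogene": r.is_pseudogene,
                    "psc_codon_positions": ",".join(map(str, r.psc_codon_positions)),
                    "psc_substitutions": ",".join(r.psc_substitutions),
                    "is_chimera": r.is_chimera,
                    "back_genome": r.back_genome,
                    **{f"n_{k}": v for k, v in r.canonical_counts.items()},
                }
            )
        return rows


# ---------------------------------------------------------------------------
# protein plans


@dataclass
class _Plan:
    """An assembled protein plus construction-time truth."""

    genome: str
    b_type: str
    segments: dict[str, str]  # insertion-ordered: the six domains
    canonical_counts: dict[str, int]
    n_alpha2: int
    n_cys: int

    @property
    def protein(self) -> str:
        return "".join(self.segments.values())

    def boundaries(self) -> dict[str, tuple[int, int]]:
        out: dict[str, tuple[int, int]] = {}
        pos = 1
        for name, seg in self.segments.items():
            out[name] = (pos, pos + len(seg))
            pos += len(seg)
        return out

    def noise_eligible(self) -> list[int]:
        """0-based protein indices where substitution noise is allowed:
        non-cysteine sites of the two unique-domain fillers."""
        bounds = self.boundaries()
        eligible = []
        lo, hi = bounds["unique_I"]
        for i in range(lo - 1, hi - 1):
            if self.protein[i] != "C":
                eligible.append(i)
        lo, hi = bounds["unique_II"]
        post_start = hi - 1 - len(UII_POST["A"])
        for i in range(post_start, hi - 1):
            if self.protein[i] != "C":
                eligible.append(i)
        return eligible


def _choice(rng: np.random.Generator, probs: Sequence[float], labels: Sequence) -> object:
    """Draw a label; any residual probability mass goes to the last label."""
    total = sum(probs)
    p = list(probs) + [max(0.0, 1.0 - total)]
    idx = rng.choice(len(p), p=np.array(p) / sum(p))
    return labels[idx] if idx < len(labels) else labels[-1]


def _build_plan(genome: str, cfg: GeneratorConfig, rng: np.random.Generator) -> _Plan:
    counts = {"DQ2.5-glia-a1": 0, "DQ2.5-glia-a2": 0,
              "DQ2.5-glia-a3": 0, "DQ8-glia-a1": 0}
    b_type = "n/a"
    n_alpha2 = 0

    if genome == "D":
        k = int(_choice(rng, [cfg.d_dup_probs[0], cfg.d_dup_probs[1]], [2, 3, 1]))
        n_alpha2 = k
        # neutral filler keeps the repetitive domain length independent of
        # the tandem copy number, so domain-anchored alignments stay tight
        a12_block = "PF" + "PQPQLPY" * k + "PQ" + "QPQPFPP" * (3 - k)
        counts["DQ2.5-glia-a1"] = k  # a1a once + a1b at each tandem junction
        counts["DQ2.5-glia-a2"] = k
        if rng.random() < cfg.d_a3_ser_rate:
            a3_block = ALPHA3_D_SER
        else:
            a3_block = ALPHA3_CANONICAL
            counts["DQ2.5-glia-a3"] = 1
        context = "F"
        spacer = UII_SPACER
        if rng.random() < cfg.d_dq8_ff_rate:
            dq8 = DQ8_D_FF
        else:
            dq8 = DQ8_CANONICAL
            counts["DQ8-glia-a1"] = 1
    elif genome == "A":
        tail = "SH" if rng.random() < cfg.a_sh_rate else "SQ"
        a12_block = "PF" + "PQPQLPY" + tail
        counts["DQ2.5-glia-a1"] = 1
        a3_block = ALPHA3_CANONICAL
        counts["DQ2.5-glia-a3"] = 1
        context = "F"
        spacer = UII_SPACER
        if rng.random() < cfg.a_dq8_canonical_rate:
            dq8 = DQ8_CANONICAL
            counts["DQ8-glia-a1"] = 1
        else:
            dq8 = DQ8_A_VAR
    elif genome == "B":
        b_type = str(_choice(rng, cfg.b_type_mix[:2], ["YG", "FV", "other"]))
        a12_block = "PFPQPLPY" + "QPQPF" + "PPQLPYPQT"  # deletion variants + T
        a3_block = ALPHA3_B_VAR
        if b_type == "YG":
            context, spacer = "Y", UII_SPACER
            if rng.random() < cfg.yg_dq8_mut_rate:
                dq8 = DQ8_YG
            else:
                dq8 = DQ8_CANONICAL
                counts["DQ8-glia-a1"] = 1
        elif b_type == "FV":
            context, spacer, dq8 = "F", UII_SPACER_FV, DQ8_FV
        else:
            context, spacer, dq8 = "Y", UII_SPACER, DQ8_FV
    else:
        raise ValueError(f"unknown genome {genome!r}")

    repetitive = REP_PREFIX[genome] + a12_block + REP_MID + a3_block + REP_END

    pq1_len = int(rng.integers(*_incl(cfg.pq_range(genome, "PQI", b_type))))
    pq2_len = int(rng.integers(*_incl(cfg.pq_range(genome, "PQII", b_type))))

    unique_i = UNIQUE_I[genome]
    n_cys = 6
    if rng.random() < cfg.cys_loss_rate:
        idx = unique_i.index("C")
        unique_i = unique_i[:idx] + "Y" + unique_i[idx + 1 :]
        n_cys -= 1
    unique_ii = UII_PRE + context + spacer + dq8 + UII_POST[genome]
    if rng.random() < cfg.extra_cys_rate:
        unique_ii = "C" + unique_ii
        n_cys += 1

    segments = {
        "signal_peptide": SIGNAL,
        "repetitive": repetitive,
        "polyQ_I": "Q" * pq1_len,
        "unique_I": unique_i,
        "polyQ_II": "Q" * pq2_len,
        "unique_II": unique_ii,
    }
    return _Plan(
        genome=genome,
        b_type=b_type,
        segments=segments,
        canonical_counts=counts,
        n_alpha2=n_alpha2 if genome == "D" else 0,
        n_cys=n_cys,
    )


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def _splice_chimera(front: _Plan, back: _Plan) -> _Plan:
    """Join two plans at the unique-domain-I midpoint."""
    mid = len(front.segments["unique_I"]) // 2
    unique_i = front.segments["unique_I"][:mid] + back.segments["unique_I"][mid:]
    segments = {
        "signal_peptide": front.segments["signal_peptide"],
        "repetitive": front.segments["repetitive"],
        "polyQ_I": front.segments["polyQ_I"],
        "unique_I": unique_i,
        "polyQ_II": back.segments["polyQ_II"],
        "unique_II": back.segments["unique_II"],
    }
    counts = dict(front.canonical_counts)
    counts["DQ8-glia-a1"] = back.canonical_counts["DQ8-glia-a1"]
    n_cys = "".join(segments.values()).count("C")
    return _Plan(
        genome=front.genome,
        b_type=back.b_type,
        segments=segments,
        canonical_counts=counts,
        n_alpha2=front.n_alpha2,
        n_cys=n_cys,
    )


def back_translate(
    protein: str,
    codon_weights: Optional[dict[str, dict[str, float]]] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Map each residue to a synonymous codon drawn by weight.

    Weights default to uniform over the standard-code synonymous codons;
    translation of the result reproduces the input protein exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    codons = []
    for aa in protein:
        options = AA_TO_CODONS.get(aa)
        if not options:
            raise ValueError(f"no codon entry for residue {aa!r}")
        if codon_weights and aa in codon_weights:
            w = np.array([codon_weights[aa].get(c, 0.0) for c in options])
            if w.sum() <= 0:
                raise ValueError(f"zero total codon weight for residue {aa!r}")
            codons.append(options[rng.choice(len(options), p=w / w.sum())])
        else:
            codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _inject_psc(
    nt: str, ct_bias: float, rng: np.random.Generator
) -> tuple[str, int, str]:
    """One single-nucleotide substitution creating an internal stop.

    Returns (mutated sequence, 1-based codon index, "REF>OBS").
    Candidate sites are drawn C->T with probability ``ct_bias`` when a
    C->T route exists, otherwise from the non-C->T routes.
    """
    n_codons = len(nt) // 3
    ct, non_ct = [], []
    for ci in range(1, n_codons - 1):  # internal codons, keep the start codon
        codon = nt[ci * 3 : ci * 3 + 3]
        if codon in _STOPS:
            continue
        for stop in _STOPS:
            diffs = [k for k in range(3) if codon[k] != stop[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            entry = (ci, k, codon[k], stop[k])
            if codon[k] == "C" and stop[k] == "T":
                ct.append(entry)
            else:
                non_ct.append(entry)
    pool = ct if (rng.random() < ct_bias and ct) else (non_ct or ct)
    if not pool:
        raise ValueError("no single-substitution stop route in sequence")
    ci, k, ref, obs = pool[rng.integers(len(pool))]
    pos = ci * 3 + k
    mutated = nt[:pos] + obs + nt[pos + 1 :]
    return mutated, ci + 1, f"{ref}>{obs}"


def _apply_noise(plan: _Plan, rate: float, rng: np.random.Generator) -> str:
    protein = plan.protein
    if rate <= 0:
        return protein
    chars = list(protein)
    for i in plan.noise_eligible():
        if rng.random() < rate:
            choices = [c for c in NOISE_ALPHABET if c != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[list[NucleotideRecord], TruthTable]:
    """Generate a cohort of transcripts plus its truth table.

    Fully reproducible: the same config (including seed) yields
    byte-identical records.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[NucleotideRecord] = []
    truths: list[TruthRecord] = []
    counter = 0
    for acc_i in range(cfg.n_accessions):
        accession = f"ACC{acc_i + 1:02d}"
        for _ in range(cfg.n_seqs_per_accession):
            counter += 1
            seq_id = f"SYN{counter:04d}"
            is_chimera = rng.random() < cfg.chimera_rate
            if is_chimera:
                g_front = str(_choice(rng, cfg.genome_mix[:2], ["A", "B", "D"]))
                g_back = g_front
                while g_back == g_front:
                    g_back = str(_choice(rng, cfg.genome_mix[:2], ["A", "B", "D"]))
                plan = _splice_chimera(
                    _build_plan(g_front, cfg, rng), _build_plan(g_back, cfg, rng)
                )
                back_genome = g_back
            else:
                genome = str(_choice(rng, cfg.genome_mix[:2], ["A", "B", "D"]))
                plan = _build_plan(genome, cfg, rng)
                back_genome = ""
            protein = _apply_noise(plan, cfg.noise_rate, rng)
            nt = back_translate(protein, rng=rng)

            is_pseudo = rng.random() < cfg.psc_rate
            psc_positions: list[int] = []
            psc_subs: list[str] = []
            if is_pseudo:
                nt, codon_idx, sub = _inject_psc(nt, cfg.psc_ct_bias, rng)
                psc_positions.append(codon_idx)
                psc_subs.append(sub)

            bounds = plan.boundaries()
            records.append(
                NucleotideRecord(id=seq_id, seq=nt, accession_label=accession)
            )
            truths.append(
                TruthRecord(
                    seq_id=seq_id,
                    accession=accession,
                    genome=plan.genome,
                    b_type=plan.b_type,
                    n_alpha2_copies=plan.n_alpha2,
                    canonical_counts=dict(plan.canonical_counts),
                    pq1_len=len(plan.segments["polyQ_I"]),
                    pq2_len=len(plan.segments["polyQ_II"]),
                    n_cys=plan.n_cys,
                    boundaries=bounds,
                    is_pseudogene=is_pseudo,
                    psc_codon_positions=psc_positions,
                    psc_substitutions=psc_subs,
                    is_chimera=is_chimera,
                    back_genome=back_genome,
                )
            )
    return records, TruthTable(records=truths)
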