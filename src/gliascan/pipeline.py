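"""End-to-end orchestration: QC -> segmentation -> epitope scan ->
genome assignment -> (optional) phylogenetic confirmation -> summaries.

Pseudogenes are classified and counted but excluded from the domain,
epitope and genome stages; all per-accession statistics cover the
full-ORF set only.  Running twice with the same inputs and seed yields
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from gliascan import annotate, epitopes, genomes, phylo, qc, seq_core

__all__ = [
    "RunConfig",
    "ResultsBundle",
    "domain_anchored_alignment",
    "run_pipeline",
    "write_table1_analog",
]

log = logging.getLogger("gliascan")

EPITOPE_COLUMNS = ("DQ2.5-glia-a1", "DQ2.5-glia-a2", "DQ2.5-glia-a3", "DQ8-glia-a1")


@dataclass
class RunConfig:
    inputs: list[str]
    out_dir: str = "gliascan_out"
    motif_path: Optional[str] = None
    epitope_path: Optional[str] = None
    refs_path: Optional[str] = None
    phylo: bool = False
    seed: int = 0
    margin_threshold: int = genomes.DEFAULT_MARGIN
    max_sub: int = 2
    allow_single_deletion: bool = True
    segmentation: annotate.SegmentationConfig = field(
        default_factory=annotate.SegmentationConfig
    )

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    sequences: pd.DataFrame
    accessions: pd.DataFrame
    variants: pd.DataFrame
    polyq: pd.DataFrame
    clusters: pd.DataFrame
    metadata: dict
    newick: Optional[str] = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self._check_consistency()
        self.sequences.to_csv(out / "sequences.tsv", sep="\t", index=False)
        self.accessions.to_csv(out / "accessions.tsv", sep="\t", index=False)
        self.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.polyq.to_csv(out / "polyq_stats.tsv", sep="\t", index=False)
        self.clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
        bundle = {
            "metadata": self.metadata,
            "sequences": self.sequences.to_dict(orient="records"),
            "accessions": self.accessions.to_dict(orient="records"),
            "variants": self.variants.to_dict(orient="records"),
            "polyq": self.polyq.to_dict(orient="records"),
        }
        (out / "bundle.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
        if self.newick:
            (out / "tree.nwk").write_text(self.newick + "\n")

    def _check_consistency(self) -> None:
        """Per-accession totals must equal sums over member sequences."""
        totals = self.accessions[self.accessions["accession"] == "TOTAL"]
        if totals.empty:
            return
        body = self.accessions[self.accessions["accession"] != "TOTAL"]
        for col in body.columns:
            if body[col].dtype.kind not in "if":
                continue
            if col.startswith("mean") or col.startswith("prop"):
                continue
            if abs(body[col].sum() - totals.iloc[0][col]) > 1e-9:
                raise ValueError(f"table inconsistency in column {col!r}")


def domain_anchored_alignment(
    proteins: dict[str, str],
    annotations: dict[str, annotate.DomainAnnotation],
) -> phylo.Alignment:
    """Gap-pad each of the six domains to its cohort-wide maximum length.

    A cheap structural alignment for domain-conserved families; only
    sequences with a successful segmentation participate.
    """
    ids = [i for i in proteins if i in annotations]
    if len(ids) < 3:
        raise ValueError("need at least 3 segmented sequences to align")
    max_len = {name: 0 for name in annotate.DOMAIN_ORDER}
    for i in ids:
        for name, (lo, hi) in annotations[i].boundaries.items():
            max_len[name] = max(max_len[name], hi - lo)
    rows = []
    for i in ids:
        parts = []
        for name in annotate.DOMAIN_ORDER:
            lo, hi = annotations[i].boundaries[name]
            seg = proteins[i][lo - 1 : hi - 1]
            parts.append(seg.ljust(max_len[name], "-"))
        rows.append("".join(parts))
    return phylo.Alignment(ids=ids, rows=rows)


def _read_inputs(cfg: RunConfig) -> list[seq_core.NucleotideRecord]:
    records: list[seq_core.NucleotideRecord] = []
    for path in cfg.inputs:
        batch = seq_core.read_fasta(path)
        if len(cfg.inputs) > 1:
            # one-FASTA-per-accession convention: filename stem is the label
            stem = Path(path).stem
            batch = [
                seq_core.NucleotideRecord(
                    id=r.id, seq=r.seq, accession_label=r.accession_label or stem
                )
                for r in batch
            ]
        records.extend(batch)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids across input files")
    return records


def run_pipeline(
    cfg: RunConfig,
    records: Optional[Sequence[seq_core.NucleotideRecord]] = None,
) -> ResultsBundle:
    """Run every stage and assemble the results bundle.

    ``records`` may be passed directly (e.g. from the generator) to skip
    file input.
    """
    if records is None:
        records = _read_inputs(cfg)
    if not records:
        raise ValueError("input stage: no records")
    log.info("input: %d records", len(records))

    motifs = genomes.load_motif_table(cfg.motif_path)
    epitope_defs = epitopes.load_epitope_definitions(cfg.epitope_path)

    proteins = {r.id: seq_core.translate(r, frame=1) for r in records}
    orf_status = {rid: qc.classify_orf(p) for rid, p in proteins.items()}
    full_ids = [r.id for r in records if not orf_status[r.id].is_pseudogene]
    log.info("qc: %d full ORF / %d pseudogenes",
             len(full_ids), len(records) - len(full_ids))

    full_nt = [r for r in records if r.id in set(full_ids)]
    clusters_rows: list[dict] = []
    if full_nt:
        nt_clusters = seq_core.cluster_identical(full_nt, "nucleotide")
        aa_clusters = seq_core.cluster_identical(
            [proteins[r.id] for r in full_nt], "protein"
        )
        clusters_rows = seq_core.clusters_to_rows(nt_clusters) + \
            seq_core.clusters_to_rows(aa_clusters)

    annotations: dict[str, annotate.DomainAnnotation] = {}
    atypical: dict[str, str] = {}
    for rid in full_ids:
        try:
            annotations[rid] = annotate.segment_domains(
                proteins[rid].aa_seq, cfg.segmentation
            )
        except (annotate.AtypicalArchitectureError, ValueError) as exc:
            atypical[rid] = str(exc)
            log.debug("segmentation %s: %s", rid, exc)

    reports: dict[str, epitopes.EpitopeReport] = {}
    for rid in full_ids:
        ann = annotations.get(rid)
        reports[rid] = epitopes.build_report(
            rid,
            proteins[rid].aa_seq,
            defs=epitope_defs,
            max_sub=cfg.max_sub,
            allow_single_deletion=cfg.allow_single_deletion,
            domain_of=ann.boundaries if ann else None,
        )

    calls: dict[str, genomes.GenomeCall] = {}
    chimera: dict[str, qc.ChimeraFlag] = {}
    for rid in full_ids:
        ann = annotations.get(rid)
        calls[rid] = genomes.assign_genome(
            proteins[rid].aa_seq, reports[rid], motifs, ann,
            margin_threshold=cfg.margin_threshold,
        )
        if ann is not None:
            chimera[rid] = qc.flag_chimera(
                proteins[rid], motifs, ann, margin_threshold=cfg.margin_threshold
            )

    newick = None
    if cfg.phylo:
        newick = _confirm_with_phylo(cfg, proteins, annotations, calls)

    sequences = _sequence_table(
        records, proteins, orf_status, annotations, atypical, reports, calls, chimera
    )
    accessions = _accession_table(records, orf_status, reports, calls)
    variants = _variant_table(reports, calls)
    polyq = _polyq_table(annotations, calls)

    metadata = {
        "n_records": len(records),
        "n_full_orf": len(full_ids),
        "n_pseudogenes": len(records) - len(full_ids),
        "seed": cfg.seed,
        "config_hash": cfg.content_hash(),
    }
    return ResultsBundle(
        sequences=sequences,
        accessions=accessions,
        variants=variants,
        polyq=polyq,
        clusters=pd.DataFrame(clusters_rows),
        metadata=metadata,
        newick=newick,
    )


def _confirm_with_phylo(cfg, proteins, annotations, calls) -> Optional[str]:
    if not cfg.refs_path:
        log.warning("phylo requested without references; skipping")
        return None
    # references are protein FASTA with a genome= tag in the description
    from Bio import SeqIO

    ref_labels: dict[str, str] = {}
    ref_proteins: dict[str, str] = {}

    for rec in SeqIO.parse(str(cfg.refs_path), "fasta"):
        label = None
        for token in rec.description.split():
            if token.startswith("genome="):
                label = token.split("=", 1)[1]
        if label not in ("A", "B", "D"):
            raise ValueError(f"reference {rec.id!r}: missing/invalid genome= tag")
        ref_labels[rec.id] = label
        ref_proteins[rec.id] = str(rec.seq).upper()

    all_proteins = {rid: p.aa_seq for rid, p in proteins.items()}
    all_anns = dict(annotations)
    for rid, aa in ref_proteins.items():
        try:
            all_anns[rid] = annotate.segment_domains(aa, cfg.segmentation)
        except (annotate.AtypicalArchitectureError, ValueError):
            continue
        all_proteins[rid] = aa
    aln = domain_anchored_alignment(all_proteins, all_anns)
    tree = phylo.neighbor_joining(phylo.poisson_distance(aln))
    motif_call_map = {rid: c.genome for rid, c in calls.items()}
    confirmed = phylo.confirm_assignment(tree, ref_labels, motif_call_map)
    for rid, (genome, concordant) in confirmed.items():
        if rid in calls:
            calls[rid].phylo_concordant = concordant
    return tree.to_newick()


def _sequence_table(
    records, proteins, orf_status, annotations, atypical, reports, calls, chimera
) -> pd.DataFrame:
    rows = []
    for rec in records:
        status = orf_status[rec.id]
        row: dict = {
            "id": rec.id,
            "accession": rec.accession_label,
            "status": status.status,
            "n_psc": len(status.psc_positions),
            "psc_codon_positions": ",".join(map(str, status.psc_positions)),
        }
        ann = annotations.get(rec.id)
        if ann is not None:
            total, per_domain = annotate.count_cysteines(
                proteins[rec.id].aa_seq, ann
            )
            row.update(
                {
                    "domains": ";".join(
                        f"{n}:{lo}-{hi - 1}" for n, (lo, hi) in ann.boundaries.items()
                    ),
                    "n_cys_total": total,
                    "n_cys_uniqueI": per_domain.get("unique_I", 0),
                    "n_cys_uniqueII": per_domain.get("unique_II", 0),
                    "q_pq1": ann.q_count_pq1,
                    "q_pq2": ann.q_count_pq2,
                    "indel_note": ann.indel_note,
                }
            )
        elif rec.id in atypical:
            row["indel_note"] = atypical[rec.id]
        report = reports.get(rec.id)
        if report is not None:
            for name in EPITOPE_COLUMNS:
                row[f"canonical_{name}"] = report.canonical_counts[name]
            row["alpha2_duplications"] = report.alpha2_duplications
            row["has_33mer"] = report.has_33mer
        call = calls.get(rec.id)
        if call is not None:
            row.update(
                {
                    "genome": call.genome,
                    "scoreA": call.scores["A"],
                    "scoreB": call.scores["B"],
                    "scoreD": call.scores["D"],
                    "margin": call.margin,
                    "b_type": call.b_type,
                    "phylo_concordant": call.phylo_concordant,
                }
            )
        flag = chimera.get(rec.id)
        if flag is not None:
            row.update(
                {
                    "chimera_flag": flag.is_chimeric,
                    "front_call": flag.front_call,
                    "back_call": flag.back_call,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _accession_table(records, orf_status, reports, calls) -> pd.DataFrame:
    order: list[str] = []
    for rec in records:
        label = rec.accession_label or "(none)"
        if label not in order:
            order.append(label)
    rows = []
    for label in order:
        members = [r for r in records if (r.accession_label or "(none)") == label]
        full = [r for r in members if not orf_status[r.id].is_pseudogene]
        row: dict = {
            "accession": label,
            "total": len(members),
            "pseudogenes": len(members) - len(full),
            "full_orf": len(full),
        }
        for g in ("A", "B", "D", "unassigned"):
            row[f"n_{g}"] = sum(
                1 for r in full if calls[r.id].genome == g
            )
        for name in EPITOPE_COLUMNS:
            for g in ("A", "B", "D"):
                row[f"{name}|{g}"] = sum(
                    reports[r.id].canonical_counts[name]
                    for r in full
                    if calls[r.id].genome == g
                )
            row[f"{name}|TOT"] = sum(
                reports[r.id].canonical_counts[name] for r in full
            )
        if full:
            summary = epitopes.summarize_accession(
                label,
                [reports[r.id] for r in full],
                {r.id: calls[r.id].genome for r in full},
            )
            row["mean_canonical_per_seq"] = summary.mean_canonical_per_seq
            for g in ("A", "B", "D"):
                row[f"prop_{g}"] = summary.genome_proportions.get(g, 0.0)
        rows.append(row)
    df = pd.DataFrame(rows)
    total_row = {"accession": "TOTAL"}
    for col in df.columns:
        if col == "accession":
            continue
        if col.startswith("mean") or col.startswith("prop"):
            total_row[col] = float("nan")
        else:
            total_row[col] = df[col].sum()
    return pd.concat([df, pd.DataFrame([total_row])], ignore_index=True)


def _variant_table(reports, calls) -> pd.DataFrame:
    agg: dict[tuple[str, str, str], int] = {}
    for rid, report in reports.items():
        genome = calls[rid].genome if rid in calls else "unassigned"
        for (epitope, observed), count in report.variant_inventory.items():
            key = (epitope, observed, genome)
            agg[key] = agg.get(key, 0) + count
    rows = [
        {"epitope": e, "observed": o, "genome": g, "count": c}
        for (e, o, g), c in sorted(agg.items())
    ]
    return pd.DataFrame(rows, columns=["epitope", "observed", "genome", "count"])


def _polyq_table(annotations, calls) -> pd.DataFrame:
    labeled = [
        (calls[rid].genome, ann)
        for rid, ann in annotations.items()
        if rid in calls and calls[rid].genome in ("A", "B", "D")
    ]
    stats = annotate.polyq_group_stats(labeled)
    return pd.DataFrame(
        [
            {
                "genome": s.genome,
                "region": s.region,
                "n": s.n,
                "mean_q": s.mean_q,
                "sd_q": s.sd_q,
                "degenerate": s.degenerate,
            }
            for s in stats
        ],
        columns=["genome", "region", "n", "mean_q", "sd_q", "degenerate"],
    )


def write_table1_analog(bundle: ResultsBundle, path) -> None:
    """Accession x genome census of full-ORF sequences and canonical
    epitope occurrences, with a TOTAL row equal to the column sums."""
    bundle._check_consistency()
    cols = ["accession", "total", "pseudogenes", "full_orf", "n_A", "n_B", "n_D"]
    cols += [
        f"{name}|{g}" for name in EPITOPE_COLUMNS for g in ("A", "B", "D", "TOT")
    ]
    bundle.accessions[cols].to_csv(path, sep="\t", index=False)
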