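import random

import numpy as np
import pytest

from gliascan import annotate, epitopes, genomes, synthetic
from gliascan.genomes import (
    GenomeCall, MotifRule, MotifTable, assign_genome, classify_b_type,
    load_motif_table, score_genomes, type_pq2_association,
)


def call_for(plan, motif_table, margin=2):
    ann = annotate.segment_domains(plan.protein)
    report = epitopes.build_report("x", plan.protein, domain_of=ann.boundaries)
    return assign_genome(plan.protein, report, motif_table, ann, margin)


class TestMotifTable:
    def test_default_table_loads(self, motif_table):
        assert len(motif_table.rules) >= 10
        assert {r.genome for r in motif_table.rules} == {"A", "B", "D"}

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            MotifRule(id="x", genome="A", kind="substring", weight=0, pattern="AAA")

    def test_unknown_genome_rejected(self):
        with pytest.raises(ValueError, match="genome"):
            MotifRule(id="x", genome="E", kind="substring", weight=1, pattern="AAA")

    def test_duplicate_ids_rejected(self):
        rule = MotifRule(id="x", genome="A", kind="substring", weight=1, pattern="AAA")
        with pytest.raises(ValueError, match="duplicate"):
            MotifTable(rules=[rule, rule])

    def test_user_override_merges(self, tmp_path, motif_table):
        override = tmp_path / "motifs.yaml"
        override.write_text(
            "rules:\n"
            "  - {id: d_canonical_a2, genome: D, kind: canonical_epitope,"
            " pattern: DQ2.5-glia-a2, weight: 5}\n"
        )
        merged = load_motif_table(override)
        assert len(merged.rules) == len(motif_table.rules)
        rule = next(r for r in merged.rules if r.id == "d_canonical_a2")
        assert rule.weight == 5


class TestAssignGenome:
    def test_d_template_confident(self, motif_table, canonical_d_plan):
        call = call_for(canonical_d_plan, motif_table)
        assert call.genome == "D"
        assert call.margin >= 2

    def test_b_yg_template(self, motif_table):
        cfg = synthetic.GeneratorConfig(seed=0, b_type_mix=(1.0, 0.0, 0.0))
        plan = synthetic._build_plan("B", cfg, np.random.default_rng(2))
        call = call_for(plan, motif_table)
        assert call.genome == "B"
        assert call.b_type == "YG"

    def test_a_template(self, motif_table):
        plan = synthetic._build_plan(
            "A", synthetic.GeneratorConfig(seed=0), np.random.default_rng(3)
        )
        call = call_for(plan, motif_table)
        assert call.genome == "A"
        assert call.b_type == "n/a"

    def test_featureless_string_unassigned(self, motif_table):
        aa = "A" * 200
        report = epitopes.build_report("x", aa)
        call = assign_genome(aa, report, motif_table)
        assert call.genome == "unassigned"
        assert call.scores == {"A": 0, "B": 0, "D": 0}

    def test_scores_order_independent(self, motif_table, canonical_d_plan):
        ann = annotate.segment_domains(canonical_d_plan.protein)
        report = epitopes.build_report(
            "x", canonical_d_plan.protein, domain_of=ann.boundaries
        )
        base = score_genomes(canonical_d_plan.protein, report, motif_table)
        shuffled = list(motif_table.rules)
        random.Random(7).shuffle(shuffled)
        other = score_genomes(
            canonical_d_plan.protein, report, MotifTable(rules=shuffled)
        )
        assert base == other

    def test_full_recovery_noise_free(self, motif_table, small_cohort):
        from gliascan import qc, seq_core

        _, records, truth = small_cohort
        tmap = truth.by_id()
        for rec in records:
            t = tmap[rec.id]
            if t.is_pseudogene:
                continue
            aa = seq_core.translate(rec).aa_seq
            ann = annotate.segment_domains(aa)
            report = epitopes.build_report(rec.id, aa, domain_of=ann.boundaries)
            call = assign_genome(aa, report, motif_table, ann)
            assert call.genome == t.genome, rec.id

    def test_recovery_under_low_noise(self, motif_table):
        from gliascan import seq_core

        cfg = synthetic.GeneratorConfig(
            seed=17, n_accessions=2, n_seqs_per_accession=50,
            noise_rate=0.01, psc_rate=0.0,
        )
        records, truth = synthetic.generate_cohort(cfg)
        tmap = truth.by_id()
        hits = 0
        for rec in records:
            aa = seq_core.translate(rec).aa_seq
            ann = annotate.segment_domains(aa)
            report = epitopes.build_report(rec.id, aa, domain_of=ann.boundaries)
            if assign_genome(aa, report, motif_table, ann).genome == tmap[rec.id].genome:
                hits += 1
        assert hits / len(records) >= 0.99


class TestClassifyBType:
    def test_yg_context(self):
        aa = "Y" + "PEHSMVAHAI" + "QGSFQSSQQ"
        assert classify_b_type(aa) == "YG"

    def test_leucine_context_is_yg(self):
        aa = "L" + "PEHSMVAHAI" + "QGSFQSSQQ"
        assert classify_b_type(aa) == "YG"

    def test_fv_window(self):
        aa = "F" + "PEHSMVAHAS" + "QVSFQPSQL"
        assert classify_b_type(aa) == "FV"

    def test_both_signatures_other(self):
        aa = "Y" + "PEHSMVAHAI" + "QVSFQPSQL"
        assert classify_b_type(aa) == "other"

    def test_no_dq8_locus_other(self):
        assert classify_b_type("A" * 50) == "other"

    def test_b_type_only_for_b_calls(self, motif_table, canonical_d_plan):
        call = call_for(canonical_d_plan, motif_table)
        assert call.genome == "D"
        assert call.b_type == "n/a"


class TestTypePq2Association:
    def _setup(self, combos):
        calls, anns = [], {}
        for i, (b_type, q2) in enumerate(combos):
            sid = f"s{i}"
            calls.append(
                GenomeCall(seq_id=sid, genome="B",
                           scores={"A": 0, "B": 4, "D": 0}, margin=4, b_type=b_type)
            )
            anns[sid] = annotate.DomainAnnotation(
                boundaries={}, cys_positions=[], q_count_pq1=10, q_count_pq2=q2
            )
        return calls, anns

    def test_perfect_association(self):
        calls, anns = self._setup([("YG", 6)] * 4 + [("FV", 20)] * 4)
        _, concordance, discordant = type_pq2_association(calls, anns)
        assert concordance == 1.0
        assert discordant == []

    def test_one_discordant_in_ten(self):
        combos = [("YG", 6)] * 5 + [("FV", 20)] * 4 + [("YG", 20)]
        calls, anns = self._setup(combos)
        table, concordance, discordant = type_pq2_association(calls, anns)
        assert concordance == pytest.approx(0.9)
        assert len(discordant) == 1
        assert table[("YG", "long")] == 1

    def test_intermediate_counts_discordant(self):
        calls, anns = self._setup([("YG", 6), ("FV", 10)])
        _, concordance, _ = type_pq2_association(calls, anns)
        assert concordance == pytest.approx(0.5)

    def test_no_b_sequences_errors(self):
        call = GenomeCall(seq_id="s", genome="A",
                          scores={"A": 2, "B": 0, "D": 0}, margin=2)
        with pytest.raises(ValueError, match="no B-genome"):
            type_pq2_association([call], {})

    def test_synthetic_cohort_concordant(self, motif_table, small_cohort):
        from gliascan import seq_core

        _, records, truth = small_cohort
        tmap = truth.by_id()
        calls, anns = [], {}
        for rec in records:
            if tmap[rec.id].is_pseudogene:
                continue
            aa = seq_core.translate(rec).aa_seq
            ann = annotate.segment_domains(aa)
            report = epitopes.build_report(rec.id, aa, domain_of=ann.boundaries)
            calls.append(assign_genome(aa, report, motif_table, ann))
            anns[rec.id] = ann
        _, concordance, _ = type_pq2_association(calls, anns)
        assert concordance == 1.0
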