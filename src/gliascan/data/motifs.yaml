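# Default genome-diagnostic motif rules. Weights are additive evidence;
# a call needs the top genome to lead the runner-up by the margin
# threshold (default 2). Edit or override per rule id with a user table.
#
# provenance "vanHerpen" marks motif classes first described for diploid
# wheats; "thisPaper" marks spelt-specific motifs and epitope-canonicity
# logic.
rules:
  # D genome: the only genome carrying canonical DQ2.5-glia-a2.
  - id: d_canonical_a2
    genome: D
    kind: canonical_epitope
    pattern: DQ2.5-glia-a2
    weight: 3
    provenance: thisPaper
  # Q->H substitution in the second copy of a duplicated a2 locus.
  - id: d_a2_second_copy_h
    genome: D
    kind: substring
    pattern: PQPHLPYPQ
    weight: 2
    provenance: thisPaper
  # P->S substitution inside DQ2.5-glia-a3.
  - id: d_a3_serine
    genome: D
    kind: substring
    pattern: FRPQQSYPQ
    weight: 2
    provenance: thisPaper
  # S->F substitution at the third DQ8 position.
  - id: d_dq8_ff
    genome: D
    kind: substring
    pattern: QGFFQPSQQ
    weight: 2
    provenance: thisPaper
  # A genome: canonical a1/a3 with a mutated (substitution) a2.
  - id: a_profile
    genome: A
    kind: profile_a
    weight: 2
    provenance: vanHerpen
  # Q->H at the last a2 position, A-specific.
  - id: a_a2_sh
    genome: A
    kind: substring
    pattern: PQPQLPYSH
    weight: 2
    provenance: thisPaper
  # B genome: no canonical DQ2.5 epitope, deletion-variant a1/a2.
  - id: b_profile
    genome: B
    kind: profile_b
    weight: 2
    provenance: vanHerpen
  # P->T immediately after the a2 locus.
  - id: b_t_after_a2
    genome: B
    kind: substring
    pattern: LPYPQT
    weight: 2
    provenance: thisPaper
  # YG-type DQ8 window (P->S at the sixth position).
  - id: b_dq8_yg
    genome: B
    kind: substring
    pattern: QGSFQSSQQ
    weight: 2
    provenance: thisPaper
  # FV-type DQ8 window (G->V, Q->L).
  - id: b_dq8_fv
    genome: B
    kind: substring
    pattern: QVSFQPSQL
    weight: 2
    provenance: vanHerpen
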