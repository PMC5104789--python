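# Canonical T-cell epitope definitions. DQ2.5-glia-a1 has two canonical
# sub-forms because the residue at its second position tracks the
# overlapping DQ2.5-glia-a2 tandem structure.
epitopes:
  - name: DQ2.5-glia-a1
    canonical: [PFPQPQLPY, PYPQPQLPY]
    anchor: repetitive
  - name: DQ2.5-glia-a2
    canonical: PQPQLPYPQ
    anchor: repetitive
  - name: DQ2.5-glia-a3
    canonical: FRPQQPYPQ
    anchor: repetitive
  - name: DQ8-glia-a1
    canonical: QGSFQPSQQ
    anchor: unique_II
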