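# Default seven-reaction synthetic pathway (shikimate-like), coupled to the
# host through fixed boundary metabolites. Concentrations in mM, dG in kJ/mol.
name: synthetic-pathway-7
temperature_K: 298.15
reactions:
  - name: rA
    substrates: {pep: 1, e4p: 1}
    products: {A: 1, pi: 1}
    mechanism: IrrevMM
    dG_kJ_mol: -12.03
  - name: rB
    substrates: {A: 1}
    products: {B: 1}
    mechanism: IrrevMM
    dG_kJ_mol: -16.12
  - name: rC
    substrates: {B: 1}
    products: {C: 1}
    mechanism: RevMM
    dG_kJ_mol: -8.47
  - name: rD
    substrates: {C: 1, nadph: 1}
    products: {D: 1, nadp: 1}
    mechanism: GenRevHill
    dG_kJ_mol: 1.10
  - name: rE
    substrates: {D: 1, atp: 1}
    products: {E: 1, adp: 1}
    mechanism: GenRevHill
    dG_kJ_mol: -6.40
  - name: rF
    substrates: {pep: 1, E: 1}
    products: {F: 1, pi: 1}
    mechanism: GenRevHill
    dG_kJ_mol: 0.41
  - name: rG
    substrates: {F: 1}
    products: {G: 1, pi: 1}
    mechanism: IrrevMM
    dG_kJ_mol: -11.77
boundary:
  pep: 2.0
  e4p: 0.5
  pi: 10.0
  nadph: 0.15
  nadp: 0.05
  atp: 3.0
  adp: 1.0
  G: 0.01
dynamic: [A, B, C, D, E, F]
bounds:
  km_mM: [1.0e-3, 1.0]
  conc_mM: [1.0e-2, 1.0]
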