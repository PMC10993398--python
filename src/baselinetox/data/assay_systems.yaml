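# Assay-system presets: 384-well geometry (40 uL medium, 30 nL cells).
# Two generic variants ship because the source tables disagree on the
# generic composition: `generic` uses the tabulated 0.001% medium lipid and
# a 6%/0.1% cell; `generic_text` uses the prose values (0.07 mL lipid per L
# medium; 30 mL protein and 5 mL lipid per L cell). The four assay presets
# are approximations from the printed medium compositions (AREc32 and
# AhR-CALUX share DMEM + 10% FBS and are therefore identical); measured
# compartment compositions should be supplied by the user when available.
provenance: "doi:10.1021/acs.est.3c09950; assay medium fractions approximate"
systems:
  - name: generic
    v_medium_L: 40.0e-6
    v_cell_L: 30.0e-9
    vf_protein_medium: 0.003
    vf_lipid_medium: 1.0e-5
    vf_protein_cell: 0.06
    vf_lipid_cell: 0.001
  - name: generic_text
    v_medium_L: 40.0e-6
    v_cell_L: 30.0e-9
    vf_protein_medium: 0.003
    vf_lipid_medium: 7.0e-5
    vf_protein_cell: 0.03
    vf_lipid_cell: 0.005
  - name: ppargamma_geneblazer
    v_medium_L: 40.0e-6
    v_cell_L: 30.0e-9
    vf_protein_medium: 6.0e-4
    vf_lipid_medium: 1.0e-5
    vf_protein_cell: 0.03
    vf_lipid_cell: 0.005
  - name: arec32
    v_medium_L: 40.0e-6
    v_cell_L: 30.0e-9
    vf_protein_medium: 0.003
    vf_lipid_medium: 7.0e-5
    vf_protein_cell: 0.03
    vf_lipid_cell: 0.005
  - name: ahr_calux
    v_medium_L: 40.0e-6
    v_cell_L: 30.0e-9
    vf_protein_medium: 0.003
    vf_lipid_medium: 7.0e-5
    vf_protein_cell: 0.03
    vf_lipid_cell: 0.005
  - name: neurotoxicity
    v_medium_L: 40.0e-6
    v_cell_L: 30.0e-9
    vf_protein_medium: 0.0015
    vf_lipid_medium: 2.0e-5
    vf_protein_cell: 0.03
    vf_lipid_cell: 0.005
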