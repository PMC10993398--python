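# Protein-lipid partition regressions: log D_protein/w = slope * log D_lip/w + intercept.
# Coefficients are data, not code. Anionic rows are OLS refits of the nine
# experimental anionic PFAS (6:2 FTSA and PFOSA excluded because their
# log D_lip/w values are themselves predicted). Neutral rows are the
# literature serum-albumin and structural-protein relationships rescaled
# from log Kow through log K_lip/w = 1.01 log Kow + 0.12.
provenance: "doi:10.1021/acs.est.3c09950 (anionic refits); Endo & Goss 2011 (neutral BSA); Endo, Bauerfeind & Goss 2012 (neutral structural protein)"
regressions:
  - charge_class: anionic
    protein_kind: BSA
    slope: 0.75
    intercept: 1.01
    source: "OLS refit, nine experimental anionic PFAS (BSA-water vs liposome-water)"
  - charge_class: anionic
    protein_kind: structural_protein
    slope: 0.46
    intercept: 1.50
    source: "OLS refit, nine experimental anionic PFAS (structural-protein-water vs liposome-water)"
  - charge_class: neutral
    protein_kind: BSA
    slope: 0.70
    intercept: 0.34
    source: "Endo & Goss 2011 serum-albumin LFER, rescaled from log Kow"
  - charge_class: neutral
    protein_kind: structural_protein
    slope: 0.52
    intercept: -0.27
    source: "Endo, Bauerfeind & Goss 2012 muscle-protein LFER, rescaled from log Kow"
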