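# Methods

This note documents the models implemented in `baselinetox`, their
assumptions, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## Dose metrics and the mass balance

A bioassay well holds medium (volume $V_\mathrm{medium}$) and cells
($V_\mathrm{cell}$); the nominal concentration is the dosed amount over
$V_\mathrm{tot} = V_\mathrm{medium} + V_\mathrm{cell}$. At steady state the
freely dissolved concentration is assumed equal in medium water and
cytosol — justified for the chemicals in scope because passive diffusion
dominates uptake even for anionic PFAS and there is no pH gradient across
the membrane under assay conditions. Sorption is attributed to two phases
per compartment, protein and lipid, giving the balance

C_nom · V_tot = C_free · (V_w + D_medium/w · V_pl,medium + D_cell/w · V_pl,cell)

where V_pl are the protein+lipid volumes and the composite ratios are
volume-weighted means over the sorptive phases, normalised to their
combined volume (units L_water / L_protein+lipid):

D_medium/w = (Vf_protein · D_BSA/w + Vf_lipid · D_lip/w) / (Vf_protein + Vf_lipid)

and analogously for cells with structural protein (muscle-type) replacing
serum albumin as the protein surrogate. The aqueous volume is taken as
$V_w = V_\mathrm{tot} - V_\mathrm{pl,medium} - V_\mathrm{pl,cell}$; since
all volume fractions are ≪ 1 this differs from $V_\mathrm{medium}$ by
well under 1% for every shipped system (asserted in the suite), so results
are insensitive to whether cell water is counted in $V_w$.

**Concentration-dependent binding.** Protein binding of several
perfluoroalkyl acids saturates: the distribution ratio falls with rising
free concentration, linear in log–log space (Freundlich-type,
`log10 D = slope · log10 C_free + intercept`, slopes typically −0.3 to 0).
With such a context the free-from-nominal inversion has no closed form and
is solved by damped fixed-point iteration on `log10 C_free` (damping 0.5,
tolerance |Δlog10| < 1e-11, ≤ 500 iterations, start at the no-sorption
limit). The tolerance is set one decade tighter than the 1e-9 relative
round-trip accuracy the suite demands, because successive-iterate
convergence bounds the solution error only up to the contraction factor.
Back-transformed ratios are floored at zero; slopes ≤ −1 emit a warning
(the balance may lose uniqueness) rather than an error. Evaluating a
Freundlich regression outside its stated concentration window warns but
proceeds — effect concentrations routinely sit at the edge of the measured
range, and hard-failing there would make the models unusable exactly where
they are needed.

## Baseline toxicity

Baseline (narcotic) cytotoxicity occurs at a constant critical membrane
burden, 69 mmol per liter of membrane lipid for 10% cytotoxicity,
independent of cell line and chemical. With liposome–water partitioning as
the membrane proxy:

IC10,free,baseline = 0.069 / D_lip/w   [mol/L]

The nominal prediction pushes this through the mass balance, with the
protein surrogates predicted from `log D_lip/w` by charge-class
regressions (`log D_protein/w = slope · log D_lip/w + intercept`):

| charge class | protein | slope | intercept | origin |
|---|---|---|---|---|
| anionic | BSA | 0.75 | 1.01 | OLS refit of the nine experimental anionic PFAS in the packaged reference table |
| anionic | structural protein | 0.46 | 1.50 | same refit |
| neutral | BSA | 0.70 | 0.34 | Endo & Goss 2011 serum-albumin LFER, rescaled from log K_ow via log K_lip/w = 1.01 log K_ow + 0.12 |
| neutral | structural protein | 0.52 | −0.27 | Endo, Bauerfeind & Goss 2012 muscle-protein LFER, rescaled likewise |

The two chemicals whose `log D_lip/w` is itself predicted rather than
measured (6:2 FTSA and the sulfonamide PFOSA) are excluded from the
anionic refits. The anionic coefficients exceed the neutral ones in both
slope and intercept for BSA — anionic PFAS bind proteins much more
strongly — which is why anionic and neutral chemicals need separate
baseline models: the two curves coincide below `log D_lip/w ≈ 2` and
separate above it, the anionic nominal prediction sitting up to ~8× higher
at `log D_lip/w = 6`. Partially charged chemicals (e.g. sulfonamides) are
grouped with the neutral model by default, overridable per chemical.
Cationic chemicals have no regression here and raise an error rather than
silently borrowing the neutral model.

**Empirical form.** The mechanistic curve is condensed into
`log10 IC10,nom,baseline = −(a + b·(1 − exp(−c · log10 D_lip/w)))`, three
parameters per assay × charge class. Packaged constants cover four
bioassays (PPARγ-GeneBLAzer, AREc32, AhR-CALUX, neurotoxicity — the middle
two share a medium and hence a curve) plus a generic 384-well system.
`fit_empirical_model` refits the form to any curve by unweighted least
squares in log10(IC10) space, with three restarts from fixed seeds
(42/43/44) perturbing a data-driven initial guess; the best residual wins,
so the fit is deterministic. The default sampling domain for condensing a
mechanistic curve is `log D_lip/w ∈ [0, 7]` at step 0.05. The fitted
parameters depend noticeably on that domain choice (the curvature
parameter c moves ~20% between plausible domains), so parameter-level
comparisons across sources are only meaningful at curve level; the suite
accordingly checks curve agreement (within a factor 2 over [1, 6], in
practice ≤ 1.27 for the generic anionic pair), not coefficient equality.

**Hydrophilic limit.** Below `log D_lip/w ≈ 2` sorption is negligible and
the nominal prediction collapses to the free one (within 1.5× at
`log D_lip/w = 1` for both charge classes in the generic system); this
limiting form is charge-class independent.

**Generic system presets.** The source tables give two inconsistent
compositions for the generic system; both ship rather than silently
picking one: `generic` (medium 0.3% protein / 0.001% lipid; cell 6% / 0.1%)
and `generic_text` (medium 0.3% / 0.007%; cell 3% / 0.5%). The four
assay-specific presets are approximations reconstructed from the published
medium recipes (FBS content), flagged as such in their provenance; users
with measured compartment compositions should supply their own config
(`mass_to_volume_fraction` converts BCA/vanillin mass concentrations to
volume fractions with protein density 1.36 kg/L, lipid 1 kg/L).

**Sensitivity structure** (verified by the suite and the acceptance
script): removing the cell compartment changes generic predictions by
< 1% (cells are 30 nL against 40 µL of medium), so medium composition is
what matters; zeroing the medium lipid moves the anionic curve by < 10%
everywhere (protein binding dominates for anions) but the neutral curve by
> 10% above `log D_lip/w = 4` — measure medium lipid if you work with
hydrophobic neutrals.

## Ratios and classification

TR = predicted baseline IC10 over experimental IC10, on either the free or
the nominal basis (identical in exact arithmetic when both concentrations
pass through the same partitioning context — asserted to 1e-9). SR =
predicted nominal baseline IC10 over an effect concentration (EC10, or
EC_SPR20 for antagonism at 20% suppression of the reference-agonist
signal). Bands: TR < 0.1 below the baseline band, 0.1–10 baseline, ≥ 10
specific; SR < 1 nonspecific, 1–10 moderate, ≥ 10 specific. The boundary
points are assigned upward (10 → specific, 1 → moderate) since the source
conventions mix strict and loose inequalities; full precision is kept
internally and summaries round to 2 decimals.

## Dose–response derivation

The default route fits a four-parameter log-logistic
(floor, ceiling, EC50, Hill slope) by least squares in log10-concentration
space — initial guesses from data quantiles, a single bounded local
optimisation, no randomness — and inverts the fitted curve in closed form
at the requested level (10% for IC10/EC10, 20% for EC_SPR20). Data that
cannot support a curve (fewer than 4 distinct concentrations, response
span < 5 percent points, fitted amplitude < 5%) raise errors instead of
returning spurious values; levels outside the observed response range are
flagged as extrapolated, or rejected when extrapolation is disallowed.

For curves whose observed effects stay low (the regime where a logistic
midpoint is unconstrained), the linear-portion method regresses response
on concentration over points with response ≤ 30% (≥ 3 required, intercept
fitted, not forced through the origin) and solves the line at 10%. The
30% cap keeps the secant error of the convex low-dose limb bounded: on
noise-free truncated curves the method lands within ~25% of the true EC10,
degrading as the cap rises. A nonpositive slope raises a no-effect error.

Cytotoxicity from confluency imaging is `100·(1 − exposed/control)`,
clipped to [0, 100]; wells more confluent than control (growth
stimulation) are clipped to 0 and flagged rather than reported negative —
a declared convention, since the source protocols do not address
stimulation.

## Synthetic validation: what it shows

The generator draws chemicals with `log D_lip/w` uniform on [1, 6] (the
PFAS range), places cytotoxic potencies exactly on the mechanistic
baseline model (ground-truth TR = 1) and effect potencies a specified
specificity factor below baseline, then renders 10-point 2-fold-dilution
4PL curves (Hill 1, floor 0, ceiling 100) with 3% additive Gaussian
response noise — the replicate scatter typical of imaging readouts. All
randomness flows from the scenario seed; identical seeds give byte-identical
files.

Under these conditions (sizes chosen to exercise the statistics at
screening scale: 200 curves for recovery statistics, 40 chemicals for the
end-to-end run) the log-logistic route recovers EC10 with ~10% median
absolute relative error, the linear route ~18% on curves truncated below
30% effect, the pipeline labels 100% of constructed baseline chemicals
"baseline", and every constructed factor-100 chemical returns SR ≥ 10.

What this does *not* show: real screening data have non-Hill curve shapes,
heteroscedastic and occasionally non-monotone responses (cytotoxicity
burst), solvent and volatility artifacts, and chemicals whose descriptors
are themselves uncertain. Passing the synthetic suite demonstrates the
pipeline's internal consistency and statistical behaviour under its own
assumptions, not field performance.

## Known limitations

- Uptake kinetics, active transport and headspace losses of volatiles
  (fluorotelomer alcohols) are out of scope; steady state is assumed.
- Charge class is user-supplied metadata; no pKa or speciation is
  computed, and no structure-based prediction of `log D_lip/w` is offered
  (the fluorinated-carbon calibration requires user-supplied calibration
  records).
- The neutral protein regressions are literature relationships rescaled
  from octanol–water space; their uncertainty propagates into the neutral
  baseline curves.
- Mixture toxicity (concentration addition of baseline toxicants) is not
  modeled.
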