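# Methods

## The model

`smadtif` implements a mass-action ODE model of canonical TGF-β/Smad
signaling with the nuclear regulator TIF1γ (TRIM33).  The core merges two
well-established published modules through their common junction species,
the internalized ligand-receptor complex in the endosome (`LRe`):

**Receptor trafficking.**  Surface type-I/II receptors (`RI`, `RII`) are
produced constitutively, internalize (`RI_e`, `RII_e`), recycle and
degrade.  Extracellular TGF-β drives trimolecular formation of the
surface complex `LR` (flux `k_a·[TGFβ]·[RI]·[RII]`), which is subject to
constitutive (`k_cd`) and ligand-induced (`k_lid`) degradation and
internalizes (`k_i`) to `LRe`.  `LRe` recycles its receptors back to the
surface (`k_r`, ~30 min); this slowly-draining endosomal pool is the
pathway's short-term memory and is what lets widely-spaced ligand pulses
either bridge or fail to bridge the gaps.  The source module is expressed
in molecules/cell and per-minute rates; at build time everything is
converted to nM and per-second using a cell volume of 2.27×10⁻¹² L
(1 nM ≈ 1367 molecules/cell).

**Smad nucleocytoplasmic shuttling.**  `LRe` phosphorylates cytoplasmic
Smad2 (`k_phos`); pSmad2 forms homomeric (`pS22`) and heteromeric
(`pS24`) complexes with Smad4 (`k_on_smad`/`k_off_smad`, Kd ≈ 8.9 nM) in
both compartments.  Monomeric Smads shuttle bidirectionally
(`k_in/k_ex`), complexes are only imported, 5.7-fold faster (`CIF`), and
a 1 nM nuclear phosphatase pool dephosphorylates monomeric nuclear pSmad2
(`k_dephos`).  The transcriptional readout is **pS24n**, the free nuclear
pSmad2–Smad4 pool (TIF1γ-bound ternary complexes are excluded; they are
reported separately).

**TIF1γ variants.**  Three mechanism hypotheses share this core:

* `REPRESSOR` — TIF1γ catalytically converts pS24n into free nuclear
  pSmad2 plus mono-ubiquitinated Smad4 (`S4ub_n`) in a single bimolecular
  step (rate `k_on_pS24nTIF1g`); the TIF1γ–Smad encounter complex is
  elided as too short-lived to track, exactly as the phosphatase is
  treated.  `S4ub_n` is exported (`k_in_S4ub`) and recycled to cytoplasmic
  Smad4 by the deubiquitinase FAM (`k_dub`, bimolecular).
* `COMPETITION` — TIF1γ reversibly sequesters nuclear pSmad2 and nuclear
  Smad4 (both with the pSmad2–Smad4 kon/koff); no ubiquitination.
* `INTEGRATED` — TIF1γ binds pS24n to a transient ternary complex
  (`pS24nTIF1g`, same kon/koff as pSmad2–Smad4) which either dissociates
  back or resolves (`k_ub`) into a pSmad2–TIF1γ complex (`pS2nTIF1g` — its
  only source) plus `S4ub_n`; export and FAM recycling as above.
* `BASE` — the TIF1γ-free merged core, used for reduction identities.

Smad2, Smad4, TIF1γ, FAM and the phosphatase are neither synthesized nor
degraded: their membership-count vectors lie in the left null space of the
stoichiometric matrix, which is asserted at build time and verified along
every trajectory (relative drift < 10⁻⁶; in practice ~10⁻¹⁴).

## Compartments and flux semantics

Five compartments: extracellular (10⁻¹⁰ L per cell, relevant only under
ligand depletion), plasma membrane and endosome (bookkept at the
2.27×10⁻¹² L cell volume, following the molecule-count convention of the
trafficking module), cytoplasm (2.27×10⁻¹² L) and nucleus (1.0×10⁻¹² L).
Reaction fluxes are amounts per time (`k · Π concentrations · V_location`);
each species' ODE divides by its own compartment volume, so transport
conserves amount exactly and import/export constants produce the familiar
concentration-ratio factors (e.g. Smad4 export is set to
`k_in_smad4·V_cyt/V_nuc` so unstimulated Smad4 distributes evenly).  This
is also SBML's semantics, which makes the SBML round trip exact to
floating-point (≈10⁻¹⁵ relative on the right-hand side).

## Parameters

All constants live in `smadtif.parameters.DEFAULTS` (nM, seconds) with a
flat `symbol: value unit` file format.  Receptor constants are the
trafficking module's published per-minute values converted to seconds,
with receptor production 8 molecules·min⁻¹·cell⁻¹ → 9.75×10⁻⁵ nM/s.
Shuttling constants are the nucleocytoplasmic-shuttling module's values
(kon 1.8×10⁻³ /(nM·s), koff 1.6×10⁻² /s, import 2.6×10⁻³ /s, CIF 5.7,
dephosphorylation 6.57×10⁻³ /(nM·s) against a 1 nM phosphatase).  Initial
totals: Smad2 60.6 nM, Smad4 50 nM, phosphatase 1 nM, TIF1γ 10 nM
(default; scans vary it), FAM 1 nM.

The TIF1γ module is pinned by equal-kinetics conventions rather than free
constants: ternary kon/koff equal the pSmad2–Smad4 constants; the
pSmad2–TIF1γ and Smad4–TIF1γ dissociations equal the same koff;
deubiquitination equals the dephosphorylation constant; Smad4ub nuclear
export is twice the Smad4 import constant (ubiquitinated Smad4 is less
efficiently retained in the nucleus).  The one constant without a direct
counterpart, the intra-complex ubiquitination rate `k_ub`, is set to
6.57×10⁻³ s⁻¹ — the effective dephosphorylation propensity at the 1 nM
phosphatase pool — implementing the "ubiquitination/deubiquitination
similar to phosphorylation/dephosphorylation" convention.

**Merge calibration.**  The shuttling module's phosphorylation constant
was fitted against that model's own receptor-activity scale, which the
merge replaces by `LRe` in nM (≈2.5 nM at 10 nM TGF-β).  `k_phos` is
therefore recalibrated to 1.5×10⁻² /(nM·s), giving an effective
phosphorylation propensity of ~0.04 s⁻¹ at saturating ligand (the source
model's fitted scale) and making the dose response saturate above 1 nM
TGF-β while 0.1 nM stays clearly sub-saturating — the regime the merged
model is designed to reproduce.  Peak pS24n then occurs ~1 h after
stimulation onset, consistent with observed pSmad2 kinetics.

**Sensitivity-scan operating point.**  One-at-a-time scans default to
TIF1γ = 5 nM (TIF1γ/Smad4 ratio 0.1, below the ternary Kd), the basal
endogenous regime of the epithelial cells the model describes.  There the
Smad4 ubiquitination/recycling cycle, not ternary-complex equilibrium,
controls the response, and the export constant `k_in_S4ub` dominates the
sensitivity ranking.  At TIF1γ ≳ 10 nM ternary sequestration takes over
and the formation/dissociation constants dominate instead; both regimes
can be explored through the `tif1g_level` argument.

## Stimulation protocols and integration

Protocols are piecewise-constant ligand inputs: none, sustained, finite
window, or disjoint pulse trains.  Without depletion the ligand is an
input clamp; with depletion it becomes an extracellular state variable
consumed stoichiometrically by complex formation (diluted into the
10⁻¹⁰ L medium share per cell) and the protocol only delivers boluses.
A pulse train with interval equal to pulse width is identical to
sustained stimulation by construction.

Before any stimulation the ligand-free system is relaxed to steady state
(max |dc/dt| < 10⁻¹⁰ nM/s) and that state is the t = 0 condition; the
basal state is cached per system.  Integration uses `scipy`'s LSODA
(stiff-capable, adaptive; BDF available) at rtol 10⁻⁸ / atol 10⁻¹² nM,
restarting at every protocol discontinuity so edges are never smeared,
and reports on the user grid with all edge times inserted.  Concentration
undershoots below −10⁻⁹ nM warn and clamp; below −10⁻⁶ nM they abort as a
solver failure.  Scan summaries sharpen the discrete peak with a local
parabolic refinement; duration scans sample at a constant 120 s so the
refinement error is identical across durations and the
response-vs-duration profile stays monotone.

## Scans and summary statistics

All scans summarize peak pS24n (the model's transcriptional proxy;
AUC is available in the fitting stage).  The variant scan varies TIF1γ
0–50 nM at 10 nM sustained ligand.  The sensitivity index of a constant
is (max − min)/reference of peak pS24n over multipliers {¼, ½, 1, 2, 4}.
Dose scans use sustained inputs; duration scans use windows followed 12 h
past ligand removal; response surfaces scan TIF1γ/Smad4 ratio × duration
with Smad4 fixed at 50 nM and normalize to 100% at the global maximum.
Pulse comparisons classify a train as "sustained-like" when, after the
first interval, its troughs stay ≥ 50% of the sustained curve at the same
times (threshold configurable; there is no canonical value).

## Synthetic experiment and fit

The wet-lab stage is emulated, not downloaded.  `synth` generates
(ratio, fold-change) datasets centred on `a·curve(ratio) + b`, where
`curve` is the model's peak-pS24n response normalized to ratio 0;
default noise is mean-centred multiplicative lognormal at 10% with
triplicates, matching qPCR fold-change scatter (fold-changes are
ratio-scale and strictly positive).  A knockdown generator produces
single-exponential siRNA recovery time courses for the TIF1γ/Smad4 ratio
axis.  `fit_scaling` recovers (a, b) by (optionally 1/sd²-weighted)
linear least squares; the affine form reflects the fold-change floor of
unresponsive genes, with a pure-scale alternative.  Genes are fitted
separately by default.  What passing these tests shows is that the
pipeline is unbiased and correctly wired under its own noise model; it
does not validate the noise model against real qPCR data, and real
experiments add ratio-measurement error (densitometry) that the generator
does not emulate.

## Numerical and design notes

* Variant-reduction identity (INTEGRATED with TIF1γ = 0 vs BASE) is
  checked at rtol 10⁻¹¹ so solver error does not mask structural
  differences; agreement is ~10⁻¹¹ relative.
* The fixed-step RK4 oracle uses dt = 0.05 s (≲ 1% of the fastest
  timescale at 10 nM ligand) over a 30-min horizon.
* Ties in peak detection resolve to the earliest time.
* SBML export targets Level 3 Version 1 with explicit mass-action
  formulas and declared units; import accepts exactly that subset and
  rejects anything else with the offending reaction id.  Conserved-group
  membership is re-inferred from the species catalog on import.
* The five-compartment table is explicit; no volume ratio is hard-coded.

## Known limitations

* Kinetic constants come from the published receptor-trafficking and
  Smad-shuttling literature plus the equal-kinetics conventions above;
  the model is built to reproduce qualitative regime behaviour, not to
  match any specific cell line's measured curves point-for-point.
* The pSmad2–TIF1γ complex uses the fast generic koff; as a result its
  response saturates within ~1 h, and the "needs long stimulation"
  character of that output appears only weakly (the surface is nearly
  flat in duration at high ratio).  Making that dissociation slow —
  plausible given reported chromatin persistence of Smad2–TIF1γ — would
  lock up TIF1γ within minutes and abolish the graded suppression, so it
  is not done.
* No Smad3, no transcription/translation, no stochastic or spatial
  effects; ligand depletion is a simple stoichiometric sink without
  matrix sequestration.
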