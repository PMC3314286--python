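# smadtif — TIF1γ regulation of TGF-β/Smad signaling, as ODE models

TIF1γ (TRIM33) has been reported both as a repressor of TGF-β signaling —
mono-ubiquitinating Smad4 inside phospho-Smad2–Smad4 complexes and expelling
it from the nucleus — and as an alternative transcription partner of
phospho-Smad2.  `smadtif` is a systems-biology package for weighing those
mechanisms quantitatively.  It implements a mass-action ODE model that
merges receptor trafficking (with its endosomal ligand–receptor "memory"
pool, LRe) and Smad nucleocytoplasmic shuttling, and adds three TIF1γ
mechanism variants on top of that shared core:

* **REPRESSOR** — catalytic conversion
  `TIF1γ + pS24n → TIF1γ + pS2n + Smad4ub_n`, with Smad4ub exported
  (`k_in-S4ub = 2 × k_in-Smad4`) and recycled in the cytoplasm by the
  deubiquitinase FAM/USP9x;
* **COMPETITION** — reversible sequestration of nuclear pSmad2 and Smad4
  by TIF1γ, no ubiquitination;
* **INTEGRATED** — a transient ternary complex
  `pS24n + TIF1γ ⇌ pS24nTIF1γ → pS2nTIF1γ + Smad4ub_n`,
  whose resolution is the only source of the pSmad2–TIF1γ complex,
  followed by the same export/recycling cycle.

The transcriptional readout throughout is **pS24n**, the free nuclear
phospho-Smad2–Smad4 pool (nM).  The package provides the simulation
engine (stiff adaptive integration with exact protocol-edge handling and
ligand-depletion support), the computational experiments (TIF1γ scans,
one-at-a-time sensitivities, dose/duration responses, ratio×duration
response surfaces, pulsed-stimulation comparisons), a synthetic-data
generator emulating the knockdown-recovery qPCR experiment, an affine
transcription-scaling fit, and SBML L3V1 export/import.

It is aimed at modelers who want to reuse or interrogate the model
(species, reactions and parameters are first-class objects, exportable to
SBML) and at analysts probing the headline questions: which
mechanism is compatible with a *graded* TIF1γ effect, and why the
TIF1γ/Smad4 ratio — via the Smad4 ubiquitination/recycling cycle — is the
control variable of the response.

## Worked example

```python
import smadtif as st

system = st.build_model("INTEGRATED", init={"TIF1g_n": 25.0})
traj = st.simulate(system, st.StimulusProtocol.sustained(10.0))  # 24 h
peak, t_peak = st.peak_response(traj, "pS24n")
print(f"peak pS24n = {peak:.2f} nM at t = {t_peak/3600:.2f} h")
```

```
peak pS24n = 21.38 nM at t = 0.90 h
```

The TIF1γ-free core peaks at 45.56 nM, so 25 nM TIF1γ suppresses the
integrated model's response by ~53%.  Running the variant comparison
(`python analysis/01_variant_comparison.py`) prints the headline contrast
at the same TIF1γ level — repressor ≈ 89% suppression (near-total),
competition ≈ 12% (slight), integrated in between and graded across the
whole 0–50 nM range.

The fitting stage maps the model onto fold-change measurements
(`python analysis/06_ratio_fit.py`):

```
relative pS24n curve: 0.0:1.000, 0.1:0.879, 0.2:0.764, 0.4:0.557, ...
CDH2: true (a=3.0, b=1.0) -> fitted (a=3.359, b=0.874), rss=2.600
CDH11: true (a=2.0, b=1.0) -> fitted (a=2.045, b=0.946), rss=0.959
```

i.e. the model's normalized pS24n-vs-ratio curve, affinely scaled,
recovers the simulated qPCR fold-changes of two target genes from noisy
triplicates.

The numbered scripts under `analysis/` run the full set of computational
experiments and write their tables to `results/`.  A CLI mirrors them
(`smadtif simulate|scan-tif1g|sensitivity|dose|duration|surface|pulses|synth|fit|export-sbml`),
each run leaving a manifest with a config hash for reproducibility.

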