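# atpfret

Single-cell quantification of organelle-targeted FRET ATP biosensor
recordings, and a fully synthetic test bed for it.

Genetically encoded ATP sensors (ATeam-style, CFP donor / YFP acceptor)
report compartment ATP through their emission ratio R = I_YFP / I_CFP.
Recording R(t) in the cytosol, mitochondrial matrix and ER while the
perfusion buffer switches hexoses (glucose ⇄ none / mannose / 2-deoxyglucose)
or adds mitochondrial inhibitors (oligomycin, antimycin A) exposes a cell's
metabolic setting: glycolytic cells lose mitochondrial ATP when glucose is
withdrawn, oxidative cells lose it when the ATP synthase is blocked. This
package implements the whole quantification chain —

1. background subtraction per channel, YFP/CFP ratio, optional
   mono-exponential photobleach correction, baseline normalization;
2. per-cell features: basal ratio, transient peak amplitude after hexose
   withdrawal, onset of decrease, depletion minimum, maximal signed changes
   Δ_glc and Δ_oligo, peak width (FWHM);
3. the two-axis metabolic fingerprint (Δ_glc, Δ_oligo) with rule-based or
   2-means classification into glycolytic / oxidative / intermediate, and
   the standard group statistics (Student's t, one-way ANOVA + Tukey HSD);
4. SIM-style colocalization: Pearson on unthresholded pixels, Manders M1/M2
   on Costes-auto-thresholded image pairs;

— together with a synthetic-data generator: a seven-state compartmental ODE
model (reversible outer-membrane hexokinase coupled to the matrix ATP pool,
ANT exchange, forward/reverse ATP synthase, glycolysis, ER import) and a
fluorescence forward model (Hill-binding sensor, donor quench / sensitized
acceptor emission, bleaching, background, read noise). Five calibrated cell
archetypes (`hela_like`, `beta_like`, `mef_young_like`, `mef_old_like`,
`mfn2_ko_like`) span the glycolytic-to-oxidative range. See
`docs/methods.md` for the model, its assumptions and its limits.

## Worked example

Simulate a mixed population through the two-phase fingerprint protocol
(glucose removal, then oligomycin while glucose-free), run the analysis
chain, and classify each cell:

```python
from atpfret import RunConfig, run_synthetic_experiment

cfg = RunConfig(populations={"hela_like": 15, "beta_like": 15},
                cv=0.3, seed=20240904)
bundle = run_synthetic_experiment(cfg)
print(bundle.fingerprint.groupby("group")[["delta_glc", "delta_oligo"]].mean())
print(bundle.stats["classification_agreement"])
```

The analysis drivers under `analysis/` run the same machinery at a larger
scale; `python analysis/04_metabolic_fingerprint.py` prints

```
75 cells, classification agreement with generating archetype: 100.0%
  beta_like        delta_glc +0.076 delta_oligo -0.507  settings: {'oxidative': 15}
  hela_like        delta_glc -0.584 delta_oligo +0.042  settings: {'glycolytic': 15}
  mef_old_like     delta_glc +0.084 delta_oligo -0.371  settings: {'oxidative': 15}
  mef_young_like   delta_glc -0.526 delta_oligo +0.058  settings: {'glycolytic': 15}
  mfn2_ko_like     delta_glc +0.094 delta_oligo -0.488  settings: {'oxidative': 15}
```

Read: glycolytic settings (cancer-cell-like, young fibroblast) lose half
their normalized mitochondrial ratio on glucose removal and gain slightly
on oligomycin (reverse-mode synthase blocked); oxidative settings
(beta-cell-like, senescent and Mfn2-null fibroblasts) are barely touched by
removal but crash under oligomycin. Δ values are maximal changes of the
normalized ratio, dimensionless.

The other drivers cover compartment-resolved removal responses (`01`),
hexokinase-dependence of the transient peak, onset statistics and hexose
substitution (`02`), repeated depletion and the mannose-withdrawal peak
with/without oligomycin (`03`), and colocalization (`05`). Each writes its
tables to `results/`.

External recordings enter through the same chain via a trace CSV
(`time_s, cell_id, compartment, cfp, yfp, bg_cfp, bg_yfp`) or multi-page
TIFF (axes TCYX), plus a protocol YAML; see the `atpfret` command line
(`atpfret simulate / analyze / fingerprint / coloc / report`).

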