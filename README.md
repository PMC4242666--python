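# casr-coop

Quantitative analysis of functional cooperativity of the calcium-sensing
receptor (CaSR), a family C GPCR whose "toggle" hinge-region mutations
(L173P/L173F, P221Q/P221L) inactivate or activate the receptor and cause
familial hypocalciuric hypercalcemia or autosomal dominant hypocalcemia.

The package is built for researchers analysing CaSR signalling data: it
quantifies single-cell Ca²⁺-oscillation patterns from ratiometric
(Fura-2-style) imaging under stepwise [Ca²⁺]ₒ protocols, fits Hill and
biphasic-Hill concentration-response models to population readouts
([Ca²⁺]ᵢ, IP₁ accumulation, ERK₁/₂ phosphorylation, L-Phe responses),
quantifies heterotropic shifts produced by the allosteric modulator L-Phe,
and analyses residue-motion coupling in structural ensembles
(cross-correlation maps and essential-dynamics PCA). A synthetic-data
module generates every input modality with known ground truth, so the
entire pipeline is testable end to end without any deposited data.

## The models

**Oscillation pattern.** A cell's [Ca²⁺]ᵢ oscillation pattern under a
stepwise [Ca²⁺]ₒ ramp is summarised by three parameters: the *starting
point* (lowest [Ca²⁺]ₒ step with ≥ 3 successive peaks after the
step-change transient), the *frequency* (qualifying peaks per minute at a
designated step), and the *ending point* (lowest step at which oscillation
ceases on a sustained plateau).

**Cooperativity.** Concentration-response curves follow the Hill equation

    r(c) = r0 + (rmax − r0) · cⁿ / (EC50ⁿ + cⁿ)

where n > 1 reflects positive homotropic cooperativity among the
receptor's Ca²⁺-binding sites. Loss-of-function mutants can split the
curve into two phases, modelled as an amplitude mixture
r0 + A·[f·h₁(c) + (1−f)·h₂(c)] of unit Hill terms with EC50₁ < EC50₂.
The heterotropic effect of L-Phe is quantified as ΔEC50 and Δn between
fits with and without the modulator. IP₁ competition-assay data are first
transformed to percent inhibition, (1 − stimulated/unstimulated) × 100.

**Dynamics.** For a coordinate ensemble (one point per residue), the
dynamic cross-correlation map is C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)
∈ [−1, 1]; essential-dynamics PCA ranks collective motions by the
eigenvalues of the coordinate covariance. Inter-site coupling scores
summarise the correlation block between two residue sets.

## Worked example

```python
import casr_coop as cc

preset = cc.get_preset("WT")
dr = cc.simulate_dose_response(preset.cai, preset.dose_conc_mM,
                               noise_cv=0.05, replicates=3, seed=42)
result = cc.HillModel(cc.normalize_to_max(dr)).fit()
print(result.summary())
```

```
Hill concentration-response fit
==============================================
readout: ca_i    phe_mM: 0
n_obs: 30    RSS: 0.009804    AICc: -231.19
converged: True
----------------------------------------------
 param     estimate      std err
  ec50        3.041      0.03299
     n        3.706       0.1366
    r0     0.003138     0.008144
  rmax        1.018      0.00995
```

The fit recovers the wild-type generator's ground truth (EC50 3.0 mM,
Hill coefficient 3.7) from noisy replicates: a strongly cooperative
response with half-maximal activation at 3.0 mM extracellular Ca²⁺.
Adding the allosteric modulator left-shifts the curve:

```python
with_phe = cc.HillModel(cc.simulate_dose_response(
    preset.cai_phe, preset.dose_conc_mM, 0.05, 3, seed=43)).fit()
shift = cc.heterotropic_shift(result, with_phe)
print(f"EC50 shift by 5 mM L-Phe: {shift.delta_ec50:.2f} mM "
      f"(ratio {shift.ec50_ratio:.2f}), delta n = {shift.delta_n:.2f}")
```

```
EC50 shift by 5 mM L-Phe: 1.11 mM (ratio 0.64), delta n = 1.17
```

Single-cell oscillation analysis of a simulated imaging field:

```python
proto = preset.protocol()
traces, truth = cc.simulate_population(preset.population_params(50), proto, seed=1)
feats = [cc.analyze_trace(t, freq_at_mM=3.0) for t in traces]
summary = cc.summarize_population(feats, [0.0] + [s.ca_mM for s in proto.steps])
print(f"oscillatory: {summary.fraction_oscillatory:.2f}, "
      f"modal start {summary.modal_start_mM()} mM, modal end {summary.modal_end_mM()} mM, "
      f"freq {summary.mean_freq:.2f} +/- {summary.se_freq:.2f} peaks/min")
```

```
oscillatory: 0.96, modal start 3.0 mM, modal end 5.0 mM, freq 1.33 +/- 0.00 peaks/min
```

Most cells start oscillating at the 3.0 mM step, plateau at 5.0 mM and
oscillate at ≈ 1.3 peaks/min there — the wild-type phenotype the
generator encodes.

## Command line

```sh
casr-coop simulate-traces --preset WT --n-cells 50 --seed 1 --out simdir/
casr-coop oscillations --traces simdir/traces.csv --protocol simdir/protocol.json \
          --freq-at 3.0 --out oscdir/
casr-coop simulate-dose --preset P221Q --readout ip1 --out ip1.csv
casr-coop fit-dose --data ip1.csv --model auto
casr-coop simulate-ensemble --spec examples/covariance_spec_example.json \
          --n-frames 2000 --out ens.pdb
casr-coop dccm --ensemble ens.pdb --no-superpose --out dccm.csv
casr-coop site-coupling --dccm dccm.csv --sites examples/sites_example.json \
          --site-a site1 --site-b site3
casr-coop run --config examples/run_example.yaml
```

Construct presets: `WT`, `L173F`, `P221L` (gain of function), `L173P`,
`P221Q` (loss of function), each with and without 5 mM L-Phe.

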