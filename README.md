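# bst1map

Bloch–Siegert B1 mapping and B1-corrected variable-flip-angle (VFA) T1
relaxometry, with inversion-recovery (IR) gold-standard validation and
test–retest reproducibility statistics.  Built for quantitative breast MRI
at 3 T, where transmit-field (B1) inhomogeneity of tens of percent across
the field of view biases VFA T1 maps — and through them any downstream
pharmacokinetic analysis that needs the precontrast T1.

## What it does

1. **B1 mapping.**  An off-resonant RF pulse imparts a phase on the
   magnetization proportional to B1² without exciting it (the
   Bloch–Siegert shift).  From a pair of images at opposite frequency
   offsets, the per-voxel phase of `img₊·conj(img₋)` is converted to B1 by
   inverting a phase-versus-B1 lookup table generated by Bloch-equation
   simulation of the actual pulse, and then to a flip-angle correction
   factor f = actual/prescribed angle.

2. **T1 mapping.**  Voxelwise least-squares fits of the spoiled
   gradient-echo model

       S(α) = S0·sin(f·α)·(1 − E1)/(1 − E1·cos(f·α)),  E1 = exp(−TR/T1)

   with f from the B1 map (or f ≡ 1, uncorrected), and of the magnitude
   inversion-recovery model

       S(TI) = S0·|cos α_inv·(1 − e^(−TD/T1))·e^(−TI/T1) + 1 − e^(−TI/T1)|

   as the gold standard.

3. **Statistics.**  Accuracy versus IR (percent error, Lin's concordance
   correlation, subject-level bootstrap of the mean absolute-deviation
   difference) and Bland–Altman test–retest reproducibility (rMSD,
   t-based 95% CI of the mean difference, wSD, repeatability coefficient
   r = 2.77·wSD, coefficient of variation, plus Shapiro–Wilk / Wilcoxon /
   Kendall pre-checks).

4. **Synthetic phantoms.**  An 8-tube gel phantom (T1 300–1600 ms) and a
   two-tissue breast phantom (adipose 420 ms, fibroglandular 1290 ms) with
   configurable smooth B1 fields and Rician noise, plus forward simulation
   of all three acquisitions — so the entire chain is testable end to end
   with no data downloads.

## Worked example

Run the noiseless gel-phantom study (simulate → B1 map → three T1 fits →
per-tube report):

```python
from bst1map import RunConfig, run_phantom_study
from bst1map.synthetic import NoiseSpec

cfg = RunConfig(study="phantom", seed=1, outdir="out/phantom",
                noise=NoiseSpec(model="none"))
table = run_phantom_study(cfg)["table"]
print(table[["roi", "ir_mean_ms", "vfa_mean_ms", "vfa_pct_err",
             "vfa_b1_mean_ms", "vfa_b1_pct_err"]].to_string(index=False))
```

```
   roi  ir_mean_ms  vfa_mean_ms  vfa_pct_err  vfa_b1_mean_ms  vfa_b1_pct_err
tube_1       322.0   225.706825           30      322.120485               0
tube_2       328.0   273.561325           17      328.103321               0
tube_3       835.0   817.504645            2      835.225146               0
tube_4       843.0   957.847072           14      843.196079               0
tube_5      1004.0   703.262567           30     1004.376299               0
tube_6      1478.0  1232.431408           17     1478.466076               0
tube_7      1500.0  1468.583958            2     1500.404274               0
tube_8      1558.0  1770.099834           14     1558.362124               0
```

Reading: with a left–right transmit ramp of f ∈ [0.8, 1.1] across the
phantom, the uncorrected VFA T1 is biased by roughly f² − 1: tubes sitting
where f < 1 read low (tube 1, at the f ≈ 0.84 edge, reads 226 instead of
322 ms) and tubes where f > 1 read high (tube 8 reads 1770 vs 1558 ms),
giving 2–30% error depending on lateral position — while the
Bloch–Siegert-corrected fit recovers every tube to well under 1% of the IR
value.  On a synthetic 16-subject test–retest cohort
(`run_cohort_study`), the same correction cuts the mean percent error
from ~7–10% to ~2%, raises the concordance correlation from ~0.5–0.6 to
~0.96, and shrinks the repeatability coefficient four- to six-fold in both
tissues — the same pattern, directionally, as in vivo breast data.

The command line mirrors the library:

```sh
bst1map run-phantom --seed 1 --outdir out/phantom
bst1map run-cohort  --seed 1 --outdir out/cohort
bst1map simulate --outdir out/session && bst1map fit out/session/vfa.json \
    --b1-sidecar out/session/bs.json --out out/t1.nii
```

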