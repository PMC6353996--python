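# fpolimg

Quantitative single-cell analysis of **methylene-blue (MB) fluorescence
polarization imaging**, the modality in which cancer cells can be
discriminated from normal epithelial cells by the rotational mobility of an
exogenous dye. The package implements the full analysis chain around three
measurements on live cells:

1. **Fluorescence polarization (Fpol).** From registered co- and
   cross-polarized 8-bit images, the per-pixel and per-cell polarization is

   ```
   Fpol = (I_co − G·I_cross) / (I_co + G·I_cross)
   ```

   where `G` is the instrument G-factor, calibrated from a reference dye
   solution of known (zero) polarization. Images are thresholded
   (inclusive bounds, default low 2 / high 254, jointly in both channels)
   to remove background and saturated pixels; per-cell statistics apply the
   formula once to the mean intensities of a compartment (whole cell,
   cell with the nucleus excluded, or nucleus alone).

2. **Co-localization.** Pearson's correlation of the MB channel with an
   organelle-tracker channel over each cell's ROI.

3. **Fluorescence lifetime (FLIM).** Bi-exponential reconvolution fitting
   of TCSPC decay histograms by Poisson maximum likelihood,
   `IRF ⊛ (a1·e^(−t/τ1) + a2·e^(−t/τ2)) + b`, with a reduced-χ²
   acceptance gate of [1.0, 1.5] and the amplitude-weighted lifetime
   `τ = (a1τ1 + a2τ2)/(a1 + a2)`.

Group-level reporting summarizes per-cell values as mean ± SE over N cells,
computes cancer-vs-normal percent differences (normal line as denominator),
and tests differences with a hierarchical permutation test that respects the
experiment (replicate) structure.

Because raw microscope data for this modality are rarely shareable, the
`synthetic` module generates every input with known ground truth —
polarized image pairs with prescribed per-compartment Fpol, multi-channel
stacks with controlled channel co-occupancy, and Poisson TCSPC decays with
known lifetimes — so the whole pipeline is validated end to end.

## Worked example

```python
import numpy as np
from fpolimg import (CellFieldSpec, DecaySpec, generate_polarized_pair,
                     generate_decay, cell_fpol_table, fit_biexponential,
                     summarize)

# a field of 100 cells: cytoplasm Fpol 0.20, nucleus 0.24, G = 0.75, shot noise
spec = CellFieldSpec(n_cells=100, fpol_cytoplasm=0.20, fpol_nucleus=0.24,
                     g_factor=0.75, noise_model="poisson", seed=4)
pair, labels, truth = generate_polarized_pair(spec)
table = cell_fpol_table(pair, labels, g=0.75)
for comp in ("whole_cell", "excl_nucleus", "nucleus"):
    s = summarize(table[table.compartment == comp].fpol, group=comp)
    print(f"{comp:13s} {s.mean:.4f} ± {s.se:.4f} (N={s.n_cells})")

# a 10^6-photon decay at cancer-cell lifetimes, fitted by reconvolution
fit = fit_biexponential(generate_decay(DecaySpec(tau1_ns=0.27, tau2_ns=0.75,
                                                 a1=1.5, a2=1.0, seed=5)))
print(f"tau1={fit.tau1_ns:.3f} ns  tau2={fit.tau2_ns:.3f} ns  "
      f"tau_amp={fit.tau_amp_ns:.3f} ns  chi2={fit.chi2_reduced:.2f}")
```

Output:

```
whole_cell    0.2106 ± 0.0004 (N=100)
excl_nucleus  0.2005 ± 0.0004 (N=100)
nucleus       0.2408 ± 0.0008 (N=100)
tau1=0.270 ns  tau2=0.748 ns  tau_amp=0.462 ns  chi2=0.98
```

The per-compartment means recover the prescribed ground truth (the
whole-cell value is the area-weighted mixture of nucleus and cytoplasm),
and the decay fit recovers both lifetimes to well under a percent at this
photon budget.

A command-line interface mirrors the library
(`fpolimg simulate | calibrate-g | fpol | coloc | flim | report`); see
`fpolimg --help`.

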