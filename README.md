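# chromatophore

Quantitative pipeline for the structural-color biology of squid
(*Doryteuthis pealeii*) chromatophore organs. Chromatophores are
neuromuscular pigment organs: radial muscles expand a pigment-filled cell
(the chromatocyte) into a colored disc, and the reflectin-containing sheath
cells wrapping it can produce dynamic iridescence. This package implements
the computational analyses such a study rests on, with a synthetic-data
generator standing in for the deposited raw data, so every stage is
runnable and testable offline.

## What it computes

**Spectral-count proteomics.** Label-free protein quantitation across
chromatophore color classes. For protein *p* in sample *s* with spectral
count *c₍p,s₎*, loading factor *f_s = T_s / T_ref* (column-total ratio,
reference fixed at 1) and expected tryptic peptide count *k_p*:

    AI₍p,s₎ = (c₍p,s₎ / f_s) / k_p × k̄

where *k̄* is the dataset-average expected peptide count. *k_p* comes from
in-silico trypsin digestion (cleavage C-terminal to K/R, suppressed before
P, configurable missed cleavages and length/mass filters). Category
breakdowns, contaminant filtering (bacterial ribosomal proteins,
preparation enzymes), and the identification/annotation acceptance rules
(protein score ≥ 22, discriminant ≥ 0.0, peptide expectation ≤ 0.01; BLAST
e-value ≤ 1e-10; S-crystallin call at coverage > 90% and identity > 60%)
are included.

**Thin-film interference optics.** The alternating sheath-cell
cytoplasm/membrane stack (measured 116 ± 102 nm and 71 ± 14 nm) is modeled
both by the two-beam constructive-interference condition

    m·λ = 2 (n_a d_a cos θ_a + n_b d_b cos θ_b)

and by the full transfer-matrix (characteristic-matrix) reflectance, with
expansion-driven layer thinning (areal factor up to 15×, volume conserved)
and CIE-1931 rendering of the perceived sRGB color. The model predicts the
blue shift of reflected color as the organ expands.

**Pigment spectra.** Xanthommatin absorption spectra from excited-state
line lists (wavelength + oscillator strength) by Lorentzian broadening with
FWHM 30 nm, and a two-state Henderson–Hasselbalch fit of
absorbance-at-430 nm titration series returning the midpoint pK.

**ROI color dynamics.** Per-frame mean RGB over a fixed region of interest
(default 20 × 20 px, 0.03 s/frame) from PNG/TIFF frame stacks.

## Worked example

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_digest_and_quantify.py
python analysis/03_interference_model.py
```

prints (seed 1):

```
mean expected peptides k̄ = 28.0 over 50 proteins
loading factors (yellow = 1): yellow: 1.00, red: 2.20, brown: 1.80
Spearman rho(abundance index, true abundance) = 0.995
measured means: d_a = 141.4 nm (n=292), d_b = 70.7 nm (n=237)
two-beam λmax = 582.4 nm; transfer-matrix peak = 581.5 nm (Δ = 0.9 nm)
expansion 1→2× blue-shifts the peak by 290 nm (582 → 291 nm)
```

The loading factors recovered from the synthetic table's column totals are
exactly the distortions the generator planted (1/2.2/1.8 for
yellow/red/brown); the abundance index recovers the true abundance ranking
at ρ = 0.995; and the two-beam prediction agrees with the full-wave
reflectance peak to ~1 nm, shifting blue as the stack thins —
the iridescence mechanism the model quantifies.
`analysis/04_pigment_titration.py` and `analysis/05_color_dynamics.py`
cover the pigment and imaging stages the same way. The `chromatophore` CLI
(`digest`, `quant`, `annotate`, `contaminants`, `optics`, `trace`,
`simulate`) exposes each stage for file-based use.

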