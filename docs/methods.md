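# Methods

## Tryptic digestion and peptide scaling

Trypsin cleaves the peptide bond C-terminal to lysine or arginine; the
proline rule (on by default) suppresses cleavage when the next residue is
proline. A cleavage at the protein C-terminus is a no-op, so a terminal K/R
never produces an empty peptide. With `missed_cleavages = m`, every run of
up to `m + 1` adjacent fully-cleaved fragments is emitted, giving
`Σ_{j=0..m} max(F − j, 0)` peptides from `F` fragments. Length and
monoisotopic-mass filters (masses via pyteomics) drop peptides from the
reported list while the unfiltered list stays recoverable; `X` residues are
accepted and contribute zero mass when a mass window is active.

Default digest parameters are 0 missed cleavages, proline rule on, and no
filters. The dataset-average expected peptide count `k̄` is always
recomputed from the protein set in hand (the study's 469-entry chromatophore
database averages 65.5; the exact digest settings behind that figure are
not published, so all parameters are exposed for sweeping).

## Spectral-count quantitation

Loading factors are column-total ratios `f_s = T_s / T_ref` with the
reference factor fixed at 1. The reference defaults to the sample with the
smallest total, which makes every factor ≥ 1 and reproduces the convention
of fixing the yellow sample at 1; any sample can be named instead. Loading
normalization is applied before peptide scaling; the reference column is
unaffected by the order. A granule mode (`loading_normalize=False`) skips
the loading step entirely, because granule/pigment preparations are
deliberately not loading-normalized.

The abundance index `AI = (c/f_s)/k_p × k̄` is reported both as a float and
as a nearest-integer view (rounding half away from zero), since published
"normalized peptide counts" are integers and it is not knowable whether
they were rounded before or after scaling — both code paths exist.

Contaminant rules are case-insensitive keyword/regex matches on
descriptions plus an id blocklist; defaults cover bacterial ribosomal
proteins and the preparation enzymes trypsin, collagenase and papain. The
filter always partitions its input exhaustively and disjointly, with the
matched rule logged per removal.

Identification filters are inclusive at their printed boundaries (score
≥ 22, discriminant ≥ 0.0, expectation ≤ 0.01, e-value ≤ 1e-10); the
S-crystallin-vs-GST rule is strict (coverage > 90 and identity > 60).
Coverage uses a qcovs column when present, otherwise alignment length /
query length; a union-of-intervals option avoids double-counting
overlapping domain hits.

## Multilayer interference

The stack alternates cytoplasm (`d_a`, `n_a = 1.33`) and membrane (`d_b`,
`n_b = 1.46`) layers; indices are config-overridable defaults — standard
values for cytoplasm and lipid bilayers, since the tissue's are not
directly measured — and ambient/substrate default to the cytoplasm index
because the stack is embedded in tissue. Dispersion is neglected (constant
n across the visible); the default wavelength grid is 380–750 nm at 1 nm.

Full-wave reflectance uses the characteristic-matrix recursion with tilted
admittances (`η = n cos θ` for s, `n / cos θ` for p; unpolarized = mean of
the two powers). For lossless stacks R + T = 1 to ~1e-14, and the
computation is validated against the bare-interface Fresnel limit and the
closed-form quarter-wave-stack admittance `Y = (n_H/n_L)^{2N} n_sub`. The
two-beam condition `m λ = 2(n_a d_a cos θ_a + n_b d_b cos θ_b)` agrees with
the transfer-matrix peak to well under 5 nm at the stack's index contrast
(0.13).

Thickness sampling uses a truncated normal with a 10 nm lower bound —
necessary because the measured cytoplasm sd (102 nm) exceeds its mean
(116 nm), which an untruncated normal would turn into negative
thicknesses. Truncation raises the distribution mean above the nominal
value (≈ 141 nm for 116/102 truncated at 10); sampled-layer summaries
therefore report truncated-normal means, checked against the closed form.

Areal expansion divides each thickness by the areal factor (volume
conservation of a spreading layer); a flag can hold membrane layers fixed,
modeling bilayers that unfold rather than stretch. The reflectance peak is
then monotonically blue-shifted in the expansion factor — at large factors
the first-order peak leaves the visible band, so sweeps that track the
peak extend the grid below 380 nm.

Color rendering integrates spectrum × illuminant against the CIE 1931 2°
color matching functions, implemented as the standard analytic multi-lobe
Gaussian fit (accurate to a few percent, ample for swatches). Linear sRGB
is normalized to the perfect diffuser (flat reflectance → white for any
illuminant), then gamma-encoded with out-of-gamut clipping logged.
Illuminants: equal-energy (default) and a Planckian D65 approximation.

## Pigment spectra and titration

Lorentzian broadening is applied in the wavelength domain because the FWHM
is specified in nm (30 nm default); each line contributes
`f_i (γ/2)² / ((λ−λ_i)² + (γ/2)²)`, so an isolated line peaks at exactly
`f_i`. An energy-domain option exists (FWHM in eV) since TD-DFT spectra
are often broadened there. Spectra are in arbitrary units with an optional
max-normalization; both the broadened-envelope maximum and the strongest
single excitation are reported, as a printed λmax may refer to either.
Line lists are read from two-column CSV — the package does not parse
quantum-chemistry program output.

The titration model is two-state Henderson–Hasselbalch mixing,
`A(pH) = A_acid + (A_base − A_acid)/(1 + 10^{n(pK − pH)})`. Fitting uses
bounded least squares with a deterministic initialization (plateaus from
the pH-ordered extremes, pK at the half-range absorbance, slope 1); flat
series and series under 4 points are rejected as degenerate. Noiseless
round trips recover parameters to 1e-6; at 2%-of-range Gaussian noise with
30 points the median pK error is ≈ 0.016 pH units.

## ROI color dynamics

ROI means are computed per channel in float with no rounding; channel
order is fixed R, G, B; no background subtraction or white balance is
applied, matching raw-RGB reporting. Frames arrive as lexicographically
ordered PNG/TIFF files or multi-page TIFF; 16-bit inputs are rescaled to
0–255 under a flag; traces are reported in raw stored units because the
movies' color space and gamma are unspecified. Defaults: 20 × 20 px ROI,
0.03 s frame interval. The dominant-channel timeline breaks ties R > G > B
(logged).

## Synthetic data

Generators define the study conditions and always emit ground truth beside
the data; one global seed derives named per-generator substreams
(`SeedSequence` spawn keys), so each module is independently reproducible
and byte-identical under a fixed seed.

- Proteomes: random sequences, Poisson lengths (mean 350 aa, floor 20),
  K/R frequency 8% and P frequency 5% by default — near natural
  frequencies, giving a wide spread of expected peptide counts
  (≈ `1 + (L−1)·p_KR·(1−p_P)`).
- Count tables: multinomial draws with observation probability
  ∝ abundance × k_p — the assumption under which dividing by k_p is the
  correct inverse — with per-sample totals depth × loading multiplier
  (defaults: depth 10⁴; multipliers 1/2.2/1.8 for yellow/red/brown).
- Layer measurements: truncated normals at 116/102 (n = 292) and 71/14
  (n = 237) nm.
- Titrations: model curve over pH 1.9–8.9 plus Gaussian noise.
- Movies: a disc whose radius grows as √(areal factor) (linear ramp from 1,
  default ceiling 15×) and whose fill color is the rendered transfer-matrix
  reflectance of the correspondingly thinned stack, plus optional pixel
  noise. The default demo caps expansion at ~1.6× so the first-order
  reflectance peak stays within the visible band.

What the synthetic data do not emulate: real MS/MS spectra and their
identification errors, correlated peptide detectability, optical textures
or camera noise structure, and pigment photodegradation. Passing tests
therefore demonstrate correctness of the computations under the stated
statistical assumptions, not instrument-level realism.

## Problem sizes

Test and acceptance runs use 50-protein proteomes at depth 10⁴ (20
replicate seeds), 1,000 random sequences for the digestion oracle, 100
titration noise seeds, 10–12-pair optical stacks on a 0.5 nm grid, and
short (≤ 20 frame) 64 × 64 movies — sizes chosen so the full pipeline
re-runs from scratch in seconds while keeping Monte-Carlo standard errors
well inside the asserted tolerances.

## Known limitations

- Refractive indices and the participating pair count per sheath-cell wrap
  are free parameters; absolute reflectance amplitudes are therefore
  indicative, not calibrated.
- Absorbing (complex-index) pigment layers are not coupled into the stack.
- The identification stage consumes search-engine tables; it cannot detect
  upstream scoring differences between engine versions.
- Reproducing the published dataset-level numbers (e.g. k̄ = 65.5 or
  specific normalized counts) requires the study's deposited supplementary
  tables as inputs; the pipeline accepts them in the documented CSV/FASTA
  formats.
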