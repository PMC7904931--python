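# lipospec

Fluorescence-spectroscopy quantitation of compound–membrane interactions in
liposome screens: membrane **dipole potential** (di-8-ANEPPS excitation
ratiometry), membrane **order** (DPH-PC steady-state anisotropy) and membrane
**polarity** (TCSPC lifetimes), with a ground-truth synthetic-data generator
so every stage is verifiable by parameter recovery.

## The scientific problem

Many polyphenols behave as pan-assay interference compounds (PAINS) by
perturbing lipid bilayers rather than binding a protein target.  A sensitive
readout of this perturbation is the membrane dipole potential ψ_d
(~200–400 mV), probed with the voltage-sensitive styryl dye di-8-ANEPPS in
large unilamellar vesicles (LUV) of POPC, POPC:Chol 1:1 and POPC:Chol:PSM
1:1:1.  The dye's blank-corrected excitation intensity ratio

    R_ex = I(420 nm) / I(520 nm)        (emission 635 nm)

maps linearly onto ψ_d:

    ψ_d [mV]  = (R_ex + (0.3 ± 0.4)) / ((4.3 ± 1.2) × 10⁻³)
    Δψ_d [mV] = (365 ± 102) · ΔR_ex

where the second (rescaled-slope) form converts the difference between a
compound condition and its control directly into a dipole-potential change,
with uncertainty propagated in quadrature from the replicate scatter and the
slope uncertainty.  Alongside, membrane order is read from the DPH-PC
steady-state anisotropy

    ⟨r⟩ = (I_VV − G·I_VH) / (I_VV + 2G·I_VH),     G = I_HV / I_HH,

and membrane polarity from TCSPC intensity decays fitted by iterative
reconvolution with a sum of exponentials I(t) = Σ αᵢ exp(−t/τᵢ), reporting
the intensity-weighted mean lifetime ⟨τ⟩ = Σαᵢτᵢ² / Σαᵢτᵢ.

The package is for membrane biophysicists and screening groups who need
these three readouts as reusable, tested code rather than instrument-vendor
spreadsheets, and for anyone validating such pipelines against simulated
data with known truth.

## Worked example

Generate a complete synthetic study (triplicates per condition, paired
blanks, both probe arms) and run the dipole-potential pipeline:

```sh
lipospec generate-study --seed 5 --out study --no-decays
lipospec rex   --manifest study/manifest.csv --out rex.tsv
lipospec shifts --rex rex.tsv --slope 365 --slope-sd 102 --out table1.tsv
```

`rex.tsv` holds one blank-corrected 420/520 ratio per sample, e.g. the three
pure-POPC control replicates (generated with ground truth 2.03):

```
sample_id                lipid_system  compound  replicate  rex
anepps-popc-control-r1   POPC          CONTROL   1          2.0408474564696157
anepps-popc-control-r2   POPC          CONTROL   2          2.0402411262304123
anepps-popc-control-r3   POPC          CONTROL   3          2.0320620317961260
```

`table1.tsv` is the compound × lipid-system table of dipole-potential
changes in mV (estimate ± SD, integer-rounded); the first rows:

```
lipid_system  compound    estimate  sd   delta_rex
POPC          PHLORETIN   -102      31   -0.279518
POPC          NOTHOFAGIN  -1        6    -0.003185
POPC          PHLORIZIN   -72       21   -0.197661
```

Read: in liquid-disordered POPC vesicles phloretin drops the dipole
potential by ≈100 mV (a strong, physiologically relevant perturbation —
the study's generator seeds this cell with −103 mV), phlorizin by ≈70 mV,
while the C-glucoside nothofagin is indistinguishable from zero.  The SD
combines the triplicate scatter with the 365 ± 102 slope uncertainty.

The anisotropy arm (`lipospec aniso --manifest study/manifest.csv --out
fig3.tsv`) likewise returns condition-level ⟨r⟩ ± SD — e.g. POPC control
`0.166001 ± 0.000225` against a generator truth of 0.165 — and
`lipospec lifetime-fit --decay d.csv --components auto --out fit.json` fits
a single TCSPC histogram, printing the fitted lifetimes, amplitudes,
reduced χ² and ⟨τ⟩.

As a library:

```python
from lipospec import (generate_excitation_pair, SpectrumShapeConfig,
                      compute_rex)
lab, blank, truth = generate_excitation_pair(2.03, SpectrumShapeConfig(), seed=1)
print(compute_rex(lab, blank))   # ~2.03 up to reading noise
```

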