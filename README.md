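# t1rhomap

A toolkit for high-resolution spin-lock T1ρ mapping of knee cartilage, built
around a 7 T acquisition protocol. It is aimed at quantitative-MRI
researchers who need to prototype, validate, or teach the full measurement
chain without scanner time: a rotating-frame Bloch simulator of the
B0/B1-compensated spin-lock preparation cluster, a synthetic knee phantom
with field inhomogeneity and Rician noise, the calibration steps the
protocol relies on (WASSR B0 mapping, double-angle B1 mapping, STEAM
reference-voltage calibration), voxel-wise mono-exponential fitting with
goodness-of-fit maps, cartilage zone/side segmentation, and test-retest
reliability statistics.

## The model

T1ρ is the relaxation time of magnetization locked along an RF field of
amplitude B1sl (here 500 Hz). A series of images at spin-lock times
TSL ∈ {0, 10, 20, 30, 40} ms is fitted voxel-wise to

    S(TSL) = S0 · exp(−TSL / T1ρ),

with R² computed on the native signal scale as the quality map. During the
lock the magnetization evolves about the effective field — the vector sum of
the transverse lock field B1sl·b1rel and the longitudinal B0 offset Δf — so
at 7 T, where |Δf| over the knee can reach ~139 Hz and b1rel spreads by
±10%, an uncompensated lock leaves oscillatory artifacts that bias T1ρ in
the deep and middle cartilage zones. The simulated preparation cluster
supports both the uncompensated (`simple`) and the rotary-echo +
refocusing (`compensated`) scheme so that this artifact and its removal are
reproducible. Statistics follow the standard test-retest battery
(two-way absolute-agreement single-measure ICC with 95% CI, Pearson r,
coefficient of variation) plus Rician-corrected SNR
(SNR = 0.655 × ROI mean / background s.d.).

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

Simulate a phantom, fit it, and calibrate a transmitter voltage:

```sh
$ t1rhomap simulate --seed 3 --out phantom/
wrote phantom to phantom

$ t1rhomap fit --series phantom/series.nii --mask phantom/labels.nii --out fit/
{"method": "linearized", "n_valid_voxels": 7400, "median_t1rho_ms": 44.309223148377356,
 "shifts": [[0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0]]}

$ t1rhomap calibrate-voltage --s1 0.6495 --s2 0.6495 --x 100
{"flip_angle_deg": 59.99999999999999, "reference_voltage_V": 150.00000000000003}
```

The fit report says all 7,400 cartilage voxels produced valid fits and the
median T1ρ is 44.3 ms — consistent with the phantom's zone ground truth of
35/45/55 ms (deep/middle/superficial) and with healthy cartilage staying
below 60 ms. The zero shifts confirm the simulated series needed no motion
correction. The voltage example: two STEAM spectra with equal peak signal at
voltages x and 2x imply the actual flip at x is 60°, so the true-90° 
reference voltage is 100 × 90/60 = 150 V.

The same operations are available as library calls (`simulate_tsl_series`,
`fit_t1rho`, `reference_voltage`, ...) for scripted studies.

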