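# tkdce — tracer-kinetic-model-constrained DCE-MRI reconstruction

Dynamic contrast-enhanced (DCE) MRI quantifies blood-brain-barrier
leakage in brain tumors by fitting tracer-kinetic models to per-pixel
contrast-concentration time courses. Accelerating the acquisition by
under-sampling (k, t)-space normally requires a sparsifying transform
and a regularization weight to tune. `tkdce` implements an alternative:
the kinetic model that will be fitted *anyway* in post-processing is
used as the temporal constraint *during* reconstruction, so the only
free parameter — the sparsity level q — is fixed a priori by the
model's degrees of freedom.

The package is aimed at MR-physics and image-reconstruction
researchers: it provides the full simulation-to-evaluation chain
(kinetic models, dictionary learning, a digital phantom, the multicoil
acquisition model, the constrained reconstruction, a compressed-sensing
baseline, and error statistics) as an importable Python library with a
thin `tkdce` command-line front end.

## Method

1. **Library.** A kinetic model generates concentration profiles
   `Z ∈ R^{l×N}` over a physiological parameter grid. Patlak
   (`C = Ktrans ∫Cp + vp Cp`; Ktrans 0–0.8 min⁻¹, vp 0–60%) gives
   l = 4941; extended Tofts-Kety
   (`C = vp Cp + Ktrans ∫ Cp(τ) e^{-(Ktrans/ve)(t-τ)} dτ`; plus ve
   1–100%) gives l = 494,100, with N = 50 frames at 5 s. The plasma
   input `Cp` is the Parker population AIF.
2. **Dictionary.** k-SVD compresses the library into r = 100 unit-norm
   temporal atoms `V ∈ R^{r×N}` such that every profile is a q-sparse
   combination `z_p ≈ u_p V`, `‖u_p‖₀ ≤ q`. q tracks the model's
   degrees of freedom: q = 2 suffices for Patlak (machine-precision
   error), q = 3 for ETK (max ≈ 2%, mean ≈ 0.007% normalized squared
   error).
3. **Reconstruction.** With the multicoil forward model
   `A = Fu · Sm · T` (SPGR signal transform, coil sensitivities,
   masked unitary FFT), the reconstruction solves

   ```
   min_{C,U} ‖A C − b‖²   s.t.  C = U V,  ‖u_p‖₀ ≤ q
   ```

   by alternating hard k-space data consistency with per-pixel OMP
   projection, inside an iterative multiscale scheme (Gaussian k-space
   filter widened from 0.1% to 100% of k_max) that avoids the poor
   local minima of this non-convex problem. Kinetic parameters are
   fitted once, after reconstruction.

A temporal-finite-difference (temporal TV) ADMM reconstruction — the
standard compressed-sensing comparator, whose weight λ must be tuned —
is included as the baseline, along with Bland-Altman / nRMSE /
Monte-Carlo bias-uncertainty evaluation and a synthetic brain-tumor
digital reference object (DRO) that generates every input the pipeline
needs (no external data).

See `docs/methods.md` for assumptions, parameter defaults, and known
limitations.

## Worked example

`examples/kinetic_models.py` (every example is a short, self-contained
script):

```text
AIF: peak plasma concentration 10.07 mM at t = 20 s
ETK profile: peak 0.768 mM, last frame 0.494 mM
ETK fit:    ktrans = 0.2500 min^-1, vp = 0.0600, ve = 0.4000
truth:      ktrans = 0.2500 min^-1, vp = 0.0600, ve = 0.4000
Patlak fit on the same profile: ktrans = 0.0945 min^-1 (model mismatch), vp = 0.0972
```

The ETK fit recovers the simulated tumor parameters exactly on
noiseless data; fitting the backflux-free Patlak model to the same
profile underestimates Ktrans severely — the classic model-mismatch
bias.

`examples/dictionary_learning.py` shows why q must match the model:

```text
Patlak library: 4941 profiles x 50 frames
numerical rank 2: singular-value ratio s3/s1 = 1.64e-16
q = 1: max error 0.199%  mean error 0.0455%
q = 2: max error 1.01e-26%  mean error 9.56e-28%
```

`examples/dro_reconstruction.py` runs the full chain (64×64 phantom,
6 coils, R = 20, SNR 30):

```text
sampled fraction per frame: 0.050 (frame 0 fully sampled)
reconstruction: 69 iterations, tumor-rim concentration nRMSE 15.2%
tumor ktrans: bias -0.0025 min^-1, limits of agreement [-0.0414, +0.0364]
(ground-truth rim ktrans spans 0.114-0.213 min^-1)
```

At 20-fold under-sampling the recovered tumor Ktrans map is essentially
unbiased (−0.0025 min⁻¹ against values of 0.11–0.21 min⁻¹).
`examples/noise_monte_carlo.py` reproduces the noise analysis showing
that a matched-q projection adds no estimation bias while q = 1 does.

## Command-line interface

Each pipeline stage is also a CLI verb operating on HDF5 containers:

```bash
tkdce build-library --model etk --out library.h5
tkdce learn-dict --library library.h5 --r 100 --q 3 --seed 0 --out dict.h5
tkdce make-dro --size 96 --seed 0 --out dro.h5
tkdce undersample --dro dro.h5 --r-factor 20 --snr 30 --out ktdata.h5
tkdce recon --ktdata ktdata.h5 --dro dro.h5 --dictionary dict.h5 --q 3 --out recon.h5
tkdce evaluate --recon recon.h5 --dro dro.h5
tkdce run            # full pipeline from a YAML config
```

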