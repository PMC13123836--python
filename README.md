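# singlepulse

2D ¹H–¹³C correlation maps of protein methyl groups from a **single-pulse**
NMR experiment: instead of magnetization-transfer periods and an indirect
evolution dimension, the ¹H FID is recorded while weak continuous-wave (CW)
¹³C decoupling is applied at a series of offsets ν_RF, and a convolutional
network transforms the resulting off-resonance dataset into a conventional
HMQC-like correlation map.

## Who this is for

NMR spectroscopists and methods developers working on large protein
assemblies (¹³CHD₂-labelled methyl probes, methyl-TROSY regime), where
transfer periods in conventional 2D experiments erode the signal, and anyone
studying learned reconstructions of spectroscopic data.

## The physics and the method

For an isolated ¹H–¹³C pair under CW ¹³C decoupling of strength B₁ applied
at offset Δ = ν_C − ν_RF from the ¹³C resonance, the ¹H signal is
approximately a doublet with effective splitting

    J_eff = ¹J_HC · |Δ| / sqrt(Δ² + B₁²)

which equals the scalar coupling ¹J_HC (~125 Hz) far off resonance and
collapses to a singlet on resonance. Sweeping ν_RF across the ¹³C region
therefore traces an X-shaped pattern centred at (ϖ_H, ϖ_C): the stack of 1D
¹H spectra encodes both chemical shifts.

The package implements:

- **`singlepulse.sim`** — exact evolution of the eight product-operator
  coherences (Hx, Hy, 2HxCx, 2HyCx, 2HxCy, 2HyCy, 2HxCz, 2HyCz) under an
  8×8 Liouvillian with rates R₂,H, R₂,MQ, R₂,APH; difference off-resonance
  stacks (decoupled minus coupled reference) with cosine-square apodization,
  zero-filling and FT. Closed-form oracles (`effective_splitting`,
  `limiting_rate_oracle`) are exposed for validation.
- **`singlepulse.synth`** — randomized training examples: two-B₁
  (~220/110 Hz) difference stacks at 16.4 T paired with noise-free target
  maps carrying 2D Gaussian peaks (amplitude I₀, ¹H FWHM max(R₂,H/π, floor),
  fixed ¹³C FWHM).
- **`singlepulse.nn`** — a seven-hidden-layer convolutional network with
  skip connections (small U-Net; ~2×10⁵ weights reduced / ~5×10⁶ full),
  written in numpy (im2col + FFT-domain convolutions, manual backprop, ADAM,
  30% dropout, L2), wrapped in the scikit-learn estimator
  `CorrelationMapper` (`fit`/`partial_fit`/`predict`), trained on a
  peak-count curriculum by MSE against the noise-free targets.
- **`singlepulse.reconstruct`** — Monte-Carlo-dropout inference: the mean of
  20 stochastic passes is the reconstructed map and 1.4× their SD its
  point-wise uncertainty.
- **`singlepulse.processing` / `singlepulse.ioformats`** — reference
  subtraction and stack assembly for raw series; NMRPipe, UCSF (Sparky) and
  npy+JSON container codecs.
- **`singlepulse.peaks`** — peak picking with parabolic interpolation,
  joint Gaussian intensity fits over the MC ensemble (σ_height = 1.4×SD),
  chemical-shift RMSD benchmarking, mixture-slope analysis, and the
  viscosity effective-size helper.

## Worked example

```python
import numpy as np
from singlepulse import (AcquisitionScheme, SpinSystem, build_liouvillian,
                         propagate_fid, synthesize_spectrum,
                         effective_splitting)

scheme = AcquisitionScheme(f_h=700.0, n_zf=16384)      # 16.4 T, fine zero-fill
spin = SpinSystem(wh=0.5, wc=13.0, j_hc=125.0,
                  r2_h=25.0, r2_mq=25.0, r2_aph=25.0)

for nu_rf in (spin.wc - 50.0, spin.wc):                # far off / on resonance
    l8 = build_liouvillian(spin, b1=110.0, nu_rf=nu_rf, scheme=scheme)
    fid = propagate_fid(l8, scheme.time_grid())
    spec = synthesize_spectrum(fid, scheme)
    y = spec.data.real
    maxima = [i for i in range(1, len(y) - 1)
              if y[i] > 0.5 * y.max() and y[i - 1] <= y[i] > y[i + 1]]
    print(len(maxima), "maxima")

print(round(effective_splitting(125.0, 110.0, 8800.0), 2), "Hz")
```

prints

```
2 maxima
1 maxima
124.99 Hz
```

— far off resonance the ¹H signal is a doublet whose measured separation
(125.0 Hz to the digital resolution) equals the scalar coupling, and with
the decoupler on resonance it collapses to a single line; the closed-form
splitting at Δ = 8.8 kHz (50 ppm at 176 MHz) agrees.

Training and reconstruction at desk scale:

```bash
singlepulse gen-data --reduced --n 64 --out shards/ --seed 7   # validation shards
singlepulse train --data shards/ --out model.npz --reduced
singlepulse fixtures --spins ff --out ff.yaml
```

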