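# sofismooth

Photodestruction (photobleaching) correction for super-resolution optical
fluctuation imaging (SOFI), by per-pixel Whittaker smoothing with automatic
V-curve selection of the smoothing parameter.

## The problem

SOFI sharpens a fluorescence movie by computing temporal cumulants of the
intensity fluctuations produced by independently blinking emitters: at second
order and zero time lag, the variance of each pixel trace and the covariance
of neighboring pixel traces (the latter filling "virtual" pixels on a
2×-refined grid). Cumulants only reward *stationary*, independent
fluctuations — any slow, spatially correlated trend such as photobleaching or
illumination drift leaks into every covariance and buries the blinking
signal under a smooth artifact.

`sofismooth` removes the trend before the cumulants are taken. Every pixel
trace `y` (length `n`) is fitted with the Whittaker smoother, the penalized
least squares minimizer of

```
S = ||y − μ||² + λ ||D μ||²,
```

where `D` is the order-`d` finite-difference matrix (`d = 2` throughout) and
`λ` sets the stiffness. The closed-form solution
`μ̂ = (I + λ DᵀD)⁻¹ y` is a banded symmetric positive-definite system,
factorized once per stack and solved for all pixels — linear time and memory
in `n`. The corrected movie `y − μ̂` retains only the fast blinking
dynamics (its per-pixel time sum is exactly zero), and second-order SOFI on
it recovers the contrast that the trend destroyed.

`λ` is chosen automatically for the image in its entirety by the V-curve:
trace `(log₁₀ Σ‖y − μ‖², log₁₀ Σ‖Dμ‖²)` over a log-spaced λ grid and take
the geometric mean of the grid pair whose consecutive points are closest.

The package also provides the standard baseline (cumulants on short frame
batches, averaged), a full synthetic benchmark — blinking fluorophores on
random lines (two-state Markov chains, exponential bleaching times),
pixel-integrated Gaussian PSF, Poisson background and shot noise, EMCCD
offset/gain camera model — and an SNR/RMSD evaluation protocol over repeated
simulations.

## Worked example

```python
import numpy as np
from sofismooth import SimulationConfig, simulate_dataset, detrend_stack, sofi_pipeline

config = SimulationConfig(fov_pixels=(16, 16), n_frames=300,
                          n_fluorophores=5000, tau_bleach_s=1.1)
stack, emitters, _ = simulate_dataset(config, seed=1)
stack = stack.astype(float)
print(f"mean counts, frames 1-10:   {stack[:10].mean():8.1f}")
print(f"mean counts, frames 291-300:{stack[-10:].mean():8.1f}")

corrected, trend, lam = detrend_stack(stack, "auto")
print(f"V-curve selected lambda:    {lam:8.3g}")

for mode in ("none", "batch", "whittaker"):
    img = sofi_pipeline(stack, mode, batch_size=50)
    virt = img.values.copy(); virt[::2, ::2] = np.nan
    print(f"mean |virtual-pixel cumulant|, {mode:9s}: {np.nanmean(np.abs(virt)):12.0f}")
```

prints

```
mean counts, frames 1-10:    25039.1
mean counts, frames 291-300:  3001.7
V-curve selected lambda:    1.41e+06
mean |virtual-pixel cumulant|, none     :     57995381
mean |virtual-pixel cumulant|, batch    :      8396784
mean |virtual-pixel cumulant|, whittaker:      6289654
```

With a 1.1 s photobleaching survival time the mean camera signal decays
roughly eight-fold over the 3 s movie. Uncorrected, that decay inflates
every cross-cumulant (the `none` row); batching in 50-frame blocks
suppresses most of the trend leakage, and Whittaker correction suppresses
it further still, leaving cumulants dominated by genuine blinking
covariance.

The same pipeline is available from the shell:

```sh
sofismooth simulate config.yaml -o stack.tif --truth emitters.csv --seed 1
sofismooth smooth stack.tif --lambda auto -o corrected.tif --vcurve vcurve.csv
sofismooth sofi stack.tif --mode whittaker -o sofi.tif
sofismooth evaluate config.yaml --tau-bl 1.1,33 --methods none,batch,whittaker \
    --reps 20 -o results.csv
```

Every output TIFF carries a JSON sidecar with the resolved configuration
(including the selected λ), and every run is reproducible from its seed.

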