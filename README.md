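# decimix

Decimation-accelerated demixing of calcium imaging video, and the two-phase
imaging protocol: identify neuron shapes at full resolution, then recover
each neuron's activity from movies whose spatial resolution has been cut by
an order of magnitude.

## Who this is for

Labs processing large fluorescence movies (light-sheet, two-photon) who
need (a) fast source extraction — turning a pixels × time movie into
per-neuron calcium traces and spike estimates — and (b) a principled way to
trade spatial resolution for imaging speed or field of view once the
neurons' footprints are known.

## The model

A movie with `D` pixels and `T` frames, flattened to `Y ∈ R^{D×T}`, is
factorized as

    Y ≈ A C + b fᵀ

with non-negative footprints `A ∈ R₊^{D×N}` confined to spatial patches
`P_n`, non-negative calcium traces `C ∈ R₊^{N×T}`, and a rank-1 background
`b fᵀ`. Fitting minimizes `‖Y − AC − b fᵀ‖²` by constrained *fast HALS*
block-coordinate descent (all traces updated with shapes fixed, then all
shapes), where each row update is an exact non-negative quadratic minimizer
and only the small products `AᵀY`, `CYᵀ` and Gram matrices are touched —
never a full residual movie.

Three ideas make this fast and robust:

- **Decimation.** Most sweeps run on data averaged over blocks of `k`
  frames and `l × l` pixels; the cheap coarse fit is then upsampled
  (zero-order hold) and polished with a few full-resolution sweeps. The
  coarse objective also tends to sit near better local optima.
- **Sparse non-negative deconvolution.** Traces follow AR(2) dynamics
  `c_t = γ₁ c_{t−1} + γ₂ c_{t−2} + s_t` with spikes `s = G c ≥ 0`; denoising
  solves `min ‖Gc‖₁ s.t. Gc ≥ 0, ‖y − c‖² ≤ σ²T` with the noise level `σ`
  estimated from the high-frequency PSD, via a warm-startable active-set
  solver in the spike domain.
- **Two-phase imaging.** Because spatial decimation is linear,
  `decimate(A C) = decimate(A) C`: a coarse movie is still a linear mixture
  of the same traces, so shapes learned at full resolution demix movies
  decimated by `8×8` or more (a `l²`-fold compression with the demixer as
  decoder). Interleaving two half-shifted coarse grids on alternating
  frames restores separability of neurons that a single coarse grid merges.

## Worked example

```python
import numpy as np
import decimix as dx

# simulate a 64x64 field of 12 neurons, 500 frames at 20 Hz
scene = dx.make_scene(dx.SceneSpec(H=64, W=64, N=12, T=500, radius=2.5,
                                   min_separation=10, noise_sigma=0.4, seed=42))

# phase 1: multi-scale fit at full resolution
init = dx.InitConfig(n_components=12, expected_radius=2.5, patch_half_width=6)
model, trace = dx.fit_multiscale(scene.noisy, dx.FitSchedule(), init)
model.normalize()
print(f"full-resolution fit: N={model.N}, final RSS {trace.full_rss[-1]:.4g}")

# per-neuron AR(2) dynamics from the fitted traces
gamma = np.vstack([dx.estimate_ar(model.C[n]) for n in range(model.N)])
print(f"median AR(2) coefficients: ({np.median(gamma[:,0]):.2f}, {np.median(gamma[:,1]):.2f})")

# phase 2: demix an 8x8-decimated movie (64x fewer pixels) with fixed shapes
Y8, _ = dx.decimate_spatial(dx.flatten(scene.noisy), 8, 8, grid=(64, 64))
res = dx.demix_lowres(Y8, dx.decimate_model(model, 8, 8), dx.ARModel(gamma))

match = [int(np.argmax([dx.pearson(scene.C_true[n], model.C[m])
                        for m in range(12)])) for n in range(12)]
corr = [dx.pearson(scene.C_true[n], res.C[match[n]]) for n in range(12)]
print(f"l=8 demixing: median corr to ground-truth traces {np.median(corr):.3f}")
```

prints

```
full-resolution fit: N=12, final RSS 3.257e+05
median AR(2) coefficients: (1.67, -0.68)
l=8 demixing: median corr to ground-truth traces 0.998
```

The fit recovers all 12 components; the estimated dynamics sit close to the
generating coefficients (1.7, −0.712); and traces demixed from the movie
with 64× fewer pixels still match the ground-truth calcium traces almost
perfectly — the point of the two-phase protocol.

A `decimix` command-line tool wraps the same pipeline: `simulate`, `fit`,
`denoise`, `demix` (with `--one-phase` and `--interleaved` variants),
`reconstruct`, and `evaluate`. Run `decimix --help` for usage.

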