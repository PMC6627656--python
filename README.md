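# radusm

Reverse anisotropic diffusion (RAD) based unsharp masking for enhancing thin
line structures — endotracheal, feeding and nasogastric tubes, catheters — in
low-contrast portable chest radiographs.

Portable ICU radiographs are acquired under non-optimized exposure and
positioning, so tube tips are often barely visible.  Classical unsharp
masking (USM) sharpens an image by adding back a high-frequency mask,

```
I_en(x, y) = I(x, y) + α_usm · (I(x, y) − I_sm(x, y)),
```

but when the smoothed image `I_sm` comes from a Gaussian blur the mask
contains noise as well as edges, and both get amplified.  `radusm` replaces
the blur with a *reverse* anisotropic diffusion: where edge-preserving
diffusion (Perona–Malik) uses a diffusivity g(‖∇I‖) that decreases with
gradient magnitude, RAD uses a monotonically increasing one,

```
g(‖∇I‖) = ‖∇I‖^β,    β ≥ 1,
```

so the smoother flattens edges and leaves flat, noisy regions essentially
untouched.  The mask `I − I_sm` then contains the edges and little else, and
the enhancement boosts line structures without raising the noise floor.

The smoothed image minimizes the energy
`E(u) = ½‖u − I‖² + α ∫ Φ(‖∇u‖) dx dy` via lagged diffusivity: the nonlinear
coefficients are frozen at the current iterate and each step solves the
linear system `[D + αL(uᵐ)] uᵐ⁺¹ = I`, where `L` is a five-point divergence
operator with half-pixel diffusivities.  The system is solved matrix-free
with a Jacobi-preconditioned bi-conjugate gradient method, so
radiograph-sized images (2500×2048 and up) never require an assembled matrix.

The package also provides the Gaussian and Perona–Malik baselines, the EMEE
blockwise contrast metric (40×40 blocks, c = 30, natural log), a simple
region SNR, readers/writers for 16-bit PNG/TIFF and the JSRT raw format, and
a reproducible chest-like phantom generator with ground-truth tube and
impulse masks.

## Worked example

```python
import radusm as R
from scipy.ndimage import binary_dilation

img, edge_map, impulse_map = R.make_standard_phantom()   # 256x256, seeded
enhanced, mask, smoothed = R.rad_usm(img, R.DiffusionParams(alpha_diff=0.02))

near_tubes = binary_dilation(edge_map, iterations=2)
print(f"EMEE original : {R.emee(img):.3f}")
print(f"EMEE enhanced : {R.emee(enhanced):.3f}")
print(f"mask energy within 2 px of tubes: "
      f"{100*(mask**2)[near_tubes].sum()/(mask**2).sum():.1f}%")
```

prints

```
EMEE original : 0.495
EMEE enhanced : 1.068
mask energy within 2 px of tubes: 76.7%
```

EMEE rises because the enhancement roughly doubles the local max/min contrast
around the tubes; the last line shows the mask is edge-selective — over
three-quarters of its energy sits within two pixels of the true tube pixels,
even though those cover only ~2% of the image.  Larger `alpha_diff` smooths
edges harder and raises EMEE further (0.83 / 1.07 / 1.11 over the sweep
0.001 / 0.02 / 0.2 on this phantom); 0.02 is the recommended default.

The same pipeline from the shell:

```
radusm phantom --out-dir work
radusm enhance work/phantom.png --out-dir work/out --emit-intermediates --bit-depth 12
radusm emee work/phantom.png work/out/phantom_enhanced.png --bit-depth 12
```

`enhance` writes the enhanced image, and with `--emit-intermediates` also the
smoothed image and the (offset-encoded) mask, plus a `run_log.jsonl` with one
JSON record per input: parameters, EMEE before/after, wall-clock seconds.

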