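# meshstrain

Surface strain, area dilation and contraction-frequency mapping from
fluorescence microscopy of a fiducial lattice mesh.

## The problem

Mechanical strain drives cell migration, cardiomyocyte contraction and
tissue morphogenesis, but measuring it directly on a living surface is
hard.  One solution is to adhere an ultra-thin fluorescent square-lattice
mesh (line width and spacing tunable from ~2 to ~100 µm) to the surface of
interest.  The mesh deforms passively with the surface, so time-lapse
fluorescence imaging of the lattice turns the surface into a dense array of
strain gauges: every lattice intersection is a trackable node, every
node-to-node segment a one-dimensional gauge, and every four-node cell a
planar strain element.

`meshstrain` is the analysis side of that experiment, plus a synthetic
renderer so the whole pipeline is testable against exact ground truth:

- **simulate** — render mesh images/movies under parametric deformation
  fields (uniaxial, incompressible-isotropic, compressible-anisotropic,
  oscillatory, band-limited random warps) with PSF blur and noise, emitting
  exact node positions, deformation gradients and frequencies.
- **segment** — background subtraction, thresholding, skeletonisation and
  subpixel node (lattice-intersection) detection, in 2D or on z-stacks via
  a max-projection roadmap.
- **lattice** — assemble detections into a lattice graph (segments and
  4-node cells) by skeleton traversal, support manual pair edits, and track
  node identities through time by gated mutual-nearest-neighbour linking.
- **mechanics** — per-segment engineering strain and stretch ratio,
  per-cell deformation gradient / Green-Lagrange tensor / principal
  strains / dilation, fractional shortening, displacement vectors, linear
  stress estimates, and stretch-ratio summaries against macroscopic
  measurements.
- **frequency** — per-pixel dominant contraction frequency from
  mesh-motion intensity fluctuations (downsample, blur, Savitzky-Golay,
  FFT power spectral density, mesh masking).

## The quantities

With reference segment length $l_0$ (frame 0, the as-applied state) and
current length $l$ (Euclidean, 2D or 3D):

$$\varepsilon = \frac{l}{l_0} - 1, \qquad \lambda = \frac{l}{l_0}$$

Positive $\varepsilon$ is tension, negative compression.  For an
incompressible isotropic material under uniaxial stretch,
$\lambda_2 = \lambda_3 = \lambda_1^{-1/2}$ and
$\lambda_1\lambda_2\lambda_3 = 1$; deviations diagnose anisotropy or
compressibility.  Per four-node cell, a planar deformation gradient $F$ is
fitted by least squares over the four edge vectors, giving the
Green-Lagrange tensor $E = \tfrac12(F^\mathsf{T}F - I)$, principal strains
$P_1 \ge P_2$ with direction, and dilation $D = |\det F|$.  Stress is the
linear estimate $\sigma = E_\text{mod}\,\varepsilon$ for a supplied elastic
modulus.  Contraction frequency per pixel is the off-DC argmax of the FFT
power spectral density of its smoothed intensity trace.

## Worked example

Render a 16-step uniaxial stretch (0 → 45 % in 3 % increments) of a
100 µm-pitch, 10 µm-line mesh on an incompressible substrate, with additive
noise at 5 % of the foreground, then recover the strain through the full
pipeline:

```python
import meshstrain as ms

mesh = ms.MeshSpec(pitch=100, line_width=10, rows=5, cols=5)
series, truth = ms.make_uniaxial_series(
    mesh, max_strain=0.45, step=0.03, mode="incompressible",
    pixel_size=1.0, noise_sigma=0.05, seed=7)

result = ms.analyze_series(series, pitch=100, line_width=10)
peak = result.strain.query("frame == 15 and orientation == 'x'")

macro = ms.MacroscopicSeries.from_frame(truth.macroscopic())
table, summary = ms.stretch_summary(result.strain, macro)
sigma = ms.stress_estimate(peak["epsilon"].mean(), 2000.0)
```

This prints (via the obvious `print` statements):

```
frames rendered:        16
nodes tracked:          25
segments / cells:       40 / 16
mean eps_1 at peak:     0.4498  (applied 0.4500)
lambda1*lambda2*lambda3: 0.9998  (incompressible -> 1)
Pearson lambda2 vs lambda3: 1.0000
stress at E = 2 kPa:    899.7 Pa
```

The 25 lattice intersections are detected to subpixel precision and
tracked across all 16 frames; the mean recovered tensile strain at the
peak frame (0.4498) matches the applied 45 % to 0.05 %, and the recovered
stretch-ratio product stays at 1 — the kinematic signature of an
incompressible isotropic material.  The last line converts the peak strain
into a stress estimate for a 2 kPa-stiff material.

The same analyses are available from the shell:

```sh
meshstrain run --config run.yaml          # simulate and/or analyse, per config
meshstrain strain --input movie.tif --pixel-size 0.5 --dt 1.0 \
    --pitch 100 --line-width 10 --output-dir out/
meshstrain beatfreq --input movie.tif --output-dir out/
```

Every run writes a `manifest.json` with the effective parameters and seed,
and deterministic stages reproduce their outputs bit-for-bit on replay.

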