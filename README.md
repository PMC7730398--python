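# ict — Individual Cell Tracking for softwood micro-CT

`ict` measures how individual wood cells deform when a sample is loaded,
from pairs of synchrotron micro-CT volumes (8-bit grayscale, ~1.6 µm
voxels).  It is aimed at wood scientists and biomechanics researchers who
want strain fields at single-cell resolution — per tracheid and per wood
ray — rather than the 100–200 µm subsets that digital volume correlation
needs.

The chain is:

1. **Segment** the cell lumens (air voids) of each state: Otsu
   binarization, two-pass 3D morphology (a coarse opening keeps wide
   earlywood lumens, a reconstruction pass recovers thin latewood and ray
   tubes), classification by elongation axis, and assignment of every wall
   voxel to its geometrically closest lumen.
2. **Parameterize** each tube as 1D profiles along its axis (Z = L for
   tracheids, X = R for rays): per-slice centroid c_X, c_Y, lumen area Σ,
   perimeter P, skeletonized section Σ_sk, P_sk, ellipse fit (e_a, e_b,
   e_Ψ), wall thickness t = 2(Σ_sk − Σ)/(P_sk + P), inclination θ.
3. **Track**: match cells between states by mutual ≥ 50% overlap; find the
   axial displacement u_z(z) by zero-normalized cross-correlation of the
   profiles over 41-sample windows (accept where I_corr > 0.5); difference
   the aligned profiles to get u_x, u_y, ε_Σ, ε_t, Δθ, Δe_Ψ.
4. **Strain fields**: smooth the scattered per-cell displacements with
   cubic smoothing splines along the axis and thin-plate splines in the
   plane (one resolution knob, default 50 px = 81 µm) and differentiate:
   ε_ij = ½(∂_j u_i + ∂_i u_j).  Ray clusters additionally get an
   affine/non-affine decomposition (ε_ray, u_ray).

Because every profile channel averages hundreds of boundary voxels, strain
sensitivity reaches deep sub-voxel scale: a 5×10⁻⁵ radial strain over a
35 µm lumen is a 1.8 nm displacement.

A synthetic spruce phantom generator (growth-ring gradient of lumen size,
aspect and wall thickness; wavy tubes; ray clusters; pits as tracking
landmarks; partial-volume rendering, blur and noise) provides exact ground
truth for every stage, so the whole chain is testable without beamline
data.

## Worked example

```python
import numpy as np
from ict import PhantomSpec, generate_phantom, ChainConfig, segment_state, pair_strain
from ict.phantom import apply_affine_deformation

spec = PhantomSpec(volume_shape=(144, 144, 192), seed=3)
vol, truth = generate_phantom(spec)          # 8-bit volume + ground truth

eps = np.zeros((3, 3)); eps[0, 0] = 1e-3     # 0.1% radial tension
deformed, _ = apply_affine_deformation(vol, truth, eps)

cfg = ChainConfig()
ref = segment_state(vol, cfg)
test = segment_state(deformed, cfg, threshold=ref.binary.threshold)
field, samples = pair_strain(ref, test, cfg)
print(f"{len(ref.profiles)} tracheids, {len(samples)} track samples")
print("median eps_RR:", samples.eps_RR.median())
```

prints

```
29 tracheids, 4408 track samples
median eps_RR: 0.0009873143155587397
```

i.e. the imposed 1×10⁻³ radial strain is recovered to a few times 10⁻⁵
from a volume where the largest cell displacement is under a tenth of a
voxel.  The `samples` table also carries ε_TT, ε_LL, the shear components,
and the per-cell geometric strains (ε_Σ, ε_t, Δθ, …).

A command-line interface covers the same workflow from the shell:

```sh
ict phantom --shape 144 144 192 --seed 3 --out ref.tif
ict segment ref.tif --out labels.h5
ict track ref.tif test.tif --out tracks.csv
ict report tracks.csv --out strain.json
ict validate --levels 1e-3 --seed 7 --out accuracy.csv
```

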