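# choromorph

Construction and morphometric measurement of 3D choroidal vessel models
from OCT-like grayscale volumes.

Given an acquired-polarity volume scan (vessels appear as dark silhouettes)
and a choroid mask, the pipeline

1. inverts and percentile-normalizes the volume,
2. enhances tubular structures with a multiscale Hessian (Frangi-type)
   filter computed in physical coordinates (anisotropic spacing honoured),
3. converts the response to 8-bit and binarizes it at a fixed threshold
   inside the choroid mask (the **vessel volume model**),
4. marks boundary voxels exposed on any of their six faces, excluding the
   scan border (the **vessel surface model**),
5. detects prominence-filtered intensity maxima in every fixed-x and
   fixed-z slice of the response and combines both passes (the **vessel
   line model**),
6. rasterizes a fovea-centred ROI — a 1-mm-diameter centre circle plus four
   quadrants of a 4.5-mm-diameter circle — and
7. reports eleven parameters per region: SFCT, CVolume, MCT, VVolume,
   VSurface, VLI, CVI, VLDI, VL–S ratio, S–V ratio and VDI, using the voxel
   scaling `v = dx·dy·dz`, `v^(2/3)` and `v^(1/3)` for volumes, surfaces
   and lengths respectively.

No clinical data ships with the package: a phantom module generates
OCT-like slab choroids containing tube networks with closed-form length,
volume, surface and diameter truth, which is how the pipeline is validated.

## Coordinate and unit conventions

- Arrays are indexed `(x, y, z)` = (fast scan, depth/A-scan, slow scan);
  the en-face plane is `(x, z)`. TIFF stacks store one z slice per page.
- All spacings are mm/voxel. The default geometry is 500 × 256 × 500 voxels
  over 6 × 3 × 6 mm, i.e. spacing (0.012, 0.01171875, 0.012); morphometric
  scaling can alternatively use the rounded depth pitch 0.01172 mm
  (`choromorph.PAPER_SPACING`) to reproduce published arithmetic.
- ROI quadrant orientation: x is horizontal with the temporal side at
  smaller x for a right eye (flipped for a left eye); z is vertical with
  superior at smaller z. Labels: 1 centre, 2 upper temporal, 3 lower
  temporal, 4 lower nasal, 5 upper nasal.

## CLI

```bash
# synthetic phantom (volume + mask + analytic truth table)
choromorph phantom --out-dir out/phantom --shape 256 128 256 --seed 1

# full chain: enhance -> models -> per-region parameter table
choromorph run out/phantom/phantom.tif out/phantom/choroid_mask.tif \
    --out-dir out/run

# individual stages
choromorph enhance VOLUME MASK --out-dir out/enh --scales 0.024 --scales 0.048 --threshold 40
choromorph model out/enh/response_8bit.tif out/enh/vessels_binary.tif --out-dir out/models
choromorph measure MASK out/models --out-csv parameters.csv --fovea 250 250
choromorph cohort per_eye_table.csv --out-dir out/stats --k 2
```

`run` writes the three model volumes (TIFF + YAML sidecars), tidy and wide
parameter CSVs, and a provenance JSON (config, software version, input
checksums). Outputs are byte-identical across reruns with the same config
and inputs.

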