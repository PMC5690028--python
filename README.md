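# emmcup

Cupping-artifact correction for reconstructed CT slices by alternating
energy minimization.

A reconstructed slice `f` is modelled over its object support as

    f(x) = sum_i c_i u_i(x)  +  w^T G(x)  +  noise

where the first term is a piecewise-constant tissue image (`u_i` a hard
partition into N tissue classes with means `c_i`), and the second is a
smooth additive cupping/bias field expanded in the complete bivariate
polynomial basis of total degree <= 3 (10 functions by default).  The
squared-residual energy is convex in each block, so the solver alternates
three closed-form updates — a Gram-matrix solve for `w`, per-class means
for `c`, a per-pixel argmin for `u` — until the tissue-mean vector changes
by less than `eps` (default 0.001 on an internal [0, 1] intensity scale).
The fitted field, recentred to zero mean over the support so the corrected
image keeps the input's mean intensity, is subtracted to remove the
artifact.

## Layout

- `emmcup.basis` — polynomial basis construction, Gram matrix, optional
  orthonormalization
- `emmcup.core` — image/partition/state types, the three closed-form
  updates, the solver loop, automatic object masking (Otsu + largest
  component + hole filling)
- `emmcup.metrics` — cupping magnitude `tau_cup = 100*(edge - center)/edge`,
  root-mean-square contrast (population sd after rescaling to [0, 255]),
  a CNR convention `|mean(center) - mean(background)| / sd(background)`,
  row profiles, JSON ROI specs
- `emmcup.synthetic` — disk phantoms (uniform, three-tissue, multi-insert)
  with exactly-known piecewise/bias/noise components, amplitude calibration
  to a target cupping magnitude, and a recovery-experiment harness
- `emmcup.io` / `emmcup.cli` — NIfTI / TIFF / PNG / raw-float readers and
  writers (DICOM read with the optional `pydicom` extra) and the CLI

## CLI

```sh
# make a synthetic water-phantom slice with ~20% cupping
emmcup simulate --geometry uniform_disk --shape 229 229 \
    --tau-target 20 --noise-sd 0.01 --seed 7 --out phantom/

# correct it and report metrics before/after
emmcup correct phantom/image.nii --tissues 1 --out corrected.nii \
    --bias-out bias.nii --metrics-out metrics.csv \
    --mask phantom/mask.nii --roi-file phantom/rois.json

# metrics only
emmcup metrics corrected.nii --roi-file phantom/rois.json
```

Solver flags: `--tissues N`, `--basis-degree` (default 3), `--eps`
(default 0.001), `--max-iter` (default 50), `--mask {auto|none|PATH}`,
`--orthonormalize`, `--seed`; a JSON/YAML `--config` file may supply the
same keys, with flags taking precedence.  Every run writes a provenance
JSON (config echo, package version, seed) next to its output.  Volumes are
processed slice-by-slice (`--slices` selects a subset).

## Conventions and caveats

- Pixel coordinates are 0-based; rectangular extents are half-open.
- The CNR definition above is a package convention; there is no single
  standard definition.
- Because the basis spans constants, the split between tissue means and
  bias field is fixed by forcing the estimated field to zero mean over the
  mask.
- Tissue-mean initialization defaults to seeded k-means on the masked
  intensities (deterministic given `--seed`); a quantile initializer is
  available via `SolverConfig(init="quantile")` but can merge classes when
  the cupping spread exceeds the class separation.
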