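# Running the pipeline on the public airborne benchmarks

The package is developed and tested entirely on generated scenes, but the
full pipeline runs unchanged on the two classic airborne hyperspectral
benchmarks distributed by Purdue's MultiSpec project:

* **AVIRIS 1992 Indian Pines** — 145 x 145 pixels, 220 bands, 400-2500 nm,
  ten agricultural ground-truth classes (tillage regimes, grasses, woods).
* **HYDICE Washington DC Mall** — a 300 x 500 subscene, 191 retained
  bands, 400-2400 nm, five urban/vegetation classes.

Both ship as integer digital-number cubes where reflectance is stored as
`DN = 10000 * reflectance`. The reader refuses to guess that factor, so it
must be passed explicitly.

## Recipe

1. Download the cube (ENVI or GeoTIFF form) and the ground-truth label
   raster; convert the truth to a single-band integer TIFF with 0 marking
   unlabeled pixels if it is not one already.
2. Prepare a `band,wavelength_nm` sidecar CSV when the ENVI header lacks a
   `wavelength` field, and (optionally) a 0/1 band-mask text file for
   water-absorption bands.
3. Run the experiment:

   ```sh
   mdshape classify --config run.yaml \
       --wavelengths wavelengths.csv --band-mask mask.txt --scale 1e-4 \
       indian_pines.img truth.tif out/
   ```

   With `--scale 1e-4` the cube is rescaled to [0, 1] reflectance on load;
   the default `md_reflectance_scale: 1.0e4` in the experiment config then
   restores the native DN magnitude for the moment-distance layers, which
   is the regime in which the MD family is shape-sensitive. A typical
   `run.yaml` for Indian Pines sets `scale: 5` (segmentation) and leaves
   the rest at defaults; the DC Mall subscene classifies well at a coarser
   segmentation scale.

4. Inspect `out/accuracy.csv` (object- and pixel-weighted OA/PA/UA/kappa
   per feature set), `out/mcnemar_z.csv` and the per-set
   `importance_set*.csv` rankings.

## Caveats — calibration-dependent, not a pass/fail check

Reported accuracies on these scenes depend on choices the original study
does not record: the exact segmentation algorithm and its scale mapping
(this package's region merge is an approximation with its own scale
units), which water-absorption bands were excluded, and the random
train/test draw. Comparisons against published accuracy tables for these
benchmarks are therefore qualitative. The quantitative guarantees of this
package are the ones its test suite establishes on generated scenes.
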