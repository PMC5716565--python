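# linacqa

Quantitative analyses for commissioning a linac used for SRS/SBRT, packaged
as a tested, reusable pipeline. Physical measurements are replaced by seeded
synthetic phantom-data generators that record their ground truth, so every
analysis can be validated by parameter recovery.

## Modules

| Module | Purpose |
| --- | --- |
| `linacqa.core_io` | Domain types (planar images, scan profiles, 6-DOF shifts), TIFF/PNG(/DICOM) and CSV readers/writers, detector-to-isocenter-plane geometry |
| `linacqa.synthetic` | Seeded generators: BB-plus-aperture portal images, picket-fence and star-shot exposures, line-pair patterns, sweeping-gap dose series, detector readings with volume averaging, dose planes, 6-DOF setup errors — each with a `GroundTruthManifest` |
| `linacqa.winston_lutz` | Sub-pixel BB and radiation-field-center detection; combination of the four cardinal gantry-angle offsets into a 3D isocenter estimate |
| `linacqa.mlc_qa` | Picket-fence spacing/FWHM analysis, star-shot minimum enclosing circle, MLC transmission, dynamic-leaf-gap fit |
| `linacqa.beam_data` | PDD queries, lateral-profile FWHM and 80–20% penumbra, small-field output-factor daisy-chaining across detectors |
| `linacqa.image_quality` | Relative MTF from line-pair group ROIs and the 50% frequency (f50) |
| `linacqa.localization` | Residual-error statistics, cross-system comparisons, rotation exceedance, rigid (Kabsch) couch-rotation verification from embedded BBs |
| `linacqa.end_to_end` | Film-to-dose conversion, 2D gamma analysis with sub-pixel search, hidden-target offsets, per-beam isocenter dose report |

## CLI

All functionality is exposed through the `linacqa` entry point, with one
subcommand group per module:

```sh
# generate a synthetic cardinal Winston-Lutz image set, then analyze it
linacqa synth wl-set --out-dir wlset \
    --offset 0.4 0.7 --offset 0.2 0.3 --offset -0.3 0.0 --offset -0.1 0.3
linacqa wl analyze --images wlset/g0.tif wlset/g90.tif wlset/g180.tif wlset/g270.tif

# MLC QA
linacqa mlc picket-fence image.tif --spacing 30
linacqa mlc star-shot image.tif
linacqa mlc dlg --gaps 1,5,10,20,50,100 --doses ... --dleak 0.126
linacqa mlc transmission --closed 1.17 --open 100

# beam data
linacqa beam pdd scans.csv --depth 100
linacqa beam profile scans.csv
linacqa beam output-factors small.csv ref.csv --intermediate 30

# image quality, localization, end-to-end
linacqa iq rmtf image.tif --rois rois.yaml
linacqa loc stats shifts.csv
linacqa loc exceedance shifts.csv --thresholds 3,5
linacqa loc couch --pre pre.csv --post post.csv
linacqa e2e gamma ref.csv eval.csv --dd 3 --dta 1
linacqa e2e dose-report plan.csv measured.csv
```

Image geometry (pixel pitch, SAD/SDD, angles) comes from a YAML sidecar
(`image.yaml` next to `image.tif`) or `--meta`.

## Conventions

- Pixel coordinates are 0-based pixel centers; all reported distances are
  isocenter-plane mm (detector mm divided by the magnification SDD/SAD).
- In-plane offsets: x left(−)/right(+), y up(−)/down(+) in the beam's-eye
  view at collimator 0.
- Standard deviations use the n−1 denominator; vector-length statistics are
  the mean/std of per-trial Euclidean norms.

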