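# ulmpipe

Super-resolution ultrasound localization microscopy (ULM) analysis pipeline
with a ground-truthed synthetic phantom.

The package takes beamformed complex IQ frame stacks through the full ULM
chain and quantifies the result:

1. **phantom** — synthetic vascular-flow phantoms: tube vessels with laminar
   (Poiseuille) flow, Gaussian microbubble echoes, exactly low-rank tissue
   clutter, depth-dependent noise, cardiac-frequency pulsatility, plus
   two-channel fluorescence section images. Every output ships with its
   ground truth, so each downstream stage is verifiable.
2. **prefilter** — SVD clutter filtering on the Casorati matrix with an
   adaptive (log-spectrum knee) or fixed rank cutoff, depth noise
   equalization, power Doppler, and heart-rate estimation from power-Doppler
   pulsatility.
3. **localize** — empirical 2D-Gaussian PSF fitting, matching-pursuit
   separation of overlapping echoes, cubic-spline upsampling to the
   4.928 µm isotropic grid, normalized cross-correlation detection and
   sub-pixel centroid refinement.
4. **track** — gated linear-assignment frame-to-frame linking (no gap
   closing), 10-frame minimum track length, per-step velocities.
5. **maps** — supercover-line accumulation of tracks into density, velocity
   and directional-flow rasters.
6. **roiquant** — ROIs from Hobby-spline control vertices, vascularity,
   median velocity, sum-of-angles tortuosity (SOAM), arteriole/venule
   splitting by flow direction, single-vessel velocity profiles with
   parabolic fits.
7. **histo** — sliding-window median adaptive thresholding, morphometric
   (overlap) exclusion of bleed-through, positive-area fractions.
8. **stats** — one-way ANOVA (raw values or printed n/mean/SD summaries),
   sequential two-way ANOVA, Benjamini–Hochberg adjustment, two-sample
   Kolmogorov–Smirnov, Pearson correlation, replicate averaging.

## CLI

```sh
ulm run --config run.yaml --out out/          # end-to-end phantom run
ulm phantom make --preset straight --seed 1 --out out/phantom
ulm prefilter run --stack out/phantom_iq.h5 --rank-mode adaptive --out out/pf
ulm localize run --stack out/pf_filtered.h5 --ncc-threshold 0.6 --out out/locs.csv
ulm track run --locs out/locs.csv --gate-um 30 --min-len 10 --out out/tracks.csv
ulm maps render --tracks out/tracks.csv --shape 512 512 --out out/map
ulm quant run --maps out/map.h5 --tracks out/tracks.csv --roi rois.json --out out/metrics.csv
ulm histo quant --fitc fitc.tiff --abeta abeta.tiff --out out/histo.csv
ulm stats run --metrics metrics.csv --adjust bh --out out/stats.csv
```

IQ stacks are HDF5 (`real`/`imag` datasets with `pixel_spacing_um` and
`frame_rate_hz` attrs) plus magnitude-only multi-page TIFF for inspection;
tracks and metrics are CSV; ROIs are JSON lists of
`{label, vertices_um, surface_normal}`.

## Conventions

Image axes are `(z, x)` — axial depth by rows, lateral by columns; positions
are µm from the top-left pixel centre (0-based); velocities are mm/s; the
super-resolved grid spacing is 4.928 µm isotropic.
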