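# iscatflow

Label-free single-particle analysis for wide-field interferometric
scattering (iSCAT) image scans of microfluidic immunoassay channels —
detection, quantification, binding kinetics and surface-marker
fingerprinting — together with a synthetic instrument simulator that
provides ground truth for every stage.

## The problem

Surface-based label-free biosensing images nanoparticles (extracellular
vesicles, liposomes, protein aggregates, substrate defects) as
diffraction-limited spots whose signed contrast arises from interference
between the particle's scattered field and the reflection from the
substrate/water interface.  Turning raw raster-scanned camera frames into
biology means solving a chain of image-analysis problems: removing
illumination structure, rejecting out-of-focus background, detecting spots
barely above substrate roughness, localizing them to sub-pixel precision,
stitching overlapping fields of view, counting per unit area, following
capture kinetics in flow, and normalizing multi-antibody panels into
fingerprints.  `iscatflow` implements this chain for people building or
evaluating such platforms, with a simulator in place of the instrument.

## The method

For a flat-fielded frame with baseline 1, the residual after subtracting a
17×17 spatial median retains diffraction-limited spots unchanged.  With a
global noise scale `σ_g = 1.4826·MAD(residual)` and a local noise map
`σ(x) = RMS{ v ∈ 65×65 window : |v| ≤ 2.5 σ_g }`, a particle is detected
where the SNR image `|residual|/σ(x)` exceeds 4 on at least 3 pixels
within a 3×3 neighbourhood.  Each detection is localized by the
radial-symmetry-centre construction (gradient lines on the rotated
midpoint lattice, weighted least-squares intersection) and measured by its
signed contrast `c` and ROI-integrated contrast (`≈ 2πσ_psf² c`).
Detections split at |c| = 7.5×10⁻³ into background (substrate) and signal
(analyte) classes; densities are counts per 100 μm².  Channel capture
follows a stream-tube transport model `dn/dt = k_c c(x,t) (1 − n/n_max)`
with downstream depletion `dc/dx = −k_c W c (1 − n/n_max)/Q`, diagnosed by
a Damköhler number `Da = k_on b_m δ / D`.  Fingerprints are per-antibody
steady-state densities normalized to the isotype-control mean.

See `docs/methods.md` for model assumptions, parameter defaults and
limitations.

## Worked example

A two-channel simulated assay (isotype control IgG1 vs an anti-CD81
channel with 3× the capture rate), from a TOML config:

```toml
seed = 7
n_tiles_row = 1
n_tiles_col = 2
output_dir = "example_out"

[optics]
frame_side = 256

[transport]
c0 = 2e8
k_c = 0.05

[[channels]]
channel_id = "ch0"
antibody = "IgG1"
concentration = 2e8
timepoints = [1.0, 2.0, 3.0, 4.0, 5.0]

[[channels]]
channel_id = "ch1"
antibody = "CD81"
concentration = 2e8
capture_multiplier = 3.0
timepoints = [1.0, 2.0, 3.0, 4.0, 5.0]
```

```text
$ iscatflow all -c example.toml
config hash 75a33a26df4a
channel ch0 [IgG1]: 74 localizations, signal 13.12 / background 0.95 per 100 um^2
channel ch1 [CD81]: 238 localizations, signal 42.39 / background 2.85 per 100 um^2
fingerprint (normalized to IgG1):
  IgG1: 1.00
  CD81: 3.23
```

Each channel was simulated (transport-limited capture for 5 h, then a
raster scan of the channel floor rendered with illumination shading,
substrate speckle and shot noise), flat-fielded from its own 60-frame
stack, stitched, localized and quantified.  The signal-class density of
the CD81 channel normalizes to 3.23× the control — recovering the
simulated 3× capture enrichment — while the background class (substrate
defects, |contrast| ≤ 7.5×10⁻³) stays near the control level in both.
Per-channel localization tables, binding curves and the fingerprint are
written to `example_out/`, each stamped with the config hash.

The library surface mirrors the chain: `simulate` (ground-truth scenes),
`preprocess` (normalize/flat-field/median-subtract), `stitch`, `localize`,
`quantify`, `kinetics`, `fingerprint`, with `scenarios` bundling standard
study conditions.

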