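# Methods

## The inspection model

The pipeline assumes a push-broom VNIR camera above a conveyor: each frame is
one spatial line (≤ 1024 samples) × one spectrum (≤ 224 bands, 400–1000 nm)
of raw digital numbers (DN). A sheet of seaweed passes under the camera once;
the along-track axis is time. Three properties of the scene drive the design:

* **Per-pixel brightness offsets are large.** The sheet surface is glossy and
  uneven, so two pixels of identical material differ mainly by a
  multiplicative gain, plus sporadic *diffuse-reflection* events that add
  brightness in the 500–680 nm window. Per-Norm — min–max scaling of each
  dark-corrected pixel spectrum to [0, 100] — removes the gain exactly and
  leaves the additive events as bounded in-band shifts.
* **Seaweed and belt separate on two band differences.** After Per-Norm, the
  difference between a red-edge band and a green band (SV), and between an
  early-NIR and a late-NIR band (SN), fall in disjoint intervals for the two
  materials. Interval membership is a per-pixel constant-time test.
* **Unanticipated contaminants need a one-class test, not a classifier.**
  Stage 2 z-scores a pixel against its segmented class's reference statistics
  and flags any excursion beyond the reference envelope plus a margin. It
  presumes nothing about the contaminant except that it differs somewhere in
  the spectrum.

### Stage-1 decision rule

For each pixel, SV and SN are tested against the class intervals (closed
bounds). Foreign wins if *either* range recognizes no class. When both
ranges recognize some class, the visible range decides; pixels on which the
two ranges disagree about the class follow the visible range and are counted
to a DEBUG log. With the shipped intervals the two classes are disjoint in
both ranges, so the rule is total and order-free.

The band pairs (26, 63) and (68, 93) and the four intervals are shipped as a
versioned YAML config for the 112-band half-binned grid, on which those
1-based indices sit at 535.1/735.1/762.2/897.3 nm. They are configuration,
not code: `select_band_pair` re-derives pairs for new materials by exhaustive
search over all in-range pairs, scored by the separation of the class-mean
differences, with deterministic lexicographic tie-breaking, and
`derive_intervals` re-derives intervals (observed min/max per class, optional
slack — default 0, since the shipped operating point uses fixed intervals).

### Stage-2 envelope

A class profile holds per-band mean μ, *population* standard deviation σ
(with ~10⁴ reference pixels the sample/population distinction is
negligible; population keeps tiny fixtures deterministic) and the envelope
[env_low, env_high]: the band-wise min/max of the standardized reference
pixels themselves, not ±kσ. By construction every reference pixel is clean
at any margin ≥ 0, and the flagged set shrinks monotonically as the margin
grows. The margin defaults to 3 z-units; lowering it raises sensitivity.
Stage-1 foreign pixels are excluded from stage 2, and belt pixels outside
the bounding box of seaweed-labeled pixels are skipped entirely. The bbox
rule is our construction for the ignored zone (the concept predates us; the
construction rule was open): belt pixels *inside* the box stay inspected,
because objects overhanging the sheet edge can segment as belt.

### Streaming

Both stages are per-line (stage 2 per-pixel), so `detect_stream` consumes an
iterator of calibrated lines and is bit-identical to whole-cube processing
when the ignored zone is off. With the bbox mode the sheet extent is
unknowable per line; streaming approximates it with a trailing window of 64
lines (column extent only), a documented divergence from batch mode.

### Sheet verdict and metrics

A sheet is rejected when ≥ `min_foreign_pixels` (default 1) pixels are
foreign; connected foreign regions are counted with 4-connectivity
(conservative choice). Sheet-level scoring treats *contaminated* as the
positive class: TP = contaminated rejected, FP = clean rejected. Display
rounding is half-up to 2 decimals; raw fractions are always retained.

### SAM baseline

The comparison classifier labels each pixel by spectral angle to labeled
training pixels. Two modes: `nearest_angle` (default; transparent, ties to
the smallest training index) and `svm_precomputed`, a one-vs-one SVM on the
kernel K = exp(−θ). The exponential transform is our choice for a
well-conditioned kernel matrix; the original multi-class SVM's internals
(variant, hyperparameters, training-set size) are not specified anywhere, so
results from this mode are labeled as a reimplementation.

## Calibration details

* The printed Per-Norm formula is ambiguous about operator order; we subtract
  the dark current per band first, then min–max scale (the readings coincide
  when D is band-constant).
* Extrema are per-pixel, never global — that is what produces the
  offset-cancelling behavior.
* `subtract_dark` clamps at zero (sensor counts are non-negative); the
  normalizations use the unclamped difference internally so Max-Norm keeps
  its (−∞, 100] range.
* Degenerate pixels (constant spectrum after dark removal) are set to 0 with
  a warning rather than raising: a dead pixel must not abort a production
  line scan.
* Spectral binning is decimation keeping the first band of each group
  (phase configurable), never averaging, and refuses non-divisible band
  counts.
* ENVI I/O is implemented in-package (header + raw raster, BIL/BIP/BSQ,
  standard data-type codes). BIL is the write default, being the native
  frame order of a line camera. Dark/white references are stored as
  single-line ENVI rasters.

## The synthetic camera

The generator reproduces the *decision structure* of the problem — interval
membership, envelope excursions, diffuse events, geometry — not radiometric
reflectance. Real seaweed spectra are only available as published figures,
so the material library is an acknowledged stand-in built from
piecewise-linear Per-Norm-space profiles mapped to DN via

    DN = dark + gain_pixel · shape/100 + boost + N(0, noise_sd),

quantized to uint16. Defaults, chosen once:

| parameter | default | why |
|---|---|---|
| band grid | 112 bands, uniform 400–1000 nm | the half-binned operating point |
| samples/line | 1024 (benchmark uses 256) | sensor width; benchmark scaled to desk size |
| pixel pitch | 0.25 mm (benchmark 1.0 mm) | 20 cm sheet spans ~800 (resp. 200) samples, leaving belt margins for the ignored zone |
| belt speed / line rate | 30 cm/s, 300 lines/s | the production operating point; a 26 cm sheet spans 260 lines |
| sheet formats | rectangular 26×20 cm, square 20×20 cm | the two commercial formats, alternating in benchmarks |
| gain jitter | ±10 % (belt ±8 %) | pixel-offset magnitude; cancelled by Per-Norm |
| diffuse boost | p = 0.35, amplitude 3–6 shape units over 500–680 nm | sporadic gloss events confined to the stated window |
| sensor noise | σ = 3 DN | small relative to material gains (700–2600 DN) |
| dark / white | smooth deterministic patterns, ~40 DN and ~3240 DN | fixed-pattern references consistent with reflectance calibration |

Material profiles are constructed so that, after Per-Norm, seaweed and belt
land inside the shipped stage-1 intervals with worst-case slack (a corner
check over all jitter bounds runs at library construction and raises on
violation); shrimp shell, insect and thread fall outside both visible
intervals (stage-1-detectable); plastic hides inside the seaweed intervals
but exceeds both class envelopes at 560–650 nm and near 780 nm
(stage-2-only). All material jitters are bounded (uniform), so reference
envelopes built from 10⁴ draws cover fresh draws up to Gaussian-noise tails
far below the margin.

One modeling subtlety: Per-Norm pins each pixel's minimum band to exactly 0
and its maximum to exactly 100, so the extremal regions must vary from pixel
to pixel or those bands would have zero reference spread. Each profile
therefore has flat extremal plateaus (e.g. 400–410 nm at 0), and the
inspected classes carry small jitter on the plateau control points: real
material varies at every band, and the envelope presumes the per-band
reference spread reflects material variation, not bare sensor noise (whose
one-sided tail at a pinned band a min/max envelope would understate).
Per-pixel plateau shifts cancel out of the subtraction features up to a
small scale distortion that the feasibility check bounds.

Everything derives from a single integer seed; a fixed seed yields
byte-identical cubes.

### What the benchmark does and does not show

The 120-sheet benchmark (60 clean + 60 contaminated, 1–3 objects of 2–6 px
per contaminated sheet) exercises every printed decision behavior: stage-1
catches interval-violating materials, stage-2 catches envelope-violating
ones, clean sheets pass at margin 3, and the verdict logic aggregates
correctly. Because the generator's spread is bounded by construction, the
synthetic recall/accuracy are near-perfect; they validate the
implementation, not the published real-data accuracy, which depended on 120
physical sheets that were never deposited. Features of real data the
generator does not emulate include mixed boundary pixels, spatially
correlated texture, wavelength-dependent illumination drift and specular
saturation — all of which would move the false-reject rate off zero.

## Numerical choices

* All detection arithmetic is float64; per-line and whole-cube paths use the
  same elementwise kernels, which is what makes streaming bit-identical.
* `sam_angle` clips cosines into [−1, 1] before `arccos`.
* Band numbers are 1-based in all user-facing configuration (matching the
  field's "26th band" convention) and 0-based internally; conversion happens
  once at config parse.
* Reference profiles serialize to a versioned plain-text TSV (class, band,
  wavelength, μ, σ, env_low, env_high) with `repr` round-tripping, so a
  detection run is reproducible without the training pixels.
* Benchmark problem sizes (256 samples/line, 10⁴ reference pixels, 24
  training pixels/class for SAM) are the package's desk-scale defaults;
  full-width scenes are a constructor argument away.

## Known limitations

* The ignored-zone bbox rule is one of several plausible constructions; with
  concave sheets it inspects more belt than a tight hull would.
* The raw bit depth of the sensor is not fixed by the design; the throughput
  calculator takes bytes/sample as a parameter (default 1, matching the
  published stream arithmetic, though cameras of this class typically emit
  12–16 bits).
* Published binning savings are quoted "per line" in the source material but
  equal per-second magnitudes; the calculator implements them per second.
* Sheet-level TN/FN prose in the source conflicts with its own count table;
  the metrics follow the arithmetic (positive = contaminated).
* Wall-clock per-line timings are hardware claims and are not asserted
  anywhere in this package.
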