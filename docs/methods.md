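# Methods

This note records the models, parameter choices and numerical decisions
behind `optopore`, and what the synthetic-data tests do and do not
demonstrate about real microscope data.

## Synthetic dish scenes (`optopore.scene`)

**Bright field.** Adherent cells in bright field show little interior
texture; what a camera sees is a contrast ring where the membrane
refracts light. Each synthetic cell is therefore a disk whose interior
sits at the background level plus a small per-cell offset (±10 % of the
edge contrast) and whose outer 2 px annulus carries the full
`edge_contrast` amplitude (default 50 counts on a 12-bit scale over a
background of 200). This is deliberately the *minimal* stimulus for an
edge detector: any algorithm that finds these rings is responding to
contour contrast, not to texture cues that real CHO cells do not
reliably offer. Additive Gaussian noise (default sd 2 counts for bright
field) is applied last and the image clipped to the bit depth; Poisson
photon statistics, point-spread blur and phase-contrast artefacts are
not modelled.

**Fluorescence.** The three channels (DAPI, EtBr, calcein) share one
label image. Each cell draws a true intensity from its
class-conditional Gaussian and is rendered as that base level times a
radial profile rising from 1× at the rim to 1.5× at the centre —
stain accumulates toward the nucleus, and this centre weighting is what
lets a maxima-based segmentation localise cells. Because every pixel is
at least the base level, a cell whose drawn intensity exceeds the
camera range saturates *wholly* at `2^bit_depth − 1`, reproducing the
pile-up in the top histogram bin that saturated cells produce on a
12-bit camera.

Default intensity models (12-bit scale, mean ± sd):

| class              | DAPI        | EtBr       | calcein    |
|--------------------|-------------|------------|------------|
| intact             | 1000 ± 100  | 0          | 1500 ± 200 |
| optoporated-alive  | 3000 ± 700  | 0          | 1500 ± 200 |
| dead               | 3000 ± 700  | 2000 ± 300 | 0          |

The intact DAPI model places the control population at ~1000 counts,
the regime in which a mean + 2 SD gate sits near 1200 raw counts; the
perforated-cell mean of 3000 ± 700 puts a visible minority of cells
into saturation. Channel noise (default sd 10) is pixelwise Gaussian,
clipped at zero, so "absent" channels (EtBr in living cells) read as a
half-normal background of a few counts — which is exactly what the
background-derived EtBr/calcein gates must tolerate.

**Randomness policy.** One root seed; placement, class assignment,
per-cell channel draws and per-channel pixel noise each use
`default_rng(seed + fixed_offset)` with documented offsets, so any
stream can be reproduced independently (the class-count test does
precisely this with a direct multinomial draw). Identical
(spec, seed) pairs give byte-identical images.

**Placement.** Rejection sampling keeps centre-to-centre distance at
least the sum of radii in non-overlapping mode, cells fully inside the
frame; 1000·n attempts before a `PlacementError`. Default cell radii
5–7 µm at 0.5 µm/px match CHO-scale cells (10–14 µm diameter).

## Rake edge detection (`optopore.detect`)

The profile scanner is a Schmitt-trigger state machine with
contrast-relative baselines. Scanning pixel by pixel (optionally after
a moving-average kernel of half-width `kernel_half_width_px`):

* a **rising** edge fires at the first index whose value exceeds the
  running *minimum* since the last event by ≥ `min_edge_strength +
  hysteresis`;
* a **falling** edge fires when the value drops below the running
  *maximum* since the last event by ≥ `min_edge_strength − hysteresis`.

Either polarity may fire first; polarities then alternate, and both
baselines reset to the value at each event. The running-extremum
baseline is the simplest scheme consistent with a first-crossing edge
definition on images whose absolute background level is arbitrary; it
is stated here explicitly and pinned down by an exhaustive oracle test
(every 3-level profile up to length 12). Hysteresis must satisfy
`0 ≤ h < min_edge_strength`, which keeps the falling release strictly
positive. When both polarities are admissible at one index, rising is
checked first.

Rake geometry: horizontal lines at rows 0, s, 2s, …; each line is
split into column segments of the search-area width and the edge
machine restarts per segment, so one segment's contrast cannot leak
into the next. Two roles of the search-area size are deliberately
separated: `search_area_size_um` fixes the column segmentation, while
`rake_spacing_um` (defaulting to it) fixes the line spacing. Varying
only the spacing leaves per-row detections identical, which makes the
line-subset property exact — spacing 2s scans a subset of the
positions of spacing s, and per-cell means are monotonically
non-increasing in spacing. Vertical scanning exists behind an
off-by-default flag.

Deduplication is a greedy pass in raster order keeping a position iff
it is ≥ `min_separation_um` (default: half the search-area size) from
every kept position; the earlier position wins, which keeps the
illumination order stable. The kept set is verified against an O(n²)
brute-force oracle and is idempotent by construction.

`estimate_cells_treated` follows the printed-precision chain used when
reporting treated-cell counts from a sampled per-cell mean: the mean
is rounded to two decimals before dividing the total position count,
and the quotient is rounded to the nearest ten (404/281 → 1.44;
6281/1.44 → 4360).

## Scan control and timing (`optopore.scan`)

The meander plan is the serpentine order (row 0 left→right, row 1
right→left, …), which visits every tile exactly once with consecutive
tiles grid-adjacent — each inter-FOV move is exactly one FOV.

Stage model: a centring move of distance d costs
`stage_overhead_ms + stage_ms_per_10um · max(d, 10)/10`. The 15 ms per
10 µm slope includes acceleration and stop; the clamp at 10 µm models
that floor for shorter moves, and the 20 ms overhead places a typical
within-FOV move in the 30–40 ms band. The model is declared linear
with a floor, not inferred: a single printed distance-time point and
an aggregate band cannot identify a richer acceleration profile, so
the overhead is exposed as a parameter. With 100 ms illumination this
yields a steady-state 7.2–7.4 positions/s, inside the expected 7–8
band; per-FOV costs (150 ms reposition, 35 ms exposure, ~1 ms/position
detection) amortise away on confluent dishes.

Event logs carry (timestamp, kind, duration); the elapsed time equals
the sum of durations *exactly* (pure accounting, no rounding), shutter
open/close events bracket exactly the illumination window, and
`execute_run` — the closed loop that acquires a virtual image per FOV,
detects, deduplicates and illuminates — must produce an event trace
identical to `simulate_run` replayed on its detected targets. Within a
FOV, positions are illuminated in detection (raster) order; a
nearest-neighbour order was considered and rejected as a default
because raster keeps the trace deterministic and moves short for
line-scanned detections. The virtual stage reports its position after
every commanded move; any mismatch aborts with a diagnostic rather
than silently illuminating the wrong place.

Focus correction fits z = a·x + b·y + c to ≥ 3 non-collinear
calibration points by least squares (rank-checked; RMS residual
reported) and evaluates it per stage position — the plane models a
tilted culture dish. Multi-height illumination (several shots a few µm
apart in z) is available as a multiplier rather than a focus search.

## Outcome classification (`optopore.classify`)

Pipeline: percentile histogram normalisation (0.5th/99.5th percentiles
to the bit-depth extremes; constant images pass through) → grey-scale
opening with a disk (default radius 3 px) to suppress small intensity
peaks → extended h-maxima (default depth 200 post-normalisation
counts) → connected components (8-connectivity) → area filter
(default ≥ 20 px) → relabel 1..K in raster order.

The extended-maxima components are used directly as cell regions; no
watershed growing. For centre-weighted nuclei the marked component is
the nucleus cap, so centroids are accurate (≤ 0.3 px mean error on
default-SNR scenes) but areas under-measure the cell footprint —
acceptable because classification uses mean intensities, measured on
the *raw* registered channels over the cap pixels, not areas. The
default h of 200 sits well below the dimmest (intact, ~1000-count)
cell amplitude and well above the post-opening noise floor, so which
cells are found is insensitive to h over a wide range; the area filter
is what rejects residual noise maxima.

Gates: DAPI = control-cell mean + 2 sample SDs (n−1 denominator). A
`gaussian_fit` mode instead fits a Gaussian to the binned histogram of
control means (least squares on counts) and returns µ̂ + 2σ̂ — robust
when a saturation pile-up would inflate the sample moments; the two
modes agree within ~2 % on clean Gaussian controls and both are kept.
EtBr and calcein gates are built by the same mean + 2 SD construction
but from *background pixels* (DAPI-dark, outside segmented cells) of
the control channels, since control cells are alive: their calcein is
positive and cannot serve as a negative reference. By construction the
DAPI gate misroutes the one-sided 2σ tail (≈ 2.28 %) of true controls;
the Monte-Carlo test checks exactly this rate, so "near-zero" control
r_o is a property of the gate, not a claim of perfection.

Decision rule per cell: DAPI ≤ gate ⇒ INTACT; else EtBr ≥ gate ⇒
DEAD; else calcein ≥ gate ⇒ OPTOPORATED_ALIVE; else AMBIGUOUS. The
AMBIGUOUS class stands in for bench-side manual inspection of dim
calcein signals and is counted in N_total only, so r_d + r_o ≤ 1
always holds. Saturated cells (any pixel at the ceiling) are flagged
and classified on their clipped means rather than excluded.

## What the synthetic tests do and do not show

Passing tests demonstrate that the algorithms implement their stated
contracts and recover known ground truth under the generator's
assumptions: circular cells, ring-contrast bright field, Gaussian
class-conditional intensities, exact channel registration, no
photobleaching or spectral bleed-through. They do not demonstrate
performance on real bright-field images of irregular cells, on
misregistered channels, or under illumination gradients — on real
data the detection threshold, search-area size and h-value must be
re-tuned per experiment, which is why all three are first-class
parameters rather than constants. Reported end-to-end numbers
(targeting recall, r_o/r_d recovery, segmentation recall) are
computed at run time by the test suite and `scripts/acceptance.py`
on dishes of 100–300 cells in 1024² frames — sizes chosen so the
statistical checks (3-SD binomial bands, 3-SE Monte-Carlo bands at
n = 10⁴) are meaningful while a full run stays under a minute.

## Known limitations

* The edge detector's internal semantics (baseline definition,
  tie-break order) follow the simplest scheme consistent with a
  first-crossing rule; proprietary implementations of rake-style
  detection may differ in unpublished internals, so the constants are
  parameters, not guesses.
* The timing model is linear-with-floor; long moves on a real stage
  may be acceleration-dominated and nonlinear.
* Whether a per-cell DAPI statistic should be the mean, sum or peak is
  a modelling choice; the mean is used, isolated behind one accessor
  (`SegmentedCell.mean_dapi`).
* Segmentation assumes non-touching nuclei; merged clumps would need
  watershed splitting, which is out of scope.
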