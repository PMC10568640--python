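# Methods

This note documents the models, numerical choices and open design decisions
behind `myodiff`, in the order the pipeline applies them, followed by the
simulator that the test suite uses as ground truth.

## FCS 3.0 input and output

The reader supports list-mode FCS 3.0/3.1 with datatypes `F` (float32) and
`I` (unsigned integers of a uniform 8/16/32-bit width); ASCII (`A`) and
double (`D`) data are rejected with an explicit unsupported-format error, as
are non-list modes. These restrictions match what bench-top cytometers of
the Guava class export and keep the reader small enough to verify byte by
byte. Integer channels declared with a decadic log amplifier
(`$PnE = f1,f2`, `f1 > 0`) are linearized on read as
`v = f2 · 10^(f1·x/R)` with `R = $PnR` and `f2 = 0` treated as 1, because
every gate in the package is expressed in linear RFU.

Merged (multi-dataset) files are followed along the `$NEXTDATA` chain. The
standard is ambiguous in practice about whether offsets of later datasets
are absolute or relative; this package consistently uses offsets relative to
the start of the owning dataset (identical to absolute offsets for the first
dataset), for both HEADER fields and `$NEXTDATA`, and documents that as its
dialect. The writer emits exactly one dialect — float32, little-endian,
TEXT delimiter `/`, no ANALYSIS segment — so write→read round-trips are
bit-exact at float32 precision; this is asserted by tests at 30,000 events.

No vendor keyword for the acquisition well is standardized, so the reader
tries `$WELLID`, `WELL ID`, `WELLID`, `WELL`, `$SMNO` in that order and
degrades to a filename-derived sample id. Channel-name matching treats `.`
and `-` as the same separator and is case-insensitive, since instrument
software renders the same channel both ways (`GRN.B.HLin` / `GRN-B-HLin`).

## Transforms

Fluorescence spans about four decades, so density estimation runs in a
log-like space. The "biexponential" display scale is implemented as a scaled
inverse hyperbolic sine, `t = asinh(v/c)/ln 10` with cofactor `c = 5` RFU:
log-like (one unit per decade) for `v ≫ c`, linear through zero, defined for
the zeros and small negatives that linear channels can contain, and
closed-form invertible. Vendor biexponential/Logicle parameterizations vary;
only strict monotonicity matters for gating correctness (a threshold in
transformed space maps to a unique RFU threshold), which every transform
here guarantees on its domain. A floored `log10` (floor 0.1 RFU) is provided
for display parity; it is invertible only above the floor and raises a
domain error below it.

## Gating primitives

* **Intervals are half-open**, `low ≤ v < high`, for bins and bounded gate
  edges. Published bin tables are sometimes printed with gaps
  (e.g. 24.1–100, 101–1000): user-specified literal bounds are honored
  verbatim (events in gaps are counted and logged as unbinned), but the
  default contiguous scheme shares boundaries at 100 and 1000 RFU so no
  event is silently unclassifiable.
* **Quantiles** are linear-interpolation (type-7) order statistics, the
  dominant convention; the fraction of events at or below the result is
  within `1/n` of the requested level, which is the property the
  calibration gate relies on.
* **GFP+ membership is `v ≥ T`** — whether the boundary event is "above"
  the threshold is not observable in practice, and `≥` keeps the bin lower
  bound and the threshold consistent.

## Density estimation and peak splitting

The MyHC distribution inside a GFP bin is background plus (possibly) a
differentiated mode, i.e. two log-scale modes. The cutpoint between them is
located as follows: transform to arcsinh space, estimate a Gaussian-kernel
density with Silverman's bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)` on a
512-point grid spanning `[min − 3bw, max + 3bw]`, keep local maxima with
prominence ≥ 5% of the density maximum, and place the cutpoint at the global
density minimum strictly between the two tallest peaks (leftmost grid point
on ties), mapped back to RFU. With fewer than two qualifying peaks the bin
is treated as single-population background and a fixed fallback threshold of
10 RFU is used — the level the instrument gains are tuned to place the
double-negative cluster at — and the result is flagged `fallback_threshold`.
Bins with fewer than 50 events are reported not-analyzable rather than
split.

Numerical details worth recording:

* the bandwidth's spread statistics are functionals of the empirical CDF
  (population sd, inverted-CDF quartiles), so the density — and hence the
  cutpoint — is exactly invariant under duplication of the event list when
  the `n` of the bandwidth rule is held; the IQR term falls back to the sd
  when heavy ties drive it to zero;
* the 5% prominence floor suppresses shot-noise bimodality at moderate n,
  but very small populations (a few hundred background events) can still
  split spuriously; such populations are control-sample corners, not the
  target bins the assay quantifies;
* the density is evaluated directly (chunked over events), normalization
  uses the true event count, and the trapezoidal integral is within 1% of 1.

The debris gate defaults to FSC ≥ 100 and SSC ≥ 50 RFU; instrument-specific
boundaries vary and the defaults are configurable, not asserted as any
instrument's. Doublet discrimination (FSC area/height within ±25% of the
median ratio) is implemented but **off by default**, matching the automated
workflow this package mirrors; it can be enabled per analysis.

## Pipeline-level decisions

* Control quantiles are computed on **non-debris** events: thresholding on
  debris-contaminated data would be inconsistent with applying the threshold
  after the debris gate. (Whether the original interactive tool orders it
  the same way is not documented; this is the package's choice.)
* The GFP+ control is accepted and reported (its GFP+ fraction should be
  high) but does not enter the threshold average — only the double-negative
  and MyHC+ controls calibrate the gate.
* Role assignment is explicit (sample id or well → role) rather than
  inferred from file order.
* The QC rule flags a differentiation control **strictly below** 5% MyHC+.
* `run_pipeline` is deterministic: identical inputs give byte-identical CSV
  outputs, and the run log records every effective default, the fitted
  threshold, and per-sample unbinned counts.

## The simulator

`simulate_sample` draws, per event: a debris flag (5% default), scatter
intensities (lognormal; cells at FSC ~1000 / SSC ~500 RFU with 0.15 decades
sd), background fluorescence in both color channels (~5 RFU, 0.15 decades),
a transfection flag (40% of cells for GFP+/target roles) with a GFP dose
drawn from a wide lognormal (10^2.2 RFU median, 0.8 decades sd, spanning
roughly 10¹–10⁴ RFU), and a differentiation flag drawn *before* intensities
from the dose response

`p(g) = p0 · [1 − (1 − E) · g^h / (g^h + K^h)]`

with baseline `p0 = 0.4`, half-point `K = 30` RFU, Hill exponent `h = 1.5`,
and rescue `E ∈ [0,1]` (`E = 1` makes the probability flat at `p0`).
Differentiated cells draw MyHC from a lognormal at ~300 RFU (0.15 decades),
undifferentiated ones from background — about 12 KDE bandwidths of
separation in transformed space inside a typical bin, so valley-splitting
tolerances are meaningful. Doublets (2% default) merge a flagged event with
a random true singlet: area channels summed, height the pair maximum, truth
flags OR-ed, so a doublet containing a differentiated member is genuinely
MyHC-bright. Debris scatter is located at ~3% of the cell locations
(FSC ~30 / SSC ~15 RFU) so that the default debris gate removes ≳99.5% of
it; placing debris nearer the gate boundary would make "non-debris" depend
on tail luck rather than on the gate.

Default acquisition size is 30,000 events per sample. `simulate_experiment`
emits the double-negative, MyHC+ and GFP+ controls plus two oncogene targets
(vehicle `E = 0.15` vs drug `E = 0.85`, chosen with `K` inside the GFP-low
bin so the rescue is visible at low construct dose). All randomness flows
through one seeded generator; identical configs give byte-identical FCS
payloads. Ground truth (label, doublet flag, true dose, differentiation
flag) lives in sidecar tables, never in FCS keywords.

What the simulator does **not** model: optics and electronics (photon
statistics, spillover/compensation — the assay's fluorophores do not
overlap spectrally), acquisition-time drift, plate-position effects, or
autofluorescence that correlates with scatter. Passing tests therefore
demonstrate correctness of the gating mathematics and the pipeline logic
under realistic intensity ranges and population structure, not robustness
to every instrument artifact of real acquisitions.

## Problem sizes used in the checks

The test suite exercises the full pipeline at the default 30,000 events per
sample, including a 20-seed parameter-recovery study (true GFP-low
differentiation at 10/40/80%, recovered within 2 percentage points) and a
quadrant-vs-density-split comparison (agreement within 3 points). The
brute-force oracle comparisons run at up to 10,000 random events; the
cutpoint-accuracy check uses 20,000-event mixtures against a dense scan of
the analytic mixture density. These sizes make the statistical tolerances
meaningful while keeping the suite fast.

## Known limitations

* Only 1–3 GFP bins are supported, and bins live on a single channel.
* Polygon/ellipse gates, mixture-model (EM) splitting and spectral
  compensation are out of scope.
* The peak splitter assumes at most two biologically meaningful modes per
  bin; heavily contaminated bins violate that silently (the peak list in
  each `SplitResult` is reported for inspection).
* Equivalence with other implementations of valley-splitting is claimed
  only against this package's own stated algorithm, not bit-for-bit against
  any external tool.
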