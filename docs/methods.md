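# Methods

This note documents the models implemented in `radiofix`, the defaults
chosen where the design was open, and what the synthetic scenes do and
do not demonstrate about real deployments.

## Propagation model

Received power in free space falls with the inverse square of distance
and frequency. In the logarithmic domain the package works with

    RSSI(d, f) = P₁ − 20·log₁₀(d / 1 m) − 20·log₁₀(f / f_ref),

where P₁ is the source strength expressed as the RSSI at 1 m and
f_ref = 150 MHz, the VHF band the defaults are tuned to. Doubling the
distance always costs 20·log₁₀2 ≈ 6.02 dB.

Ground interaction is reduced to first-Fresnel-zone obstruction. The
zone radius at a point splitting the path into d₁ + d₂ is
r = √(λ·d₁·d₂/(d₁+d₂)); at 150 MHz over 2 km the first zone is ~63 m
across at the midpoint, which is why antenna height matters so much at
these frequencies. The obstruction fraction is evaluated at the path
midpoint as q = max(0, (r − h̄)/r) with h̄ the mean of the two antenna
heights. Up to 40 % intrusion is treated as free; beyond that the loss
is linear, 30 dB per unit of excess fraction:

    L(q) = 0                      for q ≤ 0.4,
    L(q) = 30 dB · (q − 0.4)      for q > 0.4.

Only the 40 % rule and the qualitative shape (steep loss for
near-ground transmitters, none above a few metres) are empirically
anchored; the linear 30 dB/fraction slope is this package's own minimal
one-parameter choice and should be refitted if absolute levels matter.
No multipath, terrain model or diffraction is included.

## Antenna and receiver model

Each of the four directional antennas has gain sinusoidal in dB,
G(Δ) = C + S·cosΔ (default span S = 10 dB), optionally plus a tabulated
periodic distortion to emulate pattern imperfections. The sinusoid is
not an approximation of convenience: it is the unique simple pattern
under which the four-reading bearing inversion below is exact.

The receiver visits the antennas round-robin — 3.75 ms per antenna,
15 ms per cycle by default — and produces one instantaneous RSSI sample
per dwell, at the dwell midpoint. Receiver noise is i.i.d. Gaussian in
dB (default σ = 2 dB) added to every sample; pulses are rectangular.
Transmitters pulse with a configurable period (~1–2 s) and duration
(~20 ms), optionally gated by time-of-day duty windows. All randomness
flows through an explicit seed; identical specs and seed give
bit-identical recordings.

## Pulse detection

Averaging the four samples of each switch cycle (arithmetic mean in dB)
suppresses the antenna pattern — the mean of C + S·cos(az − K) over the
four K values is exactly C — and reduces noise. The mean-subtracted
averaged series is correlated with a mean-subtracted periodic
rectangular comb (normalized cross-correlation); the search covers
every phase on the cycle grid and 21 periods evenly spanning the ±3 %
timing tolerance. A transmitter whose period is off by 5 % or more
drifts through the comb within a 20–25 s dwell, destroying the on/off
separation, so such signals are rejected regardless of strength —
the intended behaviour, since timing is the discriminator between tags
on adjacent channels.

On- and off-pulse levels are means over cycles lying *entirely* inside
a pulse or entirely in silence; cycles straddling a pulse edge are
excluded from both. This implements the edge guard band: with 20 ms
pulses and 15 ms cycles a fixed one-cycle guard on each side would
leave no usable on-window, whereas straddle-exclusion degrades
gracefully. S/N = mean(on) − mean(off); a detection is valid when S/N
exceeds the acceptance threshold (default 3.3 dB). S/N is invariant
under adding a constant to the whole recording and uses dB-domain
(not linear-power) means throughout, consistent with how the rest of
the pipeline manipulates RSSI additively.

Per-antenna on-pulse values are extracted from the raw samples that
fall inside the matched pulse windows; an antenna never sampled inside
a window (possible when the pulse is shorter than a cycle) is flagged
NaN rather than invented.

## Bearing estimation

With readings relabelled about the strongest antenna (F, L, R, Re; K =
rotation of F from north; ties broken to the lowest antenna index) and
the rear reconstructed as Re = L + R − F:

    R − L = 2S·sin ΔBRG,   F − Re = 2S·cos ΔBRG
    ⇒ ΔBRG = atan2(R − L, F − Re),   BRG = (K + ΔBRG) mod 360.

The inversion is exact on the sinusoidal pattern (round-trip error
below 1e−6° on a 1° grid in the tests) and unbiased under symmetric
noise — 2,000 noisy fixes across the 50–100 dBa band show a mean
signed error well below 1°. The boresight strength is recovered as

    RSSImax = C̄ + (F − C̄)/cos ΔBRG,   C̄ = (L + R)/2,

the exact inverse ("exact" mode, the default). A "verbatim" mode
evaluating the alternative form F − C̄·cos ΔBRG + C̄ is retained for
comparison with legacy processing; it is not an exact inverse of any
simple pattern model and its bias grows off boresight.

Per-station bearing systematics are removed by a calibration vector:
the circular mean of (computed − true) azimuth per 5° node, built from
a rotation experiment, periodically linearly interpolated, and
subtracted from every computed bearing. The correction is applied at
the computed (not true) azimuth, so one pass cancels the first-order
error and leaves a second-order residual — the tests verify a large
RMSE reduction, not perfection.

## Ranging and record filters

DIST = A·B^RSSImax with A > 0 (metre scale) and 0 < B < 1 (dB slope).
Fitting is unweighted OLS of log DIST on RSSImax, exact through two
distinct points; under free-space propagation the relation is exactly
log-linear, so the pipeline round-trips distances to better than 1 %
from noiseless simulated recordings. Models are per-station, with a
`"*"` global fallback, since both receiver hardware and local terrain
enter A and B.

Filters mirror field practice with these receivers: readings above
100 dBa (detector overload region) are excluded; band fractions are
computed on half-open intervals [lo, hi), so the printed integer band
"45–100 dBa" is queried as [45, 101).

## Acceptance threshold estimation

Rather than reading the knee of the S/N-vs-error scatter by eye, the
estimator sweeps thresholds on a 0.1 dB grid from the smallest observed
S/N upwards and returns the first t at which the 0.9 quantile of
|azimuth error| among points with S/N ≥ t is within 15° (both defaults
tunable). The rule is monotone in the error bound. Note the quantile
rule finds the knee only when the sub-knee S/N range is well populated;
sparse curves bias the estimate low. Field experience with this class
of station puts the threshold at 3.0–3.5 dB; the simulated pipeline
test reports a low single-digit value but does not assert the field
number, which depends on terrain.

## Localisation

Fixes of one channel are grouped into tumbling windows anchored at the
epoch (default 60 s, recommended range 15 s–5 min; one fix per station
per window, latest wins). Bearings are *rays*, not lines: a pair whose
crossing lies behind either station contributes nothing. The position
is the area centroid of the convex hull of all pairwise ray
intersections — for one intersection the point itself, for collinear
intersections the segment midpoint. The centroid always lies in the
hull, the result is invariant to fix order, and noiseless bearings to a
common point are recovered to 1e−6 m. Triangulated and single-station
positions are never mixed silently; each `PositionFix` carries its
method and station count.

The 100 % minimum convex polygon is the convex hull of the positions
(shapely), validated in the tests against an independent gift-wrapping
oracle. The activity budget labels each inter-fix interval *feeding*
when successive positions moved ≤ 50 m (of the order of the system's
positional noise; configurable) and *search* otherwise.

## Problem sizes and what the tests show

The simulated scenes use dwells of 3–25 s (3–25 pulses), hundreds to a
few thousand Monte-Carlo fixes, and station baselines of 1–2.5 km —
sizes at which every stage's behaviour (exactness, bias, rejection
rules) is measurable while the full suite stays fast. Passing tests
demonstrate internal consistency of the model chain and exact inversion
under the stated pattern/propagation assumptions; they do not
demonstrate field accuracy, which is dominated by multipath, terrain
attenuation and pattern imperfections that the simulator only
caricatures (tabulated distortion, Gaussian dB noise, midpoint Fresnel
obstruction). Hardware-scale accuracies reported from field campaigns
are therefore out of scope for the test suite.

## Numerical conventions

Angles are stored in degrees and converted explicitly at trig calls;
azimuth comparisons are circular (wrapped to [−180, 180)). Bearings
with all four readings equal raise an ambiguity error rather than
returning an arbitrary direction. RSSImax requires |ΔBRG| < 90°.
Degenerate hulls, empty intersection sets, unsampled antennas and
sub-three-period recordings all raise or flag explicitly rather than
guessing.
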