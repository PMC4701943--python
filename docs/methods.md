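# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind spinekit, in the order data flows through the package.

## Mesh morphometry

**Inputs.** A triangle surface mesh of one spine in µm (VRML 2.0
`IndexedFaceSet`, OBJ or PLY) and the dendrite attachment point, supplied
externally (for synthetic fixtures it is the base-disk center). No axis
convention is imposed; all outputs are rigid-motion invariant.

**Area and volume.** Surface area is the plain sum of triangle areas, caps
included. Volume uses the divergence theorem (signed sum of origin
tetrahedra) and requires a watertight, consistently oriented mesh; open
meshes are rejected with the boundary-edge count.

**Spine axis and length.** The axis is built from the geodesic distance
field over the surface: Dijkstra on the edge graph seeded at the vertex
nearest the attachment (the attachment must lie within twice the median
edge length), vertices binned by distance (64 bins), per-bin centroids
ordered by distance forming a polyline from attachment to the most distant
vertex. Spine length is the polyline arc length. For straight solids the
cap vertices collapse onto the axis, so the measure reduces to the
geometric height; for curved spines it follows the bend. By construction
the length is never below the Euclidean attachment–tip distance.

**Cross-section profile and diameters.** Planes perpendicular to the local
axis tangent are cut at 32 (configurable) arc positions placed at
(i + ½)/n · length, so degenerate end planes are never sampled. At each
station the intersection loop containing the axis point is found (shapely
point-in-polygon in section-plane coordinates, nearest-boundary fallback
for grazing cuts) and converted to an *equivalent diameter* 2√(area/π).
Stations with no usable section are dropped; more than 20% failures abort
with an error. The **maximum diameter** is the profile maximum. The
**neck** is the contiguous proximal run of stations below 0.7 × max
diameter (fraction configurable); its mean is the neck mean diameter, and
its absence marks a stubby spine.

**Classification.** No neck → stubby; a neck with maximum diameter ≥ 0.43
µm (the smallest modelled head; configurable) → mushroom; otherwise thin.
The tessellated fixture at a nominal 0.43 µm head facets to an equivalent
diameter just *below* 0.43, so the generator labels such boundary solids by
the same rule the classifier uses.

**Accuracy.** On the synthetic fixtures the pipeline recovers the exact
faceted-solid truth to ~1e-13 relative for straight prisms (the acceptance
script reports the measured maxima); the stated tolerances (2% volume/area,
5% length/diameters) leave room for curved or noisy surfaces.

## Passive spine biophysics

**Model.** Lumped cylinders: parent dendrite (3 µm × 20 µm, sealed,
isopotential), then neck and head for mushroom spines or a single cylinder
for stubby spines. Per cylinder of diameter d and length L (lateral area
only, the standard lumped convention): A = πdL, C = C_m A, g_leak = A/R_m,
R_a = 4 R_i L/(πd²). Defaults C_m = 1 µF/cm², R_i = 100 Ω·cm, R_m = 20 000
Ω·cm². Adjacent compartments couple through (R_a,i + R_a,j)/2; a
`coupling: child_ra` switch selects the distal compartment's full R_a
instead (both conventions exist among simulators). The resting potential
E_m is not part of the cable constants above and must be explicit because
the peak depends on it through the driving force; the default −70 mV is a
standard cortical pyramidal value.

**Synapse.** One alpha conductance on the head (stubby spines receive it
over their whole lateral surface): g(t) = ĝ (t/τ) e^(1−t/τ), τ = 2 ms,
reversal 0 mV, onset t = 0, single activation. ĝ = 132 S/m² × head lateral
area, so head size sets synaptic strength. Units are SI internally;
voltages stay in mV throughout (the equations are linear in V).

**Feature mapping.** Measured morphometry maps to model geometry as: head
diameter = max diameter; head length = max diameter (spherical-head
convention — head length is not among the five measured features); neck
diameter = neck mean diameter; neck length = spine length − head length,
flagged missing with a warning if non-positive. Stubby: the spine's max
diameter and length. Thin spines are not modelled (missing feature).

**Integration.** Explicit exponential Euler at a fixed step (default 1 µs,
duration 50 ms ≫ all transients): per compartment, with total conductance
G = g_leak + Σ 1/R_couple + g_syn and steady state V∞ (a convex
combination of E_m, neighbor voltages and E_syn, all at start-of-step
values), V ← V∞ + (V − V∞) e^(−GΔt/C). Convexity gives the hard bound
E_m ≤ V ≤ E_syn at every step, asserted after every run together with a
divergence guard. A vectorised batch runner advances many circuits
simultaneously with the identical update (stubby chains get an inert,
zero-coupled pad compartment pinned at E_m); it matches the per-circuit
path to ~1e-9 relative and makes whole-table feature generation practical.

**Numerical behaviour — read this before trusting absolute peaks.** These
circuits are stiff: head and neck membrane time constants are tens of
nanoseconds (tiny capacitance against large coupling conductance), while
the sealed dendrite charges over milliseconds, and the dendrite-charging
current is a *small difference of large voltages* across the neck. With
start-of-step neighbor values the fast compartments track their
quasi-static solution with an effective lag of several steps, which
attenuates that current. The scheme is therefore first-order with a large
constant: across geometries spanning the observed dimension ranges the
head-peak error against an adaptive reference (LSODA at rtol 1e-11,
exposed as `reference_peak_depolarization`) is ~6–36% at dt = 1 µs and
halves with each step halving. Accordingly:

- the default dt = 1 µs is retained as the model's operating step (peaks
  are then directly comparable to pipelines built on the same scheme), and
  the acceptance script reports the measured operating bias;
- integrator *correctness* is verified in the converged regime: at
  dt = 1/64 µs the worst-case disagreement with the adaptive reference
  over 20 sampled geometries is below 1% (0.57% measured), and the test
  suite also checks the first-order error-halving itself.

The reversal-saturation check (density × 10⁴ drives the head to within
1 mV of E_syn) is insensitive to the bias because the synapse then clamps
the whole circuit. The single-compartment limit reproduces the exact
membrane decay e^(−Δt/R_m C_m) to machine precision.

## Content-based retrieval

Features are min–max normalized per feature over non-missing values
(constant features map to 0 by convention); missing values are never
imputed — a spine missing any selected feature is excluded from that query
and reported separately.

*Cell distribution*: raw score r(x) = Σ_k w_k f̂_k(x); the emitted score is
the rank percentile of r (ascending position / (N−1), ties broken by id,
N = 1 scores 1.0), so a single positive-weight feature sends the largest
value to exactly 1. Raw sums are retained in the output for transparency.

*Spine comparison*: the query signature c is the per-feature mean of the
query set's normalized vectors (centroid; the aggregation rule for
multi-item query sets is a design choice). Per feature, similarity
s_k = 1 − |f̂_k − c_k|; a positive weight contributes s_k, a negative
weight 1 − s_k; the score is Σ|w_k|·contribution / Σ|w_k| ∈ [0, 1]. This
is the simplest objective that keeps scores in [0, 1], makes a singleton
all-positive query retrieve itself at exactly 1, and makes negative
weights exact complements. Whether a deployed explorer's score column is
distance- or rank-based is a free choice; both quantities are emitted.

Post-processing: 50-bin histograms on [0, 1] (last bin closed), a
double-slider range filter with exact complement (filter ∪ complement =
all scored ids), and a linear dynamic-range rescale with clipping.

## Synthetic data

**Fixture meshes** are capped regular prisms: a single prism for stubby
spines, two coaxial welded prisms (neck under head) for mushroom and thin
spines. Ground truth uses exact faceted-solid formulas — n-gon area
(n/2)(d/2)² sin(2π/n), perimeter n·d·sin(π/n), equivalent diameter
2√(A/π) — so oracle tests are tolerance-free at any resolution; smooth
formulas are asserted only as the n→∞ limit. All fixtures are watertight
and outward-oriented by construction.

**Feature tables** emulate a reconstructed pyramidal neuron. Region
proportions follow the measured dendritic lengths (basal 4263, apical-main
540, apical-collateral 3890 of 8693 µm). Spine classes default to mushroom
0.55 / stubby 0.25 / thin 0.20 (the class mix is not constrained by the
source measurements; these are realistic adult-cortex values, chosen once).
Dimensions are drawn uniformly from the observed ranges — mushroom neck
0.175–1 µm × 0.38–4.37 µm, head 0.43–1.04 µm in both diameter and length
(neck diameter capped at 0.95 × head diameter so the profile rules apply);
stubby 0.44–1.15 µm × 0.32–1.66 µm; thin/filopodia (our choice: ranges are
not reported for excluded spines) tip 0.2–0.42 µm on a 0.1–0.3 µm shaft
1–4 µm long. Volume/area/length follow from the smooth cylinder formulas;
the membrane-potential-peak column is computed by the batch compartmental
model at the default settings (missing for thin spines). Positions sit on
straight per-region dendritic paths with unit jitter. A single
`numpy.random.default_rng(seed)` stream makes every output bit-exact per
seed. Planted effects multiply named features per region after the draw.

**Structured-neuron preset**: apical-main Volume and Area × 2, emulating a
cell whose largest spines sit on the apical trunk; ground-truth region
labels are returned for recovery experiments. Note the quantitative
ceiling this design implies: under uniform draws the population volume
distribution spans roughly a 4–5× interquartile-to-decile ratio, so a ×2
shift moves the apical-main distribution by much less than the population
spread, and the fraction of apical-main spines reaching the top Volume
quartile saturates near 0.55–0.75 depending on class mix (the acceptance
script reports the measured fraction). A rank-based query cannot recover
more than the overlap allows; this is a property of the planted effect,
not of the retrieval engine.

**What the generator does not emulate:** confocal noise and segmentation
artefacts on meshes, curved or branching spine shapes, non-uniform
(e.g. log-normal) dimension distributions, spatial autocorrelation of
spine properties along a dendrite, and any coupling between neighbouring
spines. Passing tests therefore demonstrate correctness of the algorithms
on clean geometry and well-specified statistics, not robustness to real
imaging data.

## Degenerate inputs and tie-breaking

Duplicate spine ids, missing id columns and unknown regions are schema
errors; unparseable numeric cells become missing values, not errors.
Constant features normalize to 0. Ranking ties break by id. Quartile and
percentile boundaries use ascending ordinal ranks. Meshes with boundary
edges are rejected for volume but fine for area. A query spine missing a
selected feature aborts signature computation with an error naming the
feature.

## Problem sizes used in the test and acceptance runs

Fixture meshes at 16–256 segments (64 for oracle comparisons); feature
tables of 10–2000 spines (1000 for the structured preset); 20 sampled
geometries for the integrator oracle at dt = 1/64 µs over 25 ms (the peak
always arrives before 8 ms); 50 ms at dt = 1 µs for operating-point runs.
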