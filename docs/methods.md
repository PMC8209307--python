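# Methods

## Scope and data model

`dendrodiam` operates on SWC reconstructions: ordered lists of nodes
(id, type, x, y, z, radius, parent) forming a tree rooted at a soma node.
Radii are stored as read; every user-facing quantity is a diameter
(2 × radius). Coordinates are assumed to be micrometres (the NeuroMorpho
convention); no unit conversion is applied. Type codes 3 and 4 map to the
`basal` and `apical` dendrite labels, code 1 is soma, code 2 (axon) is
excluded from all dendritic analysis, and any other code is treated as a
`generic` dendrite-like process. Validation enforces a single connected
tree, no cycles, no soma nodes hanging off dendrites; nonpositive radii and
the largest inter-node z-step are *reported* (as warnings / metadata), never
auto-excluded — published archives were curated for extreme z-shifts by
inspection, and we deliberately leave that judgement to the user.

### Soma normalization

Contour somas are rewritten before simulation or prediction. The soma
surface area is the sum of frustum lateral areas along soma-to-soma links
(a sphere for single-point somas); the sphere-equivalent radius is
r = √(area / 4π). The `three_point` mode emits the standard center ± r
triplet: a cylinder of length 2r and diameter 2r has exactly the sphere's
lateral area, so area is preserved by construction (tested to 1%, achieved
exactly). All dendrites re-attach to the center node. The operation is
idempotent. The "soma diameter" used by the predictor is the diameter of
the root soma node after normalization.

## Morphometric features

Per dendritic node: D, PD, IB, TD, PS, LP, TL (see README table), plus the
node class. Conventions that the format itself does not fix:

* **Multifurcations.** Any node with ≥ 2 dendritic children is a branch
  point; TD sums over *all* children (the two-child wording generalizes),
  and all of its children are branching children.
* **Initial-node precedence.** A soma child is `initial` even when the soma
  has many children.
* **PS origin.** PS is measured from the soma attachment point; the soma
  extent contributes 0. Whether the soma radius should be added is genuinely
  ambiguous across reconstruction tools, so `compute_features`
  exposes `ps_includes_soma_radius` (default off).
* **Terminals.** LP = TL = 0 at terminal nodes (no downstream path), TD = 1.
* **Distances** are 3-D Euclidean lengths summed along parent links.

These conventions give exact conservation laws used as oracles in the test
suite: Σ TL over initial nodes equals the total dendritic length (sum of
dendrite-to-dendrite segment lengths), TD is additive at branch points, and
LP/TL recursions agree with brute-force path enumeration.

## Regression

All diameter models are linear **through the origin**. Because there is no
intercept, R² is uncentered, R² = 1 − SSR / Σy², and the adjusted version is
1 − (1 − R²) · n / (n − p); this is the standard regression-through-origin
convention and is validated against statsmodels' no-constant OLS in the
tests. Negative adjusted R² is reported, not clipped. Rank-deficient designs
raise an error naming the offending columns.

**Feature selection** (per node class × dendrite label, candidates
{PD, IB, TD, PS, LP, TL}): score each single feature by adjusted R²; walk
features in descending single score pairing each with every other; a pair
wins only if its adjusted R² exceeds *both* of its singles by the
improvement constant (default 0.001; results are insensitive between 0.001
and 0.02 on our synthetic archives) **and** exceeds the best model seen so
far, including the best single. The final clause matters: under uncentered
R² a near-constant feature column (IB ≡ 1 for initial nodes) behaves like an
intercept and scores deceptively high, and without the clause a weak pair
that merely beats its own two singles could displace a stronger single.
Models never exceed two features. Selection is invariant to row order and
candidate order (ties broken alphabetically).

`fit_model_set` pools training nodes per (class × label), selects, fits, and
records provenance (training ids, seed, improvement constant). Classes with
fewer than four nodes fall back to a PD-only fit with a warning, or are
skipped. Train/test splits are uniform at the morphology level with a
mandatory explicit seed.

**Prediction scoring** uses Pearson's R² between original and predicted
diameters per dendrite label per morphology, averaged across morphologies.
Pearson correlation is scale-free — a uniformly rescaled prediction still
scores 1.0 — which is why simulation-based comparison complements it.

**Rall check.** At each branch point we correlate parent D^1.5 with the sum
of child D^1.5 (and, as the variant that individual-child prediction cannot
use, child D against parent D^1.5). Trees built to satisfy the 3/2 rule
exactly (child = parent · 2^(−2/3)) score R² = 1.

**Diameter autocorrelation.** For lag k (in *nodes* along parent chains) we
correlate each dendritic node's diameter with its k-step ancestor's, average
the per-morphology curves, and fit A₁e^(−k/λ₁) + A₂e^(−k/λ₂) with
nonnegative amplitudes (nonlinear least squares, tolerance 1e-8,
initialized from a log-linear single-exponential fit); λ₁ ≤ λ₂ by
convention. Lag units are node counts because the underlying question is
how far a prediction chained node-by-node can carry information;
path-distance weighting would be the natural alternative if segment lengths
varied strongly within an archive. Constant-diameter input is reported as
undefined rather than fitted; lag ranges no path supports are shrunk with a
warning. On finite AR(1) chains the sample autocorrelation carries the
classic small-sample downward bias, so the test-suite oracle compares the
fitted curve's 1/e crossing, not λ₁ alone.

## Soma-outward prediction

`predict_diameters` computes all geometry features once from the input
(they are diameter-independent), then walks the tree parent-first: initial
nodes are evaluated with PD = soma diameter; every other node is evaluated
with the *predicted* parent diameter. Options: `keep_original_initial`
retains measured initial-node diameters (the strongest published variant
for hippocampal cells) and chains predictions from them;
`uniform_diameter` bypasses the models entirely (the constant-2 μm control
used to mimic archive-submission defaults); `min_diameter` (default
0.05 μm) floors every prediction because some published equations (e.g. the
hippocampal basal initial equation, −0.5964·PD + 0.3535·PS) go nonpositive
for nodes close to a large soma, and a nonpositive diameter is
unsimulatable. Output topology, coordinates and type codes are bit-identical
to the input; only radii change.

The cerebellar branching-children equation is shipped exactly as published
(coefficients 0.6842 on both PD and TL); with TL in micrometres it produces
implausibly large diameters on realistic arbors, so the packaged file
carries a note and the predictor emits a warning whenever that model is
applied. Refitting it from data is the recommended path when archive data
are available.

## Passive simulation

One compartment per SWC segment (parent→node frustum); the soma is a single
isopotential sphere-equivalent compartment. Geometry:

* membrane area: frustum lateral area π(r₁+r₂)·√(L² + (r₂−r₁)²); membrane
  conductance area/RM, capacitance area·CM;
* axial resistance of a linearly tapering frustum: the exact integral
  RA·L/(π r₁ r₂); compartments couple through half-resistances
  (centre-to-centre), the soma contributing zero internal resistance;
* the first segment of each dendrite uses the node's own radius at both
  ends rather than inheriting the soma radius.

Defaults follow the published hippocampal parameter set: RM = 1.6 Ω·m²,
CM = 0.0186 F/m², RA = 1.98 Ω·m. The resting potential is never stated in
the source material; we default Em = −65 mV and expose it. Step-response
metrics (τ, ΔV) are Em-invariant; the synaptic driving force is not, which
is why Em is configurable. The synaptic reversal (+5 mV absolute) is
strongly depolarizing under this default.

Integration is backward Euler — unconditionally stable on stiff trees —
with a single sparse LU factorization of (C/dt + G) per simulation;
time-varying synaptic conductances enter through a Sherman–Morrison rank-one
update, so no refactorization is needed. dt defaults to 0.01 ms (0.025 ms
for the 800 ms step); halving dt changes τ₁ and ΔV by < 0.1% on the fixture
cells. Analytic anchors verified in the tests: an isopotential compartment
relaxes with τ = RM·CM (29.76 ms for the defaults, matched to 0.1%), a
sealed-end uniform cable matches the cosh((L−x)/λ)/cosh(L/λ) steady-state
attenuation to well under 0.5%, and a zero stimulus holds the membrane at
rest to machine precision.

Protocols mirror the published ones: brief 1 ms / 1.5 nA and prolonged
800 ms / 30 pA somatic current injections, and a dual-exponential synaptic
conductance g(t) = ḡ·N·(e^(−t/τd) − e^(−t/τr)) peak-normalized to ḡ
(10 pS, τr = 1 ms, τd = 5 ms, reversal +5 mV). τ₁ ≥ τ₂ come from a
double-exponential fit of the decay starting 0.2 ms after pulse offset
(log-linear peeling initialization; an effectively single-exponential
transient is flagged degenerate rather than failed); ΔV is
mean(plateau) − mean(baseline) with a drift check on the plateau window.
Comparisons between predicted and original morphologies are reported as
normalized differences |pred − orig| / |orig| per metric, which is zero for
identical responses. Active conductances are out of scope.

## Synthetic morphologies

The generator stands in for curated archives so that every stage is
testable offline. Topology: trunks grow from a 3-point soma node-by-node,
bifurcating with probability `branch_prob`, segment lengths
truncated-Gaussian (default 5 ± 1 μm), small random angular deviations with
damped z-drift, per-trunk depth limits drawn from U[0.55·max_depth,
max_depth]. The depth jitter reflects the real variability of dendritic
extent, and it is also statistically necessary: with identical trunk depths
LP is nearly constant across initial nodes, and under uncentered R² a
constant column is an intercept in disguise that masks the true predictors.
Diameters are then assigned soma-outward by a ground-truth rule — a
`ModelSet` applied exactly as the predictor applies one, or an explicit
taper callable — plus Gaussian noise (default σ = 0.05 μm, a realistic
reconstruction-noise scale well below light-microscopy resolution), floored
at the minimum diameter. By default the chained PD is the *noisy* parent
value, mimicking how reconstruction noise propagates through a traced
archive; `noisy_chaining=False` gives noise-free chaining for
exact-recovery tests. A rule that is nonpositive on more than half the
nodes before flooring is rejected as a specification error.

`spec_for_model_set` provides growth profiles under which each packaged
equation set yields positive, realistic diameters: somata near 12–14 μm
with cell-to-cell spread, a few hundred to a few thousand nodes per cell.
For the hippocampal profile, initial stems scale with soma diameter
(factor 2.6 ± 2 μm): larger neurons place their first reconstructed node
further out, and without that coupling the negative PD coefficient of the
published basal-initial equation drives large-soma cells below zero,
whereupon floor-censoring biases parameter recovery. The archive sizes used
in the recovery tests come from a power calculation — the smallest
coefficient (0.0755 on PD for apical initial nodes) needs roughly a hundred
initial nodes with a few-μm soma spread for its estimator's standard error
to sit well inside the 5% recovery band at σ = 0.05 μm — and were fixed
before the recovery seeds, not tuned against them.

What the generator does **not** emulate: reconstruction artefacts
(z-plane jumps, truncated processes, diameter quantization), within-archive
heterogeneity of staining or imaging, spines, and any biophysical growth
process. Passing recovery tests therefore demonstrates the pipeline's
statistical correctness under its own model family, not that the published
equations generalize to new biological archives.

## Known limitations

* Pearson-based scoring cannot penalize uniform scale errors; simulation
  metrics cover that gap.
* Autocorrelation space constants are in node counts; archives with very
  different inter-node spacing are not directly comparable on that axis.
* The compartmental solver lumps each SWC segment into one compartment;
  extremely long segments should be resampled upstream for accuracy.
* The packaged equations are fits to specific archives of three cell
  types; applying them to other cell types is extrapolation and the
  basal-like fallback warning should be taken seriously.
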