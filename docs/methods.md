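# Methods

## The measurement chain

A tooth crown enters the analysis as an ordered open 2-D polyline running
from the mesial crown base over the apex to the distal crown base, in
calibrated units (TPS `SCALE` applied on read; image-style y-down
digitizations are flipped crown-up). The curve is reduced to a 30-point
configuration: the two endpoints are fixed landmarks at the crown base,
and 28 semi-landmarks are placed by linear interpolation at arc-length
fractions k/29 of the curve (k = 1..28). The fixed landmarks are taken to
be the two crown-base endpoints — the natural, testable reading of
"landmarks at the base"; whether a digitizer places them at the
enamel–bone junction or the alveolar margin is a convention of the data,
not of the code. Right-jaw outlines are reflected to left-lateral on input
and flagged, so that the rotation fit never needs reflections.

### Generalized Procrustes analysis

Partial Procrustes superimposition: each configuration is centred, scaled
to unit centroid size (the square root of summed squared deviations from
the centroid), and rotated — determinant +1 only — to minimize summed
squared distance to the running consensus; the consensus is the normalized
mean, re-estimated until its RMS change falls below `tol` (default 1e-8).
Iteration continues past the tolerance while each step still contracts by
≥10%, so the fixpoint is resolved near machine precision and results are
independent of input order far below the tolerance. Unit-size scaling for
every shape (rather than variance-weighted resizing) is the common default
of the tps software family this pipeline mirrors.

Optional semi-landmark sliding minimizes Procrustes distance (not bending
energy) along chord-estimated tangents: point i slides along the unit
chord p(i+1) − p(i−1) to the foot of the perpendicular from the consensus
point. Sliding runs as a bounded phase — five Gauss–Seidel passes, each
followed by realignment and a consensus update, then a final plain
re-convergence — because interleaving one pass into every GPA iteration
lets the semi-landmarks creep along the outline for thousands of
iterations at geometrically negligible amplitude. Every step of the phase
lowers the Procrustes sum of squares from the slide-free optimum, which is
the property the tests pin. Sliding is off by default.

The converged consensus is rotated to a canonical orientation: the
crown-base chord (fixed landmark 1 → fixed landmark 30) horizontal, apex
up. Orienting on the base chord rather than on the consensus's principal
axis keeps x mesiodistal and y apicobasal regardless of whether the
sample is dominated by tall or by stout crowns; a principal-axis rule lays
tall crowns on their side, which silently transposes every aspect-ratio
reading downstream.

### Shape space and the heterodonty index

All teeth of all specimens enter one joint PCA of the flattened aligned
coordinates (covariance, not correlation — rescaling coordinates would
destroy the Procrustes metric; no relative-warp weighting, i.e. α = 0).
Eigen-solver sign ambiguity is removed deterministically: PC1 is flipped,
if necessary, so that the model shape at +1 SD has a *lower*
height/width bounding-box ratio than at −1 SD (short/stout crowns score
positive); PC2 is flipped so that shapes whose absolute turning is
concentrated in the apical third of the outline score positive
(apex-concentrated curvature positive).

The heterodonty index of a specimen is the sample variance (n − 1
denominator, declared and fixed so cross-specimen comparisons are
coherent) of the PC1 scores of its ≥ 2 teeth. Tooth-position indices are
carried through so per-position score profiles can be reported; diastema
positions yield gaps, never zeros. The PC1-vs-size association uses log10
centroid size (crown height would be an alternative "size"; centroid size
is the standard geometric-morphometric choice and is flagged as such).
Per-clade morphospace occupation is summarized as PC1/PC2 ranges plus the
convex-hull area of the clade's (PC1, PC2) scores; collinear score sets
get area 0 and clades with < 3 teeth report ranges only.

### Body mass and stage series

`mass = a · FL^b` is fitted by ordinary least squares on log10–log10 axes
(a = 10^intercept, b = slope), with r² and the residual SD of log10 mass
as diagnostics. Femur length is the predictor throughout. Because no
published coefficient set is hard-coded, the model is always fitted to a
reference table: either a user CSV (`taxon, femur_length_mm,
body_mass_kg`) or the synthetic stand-in from
`make_reference_masses`. Stage series use arithmetic means per ICS stage
(Kasimovian → Changxingian) split by diet; empty stage × diet cells are
absent (NaN), never zero, and clades on the heterodonty exclusion list
(e.g. groups lacking a pre-/postcanine dentition) are dropped from the
heterodonty means only.

### Parsimony engine

Characters are unordered multistate; cells are state sets encoded as
bitmasks (singleton = scored, full set = missing `?` and gap `-`,
multi-element = polymorphic). Tree length is the Fitch downpass summed
over characters, rooted along the edge adjacent to the first taxon
(Fitch counts are rooting-invariant; a property test checks this).
Exact search is branch-and-bound over stepwise taxon insertion, most
divergent taxa first; a partial tree is pruned when its Fitch length plus
a future-state bound (each definite state confined to still-unplaced taxa
costs at least one further step) exceeds the incumbent. All tied-best
distinct topologies are retained, keyed by bipartition sets, up to a cap
of 1000. Branch-and-bound refuses > 25 taxa as a practical bound; the
heuristic mode (10 random-addition starts, greedy stepwise insertion, SPR
hill climbing with tip prune/regraft moves, tied neighbours swept into
the MPT set) covers larger problems, seeded and deterministic.

For the ensemble indices, the per-character minimum m is computed as
(size of the smallest state set intersecting every non-missing cell) − 1,
by exact enumeration over subsets of the observed states. For data
without polymorphism this is the familiar "observed states − 1"; with
polymorphic cells the naive count can exceed the best attainable score,
whereas the hitting-set form is the exact unordered minimum. The
per-character maximum g is (non-missing taxa) − (modal state count),
resolving polymorphic cells in favour of the modal state. Then
CI = Σm / S and RI = (Σg − S)/(Σg − Σm); all included characters enter
the sums, parsimony-uninformative ones too. Characters are unordered
throughout (per-character ordering would be a config extension). The
*number* of most-parsimonious trees is deliberately not a headline
statistic: it depends on zero-length-branch collapsing conventions that
differ between programs; length, CI and RI are the reproducible outputs.

Strict consensus intersects the bipartition sets of the input trees and
rebuilds the (possibly polytomous) tree from the resulting laminar family
of clades.

## Synthetic data: what it emulates, and what it does not

The crown generator draws each flank of the outline as
y/h = 1 − u^s, where u ∈ [0, 1] is the normalized horizontal distance
from the apex and s the apex-sharpness exponent (s = 1 triangular,
larger s blunter, superellipse-like); the apex sits at height h and
horizontal offset r·w/2 (r = recurvature ∈ [−1, 1], positive = distal
lean). x is monotone along each flank, so the polyline is always simple.
Digitization noise, when seeded, is a smooth 3-harmonic perturbation
along local normals, amplitude capped at 2 % of crown height and pinned
at both endpoints, keeping arc-length resampling well-posed.

The *caniniform* profile encodes basal-sphenacodontian dentary anatomy:
three anterior teeth strictly increasing in height (1.25/1.6/2.0 × the
postcanine reference, jittered by a common factor so the order is
strict), a short physical diastema after position 3 (recorded as a gap,
not a missing tooth position — the caniniform remains tooth 4), a
caniniform at 2.2–2.5 × the postcanine reference on its own position, and
low-aspect postcanines declining gently toward the back of the row. The
*homodont* profile repeats one parameter set at every position.
Assemblages assign caniniform rows to carnivores and homodont rows to
herbivores, draw femur lengths log-normally with a stage trend (carnivore
mean log10 FL 2.15→2.25 across the stage sequence, herbivore 1.95→2.50,
SD 0.08) so mean herbivore mass overtakes carnivore mass mid-sequence,
and set true masses by mass = 1e-5 · FL³ (a 100 mm femur ↦ 10 kg, a
realistic mid-sized Permian synapsid) with log-normal noise of SD 0.1 on
log10 mass. Character matrices evolve root-to-tip with a per-edge
symmetric change probability (a continuous-time model would add nothing
at these depths for recovery tests).

What passing tests on this world do **not** show: real crowns have
serrations, carinae, wear facets and non-parametric outline variation;
real samples mix clades with very different within-row profiles, so the
near-total dominance of PC1 seen on synthetic runs (≈98 %) overstates
what pooled fossil data give (where PC1 typically carries roughly half to
two-thirds of the variance); and real stage assignments are uncertain in
ways the generator does not model (taxa spanning several stages
contribute here to each listed stage, a declared convention).

## Problem sizes and numerical choices

Default test and acceptance runs use 40-specimen assemblages (480 teeth,
30 landmarks), 200-point mass reference tables, 8-taxon matrices with
50–100 characters, exhaustive verification over all 10,395 8-taxon
topologies, 50 brute-force Fitch instances and 20 topology-recovery
replicates — sizes at which the exhaustive oracles are exact and the
whole chain runs in seconds. GPA tolerance 1e-8 (RMS consensus change)
with post-tolerance polishing as above; PCA via full SVD; convex hulls
via Qhull with collinear sets mapped to area 0; ties in parsimony search
broken by deterministic insertion order, and all stochastic components
driven by explicit integer seeds.

## Known limitations

- 2-D lateral-view outlines only; no 3-D superimposition, no missing-
  landmark estimation (incomplete teeth are excluded upstream by a
  metadata flag).
- No phylogenetically corrected regressions, no disparity-through-time
  beyond stage means, no support values (bootstrap/Bremer) and no
  ancestral-state mapping in the parsimony engine.
- Branch-and-bound is exponential in the worst case; 20–25 taxa is the
  practical ceiling, above which only the heuristic applies.
- The PC1-variance index measures shape regionalization only; size
  heterodonty (e.g. a large caniniform of the same shape) contributes
  only via allometric shape change, since scale is removed in GPA.
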