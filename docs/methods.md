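# Methods

## Model

A cell is eleven point bodies: ten on a ring of radius r = 1.5 units
(15 um; 1 unit = 10 um) and one central body.  The field is a disc of
radius R = 50 units (500 um); hexagonal close packing caps the cell
count at floor(pi R^2 / (2 r^2 sqrt(3))) = 1007.  Populations are
labelled RED/GREEN; hooks (adhesive cross-links between boundary bodies
of different cells) form only between like-coloured cells, which is the
entire encoding of differential adhesion — there is no interfacial
energy, no cell division, no signalling.

### Update schedule

One virtual time step applies, in order: leading-edge drift, Brownian
moves, hook pull, ring relaxation, volume exclusion, field confinement,
hook breakage, hook formation.  The ordering is a modelling choice
(motile cells that then adhere on contact); all state advances under a
single seeded NumPy generator, so a run is bit-reproducible from its
config, and replicate k of a config uses seed base+k.

### Ring maintenance (shape matching)

After the move and pull phases each ring is relaxed by 2D Procrustes
shape matching: the rotation best aligning the regular decagon with the
current ring is found in closed form, and every body moves a fraction
alpha = 0.6 toward its fitted nominal position, iterating (max 10
sweeps) until the worst centroid-distance error is within 5% of r.
The centroid participates as an eleventh body, relaxing toward the
ring's centre of mass each sweep — this is what turns forces applied to
individual boundary bodies (hook pulls, collisions) into net motion of
the cell.  Shape matching was chosen over pairwise distance constraints
because it also restores angular order when bodies cross, a state from
which radial/chord constraints alone do not recover.

### Adhesion kinetics

A hook of age t breaks per step with probability
P'(t) = unhook * exp(-t^2 / (2 seize^2)); seize = inf (the default)
disables strengthening, giving geometric lifetimes with mean 1/unhook.
P'(0) = unhook and P'(4*seize) ~ 3.4e-4 * unhook (effectively
permanent).  Formation: each unlinked body pair of like-coloured cells
within hook_range = 0.3 units links with probability p_hook per step;
candidates are granted nearest-first (ties: lowest cell id) and each
body holds at most one hook.  Linked pairs are pulled toward their
midpoint by k_hook = 0.5 of their separation per step.

## Parameter defaults and their calibration

| parameter | default | units | why |
|---|---|---|---|
| sigma_body | 0.03 | units/step | body jiggle, small vs r |
| sigma_centre | 0.04 | units/step | whole-cell Brownian step |
| v_edge | 0.04 | units/step | leading-edge speed |
| p_new_edge | 0.08 | 1/step | edge persistence ~12 steps |
| p_repel, k_repel | 0.25, 0.5 | — | stochastic exclusion (BASIC); ENHANCED sets p_repel = 1 |
| unhook | 5e-5 | 1/step | sticky optimum of the sweep |
| seize | inf | steps | strengthening off unless studied |
| hook_range | 0.3 | units | body contact scale |
| p_hook | 0.2 | 1/step | see below |
| k_hook | 0.5 | — | mid-range pull |

The source model states the architecture but not the motion magnitudes,
so the defaults were calibrated against two published observables of
the simulation itself:

1. **MSD slope.** With the defaults, a single non-interacting cell has
   MSD slope ~ 0.040 unit^2/step (theory v^2(2/p_new_edge - 1) +
   2 sigma_centre^2 = 0.042), matching the reported simulated-cell
   slope at medium density.  This anchors the virtual-to-real time
   conversion T_R/T_V = 100/F.
2. **Stickiness sweep.** The segregation score rises sharply as unhook
   falls from 1e-2 to 2e-3 and peaks in the 1e-4 to 1e-5 decade, with
   unhook = 0 below the optimum — the documented transition and
   optimum.
3. **Growth law.** With instant binding (p_hook = 1) the score jumps
   within a few thousand steps and then grows much slower than
   sqrt(n); with p_hook = 0.2 the 500-cell score curve follows
   S = a n^b + c with a square-root-like exponent (the acceptance
   test fits b inside 0.456 +/- 0.077 on its scaled grid).  Binding
   kinetics are otherwise unconstrained, so p_hook is set to 0.2.

These defaults are fixed; they are not adjusted per experiment.

## Scoring

RDFs are computed per pair class (RR, GG, RG) on centre coordinates in
microns, binned at 20/3 um, and normalised by the CSR expectation for
the same class pair counts in the same disc.  The expectation comes
either from Monte-Carlo CSR fields (default; at least 200x the observed
pair count, cached per field geometry) or from the closed-form disc
line-picking density; the two agree within Monte-Carlo error and the
analytic route is used in tests for speed and exactness.

The score S = (R+G)/B sums each class over the three bins covering
[20, 40) um.  This window brackets the contact separation of one cell
diameter (30 um) in its central bin.  A 10-um window ([20, 30) or
displaced) is available via `PeakWindow` and is what the
window-sensitivity scan varies; it is not the default because centroid
contact sits at ~30 um and a window ending at 30 um would miss the
model's own contact peak.  B = 0 yields an UNDEFINED score (NaN,
flagged), excluded from averages rather than propagated as infinity.
Multi-frame input averages normalised curves before scoring; simulated
runs are scored on trailing snapshot frames (default 5 in the test
harness, 20 configurable) to reduce single-frame noise.

MSD uses all overlapping time origins, a least-squares linear fit, and
a log-log slope alpha to flag non-diffusive curves (|alpha - 1| > 0.3).

## Calibration layer

F = S_R/S_V (observed over simulated MSD slope); T_R/T_V = 100/F
seconds per step, the 100 being the squared 10 um/unit distance scale —
it is derived, not configurable.  The unrounded ratio is carried
internally; display rounds to the nearest integer.  Crossing times
interpolate the replicate-mean score series linearly.  The sqrt-law fit
runs nonlinear least squares for (a, b, c) from multiple exponent
starts (the surface has shallow local minima where c trades off against
small b) plus a linear refit on sqrt(n).

## Synthetic fixtures

The fixture generator emulates digitized two-colour cell-centre fields:
CSR (uniform, independent labels), CLUSTERED (pure-type Gaussian
clusters around CSR centres) and SPLIT_HALVES (types in opposite
half-discs), with an optional hard-core spacing (30 um emulates a
confluent monolayer; 0 gives ideal CSR for normalisation tests), plus
independent Gaussian random walks with known MSD slope 4 sigma^2/dt for
the MSD estimator.  These patterns reproduce the geometry of digitized
microscopy frames but none of their biology: no cell-size variation, no
imaging noise, no density gradients, and no type-specific spacing
changes; passing metric tests therefore validates the estimators, not
any claim about real tissue.

## Problem sizes in the test suite

Dynamical claims are exercised at reduced scale, chosen as the smallest
sizes at which the qualitative behaviour is stable: the sqrt-growth-law
check runs four replicates of 500 cells for 48K steps, scoring nine
run-length grid points (3K-48K) from ten trailing snapshots of each
trajectory rather than as separate runs per length; the split-vs-mixed
gap uses 300 cells at 2K steps; trend checks use 100-400 cells and
1.5K-6K steps.  Replicate-to-replicate variability of the fitted
growth exponent is substantial at this scale (chance configurations of
a few large clusters move single-batch estimates by ~0.1), which is
why replicate means are fitted and the offset is bounded.
The full-scale experiments (500K-5M steps) are reachable with the same
code via `adhesim sweep`; a 500-cell step costs a few milliseconds.

## Known limitations

- Cells are quasi-rigid decagons; no shape-driven effects (elongation,
  intercalation) are represented.
- Exclusion acts on centroid distance, not body-body overlap, so deep
  transient interpenetration is possible at high noise.
- The RDF normalisation assumes a circular field; no edge correction
  is applied beyond the bounded-domain CSR expectation.
- Observed real-cell inputs (MSD slopes, observed scores) enter as
  scalars; nothing here re-derives them from images.
- Hook age resets on any break; re-linking the same partner starts a
  fresh counter.
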