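# Methods

This note records the models implemented in `cofirepy`, the assumptions they
make, the parameters that matter, and the design choices taken where the
design was genuinely open.

## Synthetic ensemble generator

The generator (`cofirepy.synthetic`) emulates multi-day miniscope recordings
of a CA1 ensemble exploring two environments: a 32-cm-diameter cylinder and a
28.5-cm square, visited twice each per day in interleaved order, three days
per week for three weeks (recording days 1, 2, 3, 8, 9, 10, 15, 16, 17).
Each trial is 5 min of binary deconvolved-event frames at 10 Hz together
with the trajectory, soma coordinates in a 400-um field of view, and labels.

**Trajectory.** A bounded random walk on a 24-unit grid spanning the arena:
every 0.1 s each axis moves by a random element of {-1, 0, 1} grid units
scaled by a speed variable that random-walks in [0.1, 1.0] units per step
(increments from {-0.1, 0, 0.1}); positions reflect at the boundary.  One
grid unit is extent/24, so the speed range is roughly 1.3-13 cm/s in the
cylinder.  The walk dwells on ~10-s timescales; its long-run occupancy map
(estimated once from a 40,000-s reference walk and cached) is used to
normalize tuning maps.

**Tuning.** A configurable fraction (default 22.5%) of cells are place
cells with 1-2 Gaussian fields per environment (field sd 2.5-4 cm, floor 2%
of baseline); fields are drawn independently per environment, so place maps
remap.  Every cell's map is scaled so its expected event rate under the
reference occupancy equals the cell's baseline rate (log-normal, median
0.5 events/s): place cells are spatially structured, not more active.
Narrow fields at a fixed mean rate give in-field rates of several events/s,
which is what makes the fields detectable against the shuffle null at 5-min
trials.

**Cofiring structure.** Three multiplicative gain processes act on top of
the tuning rate:

* *Assemblies*: cells are grouped into 4 assemblies (70% membership);
  each assembly has a two-state telegraph latent (dwell times uniform in
  5-20 s) gating its members by 1 +/- 0.35.  Membership is environment-
  independent in `reregister` mode and redrawn per environment in `remap`
  mode.  This is the internally organized cofiring backbone that makes
  pairwise Kendall correlations repeat across trials and environments.
* *Anti-cofiring subpopulation*: a minority (default 15%) of cells is gated
  by a separate telegraph latent with amplitude 0.9; most engaged anti cells
  are facilitated while the latent is up, and the bulk population receives a
  mild opposite gating (0.15), producing a long tail of negative 1-s
  correlations between anti cells and the rest.  The *registration* of this
  subset is environment-specific: in `reregister` mode a random half of the
  anti cells change engagement between the two environments, in `remap` mode
  engagement is redrawn independently.
* *Overdispersion*: a log-normal AR(1) gain per cell (sigma 0.5,
  autocorrelation time 10 s) makes firing trial-to-trial variable beyond a
  memoryless draw from the tuning map.

Environments additionally differ in per-cell mean rates (rate remapping):
square rates are cylinder rates times a log-normal multiplier with spread
0.25 for most cells and 0.8 for the anti subpopulation, so the environment
identity signal is carried disproportionately by the anti-cofiring cells.
Setting the non-anti spread to zero yields the "planted anti-discriminating"
construction used by several tests.

**Cross-day registration.** Cell dropout is a Bernoulli survival chain with
daily survival 0.952, i.e. about half of the cells remain identified across
a two-week gap.  Cells do not return once lost.

**What the generator does not emulate.** Raw fluorescence, photobleaching,
motion artifacts, event amplitudes (frames are binary), within-field phase
structure, or behavioral covariates.  Passing tests therefore demonstrate
that the analysis pipeline behaves correctly on data with the assumed
statistical structure, not that real CA1 data has that structure.

## STDP ring network

`cofirepy.stdp` implements a spiking network of 1000 position-tuned input
units, 500 excitatory (E) and 50 inhibitory (I) leaky integrate-and-fire
units on a ring track of length 10.  Input tuning is a sum of circular
Gaussians (variance 0.1) at 1+ centers per unit (Binomial(5, 0.2) resampled
to be at least 1; the binomial size parameter is not fixed by the parameter
table).  The input firing probability per step is
`(T(x) + alpha*eps_pink) * dt * r_pf` with pink (1/f) noise of unit
variance, clipped to [0, 1].  Voltages leak by exp(-dt) per step, integrate
presynaptic spikes weighted by the connection matrices, reset on crossing
threshold 1, and stay at zero for a 2-step absolute refractory period
(0.02/0.007 rounded down).  Initial weights are uniform on (0, Wmax/p) at
connection probability p per pathway, which conserves the expected initial
weight per potential connection (0.025) across pathways.

E->E and E->I weights follow the antisymmetric pair-based STDP rule
`dW_ij = eta * (f_i v_j - f_j v_i)` (i postsynaptic) with spike traces
`v(t) = v(t-dt) exp(-dt) + [spike]`.  For the I->E pathway the package uses
the standard homeostatic inhibitory-STDP form

    dW_ij = eta * (f_i^E v_j^I + f_j^I v_i^E - 0.01)

which potentiates whenever pre- and postsynaptic spikes occur close in time
in either order and decays at a constant rate.  This choice is deliberate:
the fully antisymmetric variant (available as `ie_symmetric=False`) has zero
mean drift and a depressive spike-correlation term, so inhibition can never
grow to balance the strong initial recurrent excitation; the network then
locks into a saturated, untuned state in which no location-specific firing
can emerge.  With the homeostatic form the inhibitory weights grow until
excitation and inhibition balance at a low rate, and position-specific
firing emerges within tens of laps.  The knockout pattern then reproduces:
freezing E->E plasticity leaves the similarity metrics essentially
unchanged, while freezing E->I and I->E abolishes the improvement.
All weights are clamped to [0, 0.5] after every update and plasticity acts
on all pairs (a weight driven to zero may regrow).

Laps are constant-velocity traversals (5 s per lap by default; the traversal
speed is not fixed by the model description).  Tuning quality is measured on
10 discrete track locations with two similarity metrics of the form
`S = 1 - (a_max - a_ctrl)/(a_max + a_ctrl)`: the nearest-neighbor metric
(control = mean of the two circular neighbors of the peak) and the halfway
metric (control = circularly opposite location); S = 1 for flat tuning,
S -> 0 for perfect tuning.  Plateau onset over seeds is the first 10-lap
block whose seed-mean metrics have reached the final block's level -- within
the two blocks' summed standard errors of the final value, or beyond it
along the overall trend (a slight overshoot counts as reached).  A strictly
two-sided reading would be degenerate here: a slow residual drift of the
E-E weights keeps early blocks outside the tiny 10-seed standard error long
after the curve has visibly flattened.

Two code paths compute the dynamics: transparent single-step Python
operations used by the unit tests and hand oracles, and a fused numba kernel
used for lap-scale runs; a test asserts step-for-step agreement.

## Analysis pipeline

**Rate maps and place cells.** Maps average activity over 2.5-cm bins; bins
with under 0.2 s occupancy are masked (the occupancy threshold is the
package's choice).  No smoothing is applied.  Linearized maps use 30 angular
bins of 12 degrees around the arena center.  Spatial coherence is the
Pearson correlation between each bin's rate and its up-to-8 valid
neighbors' mean; information content is `sum p(x) (r/R) log2(r/R)`.
Significance uses a circular time-shift null (offset at least 20 s, 100
shuffles by default) and the one-sided criterion z > 1.96; a place cell must
pass both metrics.  Day-level prevalence counts a cell that passes in at
least one of the day's trials.

**Coactivity.** Kendall tau-b (tie-corrected) on 1-s binned activity,
computed with a vectorized all-pairs sign-matrix product (agrees with
`scipy.stats.kendalltau` to ~1e-12).  Pairs of somata closer than 30 um and
cells active in under 2% of bins are masked.  The anti-cofiring threshold
tau <= -0.05 uses the inclusive boundary.  PCo is the Pearson correlation of
two recordings' jointly valid tau vectors.  PTI rates subtract the expected
rate (session map at the animal's position times 0.1 s) binned at 1 s from
the observed 1-s rate.  Network consistency sums tau_ij r_i(t) r_j(t) over
valid pairs and normalizes by the standard deviation of 100 pair-identity
shuffles.  The distance profile uses 25-um distance bins; the power-law
exponent is the log-log least-squares slope over positive-mean bins and the
correlation length is the first interpolated zero crossing.

**Decoding.** Linear SVM (hinge loss, C = 1, no standardization, so
weights stay interpretable per cell/pair), 100 stratified 2/3-1/3 splits,
accuracies and signed weights averaged.  Cross-day transfer trains on the
full reference day without cross-validation, restricted to shared cells.
Weight-ranked subsets (deciles/quintiles) are retrained independently;
comparisons across input types downsample features to the smaller dimension.
Location decoding scores the mean pairwise-bin accuracy over all bin pairs
with at least 10 samples, from 1-s activity vectors or 0/1/2 coincidence
vectors.

**Manifold.** 1-s vectors are Gaussian-filtered (sigma = 1 bin) and embedded
with PCA or IsoMap (Euclidean metric, 5 neighbors).  IsoMap is built from
the k-NN graph, with disconnected components bridged by minimum-spanning-
tree links (keeping every sample), graph shortest paths, and classical MDS;
explained variance is 1 minus the residual variance of geodesic distances
after embedding.  The discrimination ratio divides the mean distance between
same-environment average 2-D projections by the mean over different-
environment pairs (the minimum is available as a more conservative
denominator, but with only four recordings it is heavy-tailed and makes the
ratio unstable).  Betti barcodes are Vietoris-Rips persistence computed by
Z/2 boundary-matrix reduction with the filtration capped at the enclosing
radius; because the reduction is exact, second homology is limited to small
subsamples (40 points by default) rather than the hundreds of points a
specialized library would handle.  A bar is called persistent when it spans
at least 30% of the filtration range.  The participation ratio is
(tr C)^2 / tr(C^2) over the covariance of the supplied window (30/60/300-s
windows supported).  Centroid-distance diagnostics use the printed skewness
formula and a Kullback-Leibler divergence between 20-bin histograms on the
pooled range with 1e-6 additive smoothing.  The 3-D alpha-shape keeps
Delaunay tetrahedra with circumradius below the critical alpha (smallest
cutoff yielding one connected region over all points); overlap is the
fraction of one environment's points inside the other's shape, with a
planar convex-hull fallback for degenerate clouds.  Windowed planar fits
minimize the summed squared dot products of a unit normal with centered
points (least eigenvector of the scatter matrix; sign fixed to positive z,
then y, then x); smoothness is the unsigned angle (0-90 degrees) between
temporally adjacent normals and localness the distance between temporally
adjacent samples, with chance obtained by shuffling the temporal order.
The two-sample Kuiper statistic V = D+ + D- is computed on the circle with
the standard asymptotic p value; it is rotation-invariant by construction.

## Problem sizes

The test suite and the acceptance script run at desk scale: ensembles of
25-120 cells over one to two simulated days for the analysis suites
(hundreds of cells change nothing structurally, only runtime), 10 networks
of the full published size for 100 laps for the plasticity experiment, and
point clouds of 25-700 samples for the geometry operations (40 for H2
persistence).

## Known limitations

* The inhibitory-STDP sign choice (above) is a modeling judgment; both
  variants are implemented and switchable.
* The generator's anti-cofiring mechanism (latent gating against the bulk
  population) is one of several structures consistent with a long-tailed
  anti-cofiring power distribution.
* Weight-ranked subset analyses on the full generator (not the planted
  construction) show mild spurious enrichment of place cells, because slow
  gain fluctuations and finite per-trial occupancy give any spatially or
  temporally structured cell a trial signature the decoder can exploit; the
  planted construction isolates the anti-cell effect.
* Exact Rips persistence scales poorly; H2 claims are limited to small
  subsamples.
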