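# Methods

This note records the models, conventions and parameter choices behind
`filatwist`, and what the test suite does and does not establish.

## Filament geometry and the twist/bend observables

A double protofilament is represented as `n_pairs` antiparallel subunit
pairs stacked along the filament axis, two subunits per pair.  Every
subunit is reduced to five reference points: its centroid plus four
orientation markers.  For synthetic lattices the markers are placed 1 nm
from the centroid in the subunit plane; for PDB-derived filaments they are
the Cα centroids of the four actin-like fold subdomains (IA: residues 9–36
and 322–345; IB: 37–81; IIA: 151–186 and 265–321; IIB: 187–264), which are
robust to side-chain noise.

Each pair carries an orthonormal triad: d₃ is the unit vector from the
pair centroid toward the next pair's centroid (extrapolated from the
previous pair for the terminal pair); the d₂ seed is the vector between
the two subunit centroids within the pair, Gram–Schmidt-orthogonalized
against d₃; d₁ = d₃ × d₂.  Twist between two pairs is the signed rotation
about their mean d₃ (renormalized; symmetric in the pair) carrying one
projected d₂ onto the other — projection onto the plane normal to the axis
removes any bend contribution.  The reported twist uses the two pairs
straddling the filament midpoint (pairs 2–3 of a 4-pair filament, 1-based),
because terminal pairs fluctuate more.  Bending is the tilt between the
two middle d₃ vectors, decomposed in the first pair's basis into in-plane
(toward d₁) and out-of-plane (toward d₂, the membrane-normal-like
direction) angles.  All user-facing angles are degrees; pair indices are
0-based internally and 1-based in reports.

**Sign convention.** Twist is positive for a counterclockwise rotation of
d₂ about the distally pointing axis (right-hand rule); on this convention
the left-handed lattice twist of MreB crystals is positive and right-handed
twist negative.  Which atoms define the triad is itself a convention, and
on real structures the measured twist shifts by a few tenths of a degree
between reasonable choices; `frame_convention_sensitivity` quantifies the
spread between the all-points and centroid-only conventions, and any
absolute crystal value should be quoted together with it.  The deposited
crystal structure is not bundled (and cannot be fetched in an offline
environment), so geometry tests run on a synthetic stand-in lattice
constructed at the published 0.7° crystal twist
(`crystal_standin_trajectory`, explicitly labelled synthetic); validation
against real crystallographic coordinates requires `io_utils.fetch_pdb`
and a network connection.

## Synthetic data

`gen_twist_trace` draws a piecewise-constant-mean series with stationary
Gaussian AR(1) noise parameterized on the *marginal* scale: whatever the
lag-1 coefficient ρ ∈ [0, 1), the marginal standard deviation equals
`noise_sigma` (innovations scaled by √(1−ρ²); the first sample drawn from
the stationary marginal).  The default ρ = 0 is the simplest exchangeable
case; MD observables are in reality autocorrelated, which is instead
absorbed into the segmentation objective (below).

The named presets encode the reference state narratives at 1 ns/frame:
`atp1` = (950, 10.4°), (300, 12.5°), (1450, 4.2°); `adp1` = (1000, 0.5°);
`adp2` = (300, 0°), (200, 5°), (500, 10°).  Only approximate dwell times
are published, so the durations mirror the narrative timeline.  The
per-state fluctuation amplitude is not published numerically; presets
default to σ = 1.0° (1.2° for the ensemble preset), chosen once so that
neighbouring modes 2.5° apart are statistically distinct yet overlap in
the raw trace.  The `paper-modes` ensemble preset draws 3–6 segments per
2000-frame trace (each ≥ 250 frames, surplus split multinomially) with
means from {0, 5, 10, 12.5}° and no immediate repeats.

`gen_filament_trajectory` realizes a twist schedule on an ideal 4×2
lattice: pairs 5 nm apart axially (the monomer size), protofilaments
4 nm apart, pair *i* rotated by (i − (n−1)/2)·θ about the axis so that
consecutive pairs are counter-rotated symmetrically (only the relative
angle is observable) and the middle-doublet twist equals θ exactly at zero
noise.  Isotropic Gaussian positional noise is added per reference point.
The zero-noise round trip through the geometry stage is exact to numerical
precision, which is the identity the generator exists to guarantee.

What the generator does *not* emulate: force-field energetics, solvent and
membrane contacts, correlated collective motions, non-Gaussian transition
paths, and state-dependent noise.  Green tests therefore certify the
analysis pipeline (geometry extraction, detector exactness and error
control, estimator calibration), not the biology of any particular MD
system.

## Change-point segmentation

States are intervals of approximately Gaussian fluctuation about a
constant mean.  The detector minimizes, over all partitions with segments
of at least `min_segment_length` = 20 frames,

    Σ_segments  k · RSS_seg / (2 σ̂²)   +   n_cp · k · log(n) / ε

by optimal-partitioning dynamic programming (exact; ties broken toward
fewer changepoints).  σ̂ is a shared noise scale estimated from the median
absolute first difference (divided by 0.6745·√2), which is insensitive to
the state structure itself.  The per-changepoint penalty k·log(n)/ε is the
package's explicit mapping from the coupling ε = 0.6 and noise stiffness
k = 0.2 onto a BIC-like cost.  The stiffness k deliberately weights the
data-fidelity term as well: it acts as an effective-independence fraction
for autocorrelated frames (k = 0.2 ≈ one statistically independent frame
per five), so the partition is governed by the likelihood-ratio threshold
log(n)/ε ≈ 11.5 at n = 1000.  This threshold sits well above the null
distribution of the maximum single-changepoint gain on constant traces
(95th percentile ≈ 5), giving ≥ 95 % single-segment behaviour on pure
noise, while a 3σ mean shift between 100-frame segments produces gains two
orders of magnitude larger — both properties are enforced by Monte-Carlo
tests.  A consequence of k multiplying both terms is that the partition
depends on (n, ε) but not on k; k sets the scale on which objectives and
penalties are reported.  Only a zero within-state slope is supported
(flat states); a nonzero slope is rejected rather than silently ignored.

Per-state statistics trim 5 % of frames at each segment edge before the
maximum-likelihood Gaussian fit (sample mean; ML standard deviation,
ddof = 0), so transition frames do not bias the state mean or width.
`detect_states` annotates even minimum-length segments with trimmed stats;
the standalone `fit_state_gaussian` enforces a ≥ 30-frame precondition.
Constant (zero-variance) segments are rejected — a state must fluctuate
for its width, and hence its modulus, to mean anything.

## Clustering and cluster-count selection

State means are clustered in 1D by k-means (Lloyd, k-means++, 50 restarts,
fixed seed, best inertia kept), with labels renumbered so centroids are
ascending.  The default k = 4 reflects the four-mode landscape of the
reference ensemble; `select_n_clusters` makes the count auditable by
maximizing the mean silhouette over k = 2…8.  If the best silhouette falls
below 0.7 the means carry no convincing cluster structure (a single 1D
Gaussian blob scores ≈ 0.55–0.65 at k = 2) and the smallest k is returned
with a warning rather than a spurious structure.  Mode histograms default
to 0.5° bins (resolving modes 2.5° apart) and support occupancy weighting
(each state contributing its lifetime instead of one count).

## Twist modulus

Within a state, equipartition over one monomer length l gives
K = k_B T l / σ², with σ in radians.  Degrees are accepted at every
interface and converted internally; σ = 1 rad with l = 5 nm gives exactly
5 k_BT·nm, and results are reported both as multiples of k_BT·nm and in
pN·nm² (k_BT = 4.28 pN·nm at the default T = 310 K; the simulation
temperature is not published, so T is configurable and always recorded in
the estimate).  Any slow drift of the mean within a state inflates the
fitted σ and underestimates K; this caveat is pinned by a test.

## SASA

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points per atom; single isolated spheres are exact by construction, and
two-sphere interfaces agree with the closed-form spherical-cap solution to
better than 1 %).  Neighbour candidates come from a k-d tree with the
exact pairwise cutoff rᵢ + rⱼ + 2·probe, preserving exactness at linearithmic
cost.  The probe radius defaults to 1.40 Å (water).  Van der Waals radii
come from a bundled Bondi-type per-element table; because the radii set of
any particular MD stack differs slightly, absolute Å² values are
convention-dependent and only formula-level and analytic comparisons are
meaningful.  Buried SASA clips float-level negative noise to zero and
raises beyond 10⁻⁶·(A₁+A₂), which can only indicate inconsistent inputs.
SASA from fixed sampling directions is exactly translation-invariant but
rotation-invariant only to within the sampling error (< 0.5 % at 960
points).

## Pipeline, determinism and problem sizes

`run_pipeline` chains ingestion (presets, trace CSVs, or PDB trajectories)
→ segmentation → catalog/clustering → moduli, validates all input paths
before any stage runs, and emits a manifest with the package version, a
config snapshot and hash (embedded in outputs), and SHA-256 hashes of every
artifact; numeric outputs are byte-identical across reruns with the same
config (timestamps live only in the manifest).  CSVs are written at full
double precision (`%.17g`, read back with round-trip parsing).

Test and acceptance problem sizes — 20 × 2000-frame ensembles, 50-seed
state-count replicates, 200-replicate error-control and
estimator-calibration suites, 100-case exhaustive-oracle comparisons on
traces ≤ 200 frames, 960-point SASA — were chosen so each check has clear
statistical power while the whole suite runs in well under a minute on one
CPU; the exhaustive oracle materializes every admissible changepoint set
up to three changepoints, which is the regime where enumeration is a
meaningful independent check on the dynamic program.

## Known limitations

- The (ε, k) → objective mapping is this package's documented convention;
  quantitative state *boundaries* from other change-point tools are not
  comparable parameter-for-parameter (state counts and means are).
- Bending is measured at the filament midpoint only; no helical-parameter
  fitting or persistence-length estimation is attempted.
- The segmentation is 1D per observable; twist and bend are segmented
  separately, and their coupling enters only through the Pearson
  correlation of the raw traces.
- PDB parsing goes through gemmi; malformed files are reported with the
  file path but not a line number.
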