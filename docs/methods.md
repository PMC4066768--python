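# Methods

## The rigid-base model

A duplex of *n* Watson–Crick pairs is reduced to *N* = 12 *n* − 6
coordinates: for each pair the six intra-basepair coordinates (buckle,
propeller, opening in degrees; shear, stretch, stagger in Å) and for each
of the *n* − 1 steps the six step coordinates (tilt, roll, twist in
degrees; shift, slide, rise in Å), all in the 3DNA sign conventions. The
canonical in-memory and on-disk ordering is pairs 1..n first, then steps
1..n−1 (the coordinate set is standard; the ordering is this package's
convention, and the trajectory reader accepts any column permutation).

The model is a single quadratic energy over all N coordinates,
E(w) = ½ (w − ŵ)ᵀ K (w − ŵ), with no locality restriction: any base may
couple to any other. In contact with a bath at temperature T the
coordinates are Gaussian, so ŵ is the ensemble mean and K = k\_B T C⁻¹
with C the full covariance matrix. Estimation therefore reduces to two
sample moments. Assumptions worth keeping in mind: fluctuations small
enough for the harmonic picture (the model cannot represent bimodal
backbone substates), stationarity of the ensemble, and snapshots treated
as exchangeable draws (autocorrelation inflates the half-trajectory error
bars, not the estimate itself).

Numerical choices:

* **Covariance normalization** is maximum-likelihood (divide by M), since
  the fluctuation relation equates ensemble moments; a `ddof` toggle
  exposes the unbiased variant. At the M ≫ N regime the model is meant
  for, the difference is negligible.
* **Conditioning.** Estimation requires M > N; covariance eigenvalues
  below 10⁻¹⁰ of the largest raise an explicit error naming the offending
  eigenvalue rather than silently pseudo-inverting.
* **End fraying.** Terminal pairs open routinely; `trim_ends` drops a
  configurable number of pairs per end (default 1) together with their
  flanking steps before estimation, and the H-bond snapshot filter
  (cutoff 4 Å) ignores terminal pairs for the same reason.
* **Units.** Energies in kcal/mol with k\_B = 0.0019872041
  kcal·mol⁻¹·K⁻¹; default temperature 300 K.

**Marginal (partially relaxed) models.** Prescribing a coordinate subset
A and minimizing over the rest yields a quadratic with stiffness equal to
the Schur complement K\_AA − K\_AB K\_BB⁻¹ K\_BA, identically
k\_B T (C\_AA)⁻¹. `relax()` computes both routes and refuses to return if
they disagree (relative 10⁻⁶), which guards against ill-conditioned
inputs. The single-coordinate case gives the force constant
K\_a = k\_B T / Var(w\_a); keeping one step's six coordinates recovers the
familiar local dinucleotide stiffness.

**Entropy.** S\_c = ½ k\_B ln[(2πe)^N det C] is evaluated through the
log-determinant (`slogdet`), never the raw determinant, so large N cannot
overflow. Because S\_c shifts under coordinate rescaling, models are
non-dimensionalized before comparison — lengths by 1 Å, angles by
360/34 ≈ 10.6° (one helical turn over the B-DNA repeat). With a single
length factor and a single angle factor, differences of the per-coordinate
entropy s\_c = S\_c/N are exactly scale-invariant; the test suite checks
this to 10⁻¹².

**Error bars.** A statistic's uncertainty is reported as the mean absolute
difference between its full-trajectory value and its value on each half —
a deliberately simple block estimate suited to long, slowly mixing
trajectories. Vector statistics get component-wise errors.

## The elastic rod

Three frames — two ends and the middle — are each the average of the
base-pair frames over a window of consecutive pairs (default 2; the
window is configurable). Rotation averaging uses the quaternion
eigen-average (principal eigenvector of the summed quaternion outer
products, hemisphere-aligned); an SVD projection of the summed matrices is
kept as an independent path, and the two are required to agree in tests.
Orientation spreads of 90° or more are rejected as ambiguous. Frames read
off the complementary strand should be passed through `antiparallel_flip`
(negate y and z) before averaging so all frames share the reference-strand
sense.

The bend magnitude θ is the angle between the end z-axes. The bend
direction φ is the direction of the z-axis deflection z₂ − z₁ projected
into the middle frame's x–y plane, with φ = 0 toward the major groove
(+x) and φ = π toward the minor groove; the rotational sense (φ increasing
from +x toward +y) is this package's convention — only the 0/π anchors
are dictated by the geometry. At θ = 0 the direction is undefined and
flagged as such. Global roll and tilt are ρ = θ cos φ, τ = θ sin φ. Total
twist ω is the sum of local step twists between the end frames and the
contour length l the sum of local rises, both with the two boundary steps
half-weighted (they straddle the averaged end frames).

The rod energy is E\_r(u) = k\_B T/(2 l₀) (u − û)ᵀ K\_r (u − û) with
u = (ρ, τ, ω) in radians. Fitting mirrors the rigid-base case:
û and l₀ are means, K\_r = l₀ C\_u⁻¹, so K\_r is in length units (nm) and
temperature cancels. Relaxing ω (Schur complement) gives the 2 × 2 bending
stiffness whose diagonal entries are a\_g (toward the grooves) and a\_b
(toward the backbone); a\_iso is their harmonic mean,
2/a\_iso = 1/a\_g + 1/a\_b, and the off-diagonal coupling is reported so
its smallness can be checked — when it is negligible, the stiffness for
bending along any direction interpolates a\_g cos²φ + a\_b sin²φ and lies
between the two constants. Relaxing the bend instead gives the twist
stiffness c = l₀/Var(ω). No curvilinear helical axis is fitted anywhere;
the description rests entirely on the averaged frames.

## Threading

A template profile carries roll, twist and slide per step — the step
coordinates conserved across nucleosome structures. A window of the duplex
is constrained to the template slice at offset k and everything else
relaxes, so E(k) = ½ (t\_k − ŵ\_A)ᵀ K̃ (t\_k − ŵ\_A) with K̃ the marginal
stiffness of the windowed roll/twist/slide coordinates. Offsets advance by
1 bp over the half-open admissible range [0, L\_t − L\_w]; no periodic
wrap-around is applied at template ends. The energies are upper bounds on
any real incorporation cost: no binding-partner interaction or structural
adaptation is modelled. Profile summaries locate minima after a window-3
moving-average smoothing and estimate the dominant positioning period
from the first autocorrelation peak (parabolically refined); a flat
profile has no defined period and is flagged.

## The synthetic generator

The generator exists so that every stage of the pipeline can be exercised
against a known ground truth. It emulates exactly the statistical
structure the estimators assume — a stationary Gaussian process with a
prescribed ŵ and non-local K — via:

* built-in parameter tables: means and diagonal 6 × 6 stiffness blocks
  for the 10 unique dinucleotides and the 2 unique pair types, B-DNA-like
  and illustrative (twist ≈ 34°, rise ≈ 3.3 Å, propeller more negative
  and opening/stretch softer for A·T, AT steps stiff, TA steps soft).
  Untabulated step types follow by reverse complement with the tilt/shift
  sign flips, so palindromic sequences get exactly symmetric models;
* an exponential coupling kernel (default strength 0.08, decay 3 bp)
  linking like coordinates of different steps, giving K its non-local
  character; positive definiteness is enforced by a uniform diagonal
  shift (logged, bounded);
* Cholesky sampling of the implied Gaussian, seeded and reproducible;
* frame reconstruction from step coordinates by the standard mid-step
  triad composition (tilt/roll as one bend about the mid-frame, twist
  split half before and half after, displacements along the mid-frame
  axes), with the exact inverse extraction implemented alongside and
  tested as a round-trip to 10⁻⁸;
* a toy 147-step nucleosome template with sinusoidal roll of 10-bp period,
  and an H-bond distance fixture that breaks chosen pairs in a chosen
  fraction of snapshots.

What the generator does **not** emulate: anharmonicity, backbone substate
bimodality, sequence-specific non-local couplings beyond the generic
kernel, temporal autocorrelation, and any force-field-derived parameter
values. Passing recovery tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions — not that any
particular real sequence has the stiffness the tables imply. The seven
bundled 18-bp study sequences (a C/G-rich control and its A₃T₃…A₁₀
variants) are inputs for end-to-end runs, with default M = 2000 snapshots
in the `simulate` command — enough for well-conditioned estimation of the
trimmed N = 186 coordinate model at interactive speed; recovery tests use
M up to 2 × 10⁵ at N = 30, which completes in seconds.

## Known limitations

* The harmonic model assigns zero probability to H-bond breakage yet is
  fitted to filtered ensembles; the filter is part of the estimator's
  contract, not of the model.
* Half-trajectory errors underestimate uncertainty when the trajectory is
  shorter than a few correlation times.
* `mean_frame` is exact only up to the chordal metric; for the tight
  (≪ 90°) orientation clusters of consecutive base pairs the
  quaternion/SVD discrepancy is far below every tolerance used here.
* The threading energy ignores template coordinates other than roll,
  twist and slide by design; it is a rotational-positioning signal, not a
  binding free energy.
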