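# Methods

`cgtkit` analyses the thermosensitive coil–globule transition (CGT) of a
linear polymer chain from multi-temperature trajectory ensembles.  The
chain collapses on heating (LCST-like behaviour): at low temperature the
extended *coil* dominates, at high temperature the compact *globule*.
This note describes the models, estimators, numerical choices, and what
the synthetic validation does and does not establish.

## Thermodynamic model

Per-frame macrostate labels give the equilibrium constant
`K_eq(T) = p_globule / p_coil` and the transition free energy

    dG(T) = -R T ln K_eq(T)          [kJ/mol]

with `R = 8.314462 J/(mol K)`.  The temperature series is decomposed
under the van't Hoff model with temperature-independent enthalpy and
entropy,

    ln K_eq = -dH/(R T) + dS/R,

fit by ordinary least squares in the linearising coordinates
(`ln K_eq` against `1/T`).  The transition temperature is
`T* = dH/dS`, the zero crossing of `dG`.  Two goodness-of-fit numbers
are reported: `r^2` of the linear regression and `r^2` of the
back-transformed (hyperbolic) curve `K_eq(T)`; which of the two a given
report refers to is often ambiguous, so both are always computed.
Treating `dH` and `dS` as temperature-independent is an assumption of
the model, not a finding; nothing here estimates a heat capacity.

## Kinetic model

Forward (coil→globule) and backward rates are reciprocal mean first
passage times (MFPT) of a Markov model at lag `tau`:

    m_i = 0 on the target set,  m_i = 1 + sum_j T_ij m_j elsewhere,

solved linearly and averaged over the source set weighted by the
stationary distribution restricted to it; steps convert to time via
`tau * frame_spacing`.  The temperature dependence of each rate is fit
with an Eyring-type law with a linear frequency factor,

    k(T) = c T exp(-dG_dagger/(R T)),

again by OLS on `ln(k/T)` vs `1/T`.  The pre-exponential slope `c`
[1/(ns K)] is reported together with `dG_dagger` [kJ/mol] and both
`r^2` variants.

In the pipeline, the rate-bearing transition matrix is the two-state
Markov model estimated from the resolved per-frame coil/globule
sequences (per replica, at the model lag).  The two-hidden-state HMM is
used to *assign* ambiguous frames (below); estimating the kinetics from
the assigned label process, rather than from the HMM's own transition
matrix, keeps the rates insensitive to how EM partitions fast
intra-macrostate exchange — a two-state HMM fit to a multi-substate
process can legally shift its emission boundary away from the
macrostate boundary to gain likelihood, which distorts its transition
matrix but not the labels it implies for clear frames.

## Conformational descriptors

The chain is modelled as a freely jointed chain of contiguous segments
of 3 monomers (one persistence length); trailing monomers that do not
fill a segment are excluded from segment quantities but retained for
Rg, SASA and dihedrals.  Four per-frame descriptors:

* `Rg` — mass-weighted radius of gyration [nm].
* `sigma` — solvent-accessible surface area by Shrake–Rupley [nm^2]:
  bead radius 0.25 nm, probe 0.14 nm, and a deterministic golden-spiral
  point set (default 960 points, ~1% quadrature error for a single
  sphere).  The bulk pipeline uses 144 points; the quadrature error is
  common-mode across frames and irrelevant for classification.
* `Omega` — sum over *consecutive* segment pairs of the angle between
  segment end-to-end vectors [rad]; 0 for a perfectly extended chain,
  bounded by `(n_segments - 1) * pi`.  An all-pairs variant is
  available (`omega_pairs="all"`); the consecutive-pair form is the
  default because it reduces to the classic bond-angle sum of an FJC.
* `nu` — number of segment pairs `(i, j)` with `j >= i + 2` whose
  mass-weighted centres of mass are closer than a cutoff (default
  0.8 nm).  Adjacent pairs are excluded as trivially in contact.

Segment vectors are end-to-end (first→last monomer of the segment):
the simplest rotationally equivariant choice.  Degenerate geometry
(zero-length segment vector, collinear bead triple for a torsion)
raises an error naming the offending index rather than returning NaN.

## Dihedral entropy

Backbone torsions (one per consecutive bead quadruple, `n_beads - 3`
per frame) are treated as independent circular variables.  Each
torsion's density is estimated with a von Mises kernel on a uniform
360-point grid over `(-pi, pi]`; the kernel concentration defaults to a
plug-in rule: invert the mean resultant length for a sample
concentration estimate (Fisher's approximation) and scale by `n^(2/5)`,
the one-dimensional KDE rate.  Entropy is

    S = -R * integral p ln p dphi

by periodic trapezoidal quadrature (`p ln p := 0` where `p = 0`), and
`dS_pol = S_globule - S_coil` sums per-torsion differences.  Samples
larger than 20,000 are histogram-binned at 4x grid resolution before
smoothing; the binning error is negligible against the kernel bias.
Closed-form anchors used in validation: the circular maximum
`R ln(2 pi) = 15.28 J/(mol K)` and the von Mises entropy
`R [ln(2 pi I0(k)) - k I1(k)/I0(k)]` (evaluated with exponentially
scaled Bessel functions so large concentrations stay finite).
Point-mass samples are flagged as degenerate and reported at the
kernel's lower bound instead of `-inf`.  Mutual information between
torsions is ignored by construction; the sum is an upper bound on the
joint entropy.

Uncertainties are replica leave-one-out (LOO) spreads: the estimator is
recomputed on every subset that drops one replica, and min/Q1/Q3/max
are reported.  The uncertainty of the coil–globule *difference* is the
sum of the two single-state half-spreads (worst-case propagation).

## Markov state modelling

Frames are discretized by a *global* pipeline: standard-scale the four
descriptors on data pooled over all temperatures, then k-means
(k-means++ seeding, fixed seed; 250 clusters by default).  Per-frame
cluster indices are comparable across temperatures because the scaler
and centres are shared.  Transition counts use a sliding window at lag
`tau` and never cross trajectory boundaries.  The non-reversible
estimator row-normalises counts; the reversible variant row-normalises
the symmetrised counts `(C + C^T)/2`, which satisfies detailed balance
exactly — a deliberate simplification of the full reversible MLE
iteration.  Lag selection, when requested (`lag="auto"`), uses the
implied-timescale plateau rule: the smallest lag whose slowest
timescale `t_2 = -tau/ln(lambda_2)` changes by less than 10% when the
lag doubles.  The emission-generator data are Markovian at lag 1 by
construction, so the study default is `lag=1`.

Macrostate assignment is two-stage:

1. *Prescreen* on `(Rg, sigma)`: globule if `Rg < rg_low` and
   `sigma < sasa_low`; coil if `Rg > rg_high`; ambiguous otherwise.
   Thresholds default to pooled quantiles (35th/65th of Rg, 50th of
   sigma) and are fully configurable.
2. *Resolve by dynamics*: a two-hidden-state discrete-emission HMM is
   fit per temperature.  Its emissions are pinned to the PCCA split of
   the microstate transition matrix (sign of the second right
   eigenvector) and EM refines only the hidden transition and start
   probabilities (`update_emissions=False`); Viterbi then assigns each
   ambiguous frame the macrostate of its hidden state.  The hidden→
   macrostate map is a per-state majority vote over unambiguous frames,
   which makes the result invariant to hidden-state relabelling;
   agreement below 60% on unambiguous frames triggers a warning.

Baum–Welch uses scaled forward–backward recursions (numba-compiled),
strides each trajectory into `lag` phase-shifted subsequences so no
frame is discarded, floors collapsed emission rows at 1e-12, and
asserts the EM log-likelihood never decreases.  Count matrices are
never pseudocounted.

## Substate catalog

Per temperature, an HMM with `n_hidden` substates (default 4 for the
synthetic study; `"auto"` selects the largest relative implied-
timescale gap, capped at 7) is fit in the shared cluster space,
initialised from a spectral grouping of the microstate matrix (k-means
on the top right eigenvectors).  Each hidden state gets a 4D position —
the mean scaled descriptor vector of its Viterbi-assigned frames — an
occupancy (stationary probability of the hidden chain) and a macrostate
(majority vote of its frames' labels).

Substates are matched across temperatures greedily: temperatures in
sorted order (so the catalog is independent of input order), states
within a temperature by descending occupancy; a state joins the nearest
same-macrostate reference within `r_match = 1.0` scaled units (one
state per reference per temperature) and references track the running
mean of their members, which tolerates slow drift with temperature.
Unmatched states open new references and are flagged when absent at
some temperature.  Names follow the Rg-rank convention: `C0` is the
coil with the largest Rg, `C1` the next, while `G0` is the globule with
the *smallest* Rg — the two ends of the compactness scale.

## Free-energy profiles

`F(Rg) = -R T ln p_hat(Rg)` from a histogram (bin width 0.02 nm, bins
with fewer than 10 frames dropped).  Profiles from different
temperatures are aligned by fitting a parabola to the right flank
(bins above the global minimum's Rg + 0.1 nm) and shifting so the
fitted vertex sits at zero; when the flank has fewer than 3 bins or the
fit is concave, the profile minimum is used instead.

## Synthetic data: what it emulates, what it does not

Two generator tiers stand in for long atomistic simulations:

* A **Metropolis bead-chain sampler** (harmonic bonds `k = 8000
  kJ/mol/nm^2`, `b0 = 0.25 nm`, harmonic bending about the straight
  configuration, and a smooth short-range pair attraction
  `-eps (1 - (r/rc)^2)^2` among beads `|i-j| >= 2`).  The attraction
  grows linearly with temperature,
  `eps_eff(T) = eps0 + slope (T - 300 K)`, the minimal mechanism for an
  LCST-like collapse.  Single-bead moves, fixed seed, bit-reproducible.
  MC frames carry no dynamics; their nominal ns frame spacing is a
  label only.  The sampler is validated against equipartition (the 1D
  two-bead bond variance is `R T / k`) and against Boltzmann weights
  from dense quadrature over the internal coordinates of a three-bead
  toy.
* A **hidden-Markov emission generator** with exact ground truth: four
  hidden substates `[C0, C1, G1, G0]` (helical 20-bead templates with
  Rg 1.41, 1.09, 0.56, 0.35 nm; helices avoid collinear triples so all
  torsions are defined), each frame emitted as its state's template
  plus isotropic Gaussian bead noise (default sd 0.03 nm).  At each
  temperature the hidden transition matrix is the Metropolis matrix for
  the stationary vector implied by the van't Hoff law
  (`dH = 100 kJ/mol`, `dS = 351.86 J/(mol K)`, hence `T* = 284.2 K`)
  with within-macrostate splits 0.6/0.4 (coil) and 0.55/0.45 (globule);
  exchange proposals are `q = 0.3` within macrostates and `q = 0.25`
  across the two bridges (C1–G1, C0–G0).  Ground-truth rates are the
  reciprocal MFPTs of the true matrix.

The default study is 6 temperatures (277–292 K, straddling T*) x 4
replicas x 20,000 frames.  The temperature window and exchange rates
were chosen by a power analysis on the hidden chain alone, so that the
pooled occupancy estimate of `K_eq` and the lumped two-state rates are
statistically resolvable to a few percent at this sample size; both
macrostates keep at least a quarter of the population at every
temperature.  The Eyring simulation-study barrier is
`dG_dagger = 50 kJ/mol` with `c = 1e4 /(ns K)` — a typical
conformational-barrier scale consistent with `dH = 100 kJ/mol`; the
relative precision of the fitted barrier at fixed noise is inversely
proportional to its magnitude, so the barrier choice and the claimed
recovery precision go together.

What passing the synthetic study does **not** show about real data:
the emission blobs are well separated in descriptor space and exactly
Markovian at lag 1, the noise is isotropic and uncorrelated in time,
the substates do not drift with temperature, and solvent degrees of
freedom do not exist.  Real ensembles have overlapping states,
non-Markovian memory at short lags, correlated fluctuations and a
solvent-entropy contribution that torsional entropy cannot capture; the
study validates the estimators' correctness and calibration, not their
robustness to those complications.

## Randomness and determinism

All generators draw from `numpy.random.SeedSequence` spawns of a single
integer seed: one child per (temperature, replica), split again into a
hidden-chain stream and an emission stream.  k-means seeding, HMM
initialisation, and every stochastic test are seeded.  Re-running the
pipeline with an identical config (including seed) produces
byte-identical CSV/JSON artifacts: floats are serialised at 12
significant digits, JSON keys are sorted, and the run manifest carries
a config hash and artifact checksums but no timestamps (wall-clock
information goes to the log).

## Problem sizes

The validation suite runs the full study (480,000 frames through
descriptors, 250-cluster k-means, per-temperature HMMs, entropies with
LOO, substate matching) in roughly three minutes on one CPU; the bulk
SASA uses the 144-point quadrature noted above.  Determinism is
verified on a reduced configuration (3 replicas x 1,200 frames) because
it re-runs the identical code path twice.

## Known limitations

* The reversible MSM estimator is the symmetrised-count approximation,
  not the constrained MLE.
* Only consecutive-pair `Omega` has a closed FJC interpretation; the
  all-pairs variant is provided but unstudied.
* Entropy ignores torsion–torsion correlations (upper bound).
* PCCA is the two-state sign split (or spectral k-means for more
  states), not simplex-based PCCA+.
* The MC sampler's collapse mechanism is phenomenological; no solvent,
  no force-field realism, no pressure coupling, and no claim that its
  `K_eq(T)` follows a clean van't Hoff law.
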