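# Methods

This note records the model, the numerical conventions and the design
decisions behind the package, in the spirit of a model-description chapter:
what is computed, under which assumptions, and what the synthetic tests do
and do not demonstrate.

## Coarse-grained elastic network

Each residue contributes a backbone site pinned to its Cα and a sidechain
site at the sidechain center of mass; glycine contributes one site and a
single-atom ligand (a bound ion) one site.  Site masses are the summed atom
masses, but equal-time positional statistics of a harmonic model are
mass-independent (equipartition in coordinates), so masses never enter the
variance predictions; they are carried for completeness.  The backbone atom
set is {N, CA, C, O, OXT and the backbone hydrogens}; everything else in a
residue is sidechain.  Whether sidechain hydrogens enter the center of mass
is configurable (`sidechain_heavy_only`); the default uses every atom
present in the input.

The potential is a sum of independent harmonic bonds,
`E = Σ ½ k_ij (d_ij − b_ij)²`, over a bond pool fixed once per trajectory:
all site pairs whose distance drops to the cutoff (default 10 Å) in at
least one frame.  Because force constants are subsequently fitted to the
observed fluctuations, results are insensitive to the exact cutoff; the
pool only needs to be generous.

### Normal modes and thermal variances

The Hessian is evaluated at the rest geometry, where every bond sits at its
rest length, so each bond contributes `±k êêᵀ` blocks with `ê` the bond
unit vector (the tangential curvature term vanishes there).  Eigenvalues
with magnitude below `1e-8` times the largest are treated as zero.  The
rigid-body count is six (five for collinear geometries, which lack a
rotation about their own axis); a *connected* network may legitimately
carry additional zero modes when it is under-braced (fewer than `3N − 6`
bonds) — these floppy modes receive zero thermal amplitude, exactly like
the rigid-body modes, and the covariance is the pseudoinverse over the
remaining spectrum times `k_B T` (`k_B = 0.0019872041 kcal/mol/K`, default
T = 300 K).  Only a disconnected `k > 0` bond graph is an error (the
components are listed); a floppy connected network is ordinary input, since
the package's own default fixtures are of this kind.

### The bond-fluctuation observable

The method treats bond fluctuations in the Gaussian approximation: the
observable is the variance of the bond-vector component projected on the
mean bond direction, `δd = ê·(r_j − r_i) − ⟨ê·(r_j − r_i)⟩`, for which the
harmonic prediction `k_B T êᵀ(C_ii + C_jj − 2 C_ij)ê` is exact.  The
variance of the *scalar distance* differs from this at second order through
transverse fluctuations; on desk-scale networks with soft transverse modes
the difference reaches tens of percent, which would contaminate both the
sampler/normal-mode cross-checks and force-constant recovery with a bias
that belongs to the observable, not to the inversion.  `measure_targets`
therefore defaults to the projected observable and exposes
`mode="distance"` for sensitivity analysis.  Mean bond lengths are always
plain mean distances.

A subtlety of the windowed estimator: the projection direction is itself
estimated from the window, and its sampling noise couples the transverse
fluctuations into the variance estimate.  The first-order Monte-Carlo
standard error is

```
se² = [ 2 σ∥⁴ + 4 (P⊥ S ê)ᵀ S (P⊥ S ê) / b² ] / n
```

with `S` the 3×3 relative-displacement covariance of the bond, `σ∥² = êᵀSê`
and `P⊥ = I − êêᵀ`; the second term inflates the naive χ² error by up to an
order of magnitude on bonds with large transverse motion.
`predicted_bond_variance_se` implements this and is what sampler-vs-theory
comparisons use.

## Fluctuation matching

Force constants are initialized at `k⁰ = k_B T / ⟨δd²⟩_MD`, which is the
exact answer for an isolated bond and an overestimate (hence a safe start)
in a network.  The default update is the inverse-variance rule

```
k ← max(0, k + α k_B T (1/⟨δd²⟩_MD − 1/⟨δd²⟩_ENM)),   α = 0.5,
```

whose fixed point is exact variance agreement; the alternative
`variance_difference` rule applies the same step linearized in the variance
mismatch (`α k_B T (⟨δd²⟩_ENM − ⟨δd²⟩_MD)/⟨δd²⟩_MD²` — note the sign: a
too-large predicted variance means the network is too soft and `k` must
increase).  Both rules share the fixed point; the inverse-variance form
converges geometrically with ratio `1 − α` on decoupled bonds.  Iteration
stops when the RMS per-bond force-constant change between steps falls below
0.005 kcal/mol/Å² (default cap 1000 iterations; non-convergence is flagged
on the trace, not raised).  Force constants are clamped at zero after every
step; a clamped bond stays in the pool and may re-enter.  The matcher is
fully deterministic given its targets.  `α = 0.5` is a package choice — the
step constant only controls the approach rate, not the fixed point.

On under-braced networks the bond strains are linearly independent internal
coordinates, the Gaussian measure factorizes over them, and the matcher
converges at the first step; densely braced networks (bonds > 3N − 6)
couple the modes and typically need 10–20 iterations at these sizes.

## Fluctuogram and variation metrics

Windows are half-overlapping by default (stride = Δt/2, Δt even, ≥ 4
frames; window count `⌊(n − Δt)/stride⌋ + 1`); a non-overlapping stride is
available for sensitivity checks.  Windows are statistically independent
computations on a shared pool, so evaluation order is irrelevant.

Residue coupling `k_IJ` sums the force constants of all bonds between the
sites of residues I and J; intra-residue (backbone–sidechain) bonds sit on
the matrix diagonal and are excluded from `k_I = Σ_{J≠I} k_IJ`.  Near-
sequence neighbours are *included* in `k_I` by default (an optional
separation filter exists); the selection criteria apply their own
`|I − J| > 3` filter regardless.

Between consecutive windows: `δk_I` is the plain difference of `k_I`;
`Δb_I` sums `|b_ij(t) − b_ij(t−1)|` over the bonds of I carrying a non-zero
force constant in either window (intra-residue bonds included under the
same rule); `ψ_I` averages `(k_ij(t) − k_ij(t−1)) / max(k_ij(t), k_ij(t−1))`
over the `N_I` inter-residue bonds of I with a positive denominator, giving
a bounded score in [−1, 1] (+1: all bonds newly formed; −1: all vanished).
The max-normalization is the reconstruction that yields the stated ±1
range.  Residues with `N_I = 0` carry NaN, never 0.  Two-state comparison
classifies residues by the time average of `|Δk_I|`: large (> 20),
significant (10–20), weak (< 10 kcal/mol/Å²), and reports the top decile.

## Selection criteria and scoring

Pair statistics (mean, population SD, maximum of `k_IJ` over windows) feed
three criteria, all restricted to pairs with `|I − J| > 3`: Criterion A
selects residues with ≥ N_cut partners at ⟨k_IJ⟩ ≥ k_cut (defaults 10 and
2.5 kcal/mol/Å²); Criterion B selects both members of pairs with
⟨k_IJ⟩ ≥ K_B (default 11); Criterion C selects both members of pairs with
k^max ≥ K_C (default 8.0) *and* normalized variation ≥ s_C (default 0.8).
The variation statistic defaults to the coefficient of variation σ/⟨k⟩
(pairs with zero mean excluded); σ/k^max and plain σ are selectable — the
CV is the reconstruction under which an s_C of 0.8 is dimensionless.
Thresholds use ≥ throughout, so raising any cutoff can only shrink a
selection (tested as a monotonicity property).

Hit rate H is the fraction of selected residues within ±1 of a reference
residue (a selection adjacent to two reference residues counts once);
coverage C is the fraction of reference residues within ±1 of a selection;
±1 windows truncate at chain termini.  The random baseline draws the same
number of residues uniformly without replacement (default 10,000 rounds,
seeded) and reports mean ± SD of hits, covered residues, the covered/n_pick
ratio and the hit rate.  For mutually non-adjacent reference sites the mean
covered count has the closed form `R (1 − C(N−3, p)/C(N, p))`, which the
Monte-Carlo estimate reproduces within its standard error.

The package ships the compiled list of 28 gain-of-function mutation sites
from the directed-evolution literature on subtilisin
(`fluctuogram.reference`), used as the reference set for the baseline
statistic; the baseline's mean ratio depends only on the count of sites and
their distance from the termini, not on their exact identities.

## Statistical coupling analysis

Sequences are filtered by a global gap limit (default 100) and a stricter
limit inside a designated loop (default ≤ 1 gap), then de-duplicated by
greedy single-linkage clustering at ≥ 95 % identity over mutually non-gap
columns (pairs sharing < 50 % of columns count as non-redundant; the
first-seen member of each cluster is kept).  Each column is reduced to a
binary indicator of its most prevalent residue (ties break to the
alphabetically lowest; gaps count 0).  Consensus frequencies are mixed with
the residue's database background frequency (built-in 20-entry table,
overridable) by a pseudocount λ = 0.01 so that the conservation entropy
`D = f′ln(f′/q) + (1−f′)ln((1−f′)/(1−q))` (nats) and the gradient weight
`φ = |ln(f′(1−q)/(q(1−f′)))|` stay finite on constant columns.  The
coupling matrix is `φ_i φ_j |cov(x_i, x_j)|`.  The entropy-gradient
weighting convention is isolated in one function
(`conservation_weights`) so an alternative variant can be substituted.

Eigenvalue significance is calibrated by independently permuting each
column across sequences (conservation preserved, correlation destroyed),
rebuilding the matrix, and taking the 95th percentile of the null maximum
eigenvalues; the leading eigenvector of a real alignment is treated as the
collective/conservation mode and sector analysis uses the 2nd and 3rd.
Positions at distance ≥ 0.07 from the origin of the (v2, v3) plane are
selected and clustered by angle (k-means on the unit circle, seeded, labels
ordered by cluster size); matrix cleaning reconstructs
`Σ_k λ_k v_k v_kᵀ` over eigenvectors 2–4 on the selected positions, grouped
by sector and ordered by distance within sector.

## Synthetic data: what it emulates, what it does not

`sample_from_network` draws frames from exactly the Gaussian ensemble the
matcher assumes (covariance `k_B T H⁺`; rigid and floppy modes at zero
amplitude, so no superposition is needed; an optional flag adds rigid
motion to exercise the RMSF/RMSD paths).  It is the independent oracle for
the normal-mode variance prediction and the recovery target for the
matcher: the two code paths share nothing but the Hessian definition.
`two_state_trajectory` concatenates segments from two networks with
recorded change points, emulating an intermittent coupling change.

`make_toy_network` builds a self-avoiding chain (bond lengths 3.6–4.0 Å,
excluded volume 3.4 Å) plus random long-range contacts, force constants
uniform in [1, 20] kcal/mol/Å² at 300 K.  A conditioning guard resamples
(deterministically) any candidate whose softest internal mode has a thermal
RMS amplitude exceeding the shortest rest length — such near-floppy
contraptions are outside the small-fluctuation regime a harmonic network
describes, and their wild transverse excursions make the windowed
fluctuation estimator ill-behaved.  The default fixture is 20 sites with 8
extra contacts and 4000 frames, sized so a full fluctuation match runs in
well under a second; oracle-equivalence checks use densely braced networks
(bonds ≥ 3N − 6) so the coupled-mode path is exercised.

The alignment generator plants sectors via latent activity states.  The
default, clade-like mode activates exactly one sector per sequence: the
coupling matrix then shows one collective mode over all sector positions
plus contrast modes that place the three sectors at distinct angles in the
(v2, v3) plane — the canonical sector geometry.  Independent Bernoulli
activation is also available, but it assigns each sector its own
eigenvector, which a two-eigenvector plane cannot resolve for three
sectors.  Default scale: 3200 sequences × 100 positions with three sectors
of 20 positions at f_active = 0.95, f_inactive = 0.4 — the depth at which
the planted contrast eigenvalues clear the permutation-null threshold with
a comfortable margin.

What the synthetic tests do **not** show: real MD fluctuations are
anharmonic, rugged and time-correlated, real alignments carry phylogenetic
structure and gaps, and real sector geometry is messier than planted
clades.  Passing here demonstrates that every stage computes its defined
quantity correctly and that the inversion and selection machinery recover
planted truth at realistic noise levels — not that the thresholds
generalize to any particular protein.

## Numerical choices and degenerate inputs

- Zero-mode threshold `1e-8 ×` largest eigenvalue; rigid-body expectation
  derived from the geometry rank (5 collinear / 6 otherwise).
- Superposition (RMSF/RMSD) is unweighted Kabsch on all selected sites,
  with iterative mean refinement for RMSF; collinear structures trigger a
  warning.
- Population (1/n) variance conventions throughout.
- A bond with exactly zero measured fluctuation raises (inversion
  undefined) naming the bond; an all-gap alignment column warns and is
  carried with f = 0.
- TSV with `#` headers everywhere; reals serialized at `%.17g` so round
  trips are bit-faithful; residue numbering 1-based user-facing, site ids
  0-based internal, converted only at the I/O boundary.

## Known limitations

- The matcher fits variances only; cross-bond covariances are not matched,
  so degenerate force-constant solutions are possible in principle (not
  observed on the fixture family).
- Under the distance-variance mode the fitted constants absorb the
  anharmonic transverse contribution; the two modes agree only in the
  small-fluctuation limit.
- Greedy single-linkage redundancy removal is order-dependent by design
  (first-seen representative), matching the usual clustering tools'
  behavior rather than an optimal cover.
- The SCA weighting is one member of the family of conservation-weighted
  covariance definitions; swapping the weight function changes eigenvalue
  scales (the significance calibration adapts automatically).
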