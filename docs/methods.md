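# Methods

## The model

`diapart` computes canonical partition functions for systems of N
particles that each occupy one of two states, labelled 0 and 1, with a
microstate energy

    E(x) = E_off + Σ_i e_i x_i + Σ_{i<j} g_ij x_i x_j ,   x_i ∈ {0, 1}.

Protonation equilibria of ionizable residues, lattice-gas occupancies
and (after the substitution σ = 2x − 1) Ising spins all fit this form.
The canonical partition function Z = Σ_x exp(−E(x)/k_B T) sums over 2^N
microstates and is intractable beyond N ≈ 30; the package implements the
direct interaction algorithm (DIA), a deterministic O(N²) approximation,
together with the apparatus needed to measure its accuracy on the 2D
Ising model.

## The direct interaction algorithm

One particle s is *selected*.  Pair interactions touching s are
*direct*; all others *indirect*.  Microstates are partitioned by the
state of s and by the number k of non-selected particles in state 1.
Within a (s, k) slice:

* the self energies and direct interactions factor into per-particle
  Boltzmann weights w_j (with w_j picking up exp(−g_sj/k_B T) when s is
  in state 1), and their exact combinatorial contribution is the
  elementary symmetric function (ESF) of order k over the w_j;
* the indirect contribution is approximated by the mean indirect
  energy ḡ applied to all k(k−1)/2 indirect pairs:
  exp(−(k(k−1)/2) ḡ / k_B T).

Both z-branches and all k are assembled in one pass, so the whole
decomposition (and hence Z, plus any k-resolved observable) costs O(N²)
multiply–adds.  The approximation is exact to round-off whenever the
averaged energies are homogeneous — in particular for N ≤ 3, for zero
pair energies and for any system whose indirect energies are all equal.
These exactness conditions are enforced by tests at relative 1e-10.

### Merge-level averaging

The ESFs are built by a binary split–merge tree (below).  Instead of one
global ḡ, each merge of subsets A and B can use the mean cross-energy
ḡ_AB over its |A|·|B| cross pairs, entering the convolution as the
bilinear factor x^(j(k−j)) with x = exp(−ḡ_AB/k_B T).  Every indirect
pair is averaged exactly once — at the merge where its two particles
first share a subtree — and the variant is exact whenever each merge's
cross energies are homogeneous, even if they differ between merges.
With input order preserved (row-major sites for the Ising mapping) the
bottom merges pair nearby particles, so short-range structure is treated
almost exactly.  `dia_local` (merge-level) is the default;
`dia_global` is kept for ablation and degenerates from it when all
indirect energies coincide.

## Elementary symmetric functions

e_k(w_1..w_M) is the sum over k-subsets of weight products, i.e. the
coefficients of Π_i (1 + w_i ξ).  Three routes:

* **Brute force** — subset enumeration, guarded at M ≤ 25; the oracle.
* **Newton's identities** — k e_k = Σ_j (−1)^{j−1} e_{k−j} p_j from
  power sums p_j.  For positive weights the alternating signs subtract
  nearly equal large terms; in machine doubles whole digits vanish
  (catastrophic cancellation).  The recursion is included to expose
  this failure mode: `cancellation_fixture()` (63 lattice-derived
  low-temperature Boltzmann factors, four of exp(−4) and fifty-nine of
  exp(−8)) drives the double-precision recursion to sign errors while
  split–merge stays within 1e-14.  The "exact" mode reruns the
  recursion in mpmath, doubling the working precision until two runs
  agree — on that fixture ~150 digits are needed, which is the point.
* **Split–merge** — recursively halve the weight list (left branch
  ⌊n/2⌋, order preserved), take [1, w_i] at single-particle leaves, and
  convolve children bottom-up.  Every summand is non-negative, so the
  computation is cancellation-free, and the schoolbook convolution
  keeps the total cost Θ(M²).  FFT-based merging is deliberately not
  used: it would reintroduce cancellation for a constant-factor gain
  the benchmark does not need.

### Log-domain representation

At t* = 0.5 on a 128×128 lattice the k-resolved coefficients span far
more than the ~600 decades a double (even with a per-vector shared
exponent) can hold, and the small-magnitude tail is exactly what the
k-dependent indirect factor later amplifies into the dominant term.  All
coefficients are therefore stored as logarithms (−inf encoding exact
zeros) and merged by log-sum-exp convolution; plain values are exposed
only through conversions that raise on overflow instead of returning
inf.  The inner kernel is a two-pass (max, then exp-accumulate) loop,
JIT-compiled with numba, with exp calls skipped below a −40 threshold
(< 4e-18 relative contribution, invisible in a double sum); a vectorized
numpy implementation of the identical reduction serves as fallback and
in-repo cross-check.  No randomness enters anywhere, so repeated runs
are bit-identical.

## 2D Ising test bed

L×L periodic square lattice, isotropic coupling J > 0, no field:
E = −J Σ_<ij> σ_i σ_j.  Substituting σ = 2x − 1 gives self energies
2J·degree = 8J, bond pair energies −4J and offset −2NJ; the mapping
preserves microstate energies exactly (property-tested on random
configurations).  L = 2 is rejected because periodic boundaries double
every bond.  Site 0 is the selected particle — immaterial under
translation symmetry, but exposed as a parameter for heterogeneous
systems.

Observables are dimensionless: t* = k_B T/J, m = ⟨|M|⟩/N, u = U/(NJ),
cv = C_v/(N k_B).  The absolute-value magnetization convention is forced
by finite lattices: the signed mean vanishes identically, and only
⟨|M|⟩ is comparable to the spontaneous-magnetization baseline.  From the
DIA decomposition, m = Σ_{s,k} |2(k+s) − N|/N · z_s[k]/Z; U comes from
U = k_B T² ∂(ln Z)/∂T by a central difference with step dt, and C_v from
a further central difference of U (five ln Z evaluations per
temperature).  dt defaults to 1e-3 (dimensionless); halving it moves
the benchmark observables by well under 0.1% (tested), while pushing it
much lower would start amplifying the ~1e-12 round-off of ln Z by 1/dt².
Derivatives of ln Z are used rather than k-resolved energy averages
because the indirect-energy approximation lives inside Z, not inside
per-microstate energies.

## Exact baseline

Kaufman's closed form for the finite periodic lattice (in Beale's
four-product formulation) is evaluated in mpmath: the products overflow
doubles for L ≥ ~16, and near the critical point the four terms must be
resolved against each other, so the working precision doubles until two
evaluations agree to 1e-13 relative — a cancelled result is never
returned silently.  The transcription is validated against the in-repo
2^16 spin enumeration (L ≤ 4), which — not the formula — is the ground
truth for the cross-validation tests (|Δu| < 1e-6, |Δcv| < 1e-4 across
0.5 ≤ t* ≤ 5).  U and C_v use central differences with step 1e-5 in
extended precision (discretization error ≪ 1e-8).  The magnetization
baseline is Onsager's spontaneous magnetization of the infinite
lattice, m = (1 − sinh(2/t*)^{−4})^{1/8} below t*_c = 2/ln(1+√2) and 0
above: the exact finite-lattice ⟨|M|⟩ is not derivable from Z alone.
For small L this baseline omits the finite-size ⟨|M|⟩ tail (≈ 0.34 at
L = 4, t* = 5), which the RMS comparison therefore books as method
error — a documented property of the protocol, not of the algorithms.

## Metropolis comparator

Basic single-flip Metropolis: one step = one sweep of N random-site
flip attempts, acceptance min(1, exp(−ΔE/k_B T)); a thermalization
phase equal in length to the sampling phase; one measurement per sweep;
random initial spins by default (all-up available for low-T
demonstrations).  "Steps" are interpreted as sweeps — the published
per-size budgets {4: 1.5e4, 8: 1e4, 16: 2e4, 32: 2e4, 64: 6e4,
128: 2e5}, shipped as `MC_STEP_PRESETS`, correspond to ~10× the DIA's
CPU time only under that reading.  Energy and magnetization are
tracked in integer units of J, so chains accumulate no floating-point
drift and are bit-reproducible from the seed.  Standard errors use 16
batch means (cv per batch for the fluctuation estimator); they are
honest scale estimates, not rigorous autocorrelation-corrected errors.

## Benchmark protocol

The accuracy harness sweeps t* = 0.5 .. 5.0 in steps of 0.1 (the grid
is a config value; this default spans the ordered, critical and
disordered regimes) over sizes 4..128 by doubling, and reports RMS
error against the exact baseline per observable.  Pooling over all
(size, temperature) points jointly is the default; averaging per-size
RMS values is available as `rms_mode="per-size-mean"`.  Every RMS in a
report is recomputable from the stored series, and the CSV writer
preserves full double precision.  The full protocol takes ~8 minutes on
one CPU, dominated by the 128×128 lattice (5 ln Z evaluations × 46
temperatures at ~1.3 s each).

## Synthetic systems

`random_system(n, seed, heterogeneity, g0=-0.5)` draws self energies
uniform on [−1, 1] and pair energies g0 + N(0, heterogeneity²),
emulating a small strongly coupled heterogeneous system in which every
pair interacts — the hardest regime for an averaging approximation,
and deliberately unlike the sparse, translation-symmetric lattice.
`heterogeneity=0` produces the all-equal-indirect regime where the DIA
must be exact; `heterogeneity=1` against brute force measures the
genuine approximation error.  What these fixtures do *not* emulate:
distance-decaying interactions, sparsity, or sign structure of real
electrostatic couplings, so passing tests bound correctness of the
implementation, not the DIA's accuracy on any particular real system.

## Known limitations

* The DIA is mean-field-like in its treatment of indirect
  interactions: replacing the energy of each k-slice by its mean makes
  z_k an annealed average, which (by Jensen's inequality) underweights
  mid-k slices and over-stabilizes ordered configurations.  On the
  Ising bed this shifts the apparent order–disorder transition to
  t* ≈ 3.4 (the infinite-lattice critical point is 2.269), which
  dominates the magnetization and heat-capacity RMS errors in the
  benchmark; ln Z per site itself stays within 0.055 of exact
  everywhere measured.  Internal energy is overestimated in the
  disordered regime, and all observables are accurate at low
  temperature and deep in the disordered regime.
* The exact-baseline magnetization ignores finite-size tails (above).
* Only single-selected-particle decompositions are implemented; systems
  with more than two states per particle are out of scope.
* MC error bars are batch-mean estimates; near t*_c they understate the
  true uncertainty because of critical slowing down (which is precisely
  the regime the comparator is meant to expose).
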