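# diapart

Deterministic canonical partition functions for two-state systems via
the **direct interaction algorithm (DIA)**, with a complete 2D Ising
validation bed: exact Kaufman/Beale baselines, single-flip Metropolis
Monte Carlo, and an RMS-error benchmark harness.

## The problem

For N interacting two-state particles (Ising spins, lattice-gas
occupancies, protonating residues) the canonical partition function

    Z = Σ_x exp(−E(x)/k_B T),   E(x) = E_off + Σ_i e_i x_i + Σ_{i<j} g_ij x_i x_j

sums over 2^N microstates and is intractable beyond a few tens of
particles.  Metropolis Monte Carlo is the workhorse approximation, but
it converges slowly for systems with long-range correlation (e.g. near
the Ising critical point), which is costly when answers are needed
quickly — very large systems, interactive web services computing
protonation states, and similar time-constrained settings.

## The method

The DIA selects one particle s and splits pair interactions into
*direct* (touching s, treated exactly) and *indirect* (all others,
replaced by their average).  Microstates are partitioned by the state
of s and the number k of other particles in state 1; the direct
contribution of each slice is an elementary symmetric function (ESF)
e_k of per-particle Boltzmann weights, and the indirect contribution is
exp(−(k(k−1)/2) ḡ/k_B T) with ḡ the mean indirect energy:

    Z ≈ Σ_k [ e_k(w^0) + e^{−e_s/k_B T} e_k(w^1) ] · e^{−k(k−1) ḡ / 2 k_B T} · e^{−E_off/k_B T}

The ESFs are computed by a cancellation-free binary **split–merge**
convolution tree in Θ(N²) operations and log-domain arithmetic (the
classical Newton's-identity recursion is also included — precisely to
demonstrate the catastrophic cancellation that makes it unusable for
this purpose).  A refinement applies a separate cross-subset average at
every merge of the tree (`dia_local`, the default), which is exact
whenever each merge's cross-interactions are homogeneous.  The result
is deterministic, bit-reproducible, and exact to round-off for n ≤ 3,
for zero pair energies, and whenever all indirect energies are equal.

## Worked example

Compare the DIA against exact enumeration on a 4×4 periodic Ising
lattice at the critical temperature t* = k_B T/J ≈ 2.269:

```python
from diapart import build_lattice, dia_thermo, enumerate_thermo

lat = build_lattice(4)                 # 16 sites, 32 bonds, J = 1
dia = dia_thermo(lat, 2.269)           # O(N^2) deterministic approximation
ref = enumerate_thermo(lat, 2.269)     # exact sum over all 2^16 states
print(dia)
print(ref)
```

prints

```
ThermoPoint(t_star=2.269, m_per_site=0.8791202436562866, u_per_site=-1.6257313256007557, cv_per_site=0.6826775363961701)
ThermoPoint(t_star=2.269, m_per_site=0.843920253390966, u_per_site=-1.5657689313277183, cv_per_site=0.7831935745140423)
```

i.e. at the hardest temperature for any mean-field-like method the DIA
reproduces the per-site magnetization ⟨|M|⟩/N within 0.035, the
internal energy U/NJ within 0.06 and the heat capacity C_v/Nk_B within
0.10 — at a cost that scales to lattices (128×128 ≈ 1.3 s per partition
function on one CPU) where enumeration is unthinkable and Monte Carlo
needs long runs.

The same machinery runs on arbitrary two-state systems from a TSV file
(`SELF i e_i` / `PAIR i j g_ij` / `OFFSET v` records):

```
$ diapart fixture --n 8 --seed 3 --out sys.tsv
wrote 8-particle system to sys.tsv
$ diapart generic --system sys.tsv --temperature 1.3
n = 8, selected = 0, variant = local
ln Z = 11.0104529576
Z    = 60503.2860595
```

Temperature sweeps and the accuracy table are available as
`diapart sweep` and `diapart table2`.

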