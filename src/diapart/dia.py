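"""The direct interaction algorithm (DIA).

A two-state system of n particles (states {0,1}) has energy

    E(x) = E_off + sum_i e_i x_i + sum_{i<j} g_ij x_i x_j ,

with self energies e_i, symmetric pairwise energies g_ij and a
state-independent offset.  Its canonical partition function sums
exp(-E/kT) over 2^n microstates, which is intractable beyond a few tens
of particles.

The DIA picks one *selected* particle s and classifies every pairwise
term: interactions touching s are *direct*, all others *indirect*.  The
microstates are partitioned by the state of s and by the number k of
non-selected particles in state 1; within each (s, k) slice the direct
contribution is an order-k elementary symmetric function of per-particle
Boltzmann factors (computed exactly by the stable split-merge
algorithm), while the indirect contribution is approximated by the mean
indirect energy times the pair count k(k-1)/2.  Two averaging variants
are provided:

``dia_global``
    one system-wide mean indirect energy (applied as a k-dependent
    factor after the ESF is assembled);
``dia_local``
    a separate cross-subset mean at every merge of the split-merge tree,
    entering as the bilinear factor x^(j*(k-j)) inside each convolution.

Both variants are exact (to round-off) whenever the indirect energies
they average over are homogeneous, and in particular for n <= 3 or for
zero pair energies.  The cost is O(n^2) arithmetic operations.

Everything runs in the log domain, so arbitrarily large or small
Boltzmann factors never overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp

from ._kernels import log_conv
from .esf import esf_split_merge_log

__all__ = [
    "ThermoConditions",
    "TwoStateSystem",
    "PartitionDecomposition",
    "boltzmann_weights",
    "log_boltzmann_weights",
    "mean_indirect",
    "mean_cross_interaction",
    "merge_plan",
    "dia_global",
    "dia_local",
    "partition_bruteforce",
    "read_system",
    "write_system",
]

_BRUTEFORCE_MAX_N = 20


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature and the Boltzmann constant (default 1: dimensionless units)."""

    temperature: float
    boltzmann_constant: float = 1.0

    def __post_init__(self):
        if not (self.temperature > 0):
            raise ValueError("temperature must be positive")
        if not (self.boltzmann_constant > 0):
            raise ValueError("boltzmann_constant must be positive")

    @property
    def kt(self) -> float:
        return self.boltzmann_constant * self.temperature


class TwoStateSystem:
    """n particles with self energies, symmetric pair energies and an offset.

    ``pair_energy`` may be given dense (n x n) or as any scipy sparse
    matrix; it is stored CSR so that large, sparsely interacting systems
    (e.g. lattice models) stay cheap.  The diagonal must be zero and the
    matrix symmetric.
    """

    def __init__(self, self_energy, pair_energy, energy_offset: float = 0.0):
        self.self_energy = np.asarray(self_energy, dtype=np.float64)
        if self.self_energy.ndim != 1:
            raise ValueError("self_energy must be 1-D")
        n = self.self_energy.size
        if sp.issparse(pair_energy):
            P = pair_energy.tocsr().astype(np.float64)
        else:
            P = sp.csr_matrix(np.asarray(pair_energy, dtype=np.float64))
        if P.shape != (n, n):
            raise ValueError("pair_energy must be n x n")
        if P.diagonal().any():
            raise ValueError("pair_energy diagonal must be zero")
        if abs(P - P.T).sum() != 0.0:
            raise ValueError("pair_energy must be symmetric")
        if not np.all(np.isfinite(self.self_energy)) or not np.all(
            np.isfinite(P.data)
        ):
            raise ValueError("all energies must be finite")
        self.pair_energy = P
        self.energy_offset = float(energy_offset)

    @property
    def n(self) -> int:
        return self.self_energy.size

    def pair_dense(self) -> np.ndarray:
        return self.pair_energy.toarray()

    def pair(self, i: int, j: int) -> float:
        return float(self.pair_energy[i, j])

    def energy(self, states) -> float:
        """Microstate energy; states is a 0/1 vector of length n."""
        x = np.asarray(states, dtype=np.float64)
        return float(
            self.energy_offset
            + x @ self.self_energy
            + 0.5 * x @ (self.pair_energy @ x)
        )


@dataclass(frozen=True)
class PartitionDecomposition:
    """k-resolved partition sums, split by the selected particle's state.

    ``log_z0[k]`` / ``log_z1[k]`` hold the log-contribution of
    microstates with the selected particle in state 0 / 1 and k of the
    other particles in state 1 (k = 0..n-2; index n-1 is -inf).  The
    state-independent energy offset is folded into every entry, so
    z_total is exactly the sum of the table.
    """

    log_z0: np.ndarray
    log_z1: np.ndarray
    log_z_total: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "log_z_total", float(logsumexp(np.concatenate([self.log_z0, self.log_z1])))
        )

    @property
    def n(self) -> int:
        return self.log_z0.size

    @property
    def z0(self) -> np.ndarray:
        return np.exp(self.log_z0)

    @property
    def z1(self) -> np.ndarray:
        return np.exp(self.log_z1)

    @property
    def z_total(self) -> float:
        return float(np.exp(self.log_z_total))


def _others(n: int, selected: int) -> np.ndarray:
    if not 0 <= selected < n:
        raise ValueError(f"selected particle {selected} out of range for n={n}")
    return np.delete(np.arange(n), selected)


def log_boltzmann_weights(
    sys: TwoStateSystem,
    selected: int,
    cond: ThermoConditions,
    include_direct: bool,
) -> np.ndarray:
    """log of the per-particle state-1 Boltzmann factors, in input order.

    With ``include_direct`` the direct pair energy g_{s,j} rides along
    with the self energy of particle j (the selected particle is in
    state 1); without it only the self energy enters.
    """
    others = _others(sys.n, selected)
    e = sys.self_energy[others].copy()
    if include_direct:
        e += sys.pair_energy[[selected], :].toarray().ravel()[others]
    return -e / cond.kt


def boltzmann_weights(
    sys: TwoStateSystem, selected: int, cond: ThermoConditions, include_direct: bool
) -> np.ndarray:
    """Plain-value Boltzmann factors; overflow raises (use the log form)."""
    lw = log_boltzmann_weights(sys, selected, cond, include_direct)
    if np.any(lw > 709.0):
        raise OverflowError(
            "Boltzmann factors exceed double range; use log_boltzmann_weights"
        )
    return np.exp(lw)


def _mean_indirect(sys: TwoStateSystem, selected: int) -> tuple[float, bool]:
    n = sys.n
    _others(n, selected)
    if n < 3:
        return 0.0, False
    total = sys.pair_energy.sum() / 2.0
    row_s = sys.pair_energy[[selected], :].sum()
    n_pairs = (n - 1) * (n - 2) // 2
    return float((total - row_s) / n_pairs), True


def mean_indirect(sys: TwoStateSystem, selected: int) -> float:
    """Mean pair energy over all pairs not involving the selected particle."""
    g, ok = _mean_indirect(sys, selected)
    if not ok:
        warnings.warn(
            f"system of n={sys.n} has no indirect pairs; mean_indirect is 0",
            stacklevel=2,
        )
    return g


def mean_cross_interaction(sys: TwoStateSystem, group_a, group_b) -> float:
    """Mean pair energy over the |A| x |B| pairs between two disjoint groups."""
    a = np.asarray(group_a, dtype=np.intp)
    b = np.asarray(group_b, dtype=np.intp)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("groups must be disjoint")
    block = sys.pair_energy[a][:, b]
    return float(block.sum() / (a.size * b.size))


def merge_plan(sys: TwoStateSystem, selected: int = 0) -> dict:
    """Cross-subset mean indirect energies for every split-merge node.

    Temperature-independent, so a plan computed once serves a whole
    temperature sweep.  Keys are (lo, hi) half-open ranges into the
    non-selected particle list (input order); values are the mean pair
    energy between the left and right child ranges.
    """
    others = _others(sys.n, selected)
    P = sys.pair_energy
    plan: dict[tuple[int, int], float] = {}

    def build(lo: int, hi: int) -> None:
        if hi - lo <= 1:
            return
        mid = lo + (hi - lo) // 2
        a = others[lo:mid]
        b = others[mid:hi]
        plan[(lo, hi)] = float(P[a][:, b].sum() / (a.size * b.size))
        build(lo, mid)
        build(mid, hi)

    build(0, others.size)
    return plan


def _decompose(
    sys: TwoStateSystem,
    selected: int,
    cond: ThermoConditions,
    log_e0: np.ndarray,
    log_e1: np.ndarray,
    extra_log: np.ndarray,
) -> PartitionDecomposition:
    kt = cond.kt
    base = -sys.energy_offset / kt
    log_z0 = log_e0 + extra_log + base
    log_z1 = -sys.self_energy[selected] / kt + log_e1 + extra_log + base
    return PartitionDecomposition(log_z0=log_z0, log_z1=log_z1)


def dia_global(
    sys: TwoStateSystem, selected: int = 0, cond: ThermoConditions | None = None
) -> PartitionDecomposition:
    """DIA with a single system-wide mean indirect energy.

    z_s[k] = (direct ESF coefficient of order k) * exp(-k(k-1)/2 * gbar / kT),
    with the selected particle's self energy and the global offset folded in.
    """
    if cond is None:
        raise TypeError("ThermoConditions required")
    if sys.n < 2:
        raise ValueError("DIA requires at least two particles")
    kt = cond.kt
    gbar, _ = _mean_indirect(sys, selected)
    lw0 = log_boltzmann_weights(sys, selected, cond, include_direct=False)
    lw1 = log_boltzmann_weights(sys, selected, cond, include_direct=True)
    log_e0 = esf_split_merge_log(lw0)
    log_e1 = esf_split_merge_log(lw1)
    k = np.arange(sys.n, dtype=np.float64)
    extra = -(k * (k - 1) / 2.0) * gbar / kt
    return _decompose(sys, selected, cond, log_e0, log_e1, extra)


def dia_local(
    sys: TwoStateSystem,
    selected: int = 0,
    cond: ThermoConditions | None = None,
    plan: dict | None = None,
) -> PartitionDecomposition:
    """DIA with a merge-level mean indirect energy.

    Each split-merge convolution of child subsets A (j in state 1) and B
    (k-j in state 1) carries the factor x^(j(k-j)) with
    x = exp(-gbar_AB/kT), gbar_AB the mean pair energy between A and B.
    Every indirect pair is averaged exactly once, at the merge where its
    two particles first share a subtree.  Degenerates to ``dia_global``
    when all indirect energies are equal.
    """
    if cond is None:
        raise TypeError("ThermoConditions required")
    if sys.n < 2:
        raise ValueError("DIA requires at least two particles")
    kt = cond.kt
    if plan is None:
        plan = merge_plan(sys, selected)
    lw0 = log_boltzmann_weights(sys, selected, cond, include_direct=False)
    lw1 = log_boltzmann_weights(sys, selected, cond, include_direct=True)

    def run(lw: np.ndarray) -> np.ndarray:
        def build(lo: int, hi: int) -> np.ndarray:
            if hi - lo == 1:
                return np.array([0.0, lw[lo]])
            mid = lo + (hi - lo) // 2
            coupling = -plan[(lo, hi)] / kt
            return log_conv(build(lo, mid), build(mid, hi), coupling)

        return build(0, lw.size)

    zeros = np.zeros(sys.n)
    return _decompose(sys, selected, cond, run(lw0), run(lw1), zeros)


def partition_bruteforce(
    sys: TwoStateSystem, selected: int = 0, cond: ThermoConditions | None = None
) -> PartitionDecomposition:
    """Exact k-resolved partition sums by enumerating all 2^n microstates."""
    if cond is None:
        raise TypeError("ThermoConditions required")
    n = sys.n
    _others(n, selected)
    if n > _BRUTEFORCE_MAX_N:
        raise ValueError(
            f"brute force enumerates 2^n microstates; n={n} exceeds the "
            f"guard of {_BRUTEFORCE_MAX_N}"
        )
    kt = cond.kt
    P = sys.pair_dense()
    log_z0 = np.full(n, -np.inf)
    log_z1 = np.full(n, -np.inf)
    chunk = 1 << 16
    pieces0: dict[int, list] = {}
    pieces1: dict[int, list] = {}
    for start in range(0, 1 << n, chunk):
        idx = np.arange(start, min(start + chunk, 1 << n))
        X = ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(np.float64)
        E = (
            sys.energy_offset
            + X @ sys.self_energy
            + 0.5 * np.einsum("ij,jk,ik->i", X, P, X)
        )
        lw = -E / kt
        s = X[:, selected].astype(np.intp)
        k = (X.sum(axis=1) - s).astype(np.intp)
        for kk in range(n):
            for ss, pieces in ((0, pieces0), (1, pieces1)):
                mask = (k == kk) & (s == ss)
                if mask.any():
                    pieces.setdefault(kk, []).append(logsumexp(lw[mask]))
    for kk, vals in pieces0.items():
        log_z0[kk] = logsumexp(vals)
    for kk, vals in pieces1.items():
        log_z1[kk] = logsumexp(vals)
    return PartitionDecomposition(log_z0=log_z0, log_z1=log_z1)


# ---------------------------------------------------------------------------
# Generic two-state system files: tab-separated, '#' comments, 0-based
# indices.  Lines: SELF i value / PAIR i j value / OFFSET value.
# Unmentioned pair energies are zero; duplicate pair lines are an error.
# ---------------------------------------------------------------------------

def read_system(path) -> TwoStateSystem:
    self_e: dict[int, float] = {}
    pairs: dict[tuple[int, int], float] = {}
    offset = 0.0
    n_max = -1
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            tag = parts[0].upper()
            try:
                if tag == "SELF":
                    i, v = int(parts[1]), float(parts[2])
                    if i in self_e:
                        raise ValueError(f"duplicate SELF entry for particle {i}")
                    self_e[i] = v
                    n_max = max(n_max, i)
                elif tag == "PAIR":
                    i, j, v = int(parts[1]), int(parts[2]), float(parts[3])
                    if i == j:
                        raise ValueError("PAIR indices must differ")
                    key = (min(i, j), max(i, j))
                    if key in pairs:
                        raise ValueError(f"duplicate PAIR entry for {key}")
                    pairs[key] = v
                    n_max = max(n_max, i, j)
                elif tag == "OFFSET":
                    offset = float(parts[1])
                else:
                    raise ValueError(f"unknown record type {tag!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if n_max < 0:
        raise ValueError(f"{path}: no particles defined")
    n = n_max + 1
    se = np.zeros(n)
    for i, v in self_e.items():
        se[i] = v
    if pairs:
        ii, jj = np.array(list(pairs)).T
        vv = np.fromiter(pairs.values(), dtype=np.float64)
        P = sp.coo_matrix(
            (np.concatenate([vv, vv]), (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
            shape=(n, n),
        )
    else:
        P = sp.csr_matrix((n, n))
    return TwoStateSystem(se, P, offset)


def write_system(sys: TwoStateSystem, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# two-state system: SELF i e_i / PAIR i j g_ij / OFFSET value\n")
        if sys.energy_offset:
            fh.write(f"OFFSET\t{sys.energy_offset:.17g}\n")
        for i, v in enumerate(sys.self_energy):
            fh.write(f"SELF\t{i}\t{v:.17g}\n")
        upper = sp.triu(sys.pair_energy, k=1).tocoo()
        for i, j, v in zip(upper.row, upper.col, upper.data):
            fh.write(f"PAIR\t{i}\t{j}\t{v:.17g}\n")
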