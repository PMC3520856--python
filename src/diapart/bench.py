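"""Temperature sweeps and RMS-error benchmarking.

The headline experiment of the package: evaluate the DIA (either
averaging variant), Metropolis MC and the exact Kaufman/Beale baseline
over a grid of dimensionless temperatures and lattice sizes, and report
the root-mean-square error of each method against the baseline, per
observable, pooled over every (size, temperature) grid point.

The default grid is t* = 0.5 .. 5.0 in steps of 0.1 — spanning the
strongly ordered phase, the critical region near t*c ~ 2.269 and the
disordered phase — and the default sizes are 4..128 by doubling.  MC
sweep budgets default to the timing-matched presets in
``diapart.mc.MC_STEP_PRESETS``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dia import TwoStateSystem
from .exact import exact_thermo
from .ising import ThermoPoint, build_lattice, dia_thermo, enumerate_thermo
from .mc import MC_STEP_PRESETS, MCConfig, mc_run

__all__ = [
    "SweepSpec",
    "BenchReport",
    "OBSERVABLES",
    "rms_error",
    "temperature_sweep",
    "reproduce_table2",
    "random_system",
]

OBSERVABLES = ("m_per_site", "u_per_site", "cv_per_site")
_KNOWN_METHODS = ("dia-local", "dia-global", "mc", "exact", "enum")


@dataclass(frozen=True)
class SweepSpec:
    """What to run: sizes, temperature grid, methods and their knobs."""

    sizes: tuple = (4, 8, 16, 32, 64, 128)
    t_min: float = 0.5
    t_max: float = 5.0
    t_step: float = 0.1
    methods: tuple = ("dia-local", "exact")
    dt: float = 1e-3
    mc_presets: dict = field(default_factory=lambda: dict(MC_STEP_PRESETS))
    seed: int = 0
    rms_mode: str = "pooled"

    def __post_init__(self):
        if not (self.t_min > 0 and self.t_step > 0 and self.t_max >= self.t_min):
            raise ValueError("need t_min > 0, t_step > 0, t_max >= t_min")
        for m in self.methods:
            if m not in _KNOWN_METHODS:
                raise ValueError(f"unknown method {m!r}")
        if self.rms_mode not in ("pooled", "per-size-mean"):
            raise ValueError("rms_mode must be 'pooled' or 'per-size-mean'")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.t_step)) + 1
        return np.round(self.t_min + self.t_step * np.arange(n), 12)


@dataclass
class BenchReport:
    """Per-method, per-size observable series plus RMS errors vs exact."""

    spec: SweepSpec
    series: dict  # method -> {L -> DataFrame(t_star, m_per_site, u_per_site, cv_per_site)}
    rms_pooled: dict  # method -> {observable -> float}
    rms_per_size: dict  # method -> {L -> {observable -> float}}

    def to_csv_dir(self, outdir) -> None:
        """One CSV per (method, size); 17 significant digits round-trip doubles."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for method, per_size in self.series.items():
            for L, df in per_size.items():
                df.to_csv(out / f"{method}_L{L}.csv", index=False, float_format="%.17g")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            fh.write(self.summary_json())

    def summary_json(self) -> str:
        cfg = asdict(self.spec)
        cfg["sizes"] = list(cfg["sizes"])
        cfg["methods"] = list(cfg["methods"])
        return json.dumps(
            {
                "config": cfg,
                "rms_pooled": self.rms_pooled,
                "rms_per_size": {
                    m: {str(L): v for L, v in per.items()}
                    for m, per in self.rms_per_size.items()
                },
            },
            indent=2,
        )

    def table_text(self) -> str:
        """Two-column accuracy table (RMS error vs the exact baseline)."""
        methods = [m for m in self.series if m != "exact"]
        rows = {
            "m_per_site": "Average magnetization (<|M|>/N)",
            "u_per_site": "Internal energy (U/NJ)",
            "cv_per_site": "Heat capacity (Cv/N kB)",
        }
        width = max(len(v) for v in rows.values())
        lines = [" " * width + "  " + "  ".join(f"{m:>10}" for m in methods)]
        for obs, label in rows.items():
            cells = "  ".join(f"{self.rms_pooled[m][obs]:10.4f}" for m in methods)
            lines.append(f"{label:<{width}}  {cells}")
        return "\n".join(lines)


def rms_error(approx, reference) -> float:
    """sqrt(mean((approx - reference)^2)); series must be equal length."""
    a = np.asarray(approx, dtype=np.float64)
    r = np.asarray(reference, dtype=np.float64)
    if a.shape != r.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("series must be 1-D, non-empty and of equal length")
    return float(np.sqrt(np.mean((a - r) ** 2)))


def _points_frame(points: list[ThermoPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_star": [p.t_star for p in points],
            "m_per_site": [p.m_per_site for p in points],
            "u_per_site": [p.u_per_site for p in points],
            "cv_per_site": [p.cv_per_site for p in points],
        }
    )


def _eval_method(method: str, L: int, spec: SweepSpec) -> pd.DataFrame:
    ts = spec.grid
    if method == "exact":
        pts = [exact_thermo(L, t) for t in ts]
    elif method == "enum":
        lat = build_lattice(L)
        pts = [enumerate_thermo(lat, t) for t in ts]
    elif method in ("dia-local", "dia-global"):
        lat = build_lattice(L)
        variant = method.split("-")[1]
        pts = [dia_thermo(lat, t, dt=spec.dt, variant=variant) for t in ts]
    elif method == "mc":
        lat = build_lattice(L)
        steps = spec.mc_presets.get(L)
        if steps is None:
            raise ValueError(f"no MC step preset for L={L}")
        pts = []
        for i, t in enumerate(ts):
            cfg = MCConfig(steps=int(steps), seed=int(spec.seed * 100003 + L * 1009 + i))
            pts.append(mc_run(lat, t, cfg).point)
    else:  # pragma: no cover
        raise ValueError(f"unknown method {method!r}")
    return _points_frame(pts)


def temperature_sweep(spec: SweepSpec) -> BenchReport:
    """Evaluate every requested method on the full (size, temperature) grid.

    The exact baseline is always computed (it anchors the RMS columns).
    Deterministic methods are bit-reproducible; MC is seeded from
    ``spec.seed`` with a distinct stream per (size, temperature).
    """
    methods = list(spec.methods)
    if "exact" not in methods:
        methods.append("exact")
    if "enum" in methods and any(L > 4 for L in spec.sizes):
        raise ValueError("enumeration is limited to L <= 4")
    series: dict[str, dict[int, pd.DataFrame]] = {m: {} for m in methods}
    for L in spec.sizes:
        for method in methods:
            series[method][int(L)] = _eval_method(method, int(L), spec)
    rms_pooled: dict[str, dict[str, float]] = {}
    rms_per_size: dict[str, dict[int, dict[str, float]]] = {}
    for method in methods:
        if method == "exact":
            continue
        rms_per_size[method] = {}
        pooled_a = {obs: [] for obs in OBSERVABLES}
        pooled_r = {obs: [] for obs in OBSERVABLES}
        for L in spec.sizes:
            approx = series[method][int(L)]
            ref = series["exact"][int(L)]
            rms_per_size[method][int(L)] = {
                obs: rms_error(approx[obs], ref[obs]) for obs in OBSERVABLES
            }
            for obs in OBSERVABLES:
                pooled_a[obs].append(approx[obs].to_numpy())
                pooled_r[obs].append(ref[obs].to_numpy())
        if spec.rms_mode == "pooled":
            rms_pooled[method] = {
                obs: rms_error(
                    np.concatenate(pooled_a[obs]), np.concatenate(pooled_r[obs])
                )
                for obs in OBSERVABLES
            }
        else:
            rms_pooled[method] = {
                obs: float(
                    np.mean([rms_per_size[method][int(L)][obs] for L in spec.sizes])
                )
                for obs in OBSERVABLES
            }
    return BenchReport(
        spec=spec, series=series, rms_pooled=rms_pooled, rms_per_size=rms_per_size
    )


def reproduce_table2(spec: SweepSpec | None = None) -> BenchReport:
    """The timing-matched accuracy comparison over sizes 4..128.

    Default: DIA (merge-level averaging) against the exact baseline on
    the default grid; add ``"mc"`` to ``spec.methods`` for the
    Monte Carlo column with its per-size sweep presets.
    """
    if spec is None:
        spec = SweepSpec()
    return temperature_sweep(spec)


def random_system(
    n: int, seed: int, heterogeneity: float = 1.0, g0: float = -0.5
) -> TwoStateSystem:
    """Seeded random heterogeneous two-state system (test fixture generator).

    Self energies are uniform on [-1, 1]; every pair energy is the base
    value ``g0`` plus a zero-mean normal perturbation of standard
    deviation ``heterogeneity``.  ``heterogeneity=0`` makes every
    indirect interaction equal, the regime where the DIA is exact by
    construction.
    """
    if n < 2:
        raise ValueError("need at least two particles")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be >= 0")
    rng = np.random.default_rng(seed)
    self_e = rng.uniform(-1.0, 1.0, n)
    iu = np.triu_indices(n, 1)
    vals = g0 + heterogeneity * rng.standard_normal(len(iu[0]))
    G = np.zeros((n, n))
    G[iu] = vals
    G = G + G.T
    return TwoStateSystem(self_e, sp.csr_matrix(G), energy_offset=0.0)
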