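"""Model inversion: fit (G, J_NMDA, w_plus, J_i) to experimental FC and FCD.

The forward chain (neural-mass simulation -> Balloon-Windkessel BOLD -> TR
resampling -> FC/FCD observables) is evaluated on an exhaustive parameter
grid; the per-point score is the cost (1 - PCC) + KS averaged over several
RNG seeds, each seed standing for a different noise stream and initial
condition.  The argmin is the fitted parameter set; per-seed argmin
dispersion quantifies the reliability of the fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from netvb.connectome import Connectome
from netvb.hemodynamics import HemodynamicConstants, bold_forward, resample_to_tr
from netvb.metrics import (
    DEFAULT_FC_THRESHOLD,
    FCDMatrix,
    FCMatrix,
    FitMetrics,
    fc_similarity,
    fcd_distance,
    fit_cost,
    sliding_fcd,
    static_fc,
)
from netvb.rww import FitParams, NeuralMassConstants, SimConfig, simulate_network

__all__ = [
    "ObservableConfig",
    "SearchGrid",
    "FitResult",
    "evaluate_point",
    "grid_search",
    "multistart_stability",
    "default_grid",
]

#: Tie-break order for equal-cost grid points (lower value wins, in order).
TIE_ORDER = ("G", "J_i", "J_NMDA", "w_plus")


@dataclass(frozen=True)
class ObservableConfig:
    """How simulated BOLD is turned into the fitted observables."""

    TR: float = 2.4
    window_s: float = 40.0
    window_preset: str = "40s-nominal"
    fc_threshold: float = DEFAULT_FC_THRESHOLD

    def observables(self, bold) -> tuple[FCMatrix, FCDMatrix]:
        return (
            static_fc(bold, threshold=self.fc_threshold),
            sliding_fcd(bold, window_s=self.window_s, preset=self.window_preset),
        )


@dataclass(frozen=True)
class SearchGrid:
    """Ordered candidate values per parameter; singletons pin a parameter."""

    G: tuple[float, ...]
    J_NMDA: tuple[float, ...]
    w_plus: tuple[float, ...]
    J_i: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("G", "J_NMDA", "w_plus", "J_i"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"empty grid for {name}")
            if any(v < 0 for v in vals):
                raise ValueError(f"negative grid value for {name}")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"grid for {name} must be strictly increasing")
            object.__setattr__(self, name, vals)

    def points(self) -> list[FitParams]:
        return [
            FitParams(G=g, J_NMDA=j, w_plus=w, J_i=ji)
            for g, j, w, ji in itertools.product(
                self.G, self.J_NMDA, self.w_plus, self.J_i
            )
        ]

    def step(self, name: str) -> float:
        vals = getattr(self, name)
        if len(vals) < 2:
            return 0.0
        return float(min(b - a for a, b in zip(vals, vals[1:])))


def default_grid() -> SearchGrid:
    """Default search ranges covering the physiologically plausible regime."""
    return SearchGrid(
        G=tuple(np.linspace(0.1, 3.0, 15)),
        J_NMDA=tuple(np.linspace(0.05, 0.30, 6)),
        w_plus=tuple(np.linspace(0.5, 1.6, 6)),
        J_i=tuple(np.linspace(0.2, 3.0, 8)),
    )


@dataclass(frozen=True)
class FitResult:
    """Grid-search outcome: argmin parameters, their seed-averaged metrics,
    the full evaluation trace, and per-seed argmin dispersion."""

    best: FitParams
    metrics: FitMetrics
    trace: tuple[tuple[FitParams, FitMetrics, int], ...]
    seeds: tuple[int, ...]
    grid: SearchGrid

    def to_dict(self) -> dict:
        return {
            "best": self.best.as_dict(),
            "metrics": self.metrics.as_dict(),
            "seeds": list(self.seeds),
            "trace": [
                {"params": p.as_dict(), "metrics": m.as_dict(), "seed": s}
                for p, m, s in self.trace
            ],
        }


def _initial_state(seed: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Seed-derived multistart initial gating, uniform in [0, 0.2]."""
    rng = np.random.default_rng([int(seed), 0x5EED])
    return rng.uniform(0.0, 0.2, n), rng.uniform(0.0, 0.2, n)


def evaluate_point(
    C: Connectome,
    p: FitParams,
    expFC: FCMatrix,
    expFCD: FCDMatrix,
    cfg: SimConfig,
    k: NeuralMassConstants | None = None,
    h: HemodynamicConstants | None = None,
    obs: ObservableConfig | None = None,
    multistart_init: bool = True,
) -> FitMetrics:
    """Run the full forward chain at one parameter point and score the fit.

    Fully reproducible given ``cfg.seed``: the seed fixes both the noise
    stream and (with ``multistart_init``) the uniform initial gating state.
    """
    k = k or NeuralMassConstants()
    obs = obs or ObservableConfig()
    if expFC.labels != C.labels:
        raise ValueError("connectome/target label mismatch")
    init = _initial_state(cfg.seed, C.n_nodes) if multistart_init else None
    traj = simulate_network(C, p, k, cfg, initial_state=init)
    y = bold_forward(traj, h, dt=cfg.dt * cfg.record_every, init="steady")
    bold = resample_to_tr(
        y,
        obs.TR,
        cfg.dt * cfg.record_every,
        duration=cfg.duration - cfg.transient,
        labels=C.labels,
    )
    simFC, simFCD = obs.observables(bold)
    try:
        pcc = fc_similarity(expFC, simFC)
    except ValueError as e:
        if "zero-variance" not in str(e):
            raise
        # every simulated edge fell below the FC threshold: no pattern to
        # correlate, scored as complete absence of static-FC match
        pcc = 0.0
    ks = fcd_distance(expFCD, simFCD)
    return fit_cost(pcc, ks)


def _argmin(points: list[FitParams], costs: np.ndarray) -> int:
    best_cost = np.min(costs)
    tied = [i for i in range(len(points)) if costs[i] <= best_cost + 1e-15]
    key = lambda i: tuple(getattr(points[i], name) for name in TIE_ORDER)
    return min(tied, key=key)


def grid_search(
    C: Connectome,
    expFC: FCMatrix,
    expFCD: FCDMatrix,
    grid: SearchGrid,
    seeds: tuple[int, ...] | list[int],
    cfg: SimConfig,
    k: NeuralMassConstants | None = None,
    h: HemodynamicConstants | None = None,
    obs: ObservableConfig | None = None,
    multistart_init: bool = True,
) -> FitResult:
    """Exhaustive grid search; score = mean cost across seeds.

    Every grid point x seed evaluation is kept in the trace.  Cost ties are
    broken deterministically by lower (G, J_i, J_NMDA, w_plus).
    """
    seeds = tuple(int(s) for s in seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    points = grid.points()
    trace: list[tuple[FitParams, FitMetrics, int]] = []
    mean_pcc = np.zeros(len(points))
    mean_ks = np.zeros(len(points))
    for i, p in enumerate(points):
        for s in seeds:
            m = evaluate_point(
                C, p, expFC, expFCD, replace(cfg, seed=s), k=k, h=h, obs=obs,
                multistart_init=multistart_init,
            )
            trace.append((p, m, s))
            mean_pcc[i] += m.pcc / len(seeds)
            mean_ks[i] += m.ks / len(seeds)
    mean_cost = (1.0 - mean_pcc) + mean_ks
    best_i = _argmin(points, mean_cost)
    return FitResult(
        best=points[best_i],
        metrics=FitMetrics(pcc=float(mean_pcc[best_i]), ks=float(mean_ks[best_i])),
        trace=tuple(trace),
        seeds=seeds,
        grid=grid,
    )


def multistart_stability(result: FitResult) -> dict:
    """Per-parameter dispersion of per-seed argmins.

    For every seed, the argmin of that seed's own cost surface is located;
    the report gives each parameter's range and standard deviation across
    seeds and flags it unstable when the range exceeds one grid step.
    """
    if len(result.seeds) < 2:
        raise ValueError("stability assessment needs at least two seeds")
    points = result.grid.points()
    index = {p: i for i, p in enumerate(points)}
    per_seed_best: list[FitParams] = []
    for s in result.seeds:
        costs = np.full(len(points), np.inf)
        for p, m, seed in result.trace:
            if seed == s:
                costs[index[p]] = m.cost
        per_seed_best.append(points[_argmin(points, costs)])
    report: dict = {"seeds": list(result.seeds), "parameters": {}}
    for name in ("G", "J_NMDA", "w_plus", "J_i"):
        vals = np.array([getattr(p, name) for p in per_seed_best])
        rng_ = float(vals.max() - vals.min())
        step = result.grid.step(name)
        report["parameters"][name] = {
            "values": vals.tolist(),
            "range": rng_,
            "std": float(vals.std()),
            "grid_step": step,
            "unstable": bool(step > 0 and rng_ > step + 1e-12),
        }
    return report
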