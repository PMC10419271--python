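"""Reduced Wong-Wang excitatory/inhibitory neural-mass model on a connectome.

Each node carries two coupled populations described by synaptic gating
variables ``S_E`` (NMDA) and ``S_I`` (GABA).  Long-range coupling enters the
excitatory current through the structural connectome scaled by the global
coupling ``G``.  Four parameters are fitted per network: ``G``, the
excitatory coupling ``J_NMDA``, the recurrent excitation ``w_plus`` and the
inhibitory coupling ``J_i``.

Currents (nA), per node i::

    I_E_i = W_E*I_0 + w_plus*J_NMDA*S_E_i + G*J_NMDA*sum_j C_ij S_E_j - J_i*S_I_i
    I_I_i = W_I*I_0 + J_NMDA*S_E_i - S_I_i + lambda_FFI*G*J_NMDA*sum_j C_ij S_E_j

Population firing rates come from the sigmoidal transfer function
``H(x) = (a*x - b) / (1 - exp(-d*(a*x - b)))`` and the gating variables obey

    dS_E = (-S_E/tau_E + (1 - S_E)*gamma*r_E) dt + sigma dW
    dS_I = (-S_I/tau_I + r_I) dt + sigma dW

integrated with Euler-Maruyama and clipped to [0, 1] after every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import optimize

from netvb.connectome import Connectome

__all__ = [
    "NeuralMassConstants",
    "FitParams",
    "SimConfig",
    "NeuralTrajectory",
    "transfer_rate",
    "node_currents",
    "simulate_network",
    "single_node_fixed_point",
]


@dataclass(frozen=True)
class NeuralMassConstants:
    """Fixed biophysical constants of the two-population neural mass.

    Units: gains ``a_*`` in Hz/nA, thresholds ``b_*`` in Hz, curvatures
    ``d_*`` in s, time constants in s, currents in nA.
    """

    a_E: float = 310.0
    b_E: float = 125.0
    d_E: float = 0.16
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    tau_E: float = 0.1
    tau_I: float = 0.01
    gamma_k: float = 0.641
    I_0: float = 0.382
    W_E: float = 1.0
    W_I: float = 0.7
    sigma: float = 0.01
    lambda_FFI: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be positive")
        if self.d_E <= 0 or self.d_I <= 0:
            raise ValueError("curvature constants must be positive")
        if self.sigma < 0:
            raise ValueError("noise amplitude must be non-negative")


@dataclass(frozen=True)
class FitParams:
    """The four globally fitted parameters of one network model."""

    G: float
    J_NMDA: float
    w_plus: float
    J_i: float

    def __post_init__(self) -> None:
        for name in ("G", "J_NMDA", "w_plus", "J_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "G": self.G,
            "J_NMDA": self.J_NMDA,
            "w_plus": self.w_plus,
            "J_i": self.J_i,
        }


@dataclass(frozen=True)
class SimConfig:
    """Integration settings: step ``dt`` (s), total ``duration`` (s), the
    discarded initial ``transient`` (s), RNG ``seed``, and recording stride."""

    dt: float = 1e-3
    duration: float = 490.0
    transient: float = 10.0
    seed: int = 0
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.duration > self.transient >= 0:
            raise ValueError("need duration > transient >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass(frozen=True)
class NeuralTrajectory:
    """Recorded gating time series: ``times`` (s) and node-by-time matrices."""

    times: np.ndarray
    S_E_series: np.ndarray  # (n_nodes, n_samples)
    S_I_series: np.ndarray
    n_clipped: int = 0

    @property
    def n_nodes(self) -> int:
        return self.S_E_series.shape[0]


def transfer_rate(
    x: float | np.ndarray, a: float, b: float, d: float
) -> float | np.ndarray:
    """Population transfer function ``H(x) = (a x - b)/(1 - exp(-d (a x - b)))``.

    Total on the reals: the removable singularity at ``a x = b`` evaluates to
    its limit ``1/d``; a truncated Taylor expansion is used in a small
    neighborhood to keep full double precision there.
    """
    x = np.asarray(x, dtype=float)
    u = a * x - b
    t = d * u
    out = np.empty_like(u)
    small = np.abs(t) < 1e-5
    # t/(1-e^{-t}) = 1 + t/2 + t^2/12 - t^4/720 + O(t^6)
    ts = t[small]
    out[small] = (1.0 + ts / 2.0 + ts * ts / 12.0) / d
    tb = t[~small]
    ub = u[~small]
    with np.errstate(over="ignore"):
        denom = 1.0 - np.exp(-tb)
    vals = np.where(np.isfinite(denom), ub / denom, 0.0)
    vals = np.where(tb < -700.0, 0.0, vals)
    out[~small] = vals
    if out.ndim == 0:
        return float(out)
    return out


def node_currents(
    S_E: np.ndarray,
    S_I: np.ndarray,
    p: FitParams,
    k: NeuralMassConstants,
    C: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Excitatory and inhibitory input currents (nA) per node."""
    S_E = np.asarray(S_E, dtype=float)
    S_I = np.asarray(S_I, dtype=float)
    C = np.asarray(C, dtype=float)
    n = S_E.shape[0]
    if S_I.shape[0] != n or C.shape != (n, n):
        raise ValueError("state/connectome dimension mismatch")
    coupling = C @ S_E
    I_E = (
        k.W_E * k.I_0
        + p.w_plus * p.J_NMDA * S_E
        + p.G * p.J_NMDA * coupling
        - p.J_i * S_I
    )
    I_I = k.W_I * k.I_0 + p.J_NMDA * S_E - S_I + k.lambda_FFI * p.G * p.J_NMDA * coupling
    return I_E, I_I


@njit(cache=True)
def _H(u: float, d: float) -> float:
    t = d * u
    if abs(t) < 1e-5:
        return (1.0 + t / 2.0 + t * t / 12.0) / d
    if t < -700.0:
        return 0.0
    return u / (1.0 - math.exp(-t))


@njit(cache=True)
def _integrate(
    C,
    G,
    J_NMDA,
    w_plus,
    J_i,
    a_E,
    b_E,
    d_E,
    a_I,
    b_I,
    d_I,
    tau_E,
    tau_I,
    gamma_k,
    I_0,
    W_E,
    W_I,
    lambda_FFI,
    sigma,
    dt,
    n_steps,
    rec_start,
    record_every,
    S_E0,
    S_I0,
    noise,
    S_E_out,
    S_I_out,
):
    n = C.shape[0]
    sqrt_dt = math.sqrt(dt)
    S_E = S_E0.copy()
    S_I = S_I0.copy()
    n_clipped = 0
    sample = 0
    GJ = G * J_NMDA
    wJ = w_plus * J_NMDA
    if rec_start == 0:
        for i in range(n):
            S_E_out[i, 0] = S_E[i]
            S_I_out[i, 0] = S_I[i]
        sample = 1
    for step in range(n_steps):
        for i in range(n):
            coup = 0.0
            for j in range(n):
                coup += C[i, j] * S_E[j]
            I_E = W_E * I_0 + wJ * S_E[i] + GJ * coup - J_i * S_I[i]
            I_I = W_I * I_0 + J_NMDA * S_E[i] - S_I[i] + lambda_FFI * GJ * coup
            r_E = _H(a_E * I_E - b_E, d_E)
            r_I = _H(a_I * I_I - b_I, d_I)
            dSE = (-S_E[i] / tau_E + (1.0 - S_E[i]) * gamma_k * r_E) * dt
            dSI = (-S_I[i] / tau_I + r_I) * dt
            if sigma > 0.0:
                dSE += sigma * sqrt_dt * noise[step, i, 0]
                dSI += sigma * sqrt_dt * noise[step, i, 1]
            S_E[i] += dSE
            S_I[i] += dSI
            if S_E[i] < 0.0:
                S_E[i] = 0.0
                n_clipped += 1
            elif S_E[i] > 1.0:
                S_E[i] = 1.0
                n_clipped += 1
            if S_I[i] < 0.0:
                S_I[i] = 0.0
                n_clipped += 1
            elif S_I[i] > 1.0:
                S_I[i] = 1.0
                n_clipped += 1
            if not (math.isfinite(S_E[i]) and math.isfinite(S_I[i])):
                return -(step + 1), n_clipped
        k_rec = step + 1 - rec_start
        if k_rec >= 0 and k_rec % record_every == 0 and sample < S_E_out.shape[1]:
            for i in range(n):
                S_E_out[i, sample] = S_E[i]
                S_I_out[i, sample] = S_I[i]
            sample += 1
    return sample, n_clipped


def simulate_network(
    C: Connectome | np.ndarray,
    p: FitParams,
    k: NeuralMassConstants | None = None,
    cfg: SimConfig | None = None,
    initial_state: tuple[np.ndarray, np.ndarray] | None = None,
) -> NeuralTrajectory:
    """Integrate the stochastic gating dynamics on a connectome.

    Euler-Maruyama with step ``cfg.dt``; independent Gaussian increments per
    node and population drawn from a single generator seeded by ``cfg.seed``
    in node-major order with E before I, so runs are bitwise reproducible for
    a fixed seed, step, and node order.  The first ``cfg.transient`` seconds
    are discarded; recorded samples start at ``t = transient``.

    ``initial_state`` overrides the default start ``S_E = S_I = 0.001``.
    """
    k = k or NeuralMassConstants()
    cfg = cfg or SimConfig()
    W = C.weights if isinstance(C, Connectome) else np.asarray(C, dtype=float)
    n = W.shape[0]
    n_steps = int(round(cfg.duration / cfg.dt))
    rec_start = int(round(cfg.transient / cfg.dt))
    n_samples = (n_steps - rec_start) // cfg.record_every + 1
    if initial_state is None:
        S_E0 = np.full(n, 1e-3)
        S_I0 = np.full(n, 1e-3)
    else:
        S_E0 = np.asarray(initial_state[0], dtype=float).copy()
        S_I0 = np.asarray(initial_state[1], dtype=float).copy()
        if S_E0.shape != (n,) or S_I0.shape != (n,):
            raise ValueError("initial state dimension mismatch")
    if k.sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        noise = rng.standard_normal((n_steps, n, 2))
    else:
        noise = np.zeros((1, n, 2))
    S_E_out = np.empty((n, n_samples))
    S_I_out = np.empty((n, n_samples))
    status, n_clipped = _integrate(
        np.ascontiguousarray(W),
        p.G,
        p.J_NMDA,
        p.w_plus,
        p.J_i,
        k.a_E,
        k.b_E,
        k.d_E,
        k.a_I,
        k.b_I,
        k.d_I,
        k.tau_E,
        k.tau_I,
        k.gamma_k,
        k.I_0,
        k.W_E,
        k.W_I,
        k.lambda_FFI,
        k.sigma,
        cfg.dt,
        n_steps,
        rec_start,
        cfg.record_every,
        S_E0,
        S_I0,
        noise,
        S_E_out,
        S_I_out,
    )
    if status < 0:
        t_bad = -status * cfg.dt
        raise FloatingPointError(f"integration diverged at t = {t_bad:.3f} s")
    times = cfg.transient + cfg.dt * cfg.record_every * np.arange(n_samples)
    return NeuralTrajectory(
        times=times,
        S_E_series=S_E_out[:, :status],
        S_I_series=S_I_out[:, :status],
        n_clipped=int(n_clipped),
    )


def write_trajectory_tsv(
    traj: NeuralTrajectory,
    path,
    p: FitParams | None = None,
    k: NeuralMassConstants | None = None,
    cfg: SimConfig | None = None,
) -> None:
    """Write a trajectory as TSV (time + one column per node and population)
    with a JSON sidecar carrying the parameters, constants, seed and step."""
    import dataclasses
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    n = traj.n_nodes
    data = {"time_s": traj.times}
    for i in range(n):
        data[f"S_E_{i}"] = traj.S_E_series[i]
    for i in range(n):
        data[f"S_I_{i}"] = traj.S_I_series[i]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    sidecar = {
        "params": p.as_dict() if p else None,
        "constants": dataclasses.asdict(k) if k else None,
        "seed": cfg.seed if cfg else None,
        "dt": cfg.dt if cfg else None,
        "n_clipped": traj.n_clipped,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_trajectory_tsv(path) -> NeuralTrajectory:
    """Read back a trajectory written by :func:`write_trajectory_tsv`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    se_cols = [c for c in df.columns if c.startswith("S_E_")]
    si_cols = [c for c in df.columns if c.startswith("S_I_")]
    return NeuralTrajectory(
        times=df["time_s"].to_numpy(),
        S_E_series=df[se_cols].to_numpy().T,
        S_I_series=df[si_cols].to_numpy().T,
    )


def single_node_fixed_point(
    p: FitParams,
    k: NeuralMassConstants | None = None,
    guess: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Algebraic fixed point (S_E*, S_I*) of one isolated, noise-free node.

    Solves the coupled steady-state system with a numerical root finder;
    used for validating the time integration against an independent route.
    The system can be bistable; ``guess`` selects the root reached from a
    particular starting point (default: several spread starts, best residual
    wins).
    """
    k = k or NeuralMassConstants()
    C0 = np.zeros((1, 1))

    def residual(s: np.ndarray) -> np.ndarray:
        S_E = np.array([min(max(s[0], 0.0), 1.0)])
        S_I = np.array([min(max(s[1], 0.0), 1.0)])
        I_E, I_I = node_currents(S_E, S_I, p, k, C0)
        r_E = transfer_rate(I_E[0], k.a_E, k.b_E, k.d_E)
        r_I = transfer_rate(I_I[0], k.a_I, k.b_I, k.d_I)
        return np.array(
            [
                -S_E[0] / k.tau_E + (1.0 - S_E[0]) * k.gamma_k * r_E,
                -S_I[0] / k.tau_I + r_I,
            ]
        )

    starts = (
        (guess,) if guess is not None else ((0.1, 0.05), (0.3, 0.1), (0.05, 0.02), (0.6, 0.3))
    )
    best = None
    for start in starts:
        sol = optimize.root(residual, np.array(start), method="hybr", tol=1e-13)
        if sol.success:
            res = float(np.max(np.abs(residual(sol.x))))
            if best is None or res < best[1]:
                best = (sol.x, res)
    if best is None:
        raise RuntimeError("fixed-point search failed to converge")
    S_E, S_I = (float(np.clip(v, 0.0, 1.0)) for v in best[0])
    return S_E, S_I
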