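"""Balloon-Windkessel hemodynamic forward model and TR resampling.

Per node, the vasodilatory signal s, inflow f, venous volume v and
deoxyhemoglobin content q evolve as

    ds/dt    = z - kappa*s - gamma_f*(f - 1)
    df/dt    = s
    tau*dv/dt = f - v**(1/alpha)
    tau*dq/dt = f*(1 - (1-rho)**(1/f))/rho - v**(1/alpha - 1)*q

driven by the excitatory gating z = S_E, with the BOLD readout

    y = V0*(k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)).

The classical coefficient set k1 = 7*rho, k2 = 2, k3 = 2*rho - 0.2 is used.
Resting initial conditions (s=0, f=v=q=1) make zero input an exact fixed
point with y identically zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import optimize

from netvb.rww import NeuralTrajectory

__all__ = [
    "HemodynamicConstants",
    "BOLDSeries",
    "bold_forward",
    "bold_steady_state",
    "resample_to_tr",
]


@dataclass(frozen=True)
class HemodynamicConstants:
    """Balloon-Windkessel constants (rates in 1/s, tau_h in s)."""

    kappa: float = 0.65
    gamma_f: float = 0.41
    tau_h: float = 0.98
    alpha: float = 0.32
    rho: float = 0.34
    V0: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("kappa", "gamma_f", "tau_h", "rho", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k1(self) -> float:
        return 7.0 * self.rho

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.rho - 0.2


@dataclass(frozen=True)
class BOLDSeries:
    """Region-by-time BOLD matrix sampled at interval ``TR`` (s)."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n_nodes, n_volumes)
    TR: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if v.ndim != 2 or v.shape[0] != len(self.labels):
            raise ValueError("values must be a node x time matrix matching labels")
        if v.shape[1] < 2:
            raise ValueError("need at least two time points")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite BOLD values")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_volumes * self.TR


@njit(cache=True)
def _balloon(z, dt, kappa, gamma_f, tau_h, alpha, rho, V0, k1, k2, k3, f0, y):
    n, T = z.shape
    inv_alpha = 1.0 / alpha
    one_m_rho = 1.0 - rho
    for i in range(n):
        s = 0.0
        f = f0[i]
        if f == 1.0:
            v = 1.0
            q = 1.0
        else:
            v = f ** alpha
            q = v ** (1.0 - inv_alpha) * f * (1.0 - one_m_rho ** (1.0 / f)) / rho
        for t in range(T):
            ds = z[i, t] - kappa * s - gamma_f * (f - 1.0)
            df = s
            dv = (f - v**inv_alpha) / tau_h
            E_f = 1.0 - one_m_rho ** (1.0 / f)
            dq = (f * E_f / rho - v ** (inv_alpha - 1.0) * q) / tau_h
            s += dt * ds
            f += dt * df
            v += dt * dv
            q += dt * dq
            if f < 1e-6:
                f = 1e-6
            if v < 1e-6:
                v = 1e-6
            if q < 1e-6:
                q = 1e-6
            y[i, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
            if not (math.isfinite(v) and math.isfinite(q)):
                return -(t + 1)
    return T


def bold_forward(
    traj: NeuralTrajectory | np.ndarray,
    h: HemodynamicConstants | None = None,
    dt: float = 1e-3,
    init: str = "rest",
) -> np.ndarray:
    """Integrate the balloon model node-by-node, driven by ``z = S_E``.

    Accepts either a :class:`NeuralTrajectory` (its excitatory gating is the
    drive) or a raw node-by-time drive matrix.  Euler integration at the
    neural step ``dt``; deterministic.  Returns BOLD at neural resolution.

    ``init="rest"`` starts from the resting state (s=0, f=v=q=1).
    ``init="steady"`` starts each node at the algebraic steady state of its
    initial drive value, which suppresses the shared hemodynamic onset
    transient that otherwise dominates correlation observables when the
    neural drive has a non-zero baseline; the model-fitting chain uses this.
    """
    h = h or HemodynamicConstants()
    z = traj.S_E_series if isinstance(traj, NeuralTrajectory) else np.asarray(traj)
    z = np.ascontiguousarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite drive")
    if init == "rest":
        f0 = np.ones(z.shape[0])
    elif init == "steady":
        f0 = 1.0 + z[:, 0] / h.gamma_f
    else:
        raise ValueError(f"unknown init mode {init!r}")
    y = np.empty_like(z)
    status = _balloon(
        z,
        dt,
        h.kappa,
        h.gamma_f,
        h.tau_h,
        h.alpha,
        h.rho,
        h.V0,
        h.k1,
        h.k2,
        h.k3,
        f0,
        y,
    )
    if status < 0:
        raise FloatingPointError(
            f"hemodynamic integration diverged at t = {-status * dt:.3f} s"
        )
    return y


def bold_steady_state(z: float, h: HemodynamicConstants | None = None) -> float:
    """BOLD level for a constant drive ``z``, from the algebraic steady state.

    Solves ``s = 0``, ``f = 1 + z/gamma_f``, ``v = f**alpha`` and the flow
    balance for ``q`` directly; an independent check on the time integration.
    """
    h = h or HemodynamicConstants()
    f = 1.0 + z / h.gamma_f
    v = f**h.alpha
    E_f = 1.0 - (1.0 - h.rho) ** (1.0 / f)
    q = v ** (1.0 - 1.0 / h.alpha) * f * E_f / h.rho
    return h.V0 * (h.k1 * (1.0 - q) + h.k2 * (1.0 - q / v) + h.k3 * (1.0 - v))


def resample_to_tr(
    y: np.ndarray,
    TR: float,
    dt: float,
    duration: float | None = None,
    labels: tuple[str, ...] | None = None,
) -> BOLDSeries:
    """Bin-average a dt-resolution signal to scanner TR.

    ``TR`` must be an integral multiple of ``dt``; each output volume is the
    mean of the dt samples inside its TR bin.  ``duration`` defaults to the
    full input span; output has ``floor(duration/TR)`` volumes.
    """
    y = np.asarray(y, dtype=float)
    ratio = TR / dt
    if abs(ratio - round(ratio)) > 1e-9 * ratio:
        raise ValueError(f"TR {TR} not an integral multiple of dt {dt}")
    per = int(round(ratio))
    if duration is None:
        duration = y.shape[1] * dt
    n_vol = int(math.floor(duration / TR + 1e-9))
    needed = n_vol * per
    if needed > y.shape[1]:
        raise ValueError("series shorter than requested duration")
    binned = y[:, :needed].reshape(y.shape[0], n_vol, per).mean(axis=2)
    if labels is None:
        labels = tuple(f"node{i}" for i in range(y.shape[0]))
    return BOLDSeries(labels=labels, values=binned, TR=TR)


def read_bold_tsv(path, TR: float | None = None) -> BOLDSeries:
    """Read a BOLD TSV (first column time in s, one column per region).

    ``TR`` is inferred from the time column when not given.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if TR is None:
        TR = float(np.median(np.diff(times)))
    labels = tuple(str(c) for c in df.columns[1:])
    return BOLDSeries(labels=labels, values=df.iloc[:, 1:].to_numpy(float).T, TR=TR)


def write_bold_tsv(b: BOLDSeries, path) -> None:
    """Write a BOLD TSV with a leading time column."""
    import pandas as pd

    times = np.arange(b.n_volumes) * b.TR
    df = pd.DataFrame(b.values.T, columns=list(b.labels))
    df.insert(0, "time_s", times)
    df.to_csv(path, sep="\t", index=False)
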