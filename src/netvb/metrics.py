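"""Static FC, dynamic FCD, and the model-fit observables.

Static functional connectivity is the pairwise Pearson correlation of
regional BOLD time courses, Fisher z-transformed and thresholded (z below
0.1206 set to zero).  Functional connectivity dynamics (FCD) correlates the
vectorized upper triangles of sliding-window FC patterns into a
window-by-window matrix.  Model fit combines the Pearson similarity of
static FC matrices with the two-sample Kolmogorov-Smirnov distance between
FCD entry distributions into the scalar cost (1 - PCC) + KS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from netvb.hemodynamics import BOLDSeries

__all__ = [
    "FCMatrix",
    "FCDMatrix",
    "FitMetrics",
    "static_fc",
    "sliding_fcd",
    "fc_similarity",
    "fcd_distance",
    "fit_cost",
    "resolve_window",
]

DEFAULT_FC_THRESHOLD = 0.1206
DEFAULT_Z_CAP = 18.0
DEFAULT_WINDOW_S = 40.0

#: Window length presets in volumes for a 200-volume, TR 2.4 s acquisition.
#: ``"40s-nominal"`` rounds the 40 s window to the nearest volume count;
#: ``"paper-count"`` is the length that yields 178 windows from 200 volumes.
WINDOW_PRESETS = {"40s-nominal": None, "paper-count": 23}


@dataclass(frozen=True)
class FCMatrix:
    """Thresholded Fisher-z static FC; diagonal stored as zero."""

    labels: tuple[str, ...]
    z_values: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        object.__setattr__(self, "z_values", z)
        n = len(self.labels)
        if z.shape != (n, n):
            raise ValueError("z matrix does not match labels")
        if np.max(np.abs(z - z.T)) > 1e-12:
            raise ValueError("FC matrix not symmetric")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.z_values[iu]


@dataclass(frozen=True)
class FCDMatrix:
    """Window-by-window correlation of sliding-window FC patterns."""

    window_starts: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        m = len(self.window_starts)
        if v.shape != (m, m):
            raise ValueError("FCD matrix does not match window count")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_windows, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class FitMetrics:
    """Similarity of static FC (pcc), distance of FCD distributions (ks),
    and the combined cost ``(1 - pcc) + ks``."""

    pcc: float
    ks: float

    @property
    def cost(self) -> float:
        return (1.0 - self.pcc) + self.ks

    def as_dict(self) -> dict[str, float]:
        return {"pcc": self.pcc, "ks": self.ks, "cost": self.cost}


def resolve_window(window_s: float, TR: float, preset: str = "40s-nominal") -> int:
    """Window length in volumes: nearest-volume rounding of ``window_s/TR``,
    or the fixed ``paper-count`` preset (23 volumes)."""
    fixed = WINDOW_PRESETS.get(preset, None)
    if preset not in WINDOW_PRESETS:
        raise ValueError(f"unknown window preset {preset!r}")
    if fixed is not None:
        return fixed
    w = int(round(window_s / TR))
    if w < 2:
        raise ValueError("window shorter than two volumes")
    return w


def static_fc(
    b: BOLDSeries,
    threshold: float = DEFAULT_FC_THRESHOLD,
    z_cap: float = DEFAULT_Z_CAP,
    absolute: bool = False,
) -> FCMatrix:
    """Pairwise Pearson correlation -> Fisher z (capped) -> threshold.

    Entries whose z (or |z| with ``absolute``) falls below ``threshold`` are
    set exactly to zero; the diagonal is stored as zero by convention.
    """
    x = b.values
    if x.shape[1] < 3:
        raise ValueError("need at least three time points")
    sd = x.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        names = [b.labels[i] for i in bad]
        raise ValueError(f"constant time series for node(s) {names}")
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -0.9999999999999999, 0.9999999999999999))
    z = np.clip(z, -z_cap, z_cap)
    keep = np.abs(z) >= threshold if absolute else z >= threshold
    z = np.where(keep, z, 0.0)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return FCMatrix(labels=b.labels, z_values=z)


def _window_fc_vectors(x: np.ndarray, w: int) -> np.ndarray:
    """Upper-triangular FC vector of every length-w sliding window (step 1)."""
    n, T = x.shape
    iu = np.triu_indices(n, k=1)
    m = T - w + 1
    out = np.empty((m, iu[0].size))
    for s in range(m):
        r = np.corrcoef(x[:, s : s + w])
        out[s] = r[iu]
    return out


def sliding_fcd(
    b: BOLDSeries,
    window_s: float = DEFAULT_WINDOW_S,
    preset: str = "40s-nominal",
) -> FCDMatrix:
    """Sliding-window FCD matrix, window shifted by one repetition time.

    Each window's FC is vectorized over its upper triangle, and entry (m, n)
    of the result is the Pearson correlation between the vectors of windows
    m and n; symmetric with unit diagonal.
    """
    w = resolve_window(window_s, b.TR, preset)
    if b.n_volumes < w:
        raise ValueError(f"series ({b.n_volumes} volumes) shorter than window ({w})")
    vecs = _window_fc_vectors(b.values, w)
    fcd = np.corrcoef(vecs)
    fcd = np.clip(fcd, -1.0, 1.0)
    np.fill_diagonal(fcd, 1.0)
    fcd = (fcd + fcd.T) / 2.0
    starts = np.arange(vecs.shape[0]) * b.TR
    return FCDMatrix(window_starts=starts, values=fcd)


def fc_similarity(exp: FCMatrix, sim: FCMatrix) -> float:
    """Pearson correlation of the upper-triangular FC entries."""
    if exp.labels != sim.labels:
        raise ValueError("FC label mismatch")
    a = exp.upper_triangle()
    c = sim.upper_triangle()
    if a.std() == 0 or c.std() == 0:
        raise ValueError("zero-variance FC triangle")
    return float(np.corrcoef(a, c)[0, 1])


def fcd_distance(exp: FCDMatrix, sim: FCDMatrix) -> float:
    """Two-sample KS statistic between the FCD upper-triangle distributions.

    The matrices may have different window counts.
    """
    for m in (exp, sim):
        if m.n_windows < 2:
            raise ValueError("need at least two windows")
    return float(stats.ks_2samp(exp.upper_triangle(), sim.upper_triangle()).statistic)


def write_fc_tsv(fc: FCMatrix, path, sidecar: dict | None = None) -> None:
    """Write a labeled FC matrix as TSV with an optional JSON sidecar."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    pd.DataFrame(fc.z_values, index=list(fc.labels), columns=list(fc.labels)).to_csv(
        path, sep="\t"
    )
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_fc_tsv(path) -> FCMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return FCMatrix(
        labels=tuple(str(x) for x in df.index), z_values=df.to_numpy(float)
    )


def write_fcd_tsv(fcd: FCDMatrix, path, sidecar: dict | None = None) -> None:
    """Write a window-by-window FCD matrix as TSV (window starts as labels)."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    labels = [f"{t:.6g}" for t in fcd.window_starts]
    pd.DataFrame(fcd.values, index=labels, columns=labels).to_csv(path, sep="\t")
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_fcd_tsv(path) -> FCDMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return FCDMatrix(
        window_starts=np.array([float(x) for x in df.index]),
        values=df.to_numpy(float),
    )


def fit_cost(pcc: float, ks: float) -> FitMetrics:
    """Combine similarity and distance into the scalar cost ``(1-pcc)+ks``."""
    if not -1.0 <= pcc <= 1.0:
        raise ValueError(f"pcc {pcc} outside [-1, 1]")
    if not 0.0 <= ks <= 1.0:
        raise ValueError(f"ks {ks} outside [0, 1]")
    return FitMetrics(pcc=float(pcc), ks=float(ks))
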