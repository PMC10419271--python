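"""Structural connectome I/O, validation, normalization, and network extraction.

A connectome is a labeled, symmetric, non-negative square matrix whose edges
are normalized streamline counts from tractography.  Resting-state networks
(DMN, FPN, LN, AN, VN, SMN) are defined as ordered subsets of atlas region
labels; their sub-connectomes are extracted by simple label subsetting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class NetworkDefinition:
    """A named resting-state network given as an ordered list of region labels."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"network {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"network {self.name!r} has duplicate members")


@dataclass(frozen=True)
class Connectome:
    """Labeled symmetric non-negative weight matrix with zero diagonal."""

    labels: tuple[str, ...]
    weights: np.ndarray  # (n, n) float64

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = len(self.labels)
        if w.shape != (n, n):
            raise ValueError(f"weight matrix {w.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate region labels")
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite weights")
        if np.any(w < 0):
            raise ValueError("negative edge weight")
        if np.max(np.abs(w - w.T)) > SYMMETRY_TOL:
            raise ValueError("weight matrix not symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("non-zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


def _detect_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0]
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_connectome(path: str | Path, strict: bool = False) -> Connectome:
    """Read a labeled delimited-text connectome (TSV or CSV).

    First row and first column carry region labels.  With ``strict`` off,
    asymmetries are repaired by averaging ``(C + C.T) / 2`` and the diagonal
    is zeroed; each repair is logged.  With ``strict`` on, any deviation is
    an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_delimiter(path), index_col=0)
    labels = tuple(str(x).strip() for x in df.index)
    col_labels = tuple(str(x).strip() for x in df.columns)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"non-square matrix {df.shape} in {path}")
    if labels != col_labels:
        raise ValueError(f"row labels differ from column labels in {path}")
    w = df.to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError(f"negative entry in {path}")
    asym = float(np.max(np.abs(w - w.T))) if w.size else 0.0
    if asym > SYMMETRY_TOL:
        if strict:
            raise ValueError(f"asymmetry {asym:.3g} beyond tolerance in {path}")
        logger.warning("symmetrizing %s (max asymmetry %.3g)", path, asym)
        w = (w + w.T) / 2.0
    if np.any(np.diag(w) != 0):
        if strict:
            raise ValueError(f"non-zero diagonal in {path}")
        logger.warning("zeroing diagonal of %s", path)
        np.fill_diagonal(w, 0.0)
    return Connectome(labels=labels, weights=w)


def write_connectome(c: Connectome, path: str | Path) -> None:
    """Write a connectome as labeled TSV (header row + label column)."""
    pd.DataFrame(c.weights, index=list(c.labels), columns=list(c.labels)).to_csv(
        path, sep="\t"
    )


def read_network_definitions(path: str | Path) -> dict[str, NetworkDefinition]:
    """Read a two-column (network_name, region_label) membership table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_delimiter(path))
    if df.shape[1] < 2:
        raise ValueError(f"membership table needs two columns in {path}")
    name_col, member_col = df.columns[:2]
    out: dict[str, NetworkDefinition] = {}
    for name, grp in df.groupby(name_col, sort=False):
        members = tuple(str(x).strip() for x in grp[member_col])
        out[str(name)] = NetworkDefinition(name=str(name), members=members)
    return out


def normalize_weights(c: Connectome, mode: str = "max-one") -> Connectome:
    """Rescale edge weights; ``max-one`` divides by the maximum entry,
    ``unit-mean`` by the mean of positive entries.  Idempotent in both modes.
    """
    w = c.weights
    if not np.any(w > 0):
        raise ValueError("all-zero connectome cannot be normalized")
    if mode == "max-one":
        scale = float(np.max(w))
    elif mode == "unit-mean":
        scale = float(np.mean(w[w > 0]))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Connectome(labels=c.labels, weights=w / scale)


def extract_network(c: Connectome, net: NetworkDefinition) -> Connectome:
    """Extract the sub-connectome over ``net.members`` in the given order."""
    unknown = [m for m in net.members if m not in c.labels]
    if unknown:
        raise KeyError(f"unknown region label(s) {unknown} for network {net.name!r}")
    idx = np.array([c.labels.index(m) for m in net.members])
    return Connectome(labels=net.members, weights=c.weights[np.ix_(idx, idx)])


def illustrative_network_map(labels: Sequence[str]) -> dict[str, NetworkDefinition]:
    """Partition an atlas into six equally sized illustrative networks.

    The true functional-atlas membership mapping is dataset-specific; this
    helper only provides a deterministic placeholder partition so pipelines
    can run end-to-end on synthetic atlases.
    """
    names = ("DMN", "FPN", "LN", "AN", "VN", "SMN")
    chunks = np.array_split(np.asarray(labels, dtype=object), 6)
    return {
        nm: NetworkDefinition(name=nm, members=tuple(str(x) for x in ch))
        for nm, ch in zip(names, chunks)
    }
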