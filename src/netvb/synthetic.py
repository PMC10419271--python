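"""Synthetic connectomes, BOLD, and cohorts with known ground truth.

The generators emulate the statistical structure the analysis pipeline
assumes, so every stage can be exercised and validated without any imaging
data: heavy-tailed symmetric connectomes (log-normal weights, as produced
by streamline tractography), BOLD series generated by the model itself at
known parameters plus measurement noise, and cohorts whose cognitive domain
scores are linear in designated network parameters with a configurable
explained-variance band and whose group offsets follow the sign patterns
reported for neurodegenerative groups (e.g., in AD: global coupling raised
in DMN and lowered in LN, inhibition raised in AN and lowered in LN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from netvb.cohort import DOMAINS, SubjectRecord
from netvb.connectome import Connectome
from netvb.hemodynamics import (
    BOLDSeries,
    HemodynamicConstants,
    bold_forward,
    resample_to_tr,
)
from netvb.inversion import ObservableConfig, _initial_state
from netvb.rww import FitParams, NeuralMassConstants, SimConfig, simulate_network

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "gen_connectome",
    "gen_experimental_bold",
    "gen_cohort",
    "DEFAULT_OFFSETS",
    "DEFAULT_BASE",
]

NETWORKS = ("DMN", "FPN", "LN", "AN", "VN", "SMN")

#: Baseline parameter values shared by all networks of a healthy subject.
DEFAULT_BASE = {"G": 1.5, "J_NMDA": 0.15, "w_plus": 1.4, "J_i": 1.0}

#: Additive group offsets, as fractions of the base value, following the
#: reported direction-of-change patterns per group and network
#: (positive = raised relative to healthy controls).
DEFAULT_OFFSETS: dict[tuple[str, str, str], float] = {
    # AD
    ("AD", "DMN", "G"): +0.25,
    ("AD", "LN", "G"): -0.25,
    ("AD", "DMN", "J_NMDA"): +0.25,
    ("AD", "SMN", "J_NMDA"): -0.25,
    ("AD", "DMN", "w_plus"): -0.25,
    ("AD", "SMN", "w_plus"): +0.25,
    ("AD", "AN", "J_i"): +0.25,
    ("AD", "LN", "J_i"): -0.25,
    # FTD
    ("FTD", "DMN", "G"): +0.25,
    ("FTD", "LN", "G"): -0.25,
    ("FTD", "FPN", "G"): -0.25,
    ("FTD", "SMN", "J_NMDA"): -0.25,
    ("FTD", "VN", "J_NMDA"): -0.25,
    ("FTD", "FPN", "J_NMDA"): +0.25,
    ("FTD", "SMN", "w_plus"): +0.25,
    ("FTD", "FPN", "w_plus"): -0.25,
    ("FTD", "DMN", "J_i"): +0.25,
    ("FTD", "FPN", "J_i"): -0.25,
}

#: Default single-predictor loadings of each cognitive domain on a network
#: parameter feature (mirroring the kind of network-domain associations the
#: regressions are meant to detect).
DEFAULT_LOADINGS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "memory": (("LN_J_i",), (-1.0,)),
    "language_fluency": (("DMN_G",), (-1.0,)),
    "visuo_constructional": (("SMN_J_i",), (-1.0,)),
    "attention": (("AN_J_i",), (-1.0,)),
    "executive": (("FPN_J_NMDA",), (-1.0,)),
}


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth recipe for a synthetic cohort.

    ``true_offsets`` maps (group, network, parameter) to an additive offset
    expressed as a fraction of the base value.  ``score_loadings`` maps each
    cognitive domain to (feature names, coefficients on the standardized
    features); the score noise SD is calibrated internally so the population
    explained variance equals ``target_r2`` (the configured band midpoint).
    ``subject_noise_frac`` is the between-subject SD as a fraction of base.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 20, "AD": 20, "FTD": 20}
    )
    networks: tuple[str, ...] = NETWORKS
    base: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE))
    true_offsets: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS)
    )
    score_loadings: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS)
    )
    target_r2: float = 0.30
    subject_noise_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 3:
                raise ValueError(f"group {g!r} needs at least 3 subjects")
        if not 0 < self.target_r2 < 1:
            raise ValueError("target_r2 must lie in (0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    params: dict[str, dict[str, FitParams]]  # subject id -> network -> truth
    profile: dict[str, str]  # subject id -> planted group/profile label
    seed: int


def gen_connectome(
    n_nodes: int,
    density: float = 1.0,
    seed: int = 0,
    n_modules: int = 1,
    inter_scale: float = 0.15,
) -> Connectome:
    """Random symmetric connectome with log-normal weights, max-one normalized.

    Edges are kept with probability ``density``; disconnected draws are
    rejected and regenerated (up to 50 attempts).  With ``n_modules > 1``
    the nodes are split into equal contiguous modules and between-module
    weights are scaled down by ``inter_scale``, giving the community
    structure typical of anatomical connectomes (within-module integration,
    weaker long-range bridges).
    """
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if n_modules < 1 or n_modules > n_nodes:
        raise ValueError("n_modules must lie in [1, n_nodes]")
    rng = np.random.default_rng(seed)
    labels = tuple(f"R{i:03d}" for i in range(n_nodes))
    module = np.array_split(np.arange(n_nodes), n_modules)
    membership = np.empty(n_nodes, dtype=int)
    for m, idx in enumerate(module):
        membership[idx] = m
    for _ in range(50):
        w = rng.lognormal(mean=0.0, sigma=1.0, size=(n_nodes, n_nodes))
        mask = rng.random((n_nodes, n_nodes)) < density
        w = w * mask
        if n_modules > 1:
            between = membership[:, None] != membership[None, :]
            w = np.where(between, inter_scale * w, w)
        w = np.triu(w, k=1)
        w = w + w.T
        n_comp, _ = connected_components(w > 0, directed=False)
        if n_comp == 1:
            return Connectome(labels=labels, weights=w / w.max())
    raise RuntimeError(f"could not draw a connected graph at density {density}")


def gen_experimental_bold(
    C: Connectome,
    true_params: FitParams,
    cfg: SimConfig,
    obs_noise_sd: float = 0.0,
    k: NeuralMassConstants | None = None,
    h: HemodynamicConstants | None = None,
    obs: ObservableConfig | None = None,
) -> tuple[BOLDSeries, dict]:
    """Surrogate experimental BOLD: the forward chain at known parameters
    plus independent Gaussian observation noise.

    Uses the same seed-derived initial-state convention as the inversion's
    forward evaluations, so a zero-noise self-target reproduces exactly.
    Returns the series and a sidecar dict recording the ground truth.
    """
    k = k or NeuralMassConstants()
    obs = obs or ObservableConfig()
    init = _initial_state(cfg.seed, C.n_nodes)
    traj = simulate_network(C, true_params, k, cfg, initial_state=init)
    y = bold_forward(traj, h, dt=cfg.dt * cfg.record_every, init="steady")
    bold = resample_to_tr(
        y,
        obs.TR,
        cfg.dt * cfg.record_every,
        duration=cfg.duration - cfg.transient,
        labels=C.labels,
    )
    if obs_noise_sd > 0:
        noise_rng = np.random.default_rng([int(cfg.seed), 0x0B5])
        values = bold.values + noise_rng.normal(0.0, obs_noise_sd, bold.values.shape)
        bold = BOLDSeries(labels=bold.labels, values=values, TR=bold.TR)
    sidecar = {
        "true_params": true_params.as_dict(),
        "seed": cfg.seed,
        "obs_noise_sd": obs_noise_sd,
        "TR": obs.TR,
        "n_volumes": bold.n_volumes,
    }
    return bold, sidecar


def gen_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], GroundTruth]:
    """Draw a cohort with planted parameter offsets and score loadings.

    Per subject, each (network, parameter) value is the base value, plus the
    group offset, plus Gaussian subject noise (SD = ``subject_noise_frac`` x
    base), truncated at zero.  Domain scores are linear in the standardized
    designated features with noise calibrated to the target explained
    variance, then clipped to [0, 4].  MMSE decreases with the subject's
    summed pathological offset. Pure function of (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    groups = sorted(spec.n_per_group)
    subjects: list[dict] = []
    truth_params: dict[str, dict[str, FitParams]] = {}
    profile: dict[str, str] = {}
    for g in groups:
        for i in range(spec.n_per_group[g]):
            sid = f"{g}{i:03d}"
            params: dict[str, FitParams] = {}
            vals: dict[str, float] = {}
            for net in spec.networks:
                kw = {}
                for pname, base in spec.base.items():
                    off = spec.true_offsets.get((g, net, pname), 0.0) * base
                    noise = rng.normal(0.0, spec.subject_noise_frac * base)
                    kw[pname] = max(base + off + noise, 0.0)
                params[net] = FitParams(**kw)
                for pname, v in kw.items():
                    vals[f"{net}_{pname}"] = v
            age = float(np.clip(rng.normal(70.0, 8.0), 40.0, 95.0))
            sex = "F" if rng.random() < 0.5 else "M"
            subjects.append(
                {"id": sid, "group": g, "age": age, "sex": sex, "vals": vals}
            )
            truth_params[sid] = params
            profile[sid] = g

    # calibrated domain scores: R^2 = var(signal)/(var(signal)+sd^2)
    all_vals = {
        f: np.array([s["vals"][f] for s in subjects])
        for f in subjects[0]["vals"]
    }
    scores: dict[str, np.ndarray] = {}
    for domain in DOMAINS:
        feats, coefs = spec.score_loadings.get(domain, ((), ()))
        signal = np.zeros(len(subjects))
        for f, c in zip(feats, coefs):
            x = all_vals[f]
            sd = x.std(ddof=0)
            signal += c * (x - x.mean()) / (sd if sd > 0 else 1.0)
        sig_sd = signal.std(ddof=0)
        noise_sd = (
            sig_sd * np.sqrt((1.0 - spec.target_r2) / spec.target_r2)
            if sig_sd > 0
            else 1.0
        )
        raw = 2.0 + signal + rng.normal(0.0, noise_sd, len(subjects))
        scores[domain] = np.clip(raw, 0.0, 4.0)

    # MMSE: healthy ceiling minus standardized pathological burden
    burden = np.array(
        [
            np.mean(
                [
                    abs(spec.true_offsets.get((s["group"], net, p), 0.0))
                    for net in spec.networks
                    for p in spec.base
                ]
            )
            for s in subjects
        ]
    )
    b_sd = burden.std(ddof=0)
    burden_z = (burden - burden.mean()) / b_sd if b_sd > 0 else burden * 0.0
    mmse = np.clip(29.0 - 6.0 * burden_z + rng.normal(0.0, 1.0, len(subjects)), 0, 30)

    cohort: list[SubjectRecord] = []
    for j, s in enumerate(subjects):
        cohort.append(
            SubjectRecord(
                id=s["id"],
                group=s["group"],
                phenotype=s["group"],
                age=s["age"],
                sex=s["sex"],
                mmse=float(mmse[j]),
                domain_scores={d: float(scores[d][j]) for d in DOMAINS},
                params=truth_params[s["id"]],
                therapy={
                    "antidepressant": bool(rng.random() < 0.2),
                    "anxiolytic": bool(rng.random() < 0.1),
                },
            )
        )
    return cohort, GroundTruth(params=truth_params, profile=profile, seed=spec.seed)
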