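"""Truth-known synthetic microcosm experiments.

Generates everything the analysis stages consume — binary affinity matrices,
overlap-dependent species-abundance dynamics, composite multi-probe Eh traces
and activity/decomposition endpoints — with the qualitative structure the
pipeline is meant to detect:

* substrate sharing is controlled by a Dirichlet popularity vector (lower
  concentration => heavier sharing => higher niche overlap and a saturating
  CMD-vs-richness curve);
* species abundances follow a mean-reverting share process in which a
  compensation term anti-couples overlapping species, so redundant consortia
  damp their aggregate fluctuation;
* each species carries a redox setpoint derived from its substrate profile
  (identical profiles => identical setpoints), and the community Eh is the
  abundance-weighted mixture of member setpoints plus an exponential
  incubation drift, partially probe-correlated perturbations and white
  observation noise;
* endpoints are linear in CMD with Gaussian noise, clipped at zero.

All randomness flows through named substreams of a single seed, so outputs
are byte-identical across runs for a given config.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import DomainError
from .niche_profiles import (
    AffinityMatrix,
    Consortium,
    ConsortiumDesign,
    build_design,
    community_metabolic_diversity,
    community_redundancy,
    design_to_json,
    mean_pairwise_overlap,
    niche_breadth,
    write_affinity_matrix,
)
from .wavelet_stability import EhSeries, write_eh_csv

__all__ = [
    "GeneratorConfig",
    "AbundancePaths",
    "SyntheticExperiment",
    "generate_affinity_matrix",
    "species_setpoints",
    "simulate_abundances",
    "simulate_eh",
    "simulate_endpoints",
    "generate_experiment",
    "write_experiment",
]

DAY = 86400.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic experiment.

    ``fluctuation_sd`` is the per-step standard deviation of abundance-share
    shocks (dimensionless; internally scaled by 1/sqrt(richness)); its mV
    footprint on Eh arises through the setpoint mixture.
    ``substrate_popularity_concentration`` is the symmetric Dirichlet shape
    of the shared substrate popularity weights; ``None`` means uniform
    weights (the concentration -> infinity limit).
    """

    n_species: int = 12
    n_substrates: int = 95
    substrate_popularity_concentration: float | None = 20.0
    breadth_range: tuple[int, int] = (65, 75)
    redox_setpoint_range: tuple[float, float] = (-250.0, 150.0)
    fluctuation_sd: float = 0.15
    compensation_strength: float = 0.7
    mean_reversion: float = 0.05
    observation_noise_sd: float = 1.5
    probe_noise_sd: float = 2.0
    probe_decorrelation: float = 0.5
    drift_amplitude_mV: float = 20.0
    drift_tau_s: float = 1.5 * DAY
    dt: float = 900.0
    duration: float = 13 * DAY
    n_probes: int = 8
    etsa_slope: float = 1.6
    doc_slope: float = 4.0
    endpoint_noise_sd: float = 12.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.breadth_range
        if not (0 <= lo <= hi):
            raise DomainError(f"invalid breadth_range {self.breadth_range}")
        if hi > self.n_substrates:
            raise DomainError(
                f"breadth_range upper bound {hi} exceeds n_substrates {self.n_substrates}"
            )
        for name in ("fluctuation_sd", "observation_noise_sd", "probe_noise_sd",
                     "endpoint_noise_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not 0.0 <= self.compensation_strength <= 1.0:
            raise DomainError("compensation_strength must be in [0, 1]")
        if not 0.0 <= self.probe_decorrelation <= 1.0:
            raise DomainError("probe_decorrelation must be in [0, 1]")
        if self.duration / self.dt < 16:
            raise DomainError("duration/dt must be >= 16 samples")
        if self.n_probes < 1:
            raise DomainError("n_probes must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["breadth_range"] = list(d["breadth_range"])
        d["redox_setpoint_range"] = list(d["redox_setpoint_range"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        if "breadth_range" in d:
            d["breadth_range"] = tuple(d["breadth_range"])
        if "redox_setpoint_range" in d:
            d["redox_setpoint_range"] = tuple(d["redox_setpoint_range"])
        return cls(**d)


def generate_affinity_matrix(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> AffinityMatrix:
    """Draw a binary affinity matrix with shared substrate popularity.

    Each species draws its breadth uniformly from ``breadth_range`` and then
    samples that many substrates without replacement with probability
    proportional to a popularity weight vector shared by all species.
    """
    if rng is None:
        rng = substream(config.seed, "affinity")
    m = config.n_substrates
    conc = config.substrate_popularity_concentration
    if conc is None or math.isinf(conc):
        weights = np.full(m, 1.0 / m)
    else:
        if conc <= 0:
            raise DomainError("substrate_popularity_concentration must be positive")
        weights = rng.dirichlet(np.full(m, conc))
        weights = np.clip(weights, 1e-12, None)
        weights /= weights.sum()
    lo, hi = config.breadth_range
    species = tuple(f"sp{i + 1:02d}" for i in range(config.n_species))
    substrates = tuple(f"sub{j + 1:02d}" for j in range(m))
    cells = np.zeros((config.n_species, m), dtype=np.int8)
    for i in range(config.n_species):
        b = int(rng.integers(lo, hi + 1))
        if b > 0:
            chosen = rng.choice(m, size=b, replace=False, p=weights)
            cells[i, chosen] = 1
    return AffinityMatrix(species, substrates, cells)


def species_setpoints(
    matrix: AffinityMatrix,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Species redox setpoints (mV) derived from substrate profiles.

    Each substrate gets a latent redox weight in [0, 1]; a species' score is
    the breadth-standardized mean weight over its utilized substrates.  The
    pool's scores are then rank-spaced (ties share the average rank) and
    affinely mapped into ``redox_setpoint_range``, so metabolically identical
    species share a setpoint, high-overlap species get nearby ones, and
    distinct profiles are kept a bounded distance apart.  Zero-breadth
    species score 0 (range midpoint territory by rank).
    """
    if rng is None:
        rng = substream(config.seed, "setpoints")
    v = rng.uniform(0.0, 1.0, size=matrix.n_substrates)
    lo, hi = config.redox_setpoint_range
    scores = []
    for s in matrix.species_ids:
        row = matrix.row(s).astype(float)
        b = row.sum()
        # mean of b iid U(0,1) has sd 1/sqrt(12 b); standardize across breadths
        scores.append((float(row @ v / b) - 0.5) * math.sqrt(12.0 * b) if b > 0 else 0.0)
    scores_arr = np.asarray(scores)
    order = np.argsort(np.argsort(scores_arr, kind="stable"), kind="stable").astype(float)
    # average ranks for exact ties so identical profiles share a setpoint
    for val in np.unique(scores_arr):
        mask = scores_arr == val
        if mask.sum() > 1:
            order[mask] = order[mask].mean()
    frac = (order + 0.5) / len(scores_arr)
    return {
        s: lo + (hi - lo) * float(f) for s, f in zip(matrix.species_ids, frac)
    }


@dataclass(frozen=True)
class AbundancePaths:
    members: tuple[str, ...]
    shares: np.ndarray  # shape (n_steps, k), rows sum to 1

    def path(self, species: str) -> np.ndarray:
        return self.shares[:, self.members.index(species)]


def _overlap_matrix(matrix: AffinityMatrix, members: tuple[str, ...]) -> np.ndarray:
    k = len(members)
    rows = np.stack([matrix.row(m) for m in members]).astype(bool)
    J = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            union = np.logical_or(rows[i], rows[j]).sum()
            if union:
                J[i, j] = J[j, i] = np.logical_and(rows[i], rows[j]).sum() / union
    return J


def _niche_coverage(matrix: AffinityMatrix, members: tuple[str, ...]) -> np.ndarray:
    """Per species: fraction of its substrates also used by >= 1 partner."""
    rows = np.stack([matrix.row(m) for m in members]).astype(bool)
    k = len(members)
    cov = np.zeros(k)
    for i in range(k):
        b = rows[i].sum()
        if b and k > 1:
            others = np.logical_or.reduce(np.delete(rows, i, axis=0))
            cov[i] = np.logical_and(rows[i], others).sum() / b
    return cov


def simulate_abundances(
    consortium: Consortium,
    matrix: AffinityMatrix,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> AbundancePaths:
    """Mean-reverting share dynamics with overlap-proportional compensation.

    Per step each species receives an independent Gaussian shock of
    per-capita scale ``fluctuation_sd / k``.  Compensation redistributes each
    species' shock pairwise: every partner u absorbs a fraction
    ``compensation_strength * J(s, u)`` of species s's shock (metabolic slack
    taken up by niche-mates), so the shock retained by s is the product of
    the per-pair factors ``prod_u (1 - c J(s, u))`` — a species whose niche
    is fully covered by many partners is almost completely buffered, while a
    member of a disjoint consortium keeps its full shock.  Because total
    share is conserved exactly (shocks recentred, shares clipped at zero and
    renormalized), redundant pairs end up with anti-correlated realized
    paths and the community's composite metabolic signal steadies as overlap
    rises.
    """
    if rng is None:
        rng = substream(config.seed, "abundance", consortium.label)
    members = tuple(sorted(consortium.member_ids))
    k = len(members)
    n = config.n_samples
    baseline = 1.0 / k
    theta = config.mean_reversion
    sd = config.fluctuation_sd / k
    J = _overlap_matrix(matrix, members)
    c = config.compensation_strength
    damp = np.prod(1.0 - c * J, axis=1)  # J has zero diagonal

    shares = np.empty((n, k))
    x = np.full(k, baseline)
    shares[0] = x
    eta = rng.normal(0.0, sd, size=(n - 1, k)) if sd > 0 else np.zeros((n - 1, k))
    for t in range(1, n):
        e = damp * eta[t - 1]
        eps = e - e.mean()
        x = x + theta * (baseline - x) + eps
        np.clip(x, 0.0, None, out=x)
        total = x.sum()
        x = x / total if total > 0 else np.full(k, baseline)
        shares[t] = x
    return AbundancePaths(members, shares)


def simulate_eh(
    consortium: Consortium,
    abundances: AbundancePaths,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    setpoints: Mapping[str, float] | None = None,
    matrix: AffinityMatrix | None = None,
    microcosm_id: str = "M1",
) -> list[EhSeries]:
    """Composite Eh traces for every probe of one microcosm.

    Eh(t) = sum_s share_s(t) * setpoint_s + drift + probe perturbation + white
    noise.  The probe perturbation mixes a shared and a probe-specific smooth
    AR(1) stream according to ``probe_decorrelation`` (0 = all probes see the
    same perturbation, 1 = fully independent).
    """
    if rng is None:
        rng = substream(config.seed, "eh", microcosm_id)
    if setpoints is None:
        if matrix is not None:
            setpoints = species_setpoints(matrix, config)
        else:
            lo, hi = config.redox_setpoint_range
            setpoints = {m: float(rng.uniform(lo, hi)) for m in abundances.members}
    sp = np.array([setpoints[m] for m in abundances.members])
    n = abundances.shares.shape[0]
    t = np.arange(n) * config.dt

    composite = abundances.shares @ sp
    drift = config.drift_amplitude_mV * np.exp(-t / config.drift_tau_s)

    phi = 0.9  # AR(1) smoothness of probe perturbations
    innov_sd = config.probe_noise_sd * math.sqrt(1 - phi**2)

    def ar1() -> np.ndarray:
        if config.probe_noise_sd == 0:
            return np.zeros(n)
        z = np.empty(n)
        innov = rng.normal(0.0, innov_sd, size=n)
        z[0] = rng.normal(0.0, config.probe_noise_sd)
        for i in range(1, n):
            z[i] = phi * z[i - 1] + innov[i]
        return z

    rho = config.probe_decorrelation
    shared = ar1()
    out = []
    for p in range(config.n_probes):
        own = ar1()
        perturb = math.sqrt(1 - rho) * shared + math.sqrt(rho) * own
        white = (
            rng.normal(0.0, config.observation_noise_sd, size=n)
            if config.observation_noise_sd > 0
            else np.zeros(n)
        )
        out.append(EhSeries(microcosm_id, p, t, composite + drift + perturb + white))
    return out


def simulate_endpoints(
    design: ConsortiumDesign,
    matrix: AffinityMatrix,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """ETSA and DOC endpoints, linear in CMD with Gaussian noise, clipped at 0."""
    if rng is None:
        rng = substream(config.seed, "endpoints")
    rows = []
    for c in design.consortia:
        cmd = community_metabolic_diversity(matrix, c)
        for r in range(design.replicates_per_consortium):
            noise = rng.normal(0.0, config.endpoint_noise_sd, size=2)
            rows.append(
                {
                    "microcosm_id": f"{c.label}-r{r + 1}",
                    "consortium_label": c.label,
                    "level": c.level,
                    "richness": c.richness,
                    "cmd": cmd,
                    "etsa": max(0.0, config.etsa_slope * cmd + noise[0]),
                    "doc": max(0.0, config.doc_slope * cmd + noise[1]),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticExperiment:
    config: GeneratorConfig
    matrix: AffinityMatrix
    design: ConsortiumDesign
    eh: dict[str, list[EhSeries]]  # microcosm_id -> one series per probe
    endpoints: pd.DataFrame
    setpoints: dict[str, float]
    truth: dict = field(default_factory=dict)


def generate_experiment(config: GeneratorConfig) -> SyntheticExperiment:
    """Full synthetic experiment: matrix, nested design, Eh traces, endpoints."""
    if config.n_species != 12:
        raise DomainError("the default nested design requires exactly 12 species")
    matrix = generate_affinity_matrix(config)
    design = build_design(matrix.species_ids, config.replicates)
    setpoints = species_setpoints(matrix, config)
    eh: dict[str, list[EhSeries]] = {}
    truth_mc: dict[str, dict] = {}
    for c in design.consortia:
        for r in range(design.replicates_per_consortium):
            mc_id = f"{c.label}-r{r + 1}"
            rng = substream(config.seed, "microcosm", mc_id)
            paths = simulate_abundances(c, matrix, config, rng)
            eh[mc_id] = simulate_eh(
                c, paths, config, rng, setpoints=setpoints, microcosm_id=mc_id
            )
            truth_mc[mc_id] = {
                "consortium_label": c.label,
                "richness": c.richness,
                "cmd": community_metabolic_diversity(matrix, c),
                "mean_pairwise_overlap": mean_pairwise_overlap(matrix, c),
                "redundancy": community_redundancy(matrix, c),
            }
    endpoints = simulate_endpoints(design, matrix, config)
    truth = {
        "etsa_slope": config.etsa_slope,
        "doc_slope": config.doc_slope,
        "compensation_strength": config.compensation_strength,
        "breadths": {s: niche_breadth(matrix, s) for s in matrix.species_ids},
        "setpoints": setpoints,
        "microcosms": truth_mc,
    }
    return SyntheticExperiment(config, matrix, design, eh, endpoints, setpoints, truth)


def write_experiment(exp: SyntheticExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write the experiment in the formats the analysis modules read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "affinity": outdir / "affinity.tsv",
        "design": outdir / "design.json",
        "eh": outdir / "eh.csv",
        "endpoints": outdir / "endpoints.csv",
        "truth": outdir / "truth.json",
        "config": outdir / "generator_config.json",
    }
    write_affinity_matrix(exp.matrix, paths["affinity"])
    paths["design"].write_text(design_to_json(exp.design))
    write_eh_csv(exp.eh, paths["eh"])
    exp.endpoints.to_csv(paths["endpoints"], index=False)
    paths["truth"].write_text(json.dumps(exp.truth, indent=2, default=float))
    paths["config"].write_text(exp.config.to_json())
    return paths
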