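"""Seeded synthetic polysomnography cohorts.

Because no sleep-EEG recordings ship with the package, every downstream
stage is exercised on simulated data whose causal structure is known.  The
generator builds, per subject and sleep stage, a directed Watts-Strogatz
style coupling graph, embeds it in a stable band-structured vector
autoregressive (VAR) model (each channel carries a damped oscillation at a
stage-typical frequency; cross-channel coefficients sit exactly on the graph
edges), and simulates a night-like recording with a 20-s hypnogram and a
Bernoulli artifact mask.

The cohort-level structure mirrors the study design it emulates: 28 men and
16 women; women's REM coupling graphs use a higher rewiring probability than
men's (so their REM networks are less lattice-like, i.e. larger omega);
within women a BDI-like depression score is rank-coupled to the REM
rewiring probability (Gaussian copula, target Spearman rho 0.6); men's BDI
is independent of topology; stage-3/4 graph parameters are identical across
sexes.
"""

from __future__ import annotations

import math
from collections.abc import Iterator
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm as _norm

from .errors import InvalidParameterError, StabilityError
from .mvgc import MVARModel, companion_spectral_radius
from .recording import MONTAGE_10_20, ArtifactMask, Hypnogram, RawRecording, SubjectRecord

__all__ = [
    "CouplingGraph",
    "StageProfile",
    "CohortConfig",
    "DEFAULT_PROFILES",
    "make_coupling_graph",
    "graph_to_mvar",
    "simulate_recording",
    "default_template",
    "draw_subjects",
    "build_recording",
    "make_cohort",
    "iter_cohort",
    "score_bdi",
    "bdi_severity",
]


# ---------------------------------------------------------------------------
# types

@dataclass
class CouplingGraph:
    """Directed coupling graph: ground truth for the effective connectivity."""

    n_nodes: int
    edges: tuple[tuple[int, int], ...]   # (source, target)
    weights: np.ndarray
    rewiring_prob: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.n_nodes < 2:
            raise InvalidParameterError("need at least 2 nodes")
        if len(self.weights) != len(self.edges):
            raise InvalidParameterError("one weight per edge required")
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise InvalidParameterError("weights must be finite and >= 0")
        for s, t in self.edges:
            if s == t:
                raise InvalidParameterError("self-loops are not allowed")
            if not (0 <= s < self.n_nodes and 0 <= t < self.n_nodes):
                raise InvalidParameterError("edge endpoint out of range")

    def adjacency(self) -> np.ndarray:
        """Directed adjacency A[s, t] = weight of edge s -> t (0 if absent)."""
        A = np.zeros((self.n_nodes, self.n_nodes))
        for (s, t), w in zip(self.edges, self.weights):
            A[s, t] = w
        return A


@dataclass
class StageProfile:
    """Oscillatory and coupling parameters of one sleep stage."""

    stage: str
    oscillation_bands: tuple[tuple[float, float], ...]  # (center Hz, rel power)
    rewiring_prob: float
    coupling_strength: float = 0.25
    pole_radius: float = 0.92
    noise_std: float = 5.0  # innovation std, uV

    def __post_init__(self) -> None:
        if not 0 <= self.rewiring_prob <= 1:
            raise InvalidParameterError("rewiring_prob must lie in [0, 1]")
        if self.coupling_strength < 0:
            raise InvalidParameterError("coupling_strength must be >= 0")


#: Stage-typical oscillations (center Hz, relative power).  Wake before sleep
#: onset is alpha-dominated; stages 3/4 are delta-dominated slow-wave sleep;
#: REM is low-voltage mixed-frequency with a theta emphasis.
DEFAULT_PROFILES: dict[str, StageProfile] = {
    "W": StageProfile("W", ((10.0, 1.0), (19.0, 0.4)), rewiring_prob=0.10),
    "3": StageProfile("3", ((1.2, 1.0), (6.0, 0.3)), rewiring_prob=0.08),
    "4": StageProfile("4", ((0.8, 1.0), (5.0, 0.2)), rewiring_prob=0.08),
    "REM": StageProfile("REM", ((6.0, 1.0), (10.0, 0.5), (20.0, 0.3)), rewiring_prob=0.10),
}


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    The sex effect is expressed through the REM coupling-graph rewiring
    probability (men around ``rem_rewiring_men``, women around
    ``rem_rewiring_women``); the women-only depression association through a
    Gaussian-copula rank coupling between the subject's REM rewiring
    probability and her BDI score with target Spearman ``bdi_omega_rho_women``.
    Setting the two rewiring centers equal and the rho to zero yields a null
    cohort.
    """

    n_men: int = 28
    n_women: int = 16
    rem_rewiring_men: float = 0.05
    rem_rewiring_women: float = 0.15
    rewiring_jitter: float = 0.07
    bdi_omega_rho_women: float = 0.6
    seed: int = 0
    fs: float = 200.0
    epochs_per_stage: int = 16
    stages: tuple[str, ...] = ("W", "3", "4", "REM")
    mean_degree: int = 4
    order: int = 3
    stability_margin: float = 0.9
    artifact_fraction: float = 0.1
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))

    def __post_init__(self) -> None:
        if self.n_men < 1 or self.n_women < 1:
            raise InvalidParameterError("cohort needs at least one subject per group")
        if abs(self.bdi_omega_rho_women) > 1:
            raise InvalidParameterError("|bdi_omega_rho_women| must be <= 1")
        for p in (self.rem_rewiring_men, self.rem_rewiring_women):
            if not 0 <= p <= 1:
                raise InvalidParameterError("rewiring probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# graphs and models

def make_coupling_graph(
    n_nodes: int, mean_degree: int, rewiring_prob: float, seed: int = 0
) -> CouplingGraph:
    """Directed Watts-Strogatz style coupling graph.

    Starts from a directed ring lattice (out-edges to the mean_degree/2
    nearest neighbours on each side) and rewires each edge's target with
    probability ``rewiring_prob``, avoiding self-loops and duplicates, so
    the number of edges (n_nodes * mean_degree) and every out-degree are
    conserved.
    """
    if mean_degree >= n_nodes:
        raise InvalidParameterError("mean_degree must be < n_nodes")
    if mean_degree < 2 or mean_degree % 2:
        raise InvalidParameterError("mean_degree must be even and >= 2")
    if not 0 <= rewiring_prob <= 1:
        raise InvalidParameterError("rewiring_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    half = mean_degree // 2
    targets: dict[int, set[int]] = {s: set() for s in range(n_nodes)}
    for s in range(n_nodes):
        for off in range(1, half + 1):
            targets[s].add((s + off) % n_nodes)
            targets[s].add((s - off) % n_nodes)
    for s in range(n_nodes):
        for t in sorted(targets[s]):
            if rng.random() < rewiring_prob:
                candidates = [c for c in range(n_nodes) if c != s and c not in targets[s]]
                if not candidates:
                    continue
                new_t = int(rng.choice(candidates))
                targets[s].remove(t)
                targets[s].add(new_t)
    edges = tuple((s, t) for s in range(n_nodes) for t in sorted(targets[s]))
    return CouplingGraph(
        n_nodes=n_nodes,
        edges=edges,
        weights=np.ones(len(edges)),
        rewiring_prob=rewiring_prob,
    )


def graph_to_mvar(
    graph: CouplingGraph,
    profile: StageProfile,
    order: int = 3,
    fs: float = 200.0,
    stability_margin: float = 0.9,
    seed: int = 0,
) -> MVARModel:
    """Embed a coupling graph in a stable band-structured VAR model.

    Each channel gets damped-oscillator self-dynamics (an AR(2) pole pair at
    one of the profile's band centers, chosen with probability proportional
    to relative power); each graph edge j -> i contributes a lag-1 cross
    coefficient weight * coupling_strength.  If the companion spectral radius
    exceeds ``stability_margin`` the lag-k coefficients are scaled by s^k
    (which scales every companion eigenvalue by s exactly), so the returned
    model always satisfies the margin.
    """
    if order < 2:
        raise InvalidParameterError("order must be >= 2 to place oscillatory pole pairs")
    if not 0 < stability_margin < 1:
        raise InvalidParameterError("stability_margin must lie in (0, 1)")
    nyq = fs / 2.0
    for fc, _ in profile.oscillation_bands:
        if fc >= nyq:
            raise InvalidParameterError(f"band center {fc} Hz is not below Nyquist {nyq} Hz")
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    coeffs = np.zeros((order, n, n))

    centers = np.array([fc for fc, _ in profile.oscillation_bands])
    powers = np.array([pw for _, pw in profile.oscillation_bands], dtype=float)
    probs = powers / powers.sum()
    for i in range(n):
        fc = centers[rng.choice(len(centers), p=probs)]
        r = profile.pole_radius * (1.0 + 0.02 * rng.standard_normal())
        r = float(np.clip(r, 0.5, 0.98))
        theta = 2 * math.pi * fc / fs
        coeffs[0, i, i] += 2 * r * math.cos(theta)
        coeffs[1, i, i] += -(r * r)
    for (s, t), w in zip(graph.edges, graph.weights):
        coeffs[0, t, s] += w * profile.coupling_strength

    rho = companion_spectral_radius(coeffs)
    if rho > stability_margin:
        scale = stability_margin / rho * 0.999
        for k in range(order):
            coeffs[k] *= scale ** (k + 1)
        rho = companion_spectral_radius(coeffs)
        if rho > stability_margin + 1e-9:
            raise StabilityError(f"could not stabilize model (radius {rho:.4f})")

    std = profile.noise_std * (1.0 + 0.1 * rng.standard_normal(n))
    std = np.clip(std, 0.2 * profile.noise_std, None)
    sigma = np.diag(std ** 2)
    return MVARModel(order=order, coeffs=coeffs, resid_cov=sigma)


def _simulate_var(model: MVARModel, n_samples: int, rng: np.random.Generator,
                  burn_in: int | None = None) -> np.ndarray:
    """Simulate a VAR model; returns (n_channels, n_samples) after burn-in."""
    p, n = model.order, model.n_channels
    if burn_in is None:
        burn_in = 10 * p
    total = n_samples + burn_in + p
    chol = np.linalg.cholesky(model.resid_cov)
    e = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total, n))
    A = model.coeffs
    for t in range(p, total):
        acc = e[t].copy()
        for k in range(p):
            acc += A[k] @ x[t - k - 1]
        x[t] = acc
    return x[p + burn_in:].T


def default_template(stages: tuple[str, ...] = ("W", "3", "4", "REM"),
                     epochs_per_stage: int = 16) -> tuple[str, ...]:
    """Night-template hypnogram: contiguous blocks of scoring epochs per stage."""
    out: list[str] = []
    for s in stages:
        out.extend([s] * epochs_per_stage)
    return tuple(out)


def simulate_recording(
    models: dict[str, MVARModel],
    hypnogram_template: tuple[str, ...],
    fs: float = 200.0,
    seed: int = 0,
    scoring_epoch_s: float = 20.0,
    artifact_fraction: float = 0.1,
    channel_labels: tuple[str, ...] = MONTAGE_10_20,
) -> tuple[RawRecording, Hypnogram, ArtifactMask]:
    """Simulate a stage-labelled EEG recording from per-stage VAR models.

    Consecutive same-stage scoring epochs form one contiguous simulation
    block; each block's transient is killed by a burn-in of 10x the model
    order which is discarded.  The artifact mask flags each scoring epoch
    as artifactual independently with probability ``artifact_fraction``.
    """
    if fs < 64:
        raise InvalidParameterError("fs must be >= 64 Hz so the beta band is below Nyquist")
    if len(hypnogram_template) < 1:
        raise InvalidParameterError("template must contain at least one scoring epoch")
    missing = sorted(set(hypnogram_template) - set(models))
    if missing:
        raise InvalidParameterError(f"no model for stage(s): {missing}")
    samples_per = int(round(scoring_epoch_s * fs))
    rng = np.random.default_rng(seed)

    blocks: list[tuple[str, int]] = []
    for s in hypnogram_template:
        if blocks and blocks[-1][0] == s:
            blocks[-1] = (s, blocks[-1][1] + 1)
        else:
            blocks.append((s, 1))

    parts = []
    for stage, count in blocks:
        model = models[stage]
        parts.append(_simulate_var(model, count * samples_per, rng))
    samples = np.concatenate(parts, axis=1)
    rec = RawRecording(samples=samples, fs=fs, channel_labels=channel_labels)
    hyp = Hypnogram(stages=tuple(hypnogram_template), scoring_epoch_s=scoring_epoch_s)
    clean = rng.random(len(hypnogram_template)) >= artifact_fraction
    return rec, hyp, ArtifactMask(clean=clean)


# ---------------------------------------------------------------------------
# cohort

def _copula_rho(rho_s: float) -> float:
    """Pearson correlation of the Gaussian copula with target Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def draw_subjects(config: CohortConfig) -> list[SubjectRecord]:
    """Draw the cohort metadata (sex, age, BDI, per-stage rewiring probs).

    The hidden generator parameters (per-stage rewiring probability, subject
    seed) ride along in ``SubjectRecord.extras`` so recordings can be built
    lazily per subject.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    subjects: list[SubjectRecord] = []
    rho_z = _copula_rho(config.bdi_omega_rho_women)
    j = config.rewiring_jitter

    def stage_rewiring(rem_p: float) -> dict[str, float]:
        out = {}
        for s in config.stages:
            if s == "REM":
                out[s] = rem_p
            else:
                out[s] = config.profiles[s].rewiring_prob
        return out

    for i in range(config.n_men):
        rem_p = float(np.clip(config.rem_rewiring_men + rng.uniform(-j, j), 0.0, 1.0))
        age = float(np.clip(round(rng.lognormal(math.log(26), 0.18)), 20, 50))
        bdi = int(min(rng.poisson(1.5), 39))
        subjects.append(SubjectRecord(
            subject_id=f"M{i + 1:02d}", sex="M", age=age, bdi=bdi, group="men",
            extras={"rewiring": stage_rewiring(rem_p), "subject_index": i},
        ))
    for i in range(config.n_women):
        u = rng.uniform()
        rem_p = float(np.clip(
            config.rem_rewiring_women + (2 * u - 1) * j, 0.0, 1.0))
        z_p = _norm.ppf(np.clip(u, 1e-9, 1 - 1e-9))
        eps = rng.standard_normal()
        z_b = rho_z * z_p + math.sqrt(max(0.0, 1 - rho_z ** 2)) * eps
        bdi = int(np.clip(round(4 + 2.2 * z_b), 0, 39))
        age = float(np.clip(round(rng.lognormal(math.log(23), 0.10)), 20, 45))
        subjects.append(SubjectRecord(
            subject_id=f"F{i + 1:02d}", sex="F", age=age, bdi=bdi, group="women",
            extras={"rewiring": stage_rewiring(rem_p),
                    "subject_index": config.n_men + i},
        ))
    return subjects


def coupling_graphs_for(subject: SubjectRecord, config: CohortConfig) -> dict[str, CouplingGraph]:
    """The subject's per-stage ground-truth coupling graphs (seeded)."""
    idx = subject.extras["subject_index"]
    out = {}
    for k, stage in enumerate(config.stages):
        seed = int(np.random.SeedSequence([int(config.seed), 1, idx, k]).generate_state(1)[0])
        out[stage] = make_coupling_graph(
            n_nodes=len(MONTAGE_10_20),
            mean_degree=config.mean_degree,
            rewiring_prob=subject.extras["rewiring"][stage],
            seed=seed,
        )
    return out


def build_recording(
    subject: SubjectRecord, config: CohortConfig
) -> tuple[RawRecording, Hypnogram, ArtifactMask]:
    """Simulate one subject's recording from their coupling graphs."""
    idx = subject.extras["subject_index"]
    graphs = coupling_graphs_for(subject, config)
    models = {}
    for k, stage in enumerate(config.stages):
        prof = config.profiles[stage]
        prof = replace(prof, rewiring_prob=subject.extras["rewiring"][stage])
        seed = int(np.random.SeedSequence([int(config.seed), 2, idx, k]).generate_state(1)[0])
        models[stage] = graph_to_mvar(
            graphs[stage], prof, order=config.order, fs=config.fs,
            stability_margin=config.stability_margin, seed=seed,
        )
    sim_seed = int(np.random.SeedSequence([int(config.seed), 3, idx]).generate_state(1)[0])
    template = default_template(config.stages, config.epochs_per_stage)
    return simulate_recording(
        models, template, fs=config.fs, seed=sim_seed,
        artifact_fraction=config.artifact_fraction,
    )


def iter_cohort(config: CohortConfig) -> Iterator[
    tuple[SubjectRecord, RawRecording, Hypnogram, ArtifactMask]
]:
    """Lazily generate the cohort, one subject bundle at a time."""
    for subject in draw_subjects(config):
        rec, hyp, mask = build_recording(subject, config)
        yield subject, rec, hyp, mask


def make_cohort(config: CohortConfig) -> list[
    tuple[SubjectRecord, RawRecording, Hypnogram, ArtifactMask]
]:
    """Materialize the whole cohort (memory scales with cohort size)."""
    return list(iter_cohort(config))


# ---------------------------------------------------------------------------
# BDI

_BDI_CUTOFFS = (
    (4, "absence of depression"),
    (7, "subclinical depression"),
    (15, "moderate depression"),
    (39, "severe depression"),
)


def bdi_severity(score: int) -> str:
    """Severity label of a 13-item BDI total score (0-4 none, 5-7
    subclinical, 8-15 moderate, >= 16 severe)."""
    if not 0 <= score <= 39:
        raise InvalidParameterError(f"BDI score must lie in [0, 39], got {score}")
    for hi, label in _BDI_CUTOFFS:
        if score <= hi:
            return label
    raise AssertionError("unreachable")


def score_bdi(item_responses) -> int:
    """Total score of the 13-item short-form Beck Depression Inventory.

    Each of the 13 items is scored 0-3; the total therefore spans 0-39.
    """
    items = list(item_responses)
    if len(items) != 13:
        raise InvalidParameterError(f"expected 13 item responses, got {len(items)}")
    for v in items:
        if int(v) != v or not 0 <= int(v) <= 3:
            raise InvalidParameterError(f"item responses must be integers in 0..3, got {v!r}")
    return int(sum(int(v) for v in items))
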