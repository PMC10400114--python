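"""Synthetic inputs for every pipeline stage: networks, BOLD, volumes, cohorts.

The generator emulates a two-group resting-state study at desk scale:
per-subject ground-truth weighted networks whose assortativity is tuned to
a group target by degree-preserving double-edge swaps, multivariate-normal
BOLD series whose population correlation follows the network, optional 4D
volumes with spherical ROI signals, motion traces with spikes, and cohort
covariate tables (age, lifetime injury count binned 0 / 1-2 / 3+, recency
categories).  Everything is deterministic given a seed.

Default study conditions: 40-node networks at edge density 0.35, 30
subjects per group, 265 frames at TR 2.3 s, group assortativity targets
-0.10 (control) vs -0.30 (injury history).  Ages and count/recency
distributions follow the demographic structure of the emulated cohort
(control 31.9 +/- 3.7 y, history 34.1 +/- 4.5 y, median lifetime count 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import RoiTable, RoiTimeSeries, build_connectome
from .confounds import MotionTrace, VolumeSeries
from .metrics import WeightedGraph, assortativity_weighted, compute_all

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "TuneResult",
    "generate_base_graph",
    "tune_assortativity",
    "covariance_from_graph",
    "simulate_bold",
    "simulate_volume",
    "simulate_motion",
    "generate_cohort",
]

#: Default coupling in the network-to-correlation map (population edge
#: correlations reach ~0.6 before positive-definiteness loading).
DEFAULT_COUPLING = 0.6
#: Observation noise SD relative to the unit-variance network signal.
DEFAULT_NOISE_SD = 0.3
AC_TOLERANCE = 0.05


@dataclass
class CohortSpec:
    """Study conditions for a synthetic two-group cohort."""

    subjects_per_group: int = 30
    nodes: int = 40
    density: float = 0.35
    target_ac_control: float = -0.10
    target_ac_history: float = -0.30
    frames: int = 265
    tr: float = 2.3
    noise_sd: float = DEFAULT_NOISE_SD
    coupling: float = DEFAULT_COUPLING
    age_mean_control: float = 31.9
    age_sd_control: float = 3.7
    age_mean_history: float = 34.1
    age_sd_history: float = 4.5
    count_poisson_lambda: float = 2.3  # counts = 1 + Poisson(lambda); median 3
    count_missing_prob: float = 0.025
    recency_probs: tuple[float, float, float, float] = (
        8 / 82,
        12 / 82,
        51 / 82,
        11 / 82,
    )  # past_month, past_year, year_plus, not_reported
    max_tune_iterations: int = 30000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.frames < self.nodes + 1:
            import warnings

            warnings.warn("frames < nodes + 1: sample correlations will be rank-deficient")


@dataclass
class GroundTruth:
    """Per-subject generative truth stored alongside the cohort table."""

    subject_id: str
    group: str
    matrix: np.ndarray
    metrics: dict
    tuned_ac: float
    tune_converged: bool


@dataclass
class TuneResult:
    graph: WeightedGraph
    assortativity: float
    converged: bool
    iterations: int


def generate_base_graph(nodes: int, density: float, seed: int) -> WeightedGraph:
    """Connected random weighted graph at (approximately) the given density.

    Edges are sampled uniformly among node pairs; connectivity is repaired
    by adding bridge edges between components.  Weights are uniform on
    (0.2, 1.0).
    """
    if nodes < 4:
        raise ValueError("need at least 4 nodes")
    n_pairs = nodes * (nodes - 1) // 2
    m = int(round(density * n_pairs))
    if m < nodes - 1:
        raise ValueError(f"density {density} yields {m} edges < {nodes - 1} needed for connectivity")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_pairs, size=m, replace=False)
    iu, ju = np.triu_indices(nodes, k=1)
    W = np.zeros((nodes, nodes))
    W[iu[chosen], ju[chosen]] = rng.uniform(0.2, 1.0, size=m)
    W = W + W.T
    # repair connectivity: bridge successive components
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components((W > 0).astype(np.int8), directed=False)
    while n_comp > 1:
        a = rng.choice(np.flatnonzero(labels == 0))
        b = rng.choice(np.flatnonzero(labels == 1))
        W[a, b] = W[b, a] = rng.uniform(0.2, 1.0)
        n_comp, labels = connected_components((W > 0).astype(np.int8), directed=False)
    return WeightedGraph(weights=W)


def _edge_assortativity(su: np.ndarray, sv: np.ndarray) -> float:
    """Symmetric endpoint Pearson correlation over an edge list."""
    K = su.size
    num = (su * sv).mean()
    mean = 0.5 * (su + sv).mean()
    sq = 0.5 * (su**2 + sv**2).mean()
    denom = sq - mean**2
    if denom <= 0:
        return float("nan")
    return float((num - mean**2) / denom)


def tune_assortativity(
    graph: WeightedGraph,
    target: float,
    max_iterations: int = 30000,
    seed: int = 0,
    tolerance: float = AC_TOLERANCE,
) -> TuneResult:
    """Drive assortativity toward a target by degree-preserving edge swaps.

    Repeatedly proposes double-edge swaps ((a,b),(c,d) -> (a,d),(c,b), each
    weight travelling with its surviving endpoint *a*/*c*), accepting a swap
    only when it moves the assortativity strictly toward the target.  The
    binary degree sequence is exactly preserved.  Stops at
    ``|AC - target| <= tolerance`` or at the iteration cap, in which case the
    best-found graph is returned with ``converged=False``.
    """
    W = graph.weights.copy()
    iu, ju = np.nonzero(np.triu(W, 1) > 0)
    if iu.size < 4:
        raise ValueError("need at least 4 edges to rewire")
    u = iu.copy()
    v = ju.copy()
    w = W[iu, ju].copy()
    n = W.shape[0]
    strength = W.sum(axis=1)
    edge_set = {(int(a), int(b)) for a, b in zip(u, v)}

    def _ac() -> float:
        return _edge_assortativity(strength[u], strength[v])

    current = _ac()
    best = abs(current - target)
    if np.isfinite(current) and best <= tolerance:
        return TuneResult(graph, float(current), True, 0)
    rng = np.random.default_rng(seed)
    m = u.size
    it = 0
    for it in range(1, max_iterations + 1):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = int(u[e1]), int(v[e1])
        c, d = int(u[e2]), int(v[e2])
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        k1 = (min(a, d), max(a, d))
        k2 = (min(c, b), max(c, b))
        if k1 in edge_set or k2 in edge_set:
            continue
        w1, w2 = w[e1], w[e2]
        # strengths: b swaps w1 for w2, d swaps w2 for w1; a and c unchanged
        strength[b] += w2 - w1
        strength[d] += w1 - w2
        old = (u[e1], v[e1], u[e2], v[e2])
        u[e1], v[e1] = k1
        u[e2], v[e2] = k2
        new_ac = _ac()
        dist = abs(new_ac - target) if np.isfinite(new_ac) else np.inf
        if dist < best:
            edge_set.discard((min(a, b), max(a, b)))
            edge_set.discard((min(c, d), max(c, d)))
            edge_set.add(k1)
            edge_set.add(k2)
            current, best = new_ac, dist
            if best <= tolerance:
                break
        else:  # revert
            u[e1], v[e1], u[e2], v[e2] = old
            strength[b] -= w2 - w1
            strength[d] -= w1 - w2
    out = np.zeros_like(W)
    out[u, v] = w
    out = out + out.T
    result = WeightedGraph(weights=out, labels=graph.labels)
    return TuneResult(result, float(current), best <= tolerance, it)


def covariance_from_graph(
    graph: WeightedGraph, coupling: float = DEFAULT_COUPLING
) -> np.ndarray:
    """Valid correlation matrix whose off-diagonal structure follows the graph.

    ``Sigma = I + coupling * W`` (rescaled if any off-diagonal would reach 1);
    if the result is not positive definite, diagonal loading is applied and
    the matrix renormalized to unit diagonal.  Larger edge weights map to
    larger population correlations (monotone).
    """
    if coupling <= 0:
        raise ValueError("coupling must be positive")
    S = coupling * graph.weights
    mx = S.max(initial=0.0)
    if mx >= 1.0:
        S *= 0.99 / mx
    sigma = np.eye(graph.n_nodes) + S
    lam = np.linalg.eigvalsh(sigma)[0]
    if lam <= 1e-8:
        sigma += (abs(lam) + 1e-6) * np.eye(graph.n_nodes)
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    return sigma


def simulate_bold(
    correlation: np.ndarray,
    frames: int,
    tr: float,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    labels: list[str] | None = None,
) -> RoiTimeSeries:
    """Zero-mean multivariate-normal draws plus independent observation noise."""
    if frames < 3:
        raise ValueError("need at least 3 frames")
    sigma = np.asarray(correlation, dtype=float)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    n = sigma.shape[0]
    data = rng.standard_normal((frames, n)) @ L.T
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=(frames, n))
    if labels is None:
        labels = [f"roi{i}" for i in range(n)]
    return RoiTimeSeries(data=data, tr=tr, labels=labels)


def simulate_volume(
    ts: RoiTimeSeries,
    rois: RoiTable,
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    background_noise_sd: float = 0.0,
    seed: int = 0,
    radius: float = 4.0,
) -> VolumeSeries:
    """Paint each ROI's signal onto the voxels of its sphere; noise elsewhere.

    Spheres must fit inside the grid and be mutually disjoint so the
    round-trip through spherical extraction is exact at zero noise.
    """
    nx, ny, nz = grid_shape
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    world = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * voxel_size
    rng = np.random.default_rng(seed)
    data = np.zeros((nx * ny * nz, ts.n_frames))
    if background_noise_sd > 0:
        data += rng.normal(0.0, background_noise_sd, size=data.shape)
    claimed = np.zeros(world.shape[0], dtype=bool)
    for idx, (label, center) in enumerate(zip(rois.labels, rois.centers)):
        dist2 = ((world - center) ** 2).sum(axis=1)
        sel = dist2 <= radius**2
        if not sel.any():
            raise ValueError(f"ROI {label!r}: sphere lies outside the grid")
        if (sel & claimed).any():
            raise ValueError(f"ROI {label!r}: sphere overlaps a previous ROI")
        claimed |= sel
        data[sel] = ts.data[:, idx]
        if background_noise_sd > 0:
            data[sel] += rng.normal(0.0, background_noise_sd, size=(sel.sum(), ts.n_frames))
    return VolumeSeries(
        data=data.reshape(nx, ny, nz, ts.n_frames),
        voxel_size=voxel_size,
        tr=ts.tr,
        affine=affine,
    )


def simulate_motion(
    frames: int,
    spike_probability: float = 0.0,
    spike_scale: float = 1.0,
    walk_scale: float = 0.005,
    tr: float = 2.3,
    seed: int = 0,
) -> MotionTrace:
    """Smooth low-amplitude random-walk motion with occasional level-shift spikes.

    Spikes are step changes (the head settles at a new position), so each
    spiked frame produces exactly one high-FD frame: the expected flagged
    fraction at default thresholds is approximately ``spike_probability``.
    """
    if frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, walk_scale, size=(frames, 6))
    steps[:, 3:] *= 0.01  # rotations in radians, ~2 orders smaller
    steps[0] = 0.0
    spikes = rng.random(frames) < spike_probability
    spikes[0] = False
    axes = rng.integers(0, 3, size=frames)
    signs = rng.choice([-1.0, 1.0], size=frames)
    for t in np.flatnonzero(spikes):
        steps[t, axes[t]] += signs[t] * spike_scale
    params = np.cumsum(steps, axis=0)
    return MotionTrace(params=params, tr=tr)


def _spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def generate_cohort(
    spec: CohortSpec,
    metrics: tuple[str, ...] = ("ge", "le", "ac"),
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Full synthetic cohort: networks, BOLD, pipeline metrics, covariates.

    Each subject gets a ground-truth network tuned to the group's
    assortativity target, a simulated BOLD run, and metrics computed through
    the *real* pipeline (Pearson -> Fisher z -> zero negatives -> graph
    metrics).  ``metrics`` can be restricted (e.g. ``("ac",)``) to speed up
    large replicate simulations.
    """
    n_subj = 2 * spec.subjects_per_group
    seeds = _spawn_seeds(spec.seed, n_subj)
    rows = []
    truths: list[GroundTruth] = []
    for i in range(n_subj):
        history = i >= spec.subjects_per_group
        group = "history" if history else "control"
        target = spec.target_ac_history if history else spec.target_ac_control
        rng = np.random.default_rng(seeds[i])
        sub_seeds = rng.integers(0, 2**31 - 1, size=4)
        base = generate_base_graph(spec.nodes, spec.density, int(sub_seeds[0]))
        tuned = tune_assortativity(
            base, target, max_iterations=spec.max_tune_iterations, seed=int(sub_seeds[1])
        )
        sigma = covariance_from_graph(tuned.graph, coupling=spec.coupling)
        ts = simulate_bold(
            sigma, spec.frames, spec.tr, noise_sd=spec.noise_sd, seed=int(sub_seeds[2])
        )
        conn = build_connectome(ts)
        est_graph = WeightedGraph(weights=conn.values, labels=conn.labels)
        row: dict = {
            "subject_id": f"sub-{i:03d}",
            "mtbi_history": history,
            "group": group,
        }
        if metrics == ("ac",):
            ac = assortativity_weighted(est_graph)
            row.update(ge=np.nan, le=np.nan, ac=np.nan if ac is None else ac)
            true_metrics = {"ac": assortativity_weighted(tuned.graph)}
        else:
            gm = compute_all(est_graph)
            row.update(
                ge=gm.global_efficiency,
                le=gm.local_efficiency_mean,
                ac=np.nan if gm.assortativity is None else gm.assortativity,
            )
            tm = compute_all(tuned.graph)
            true_metrics = {
                "ge": tm.global_efficiency,
                "le": tm.local_efficiency_mean,
                "ac": tm.assortativity,
            }
        if history:
            row["age"] = rng.normal(spec.age_mean_history, spec.age_sd_history)
            if rng.random() < spec.count_missing_prob:
                row["mtbi_count"] = np.nan
            else:
                row["mtbi_count"] = float(1 + rng.poisson(spec.count_poisson_lambda))
            row["mtbi_recency"] = rng.choice(
                ["past_month", "past_year", "year_plus", "not_reported"],
                p=np.asarray(spec.recency_probs) / np.sum(spec.recency_probs),
            )
        else:
            row["age"] = rng.normal(spec.age_mean_control, spec.age_sd_control)
            row["mtbi_count"] = 0.0
            row["mtbi_recency"] = None
        rows.append(row)
        truths.append(
            GroundTruth(
                subject_id=row["subject_id"],
                group=group,
                matrix=tuned.graph.weights,
                metrics=true_metrics,
                tuned_ac=tuned.assortativity,
                tune_converged=tuned.converged,
            )
        )
    cohort = pd.DataFrame(rows)
    return cohort, truths
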