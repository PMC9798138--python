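"""Linear-Gaussian network simulation for benchmarking association measures.

Synthetic time-series are drawn from a first-order vector autoregressive
(VAR(1)) model over a fixed directed network, by default the 11-node
Raf/MAPK signalling pathway.  Each node follows

    X_i(t) = sum_{k in parents(i)} w_ik X_k(t-1) + e_i(t)

with independent Gaussian innovations e_i ~ N(0, sigma^2).  Edge-weight
magnitudes are drawn uniformly from a configurable interval (default
[0.5, 2]) with random sign.  By default only parent edges carry weight
(the sum extends over the parents); on a DAG the transition matrix is
then nilpotent, so the process is stationary for any weight magnitude.
Optional autoregressive self-weights w_ii can be switched on, in which
case the full weight matrix is rescaled to a spectral radius of 0.95
(configurable) to preserve stationarity.

An "instantaneous" mode is also provided in which each timepoint is an
independent draw obtained by propagating innovations through the DAG in
topological order within a single timepoint - the same-time structural
reading of the generative equations.  The two modes bound the plausible
readings of the generating process and behave differently under
subsampling: lagged dynamics lose most of their recoverable signal when
sampled intermittently or scored with time-lagged pairs, while
instantaneous sampling is only sensitive to the number of samples.

The module also builds the derived datasets used in the simulation study:
intermittently subsampled series (every 2nd, 3rd, ... timepoint) and
time-lagged sample pairs (t = 1..n-1 against t = 2..n), and runs AUROC
sweeps over series length or sampling interval.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DirectedNetwork",
    "SimulationConfig",
    "TimeSeriesDataset",
    "load_raf_network",
    "sample_weights",
    "simulate_dataset",
    "subsample",
    "make_lagged_pairs",
    "run_sweep",
]


@dataclass
class DirectedNetwork:
    """A weighted directed network.

    ``weights[(parent, child)]`` holds the signed interaction strength of
    each edge; ``self_weights[node]`` the autoregressive weight of a node on
    its own past.  Both may be ``None`` before :func:`sample_weights`.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    weights: dict[tuple[str, str], float] | None = None
    self_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        for parent, child in self.edges:
            if parent not in node_set or child not in node_set:
                raise ValueError(f"edge ({parent}, {child}) references undeclared node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight_matrix(self) -> np.ndarray:
        """Transition matrix A with A[child, parent] = w_{parent->child}."""
        if self.weights is None:
            raise ValueError("weights not set; call sample_weights first")
        idx = {n: i for i, n in enumerate(self.nodes)}
        A = np.zeros((self.n_nodes, self.n_nodes))
        for (parent, child), w in self.weights.items():
            A[idx[child], idx[parent]] = w
        if self.self_weights:
            for node, w in self.self_weights.items():
                A[idx[node], idx[node]] = w
        return A

    def adjacency(self) -> np.ndarray:
        """Boolean truth matrix T with T[parent, child] = True for each edge."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        T = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for parent, child in self.edges:
            T[idx[parent], idx[child]] = True
        return T

    def topological_order(self) -> list[int]:
        """Topological node order; raises on cyclic topology."""
        n = self.n_nodes
        idx = {name: i for i, name in enumerate(self.nodes)}
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = [0] * n
        for parent, child in self.edges:
            children[idx[parent]].append(idx[child])
            indeg[idx[child]] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        order: list[int] = []
        while queue:
            i = queue.pop()
            order.append(i)
            for j in children[i]:
                indeg[j] -= 1
                if indeg[j] == 0:
                    queue.append(j)
        if len(order) != n:
            raise ValueError("topology contains a cycle")
        return order


@dataclass
class SimulationConfig:
    """Parameters of the VAR(1) simulation.

    series_length
        Number of retained timepoints k (>= 2).
    noise_sd
        Innovation standard deviation sigma.
    weight_magnitude_range
        Interval from which |w| is drawn uniformly (default [0.5, 2]).
    spectral_radius
        Target spectral radius after rescaling the weight matrix; values
        below 1 guarantee stationarity.  Set to ``None`` to disable.
    n_datasets
        Replicate datasets per sweep grid point.
    dynamics_mode
        "lagged" (VAR(1)) or "instantaneous" (i.i.d. DAG sampling).
    burn_in
        Timepoints discarded before recording, so samples come from the
        stationary distribution (lagged mode only).
    """

    series_length: int = 100
    noise_sd: float = 1.0
    weight_magnitude_range: tuple[float, float] = (0.5, 2.0)
    spectral_radius: float | None = 0.95
    n_datasets: int = 200
    seed: int = 0
    dynamics_mode: str = "lagged"
    burn_in: int = 50
    include_self_weights: bool = False

    def __post_init__(self) -> None:
        if self.series_length < 2:
            raise ValueError("series_length must be >= 2")
        if self.noise_sd <= 0 and self.dynamics_mode == "lagged" and self.burn_in > 0:
            # sigma == 0 is allowed only for deterministic recursions from an
            # explicit initial state
            raise ValueError("noise_sd must be positive when burning in")
        lo, hi = self.weight_magnitude_range
        if lo <= 0 or hi < lo:
            raise ValueError("weight magnitude range must satisfy 0 < lo <= hi")
        if self.dynamics_mode not in ("lagged", "instantaneous"):
            raise ValueError(f"unknown dynamics_mode {self.dynamics_mode!r}")


@dataclass
class TimeSeriesDataset:
    """A variables x samples matrix with sample metadata.

    ``sample_labels`` are timepoint indices (1-based) for time-series data
    or condition identifiers for perturbation panels.  ``truth`` carries the
    generating network when the data are simulated.
    """

    values: np.ndarray
    sample_labels: list
    variable_labels: list[str]
    truth: DirectedNetwork | None = None
    sample_kind: str = "timepoint"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (variables x samples)")
        if self.values.shape[0] != len(self.variable_labels):
            raise ValueError("variable_labels length mismatch")
        if self.values.shape[1] != len(self.sample_labels):
            raise ValueError("sample_labels length mismatch")
        if self.values.shape[1] and np.isnan(self.values).all(axis=1).any():
            raise ValueError("entirely-missing variable row")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]


def load_raf_network() -> DirectedNetwork:
    """Load the bundled 11-node, 19-edge Raf signalling pathway topology.

    The edge list follows the consensus map of the Raf/MAPK pathway from
    single-cell flow-cytometry studies (PKC/PKA signalling onto the
    Raf-Mek-Erk cascade plus the PLCg/PIP2/PIP3 and Akt/JNK/p38 arms).
    Weights are unset; call :func:`sample_weights`.
    """
    ref = importlib.resources.files("phosphonet").joinpath("data/raf_edges.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if list(df.columns) != ["parent", "child"]:
        raise ValueError("corrupt Raf fixture: expected columns parent, child")
    edges = [(str(p), str(c)) for p, c in zip(df["parent"], df["child"])]
    nodes: list[str] = []
    for p, c in edges:
        for n in (p, c):
            if n not in nodes:
                nodes.append(n)
    return DirectedNetwork(nodes=nodes, edges=edges)


def sample_weights(
    net: DirectedNetwork, cfg: SimulationConfig, seed: int | None = None
) -> DirectedNetwork:
    """Draw signed edge (and self) weights for a network topology.

    Magnitudes are uniform on ``cfg.weight_magnitude_range`` with
    independent random signs.  Self-weights are drawn the same way when
    ``cfg.include_self_weights`` is set, and are zero otherwise (the
    default: the generative sum runs over the parents).  When
    ``cfg.spectral_radius`` is set and the transition matrix has a
    positive spectral radius, the matrix is rescaled to that target so
    the VAR(1) process stays stationary; a DAG without self-weights has a
    nilpotent transition matrix and is left untouched.
    """
    if not net.edges:
        raise ValueError("network has no edges")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.weight_magnitude_range

    def draw(k: int) -> np.ndarray:
        return rng.uniform(lo, hi, size=k) * rng.choice([-1.0, 1.0], size=k)

    weights = dict(zip(net.edges, draw(len(net.edges))))
    self_weights = (
        dict(zip(net.nodes, draw(len(net.nodes))))
        if cfg.include_self_weights
        else {n: 0.0 for n in net.nodes}
    )
    out = DirectedNetwork(
        nodes=list(net.nodes),
        edges=list(net.edges),
        weights=weights,
        self_weights=self_weights,
    )
    if cfg.spectral_radius is not None:
        rho = max(abs(np.linalg.eigvals(out.weight_matrix())))
        if rho > 0:
            scale = cfg.spectral_radius / rho
            out.weights = {e: w * scale for e, w in out.weights.items()}
            out.self_weights = {n: w * scale for n, w in out.self_weights.items()}
    return out


def simulate_dataset(
    net: DirectedNetwork,
    cfg: SimulationConfig,
    seed: int | None = None,
    initial_state: np.ndarray | None = None,
) -> TimeSeriesDataset:
    """Simulate one dataset of ``cfg.series_length`` timepoints.

    In lagged mode the VAR(1) recursion is iterated from ``initial_state``
    (default: innovations) for ``cfg.burn_in`` discarded steps plus the
    recorded steps.  In instantaneous mode every timepoint is an
    independent draw obtained by propagating innovations through the DAG in
    topological order (self weights do not apply within a timepoint).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k = cfg.series_length
    n = net.n_nodes
    A = net.weight_matrix()

    if cfg.dynamics_mode == "lagged":
        x = (
            np.asarray(initial_state, dtype=float)
            if initial_state is not None
            else rng.normal(0.0, cfg.noise_sd, size=n)
        )
        burn = cfg.burn_in if initial_state is None else 0
        values = np.empty((n, k))
        for t in range(burn + k):
            eps = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
            x = A @ x + eps
            if t >= burn:
                values[:, t - burn] = x
    else:
        order = net.topological_order()  # raises on cycles
        values = np.empty((n, k))
        for t in range(k):
            eps = rng.normal(0.0, cfg.noise_sd, size=n)
            x = np.zeros(n)
            for i in order:
                x[i] = A[i] @ x + eps[i]
            values[:, t] = x

    return TimeSeriesDataset(
        values=values,
        sample_labels=list(range(1, k + 1)),
        variable_labels=list(net.nodes),
        truth=net,
    )


def subsample(ds: TimeSeriesDataset, interval: int) -> TimeSeriesDataset:
    """Keep every ``interval``-th timepoint, starting from the first."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if interval >= ds.n_samples:
        raise ValueError("interval must be smaller than the series length")
    keep = np.arange(0, ds.n_samples, interval)
    return TimeSeriesDataset(
        values=ds.values[:, keep],
        sample_labels=[ds.sample_labels[i] for i in keep],
        variable_labels=list(ds.variable_labels),
        truth=ds.truth,
        sample_kind=ds.sample_kind,
    )


def make_lagged_pairs(ds: TimeSeriesDataset) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (leading, trailing) matrices over t = 1..n-1 and t = 2..n.

    An association between row i of the leading matrix and row j of the
    trailing matrix is interpreted as a directed i -> j candidate.  Rows
    that become constant after lagging are left as-is; downstream measures
    flag zero-variance rows as NA.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples to build lagged pairs")
    return ds.values[:, :-1], ds.values[:, 1:]


def _directed_candidates(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten an n x n score matrix over off-diagonal ordered pairs."""
    n = scores.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return scores[mask], truth[mask].astype(float)


def _auroc_vs_truth(score_matrix: np.ndarray, truth: np.ndarray) -> float:
    # local import to avoid a cycle (evaluate imports nothing from simnet)
    from .evaluate import auroc

    s, y = _directed_candidates(score_matrix, truth)
    ok = ~np.isnan(s)
    # rank by |score|: strongly negative associations are informative edges
    return auroc(np.abs(s[ok]), y[ok])


def run_sweep(
    net: DirectedNetwork,
    cfg: SimulationConfig,
    *,
    lengths: Iterable[int] | None = None,
    intervals: Iterable[int] | None = None,
    measures: Sequence[str] | None = None,
    seed: int | None = None,
    lagged: bool = False,
) -> pd.DataFrame:
    """AUROC sweep over series lengths or sampling intervals.

    For each grid point, ``cfg.n_datasets`` replicate weighted networks and
    datasets are simulated, every requested measure scores all ordered node
    pairs (symmetric measures fill both orientations; in lagged mode the
    measures are applied to the (leading, trailing) pair), and the AUROC of
    recovering the true directed edges is recorded.

    Returns a tidy frame with columns
    ``grid`` (``length`` or ``interval``), ``grid_value``, ``replicate``,
    ``measure``, ``auc``.
    """
    from . import measures as M

    if (lengths is None) == (intervals is None):
        raise ValueError("specify exactly one of lengths= or intervals=")
    measure_names = list(measures) if measures is not None else list(M.MEASURES)
    for m in measure_names:
        if m not in M.MEASURES:
            raise ValueError(f"unknown measure {m!r}")

    grid_name = "length" if lengths is not None else "interval"
    grid_values = list(lengths if lengths is not None else intervals)
    base_seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    truth = net.adjacency()

    rows = []
    for gv in grid_values:
        run_cfg = replace(cfg, series_length=gv if grid_name == "length" else cfg.series_length)
        child_seeds = ss.spawn(cfg.n_datasets)
        for rep, child in enumerate(child_seeds):
            s1, s2 = child.spawn(2)
            wnet = sample_weights(net, run_cfg, seed=s1)
            ds = simulate_dataset(wnet, run_cfg, seed=s2)
            if grid_name == "interval" and gv > 1:
                ds = subsample(ds, gv)
            if lagged:
                lead, trail = make_lagged_pairs(ds)
            for m in measure_names:
                if lagged:
                    am = M.score_lagged(lead, trail, m)
                else:
                    am = M.score_matrix(ds.values, m)
                rows.append(
                    {
                        "grid": grid_name,
                        "grid_value": gv,
                        "replicate": rep,
                        "measure": m,
                        "auc": _auroc_vs_truth(am.scores, truth),
                    }
                )
    return pd.DataFrame(rows)
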