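"""Synthetic two-experiment circadian expression data and phase-labelled networks.

The generator emulates the statistical structure the detection pipeline
assumes: two independent experiments (V1, V2) at two constant temperatures
(18C, 25C), each a bulk-RNA-seq time course over Zeitgeber time. Expression
is simulated on the log2 scale as

    log2-expr = baseline + A * cos(2*pi*(t - phi)/24) * 1[cycling] + noise

and exponentiated to TPM (``2^x - 1`` floored at 0), so amplitudes and
noise are multiplicative on the TPM scale. Gene-level truth (cycling flags,
phases, amplitudes, baselines) depends only on the config seed, so the same
gene carries the same rhythm in both experiments; measurement noise is
re-drawn per (experiment, condition).

Sampling designs mirror the two study arms: V1 samples every 2 h over one
day (ZT02-ZT24) with two replicates; V2 covers two consecutive days with
one replicate every 2 h plus a sparser ~6-hourly second replicate, all
timestamps collapsed modulo 24.

Networks for the phase-organization analysis are generated separately:
cycling genes are either placed on a connected region with phases drifting
by a fixed step per edge (assortative mode, giving a controllable
phase-vs-distance slope) or scattered uniformly with shuffled phases
(random mode, the null).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .circstat import PERIOD
from .ingest import ExpressionMatrix

_EXP_CODE = {"V1": 1, "V2": 2}
_COND_CODE = {"18C": 18, "25C": 25}

# Phase-model peaks (ZT hours) mimicking a bimodal circadian transcriptome:
# morning/evening clusters, with the daytime peak later at low temperature.
BIMODAL_PEAKS = {"25C": (2.0, 20.0), "18C": (8.5, 22.0)}
UNIMODAL_PEAK = {"25C": 20.0, "18C": 22.0}


def default_v1_scheme() -> list:
    """ZT02..ZT24 every 2 h, 2 replicates (24 samples)."""
    return [(float(zt % 24), 2) for zt in range(2, 26, 2)]


def default_v2_scheme() -> list:
    """Two-day design collapsed mod 24: 2-hourly single replicates over
    day 4 (ZT4-ZT22) and day 5 (ZT0-ZT18), plus a ~6-hourly second
    replicate (ZT 4/10/16/22 day 4, ZT 4/10/16 day 5). 27 samples."""
    counts: dict[float, int] = {}
    for zt in range(4, 24, 2):  # day 4
        counts[float(zt)] = counts.get(float(zt), 0) + 1
    for zt in range(0, 20, 2):  # day 5
        counts[float(zt)] = counts.get(float(zt), 0) + 1
    for zt in (4.0, 10.0, 16.0, 22.0):  # extra replicate, day 4
        counts[zt] += 1
    for zt in (4.0, 10.0, 16.0):  # extra replicate, day 5
        counts[zt] += 1
    return sorted(counts.items())


@dataclass
class SimConfig:
    """Study-design and signal parameters for the expression simulator."""

    n_genes: int = 2000
    frac_cycling_18: float = 0.05
    frac_cycling_25: float = 0.05
    frac_shared: float = 0.4  # fraction of the smaller cycling set shared
    amplitude_range: tuple = (0.5, 2.0)  # log2-TPM half peak-to-trough
    phase_model: str = "bimodal"  # or "unimodal"
    phase_kappa: float = 2.0  # von Mises concentration of peak clusters
    baseline_log_tpm_mean: float = 4.0
    baseline_log_tpm_sd: float = 1.5
    noise_sd: float = 0.5  # log2-TPM
    shared_phase_advance: float = 1.9  # hours, 18C relative to 25C
    shared_phase_jitter_sd: float = 0.75  # hours
    sampling_scheme_v1: list = field(default_factory=default_v1_scheme)
    sampling_scheme_v2: list = field(default_factory=default_v2_scheme)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_cycling_18", "frac_cycling_25", "frac_shared"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.amplitude_range
        if not 0 < lo <= hi:
            raise ValueError("amplitude_range must satisfy 0 < low <= high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.phase_model not in ("unimodal", "bimodal"):
            raise ValueError(f"unknown phase_model {self.phase_model!r}")
        for name in ("sampling_scheme_v1", "sampling_scheme_v2"):
            scheme = getattr(self, name)
            if not scheme:
                raise ValueError(f"{name} is empty")
            if any(not (0 <= zt < PERIOD) for zt, _ in scheme):
                raise ValueError("ZT values must be in [0, 24)")

    def scheme(self, experiment_id: str) -> list:
        return {"V1": self.sampling_scheme_v1, "V2": self.sampling_scheme_v2}[experiment_id]


def _draw_phases(rng: np.random.Generator, n: int, condition: str, config: SimConfig) -> np.ndarray:
    """Phases from the condition's (von Mises or mixture) phase model, hours."""
    if n == 0:
        return np.empty(0)
    kappa = config.phase_kappa
    if config.phase_model == "unimodal":
        mu = UNIMODAL_PEAK[condition] * 2 * np.pi / PERIOD
        theta = rng.vonmises(mu, kappa, size=n)
    else:
        peaks = BIMODAL_PEAKS[condition]
        comp = rng.integers(0, 2, size=n)
        mus = np.array(peaks) * 2 * np.pi / PERIOD
        theta = rng.vonmises(mus[comp], kappa)
    return (theta * PERIOD / (2 * np.pi)) % PERIOD


def ground_truth(config: SimConfig) -> pd.DataFrame:
    """Gene-level truth table, a pure function of the config (incl. seed).

    Columns: is_cycling_18, is_cycling_25, phase_18, phase_25 (NaN where
    not cycling), amplitude, baseline. Shared cyclers get an 18C phase
    advanced relative to 25C by ``shared_phase_advance`` plus jitter.
    """
    rng = np.random.default_rng([config.seed, 1000])
    n = config.n_genes
    n18 = int(round(config.frac_cycling_18 * n))
    n25 = int(round(config.frac_cycling_25 * n))
    n_shared = int(round(config.frac_shared * min(n18, n25)))
    gene_ids = pd.Index([f"g{i:06d}" for i in range(n)], name="gene_id")
    is18 = np.zeros(n, dtype=bool)
    is25 = np.zeros(n, dtype=bool)
    is18[:n_shared] = True
    is25[:n_shared] = True
    is18[n_shared : n_shared + (n18 - n_shared)] = True
    lo = n_shared + (n18 - n_shared)
    is25[lo : lo + (n25 - n_shared)] = True

    phase_18 = np.full(n, np.nan)
    phase_25 = np.full(n, np.nan)
    phase_25[is25] = _draw_phases(rng, int(is25.sum()), "25C", config)
    # shared genes: 18C phase tied to 25C with an advance; 18C-only genes
    # drawn from the 18C phase model
    shared = is18 & is25
    jitter = rng.normal(0.0, config.shared_phase_jitter_sd, size=int(shared.sum()))
    phase_18[shared] = (phase_25[shared] + config.shared_phase_advance + jitter) % PERIOD
    only18 = is18 & ~is25
    phase_18[only18] = _draw_phases(rng, int(only18.sum()), "18C", config)

    amplitude = rng.uniform(*config.amplitude_range, size=n)
    amplitude[~(is18 | is25)] = 0.0
    baseline = rng.normal(config.baseline_log_tpm_mean, config.baseline_log_tpm_sd, size=n)
    return pd.DataFrame(
        {
            "is_cycling_18": is18,
            "is_cycling_25": is25,
            "phase_18": phase_18,
            "phase_25": phase_25,
            "amplitude": amplitude,
            "baseline": baseline,
        },
        index=gene_ids,
    )


def simulate_experiment(config: SimConfig, experiment_id: str, condition: str):
    """Simulate one (experiment, condition) TPM matrix.

    Returns ``(ExpressionMatrix, truth)`` where truth is the gene-level
    ground-truth table (identical across experiments for a given config).
    Identical (config, seed) gives bit-identical output.
    """
    if experiment_id not in _EXP_CODE:
        raise ValueError(f"unknown experiment {experiment_id!r}")
    if condition not in _COND_CODE:
        raise ValueError(f"unknown condition {condition!r}")
    truth = ground_truth(config)
    scheme = config.scheme(experiment_id)
    rng = np.random.default_rng([config.seed, _EXP_CODE[experiment_id], _COND_CODE[condition]])

    times, sample_ids, reps = [], [], []
    for zt, n_rep in scheme:
        for r in range(1, n_rep + 1):
            times.append(zt)
            reps.append(r)
            sample_ids.append(f"{experiment_id}_{condition}_ZT{zt:04.1f}_r{r}")
    t = np.asarray(times)

    cycling = truth[f"is_cycling_{condition[:2]}"].to_numpy()
    phase = np.where(cycling, np.nan_to_num(truth[f"phase_{condition[:2]}"].to_numpy()), 0.0)
    amp = np.where(cycling, truth["amplitude"].to_numpy(), 0.0)
    baseline = truth["baseline"].to_numpy()

    signal = baseline[:, None] + amp[:, None] * np.cos(2 * np.pi * (t[None, :] - phase[:, None]) / PERIOD)
    log2_expr = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    tpm = np.maximum(np.exp2(log2_expr) - 1.0, 0.0)

    values = pd.DataFrame(tpm, index=truth.index, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "experiment": experiment_id,
            "condition": condition,
            "zt_hours": t,
            "replicate": reps,
        }
    )
    return ExpressionMatrix(values, samples), truth


def simulate_study(config: SimConfig):
    """All four (experiment x condition) matrices plus the shared truth."""
    mats = {}
    for exp in ("V1", "V2"):
        for cond in ("18C", "25C"):
            mats[(exp, cond)], truth = simulate_experiment(config, exp, cond)
    return mats, truth


# ---------------------------------------------------------------------------
# Networks


@dataclass
class NetSimConfig:
    """Parameters for phase-labelled network generation."""

    n_nodes: int = 300
    graph_model: str = "watts-strogatz"  # watts-strogatz | barabasi-albert | erdos-renyi | path
    graph_params: dict = field(default_factory=dict)
    assortativity_mode: str = "assortative"  # or "random"
    per_edge_phase_step: float = 0.3  # hours of phase drift per hop
    placement_noise_sd: float = 0.5  # hours
    root: str | int | None = None  # BFS root; default: smallest node label
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.per_edge_phase_step < 0:
            raise ValueError("per_edge_phase_step must be >= 0")
        if self.placement_noise_sd < 0:
            raise ValueError("placement_noise_sd must be >= 0")
        if self.assortativity_mode not in ("assortative", "random"):
            raise ValueError(f"unknown assortativity_mode {self.assortativity_mode!r}")


def _make_graph(config: NetSimConfig, rng: np.random.Generator) -> nx.Graph:
    n = config.n_nodes
    p = config.graph_params
    seed = int(rng.integers(0, 2**31 - 1))
    if config.graph_model == "watts-strogatz":
        g = nx.connected_watts_strogatz_graph(n, p.get("k", 6), p.get("p", 0.1), seed=seed)
    elif config.graph_model == "barabasi-albert":
        g = nx.barabasi_albert_graph(n, p.get("m", 3), seed=seed)
    elif config.graph_model == "erdos-renyi":
        g = nx.erdos_renyi_graph(n, p.get("p", min(1.0, 4.0 / n)), seed=seed)
    elif config.graph_model == "path":
        g = nx.path_graph(n)
    else:
        raise ValueError(f"unknown graph_model {config.graph_model!r}")
    g = nx.Graph(g)  # simple, undirected
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def simulate_network(config: NetSimConfig, cycler_phases):
    """Generate a graph and place cycling genes on it with known structure.

    Returns ``(graph, placement)`` where placement maps node -> phase in
    hours for the ``len(cycler_phases)`` placed cyclers.

    In *assortative* mode the cyclers occupy a connected region grown
    breadth-first from a deterministic root (smallest node label unless
    ``config.root`` is set) and each node's phase is ``anchor + step *
    depth + noise`` mod 24, with the anchor taken from the first input
    phase — so the expected median |dphi| grows linearly with geodesic
    distance at ``per_edge_phase_step`` hours per hop. In *random* mode the
    cyclers are scattered uniformly and the input phases shuffled onto
    them, the exchangeable null.
    """
    phases = np.asarray(list(cycler_phases), dtype=float)
    m = phases.size
    if m == 0:
        raise ValueError("no cycler phases given")
    if m > config.n_nodes:
        raise ValueError(f"more cyclers ({m}) than nodes ({config.n_nodes})")
    rng = np.random.default_rng([config.seed, 77])
    g = _make_graph(config, rng)
    nodes = sorted(g.nodes())
    if config.assortativity_mode == "random":
        chosen = [nodes[i] for i in rng.choice(len(nodes), size=m, replace=False)]
        shuffled = phases[rng.permutation(m)]
        placement = dict(zip(chosen, shuffled))
    else:
        root = config.root if config.root is not None else nodes[0]
        if root not in g:
            raise ValueError(f"root {root!r} not in graph")
        depths = nx.single_source_shortest_path_length(g, root)
        if len(depths) < m:
            raise ValueError(
                f"connected region from root has {len(depths)} nodes < {m} cyclers; "
                "graph too disconnected for assortative placement"
            )
        region = sorted(depths.items(), key=lambda kv: (kv[1], str(kv[0])))[:m]
        anchor = float(phases[0])
        noise = rng.normal(0.0, config.placement_noise_sd, size=m) if config.placement_noise_sd > 0 else np.zeros(m)
        placement = {
            node: (anchor + config.per_edge_phase_step * depth + eps) % PERIOD
            for (node, depth), eps in zip(region, noise)
        }
    return g, placement


def null_config(config: SimConfig, n_genes: int | None = None) -> SimConfig:
    """A copy of ``config`` with all cycling switched off (pure noise)."""
    return replace(
        config,
        n_genes=config.n_genes if n_genes is None else n_genes,
        frac_cycling_18=0.0,
        frac_cycling_25=0.0,
    )
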