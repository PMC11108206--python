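"""Phase organization of cycling genes on a gene-interaction network.

The central statistic: for every pair of cycling genes at geodesic
(shortest-path) distance d on the network, compute the absolute circular
phase difference |dphi| in hours; summarize each distance bin 1..d_max by
its median; regress the medians on d. A positive slope means nearby genes
peak at similar times — phases are organized with respect to the network.
Significance per distance comes from a permutation null that re-places the
cycling-gene set uniformly over the network's nodes (phases kept attached
to their multiset order) and recomputes the per-distance medians.

Control analyses: two-sample KS comparisons of degree distributions
(cyclers vs all genes) and a Wilcoxon rank-sum test of whether cyclers sit
closer together than gene pairs at large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .circstat import abs_phase_difference

logger = logging.getLogger(__name__)


def load_network(edge_list_path) -> nx.Graph:
    """Read a two-column TSV edge list into a simple undirected graph.

    Duplicate edges and self-loops are dropped (counts logged). Blank or
    malformed lines raise with the offending line number.
    """
    g = nx.Graph()
    n_self, n_dup, n_edges = 0, 0, 0
    with open(edge_list_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                raise ValueError(f"{edge_list_path}: blank line at line {lineno}")
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{edge_list_path}: expected 2 columns at line {lineno}, got {len(parts)}")
            u, v = (p.strip() for p in parts)
            n_edges += 1
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    if n_edges == 0:
        raise ValueError(f"{edge_list_path}: empty edge list")
    if n_self or n_dup:
        logger.info("load_network: dropped %d self-loop(s) and %d duplicate edge(s)", n_self, n_dup)
    return g


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component (ties: smallest member node)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(net))
    # tie-break: among max-size components, lexicographically smallest member
    max_size = max(len(c) for c in comps)
    ties = [c for c in comps if len(c) == max_size]
    best = min(ties, key=lambda c: str(min(c, key=str)))
    return net.subgraph(best).copy()


def write_network(net: nx.Graph, path) -> None:
    """Write the graph as a two-column TSV edge list (sorted, deterministic)."""
    with open(path, "w") as fh:
        for u, v in sorted((sorted((str(a), str(b))) for a, b in net.edges()), key=tuple):
            fh.write(f"{u}\t{v}\n")


def _distance_matrix(net: nx.Graph, nodelist) -> np.ndarray:
    """All-pairs unweighted geodesic distances (float, inf = disconnected)."""
    adj = nx.to_scipy_sparse_array(net, nodelist=nodelist, format="csr")
    return shortest_path(adj, method="D", unweighted=True, directed=False)


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def degree_comparison(net: nx.Graph, cyclers_18, cyclers_25) -> dict:
    """KS comparisons of degree distributions: 18 vs 25, 18 vs all, 25 vs all."""
    deg = dict(net.degree())
    sets = {"18C": list(cyclers_18), "25C": list(cyclers_25)}
    for name, s in sets.items():
        if not s:
            raise ValueError(f"empty cycler set for {name}")
        missing = [g for g in s if g not in deg]
        if missing:
            raise ValueError(f"cyclers not on network ({name}): {missing[:3]}")
    d18 = np.array([deg[g] for g in sets["18C"]], dtype=float)
    d25 = np.array([deg[g] for g in sets["25C"]], dtype=float)
    dall = np.array(list(deg.values()), dtype=float)
    out = {}
    for key, (a, b) in {
        "18C_vs_25C": (d18, d25),
        "18C_vs_all": (d18, dall),
        "25C_vs_all": (d25, dall),
    }.items():
        res = stats.ks_2samp(a, b)
        out[key] = KSResult(float(res.statistic), float(res.pvalue), a.size, b.size)
    return out


@dataclass
class LocalizationResult:
    statistic: float
    p_value: float
    n_pairs_cyclers: int
    n_pairs_all: int
    n_disconnected: int


def _condensed_finite(dist: np.ndarray):
    iu = np.triu_indices(dist.shape[0], 1)
    d = dist[iu]
    finite = np.isfinite(d)
    return d[finite], int((~finite).sum())


def localization_test(net: nx.Graph, cyclers, all_genes_on_net=None) -> LocalizationResult:
    """Are cyclers closer to each other than gene pairs at large?

    One-sided Wilcoxon rank-sum (Mann-Whitney U, alternative 'less') of
    pairwise geodesic distances among cyclers against pairwise distances
    among all network genes. Disconnected pairs are excluded and counted.
    """
    cyclers = list(cyclers)
    if len(cyclers) < 2:
        raise ValueError("need at least 2 cyclers")
    nodes = list(all_genes_on_net) if all_genes_on_net is not None else sorted(net.nodes(), key=str)
    missing = [g for g in cyclers if g not in net]
    if missing:
        raise ValueError(f"cyclers not on network: {missing[:3]}")
    dist_all = _distance_matrix(net, nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    cyc_ix = np.array([idx[g] for g in cyclers])
    d_cyc, bad_cyc = _condensed_finite(dist_all[np.ix_(cyc_ix, cyc_ix)])
    d_all, bad_all = _condensed_finite(dist_all)
    if d_cyc.size == 0:
        raise ValueError("all cycler pairs disconnected")
    res = stats.mannwhitneyu(d_cyc, d_all, alternative="less")
    return LocalizationResult(
        float(res.statistic), float(res.pvalue), d_cyc.size, d_all.size, bad_cyc + bad_all
    )


@dataclass
class PhaseProfile:
    """Per-distance |dphi| distributions, medians and the slope regression."""

    distances: np.ndarray  # bins with >= 1 pair, ascending
    medians: np.ndarray  # hours, per bin
    pair_counts: np.ndarray
    dphi_values: dict  # distance -> array of |dphi| hours
    slope: float  # hours per geodesic step
    intercept: float
    slope_p: float
    df: int
    d_max: int
    dropped_bins: list = field(default_factory=list)


def _profile_from_condensed(dphi_cond, dist_cond, d_max):
    dists, medians, counts, values = [], [], [], {}
    for d in range(1, d_max + 1):
        sel = dist_cond == d
        n = int(sel.sum())
        if n == 0:
            continue
        dists.append(d)
        counts.append(n)
        vals = dphi_cond[sel]
        values[d] = vals
        medians.append(float(np.median(vals)))
    return np.array(dists), np.array(medians), np.array(counts), values


def phase_distance_profile(net: nx.Graph, phases: dict, d_max: int = 6) -> PhaseProfile:
    """Median |dphi| per geodesic distance 1..d_max, with a slope regression.

    ``phases`` maps gene -> phase in hours; all keys must be network nodes.
    Pairs beyond d_max or disconnected are excluded. The per-bin medians
    are regressed on distance by OLS; the slope p-value is the two-sided
    t-test with df = (number of non-empty bins) - 2. Empty bins are dropped
    from the regression and recorded in ``dropped_bins``.
    """
    genes = sorted(phases, key=str)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes with phases")
    missing = [g for g in genes if g not in net]
    if missing:
        raise ValueError(f"phase map keys not on network: {missing[:3]}")
    phi = np.array([phases[g] for g in genes], dtype=float)
    dist = _distance_matrix(net, genes) if len(genes) == net.number_of_nodes() else None
    if dist is None:
        # distances must run through the full graph, not just mapped genes
        index = {g: i for i, g in enumerate(genes)}
        dist = np.full((len(genes), len(genes)), np.inf)
        for g in genes:
            lengths = nx.single_source_shortest_path_length(net, g, cutoff=d_max)
            i = index[g]
            for node, d in lengths.items():
                j = index.get(node)
                if j is not None:
                    dist[i, j] = d
    iu = np.triu_indices(len(genes), 1)
    dist_cond = dist[iu]
    dphi_cond = abs_phase_difference(phi[iu[0]], phi[iu[1]])
    finite = np.isfinite(dist_cond)
    dist_cond = np.where(finite, dist_cond, -1).astype(int)
    return _finalize_profile(dphi_cond, dist_cond, d_max)


def _finalize_profile(dphi_cond, dist_cond, d_max) -> PhaseProfile:
    dists, medians, counts, values = _profile_from_condensed(dphi_cond, dist_cond, d_max)
    if dists.size == 0:
        raise ValueError(f"no gene pair within geodesic distance {d_max}")
    dropped = [d for d in range(1, d_max + 1) if d not in set(dists.tolist())]
    if dropped:
        logger.info("phase_distance_profile: empty distance bin(s) %s dropped from regression", dropped)
    if dists.size >= 3:
        reg = stats.linregress(dists.astype(float), medians)
        slope, intercept, slope_p = float(reg.slope), float(reg.intercept), float(reg.pvalue)
        df = int(dists.size - 2)
    else:
        slope = intercept = slope_p = float("nan")
        df = 0
    return PhaseProfile(
        distances=dists,
        medians=medians,
        pair_counts=counts,
        dphi_values=values,
        slope=slope,
        intercept=intercept,
        slope_p=slope_p,
        df=df,
        d_max=d_max,
        dropped_bins=dropped,
    )


@dataclass
class PermutationNull:
    """Permutation-null medians per distance with quantiles and p-values."""

    n_perm: int
    seed: int
    distances: np.ndarray  # observed non-empty bins
    observed_medians: np.ndarray
    null_medians: np.ndarray  # (n_perm, n_bins), NaN where a draw had an empty bin
    q025: np.ndarray
    q975: np.ndarray
    p_two_sided: np.ndarray
    profile: PhaseProfile


def permutation_null(
    net: nx.Graph, phases: dict, n_perm: int = 5000, d_max: int = 6, seed: int = 0
) -> PermutationNull:
    """Null distribution of per-distance median |dphi| under random placement.

    Each permutation draws ``len(phases)`` node positions uniformly without
    replacement from the graph's nodes and attaches the observed phase
    multiset to them in fixed order, then recomputes per-distance medians.
    Reports per-distance 0.025/0.975 null quantiles and the add-one
    empirical two-sided p-value ``2*min(r, 1-r)`` with
    ``r = (1 + #{null <= observed}) / (n_perm + 1)``. Deterministic for a
    fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100: null quantiles would be unstable")
    observed = phase_distance_profile(net, phases, d_max=d_max)
    nodes = sorted(net.nodes(), key=str)
    n = len(nodes)
    m = len(phases)
    if m > n:
        raise ValueError("more phases than network nodes")
    dist_full = _distance_matrix(net, nodes)
    phi = np.array([phases[g] for g in sorted(phases, key=str)], dtype=float)
    iu = np.triu_indices(m, 1)
    dphi_cond = abs_phase_difference(phi[iu[0]], phi[iu[1]])  # fixed across perms

    rng = np.random.default_rng(seed)
    bins = observed.distances
    null_meds = np.full((n_perm, bins.size), np.nan)
    for b in range(n_perm):
        pos = rng.choice(n, size=m, replace=False)
        sub = dist_full[np.ix_(pos, pos)][iu]
        ok = np.isfinite(sub)
        sub_i = np.where(ok, sub, -1).astype(int)
        for j, d in enumerate(bins):
            sel = sub_i == d
            if sel.any():
                null_meds[b, j] = np.median(dphi_cond[sel])

    q025 = np.nanquantile(null_meds, 0.025, axis=0)
    q975 = np.nanquantile(null_meds, 0.975, axis=0)
    valid = ~np.isnan(null_meds)
    n_valid = valid.sum(axis=0)
    le = np.nansum(null_meds <= observed.medians[None, :], axis=0)
    r = (1.0 + le) / (n_valid + 1.0)
    p = 2.0 * np.minimum(r, 1.0 - r)
    p = np.minimum(p, 1.0)
    return PermutationNull(
        n_perm=n_perm,
        seed=seed,
        distances=bins,
        observed_medians=observed.medians,
        null_medians=null_meds,
        q025=q025,
        q975=q975,
        p_two_sided=p,
        profile=observed,
    )


def profile_table(null: PermutationNull) -> pd.DataFrame:
    """Tidy per-distance table: counts, medians, null quantiles, p-values."""
    return pd.DataFrame(
        {
            "distance": null.distances,
            "n_pairs": null.profile.pair_counts,
            "median_dphi": null.observed_medians,
            "null_q025": null.q025,
            "null_q975": null.q975,
            "p_two_sided": null.p_two_sided,
        }
    )
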