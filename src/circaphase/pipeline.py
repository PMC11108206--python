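"""End-to-end orchestration: simulate/ingest -> detect -> phase stats -> network test.

The pipeline mirrors the analysis workflow: filter genes by expression,
fit harmonic regressions per experiment and condition, call consensus
cyclers with the dual-experiment criterion and price the analytic FDR,
characterize the consensus phase distributions (two-sample Watson-Wheeler,
von Mises mixture peaks, circular correlation and phase-advance sign test
for common cyclers), and finally test phase organization on the gene
network (per-distance median |dphi|, slope regression, permutation null).
All randomness fans out from one seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, circstat, ingest, netphase, rhythm, simdata

CONDITIONS = ("18C", "25C")
EXPERIMENTS = ("V1", "V2")


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    matrix_path: str | None = None
    samplesheet_path: str | None = None
    network_path: str | None = None
    truth_path: str | None = None
    p_threshold: float = 0.1
    dphi_threshold: float = 3.0
    tpm_threshold: float = 5.0
    d_max: int = 6
    n_perm: int = 5000
    seed: int = 0
    outdir: str = "results"
    skip_network: bool = False
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.dphi_threshold <= 0 or self.tpm_threshold < 0:
            raise ValueError("thresholds must be positive")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")


def _child_seeds(seed: int, n: int = 8) -> list:
    """Deterministic per-stage child seeds below 2**31."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_bundle(sim_config: simdata.SimConfig, net_config: simdata.NetSimConfig | None = None,
                    network_condition: str = "18C"):
    """Simulate a full study: four matrices, truth, and a gene-id network.

    The network (if requested) places the genes cycling at
    ``network_condition`` on the graph so that their *true* phases follow
    the graph's assortativity mode: placed nodes are matched to cycling
    genes by phase rank, remaining nodes get background ids.
    """
    mats, truth = simdata.simulate_study(sim_config)
    graph = None
    if net_config is not None:
        col = f"phase_{network_condition[:2]}"
        cyc = truth[truth[f"is_cycling_{network_condition[:2]}"]]
        phases = cyc[col].to_numpy()
        g, placement = simdata.simulate_network(net_config, phases)
        anchor = float(phases[0]) if phases.size else 0.0
        placed = sorted(placement, key=lambda n: ((placement[n] - anchor) % 24.0, str(n)))
        genes = list(cyc.index[np.argsort((phases - anchor) % 24.0, kind="stable")])
        mapping = dict(zip(placed, genes))
        bg = iter(range(g.number_of_nodes()))
        relabel = {node: mapping.get(node, None) or f"bg{next(bg):05d}" for node in g.nodes()}
        graph = type(g)()
        graph.add_nodes_from(relabel.values())
        graph.add_edges_from((relabel[u], relabel[v]) for u, v in g.edges())
    return mats, truth, graph


def _combine_matrices(mats: dict) -> ingest.ExpressionMatrix:
    values = pd.concat([m.values for m in mats.values()], axis=1)
    samples = pd.concat([m.samples for m in mats.values()], ignore_index=True)
    return ingest.ExpressionMatrix(values, samples)


def write_simulation(mats, truth, graph, outdir) -> dict:
    """Write a simulated bundle (matrix TSV, sheet CSV, truth CSV, edges TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined = _combine_matrices(mats)
    paths = {
        "matrix": outdir / "expression_tpm.tsv",
        "samplesheet": outdir / "samples.csv",
        "truth": outdir / "ground_truth.csv",
    }
    ingest.write_expression(combined, paths["matrix"], paths["samplesheet"])
    truth.to_csv(paths["truth"])
    if graph is not None:
        paths["network"] = outdir / "network_edges.tsv"
        netphase.write_network(graph, paths["network"])
    return {k: str(v) for k, v in paths.items()}


def run_pipeline(config: RunConfig, mats: dict | None = None, network=None) -> dict:
    """Execute the full analysis and write the report bundle to outdir.

    Either pass in-memory matrices (dict keyed by (experiment, condition))
    or paths in the config. Returns the bundle: fits, cyclers, phase
    statistics, network results and the run manifest. Deterministic for a
    fixed config + seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)
    stage = "ingest"
    try:
        if mats is None:
            if not config.matrix_path or not config.samplesheet_path:
                raise ValueError("matrix_path and samplesheet_path required when no matrices given")
            combined = ingest.read_expression(config.matrix_path, config.samplesheet_path)
            mats = {
                (e, c): combined.subset(experiment=e, condition=c)
                for e in EXPERIMENTS
                for c in CONDITIONS
            }
        kept = ingest.filter_genes(mats, tpm_threshold=config.tpm_threshold)
        mats = {k: ingest.ExpressionMatrix(m.values.loc[kept], m.samples) for k, m in mats.items()}

        stage = "detect"
        fits = {
            k: rhythm.fit_experiment(m, log_transform=config.log_transform) for k, m in mats.items()
        }
        cyclers = {}
        fdr = {}
        for cond in CONDITIONS:
            cyc = rhythm.consensus_cyclers(
                fits[("V1", cond)], fits[("V2", cond)], config.p_threshold, config.dphi_threshold
            )
            cyclers[cond] = cyc
            efp = rhythm.expected_false_positives(len(kept), config.p_threshold, config.dphi_threshold)
            fdr[cond] = {
                "n_detected": len(cyc),
                "expected_fp": efp,
                "fdr": rhythm.fdr_estimate(efp, len(cyc)) if len(cyc) else None,
            }

        stage = "phases"
        phase_stats = _phase_statistics(cyclers, seeds[1])

        network_results = None
        if not config.skip_network:
            stage = "network"
            if network is None:
                if not config.network_path:
                    raise FileNotFoundError("network stage enabled but no network_path given")
                if not Path(config.network_path).exists():
                    raise FileNotFoundError(f"network file not found: {config.network_path}")
                network = netphase.load_network(config.network_path)
            network_results = _network_analysis(network, cyclers, config, seeds[2])

        stage = "report"
        bundle = {
            "config": asdict(config),
            "n_genes_filtered": len(kept),
            "fits": fits,
            "cyclers": cyclers,
            "fdr": fdr,
            "phase_stats": phase_stats,
            "network": network_results,
        }
        _write_bundle(bundle, outdir)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _phase_statistics(cyclers: dict, seed: int) -> dict:
    out = {}
    ph18 = cyclers["18C"]["consensus_phase"].to_numpy()
    ph25 = cyclers["25C"]["consensus_phase"].to_numpy()
    if ph18.size >= 10 and ph25.size >= 10:
        w, p = circstat.watson_wheeler_test(ph18, ph25)
        out["watson_wheeler"] = {"W": w, "p": p, "n_18": int(ph18.size), "n_25": int(ph25.size)}
    out["mixture_peaks"] = {}
    for cond, ph in (("18C", ph18), ("25C", ph25)):
        if ph.size >= 10:
            mix = circstat.fit_vonmises_mixture(ph, k=2, seed=seed)
            out["mixture_peaks"][cond] = {
                "means": mix.means_.tolist(),
                "kappas": mix.kappas_.tolist(),
                "weights": mix.weights_.tolist(),
                "log_likelihood": mix.log_likelihood_,
            }
    common = cyclers["18C"].index.intersection(cyclers["25C"].index)
    out["n_common"] = int(len(common))
    if len(common) >= 5:
        c18 = cyclers["18C"].loc[common]
        c25 = cyclers["25C"].loc[common]
        out["circular_correlation"] = circstat.circular_correlation(
            c18["consensus_phase"], c25["consensus_phase"]
        )
        out["phase_advance"] = {}
        for exp, col in (("V1", "phase_v1"), ("V2", "phase_v2")):
            d = circstat.signed_phase_difference(c18[col].to_numpy(), c25[col].to_numpy())
            d = np.atleast_1d(d)
            out["phase_advance"][exp] = {
                "n_advance": int((d > 0).sum()),
                "n_total": int(d.size),
                "median_shift_hours": float(np.median(d)),
                "p_median_test": circstat.circular_median_test(d),
            }
    return out


def _network_analysis(network, cyclers: dict, config: RunConfig, seed: int) -> dict:
    lcc = netphase.largest_connected_component(network)
    on_net = {
        cond: {g: float(p) for g, p in cyc["consensus_phase"].items() if g in lcc}
        for cond, cyc in cyclers.items()
    }
    out = {
        "n_nodes": lcc.number_of_nodes(),
        "n_edges": lcc.number_of_edges(),
        "n_cyclers_on_network": {c: len(v) for c, v in on_net.items()},
    }
    if all(len(v) >= 2 for v in on_net.values()):
        deg = netphase.degree_comparison(lcc, list(on_net["18C"]), list(on_net["25C"]))
        out["degree_ks"] = {k: asdict(v) for k, v in deg.items()}
    out["profiles"] = {}
    for i, cond in enumerate(CONDITIONS):
        phases = on_net[cond]
        if len(phases) < 2:
            continue
        null = netphase.permutation_null(
            lcc, phases, n_perm=config.n_perm, d_max=config.d_max, seed=seed + i
        )
        loc = netphase.localization_test(lcc, list(phases))
        out["profiles"][cond] = {
            "table": netphase.profile_table(null),
            "slope": null.profile.slope,
            "slope_p": null.profile.slope_p,
            "df": null.profile.df,
            "localization": asdict(loc),
        }
    return out


def _write_bundle(bundle: dict, outdir: Path) -> None:
    for (exp, cond), df in bundle["fits"].items():
        df.to_csv(outdir / f"fits_{exp}_{cond}.csv")
    for cond, df in bundle["cyclers"].items():
        df.to_csv(outdir / f"cyclers_{cond}.csv")
    net = bundle.get("network")
    if net:
        for cond, prof in net["profiles"].items():
            prof["table"].to_csv(outdir / f"network_profile_{cond}.csv", index=False)
    text, summary = report_summary(bundle)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "summary.txt").write_text(text)
    manifest = {
        "package_version": __version__,
        "seed": bundle["config"]["seed"],
        "thresholds": {
            k: bundle["config"][k]
            for k in ("p_threshold", "dphi_threshold", "tpm_threshold", "d_max", "n_perm")
        },
        "n_genes_filtered": bundle["n_genes_filtered"],
        "n_cyclers": {c: len(bundle["cyclers"][c]) for c in CONDITIONS},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def report_summary(bundle: dict):
    """One-page human-readable summary and its JSON twin."""
    for key in ("cyclers", "fdr", "phase_stats"):
        if key not in bundle:
            raise ValueError(f"incomplete bundle: missing {key!r}")
    cyclers = bundle["cyclers"]
    summary = {
        "n_genes_filtered": bundle["n_genes_filtered"],
        "n_cyclers": {c: len(cyclers[c]) for c in CONDITIONS},
        "n_common_cyclers": bundle["phase_stats"].get("n_common"),
        "fdr": {
            c: {k: v for k, v in bundle["fdr"][c].items()} for c in CONDITIONS
        },
        "phase_stats": {
            k: v for k, v in bundle["phase_stats"].items() if k != "n_common"
        },
        "network": None,
    }
    net = bundle.get("network")
    if net:
        summary["network"] = {
            "n_nodes": net["n_nodes"],
            "n_edges": net["n_edges"],
            "n_cyclers_on_network": net["n_cyclers_on_network"],
            "profiles": {
                cond: {
                    "slope": prof["slope"],
                    "slope_p": prof["slope_p"],
                    "df": prof["df"],
                    "significant_distances": [
                        int(d)
                        for d, p in zip(prof["table"]["distance"], prof["table"]["p_two_sided"])
                        if p < 0.05
                    ],
                }
                for cond, prof in net["profiles"].items()
            },
        }
    lines = [
        "circaphase run summary",
        "=" * 40,
        f"genes passing expression filter: {summary['n_genes_filtered']}",
    ]
    for c in CONDITIONS:
        fdr = bundle["fdr"][c]
        fdr_txt = f"{fdr['fdr']:.3f}" if fdr["fdr"] is not None else "n/a"
        lines.append(
            f"cyclers at {c}: {fdr['n_detected']}"
            f" (expected false positives {fdr['expected_fp']:.2f}, FDR {fdr_txt})"
        )
    lines.append(f"common cyclers: {summary['n_common_cyclers']}")
    ps = bundle["phase_stats"]
    if "watson_wheeler" in ps:
        ww = ps["watson_wheeler"]
        lines.append(f"Watson-Wheeler 18C vs 25C: W={ww['W']:.2f}, p={ww['p']:.3g}")
    for cond, mx in ps.get("mixture_peaks", {}).items():
        peaks = ", ".join(f"ZT{m:.2f}" for m in mx["means"])
        lines.append(f"phase peaks at {cond}: {peaks}")
    if "circular_correlation" in ps:
        lines.append(f"circular correlation of common cyclers: {ps['circular_correlation']:.3f}")
    for exp, adv in ps.get("phase_advance", {}).items():
        lines.append(
            f"phase advance at 18C ({exp}): {adv['n_advance']}/{adv['n_total']} genes,"
            f" median {adv['median_shift_hours']:+.2f} h, p={adv['p_median_test']:.3g}"
        )
    if summary["network"]:
        nw = summary["network"]
        lines.append(f"network: {nw['n_nodes']} nodes / {nw['n_edges']} edges (largest component)")
        for cond, prof in nw["profiles"].items():
            lines.append(
                f"phase-distance slope at {cond}: {prof['slope']:.3f} h/step"
                f" (p={prof['slope_p']:.3g}, df={prof['df']};"
                f" significant distances: {prof['significant_distances'] or 'none'})"
            )
    return "\n".join(lines) + "\n", summary
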