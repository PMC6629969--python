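"""Workflow orchestration: fit -> base network -> map -> evolve -> compare.

Mirrors the three-stage modelling workflow: (A) score candidate random
networks against the reference connectome, (B) estimate the utility
coefficients from the reference by linear programming, (C) build the
strategic model on a degree-matched directed Havel-Hakimi base network and
run the pairwise-stability dynamics.  One global seed drives everything;
per-stage child seeds are derived deterministically so stages can be rerun
in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import fitting, game, generators, metrics, netio

logger = logging.getLogger("netgame")


def child_seeds(seed: int, k: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from one seed."""
    return [int(s) for s in np.random.default_rng(seed).integers(2**31, size=k)]


@dataclass
class PipelineConfig:
    reference_network: str | Path
    attributes: str | Path
    out_dir: str | Path
    seed: int
    undirected_reference: bool = False
    fit_convention: str = "as_printed"
    fit_mode: str = "soft"
    fit_bounds: tuple[float, float] = (-1.0, 1.0)
    fit_normalize: bool = True
    evolve_max_sweeps: int = 60
    evolve_deletion_rule: str = "either"
    evolve_edge_direction: str = "coin"
    coefficients: dict | None = None  # skip the fit stage when given


@dataclass
class PipelineResult:
    coefficients: game.UtilityCoefficients
    fit: fitting.FitResult | None
    base: nx.DiGraph
    evolution: game.EvolutionResult
    reports: dict[str, metrics.MetricsReport]
    comparison: "object"  # pandas DataFrame
    stable: bool


def run_pipeline(reference: nx.DiGraph, attrs: netio.AttributeTable, *,
                 seed: int, out_dir: str | Path | None = None,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run stages B and C end to end on an in-memory reference network."""
    cfg = config
    fit_convention = cfg.fit_convention if cfg else "as_printed"
    fit_mode = cfg.fit_mode if cfg else "soft"
    fit_bounds = cfg.fit_bounds if cfg else (-1.0, 1.0)
    fit_normalize = cfg.fit_normalize if cfg else True
    game_cfg = game.GameConfig(
        deletion_rule=cfg.evolve_deletion_rule if cfg else "either",
        edge_direction=cfg.evolve_edge_direction if cfg else "coin",
        max_sweeps=cfg.evolve_max_sweeps if cfg else 60,
    )
    s_fit, s_gen, s_evolve = child_seeds(seed, 3)

    # stage B: estimate coefficients from the reference network
    fit_result = None
    if cfg is not None and cfg.coefficients is not None:
        coeffs = game.UtilityCoefficients.from_dict(cfg.coefficients)
    else:
        logger.info("pipeline: building constraints on the reference network")
        constraints = fitting.build_constraints(reference, attrs,
                                                convention=fit_convention)
        fit_result = fitting.fit_coefficients(
            constraints, bounds=fit_bounds, mode=fit_mode, normalize=fit_normalize
        )
        if fit_result.coefficients is None:
            raise RuntimeError(f"fit stage failed: {fit_result.solver_status}")
        # evolve consumes raw-unit attributes, so map a normalized estimate back
        coeffs = fit_result.raw_coefficients()
        logger.info("pipeline: fitted coefficients %s", coeffs.to_dict())

    # stage C1: degree-matched directed Havel-Hakimi base network
    nodes = sorted(reference.nodes)
    in_seq = [reference.in_degree(v) for v in nodes]
    out_seq = [reference.out_degree(v) for v in nodes]
    base = generators.havel_hakimi_directed(
        in_seq, out_seq, seed=s_gen, ids=[f"h{k}" for k in range(len(nodes))]
    )

    # stage C2: pull real attributes onto base nodes by degree rank
    mapping = game.map_nodes_by_degree(base, reference)
    base_attrs = game.transfer_attributes(mapping, attrs)

    # stage C3: evolve to pairwise stability
    evo = game.evolve(base, base_attrs, coeffs, config=game_cfg, seed=s_evolve)
    logger.info("pipeline: evolve made %d moves in %d sweeps (converged=%s)",
                len(evo.moves), evo.sweeps, evo.converged)
    stable = game.is_pairwise_stable(evo.graph, base_attrs, coeffs,
                                     config=evo.config).stable

    reports = {
        "reference": metrics.compute_metrics(reference, directed=True,
                                             label="reference"),
        "havel_hakimi_base": metrics.compute_metrics(base, directed=True,
                                                     label="havel_hakimi_base"),
        "strategic_model": metrics.compute_metrics(evo.graph, directed=True,
                                                   label="strategic_model"),
    }
    comparison = metrics.compare_networks(list(reports.values()))
    result = PipelineResult(
        coefficients=coeffs, fit=fit_result, base=base, evolution=evo,
        reports=reports, comparison=comparison, stable=stable,
    )
    if out_dir is not None:
        _write_pipeline_outputs(result, attrs, Path(out_dir))
    return result


def _write_pipeline_outputs(result: PipelineResult, attrs, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    netio.write_outputs(
        result.evolution.graph,
        {
            "coefficients": result.coefficients.to_dict(),
            "converged": result.evolution.converged,
            "sweeps": result.evolution.sweeps,
            "n_moves": len(result.evolution.moves),
            "pairwise_stable": result.stable,
            **(
                {
                    "fit_status": result.fit.solver_status,
                    "fit_n_satisfied": result.fit.n_satisfied,
                    "fit_n_violated": result.fit.n_violated,
                }
                if result.fit
                else {}
            ),
        },
        out_dir,
        stem="strategic_model",
    )
    netio.write_edge_list(result.base, out_dir / "havel_hakimi_base.edges")
    for name, rep in result.reports.items():
        netio.write_report(rep.to_dict(), out_dir / f"metrics_{name}.json")
    result.comparison.to_csv(out_dir / "comparison.csv")
    import csv

    with open(out_dir / "moves.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sweep", "node_i", "node_j", "action", "gain_i", "gain_j"])
        for mv in result.evolution.moves:
            w.writerow([mv.sweep, mv.pair[0], mv.pair[1], mv.action,
                        mv.gain_i, mv.gain_j])


BASELINE_KINDS_UNDIRECTED = ("watts_strogatz_distance", "expected_degree",
                             "powerlaw_cluster")
BASELINE_KINDS_DIRECTED = ("havel_hakimi_directed", "scale_free_directed",
                           "erdos_renyi_directed")


def baseline_params(reference: nx.DiGraph, kind: str, *,
                    er_p: float = 0.5, ws_k: int = 5, ws_rewire_p: float = 0.5,
                    pl_m: int = 6, pl_triangle_p: float = 0.2,
                    sf_alpha: float = 0.15, sf_beta: float = 0.8,
                    sf_gamma: float = 0.05, sf_delta_in: float = 0.2,
                    sf_delta_out: float = 0.0) -> dict:
    """Reference-matched parameters for one baseline generator."""
    nodes = sorted(reference.nodes)
    n = len(nodes)
    und = reference.to_undirected()
    if kind == "watts_strogatz_distance":
        return {"k": min(ws_k, n - 1), "rewire_p": ws_rewire_p}
    if kind == "expected_degree":
        return {"degree_seq": [und.degree(v) for v in nodes], "ids": nodes}
    if kind == "powerlaw_cluster":
        return {"n": n, "m": min(pl_m, n - 1), "triangle_p": pl_triangle_p}
    if kind == "havel_hakimi_directed":
        return {"in_seq": [reference.in_degree(v) for v in nodes],
                "out_seq": [reference.out_degree(v) for v in nodes],
                "ids": nodes}
    if kind == "scale_free_directed":
        return {"n_target": n, "alpha": sf_alpha, "beta": sf_beta,
                "gamma": sf_gamma, "delta_in": sf_delta_in,
                "delta_out": sf_delta_out,
                "edge_budget": reference.number_of_edges()}
    if kind == "erdos_renyi_directed":
        return {"n": n, "p": er_p}
    raise ValueError(kind)


def run_baselines(reference: nx.DiGraph, attrs: netio.AttributeTable, *,
                  seed: int, out_dir: str | Path | None = None,
                  er_p: float = 0.5) -> dict:
    """Generate the six reference-matched random networks and the two
    comparison tables (undirected kinds vs the undirected reference,
    directed kinds vs the directed reference)."""
    seeds = child_seeds(seed, 6)
    und_reports = [metrics.compute_metrics(reference, directed=False,
                                           label="reference")]
    dir_reports = [metrics.compute_metrics(reference, directed=True,
                                           label="reference")]
    graphs = {}
    for kind, s in zip(BASELINE_KINDS_UNDIRECTED + BASELINE_KINDS_DIRECTED, seeds):
        params = baseline_params(reference, kind, er_p=er_p)
        spec = generators.GeneratorSpec(kind=kind, params=params, seed=s)
        g = generators.from_spec(spec, attrs=attrs)
        graphs[kind] = g
        if kind in BASELINE_KINDS_UNDIRECTED:
            und_reports.append(metrics.compute_metrics(g, directed=False, label=kind))
        else:
            dir_reports.append(metrics.compute_metrics(g, directed=True, label=kind))
    und_table = metrics.compare_networks(und_reports)
    dir_table = metrics.compare_networks(dir_reports)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        und_table.to_csv(out_dir / "baselines_undirected.csv")
        dir_table.to_csv(out_dir / "baselines_directed.csv")
        for kind, g in graphs.items():
            gg = nx.DiGraph(g) if not g.is_directed() else g
            netio.write_edge_list(gg, out_dir / f"baseline_{kind}.edges")
    return {"graphs": graphs, "undirected_table": und_table,
            "directed_table": dir_table}
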