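"""End-to-end orchestration: matrices -> networks -> extraction -> reports.

``run_from_data`` drives the whole analysis on in-memory objects and is the
canonical API; ``run_pipeline`` wraps it with TSV input and report files.
All randomness flows from a single seed, and the written reports carry no
timestamps, so identical configurations produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .matrices import (AlterationCalls, ExpressionMatrix, MutationMatrix,
                       build_binary_mutation_matrix, collapse_metagenes,
                       compute_gene_universe)
from .networks import (IntegrativeNetwork, build_expression_network,
                       build_mutation_network, integrate_networks)
from .optimize import OptimizerConfig, sequential_extraction
from .stats import (CoreModule, coverage_statistic, exclusivity_test,
                    module_weight_sum, reduce_module, significance_test)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_from_data",
           "run_pipeline"]

_MAX_SEED = 2**31 - 1


@dataclass
class RunConfig:
    somatic: str | None = None
    cnv: str | None = None
    expression: str | None = None
    out_dir: str | None = None
    k: float = 1.0
    lambda_: float = 1.0
    beta: float = 1.0
    cutoff: float = 0.1
    network_source: str = "full"  # "full" | "mutation_only" | "no_cnv"
    exclude: list[str] = field(default_factory=list)
    p1_threshold: float = 0.05
    p2_threshold: float = 0.05
    n_perm_significance: int = 1000
    n_perm_exclusivity: int = 1000
    swaps_multiplier: int = 10
    exclusivity_statistic: str = "coverage"
    ttest: str = "pooled"  # "pooled" | "welch"
    edge_mode: str = "ordered"  # "ordered" | "plain"
    restrict_mutation_network_to_common_samples: bool = False
    tol: float = 1e-10
    max_iter: int = 10_000
    stop_on_insignificant: bool = True
    max_rounds: int | None = None
    export_networks: bool = False
    seed: int = 0


def validate_config(cfg: RunConfig) -> RunConfig:
    """Range-check every numeric field; returns the config unchanged."""
    problems = []
    if cfg.k <= 0:
        problems.append("k must be > 0")
    if cfg.lambda_ < 0:
        problems.append("lambda must be >= 0")
    if cfg.beta < 1:
        problems.append("beta must be >= 1")
    if not 0 < cfg.cutoff < 1:
        problems.append("cutoff must lie in (0, 1)")
    if cfg.network_source not in ("full", "mutation_only", "no_cnv"):
        problems.append(f"unknown network_source {cfg.network_source!r}")
    for name in ("p1_threshold", "p2_threshold"):
        if not 0 < getattr(cfg, name) <= 1:
            problems.append(f"{name} must lie in (0, 1]")
    for name in ("n_perm_significance", "n_perm_exclusivity", "max_iter",
                 "swaps_multiplier"):
        if getattr(cfg, name) < 1:
            problems.append(f"{name} must be >= 1")
    if cfg.tol <= 0:
        problems.append("tol must be > 0")
    if cfg.ttest not in ("pooled", "welch"):
        problems.append(f"unknown ttest flavour {cfg.ttest!r}")
    if cfg.edge_mode not in ("ordered", "plain"):
        problems.append(f"unknown edge_mode {cfg.edge_mode!r}")
    if cfg.exclusivity_statistic not in ("coverage", "exclusive_coverage"):
        problems.append(f"unknown exclusivity statistic {cfg.exclusivity_statistic!r}")
    for name in ("somatic", "cnv", "expression"):
        path = getattr(cfg, name)
        if path is not None and not Path(path).exists():
            problems.append(f"{name} file not found: {path}")
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    return cfg


@dataclass
class RunReport:
    modules: list[CoreModule]
    counts: dict[str, int]
    constants: dict[str, float]
    rounds: list[dict]
    config: dict

    def summary_lines(self) -> list[str]:
        lines = [
            "mutated core module report",
            f"  units in network |G|: {self.counts['n_units_G']}"
            f"  (|G0|={self.counts['n_units_G0']},"
            f" collapsed units={self.counts['n_units_collapsed']},"
            f" |S|={self.counts['n_common_samples']})",
            f"  certified modules: {len(self.modules)}",
        ]
        n_perm = self.config.get("n_perm_significance", 1000)

        def fmt_p(p, n):
            return f"< {1.0 / n:g}" if p == 0 else f"= {p:g}"

        for k, mod in enumerate(self.modules, start=1):
            lines.append(
                f"  module {k}: {', '.join(mod.unit_ids)}"
                f" | coverage {mod.coverage_rate}"
                f" | p1 {fmt_p(mod.p1, n_perm)}"
                f" | p2 {fmt_p(mod.p2, self.config.get('n_perm_exclusivity', 1000))}"
            )
        if self.config.get("network_source", "full") != "full":
            lines.append(f"  network source mode: {self.config['network_source']}")
        return lines

    def to_dict(self) -> dict:
        return {
            "modules": [m.to_dict() for m in self.modules],
            "counts": self.counts,
            "constants": self.constants,
            "rounds": self.rounds,
            "config": self.config,
        }


def _make_tester(net: IntegrativeNetwork, mn, a: MutationMatrix, cfg: RunConfig,
                 rng: np.random.Generator):
    """Wire the two statistical tests into a sequential-extraction tester."""

    def tester(cand, sol):
        sig = significance_test(cand, net, n_perm=cfg.n_perm_significance,
                                rng=np.random.default_rng(int(rng.integers(_MAX_SEED))))
        if sig.p1 >= cfg.p1_threshold:
            logger.info("candidate %s rejected: p1=%.3g", cand.unit_ids, sig.p1)
            return "rejected_p1", None
        units, exc, trace, certified = reduce_module(
            cand, sol, mn, a, alpha=cfg.p2_threshold,
            n_perm=cfg.n_perm_exclusivity, swaps_multiplier=cfg.swaps_multiplier,
            statistic=cfg.exclusivity_statistic,
            rng=np.random.default_rng(int(rng.integers(_MAX_SEED))),
        )
        if not certified or len(units) < 2:
            logger.info("candidate %s rejected: p2=%.3g after reduction to %s",
                        cand.unit_ids, exc.p2, units)
            return "rejected_p2", None
        member_genes = tuple(g for u in units for g in a.metagene_map[u])
        module = CoreModule(
            unit_ids=tuple(units),
            member_genes=member_genes,
            x_values={u: float(sol.x[u]) for u in units},
            C=module_weight_sum(cand, net),
            p1=sig.p1,
            p2=exc.p2,
            coverage=coverage_statistic(units, a),
            m=a.m,
            reduction_trace=trace,
        )
        return "certified", module

    return tester


def run_from_data(somatic: AlterationCalls, cnv: AlterationCalls | None,
                  expression: ExpressionMatrix, cfg: RunConfig | None = None) -> RunReport:
    """Run the full analysis on in-memory inputs and return the report."""
    cfg = cfg or RunConfig()
    validate_config(cfg)
    rng = np.random.default_rng(cfg.seed)

    use_cnv = cnv if cfg.network_source != "no_cnv" else None
    a0 = build_binary_mutation_matrix(somatic, use_cnv)
    a = collapse_metagenes(a0)
    universe = compute_gene_universe(a, expression)

    mn = build_mutation_network(
        a, universe,
        restrict_to_common_samples=cfg.restrict_mutation_network_to_common_samples,
    )
    en = None
    if cfg.network_source != "mutation_only":
        en = build_expression_network(a, expression, universe, ttest=cfg.ttest,
                                      edge_mode=cfg.edge_mode)
    source = "mutation_only" if cfg.network_source == "mutation_only" else "full"
    net = integrate_networks(en, mn, k=cfg.k, source=source)

    opt = OptimizerConfig(lambda_=cfg.lambda_, beta=cfg.beta, cutoff=cfg.cutoff,
                          tol=cfg.tol, max_iter=cfg.max_iter, seed=cfg.seed)
    tester = _make_tester(net, mn, a, cfg, rng)
    extraction = sequential_extraction(
        net, opt, tester, exclude=cfg.exclude,
        stop_on_insignificant=cfg.stop_on_insignificant,
        max_rounds=cfg.max_rounds,
    )

    counts = {
        "n_samples_A": a.m,
        "n_units_A0": len(a0.unit_ids),
        "n_units_collapsed": len(a.unit_ids),
        "n_units_G0": len(universe.g0),
        "n_units_G": len(universe.units),
        "n_common_samples": len(universe.samples),
    }
    rounds = [
        {
            "candidate_units": list(r.candidate_units),
            "x_values": r.x_values,
            "n_iterations": r.n_iterations,
            "objective": r.objective,
            "status": r.status,
        }
        for r in extraction.rounds
    ]
    config_dict = dataclasses.asdict(cfg)
    return RunReport(modules=extraction.modules, counts=counts,
                     constants=net.constants, rounds=rounds, config=config_dict)


def _write_report(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "modules.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    rows = ["\t".join(["module", "unit_ids", "member_genes", "C", "p1", "p2",
                       "coverage_rate"])]
    for k, mod in enumerate(report.modules, start=1):
        rows.append("\t".join([
            str(k), ",".join(mod.unit_ids), ",".join(mod.member_genes),
            f"{mod.C:.6g}", f"{mod.p1:.6g}", f"{mod.p2:.6g}", mod.coverage_rate,
        ]))
    (out_dir / "modules.tsv").write_text("\n".join(rows) + "\n")
    (out_dir / "summary.txt").write_text("\n".join(report.summary_lines()) + "\n")
    log_lines = [f"{k} = {v}" for k, v in sorted(report.counts.items())]
    log_lines += [f"{k} = {v:.6g}" for k, v in sorted(report.constants.items())]
    log_lines += [f"config.{k} = {v}" for k, v in sorted(report.config.items())]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")


def run_pipeline(cfg: RunConfig) -> RunReport:
    """File-based entry point: read TSV inputs, run, write the report."""
    validate_config(cfg)
    if cfg.somatic is None or cfg.expression is None:
        raise ValueError("somatic and expression input paths are required")
    somatic = cio.read_alteration_calls(cfg.somatic)
    cnv = cio.read_alteration_calls(cfg.cnv) if cfg.cnv else None
    expression = cio.read_expression_matrix(cfg.expression)
    report = run_from_data(somatic, cnv, expression, cfg)
    if cfg.out_dir:
        out_dir = Path(cfg.out_dir)
        _write_report(report, out_dir)
        if cfg.export_networks:
            a = collapse_metagenes(build_binary_mutation_matrix(
                somatic, cnv if cfg.network_source != "no_cnv" else None))
            universe = compute_gene_universe(a, expression)
            mn = build_mutation_network(a, universe)
            cio.write_network_tables(mn, out_dir / "mutation_network")
            if cfg.network_source != "mutation_only":
                en = build_expression_network(a, expression, universe,
                                              ttest=cfg.ttest, edge_mode=cfg.edge_mode)
                cio.write_network_tables(en, out_dir / "expression_network")
                net = integrate_networks(en, mn, k=cfg.k)
                cio.write_network_tables(net, out_dir / "integrative_network")
                cio.write_graphml(net, out_dir / "integrative_network.graphml",
                                  en=en, mn=mn)
    return report
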