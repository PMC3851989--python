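"""Constrained quadratic module extraction by multiplicative updates.

The module score is ``x' W x + lambda * c' x`` maximised over the simplex
``sum_i x_i^beta = 1, x >= 0``; ``beta = 1`` gives sparse solutions whose
support is read off as the module.  A local maximum is found with the
multiplicative (growth-transform) update

    x_i <- [ x_i * (2 (W x)_i + lambda c_i) / (2 x' W x + lambda c' x) ]^(1/beta)

which for ``beta = 1`` keeps the iterate exactly on the simplex and never
decreases the objective.  Modules are extracted sequentially: solve, take the
entries above the cutoff, hand the candidate to a statistical tester, remove
its vertices from the network, repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import IntegrativeNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizerConfig",
    "SolutionVector",
    "CandidateModule",
    "NoModuleAboveCutoff",
    "objective",
    "update_step",
    "solve_local_optimum",
    "extract_subnetwork",
    "sequential_extraction",
]


class NoModuleAboveCutoff(RuntimeError):
    """No entry of the converged solution exceeds the membership cutoff."""


@dataclass
class OptimizerConfig:
    lambda_: float = 1.0
    beta: float = 1.0
    cutoff: float = 0.1
    tol: float = 1e-10
    max_iter: int = 10_000
    init: str = "uniform"  # "uniform" | "random"
    n_restarts: int = 1
    support_size_limit: int | None = None
    seed: int | None = None

    def validate(self) -> "OptimizerConfig":
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")
        if self.init not in ("uniform", "random"):
            raise ValueError(f"unknown init rule {self.init!r}")
        return self


@dataclass
class SolutionVector:
    x: pd.Series
    objective_trace: np.ndarray
    iterations: int
    converged: bool
    max_simplex_error: float  # max |sum x_i^beta - 1| seen along the trace


@dataclass
class CandidateModule:
    unit_ids: tuple[str, ...]
    x_values: pd.Series
    source_network: IntegrativeNetwork

    def __len__(self) -> int:
        return len(self.unit_ids)


def _as_arrays(m: IntegrativeNetwork):
    return m.edge_weight.to_numpy(), m.vertex_weight.to_numpy()


def objective(x: np.ndarray, m: IntegrativeNetwork, lambda_: float) -> float:
    """x' W x + lambda * c' x (each symmetric edge counted twice)."""
    w, c = _as_arrays(m)
    x = np.asarray(x, dtype=float)
    if x.shape != c.shape:
        raise ValueError(f"x has shape {x.shape}, network has {c.shape[0]} units")
    return float(x @ w @ x + lambda_ * c @ x)


def update_step(x: np.ndarray, m: IntegrativeNetwork, config: OptimizerConfig) -> np.ndarray:
    """One multiplicative update; zeros stay zero, the simplex is preserved."""
    w, c = _as_arrays(m)
    x = np.asarray(x, dtype=float)
    num = x * (2.0 * (w @ x) + config.lambda_ * c)
    den = 2.0 * (x @ w @ x) + config.lambda_ * (c @ x)
    if den <= 0:
        raise ZeroDivisionError(
            "update denominator is zero; remove isolated zero-weight vertices"
        )
    y = num / den
    if config.beta != 1:
        y = y ** (1.0 / config.beta)
    return y


def _initial(n: int, config: OptimizerConfig, rng: np.random.Generator,
             perturb: float = 0.0) -> np.ndarray:
    if config.init == "random":
        x = rng.random(n) + 1e-3
    else:
        x = np.ones(n)
    if perturb > 0:
        x = x * (1.0 + perturb * rng.random(n))
    x = x / x.sum()
    if config.beta != 1:
        x = x / (x ** config.beta).sum() ** (1.0 / config.beta)
    return x


def _iterate(x: np.ndarray, m: IntegrativeNetwork, config: OptimizerConfig) -> SolutionVector:
    trace = [objective(x, m, config.lambda_)]
    simplex_err = abs((x ** config.beta).sum() - 1.0)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        x_new = update_step(x, m, config)
        trace.append(objective(x_new, m, config.lambda_))
        simplex_err = max(simplex_err, abs((x_new ** config.beta).sum() - 1.0))
        delta = np.abs(x_new - x).max()
        x = x_new
        if delta < config.tol:
            converged = True
            break
    if not converged:
        logger.warning("optimizer hit max_iter=%d without converging", config.max_iter)
    return SolutionVector(
        x=pd.Series(x, index=list(m.units)),
        objective_trace=np.asarray(trace),
        iterations=it,
        converged=converged,
        max_simplex_error=float(simplex_err),
    )


def solve_local_optimum(m: IntegrativeNetwork, config: OptimizerConfig | None = None) -> SolutionVector:
    """Iterate the multiplicative update to a local maximum.

    With random restarts the best local optimum by objective is kept.  If the
    converged support exceeds ``support_size_limit`` (a symmetry-tie guard),
    the solve is repeated once from a seeded epsilon-perturbed start.
    """
    config = (config or OptimizerConfig()).validate()
    rng = np.random.default_rng(config.seed)
    n = m.n_units
    if n == 0:
        raise ValueError("empty network")
    best: SolutionVector | None = None
    for _ in range(max(1, config.n_restarts)):
        sol = _iterate(_initial(n, config, rng), m, config)
        if best is None or sol.objective_trace[-1] > best.objective_trace[-1]:
            best = sol
    assert best is not None
    if (config.support_size_limit is not None
            and int((best.x > config.cutoff).sum()) > config.support_size_limit):
        logger.info("support exceeds %d units; re-solving from a perturbed start",
                    config.support_size_limit)
        sol = _iterate(_initial(n, config, rng, perturb=1e-6), m, config)
        if sol.objective_trace[-1] >= best.objective_trace[-1] - 1e-12:
            best = sol
    return best


def extract_subnetwork(sol: SolutionVector, config: OptimizerConfig | None = None) -> CandidateModule:
    """Units whose membership entry exceeds the cutoff."""
    config = (config or OptimizerConfig()).validate()
    mask = sol.x > config.cutoff
    if not mask.any():
        raise NoModuleAboveCutoff(
            f"no entry above cutoff {config.cutoff} (max x = {sol.x.max():.4g})"
        )
    units = tuple(sol.x.index[mask])
    return CandidateModule(unit_ids=units, x_values=sol.x[mask].copy(),
                           source_network=None)  # filled by caller


@dataclass
class ExtractionRound:
    candidate_units: tuple[str, ...]
    x_values: dict[str, float]
    n_iterations: int
    objective: float
    status: str  # "certified" | "rejected_p1" | "rejected_p2" | "singleton" | "untested"
    module: object | None = None


@dataclass
class ExtractionResult:
    modules: list = field(default_factory=list)
    rounds: list[ExtractionRound] = field(default_factory=list)


def sequential_extraction(m: IntegrativeNetwork, config: OptimizerConfig | None = None,
                          tester=None, *, exclude=(), stop_on_insignificant: bool = True,
                          max_rounds: int | None = None) -> ExtractionResult:
    """Solve / extract / test / remove until the network is exhausted.

    ``tester(candidate, solution)`` must return a pair ``(status, module)``
    with status "certified", "rejected_p1" or "rejected_p2"; with no tester
    every multi-unit candidate is recorded untested.  Excluded units are
    removed before the first round.  Candidate vertices are removed from the
    network whether or not they certify; by default extraction stops once a
    candidate fails the weight-sum significance test.
    """
    config = (config or OptimizerConfig()).validate()
    exclude = [u for u in exclude if u in set(m.units)]
    if exclude:
        logger.info("excluding %d units up front: %s", len(exclude), exclude)
        m = m.drop(exclude)
    result = ExtractionResult()
    net = m
    rounds = 0
    while net.n_units >= 2:
        if max_rounds is not None and rounds >= max_rounds:
            break
        rounds += 1
        sol = solve_local_optimum(net, config)
        try:
            cand = extract_subnetwork(sol, config)
        except NoModuleAboveCutoff:
            logger.info("round %d: no entry above cutoff; stopping", rounds)
            break
        cand.source_network = net
        record = ExtractionRound(
            candidate_units=cand.unit_ids,
            x_values={u: float(v) for u, v in cand.x_values.items()},
            n_iterations=sol.iterations,
            objective=float(sol.objective_trace[-1]),
            status="untested",
        )
        if len(cand) < 2:
            record.status = "singleton"
            result.rounds.append(record)
            net = net.drop(cand.unit_ids)
            continue
        if tester is not None:
            status, module = tester(cand, sol)
            record.status = status
            record.module = module
            result.rounds.append(record)
            if status == "certified" and module is not None:
                result.modules.append(module)
            net = net.drop(cand.unit_ids)
            if status == "rejected_p1" and stop_on_insignificant:
                logger.info("round %d: candidate failed the significance test; stopping",
                            rounds)
                break
        else:
            result.rounds.append(record)
            net = net.drop(cand.unit_ids)
    return result
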