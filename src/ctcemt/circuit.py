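"""Ensemble ODE simulation of the EMT regulatory circuit (RACIPE-style).

A gene regulatory network is simulated as a system of ordinary differential
equations in which every regulatory edge contributes a *shifted Hill*
factor

    HS(X; X0, n, λ) = λ + (1 − λ) / (1 + (X / X0)^n)

with baseline 1 at X = 0 and asymptote λ (fold-change: λ > 1 activation,
0 < λ < 1 inhibition).  Node dynamics are

    dY/dt = l_Y · ∏_{X → Y} HS(X) − k_Y · Y

with production rate ``l`` and linear degradation ``k``; unregulated nodes
settle at ``l / k``.

Rather than fitting one parameter set, an *ensemble* of models is sampled
uniformly from biologically plausible ranges (production U(1,100),
degradation U(0.1,1), integer Hill coefficients 1–6, fold-changes up to
100, thresholds around the regulator's median unregulated level — the
half-functional rule).  Each model is relaxed to steady state from many
random initial conditions, the distinct stable states are censused, and
expression patterns robust to parameter choice — e.g. the CDH1–VIM
anti-correlation generated by the miR-200/ZEB/GRHL2 double-negative
feedback core — emerge as properties of the network topology itself.
Ensembles are run in triplicate to guard against sampling artifacts.

The integrator is a positivity-preserving exponential-Euler relaxation
(exact for linear degradation) with a convergence test at fixed intervals;
any state it reports satisfies ‖dX/dt‖∞ < tol when re-evaluated
independently, so the scheme cannot converge to a non-fixed-point.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "ParameterRanges",
    "CircuitModel",
    "SteadyStateEnsemble",
    "shifted_hill",
    "load_emt_network",
    "sample_parameters",
    "build_rhs",
    "solve_steady_states",
    "run_ensemble",
    "expression_correlation",
]

ACTIVATION, INHIBITION = 1, -1


class CircuitError(ValueError):
    pass


@dataclass(frozen=True)
class GeneNetwork:
    """Signed regulatory edge list over named nodes."""

    nodes: tuple
    edges: tuple  # of (source, target, sign)

    def __post_init__(self):
        names = set(self.nodes)
        if len(names) != len(self.nodes):
            raise CircuitError("duplicate node names")
        seen = {}
        for s, t, sign in self.edges:
            if s not in names or t not in names:
                raise CircuitError(f"edge endpoint not a node: {(s, t)}")
            if sign not in (ACTIVATION, INHIBITION):
                raise CircuitError(f"edge sign must be +1 or -1, got {sign!r}")
            if (s, t) in seen and seen[(s, t)] != sign:
                raise CircuitError(f"contradictory duplicate edge {s}->{t}")
            seen[(s, t)] = sign

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict:
        return {n: i for i, n in enumerate(self.nodes)}

    def incoming(self, node: str) -> list:
        return [(s, t, sign) for (s, t, sign) in self.edges if t == node]

    @classmethod
    def from_tsv(cls, path) -> "GeneNetwork":
        df = pd.read_csv(path, sep="\t")
        need = {"source", "target", "sign"}
        if not need.issubset(df.columns):
            raise CircuitError(f"network TSV needs columns {sorted(need)}")
        edges = tuple(
            (str(r.source), str(r.target), int(r.sign)) for r in df.itertuples()
        )
        nodes = tuple(dict.fromkeys(
            [e[0] for e in edges] + [e[1] for e in edges]
        ))
        return cls(nodes=nodes, edges=edges)

    def to_tsv(self, path) -> None:
        pd.DataFrame(list(self.edges), columns=["source", "target", "sign"]).to_csv(
            path, sep="\t", index=False
        )


def load_emt_network() -> GeneNetwork:
    """The shipped EMT circuit: SNAIL-type input driving the miR-200/ZEB/GRHL2
    double-negative feedback core, with CDH1 and VIM as E/M readouts."""
    ref = importlib.resources.files("ctcemt") / "data" / "emt_network.tsv"
    with importlib.resources.as_file(ref) as p:
        return GeneNetwork.from_tsv(p)


@dataclass(frozen=True)
class ParameterRanges:
    """Uniform sampling ranges for the kinetic parameters."""

    production: tuple = (1.0, 100.0)
    degradation: tuple = (0.1, 1.0)
    hill: tuple = (1, 6)  # integer, inclusive
    fold_change: tuple = (1.0, 100.0)  # activation λ; inhibition uses 1/λ
    threshold_spread: tuple = (0.02, 1.98)  # × median unregulated level

    def validate(self) -> None:
        for name in ("production", "degradation", "fold_change", "threshold_spread"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise CircuitError(f"inverted or non-positive range for {name}")
        lo, hi = self.hill
        if not 1 <= lo <= hi:
            raise CircuitError("hill range must satisfy 1 <= min <= max")

    @property
    def median_unregulated_level(self) -> float:
        """Half-functional rule reference: median l over median k."""
        return (sum(self.production) / 2) / (sum(self.degradation) / 2)


@dataclass
class CircuitModel:
    """One kinetic parameterization of a network."""

    network: GeneNetwork
    production: np.ndarray  # (n_nodes,)
    degradation: np.ndarray  # (n_nodes,)
    threshold: np.ndarray  # (n_edges,)
    hill: np.ndarray  # (n_edges,) integers
    fold_change: np.ndarray  # (n_edges,) λ per edge

    def __post_init__(self):
        net = self.network
        for name, arr, n in (
            ("production", self.production, net.n_nodes),
            ("degradation", self.degradation, net.n_nodes),
            ("threshold", self.threshold, net.n_edges),
            ("hill", self.hill, net.n_edges),
            ("fold_change", self.fold_change, net.n_edges),
        ):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise CircuitError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        if (self.production <= 0).any() or (self.degradation <= 0).any():
            raise CircuitError("production and degradation must be > 0")
        if (self.threshold <= 0).any():
            raise CircuitError("thresholds must be > 0")
        if (self.hill < 1).any():
            raise CircuitError("Hill coefficients must be >= 1")
        for e, (_, _, sign) in enumerate(net.edges):
            lam = self.fold_change[e]
            if sign == ACTIVATION and lam < 1:
                raise CircuitError(f"activation edge {e} needs λ >= 1, got {lam}")
            if sign == INHIBITION and not 0 < lam <= 1:
                raise CircuitError(f"inhibition edge {e} needs 0 < λ <= 1, got {lam}")


def shifted_hill(X, X0, n, lam):
    """Shifted Hill regulation factor λ + (1 − λ) / (1 + (X/X0)^n).

    Equals 1 at X = 0, (1 + λ)/2 at X = X0 and tends to λ as X → ∞; the
    value always lies in [min(1, λ), max(1, λ)].
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise CircuitError("X must be >= 0")
    if np.any(np.asarray(X0) <= 0) or np.any(np.asarray(lam) <= 0):
        raise CircuitError("X0 and λ must be > 0")
    if np.any(np.asarray(n) < 1):
        raise CircuitError("n must be >= 1")
    out = lam + (1.0 - lam) / (1.0 + (X / X0) ** n)
    return out if out.shape else float(out)


def sample_parameters(
    network: GeneNetwork,
    ranges: ParameterRanges | None = None,
    seed: int | np.random.Generator = 0,
) -> CircuitModel:
    """Draw one model uniformly from the parameter ranges (seeded)."""
    models = _sample_parameter_block(network, 1, ranges, seed)
    return CircuitModel(
        network=network,
        production=models["production"][:, 0],
        degradation=models["degradation"][:, 0],
        threshold=models["threshold"][:, 0],
        hill=models["hill"][:, 0],
        fold_change=models["fold_change"][:, 0],
    )


def _sample_parameter_block(
    network: GeneNetwork,
    n_models: int,
    ranges: ParameterRanges | None,
    seed: int | np.random.Generator,
) -> dict:
    """Vectorized parameter draws; arrays have a trailing model axis."""
    ranges = ranges or ParameterRanges()
    ranges.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nn, ne = network.n_nodes, network.n_edges
    prod = rng.uniform(*ranges.production, (nn, n_models))
    deg = rng.uniform(*ranges.degradation, (nn, n_models))
    med = ranges.median_unregulated_level
    thr = rng.uniform(
        ranges.threshold_spread[0] * med, ranges.threshold_spread[1] * med,
        (ne, n_models),
    )
    hill = rng.integers(ranges.hill[0], ranges.hill[1] + 1, (ne, n_models)).astype(float)
    lam = rng.uniform(*ranges.fold_change, (ne, n_models))
    signs = np.array([sign for (_, _, sign) in network.edges])
    lam = np.where(signs[:, None] == INHIBITION, 1.0 / lam, lam)
    return {
        "production": prod, "degradation": deg, "threshold": thr,
        "hill": hill, "fold_change": lam,
    }


def build_rhs(network: GeneNetwork, model: CircuitModel) -> Callable:
    """Right-hand side f(t, x) of the circuit ODE system.

    dX/dt = l_X · ∏(incoming) HS(regulator) − k_X X; nodes without
    regulators reduce to l_X − k_X X.
    """
    if model.network is not network and model.network.edges != network.edges:
        raise CircuitError("model parameterizes a different network")
    idx = network.node_index()
    src = np.array([idx[s] for (s, _, _) in network.edges], dtype=int)
    tgt = np.array([idx[t] for (_, t, _) in network.edges], dtype=int)

    def rhs(t, x):
        x = np.asarray(x, dtype=float)
        H = np.ones(network.n_nodes)
        for e in range(network.n_edges):
            H[tgt[e]] *= model.fold_change[e] + (1.0 - model.fold_change[e]) / (
                1.0 + (x[src[e]] / model.threshold[e]) ** model.hill[e]
            )
        return model.production * H - model.degradation * x

    return rhs


# ---------------------------------------------------------------------------
# batched steady-state relaxation


def _batched_hill_product(X, thr, hill, lam, src, tgt):
    """Product of shifted-Hill factors per node; X is (n_nodes, M)."""
    H = np.ones_like(X)
    for e in range(len(src)):
        H[tgt[e]] *= lam[e] + (1.0 - lam[e]) / (1.0 + (X[src[e]] / thr[e]) ** hill[e])
    return H


def _relax_batch(
    X, prod, deg, thr, hill, lam, src, tgt,
    dt: float, t_max: float, tol: float, check_every: float,
):
    """Exponential-Euler relaxation of all columns to steady state.

    Returns (X_final, converged mask).  Columns whose residual
    ‖l·H − k·X‖∞ drops below ``tol`` are frozen and removed from the active
    set; positivity is preserved by the scheme itself.
    """
    n_nodes, M = X.shape
    steps = max(1, int(round(check_every / dt)))
    n_chunks = int(np.ceil(t_max / check_every))
    out = X.copy()
    converged = np.zeros(M, dtype=bool)
    active = np.arange(M)
    Xa = X.copy()
    Pa, Da, Ta, Ha_, La = prod, deg, thr, hill, lam
    Ea = np.exp(-Da * dt)
    for _ in range(n_chunks):
        for _ in range(steps):
            H = _batched_hill_product(Xa, Ta, Ha_, La, src, tgt)
            target = Pa * H / Da
            Xa = target + (Xa - target) * Ea
        H = _batched_hill_product(Xa, Ta, Ha_, La, src, tgt)
        res = np.abs(Pa * H - Da * Xa).max(axis=0)
        done = res < tol
        if done.any():
            out[:, active[done]] = Xa[:, done]
            converged[active[done]] = True
            keep = ~done
            if not keep.any():
                return out, converged
            active = active[keep]
            Xa = Xa[:, keep]
            Pa, Da, Ea = Pa[:, keep], Da[:, keep], Ea[:, keep]
            Ta, Ha_, La = Ta[:, keep], Ha_[:, keep], La[:, keep]
    out[:, active] = Xa  # non-converged endpoints, flagged by the mask
    return out, converged


def _initial_conditions(rng, prod, deg, n_cols):
    """Log-uniform positive initial conditions up to each node's ceiling."""
    cap = prod / deg  # unregulated level; Hill factors rescale around it
    lo = np.log(1e-4 * cap)
    hi = np.log(10.0 * cap)
    return np.exp(rng.uniform(lo, hi))


def _cluster_states(states: np.ndarray, rel_tol: float = 1e-2):
    """Group endpoint columns into distinct states by relative L∞ distance."""
    reps: list[np.ndarray] = []
    counts: list[int] = []
    for col in states.T:
        for i, r in enumerate(reps):
            d = np.abs(col - r).max() / (1.0 + max(np.abs(col).max(), np.abs(r).max()))
            if d < rel_tol:
                counts[i] += 1
                break
        else:
            reps.append(col.copy())
            counts.append(1)
    return np.array(reps), np.array(counts)


@dataclass
class SteadyStateResult:
    """Distinct steady states of one model with basin multiplicities."""

    network: GeneNetwork
    states: np.ndarray  # (n_states, n_nodes)
    multiplicity: np.ndarray  # (n_states,)
    n_inits: int
    n_converged: int

    @property
    def n_states(self) -> int:
        return len(self.states)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.network.nodes))
        df.insert(0, "multiplicity", self.multiplicity)
        return df


def solve_steady_states(
    network: GeneNetwork,
    model: CircuitModel,
    n_inits: int = 50,
    tol: float = 1e-6,
    t_max: float = 200.0,
    dt: float = 0.1,
    seed: int | np.random.Generator = 0,
    cluster_tol: float = 1e-2,
) -> SteadyStateResult:
    """Relax one model from many random initial conditions and census the
    distinct steady states (relative-L∞ clustering of converged endpoints)."""
    if n_inits < 1:
        raise CircuitError("n_inits must be >= 1")
    if tol <= 0:
        raise CircuitError("tol must be > 0")
    idx = network.node_index()
    src = np.array([idx[s] for (s, _, _) in network.edges], dtype=int)
    tgt = np.array([idx[t] for (_, t, _) in network.edges], dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tile = lambda a, n: np.repeat(np.asarray(a, float)[:, None], n, axis=1)
    prod, deg = tile(model.production, n_inits), tile(model.degradation, n_inits)
    thr, hill = tile(model.threshold, n_inits), tile(model.hill, n_inits)
    lam = tile(model.fold_change, n_inits)
    X0 = _initial_conditions(rng, prod, deg, n_inits)
    X, conv = _relax_batch(X0, prod, deg, thr, hill, lam, src, tgt,
                           dt=dt, t_max=t_max, tol=tol, check_every=5.0)
    n_conv = int(conv.sum())
    if n_conv == 0:
        logger.warning("model non-convergent from all %d initial conditions", n_inits)
        return SteadyStateResult(network, np.empty((0, network.n_nodes)),
                                 np.empty(0, int), n_inits, 0)
    states, mult = _cluster_states(X[:, conv], cluster_tol)
    return SteadyStateResult(network, states, mult, n_inits, n_conv)


@dataclass
class SteadyStateEnsemble:
    """Pooled steady states of a triplicate random-parameter ensemble.

    ``states`` has one row per (replicate, model, distinct state) with the
    node concentrations and the basin multiplicity; ``parameters`` records
    every sampled model.
    """

    network: GeneNetwork
    states: pd.DataFrame
    parameters: pd.DataFrame
    n_models: int
    replicates: int
    n_nonconvergent: int

    def replicate_states(self, r: int) -> pd.DataFrame:
        return self.states[self.states["replicate"] == r]


def run_ensemble(
    network: GeneNetwork,
    n_models: int = 1000,
    n_inits: int = 50,
    replicates: int = 3,
    seed: int = 42,
    ranges: ParameterRanges | None = None,
    tol: float = 1e-6,
    t_max: float = 200.0,
    dt: float = 0.1,
    cluster_tol: float = 1e-2,
    min_converged: int | None = None,
) -> SteadyStateEnsemble:
    """RACIPE-style ensemble: per replicate, draw ``n_models`` random
    parameterizations (replicate-offset seeds), relax each from ``n_inits``
    random initial conditions, and pool the distinct steady states.

    A model is *converged* when at least one initial condition reaches the
    residual tolerance; with ``min_converged`` set, extra models are sampled
    until that many converge in every replicate.  Fails if more than half of
    all sampled models are non-convergent.
    """
    if n_models < 1:
        raise CircuitError("n_models must be >= 1")
    idx = network.node_index()
    src = np.array([idx[s] for (s, _, _) in network.edges], dtype=int)
    tgt = np.array([idx[t] for (_, t, _) in network.edges], dtype=int)

    state_rows, param_rows = [], []
    total_models = 0
    total_bad = 0
    for r in range(replicates):
        rng = np.random.default_rng([int(seed), r])
        n_ok = 0
        model_offset = 0
        want = n_models
        while True:
            block = _sample_parameter_block(network, want, ranges, rng)
            expand = lambda a: np.repeat(a, n_inits, axis=1)
            prod, deg = expand(block["production"]), expand(block["degradation"])
            thr, hill = expand(block["threshold"]), expand(block["hill"])
            lam = expand(block["fold_change"])
            Xi = _initial_conditions(rng, prod, deg, want * n_inits)
            X, conv = _relax_batch(Xi, prod, deg, thr, hill, lam, src, tgt,
                                   dt=dt, t_max=t_max, tol=tol, check_every=5.0)
            for m in range(want):
                cols = slice(m * n_inits, (m + 1) * n_inits)
                c = conv[cols]
                mid = model_offset + m
                prow = {"replicate": r, "model": mid}
                for j, node in enumerate(network.nodes):
                    prow[f"l_{node}"] = block["production"][j, m]
                    prow[f"k_{node}"] = block["degradation"][j, m]
                for e_i, (s_, t_, _) in enumerate(network.edges):
                    prow[f"thr_{s_}->{t_}"] = block["threshold"][e_i, m]
                    prow[f"hill_{s_}->{t_}"] = block["hill"][e_i, m]
                    prow[f"lam_{s_}->{t_}"] = block["fold_change"][e_i, m]
                param_rows.append(prow)
                if not c.any():
                    total_bad += 1
                    continue
                n_ok += 1
                sts, mult = _cluster_states(X[:, cols][:, c], cluster_tol)
                for si, (svec, sm) in enumerate(zip(sts, mult)):
                    row = {"replicate": r, "model": mid, "state": si,
                           "multiplicity": int(sm)}
                    row.update({node: svec[j] for j, node in enumerate(network.nodes)})
                    state_rows.append(row)
            total_models += want
            model_offset += want
            target_ok = min_converged if min_converged is not None else 0
            if n_ok >= target_ok or min_converged is None:
                break
            want = max(8, int(np.ceil((target_ok - n_ok) * 1.2)))
        logger.info("replicate %d: %d converged models", r, n_ok)
    if total_bad > 0.5 * total_models:
        raise CircuitError(
            f"{total_bad}/{total_models} models non-convergent (> 50 %)"
        )
    return SteadyStateEnsemble(
        network=network,
        states=pd.DataFrame(state_rows),
        parameters=pd.DataFrame(param_rows),
        n_models=total_models,
        replicates=replicates,
        n_nonconvergent=total_bad,
    )


def expression_correlation(
    ensemble: SteadyStateEnsemble,
    gene_a: str,
    gene_b: str,
    method: str = "pearson",
    scale: str = "log2",
) -> dict:
    """Correlation between two genes' steady-state levels across the ensemble.

    Levels are log2(x + 1)-scaled and correlated with Pearson's r by
    default — the usual convention for random-parameter ensemble output —
    per replicate plus pooled over all states (``method="spearman"`` and
    ``scale="linear"`` are available).  Returns
    ``{"per_replicate": [...], "pooled": rho, "n_states": ...}``; zero
    variance yields NaN with a reason.
    """
    for g in (gene_a, gene_b):
        if g not in ensemble.network.nodes:
            raise CircuitError(f"gene {g!r} not in network")
    if len(ensemble.states) < 3:
        raise CircuitError("need at least 3 steady states")

    def rho(df):
        a, b = df[gene_a].to_numpy(float), df[gene_b].to_numpy(float)
        if scale == "log2":
            a, b = np.log2(a + 1.0), np.log2(b + 1.0)
        if len(a) < 3 or a.std() == 0 or b.std() == 0:
            return float("nan")
        if method == "spearman":
            return float(scipy.stats.spearmanr(a, b).statistic)
        if method == "pearson":
            return float(scipy.stats.pearsonr(a, b).statistic)
        raise CircuitError(f"unknown method {method!r}")

    per_rep = [rho(ensemble.replicate_states(r)) for r in range(ensemble.replicates)]
    return {
        "per_replicate": per_rep,
        "pooled": rho(ensemble.states),
        "n_states": len(ensemble.states),
        "method": method,
        "scale": scale,
    }
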