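"""Supermatrix assembly, limiting, and synthesis of global priorities.

The supermatrix is a square block matrix over all network nodes (criteria +
sub-criteria + alternatives).  Cell (row = source, column = target) holds
the source's local priority in the comparison context "with respect to
target"; columns therefore stack one priority vector per incoming cluster.
Multiplying each block by a cluster weight makes every nonzero column sum
to one (the *weighted* supermatrix, a column-stochastic transition matrix),
and raising it to high powers yields the *limit* matrix whose columns carry
the long-run global priorities.

Sink nodes (typically the alternatives, which influence nothing) would
leave zero columns; the default policy gives them a self-loop of weight 1,
which makes the chain absorbing and is what common ANP solvers do.  Cyclic
(periodic) chains never converge entrywise, so the limit falls back to the
Cesaro average of powers over one period, which always exists for a
stochastic matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkStructure, comparison_contexts

__all__ = [
    "Supermatrix",
    "ClusterWeights",
    "GlobalPriorities",
    "DesirabilityInputs",
    "Ranking",
    "uniform_cluster_weights",
    "assemble_unweighted",
    "weight_supermatrix",
    "limit_supermatrix",
    "extract_priorities",
    "global_alternative_weights",
    "desirability_index",
    "rank_alternatives",
]


@dataclass(frozen=True)
class Supermatrix:
    values: np.ndarray
    node_order: tuple[str, ...]
    stage: str  # unweighted | weighted | limit
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (len(self.node_order),) * 2:
            raise ValueError("supermatrix shape does not match node order")
        object.__setattr__(self, "values", v)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.node_order),
                            columns=list(self.node_order))

    def to_csv(self, path):
        self.to_dataframe().to_csv(path)

    def column(self, node_id: str) -> np.ndarray:
        return self.values[:, self.node_order.index(node_id)]


@dataclass(frozen=True)
class ClusterWeights:
    """Weights of source clusters within each target cluster's columns.

    ``weights[(source_cluster, target_cluster)]``; for every target
    cluster the incoming weights must sum to 1.
    """

    weights: dict[tuple[str, str], float]

    def __post_init__(self):
        by_target: dict[str, float] = {}
        for (s, t), w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative cluster weight for {(s, t)}")
            by_target[t] = by_target.get(t, 0.0) + w
        for t, total in by_target.items():
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"cluster weights into {t!r} sum to {total}, expected 1")

    def get(self, source_cluster: str, target_cluster: str) -> float:
        return self.weights.get((source_cluster, target_cluster), 0.0)


def uniform_cluster_weights(net: NetworkStructure) -> ClusterWeights:
    """Equal weight to every cluster with a dependency into a target
    cluster — the reproducible default when no cluster-level judgments
    are supplied (the study never published its cluster weights)."""
    pairs: dict[str, set[str]] = {}
    for e in net.edges:
        if e.target == net.goal.id:
            continue
        pairs.setdefault(net.cluster_of(e.target), set()).add(net.cluster_of(e.source))
    weights = {}
    for t, sources in pairs.items():
        for s in sources:
            weights[(s, t)] = 1.0 / len(sources)
    return ClusterWeights(weights)


def assemble_unweighted(net: NetworkStructure,
                        local_priorities: dict[str, np.ndarray]) -> Supermatrix:
    """Place every context's priority vector into its supermatrix block.

    ``local_priorities`` maps context id -> vector aligned with the
    context's node order; single-element contexts default to the forced
    priority 1.  The goal is not a supermatrix column; its context feeds
    synthesis downstream.  Columns with no incoming dependency are left
    zero and flagged in ``meta['zero_columns']``.
    """
    order = net.node_order
    pos = {nid: k for k, nid in enumerate(order)}
    m = np.zeros((len(order), len(order)))
    for ctx in comparison_contexts(net):
        if ctx.target == net.goal.id:
            continue
        if ctx.n == 1:
            w = np.array([1.0])
        elif ctx.id in local_priorities:
            w = np.asarray(local_priorities[ctx.id], float)
        else:
            raise KeyError(f"no priority vector supplied for context {ctx.id!r}")
        if w.shape != (ctx.n,):
            raise ValueError(f"context {ctx.id!r}: priority length {w.shape} != n={ctx.n}")
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"context {ctx.id!r}: priorities must be >= 0 and sum to 1")
        for nid, wi in zip(ctx.node_ids, w):
            m[pos[nid], pos[ctx.target]] = wi
    zero_cols = tuple(nid for k, nid in enumerate(order) if m[:, k].sum() == 0)
    return Supermatrix(m, order, "unweighted", {"zero_columns": zero_cols})


def weight_supermatrix(unweighted: Supermatrix, net: NetworkStructure,
                       cluster_weights: ClusterWeights | None = None,
                       sink_policy: str = "self_loop") -> Supermatrix:
    """Scale cluster blocks by cluster weights to a column-stochastic matrix.

    Within each column, cluster weights are renormalized over the clusters
    actually present in that column, so partial dependency patterns stay
    stochastic.  ``sink_policy='self_loop'`` (default) puts weight 1 on the
    diagonal of zero columns; ``'leave_zero'`` keeps them empty (such a
    matrix is substochastic and its limit drains to zero).
    """
    if sink_policy not in ("self_loop", "leave_zero"):
        raise ValueError(f"unknown sink policy {sink_policy!r}")
    if cluster_weights is None:
        cluster_weights = uniform_cluster_weights(net)
    order = unweighted.node_order
    cluster_of = {nid: net.cluster_of(nid) for nid in order}
    m = unweighted.values.copy()
    out = np.zeros_like(m)
    sinks = []
    for j, target in enumerate(order):
        col = m[:, j]
        present = {cluster_of[order[i]] for i in np.nonzero(col)[0]}
        if not present:
            sinks.append(target)
            if sink_policy == "self_loop":
                out[j, j] = 1.0
            continue
        total = sum(cluster_weights.get(s, cluster_of[target]) for s in present)
        if total <= 0:
            raise ValueError(
                f"cluster weights assign no mass to column {target!r} "
                f"(incoming clusters {sorted(present)})")
        for i in np.nonzero(col)[0]:
            s = cluster_of[order[i]]
            out[i, j] = col[i] * cluster_weights.get(s, cluster_of[target]) / total
        if abs(out[:, j].sum() - 1.0) > 1e-9:
            raise ValueError(f"column {target!r} failed to normalize "
                             f"(sum {out[:, j].sum()})")
    return Supermatrix(out, order, "weighted",
                       {**unweighted.meta, "sink_nodes": tuple(sinks),
                        "sink_policy": sink_policy})


def limit_supermatrix(weighted: Supermatrix, power_cap: int = 64,
                      tol: float = 1e-10, max_period: int = 48) -> Supermatrix:
    """Limit of supermatrix powers by repeated squaring.

    Squaring up to ``power_cap`` doublings (i.e. powers up to 2**power_cap)
    reaches the same limit as the odd-power prescription for aperiodic
    chains, in logarithmically many multiplications.  A squaring fixed
    point that is not stationary under the original matrix signals
    periodicity; the Cesaro average of powers over one detected period is
    returned instead (e.g. a pure 2-cycle averages to the uniform
    two-point distribution).
    """
    w = weighted.values
    m = w.copy()
    converged = False
    for k in range(power_cap):
        m2 = m @ m
        if np.max(np.abs(m2 - m)) < tol:
            m = m2
            converged = True
            break
        m = m2
    if not converged:
        raise RuntimeError(
            f"supermatrix powers did not stabilize within 2^{power_cap} "
            f"(residual {float(np.max(np.abs(m @ m - m))):.3e})")
    meta = {**weighted.meta, "squarings": k + 1}
    if np.max(np.abs(w @ m - m)) < max(1e-8, 10 * tol):
        meta["cesaro"] = False
        return Supermatrix(m, weighted.node_order, "limit", meta)
    # periodic: average the power cycle starting from the squaring fixed point
    cycle = [m]
    cur = m
    for p in range(1, max_period + 1):
        cur = w @ cur
        if np.max(np.abs(cur - m)) < max(1e-8, 10 * tol):
            limit = np.mean(cycle, axis=0)
            meta.update(cesaro=True, period=p)
            return Supermatrix(limit, weighted.node_order, "limit", meta)
        cycle.append(cur)
    raise RuntimeError(
        f"supermatrix is cyclic with period > {max_period}; no limit computed")


@dataclass(frozen=True)
class GlobalPriorities:
    """Per-cluster normalized weights, presented the way the study tables
    are: criterion weights sum to 1, each criterion's sub-criterion weights
    sum to 1 locally, alternative weights sum to 1."""

    criteria: dict[str, float]
    subcriteria_local: dict[str, dict[str, float]]
    alternatives: dict[str, float]

    def subcriteria_global(self) -> dict[str, dict[str, float]]:
        """Global sub-criterion weights: criterion weight x local weight."""
        return {c: {k: self.criteria[c] * v for k, v in subs.items()}
                for c, subs in self.subcriteria_local.items()}


def _renormalize(vals: dict[str, float], what: str) -> dict[str, float]:
    total = sum(vals.values())
    if total <= 0:
        raise ValueError(f"all-zero {what} mass in limit matrix; cannot normalize")
    return {k: v / total for k, v in vals.items()}


def extract_priorities(limit: Supermatrix, net: NetworkStructure,
                       reference: np.ndarray | None = None,
                       col_tol: float = 1e-6) -> GlobalPriorities:
    """Per-cluster renormalization of the limit column.

    Without an explicit ``reference`` vector the nonzero limit columns must
    agree (irreducible networks, or a fixture loaded as a pseudo-limit);
    their mean column is used.  Clusters with zero limit mass raise — for
    hierarchies, whose limit mass sits entirely on the alternatives, use
    :func:`global_alternative_weights` plus the local context priorities.
    """
    m = limit.values
    if reference is None:
        nz = [j for j in range(m.shape[1]) if m[:, j].sum() > 0]
        if not nz:
            raise ValueError("limit matrix is identically zero")
        cols = m[:, nz] / m[:, nz].sum(axis=0, keepdims=True)
        if np.max(cols.max(axis=1) - cols.min(axis=1)) > col_tol:
            raise ValueError(
                "limit columns disagree; pass an explicit reference vector")
        reference = cols.mean(axis=1)
    ref = {nid: float(reference[k]) for k, nid in enumerate(limit.node_order)}

    crit = net.by_kind("criteria")
    alts = net.by_kind("alternatives")
    criteria = _renormalize({c: ref[c] for c in crit.member_ids}, "criteria cluster")
    alternatives = _renormalize({a: ref[a] for a in alts.member_ids},
                                "alternatives cluster")
    subs_local: dict[str, dict[str, float]] = {}
    try:
        subc = net.by_kind("subcriteria")
    except KeyError:
        subc = None
    if subc is not None:
        for c in crit.member_ids:
            fam = {s: ref[s] for s in subc.member_ids if net.nodes[s].parent == c}
            if fam:
                subs_local[c] = _renormalize(fam, f"sub-criteria of {c}")
    return GlobalPriorities(criteria=criteria, subcriteria_local=subs_local,
                            alternatives=alternatives)


def global_alternative_weights(limit: Supermatrix, net: NetworkStructure,
                               goal_priorities: dict[str, float]) -> dict[str, float]:
    """Overall alternative weights: push the goal's criterion priorities
    through the limit matrix and renormalize over the alternatives.

    For a pure hierarchy this reproduces the weighted-sum composition over
    criteria and sub-criteria exactly; with feedback it is the standard
    limit-matrix synthesis.
    """
    order = limit.node_order
    v0 = np.array([goal_priorities.get(nid, 0.0) for nid in order])
    if v0.sum() <= 0:
        raise ValueError("goal priorities assign no mass to any supermatrix node")
    v0 = v0 / v0.sum()
    v = limit.values @ v0
    alts = net.by_kind("alternatives").member_ids
    pos = {nid: k for k, nid in enumerate(order)}
    return _renormalize({a: float(v[pos[a]]) for a in alts}, "alternatives cluster")


@dataclass(frozen=True)
class DesirabilityInputs:
    """Components of the desirability score

        D_i = sum_j sum_k  P_j * AD_kj * A1_kj * S_ikj

    with P_j the criterion weights, A1_kj the stabilized independent
    weight of sub-criterion k under criterion j (sums to 1 over k for each
    j), AD_kj the interdependence adjustment for that sub-criterion
    (1 when no interdependence judgments exist), and S_ikj the impact of
    alternative i on sub-criterion k of j (sums to 1 over i).  The number
    of alternatives is taken from the data.
    """

    criteria_weights: dict[str, float]                       # P_j
    independent_weights: dict[str, dict[str, float]]         # A1[j][k]
    alternative_impacts: dict[str, dict[str, dict[str, float]]]  # S[j][k][i]
    dependency_weights: dict[str, dict[str, float]] | None = None  # AD[j][k]
    alternative_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.alternative_ids:
            first = next(iter(next(iter(self.alternative_impacts.values())).values()))
            object.__setattr__(self, "alternative_ids", tuple(first))
        for j, subs in self.independent_weights.items():
            if j not in self.criteria_weights:
                raise ValueError(f"criterion {j!r} has sub-weights but no P_j")
            if any(v < 0 for v in subs.values()):
                raise ValueError(f"negative independent weight under {j!r}")
            if abs(sum(subs.values()) - 1.0) > 1e-6:
                raise ValueError(f"independent weights under {j!r} do not sum to 1")
            for k in subs:
                s = self.alternative_impacts.get(j, {}).get(k)
                if s is None:
                    raise ValueError(f"missing alternative impacts for ({j!r}, {k!r})")
                if set(s) != set(self.alternative_ids):
                    raise ValueError(f"impact vector ({j!r}, {k!r}) covers wrong alternatives")
                if abs(sum(s.values()) - 1.0) > 1e-6:
                    raise ValueError(f"impacts for ({j!r}, {k!r}) do not sum to 1")


def desirability_index(inputs: DesirabilityInputs,
                       normalized: bool = True) -> dict[str, float]:
    """Per-alternative desirability; raw scores, or normalized to sum 1."""
    d = dict.fromkeys(inputs.alternative_ids, 0.0)
    for j, subs in inputs.independent_weights.items():
        pj = inputs.criteria_weights[j]
        for k, a1 in subs.items():
            ad = 1.0
            if inputs.dependency_weights is not None:
                ad = inputs.dependency_weights.get(j, {}).get(k, 1.0)
            s = inputs.alternative_impacts[j][k]
            for i in inputs.alternative_ids:
                d[i] += pj * ad * a1 * s[i]
    if normalized:
        total = sum(d.values())
        if total > 0:
            d = {i: v / total for i, v in d.items()}
    return d


@dataclass(frozen=True)
class Ranking:
    order: tuple[str, ...]
    weights: dict[str, float]
    tied: bool

    def __iter__(self):
        return iter(self.order)


def rank_alternatives(weights: dict[str, float], tie_tol: float = 1e-9) -> Ranking:
    """Descending ranking; ties broken lexicographically by id and flagged."""
    order = tuple(sorted(weights, key=lambda a: (-weights[a], a)))
    vals = sorted(weights.values(), reverse=True)
    tied = any(abs(x - y) <= tie_tol for x, y in zip(vals, vals[1:]))
    return Ranking(order=order, weights=dict(weights), tied=tied)
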