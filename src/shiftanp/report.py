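"""End-to-end pipeline: judgments -> screening -> aggregation ->
supermatrix -> global weights -> desirability -> ranked report.

The report mirrors the study's presentation per group: criterion weights
(summing to 1), sub-criterion weights local to each criterion (each family
summing to 1), the alternative (shift) weights from the limit supermatrix,
the desirability index over alternatives, and the consistency log.  JSON
output carries full precision; rendered tables round to 3 decimals
(round-half-even).  Reports are deterministic: same config and seed give
byte-identical JSON (no timestamps are embedded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import (GROUPS, NetworkStructure, comparison_contexts,
                      load_shiftwork_network, published_fixture)
from .pairwise import consistency_report, priority_vector
from .supermatrix import (ClusterWeights, DesirabilityInputs, Ranking,
                          assemble_unweighted, desirability_index,
                          global_alternative_weights, limit_supermatrix,
                          rank_alternatives, weight_supermatrix)
from .survey import aggregate_priorities, group_judgments, read_responses
from .synthetic import (CohortDesign, GroundTruth, NoiseModel,
                        generate_cohort, ground_truth_from_fixtures)

__all__ = [
    "RunConfig",
    "GroupReport",
    "ReportBundle",
    "PipelineError",
    "run_pipeline",
    "report_from_fixture",
    "compare_to_published",
]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.  Exactly one input source: a responses CSV
    (``responses``) or a synthetic cohort design (``design``)."""

    network: NetworkStructure | None = None
    responses: str | Path | None = None
    design: CohortDesign | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    ground_truth: GroundTruth | None = None
    groups: tuple[str, ...] | None = None
    aggregation: str = "aij"  # aij | aip
    cr_threshold: float = 0.1
    cluster_weights: ClusterWeights | None = None
    sink_policy: str = "self_loop"

    def __post_init__(self):
        if (self.responses is None) == (self.design is None):
            raise ValueError(
                "exactly one input source required: responses CSV xor synthetic design")
        if self.aggregation not in ("aij", "aip"):
            raise ValueError(f"unknown aggregation mode {self.aggregation!r}")


@dataclass(frozen=True)
class GroupReport:
    group: str
    criteria: dict[str, float]
    subcriteria_local: dict[str, dict[str, float]]
    alternatives: dict[str, float]
    ranking: Ranking
    desirability: dict[str, float]
    desirability_raw: dict[str, float]
    consistency: dict[str, dict]
    n_respondents: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "criteria": self.criteria,
            "subcriteria_local": self.subcriteria_local,
            "alternatives": self.alternatives,
            "ranking": {"order": list(self.ranking.order), "tied": self.ranking.tied},
            "desirability": self.desirability,
            "desirability_raw": self.desirability_raw,
            "consistency": self.consistency,
            "n_respondents": self.n_respondents,
            "n_excluded": self.n_excluded,
        }


@dataclass(frozen=True)
class ReportBundle:
    groups: dict[str, GroupReport]
    network_name: str
    settings: dict

    def to_dict(self) -> dict:
        return {"network": self.network_name, "settings": self.settings,
                "groups": {g: r.to_dict() for g, r in sorted(self.groups.items())}}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_table(self, group: str, decimals: int = 3) -> str:
        """Per-group markdown table in the published layout."""
        r = self.groups[group]
        lines = [f"### {group}",
                 "| Criterion | Criterion weight | Sub-criterion | Sub-criterion weight |",
                 "| --- | --- | --- | --- |"]
        for crit, cw in r.criteria.items():
            subs = r.subcriteria_local.get(crit, {})
            first = True
            for sub, sw in subs.items() or {"": float("nan")}.items():
                lines.append(
                    f"| {crit if first else ''} | "
                    f"{f'{cw:.{decimals}f}' if first else ''} | {sub} | {sw:.{decimals}f} |")
                first = False
            if not subs:
                lines.append(f"| {crit} | {cw:.{decimals}f} | | |")
        lines.append("")
        lines.append("Alternative weights: " + ", ".join(
            f"{a} = {r.alternatives[a]:.{decimals}f}" for a in r.ranking.order))
        lines.append("Desirability index: " + ", ".join(
            f"{a} = {r.desirability[a]:.{decimals}f}" for a in r.ranking.order))
        return "\n".join(lines)

    def write(self, outdir) -> dict[str, Path]:
        """JSON + per-group weight CSVs + human-readable tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"json": outdir / "report.json"}
        paths["json"].write_text(self.to_json() + "\n")
        rows = []
        for g, r in sorted(self.groups.items()):
            for crit, cw in r.criteria.items():
                rows.append((g, "criterion", crit, "", cw))
                for sub, sw in r.subcriteria_local.get(crit, {}).items():
                    rows.append((g, "subcriterion", crit, sub, sw))
            for a, w in r.alternatives.items():
                rows.append((g, "alternative", "", a, w))
        paths["weights_csv"] = outdir / "weights.csv"
        pd.DataFrame(rows, columns=["group", "level", "criterion", "node", "weight"]
                     ).to_csv(paths["weights_csv"], index=False)
        paths["tables"] = outdir / "tables.md"
        paths["tables"].write_text(
            "\n\n".join(self.to_table(g) for g in sorted(self.groups)) + "\n")
        return paths


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full prioritization pipeline for every requested group."""
    with _stage("network"):
        net = config.network or load_shiftwork_network()
        contexts = comparison_contexts(net)
        goal_ctx = next(c for c in contexts if c.target == net.goal.id)

    with _stage("input"):
        if config.responses is not None:
            records = read_responses(config.responses, net)
            if not records:
                raise ValueError(f"no respondents found in {config.responses}")
        else:
            truth = config.ground_truth or ground_truth_from_fixtures(
                net, groups=tuple(config.design.groups))
            records = generate_cohort(config.design, truth, config.noise, net)
        groups = config.groups or tuple(
            dict.fromkeys(r.group for r in records))

    reports = {}
    for group in groups:
        with _stage(f"aggregate:{group}"):
            gj, screening = group_judgments(
                records, net, group, threshold=config.cr_threshold,
                method=config.aggregation)
            local: dict[str, np.ndarray] = {}
            for ctx in contexts:
                if ctx.n < 2:
                    continue
                if config.aggregation == "aij":
                    local[ctx.id] = priority_vector(gj.matrices[ctx.id])
                else:
                    local[ctx.id] = aggregate_priorities(screening.kept, ctx.id)
        with _stage(f"supermatrix:{group}"):
            unweighted = assemble_unweighted(net, local)
            weighted = weight_supermatrix(unweighted, net, config.cluster_weights,
                                          sink_policy=config.sink_policy)
            limit = limit_supermatrix(weighted)
        with _stage(f"synthesize:{group}"):
            reports[group] = _synthesize(net, goal_ctx, contexts, local, limit,
                                         gj, screening)
    return ReportBundle(
        groups=reports, network_name=net.name,
        settings={
            "aggregation": config.aggregation,
            "cr_threshold": config.cr_threshold,
            "sink_policy": config.sink_policy,
            "source": "responses" if config.responses is not None else "synthetic",
            "sigma": None if config.responses is not None else config.noise.sigma,
            "seed": None if config.design is None else config.design.seed,
        })


def _leaf_families(net: NetworkStructure):
    """criterion -> list of leaves (its sub-criteria, or itself)."""
    crit = net.by_kind("criteria")
    try:
        subc = net.by_kind("subcriteria")
        children = {c: [s for s in subc.member_ids if net.nodes[s].parent == c]
                    for c in crit.member_ids}
    except KeyError:
        children = {c: [] for c in crit.member_ids}
    return {c: (kids or [c]) for c, kids in children.items()}


def _synthesize(net, goal_ctx, contexts, local, limit, gj, screening) -> GroupReport:
    ctx_by_id = {c.id: c for c in contexts}
    by_target = {}
    for c in contexts:
        by_target.setdefault(c.target, []).append(c)

    goal_w = local[goal_ctx.id]
    criteria = {nid: float(w) for nid, w in zip(goal_ctx.node_ids, goal_w)}

    families = _leaf_families(net)
    subs_local: dict[str, dict[str, float]] = {}
    a1: dict[str, dict[str, float]] = {}
    impacts: dict[str, dict[str, dict[str, float]]] = {}
    alt_cluster = net.by_kind("alternatives").id
    for crit_id, leaves in families.items():
        if leaves != [crit_id]:
            ctx = next(c for c in by_target.get(crit_id, [])
                       if c.cluster_id == net.cluster_of(leaves[0]))
            w = local[ctx.id] if ctx.n >= 2 else np.array([1.0])
            subs_local[crit_id] = {nid: float(x) for nid, x in zip(ctx.node_ids, w)}
            a1[crit_id] = subs_local[crit_id]
        else:
            a1[crit_id] = {crit_id: 1.0}
        impacts[crit_id] = {}
        for leaf in leaves:
            actx = next(c for c in by_target.get(leaf, [])
                        if c.cluster_id == alt_cluster)
            w = local[actx.id] if actx.n >= 2 else np.array([1.0])
            impacts[crit_id][leaf] = {nid: float(x) for nid, x in zip(actx.node_ids, w)}

    alternatives = global_alternative_weights(limit, net, criteria)
    des_inputs = DesirabilityInputs(
        criteria_weights=criteria, independent_weights=a1,
        alternative_impacts=impacts,
        alternative_ids=net.by_kind("alternatives").member_ids)
    des_raw = desirability_index(des_inputs, normalized=False)
    des = desirability_index(des_inputs, normalized=True)

    consistency = {}
    for cid, mat in sorted(gj.matrices.items()):
        rep = consistency_report(mat)
        consistency[cid] = {
            "n": rep.n, "lambda_max": rep.lambda_max, "ci": rep.ci,
            "cr": rep.cr, "acceptable": rep.acceptable,
            "n_respondents_used": gj.n_used[cid]}

    return GroupReport(
        group=gj.group, criteria=criteria, subcriteria_local=subs_local,
        alternatives=alternatives, ranking=rank_alternatives(alternatives),
        desirability=des, desirability_raw=des_raw, consistency=consistency,
        n_respondents=gj.n_respondents, n_excluded=gj.n_excluded)


def report_from_fixture(group: str) -> GroupReport:
    """A pseudo-report holding the published weights verbatim — the
    identity reference for delta tables (all deltas are zero against
    itself)."""
    fx = published_fixture(group)
    alts = dict(fx.alternatives)
    total = sum(alts.values())
    des = {a: w / total for a, w in alts.items()}
    return GroupReport(
        group=group, criteria=dict(fx.criteria),
        subcriteria_local={k: dict(v) for k, v in fx.subcriteria.items()},
        alternatives=alts, ranking=rank_alternatives(alts),
        desirability=des, desirability_raw=alts, consistency={},
        n_respondents=0, n_excluded=0)


def compare_to_published(report: GroupReport | ReportBundle,
                         groups=None) -> pd.DataFrame:
    """Delta table: computed vs published weight for every printed value,
    plus rank-agreement summary rows.

    Deltas cover exactly the published entries (an alternative missing
    from a printed ranking contributes no row).  Rank agreement compares
    the computed ordering with the published one over the shared keys.
    """
    if isinstance(report, ReportBundle):
        frames = [compare_to_published(r) for g, r in sorted(report.groups.items())
                  if groups is None or g in groups]
        if not frames:
            raise KeyError(f"no requested group present in report: {groups}")
        merged = pd.concat(frames, ignore_index=True)  # concat drops attrs
        merged.attrs["rank_agreement"] = {
            f.iloc[0]["group"]: f.attrs["rank_agreement"] for f in frames}
        return merged

    group = report.group
    if group not in GROUPS:
        raise KeyError(f"group {group!r} has no published fixture")
    fx = published_fixture(group)
    rows = []

    def add(level, criterion, node, computed, published):
        rows.append({"group": group, "level": level, "criterion": criterion,
                     "node": node, "computed": computed, "published": published,
                     "abs_diff": abs(computed - published)})

    for c, w in fx.criteria.items():
        add("criterion", c, c, report.criteria.get(c, float("nan")), w)
    for c, subs in fx.subcriteria.items():
        for s, w in subs.items():
            add("subcriterion", c, s,
                report.subcriteria_local.get(c, {}).get(s, float("nan")), w)
    for a, w in fx.alternatives.items():
        add("alternative", "", a, report.alternatives.get(a, float("nan")), w)

    df = pd.DataFrame(rows)

    def _order(d):
        return tuple(sorted(d, key=lambda k: (-d[k], k)))

    shared_alts = [a for a in fx.alternatives if a in report.alternatives]
    agreement = {
        "criteria_rank_match": _order(fx.criteria) == _order(report.criteria),
        "alternative_rank_match": (
            _order(fx.alternatives)
            == _order({a: report.alternatives[a] for a in shared_alts})),
    }
    df.attrs["rank_agreement"] = agreement
    return df
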