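"""Questionnaire reading, consistency screening, and group aggregation.

Responses arrive in a long-format CSV with one judgment per row:

    respondent_id,group,context_id,row_node,col_node,judgment

Judgments may be decimals or fraction strings ("1/5") and must lie on the
17-value scale.  Only one triangle need be supplied; diagonal and
reciprocal cells are completed automatically, and contradictory duplicates
are rejected.  Respondents whose matrices exceed the consistency threshold
are screened out whole (the conservative policy; per-matrix screening is
available), and the survivors are pooled per comparison context by the
entrywise geometric mean of judgments (AIJ) — which provably preserves
reciprocity — or alternatively by averaging individual priority vectors
(AIP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkStructure, comparison_contexts
from .pairwise import (ComparisonMatrix, ConsistencyReport, consistency_report,
                       is_admissible, parse_judgment, priority_vector)

__all__ = [
    "RespondentRecord",
    "GroupJudgment",
    "ScreeningResult",
    "SurveyFormatError",
    "read_responses",
    "write_responses_csv",
    "screen_by_cr",
    "aggregate_geometric_mean",
    "aggregate_priorities",
    "group_judgments",
]

CSV_COLUMNS = ("respondent_id", "group", "context_id", "row_node", "col_node", "judgment")


class SurveyFormatError(ValueError):
    pass


@dataclass(frozen=True)
class RespondentRecord:
    respondent_id: str
    group: str
    #: context id -> matrix; contexts absent from the map are "missing"
    matrices: dict[str, ComparisonMatrix]
    demographics: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupJudgment:
    group: str
    #: context id -> aggregated matrix (entries may lie off-grid)
    matrices: dict[str, ComparisonMatrix]
    n_respondents: int
    n_excluded: int
    #: context id -> number of respondents who supplied it
    n_used: dict[str, int] = field(default_factory=dict)


def read_responses(csv_source, net: NetworkStructure) -> list[RespondentRecord]:
    """Parse and validate a long-format questionnaire CSV.

    Every judgment cell is checked against the network's comparison
    contexts and the admissible scale; matrices must arrive complete (a
    full triangle) or not at all — a context absent from a respondent is
    recorded as missing, a partial one is an error.
    """
    df = pd.read_csv(csv_source, dtype=str).rename(columns=str.strip)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SurveyFormatError(f"CSV is missing required columns {missing_cols}")

    contexts = {c.id: c for c in comparison_contexts(net) if c.n >= 2}
    records = []
    for (rid, group), sub in df.groupby(["respondent_id", "group"], sort=True):
        cells: dict[str, dict[tuple[int, int], float]] = {}
        for row in sub.itertuples(index=False):
            ctx = contexts.get(row.context_id)
            if ctx is None:
                raise SurveyFormatError(
                    f"respondent {rid}: unknown context {row.context_id!r}")
            pos = {nid: k for k, nid in enumerate(ctx.node_ids)}
            for node in (row.row_node, row.col_node):
                if node not in pos:
                    raise SurveyFormatError(
                        f"respondent {rid}: node {node!r} is not compared in "
                        f"context {ctx.id!r}")
            try:
                j = parse_judgment(row.judgment)
            except ValueError as exc:
                raise SurveyFormatError(f"respondent {rid}: {exc}") from exc
            i, k = pos[row.row_node], pos[row.col_node]
            if i == k:
                if abs(j - 1.0) > 1e-12:
                    raise SurveyFormatError(
                        f"respondent {rid}: diagonal cell ({row.row_node}) must be 1")
                continue
            if not is_admissible(j):
                raise SurveyFormatError(
                    f"respondent {rid}: judgment {row.judgment} at "
                    f"({row.row_node}, {row.col_node}) in {ctx.id} is not an "
                    f"admissible scale value")
            mat = cells.setdefault(ctx.id, {})
            for key, val in (((i, k), j), ((k, i), 1.0 / j)):
                if key in mat:
                    kind = ("contradictory duplicate" if abs(mat[key] - val) > 1e-9
                            else "duplicate cell")
                    raise SurveyFormatError(
                        f"respondent {rid}: {kind} at ({row.row_node}, "
                        f"{row.col_node}) in {ctx.id}")
                mat[key] = val
        matrices = {}
        for cid, mat in cells.items():
            n = contexts[cid].n
            expected = n * (n - 1)
            if len(mat) != expected:
                raise SurveyFormatError(
                    f"respondent {rid}: context {cid!r} is partially filled "
                    f"({len(mat) // 2} of {expected // 2} judgments)")
            a = np.eye(n)
            for (i, k), v in mat.items():
                a[i, k] = v
            matrices[cid] = ComparisonMatrix(a, on_grid=True)
        records.append(RespondentRecord(respondent_id=str(rid), group=str(group),
                                        matrices=matrices))
    return records


def write_responses_csv(records, net: NetworkStructure, path):
    """Emit the upper triangle of every matrix in the long CSV dialect."""
    contexts = {c.id: c for c in comparison_contexts(net)}
    rows = []
    for rec in records:
        for cid, mat in sorted(rec.matrices.items()):
            ids = contexts[cid].node_ids
            for i in range(mat.n):
                for k in range(i + 1, mat.n):
                    rows.append((rec.respondent_id, rec.group, cid, ids[i], ids[k],
                                 repr(float(mat.values[i, k]))))
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


@dataclass(frozen=True)
class ScreeningResult:
    kept: tuple[RespondentRecord, ...]
    excluded: tuple[RespondentRecord, ...]
    #: respondent id -> context id -> consistency report
    reports: dict[str, dict[str, ConsistencyReport]]

    @property
    def failing_contexts(self) -> dict[str, tuple[str, ...]]:
        return {rid: tuple(c for c, rep in ctxs.items() if not rep.acceptable)
                for rid, ctxs in self.reports.items()
                if any(not rep.acceptable for rep in ctxs.values())}


def screen_by_cr(records, threshold: float = 0.1,
                 per_matrix: bool = False) -> ScreeningResult:
    """Consistency screen: exclude a respondent when ANY of their matrices
    has CR >= threshold (strict acceptance CR < threshold).

    With ``per_matrix=True`` only the failing matrices are dropped and the
    respondent is kept with the remainder marked missing.
    """
    kept, excluded, reports = [], [], {}
    for rec in records:
        reps = {cid: consistency_report(m) for cid, m in rec.matrices.items()}
        reports[rec.respondent_id] = reps
        failing = {cid for cid, rep in reps.items() if rep.cr >= threshold}
        if not failing:
            kept.append(rec)
        elif per_matrix:
            keep_m = {cid: m for cid, m in rec.matrices.items() if cid not in failing}
            kept.append(RespondentRecord(rec.respondent_id, rec.group, keep_m,
                                         rec.demographics,
                                         rec.warnings + tuple(sorted(failing))))
        else:
            excluded.append(rec)
    return ScreeningResult(tuple(kept), tuple(excluded), reports)


def aggregate_geometric_mean(records, context_id: str) -> ComparisonMatrix:
    """Entrywise geometric mean over the respondents supplying a context.

    The geometric mean of reciprocal matrices is reciprocal exactly:
    computed on the log scale of the upper triangle with the lower
    triangle refilled as reciprocals.  Aggregates generally lie off the
    17-value grid but remain within [1/9, 9].
    """
    mats = [r.matrices[context_id] for r in records if context_id in r.matrices]
    if not mats:
        raise ValueError(f"no respondent supplies context {context_id!r}")
    n = mats[0].n
    logs = np.mean([np.log(m.values) for m in mats], axis=0)
    a = np.eye(n)
    iu, ju = np.triu_indices(n, 1)
    a[iu, ju] = np.exp(logs[iu, ju])
    a[ju, iu] = 1.0 / a[iu, ju]
    return ComparisonMatrix(a, on_grid=False)


def aggregate_priorities(records, context_id: str) -> np.ndarray:
    """AIP alternative: arithmetic mean of individual eigenvector
    priorities, renormalized."""
    ws = [priority_vector(r.matrices[context_id]) for r in records
          if context_id in r.matrices]
    if not ws:
        raise ValueError(f"no respondent supplies context {context_id!r}")
    w = np.mean(ws, axis=0)
    return w / w.sum()


def group_judgments(records, net: NetworkStructure, group: str,
                    threshold: float = 0.1, method: str = "aij",
                    per_matrix: bool = False) -> tuple[GroupJudgment, ScreeningResult]:
    """Screen one group's respondents and aggregate every context.

    Returns the aggregated judgment set (AIJ; for AIP the matrices hold the
    consistent matrix implied by the averaged priorities is NOT built —
    callers use :func:`aggregate_priorities` directly) plus the screening
    log.
    """
    if method not in ("aij", "aip"):
        raise ValueError(f"unknown aggregation method {method!r}")
    members = [r for r in records if r.group == group]
    if not members:
        raise ValueError(f"no respondents in group {group!r}")
    screening = screen_by_cr(members, threshold=threshold, per_matrix=per_matrix)
    if not screening.kept:
        raise ValueError(f"group {group!r}: every respondent failed the CR screen")
    matrices, n_used = {}, {}
    for ctx in comparison_contexts(net):
        if ctx.n < 2:
            continue
        suppliers = [r for r in screening.kept if ctx.id in r.matrices]
        if not suppliers:
            raise ValueError(f"group {group!r}: no kept respondent supplies "
                             f"context {ctx.id!r}")
        matrices[ctx.id] = aggregate_geometric_mean(suppliers, ctx.id)
        n_used[ctx.id] = len(suppliers)
    gj = GroupJudgment(group=group, matrices=matrices,
                       n_respondents=len(members),
                       n_excluded=len(screening.excluded), n_used=n_used)
    return gj, screening
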