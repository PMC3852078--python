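"""Differential-expression candidate-gene selection from two-group data.

Candidate disease genes are called from a probes-by-samples matrix of
log-scale expression values with a two-group (case/control) design, using
either a per-gene p-value threshold on the two-sample t-test or a
top-fraction rule on the t statistic.  Probes are aggregated to genes by
minimum p-value (any significant probe flags its gene) or by mean p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientReplicatesError, ParameterError

Direction = Literal["over", "under", "mixed"]

_TINY_P = 5e-324  # smallest subnormal float: keeps p in (0, 1] for zero-variance separations


@dataclass
class ExpressionMatrix:
    """Probes-by-samples expression values with a two-group design.

    ``values[i, j]`` is the (log-scale) expression of probe ``probe_ids[i]``
    in sample ``sample_ids[j]``.  ``groups`` maps every sample id to
    ``"case"`` or ``"control"``; both groups must be non-empty.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]
    gene_of_probe: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ParameterError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ParameterError(f"samples without a group label: {missing[:5]}")
        bad = {g for g in self.groups.values()} - {"case", "control"}
        if bad:
            raise ParameterError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.values).all():
            raise ParameterError("expression matrix contains missing/non-finite values")
        if not self.gene_of_probe:
            self.gene_of_probe = {p: p for p in self.probe_ids}
        for grp in ("case", "control"):
            if not any(self.groups[s] == grp for s in self.sample_ids):
                raise ParameterError(f"group '{grp}' has no samples")

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([j for j, s in enumerate(self.sample_ids) if self.groups[s] == group])


@dataclass(frozen=True)
class DEResult:
    gene: str
    t_stat: float
    p_value: float
    mean_case: float
    mean_control: float
    direction: str


@dataclass
class CandidateGeneSet:
    """A labelled candidate gene list with per-gene direction and provenance.

    ``members`` maps gene -> direction ("over"/"under"; "mixed" only in merged
    sets where sources disagree).  ``provenance`` maps gene -> list of
    (source label, direction) pairs and always retains conflicting calls
    side by side.
    """

    label: str
    disease: str = "other"
    members: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.provenance:
            self.provenance = {g: [(self.label, d)] for g, d in self.members.items()}

    def genes(self) -> set[str]:
        return set(self.members)

    def genes_with_direction(self, direction: str) -> set[str]:
        return {g for g, d in self.members.items() if d == direction}

    def __len__(self) -> int:
        return len(self.members)


def student_t(
    values_case: Sequence[float],
    values_control: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default).

    Returns ``(t, p)``.  Two constant, equal groups give ``(0.0, 1.0)``;
    a zero-variance separation gives the smallest positive p rather than 0.
    """
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"need >=2 values per group, got {a.size} and {b.size}"
        )
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return _sanitize_tp(float(t), float(p), float(a.mean() - b.mean()))


def _sanitize_tp(t: float, p: float, mean_diff: float) -> tuple[float, float]:
    if np.isnan(t):  # zero variance in both groups
        if mean_diff == 0.0:
            return 0.0, 1.0
        return (np.inf if mean_diff > 0 else -np.inf), _TINY_P
    return t, min(max(p, _TINY_P), 1.0)


def de_table(expr: ExpressionMatrix, equal_var: bool = True) -> pd.DataFrame:
    """Per-probe t-test table: probe, gene, t_stat, p_value, means, direction."""
    case = expr.values[:, expr.group_columns("case")]
    ctrl = expr.values[:, expr.group_columns("control")]
    t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    diff = mean_case - mean_ctrl
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    nan = np.isnan(t)
    # constant-in-both-groups probes: p=1 when means agree, else maximally significant
    t[nan & (diff == 0)] = 0.0
    p[nan & (diff == 0)] = 1.0
    t[nan & (diff > 0)] = np.inf
    t[nan & (diff < 0)] = -np.inf
    p[nan & (diff != 0)] = _TINY_P
    p = np.clip(p, _TINY_P, 1.0)
    return pd.DataFrame(
        {
            "probe": expr.probe_ids,
            "gene": [expr.gene_of_probe[pr] for pr in expr.probe_ids],
            "t_stat": t,
            "p_value": p,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "direction": np.where(diff > 0, "over", "under"),
        }
    )


def aggregate_probes(
    probe_table: pd.DataFrame, method: Literal["min", "mean"] = "min"
) -> pd.DataFrame:
    """Collapse a per-probe table to one row per gene.

    ``min``: a gene's p is the minimum over its probes and t/direction come
    from that minimal-p probe.  ``mean``: the gene's p is the mean over its
    probes; t/direction still come from the most significant probe so the
    direction call is well defined.
    """
    if method not in ("min", "mean"):
        raise ParameterError(f"unknown probe aggregation method: {method!r}")
    # deterministic tie-break: lowest p, then probe id
    ordered = probe_table.sort_values(["gene", "p_value", "probe"], kind="mergesort")
    best = ordered.drop_duplicates("gene", keep="first").set_index("gene")
    out = best[["t_stat", "p_value", "mean_case", "mean_control", "direction"]].copy()
    if method == "mean":
        out["p_value"] = probe_table.groupby("gene")["p_value"].mean()
    return out.sort_index()


def select_by_pvalue(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    label: str = "de_pvalue",
    disease: str = "other",
    equal_var: bool = True,
    aggregate: Literal["min", "mean"] = "min",
) -> CandidateGeneSet:
    """Select genes whose aggregated two-sided t-test p is below ``alpha``."""
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must be in (0,1), got {alpha}")
    genes = aggregate_probes(de_table(expr, equal_var=equal_var), method=aggregate)
    hits = genes[genes["p_value"] < alpha]
    members = dict(zip(hits.index, hits["direction"]))
    return CandidateGeneSet(label=label, disease=disease, members=members)


def select_top_fraction(
    expr: ExpressionMatrix,
    fraction: float = 0.01,
    label: str = "de_top",
    disease: str = "other",
    equal_var: bool = True,
    aggregate: Literal["min", "mean"] = "min",
) -> CandidateGeneSet:
    """Select the top ``fraction`` most over- and under-expressed genes by t.

    With G testable genes, the floor(fraction*G) most-positive t statistics
    become "over" calls and the floor(fraction*G) most-negative become
    "under"; ties are broken by lexicographic gene symbol.
    """
    if not (0.0 < fraction <= 0.5):
        raise ParameterError(f"fraction must be in (0, 0.5], got {fraction}")
    genes = aggregate_probes(de_table(expr, equal_var=equal_var), method=aggregate)
    n_top = int(np.floor(fraction * len(genes)))
    if n_top < 1:
        raise DegenerateInputError(
            f"fraction {fraction} of {len(genes)} genes selects 0 genes per tail"
        )
    if len(genes) < 2 * n_top:
        raise DegenerateInputError(
            f"{len(genes)} testable genes cannot supply two disjoint tails of {n_top}"
        )
    tbl = genes.reset_index().sort_values(
        ["t_stat", "gene"], ascending=[False, True], kind="mergesort"
    )
    over = tbl.head(n_top)["gene"].tolist()
    under = tbl.tail(n_top).sort_values(
        ["t_stat", "gene"], ascending=[True, True], kind="mergesort"
    ).head(n_top)["gene"].tolist()
    members = {g: "over" for g in over}
    members.update({g: "under" for g in under})
    return CandidateGeneSet(label=label, disease=disease, members=members)


def merge_gene_sets(
    sets: Iterable[CandidateGeneSet], label: str = "merged", disease: str = "other"
) -> CandidateGeneSet:
    """Union candidate sets, retaining per-source direction calls.

    A gene called "over" by one source and "under" by another keeps both
    calls in ``provenance`` and is summarised as "mixed" in ``members``.
    """
    members: dict[str, str] = {}
    provenance: dict[str, list[tuple[str, str]]] = {}
    for s in sets:
        for gene in s.members:
            for src in s.provenance.get(gene, [(s.label, s.members[gene])]):
                entry = provenance.setdefault(gene, [])
                if src not in entry:
                    entry.append(src)
    for gene, sources in provenance.items():
        dirs = {d for _, d in sources if d in ("over", "under")}
        members[gene] = dirs.pop() if len(dirs) == 1 else "mixed"
    return CandidateGeneSet(label=label, disease=disease, members=members, provenance=provenance)


def direction_annotations(
    sets: Iterable[CandidateGeneSet],
) -> dict[str, dict[str, str]]:
    """Per-gene {disease tag: direction} map used to annotate network nodes."""
    out: dict[str, dict[str, str]] = {}
    for s in sets:
        for gene, direction in s.members.items():
            out.setdefault(gene, {})[s.disease] = direction
    return out
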