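"""miRNA-mRNA pathway interaction scoring.

For every differentially regulated precursor miRNA, a pathway-database export
lists its significantly enriched pathways together with the miRNA's annotated
target genes in each pathway.  Cross-referencing those target lists with the
differentially expressed (DE) mRNA list yields one scored node per
(miRNA, pathway) pair:

* ``intersects`` -- the export's enrichment p-value is below 0.05 (the miRNA
  has more targets in the pathway than expected by chance);
* ``percent_overlap`` -- 100 x (DE targets in the pathway) / (all targets in
  the pathway), a count-normalised measure of how much of the pathway's
  targeting is dysregulated;
* ``cumulative_abs_fc`` -- the sum of |fold change| over the DE targets, a
  magnitude-weighted measure independent of target count.

Pathways are binned into seven functional groups (Cancer, Motility, DNA
Repair, Cell Cycle, Apoptosis, Miscellaneous, Canonical) by ordered keyword
inclusion/exclusion rules, and node values are averaged by pathway group, by
miRNA, and by a two-class miRNA relevance annotation, with ANOVA +
Tukey-Kramer HSD group comparisons.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PATHWAY_GROUPS",
    "SubstitutionRule",
    "PathwayGroupRule",
    "InteractionNode",
    "InteractionMatrix",
    "GroupComparison",
    "RuleConfigError",
    "load_rules",
    "default_rules",
    "apply_substitutions",
    "classify_pathway",
    "consolidate_exports",
    "score_node",
    "build_interaction_matrix",
    "count_intersections",
    "aggregate",
    "compare_groups",
    "export_heatmaps",
]

logger = logging.getLogger(__name__)

PATHWAY_GROUPS = (
    "Cancer",
    "Motility",
    "DNA Repair",
    "Cell Cycle",
    "Apoptosis",
    "Miscellaneous",
    "Canonical",
)

#: Enrichment p-value below which a miRNA-pathway pair counts as intersecting.
INTERSECTION_ALPHA = 0.05

EXPORT_COLUMNS = ["mirna", "pathway", "database", "enrichment_p", "targets"]

_SUB_REASONS = ("host_gene", "isoform_merge", "precursor_variant")


class RuleConfigError(ValueError):
    """Malformed or conflicting rule configuration."""


@dataclass(frozen=True)
class SubstitutionRule:
    """Replace an array-reported id with the id used by the pathway database.

    Arrays report some miRNAs via their host gene (e.g. a ``-HG`` suffix) or a
    precursor variant whose mature sequence is identical; the pathway database
    indexes by the canonical mature id, so a one-to-one substitution is needed
    before the exports can be matched.
    """

    reported_id: str
    substituted_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in _SUB_REASONS:
            raise RuleConfigError(
                f"reason must be one of {_SUB_REASONS}, got {self.reason!r}"
            )


@dataclass(frozen=True)
class PathwayGroupRule:
    group: str
    include_keywords: tuple[str, ...]
    exclude_keywords: tuple[str, ...] = ()

    def matches(self, name_lower: str) -> bool:
        if any(kw in name_lower for kw in self.exclude_keywords):
            return False
        return any(kw in name_lower for kw in self.include_keywords)


@dataclass(frozen=True)
class RuleSet:
    substitutions: tuple[SubstitutionRule, ...]
    group_rules: tuple[PathwayGroupRule, ...]  # priority order; Misc fallback


@dataclass(frozen=True)
class InteractionNode:
    mirna: str
    pathway: str
    group: str
    intersects: bool
    n_targets: int
    n_de_targets: int
    percent_overlap: float
    cumulative_abs_fc: float


@dataclass
class InteractionMatrix:
    """All scored nodes plus deterministic row/column orderings.

    ``nodes`` holds one row per (miRNA, pathway) pair present in the exports;
    pairs absent from an export are not nodes and do not enter averages.
    """

    nodes: pd.DataFrame
    mirna_order: list[str]
    pathway_order: list[str]
    pathway_groups: dict[str, str]
    relevance: dict[str, str] = field(default_factory=dict)

    def metric_view(self, metric: str) -> pd.DataFrame:
        """Pivot one metric into a miRNA x pathway matrix (absent pairs 0)."""
        if metric not in ("intersections", "percent_overlap", "cumulative_abs_fc"):
            raise ValueError(f"unknown metric {metric!r}")
        col = "intersects" if metric == "intersections" else metric
        wide = self.nodes.pivot(index="mirna", columns="pathway", values=col)
        wide = wide.reindex(index=self.mirna_order, columns=self.pathway_order)
        wide = wide.fillna(0)
        if metric == "intersections":
            wide = wide.astype(int)
        return wide


def _load_yaml_rules(payload: Mapping) -> RuleSet:
    subs = []
    seen: dict[str, str] = {}
    for entry in payload.get("substitutions", []):
        rule = SubstitutionRule(
            reported_id=entry["reported_id"],
            substituted_id=entry["substituted_id"],
            reason=entry["reason"],
        )
        prior = seen.get(rule.reported_id)
        if prior is not None and prior != rule.substituted_id:
            raise RuleConfigError(
                f"conflicting substitutions for {rule.reported_id!r}: "
                f"{prior!r} vs {rule.substituted_id!r}"
            )
        seen[rule.reported_id] = rule.substituted_id
        subs.append(rule)
    groups = []
    for entry in payload.get("pathway_groups", []):
        groups.append(
            PathwayGroupRule(
                group=entry["group"],
                include_keywords=tuple(k.lower() for k in entry.get("include", [])),
                exclude_keywords=tuple(k.lower() for k in entry.get("exclude", [])),
            )
        )
    for rule in groups:
        if rule.group not in PATHWAY_GROUPS:
            raise RuleConfigError(f"unknown pathway group {rule.group!r}")
    return RuleSet(substitutions=tuple(subs), group_rules=tuple(groups))


def load_rules(path: str | Path) -> RuleSet:
    """Load substitution + pathway-group rules from a YAML file."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, Mapping):
        raise RuleConfigError(f"rule file {path} does not contain a mapping")
    return _load_yaml_rules(payload)


_DEFAULT_RULES: RuleSet | None = None


def default_rules() -> RuleSet:
    """The packaged default rule set (data/interaction_rules.yaml)."""
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        path = importlib.resources.files("mechanomir") / "data" / "interaction_rules.yaml"
        _DEFAULT_RULES = _load_yaml_rules(yaml.safe_load(path.read_text()))
    return _DEFAULT_RULES


def apply_substitutions(
    reported_ids: Sequence[str],
    rules: Iterable[SubstitutionRule] | None = None,
) -> list[str]:
    """Map reported ids through the substitution rules; unmatched ids pass.

    Substitutions performed are logged; conflicting rules for one reported id
    raise RuleConfigError.
    """
    rules = list(rules) if rules is not None else list(default_rules().substitutions)
    mapping: dict[str, str] = {}
    for rule in rules:
        prior = mapping.get(rule.reported_id)
        if prior is not None and prior != rule.substituted_id:
            raise RuleConfigError(
                f"conflicting substitutions for {rule.reported_id!r}"
            )
        mapping[rule.reported_id] = rule.substituted_id
    out = []
    for rid in reported_ids:
        sub = mapping.get(rid, rid)
        if sub != rid:
            logger.info("substituted %s -> %s", rid, sub)
        out.append(sub)
    return out


def classify_pathway(
    name: str, rules: Sequence[PathwayGroupRule] | None = None
) -> str:
    """Assign a pathway name to a functional group by ordered keyword rules.

    The first rule (in priority order) whose include keyword appears in the
    lowercased name -- and none of whose exclude keywords do -- wins;
    anything unmatched falls back to Miscellaneous, so the function is total.
    """
    rules = rules if rules is not None else default_rules().group_rules
    name_lower = name.lower()
    for rule in rules:
        if rule.matches(name_lower):
            return rule.group
    return "Miscellaneous"


def _coerce_targets(value) -> frozenset[str]:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, str):
        return frozenset(t for t in value.split(";") if t)
    return frozenset(value)


def consolidate_exports(exports: pd.DataFrame) -> pd.DataFrame:
    """Merge duplicate (miRNA, pathway) rows into one node-candidate each.

    Rows for the same pathway reported by several source databases (or listed
    twice) are merged: target sets are unioned, the minimum enrichment p is
    kept, and the database labels are join-sorted.  The result carries one
    row per (mirna, pathway).
    """
    missing = [c for c in EXPORT_COLUMNS if c not in exports.columns]
    if missing:
        raise KeyError(f"export table missing columns: {missing}")
    df = exports.copy()
    df["targets"] = df["targets"].map(_coerce_targets)
    grouped = df.groupby(["mirna", "pathway"], sort=False).agg(
        database=("database", lambda s: ";".join(sorted(set(s)))),
        enrichment_p=("enrichment_p", "min"),
        targets=("targets", lambda s: frozenset().union(*s)),
    )
    return grouped.reset_index()


def score_node(
    targets: Iterable[str],
    enrichment_p: float,
    de_map: Mapping[str, float],
    *,
    mirna: str = "",
    pathway: str = "",
    group: str = "",
) -> InteractionNode:
    """Score one miRNA-pathway pair against the DE mRNA list.

    ``de_map`` maps DE gene ids to their signed fold change; only |FC| enters
    the cumulative score.
    """
    tset = frozenset(targets)
    if not tset:
        raise ValueError("target set must be nonempty")
    de_hits = [t for t in tset if t in de_map]
    n_de = len(de_hits)
    return InteractionNode(
        mirna=mirna,
        pathway=pathway,
        group=group,
        intersects=bool(enrichment_p < INTERSECTION_ALPHA),
        n_targets=len(tset),
        n_de_targets=n_de,
        percent_overlap=100.0 * n_de / len(tset),
        cumulative_abs_fc=float(sum(abs(de_map[t]) for t in de_hits)),
    )


def build_interaction_matrix(
    exports: pd.DataFrame,
    de_map: Mapping[str, float],
    rules: RuleSet | None = None,
    relevance: Mapping[str, str] | None = None,
) -> InteractionMatrix:
    """Score every export row and assemble the full interaction matrix.

    Reported miRNA ids are passed through the substitution rules, duplicate
    pathways consolidated, every pathway classified, and every surviving
    (miRNA, pathway) pair scored.  Row order groups miRNAs by the relevance
    annotation (annotated classes sorted, unannotated last), column order
    blocks pathways by functional group.
    """
    rules = rules if rules is not None else default_rules()
    relevance = dict(relevance or {})
    df = exports.copy()
    df["mirna"] = apply_substitutions(list(df["mirna"]), rules.substitutions)
    df = consolidate_exports(df)
    groups = {p: classify_pathway(p, rules.group_rules) for p in df["pathway"].unique()}
    for p, g in groups.items():
        if g == "Miscellaneous":
            logger.info("pathway %r unmatched by keyword rules -> Miscellaneous", p)

    records = []
    for row in df.itertuples(index=False):
        node = score_node(
            row.targets,
            row.enrichment_p,
            de_map,
            mirna=row.mirna,
            pathway=row.pathway,
            group=groups[row.pathway],
        )
        rec = node.__dict__ | {"database": row.database}
        records.append(rec)
    nodes = pd.DataFrame.from_records(
        records,
        columns=[
            "mirna", "pathway", "group", "database", "intersects",
            "n_targets", "n_de_targets", "percent_overlap", "cumulative_abs_fc",
        ],
    )
    if relevance:
        nodes["relevance_group"] = nodes["mirna"].map(
            lambda m: relevance.get(m, "unannotated")
        )

    mirnas = sorted(
        nodes["mirna"].unique(),
        key=lambda m: (relevance.get(m, "~unannotated"), m),
    )
    group_rank = {g: i for i, g in enumerate(PATHWAY_GROUPS)}
    pathways = sorted(groups, key=lambda p: (group_rank[groups[p]], p))
    return InteractionMatrix(
        nodes=nodes,
        mirna_order=list(mirnas),
        pathway_order=pathways,
        pathway_groups=groups,
        relevance=relevance,
    )


def count_intersections(matrix: InteractionMatrix, pathway: str) -> int:
    """Number of miRNAs whose targets are significantly enriched in a pathway."""
    if pathway not in matrix.pathway_groups:
        raise KeyError(f"unknown pathway {pathway!r}")
    sel = matrix.nodes[matrix.nodes["pathway"] == pathway]
    return int(sel["intersects"].sum())


_BY_COLUMN = {
    "pathway_group": "group",
    "mirna": "mirna",
    "relevance_group": "relevance_group",
}


def aggregate(
    matrix: InteractionMatrix, by: str, metric: str
) -> pd.DataFrame:
    """Mean +/- SEM of a node metric per group of nodes.

    Every node present in the exports contributes, including zero-valued
    ones.  For ``by="pathway_group"`` all seven groups are reported; a group
    with no nodes comes back with n = 0 and NaN mean/SEM.
    """
    if metric not in ("percent_overlap", "cumulative_abs_fc"):
        raise ValueError(f"unknown metric {metric!r}")
    if by not in _BY_COLUMN:
        raise ValueError(f"unknown grouping {by!r}; options: {sorted(_BY_COLUMN)}")
    col = _BY_COLUMN[by]
    nodes = matrix.nodes
    if col not in nodes.columns:
        raise ValueError(
            f"grouping {by!r} requires a relevance annotation on the matrix"
        )
    agg = nodes.groupby(col)[metric].agg(
        mean="mean", sem=lambda s: stats.sem(s) if len(s) > 1 else np.nan, n="size"
    )
    if by == "pathway_group":
        agg = agg.reindex(PATHWAY_GROUPS)
        agg["n"] = agg["n"].fillna(0).astype(int)
    out = agg.reset_index().rename(columns={col: by})
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus ANOVA + Tukey-Kramer pairwise comparisons over node values."""

    metric: str
    by: str
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]  # compact letter display; shared letter = n.s.
    alpha: float
    skipped: str | None = None  # reason, when the tests could not run


def _compact_letters(
    groups: Sequence[str], reject: Mapping[tuple[str, str], bool]
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups sharing a letter are not significantly different.
    """
    sets: list[set[str]] = [set(groups)]
    for (g1, g2), rej in reject.items():
        if not rej:
            continue
        for s in list(sets):
            if g1 in s and g2 in s:
                sets.remove(s)
                sets.extend([s - {g1}, s - {g2}])
        # absorb subsets
        sets = [s for s in sets if s and not any(s < t for t in sets)]
        deduped = []
        for s in sets:
            if s not in deduped:
                deduped.append(s)
        sets = deduped
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        for g in s:
            letters[g] += alphabet[i % len(alphabet)]
    return letters


def compare_groups(
    matrix: InteractionMatrix, by: str, metric: str, alpha: float = 0.05
) -> GroupComparison:
    """ANOVA + Tukey-Kramer HSD on node values grouped by pathway group,
    miRNA, or relevance class.

    Groups with fewer than two nodes are dropped from the tests; if fewer
    than two groups remain, or the pooled values are degenerate (zero
    variance), the comparison is reported as skipped rather than invented.
    """
    col = _BY_COLUMN[by]
    nodes = matrix.nodes
    if col not in nodes.columns:
        raise ValueError(f"grouping {by!r} requires a relevance annotation")
    counts = nodes[col].value_counts()
    keep = counts[counts >= 2].index
    sub = nodes[nodes[col].isin(keep)]
    groups = sorted(sub[col].unique())

    def _skip(reason: str) -> GroupComparison:
        return GroupComparison(
            metric=metric, by=by, anova_p=float("nan"),
            tukey=pd.DataFrame(
                columns=["group1", "group2", "meandiff", "p_adj", "reject"]
            ),
            letters={g: "a" for g in groups}, alpha=alpha, skipped=reason,
        )

    if len(groups) < 2:
        return _skip("fewer than two groups with >= 2 nodes")
    samples = [sub.loc[sub[col] == g, metric].to_numpy(float) for g in groups]
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(np.concatenate(samples)) == 0:
        return _skip("degenerate (zero-variance) node values")
    anova_p = float(stats.f_oneway(*samples).pvalue)
    res = pairwise_tukeyhsd(
        endog=sub[metric].to_numpy(float),
        groups=sub[col].to_numpy(),
        alpha=alpha,
    )
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )[["group1", "group2", "meandiff", "p-adj", "reject"]]
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    reject = {
        (str(r.group1), str(r.group2)): bool(r.reject)
        for r in tukey.itertuples(index=False)
    }
    letters = _compact_letters(groups, reject)
    return GroupComparison(
        metric=metric, by=by, anova_p=anova_p, tukey=tukey,
        letters=letters, alpha=alpha,
    )


def export_heatmaps(
    matrix: InteractionMatrix, outdir: str | Path, prefix: str = "heatmap"
) -> dict[str, Path]:
    """Write the three metric matrices as TSV (rows miRNA, columns pathways).

    Returns the metric -> path mapping.  Files round-trip bit-exactly through
    pandas.read_csv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for metric in ("intersections", "percent_overlap", "cumulative_abs_fc"):
        view = matrix.metric_view(metric)
        path = outdir / f"{prefix}_{metric}.tsv"
        view.to_csv(path, sep="\t")
        paths[metric] = path
    return paths
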