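"""Stage-robust miRNA-family / target-network inference.

The five-filter cascade, applied to families of differentially expressed
miRNAs (DEmiRs) against stage-wise differentially expressed genes (DEGs):

1. top-k & stage-robust DE — the family has a member among the top-k
   (default 50) most highly expressed DEmiRs (mean RPM across all samples)
   and is DE with a consistent sign at every stage;
2. conservation — the family is conserved in mouse, rat and human;
3. target filter — it has predicted targets with weighted context++ score
   percentile strictly above 50 and at least one seed site;
4. anti-correlation — at every stage at least one filtered target is a DEG
   moving opposite to the family;
5. minimum conserved targets — at every stage at least ``min_targets``
   (default 10) of those anti-correlated targets have a conserved site.

Families eliminated at step 1 carry a fine-grained reason (``top_k`` vs
``de_all_stages``) in the elimination record, so every negative control can
be attributed to exactly one filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .containers import (
    DETable,
    ExpressionMatrix,
    FamilyRegistry,
    MirnetError,
    TargetPredictionTable,
    TransformState,
)

CASCADE_STEPS = (
    "de_all_stages_top_k",
    "conservation",
    "target_filter",
    "anti_correlation",
    "min_conserved_targets",
)


@dataclass
class MiRFamilyRecord:
    family_id: str
    members: list[str]
    species_conservation: set[str]
    direction_by_stage: dict[str, str]  # up/down/ns per stage
    mean_rpm_rank: int | None = None

    def consistent_direction(self, stages: list[str]) -> str | None:
        """The single non-ns direction shared across all stages, else None."""
        dirs = {self.direction_by_stage.get(s, "ns") for s in stages}
        if len(dirs) == 1 and "ns" not in dirs:
            return dirs.pop()
        return None


@dataclass(frozen=True)
class NetworkEdge:
    family_id: str
    gene_id: str
    stage: str
    mirna_direction: str
    gene_direction: str
    conserved_site: bool

    def __post_init__(self) -> None:
        if self.mirna_direction == "ns" or self.gene_direction == "ns":
            raise MirnetError("network edges require non-ns directions on both ends")
        if self.mirna_direction == self.gene_direction:
            raise MirnetError("network edges must be anti-correlated")


@dataclass
class IntegrationResult:
    selected_families: list[str]
    edges_by_stage: dict[str, list[NetworkEdge]]
    cascade: list[tuple[str, int]]  # (filter name, surviving family count)
    eliminated: dict[str, str]  # family -> fine-grained filter that removed it
    top_share: float
    family_records: dict[str, MiRFamilyRecord] = field(default_factory=dict)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": e.stage,
                "family_id": e.family_id,
                "gene_id": e.gene_id,
                "mirna_direction": e.mirna_direction,
                "gene_direction": e.gene_direction,
                "conserved_site": e.conserved_site,
            }
            for stage in self.edges_by_stage
            for e in self.edges_by_stage[stage]
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "stage",
                "family_id",
                "gene_id",
                "mirna_direction",
                "gene_direction",
                "conserved_site",
            ],
        )

    def to_networkx(self) -> nx.Graph:
        """Bipartite family-gene graph of the selected networks."""
        g = nx.Graph()
        for stage, edges in self.edges_by_stage.items():
            for e in edges:
                if e.family_id not in self.selected_families:
                    continue
                g.add_node(e.family_id, kind="family")
                g.add_node(e.gene_id, kind="gene")
                if g.has_edge(e.family_id, e.gene_id):
                    g[e.family_id][e.gene_id]["stages"].append(stage)
                else:
                    g.add_edge(
                        e.family_id, e.gene_id, stages=[stage], conserved_site=e.conserved_site
                    )
        return g


def expression_share(expr: ExpressionMatrix, k: int) -> float:
    """Fraction of total mean expression carried by the k most abundant features.

    Operates on linear (RPM) values; boundary ties are broken by feature id.
    """
    if k <= 0:
        raise MirnetError("k must be positive")
    expr.require_state(TransformState.LINEAR)
    if k > expr.values.shape[0]:
        raise MirnetError(f"k={k} exceeds the {expr.values.shape[0]} available features")
    means = expr.values.mean(axis=1)
    ordered = means.sort_index().sort_values(ascending=False, kind="stable")
    return float(ordered.iloc[:k].sum() / ordered.sum())


def rank_by_mean_expression(expr: ExpressionMatrix) -> pd.Series:
    """Features sorted by descending mean linear expression (ties by id)."""
    expr.require_state(TransformState.LINEAR)
    means = expr.values.mean(axis=1)
    return means.sort_index().sort_values(ascending=False, kind="stable")


def build_family_records(
    demirs: DETable, registry: FamilyRegistry, expr: ExpressionMatrix | None = None
) -> dict[str, MiRFamilyRecord]:
    """Aggregate per-miRNA DE calls to the family level.

    A family is DE at a stage if at least one member is DE there; its
    direction is the sign shared by every DE member, and ns when members
    disagree.
    """
    stages = demirs.stages
    direction = {
        (r.feature_id, r.stage): r.direction for r in demirs.records.itertuples(index=False)
    }
    records: dict[str, MiRFamilyRecord] = {}
    members_by_family: dict[str, list[str]] = {}
    for row in registry.table.itertuples(index=False):
        members_by_family.setdefault(row.family_id, []).append(row.mirna_id)
    for fam in registry.families():
        members = members_by_family[fam]
        direction_by_stage = {}
        for s in stages:
            dirs = {
                d for m in members if (d := direction.get((m, s), "ns")) != "ns"
            }
            direction_by_stage[s] = dirs.pop() if len(dirs) == 1 else "ns"
        records[fam] = MiRFamilyRecord(
            family_id=fam,
            members=members,
            species_conservation=registry.species_conservation(fam),
            direction_by_stage=direction_by_stage,
        )
    if expr is not None:
        ranking = rank_by_mean_expression(expr)
        rank_of = {f: i for i, f in enumerate(ranking.index, start=1)}
        for rec in records.values():
            ranks = [rank_of[m] for m in rec.members if m in rank_of]
            rec.mean_rpm_rank = min(ranks) if ranks else None
    return records


def select_top_expressed(
    demirs: DETable, expr: ExpressionMatrix, registry: FamilyRegistry, k: int = 50
) -> set[str]:
    """Families with a member among the top-k most highly expressed DEmiRs.

    DEmiRs (DE at >=1 stage) are ranked by mean RPM across all samples; the
    top k miRNAs are kept and mapped to families (a family survives if any
    member survives). k larger than the DEmiR count keeps every DEmiR.
    """
    de_features = demirs.de_features()
    ranking = rank_by_mean_expression(expr)
    ranked_demirs = [f for f in ranking.index if f in de_features]
    kept = set(ranked_demirs[:k])
    return {registry.family_of(m) for m in kept}


def conservation_filter(
    families: set[str], records: dict[str, MiRFamilyRecord]
) -> set[str]:
    """Retain families conserved in all of mouse, rat and human."""
    return {
        f
        for f in families
        if records[f].species_conservation >= {"mouse", "rat", "human"}
    }


def filter_targets(
    predictions: TargetPredictionTable, wcsp_threshold: float = 50.0, min_seed_sites: int = 1
) -> TargetPredictionTable:
    """Keep predictions with WCSP strictly above the threshold and enough seed sites."""
    t = predictions.table
    kept = t[(t["wcsp"] > wcsp_threshold) & (t["seed_sites"] >= min_seed_sites)]
    return TargetPredictionTable(kept.reset_index(drop=True))


def anti_correlated_targets(
    family: MiRFamilyRecord,
    degs: DETable,
    predictions: TargetPredictionTable,
    stage: str,
) -> list[NetworkEdge]:
    """Edges to predicted targets whose DEG direction opposes the family's.

    ``predictions`` must already be WCSP/seed filtered. A family that is ns
    at the stage contributes no edges (not an error). Multiple prediction
    rows for one gene collapse to a single edge; the edge is conserved-site
    if any row is.
    """
    fam_dir = family.direction_by_stage.get(stage, "ns")
    if fam_dir == "ns":
        return []
    opposite = "down" if fam_dir == "up" else "up"
    opp_genes = degs.features_with_direction(stage, opposite)
    sub = predictions.for_family(family.family_id)
    sub = sub[sub["gene_id"].isin(opp_genes)]
    if sub.empty:
        return []
    conserved = sub.groupby("gene_id", sort=True)["conserved_site"].any()
    return [
        NetworkEdge(
            family_id=family.family_id,
            gene_id=gene,
            stage=stage,
            mirna_direction=fam_dir,
            gene_direction=opposite,
            conserved_site=bool(cons),
        )
        for gene, cons in conserved.items()
    ]


def select_robust_families(
    demirs: DETable,
    degs: DETable,
    mirna_expr: ExpressionMatrix,
    predictions: TargetPredictionTable,
    registry: FamilyRegistry,
    k: int = 50,
    min_targets: int = 10,
    wcsp_threshold: float = 50.0,
    min_seed_sites: int = 1,
) -> IntegrationResult:
    """Run the full five-filter cascade and return the selected networks."""
    stages = demirs.stages
    records = build_family_records(demirs, registry, mirna_expr)
    eliminated: dict[str, str] = {}
    cascade: list[tuple[str, int]] = []

    # families that are DEmiR families at all (candidates entering the cascade)
    entering = {
        f for f, rec in records.items() if any(d != "ns" for d in rec.direction_by_stage.values())
    }

    # -- filter 1: top-k DEmiRs AND DE with consistent sign at every stage
    top_families = select_top_expressed(demirs, mirna_expr, registry, k)
    survivors = set()
    for f in sorted(entering):
        if f not in top_families:
            eliminated[f] = "top_k"
        elif records[f].consistent_direction(stages) is None:
            eliminated[f] = "de_all_stages"
        else:
            survivors.add(f)
    cascade.append((CASCADE_STEPS[0], len(survivors)))

    # -- filter 2: 3-species conservation
    conserved = conservation_filter(survivors, records)
    for f in sorted(survivors - conserved):
        eliminated[f] = "conservation"
    survivors = conserved
    cascade.append((CASCADE_STEPS[1], len(survivors)))

    # -- filter 3: predicted targets passing WCSP/seed-site thresholds
    filtered_predictions = filter_targets(predictions, wcsp_threshold, min_seed_sites)
    with_targets = {f for f in survivors if not filtered_predictions.for_family(f).empty}
    for f in sorted(survivors - with_targets):
        eliminated[f] = "target_filter"
    survivors = with_targets
    cascade.append((CASCADE_STEPS[2], len(survivors)))

    # -- filter 4: anti-correlated counterpart DEGs at every stage
    edges_by_stage: dict[str, list[NetworkEdge]] = {s: [] for s in stages}
    per_family_edges: dict[str, dict[str, list[NetworkEdge]]] = {}
    for f in sorted(survivors):
        per_family_edges[f] = {
            s: anti_correlated_targets(records[f], degs, filtered_predictions, s) for s in stages
        }
    anti = {f for f in survivors if all(per_family_edges[f][s] for s in stages)}
    for f in sorted(survivors - anti):
        eliminated[f] = "anti_correlation"
    survivors = anti
    cascade.append((CASCADE_STEPS[3], len(survivors)))
    for f in sorted(survivors):
        for s in stages:
            edges_by_stage[s].extend(per_family_edges[f][s])

    # -- filter 5: >= min_targets conserved-site targets at every stage
    robust = {
        f
        for f in survivors
        if all(
            sum(1 for e in per_family_edges[f][s] if e.conserved_site) >= min_targets
            for s in stages
        )
    }
    for f in sorted(survivors - robust):
        eliminated[f] = "min_conserved_targets"
    cascade.append((CASCADE_STEPS[4], len(robust)))

    counts = [c for _, c in cascade]
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise MirnetError("cascade counts must be non-increasing")

    return IntegrationResult(
        selected_families=sorted(robust),
        edges_by_stage=edges_by_stage,
        cascade=cascade,
        eliminated=eliminated,
        top_share=expression_share(mirna_expr, min(k, mirna_expr.values.shape[0])),
        family_records=records,
    )


def export_network(result: IntegrationResult, outdir) -> dict[str, object]:
    """Write per-stage edge lists and a per-family summary; return the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edge_path = outdir / "network_edges.tsv"
    result.edge_frame().to_csv(edge_path, sep="\t", index=False)

    rows = []
    stages = list(result.edges_by_stage)
    for fam in sorted(result.family_records):
        rec = result.family_records[fam]
        if fam not in {e.family_id for es in result.edges_by_stage.values() for e in es} and (
            fam not in result.selected_families
        ):
            continue
        row = {
            "family_id": fam,
            "selected": fam in result.selected_families,
            "direction": rec.consistent_direction(stages) or "mixed",
        }
        for s in stages:
            edges = [e for e in result.edges_by_stage[s] if e.family_id == fam]
            row[f"n_targets_{s}"] = len(edges)
            row[f"n_conserved_targets_{s}"] = sum(1 for e in edges if e.conserved_site)
        rows.append(row)
    summary_cols = ["family_id", "selected", "direction"]
    for s in stages:
        summary_cols += [f"n_targets_{s}", f"n_conserved_targets_{s}"]
    summary_path = outdir / "network_summary.tsv"
    pd.DataFrame(rows, columns=summary_cols).to_csv(summary_path, sep="\t", index=False)

    cascade_path = outdir / "cascade.tsv"
    pd.DataFrame(result.cascade, columns=["filter", "n_families"]).to_csv(
        cascade_path, sep="\t", index=False
    )
    return {"edges": edge_path, "summary": summary_path, "cascade": cascade_path}
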