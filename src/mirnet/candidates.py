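"""Candidate-target cascade: from predicted targets to apoptosis candidates.

For a stage-consistent DE miRNA family, the cascade narrows its predicted
target genes in four steps: (1) all predicted targets; (2) targets with
WCSP > 50 and at least one seed site; (3) targets that are DEGs moving
opposite to the family (union over stages by default, or a single stage);
(4) targets annotated with an apoptosis GO term chosen by the family's
direction — a down-regulated family is intersected with "positive regulation
of apoptotic process" (its de-repressed targets are pro-apoptotic) and an
up-regulated family with "negative regulation of apoptotic process".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .containers import DETable, GOAnnotationTable, MirnetError, TargetPredictionTable
from .integrate import filter_targets
from .simulate import NEGATIVE_APOPTOSIS_TERM, POSITIVE_APOPTOSIS_TERM

STEP_NAMES = ("predicted_targets", "wcsp_seed_filter", "opposite_degs", "go_term")


@dataclass
class CandidateCascade:
    family_id: str
    direction: str
    stage_scope: str  # "union" or a stage label
    go_term: str
    counts: list[tuple[str, int]]  # ordered (step name, surviving gene count)
    final_candidates: set[str]

    def __post_init__(self) -> None:
        sizes = [n for _, n in self.counts]
        if any(b > a for a, b in zip(sizes, sizes[1:])):
            raise MirnetError("cascade counts must be non-increasing")


def default_go_term(direction: str) -> str:
    if direction == "down":
        return POSITIVE_APOPTOSIS_TERM
    if direction == "up":
        return NEGATIVE_APOPTOSIS_TERM
    raise MirnetError(f"family direction must be up or down, got {direction!r}")


def apoptosis_candidates(
    family_id: str,
    direction: str,
    predictions: TargetPredictionTable,
    degs: DETable,
    go: GOAnnotationTable,
    go_term: str | None = None,
    stage_scope: str = "union",
    wcsp_threshold: float = 50.0,
    min_seed_sites: int = 1,
) -> CandidateCascade:
    """Run the four-step candidate cascade for one family."""
    if go_term is None:
        go_term = default_go_term(direction)
    if not go.has_term(go_term):
        raise MirnetError(f"GO term {go_term!r} absent from the annotation table")
    if direction not in ("up", "down"):
        raise MirnetError(f"family direction must be up or down, got {direction!r}")

    predicted = set(predictions.for_family(family_id)["gene_id"])
    filtered = set(
        filter_targets(predictions, wcsp_threshold, min_seed_sites).for_family(family_id)["gene_id"]
    )

    opposite = "up" if direction == "down" else "down"
    if stage_scope == "union":
        opp_degs: set[str] = set()
        for stage in degs.stages:
            opp_degs |= degs.features_with_direction(stage, opposite)
    else:
        if stage_scope not in degs.stages:
            raise MirnetError(f"stage {stage_scope!r} absent from DE table")
        opp_degs = degs.features_with_direction(stage_scope, opposite)
    step3 = filtered & opp_degs
    step4 = step3 & go.genes_for(go_term)

    counts = [
        (STEP_NAMES[0], len(predicted)),
        (STEP_NAMES[1], len(filtered)),
        (STEP_NAMES[2], len(step3)),
        (STEP_NAMES[3], len(step4)),
    ]
    return CandidateCascade(
        family_id=family_id,
        direction=direction,
        stage_scope=stage_scope,
        go_term=go_term,
        counts=counts,
        final_candidates=step4,
    )


def cascade_report(cascades: list[CandidateCascade], path: str | Path | None = None) -> pd.DataFrame:
    """One row per (family, step) with surviving counts; stable ordering."""
    rows = []
    for c in sorted(cascades, key=lambda c: c.family_id):
        for i, (step_name, n) in enumerate(c.counts):
            rows.append(
                {
                    "family_id": c.family_id,
                    "step": i + 1,
                    "step_name": step_name,
                    "n_surviving": n,
                    "final": i == len(c.counts) - 1,
                }
            )
    df = pd.DataFrame(rows, columns=["family_id", "step", "step_name", "n_surviving", "final"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def candidate_list(cascades: list[CandidateCascade], path: str | Path | None = None) -> pd.DataFrame:
    rows = [
        {"family_id": c.family_id, "gene_id": g, "go_term": c.go_term}
        for c in sorted(cascades, key=lambda c: c.family_id)
        for g in sorted(c.final_candidates)
    ]
    df = pd.DataFrame(rows, columns=["family_id", "gene_id", "go_term"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
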