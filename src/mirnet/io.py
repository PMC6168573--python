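"""Readers and writers for the pipeline's on-disk formats.

All tables are UTF-8 TSV with a header row, '.' decimal, no thousands
separators; matrices keep the feature id in the first column. The mRNA count
matrix carries the feature length (bases) as its second column. Gene sets use
the standard GMT layout (name, description, tab-separated members). The
planted-truth document and expression-matrix sidecars are YAML with sorted
keys so serialization is byte-stable.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import yaml

from .containers import (
    CountMatrix,
    DETable,
    ExpressionMatrix,
    FamilyRegistry,
    GeneSet,
    GeneSetCollection,
    GOAnnotationTable,
    MirnetError,
    SampleDesign,
    TargetPredictionTable,
    TransformState,
)

_BOOL_MAP = {"True": True, "False": False, "1": True, "0": False}


def _read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MirnetError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except Exception as exc:  # surface the offending path
        raise MirnetError(f"failed to parse {path}: {exc}") from exc


def write_design(design: SampleDesign, path: str | os.PathLike) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_design(path: str | os.PathLike) -> SampleDesign:
    return SampleDesign(_read_tsv(path, dtype={"sample_id": str, "stage": str}))


def write_counts(counts: CountMatrix, path: str | os.PathLike) -> None:
    df = counts.counts.copy()
    if counts.lengths is not None:
        df.insert(0, "length", counts.lengths)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_counts(path: str | os.PathLike, design: SampleDesign, layer: str) -> CountMatrix:
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise MirnetError(f"{path}: duplicate feature ids {dupes}")
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length").astype(int)
    return CountMatrix(df.astype(int), design, layer, lengths)


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = expr.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")
    meta = {"layer": expr.layer, "transform_state": expr.transform_state.value}
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_expression(path: str | os.PathLike, design: SampleDesign) -> ExpressionMatrix:
    df = _read_tsv(path, index_col=0)
    meta_path = Path(str(path) + ".meta.yaml")
    if not meta_path.exists():
        raise MirnetError(f"missing expression sidecar: {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    return ExpressionMatrix(
        df.astype(float), design, meta["layer"], TransformState(meta["transform_state"])
    )


def write_de_table(table: DETable, path: str | os.PathLike) -> None:
    df = table.records.copy()
    df["alpha"] = table.alpha
    df["fc_threshold"] = table.fc_threshold
    df.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | os.PathLike) -> DETable:
    df = _read_tsv(path, dtype={"feature_id": str, "stage": str})
    alpha = float(df["alpha"].iloc[0]) if "alpha" in df.columns else 0.05
    fc = float(df["fc_threshold"].iloc[0]) if "fc_threshold" in df.columns else 2.0
    df = df.drop(columns=[c for c in ("alpha", "fc_threshold") if c in df.columns])
    return DETable(df, alpha=alpha, fc_threshold=fc)


def write_predictions(pred: TargetPredictionTable, path: str | os.PathLike) -> None:
    pred.table.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | os.PathLike) -> TargetPredictionTable:
    df = _read_tsv(path, dtype={"family_id": str, "gene_id": str})
    for col in ("conserved_mouse", "conserved_rat", "conserved_human", "conserved_site"):
        if df[col].dtype == object:
            df[col] = df[col].map(_BOOL_MAP)
    return TargetPredictionTable(df)


def write_families(reg: FamilyRegistry, path: str | os.PathLike) -> None:
    reg.table.to_csv(path, sep="\t", index=False)


def read_families(path: str | os.PathLike) -> FamilyRegistry:
    df = _read_tsv(path, dtype={"mirna_id": str, "family_id": str})
    for col in ("conserved_mouse", "conserved_rat", "conserved_human"):
        if df[col].dtype == object:
            df[col] = df[col].map(_BOOL_MAP)
    return FamilyRegistry(df)


def write_go_annotations(go: GOAnnotationTable, path: str | os.PathLike) -> None:
    go.table.to_csv(path, sep="\t", index=False)


def read_go_annotations(path: str | os.PathLike) -> GOAnnotationTable:
    return GOAnnotationTable(_read_tsv(path, dtype=str))


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.name}\t{s.description}\t{members}\n")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    path = Path(path)
    if not path.exists():
        raise MirnetError(f"input file not found: {path}")
    sets = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise MirnetError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
        name, description, *members = parts
        sets.append(GeneSet(name, description, frozenset(members)))
    return GeneSetCollection(sets)


def write_yaml(obj: dict, path: str | os.PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True, default_flow_style=False))


def read_yaml(path: str | os.PathLike) -> dict:
    path = Path(path)
    if not path.exists():
        raise MirnetError(f"input file not found: {path}")
    return yaml.safe_load(path.read_text())
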