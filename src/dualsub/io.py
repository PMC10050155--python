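"""Readers and writers for the tool's on-disk formats.

Expression matrices are tab-separated with genes as row names and samples
in columns; gene sets use standard GMT (name, description, members...);
ortholog maps are two-column TSV; classification results are TSV with one
row per sample.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from dualsub.types import (
    ClassificationResult,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologMap,
    UNCLASSIFIED,
)

# header words recognised when deciding whether the first line of an
# ortholog TSV is a header rather than a symbol pair
_ORTHOLOG_HEADER_WORDS = {
    "source", "target", "human", "mouse", "from", "to",
    "gene", "symbol", "ortholog", "orthologue", "human_symbol", "mouse_symbol",
    "hgnc", "mgi", "hsapiens", "mmusculus",
}

RAW_COUNT_WARN_THRESHOLD = 50.0


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-by-samples TSV into an :class:`ExpressionMatrix`.

    The first column holds feature ids, the header row sample ids.
    Duplicate ids, non-numeric cells and missing values are rejected with
    an error naming the offending row/column; values that look like raw
    counts (max > 50) trigger a warning since the classifier expects
    normalised log-scale data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty expression file: {path}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"expression file has no data rows or columns: {path}")
    idx = raw.index.astype(str)
    if idx.duplicated().any():
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValueError(f"duplicate feature row(s) in {path}: {dups}")
    cols = raw.columns.astype(str)
    if cols.duplicated().any():
        dups = sorted(set(cols[cols.duplicated()]))
        raise ValueError(f"duplicate sample column(s) in {path}: {dups}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {raw.iloc[i, j]!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r} in {path}"
        )
    if numeric.to_numpy().max() > RAW_COUNT_WARN_THRESHOLD:
        warnings.warn(
            f"max value {numeric.to_numpy().max():.3g} > {RAW_COUNT_WARN_THRESHOLD:g}: "
            "input looks like raw counts; the classifier expects normalised "
            "log-scale expression",
            UserWarning,
            stacklevel=2,
        )
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, preserving values to 10 significant digits."""
    matrix.data.to_csv(path, sep="\t", float_format="%.12g", index_label="")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need at least name, description and one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.set_names:
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


def read_ortholog_map(
    path: str | Path, direction: str = "human->mouse"
) -> OrthologMap:
    """Read a two-column source/target symbol TSV (optional header row)."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got "
                    f"{len(fields)}"
                )
            s, t = fields[0].strip(), fields[1].strip()
            if lineno == 1 and s.lower() in _ORTHOLOG_HEADER_WORDS and (
                t.lower() in _ORTHOLOG_HEADER_WORDS
            ):
                continue  # header row
            if not s or not t:
                raise ValueError(f"{path}:{lineno}: blank symbol in ortholog pair")
            pairs.append((s, t))
    if not pairs:
        raise ValueError(f"no ortholog pairs found in {path}")
    return OrthologMap.from_pairs(pairs, direction=direction)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for s, t in omap.pairs:
            fh.write(f"{s}\t{t}\n")


def write_results(result: ClassificationResult, path: str | Path) -> None:
    """Serialise calls as TSV: sample, predicted_class, d.<class>..., p, FDR.

    Distances, p-values and FDR are written with 10 significant digits so a
    read-back reproduces them to 1e-9.
    """
    df = result.frame
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(df.columns.tolist())
        for _, row in df.iterrows():
            out = [row["sample"], row["predicted_class"]]
            for col in df.columns[2:]:
                out.append(f"{row[col]:.10g}")
            writer.writerow(out)


def read_results(path: str | Path) -> ClassificationResult:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    dist_cols = [c for c in df.columns if c.startswith("d.")]
    classes = [c[2:] for c in dist_cols]
    for col in ("sample", "predicted_class", "p_value", "FDR"):
        if col not in df.columns:
            raise ValueError(f"results file {path} missing column {col!r}")
    return ClassificationResult(
        samples=df["sample"].astype(str).tolist(),
        classes=classes,
        predicted=df["predicted_class"].astype(str).tolist(),
        distances=df[dist_cols].to_numpy(dtype=float),
        p_values=df["p_value"].to_numpy(dtype=float),
        fdr=df["FDR"].to_numpy(dtype=float),
    )


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample/class TSV (optional header) into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (sample, class)")
    first = df.iloc[0]
    if first.iloc[0].lower() in {"sample", "sample_id", "id"}:
        df = df.iloc[1:]
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="class")
    if ser.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in label file {path}")
    return ser


def write_template_gmt(template, path: str | Path) -> None:
    """Serialise a template as GMT with one line per class.

    Each line is ``<class>|template`` followed by the class's features, so
    a template round-trips through the standard GMT machinery.
    """
    with open(path, "w") as fh:
        for cls in template.classes:
            feats = template.features_by_class[cls]
            if not feats:
                continue
            fh.write("\t".join([f"{cls}|template", template.feature_space, *feats]) + "\n")


def read_template_gmt(path: str | Path):
    """Read a template written by :func:`write_template_gmt`.

    Also accepts plain GMT files whose set names are bare class labels.
    """
    from dualsub.types import SubtypeTemplate

    coll = read_gmt(path)
    features_by_class: dict[str, list[str]] = {}
    spaces = set()
    for name in coll.set_names:
        cls = name.split("|", 1)[0]
        if cls in features_by_class:
            raise ValueError(f"class {cls!r} appears twice in template {path}")
        features_by_class[cls] = coll.sets[name]
        spaces.add(coll.descriptions.get(name, "gene"))
    space = spaces.pop() if len(spaces) == 1 and spaces <= {"gene", "gene_set"} else "gene"
    return SubtypeTemplate(features_by_class, feature_space=space)
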