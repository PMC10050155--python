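"""Cross-species translation of gene lists, templates and matrices.

Ortholog maps are many-to-many: a human symbol may have zero, one or
several mouse counterparts (and vice versa). Gene-list translation keeps
every target of every mappable source, so translated templates can grow;
unmapped symbols are dropped and reported rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dualsub.types import ExpressionMatrix, OrthologMap, SubtypeTemplate

logger = logging.getLogger(__name__)

COLLAPSE_RULES = ("max_variance", "mean", "first")


@dataclass
class TranslationReport:
    """Bookkeeping for one gene-list translation.

    ``n_mapped`` counts distinct input symbols with at least one target;
    ``n_expanded`` counts inputs with more than one target (one-to-many).
    """

    n_input: int
    n_mapped: int
    n_dropped: int
    dropped_symbols: list[str] = field(default_factory=list)
    n_expanded: int = 0

    def __post_init__(self) -> None:
        if self.n_input != self.n_mapped + self.n_dropped:
            raise ValueError("n_input must equal n_mapped + n_dropped")
        if len(self.dropped_symbols) != self.n_dropped:
            raise ValueError("dropped_symbols length must equal n_dropped")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_mapped": self.n_mapped,
            "n_dropped": self.n_dropped,
            "dropped_symbols": list(self.dropped_symbols),
            "n_expanded": self.n_expanded,
        }


def map_genes(
    genes: list[str], omap: OrthologMap
) -> tuple[list[str], TranslationReport]:
    """Translate an ordered gene list through an ortholog map.

    Output is the ordered union of all targets of all mappable inputs,
    de-duplicated by first occurrence; unmapped inputs are reported.
    """
    if not genes:
        raise ValueError("map_genes: empty input gene list")
    fwd = omap.forward
    out: list[str] = []
    seen: set[str] = set()
    dropped: list[str] = []
    n_mapped = 0
    n_expanded = 0
    for g in genes:
        targets = fwd.get(g)
        if not targets:
            dropped.append(g)
            continue
        n_mapped += 1
        if len(targets) > 1:
            n_expanded += 1
        for t in targets:
            if t not in seen:
                seen.add(t)
                out.append(t)
    report = TranslationReport(
        n_input=len(genes),
        n_mapped=n_mapped,
        n_dropped=len(dropped),
        dropped_symbols=dropped,
        n_expanded=n_expanded,
    )
    return out, report


def translate_template(
    template: SubtypeTemplate, omap: OrthologMap
) -> tuple[SubtypeTemplate, dict[str, TranslationReport], list[str]]:
    """Translate a gene-level template class by class.

    Each class list is translated independently via :func:`map_genes`. A
    target symbol reached from more than one class is uninformative as a
    marker and is removed from every class (returned as ``conflicts``).

    Returns (translated template, per-class reports, conflicting symbols).
    """
    if template.feature_space != "gene":
        raise ValueError("translate_template requires a gene-space template")
    translated: dict[str, list[str]] = {}
    reports: dict[str, TranslationReport] = {}
    for cls in template.classes:
        mapped, rep = map_genes(template.features_by_class[cls], omap)
        translated[cls] = mapped
        reports[cls] = rep
    # cross-class collisions: remove from all classes
    owner_count: dict[str, int] = {}
    for cls in template.classes:
        for t in translated[cls]:
            owner_count[t] = owner_count.get(t, 0) + 1
    conflicts = sorted([t for t, n in owner_count.items() if n > 1])
    if conflicts:
        logger.warning(
            "removing %d target symbol(s) mapped from multiple classes: %s",
            len(conflicts), conflicts[:10],
        )
        translated = {
            cls: [t for t in feats if t not in conflicts]
            for cls, feats in translated.items()
        }
    empty = [cls for cls in template.classes if not translated[cls]]
    if empty:
        raise ValueError(
            f"class(es) left empty after ortholog translation: {empty}"
        )
    new_template = SubtypeTemplate(
        translated, feature_space="gene", classes=template.classes
    )
    return new_template, reports, conflicts


def translate_matrix(
    matrix: ExpressionMatrix,
    omap: OrthologMap,
    collapse: str = "max_variance",
) -> ExpressionMatrix:
    """Re-key a matrix's feature rows into the target species' namespace.

    A source row with several targets is duplicated under each; several
    source rows landing on the same target are collapsed by ``collapse``:
    ``max_variance`` keeps the most variable source row, ``mean`` averages
    elementwise, ``first`` keeps the first source row in matrix order.
    Unmapped rows are dropped (count logged).
    """
    if collapse not in COLLAPSE_RULES:
        raise ValueError(f"collapse must be one of {COLLAPSE_RULES}")
    fwd = omap.forward
    target_sources: dict[str, list[str]] = {}
    n_unmapped = 0
    for feat in matrix.feature_ids:
        targets = fwd.get(feat)
        if not targets:
            n_unmapped += 1
            continue
        for t in targets:
            target_sources.setdefault(t, []).append(feat)
    if not target_sources:
        raise ValueError("no matrix rows are mappable through the ortholog map")
    if n_unmapped:
        logger.info("translate_matrix: dropped %d unmapped row(s)", n_unmapped)
    df = matrix.data
    rows = {}
    for target, sources in target_sources.items():
        block = df.loc[sources]
        if len(sources) == 1:
            rows[target] = block.iloc[0]
        elif collapse == "mean":
            rows[target] = block.mean(axis=0)
        elif collapse == "first":
            rows[target] = block.iloc[0]
        else:  # max_variance
            variances = block.var(axis=1, ddof=1).to_numpy()
            rows[target] = block.iloc[int(np.argmax(variances))]
    out_df = pd.DataFrame(rows).T
    return ExpressionMatrix(out_df[matrix.sample_ids])
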