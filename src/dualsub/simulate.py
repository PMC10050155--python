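"""Synthetic dual-species cohorts with planted subtype structure.

Generates a labelled bulk-expression cohort in which each class has a
block of planted marker gene sets shifted upwards by ``delta`` log2
units, an optional fraction of signal-free samples whose truth label is
"unclassified", and a paired second-species gene namespace produced by an
ortholog map with configurable dropout and one-to-many expansion.

Log-scale Gaussian expression is used rather than negative-binomial
counts: the classifier consumes normalised data and its scoring is
rank-based, so the marginal family is immaterial to what the simulation
exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from dualsub.types import (
    ClassificationResult,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologMap,
    UNCLASSIFIED,
)


@dataclass(frozen=True)
class SimParams:
    """Cohort generator settings.

    delta is the class effect (log2 units) added to a class's planted
    marker genes in that class's samples; sigma is the per-gene noise SD.
    frac_null appends extra signal-free samples (truth "unclassified") on
    top of the n_classes * n_per_class labelled samples.
    """

    n_classes: int = 4
    n_per_class: int = 25
    n_genes: int = 2000
    sets_per_class: int = 5
    genes_per_set: int = 20
    delta: float = 1.5
    sigma: float = 1.0
    frac_null: float = 0.2
    ortholog_dropout: float = 0.05
    ortholog_expand: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for p in (self.frac_null, self.ortholog_dropout, self.ortholog_expand):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_classes, self.n_per_class, self.n_genes,
               self.sets_per_class, self.genes_per_set) < 1:
            raise ValueError("counts must be positive")
        if self.ortholog_dropout + self.ortholog_expand > 1:
            raise ValueError("ortholog_dropout + ortholog_expand must be <= 1")

    @property
    def class_names(self) -> list[str]:
        return [f"CMS{i + 1}" for i in range(self.n_classes)]


def simulate_cohort(
    params: SimParams | None = None,
) -> tuple[ExpressionMatrix, pd.Series, GeneSetCollection, OrthologMap, dict]:
    """Generate one reproducible labelled cohort.

    Returns (expression matrix, sample labels, planted gene sets with the
    class truth encoded in set names and descriptions, ortholog map to the
    second-species namespace, truth record).
    """
    params = params or SimParams()
    n_marker_genes = params.n_classes * params.sets_per_class * params.genes_per_set
    if n_marker_genes > params.n_genes:
        raise ValueError(
            f"planted sets need {n_marker_genes} genes but n_genes="
            f"{params.n_genes}"
        )
    rng = np.random.default_rng(params.seed)
    classes = params.class_names

    genes = [f"GENE{i + 1:05d}" for i in range(params.n_genes)]
    n_core = params.n_classes * params.n_per_class
    n_null = int(round(params.frac_null * n_core))
    samples = [f"S{i + 1:04d}" for i in range(n_core + n_null)]
    labels = pd.Series(
        [classes[i // params.n_per_class] for i in range(n_core)]
        + [UNCLASSIFIED] * n_null,
        index=samples,
        name="class",
    )

    mu = rng.uniform(4.0, 10.0, size=params.n_genes)
    values = rng.normal(
        mu[:, None], params.sigma, size=(params.n_genes, len(samples))
    )

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    set_truth: dict[str, str] = {}
    gi = 0
    for ci, cls in enumerate(classes):
        class_gene_idx: list[int] = []
        for si in range(params.sets_per_class):
            members_idx = list(range(gi, gi + params.genes_per_set))
            gi += params.genes_per_set
            name = f"SET_{cls}_{si + 1:02d}"
            sets[name] = [genes[i] for i in members_idx]
            descriptions[name] = f"planted markers of {cls}"
            set_truth[name] = cls
            class_gene_idx.extend(members_idx)
        cols = np.where((labels == cls).to_numpy())[0]
        if params.delta > 0 and cols.size:
            values[np.ix_(class_gene_idx, cols)] += params.delta

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    collection = GeneSetCollection(sets, descriptions)

    # second-species namespace
    pairs: list[tuple[str, str]] = []
    u = rng.uniform(size=params.n_genes)
    for i, g in enumerate(genes):
        stem = f"Gene{i + 1:05d}"
        if u[i] < params.ortholog_dropout:
            continue
        if u[i] < params.ortholog_dropout + params.ortholog_expand:
            pairs.append((g, stem + "a"))
            pairs.append((g, stem + "b"))
        else:
            pairs.append((g, stem))
    omap = OrthologMap.from_pairs(pairs, direction="human->mouse")

    truth = {
        "params": asdict(params),
        "labels": labels.to_dict(),
        "set_truth": set_truth,
        "n_null": n_null,
    }
    return matrix, labels, collection, omap, truth


def concordance(
    calls_a: ClassificationResult, calls_b: ClassificationResult
) -> dict:
    """Agreement between two classification runs on the same samples.

    Computed over samples classified (non-"unclassified") by *both* runs;
    also reports how many calls swapped and how many were unknown in one
    or both runs. With zero co-classified samples the fraction is
    undefined and flagged.
    """
    if set(calls_a.samples) != set(calls_b.samples):
        raise ValueError("the two runs cover different sample universes")
    a = calls_a.calls()
    b = calls_b.calls().loc[a.index]
    both = (a != UNCLASSIFIED) & (b != UNCLASSIFIED)
    n_co = int(both.sum())
    n_agree = int((a[both] == b[both]).sum())
    out = {
        "n_samples": len(a),
        "n_co_classified": n_co,
        "n_agree": n_agree,
        "n_swapped": n_co - n_agree,
        "n_unknown_either": int(len(a) - n_co),
        "defined": n_co > 0,
        "concordance": (n_agree / n_co) if n_co else float("nan"),
    }
    return out
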