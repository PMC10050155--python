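"""Template derivation from a labelled reference cohort.

Three routes produce a subtype template:

* **Option A** (gene level): translate an existing human gene template
  into the mouse namespace through an ortholog map.
* **Option B** (ontology level): ssGSEA-score a large gene-set collection,
  average scores per class, z-score each set's class means and keep sets
  positive in exactly one class and negative in all others.
* **Option C** (curated pathway level): filter four signature collections
  (curated subtype signatures, hallmark pathways, microenvironment
  cell-population markers, and an immune gene panel grouped by an
  L1-penalised multinomial model) with pairwise Welch tests, and take the
  union of the survivors.

Also houses the reverse-translation meta-signature check and the
cross-cohort mean-score concordance used to compare species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.exceptions import ConvergenceWarning

from dualsub.enrichment import ScoringParams, mean_scores_by_class, ssgsea_score
from dualsub.ortholog import TranslationReport, translate_template
from dualsub.types import (
    ExpressionMatrix,
    GeneSetCollection,
    OrthologMap,
    SubtypeTemplate,
    UNCLASSIFIED,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeriveParams:
    """Knobs for template derivation.

    p_threshold
        Pairwise Welch-test cutoff for keeping a signature (default 0.01).
    lasso_folds / lasso_rule / lasso_seed
        Cross-validation setup for the immune-gene grouping; the penalty
        is chosen as the largest lambda whose CV deviance is within one
        standard error of the minimum ("lambda.1se").
    fc_threshold / meta_p / meta_top_n
        Meta-signature gene selection: fold change > fc_threshold (linear
        scale from log2 data), Welch p < meta_p, top meta_top_n by fold
        change.
    """

    p_threshold: float = 0.01
    z_rule: str = "pos_one_neg_rest"
    lasso_folds: int = 10
    lasso_rule: str = "lambda.1se"
    lasso_seed: int = 0
    fc_threshold: float = 4.0
    meta_p: float = 0.05
    meta_top_n: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.lasso_folds < 2:
            raise ValueError("lasso_folds must be >= 2")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")


# ---------------------------------------------------------------------------
# option B: z-score selection


def zscore_class_means(class_means: pd.DataFrame) -> pd.DataFrame:
    """Standardise each set's row of class means to z-scores.

    Uses the sample SD (ddof=1) across the class means. Rows with zero SD
    carry no between-class signal; they are dropped with a warning.
    """
    if class_means.shape[1] < 2:
        raise ValueError("need >= 2 classes to z-score class means")
    mu = class_means.mean(axis=1)
    sd = class_means.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "excluding %d degenerate set(s) with identical class means",
            int(degenerate.sum()),
        )
    kept = class_means.loc[~degenerate]
    return kept.sub(mu[~degenerate], axis=0).div(sd[~degenerate], axis=0)


def select_class_specific_sets(z: pd.DataFrame) -> SubtypeTemplate:
    """Keep sets with z > 0 in exactly one class and z < 0 in all others."""
    classes = list(z.columns)
    features_by_class: dict[str, list[str]] = {c: [] for c in classes}
    zv = z.to_numpy()
    for i, name in enumerate(z.index):
        pos = zv[i] > 0
        if pos.sum() == 1 and (zv[i][~pos] < 0).all():
            features_by_class[classes[int(np.argmax(pos))]].append(name)
    empty = [c for c in classes if not features_by_class[c]]
    if empty:
        raise ValueError(f"no class-specific sets selected for: {empty}")
    return SubtypeTemplate(features_by_class, feature_space="gene_set", classes=classes)


def _labelled_subset(
    expr: ExpressionMatrix, labels: pd.Series
) -> tuple[ExpressionMatrix, pd.Series]:
    """Restrict to confidently labelled samples (drops "unclassified")."""
    lab = labels.astype(str)
    lab = lab[lab != UNCLASSIFIED]
    keep = [s for s in expr.sample_ids if s in set(lab.index)]
    if not keep:
        raise ValueError("no labelled samples available for derivation")
    return ExpressionMatrix(expr.data[keep]), lab.loc[keep]


def derive_option_b(
    expr: ExpressionMatrix,
    labels: pd.Series,
    sets: GeneSetCollection,
    scoring: ScoringParams | None = None,
) -> SubtypeTemplate:
    """Full ontology-level derivation: ssGSEA -> class means -> z -> select."""
    expr, labels = _labelled_subset(expr, labels)
    scores = ssgsea_score(expr, sets, scoring)
    means = mean_scores_by_class(scores, labels)
    return select_class_specific_sets(zscore_class_means(means))


# ---------------------------------------------------------------------------
# option C building blocks


def ttest_filter(
    scores: ExpressionMatrix,
    labels: pd.Series | dict,
    params: DeriveParams | None = None,
    allow_empty: bool = False,
) -> SubtypeTemplate:
    """Keep a set for class k iff it is significantly higher in k than in
    every other class in turn (pairwise Welch test, p < p_threshold, with
    mean_k > mean_j)."""
    params = params or DeriveParams()
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = labels.astype(str)
    lab = labels.loc[scores.sample_ids]
    classes = list(dict.fromkeys(lab))
    counts = lab.value_counts()
    small = [c for c in classes if counts[c] < 3]
    if small:
        raise ValueError(f"class(es) with < 3 samples: {small}")
    groups = {c: scores.data.loc[:, list(lab.index[lab == c])] for c in classes}
    features_by_class: dict[str, list[str]] = {c: [] for c in classes}
    for name in scores.feature_ids:
        vals = {c: groups[c].loc[name].to_numpy(dtype=float) for c in classes}
        means = {c: vals[c].mean() for c in classes}
        k = max(means, key=means.get)
        keep = True
        for j in classes:
            if j == k:
                continue
            stat = scipy.stats.ttest_ind(vals[k], vals[j], equal_var=False)
            if not (means[k] > means[j] and stat.pvalue < params.p_threshold):
                keep = False
                break
        if keep:
            features_by_class[k].append(name)
    return SubtypeTemplate(
        features_by_class,
        feature_space="gene_set",
        classes=classes,
        allow_empty=allow_empty,
    )


def _lambda_path(X: np.ndarray, y_onehot: np.ndarray, n_path: int = 20,
                 eps: float = 3e-3) -> np.ndarray:
    n = X.shape[0]
    resid = y_onehot - y_onehot.mean(axis=0, keepdims=True)
    lam_max = np.abs(X.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * eps, n_path)


def lasso_group_genes(
    expr_subset: ExpressionMatrix,
    labels: pd.Series | dict,
    params: DeriveParams | None = None,
) -> dict[str, list[str]]:
    """Assign candidate genes to classes by L1 multinomial regression.

    Features are standardised; the penalty path is scanned with K-fold
    stratified cross-validated multinomial deviance and lambda chosen by
    the one-standard-error rule. A gene is assigned to the class whose
    coefficient is positive at the chosen lambda; genes positive in
    several classes go to the class with the largest coefficient (logged).
    """
    params = params or DeriveParams()
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = labels.astype(str)
    lab = labels.loc[expr_subset.sample_ids]
    classes = sorted(lab.unique())
    counts = lab.value_counts()
    if (counts < 2).any():
        raise ValueError("need >= 2 samples per class for the LASSO grouping")
    if counts.min() < params.lasso_folds:
        raise ValueError(
            f"smallest class ({counts.min()} samples) cannot fill "
            f"{params.lasso_folds} stratified CV folds without a fold "
            "missing that class"
        )

    df = expr_subset.data
    sd = df.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant gene(s) before the "
            f"LASSO fit: {list(df.index[constant])[:10]}",
            UserWarning,
            stacklevel=2,
        )
        df = df.loc[~constant]
        sd = sd[~constant]
    genes = list(df.index)
    X = ((df.sub(df.mean(axis=1), axis=0)).div(sd, axis=0)).to_numpy().T  # n x p
    y = lab.to_numpy()
    n = X.shape[0]
    y_onehot = np.stack([(y == c).astype(float) for c in classes], axis=1)

    lambdas = _lambda_path(X, y_onehot)
    cv = StratifiedKFold(
        n_splits=params.lasso_folds, shuffle=True, random_state=params.lasso_seed
    )
    folds = list(cv.split(X, y))
    dev = np.full((len(lambdas), len(folds)), np.nan)
    n_eval = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for li, lam in enumerate(lambdas):
            C = 1.0 / (n * lam)
            for fi, (tr, te) in enumerate(folds):
                if len(np.unique(y[tr])) < len(classes):
                    raise ValueError("CV fold missing a class")
                clf = LogisticRegression(
                    l1_ratio=1.0, C=C, solver="saga", max_iter=2000, tol=1e-3
                )
                clf.fit(X[tr], y[tr])
                proba = clf.predict_proba(X[te])
                dev[li, fi] = 2.0 * log_loss(y[te], proba, labels=clf.classes_)
            n_eval = li + 1
            # once held-out deviance has clearly blown past its minimum
            # the rest of the path cannot matter for lambda.min or .1se
            if dev[: n_eval].mean(axis=1)[li] > 2.0 * dev[: n_eval].mean(axis=1).min() + 1.0:
                break
    dev = dev[:n_eval]
    lambdas = lambdas[:n_eval]
    cvm = dev.mean(axis=1)
    cvse = dev.std(axis=1, ddof=1) / np.sqrt(len(folds))
    i_min = int(np.argmin(cvm))
    if params.lasso_rule == "lambda.min":
        i_sel = i_min
    else:  # lambda.1se: largest lambda within one SE of the minimum
        within = np.where(cvm <= cvm[i_min] + cvse[i_min])[0]
        i_sel = int(within[0])  # lambdas are in decreasing order
    lam_sel = lambdas[i_sel]

    final = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam_sel), solver="saga",
        max_iter=10000, tol=1e-5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            final.fit(X, y)
        except ConvergenceWarning as exc:  # pragma: no cover
            raise RuntimeError(
                f"LASSO refit did not converge at lambda={lam_sel:.4g} "
                f"(n={n}, p={len(genes)}): {exc}"
            ) from exc
    coef = pd.DataFrame(final.coef_, index=list(final.classes_), columns=genes)

    groups: dict[str, list[str]] = {c: [] for c in classes}
    for g in genes:
        col = coef[g]
        pos = col[col > 0]
        if pos.empty:
            continue
        if len(pos) > 1:
            logger.info(
                "gene %s positive for %s; assigned to %s (largest coefficient)",
                g, list(pos.index), pos.idxmax(),
            )
        groups[str(pos.idxmax())].append(g)
    return groups


def assemble_option_c(
    curated: GeneSetCollection,
    hallmarks: GeneSetCollection,
    mcp: GeneSetCollection,
    immune_genes: list[str],
    expr: ExpressionMatrix,
    labels: pd.Series | dict,
    params: DeriveParams | None = None,
    scoring: ScoringParams | None = None,
) -> tuple[SubtypeTemplate, dict]:
    """Four-step pathway-level template assembly.

    Steps 1-3 ssGSEA-score the curated, hallmark and microenvironment
    collections and keep class-specific sets via :func:`ttest_filter`.
    Step 4 groups the immune panel genes by :func:`lasso_group_genes`,
    wraps each class's group as one new gene set, and keeps it only if its
    ssGSEA score passes the same pairwise filter *for that class*. The
    template is the union of survivors; the report traces every member to
    its step.
    """
    params = params or DeriveParams()
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    expr, labels = _labelled_subset(expr, labels)
    step_templates: dict[str, SubtypeTemplate] = {}
    for step_name, coll in (
        ("curated", curated), ("hallmark", hallmarks), ("mcp", mcp)
    ):
        scores = ssgsea_score(expr, coll, scoring)
        step_templates[step_name] = ttest_filter(
            scores, labels, params, allow_empty=True
        )

    present = [g for g in immune_genes if g in set(expr.feature_ids)]
    if not present:
        raise ValueError("no immune panel genes found in the matrix")
    groups = lasso_group_genes(expr.subset_features(present), labels, params)
    immune_sets = {
        f"IMMUNE_{cls}": genes for cls, genes in groups.items() if genes
    }
    immune_by_class: dict[str, list[str]] = {}
    if immune_sets:
        iscores = ssgsea_score(expr, GeneSetCollection(immune_sets), scoring)
        ifilter = ttest_filter(iscores, labels, params, allow_empty=True)
        for cls, feats in ifilter.features_by_class.items():
            # a class's grouped signature must be specific to that same class
            immune_by_class[cls] = [
                f for f in feats if f == f"IMMUNE_{cls}"
            ]

    classes = list(step_templates["curated"].classes)
    union: dict[str, list[str]] = {c: [] for c in classes}
    provenance: dict[str, str] = {}
    for step_name in ("curated", "hallmark", "mcp"):
        for cls in classes:
            for feat in step_templates[step_name].features_by_class.get(cls, []):
                if feat in provenance:
                    raise ValueError(
                        f"gene set {feat!r} appears in both "
                        f"{provenance[feat]!r} and {step_name!r} collections"
                    )
                provenance[feat] = step_name
                union[cls].append(feat)
    for cls, feats in immune_by_class.items():
        for feat in feats:
            provenance[feat] = "immune"
            union[cls].append(feat)

    empty = [c for c in classes if not union[c]]
    if empty:
        raise ValueError(f"option C assembly left class(es) empty: {empty}")
    template = SubtypeTemplate(union, feature_space="gene_set", classes=classes)
    report = {
        "per_step_counts": {
            step: sum(
                1 for f, s in provenance.items() if s == step
            )
            for step in ("curated", "hallmark", "mcp", "immune")
        },
        "per_class_counts": template.class_sizes(),
        "provenance": provenance,
        "immune_groups": groups,
    }
    return template, report


def build_option_a(
    human_template: SubtypeTemplate, omap: OrthologMap
) -> tuple[SubtypeTemplate, dict[str, TranslationReport], list[str]]:
    """Gene-level template by ortholog translation (delegates)."""
    return translate_template(human_template, omap)


# ---------------------------------------------------------------------------
# diagnostics


def meta_signature_check(
    expr: ExpressionMatrix,
    calls,
    params: DeriveParams | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Reverse-translation check with per-class meta-signatures.

    For each called class, selects up to ``meta_top_n`` genes with linear
    fold change > ``fc_threshold`` (class vs rest; log2 input assumed) and
    Welch p < ``meta_p``, ranked by fold change; scores every sample by
    the median expression of each class's gene list and returns the
    class-by-class matrix of median scores (rows: signature class,
    columns: sample class). A reliable class shows its maximum on the
    diagonal. Classes with no qualifying genes are flagged (NaN rows).
    """
    params = params or DeriveParams()
    lab = calls.calls() if hasattr(calls, "calls") else pd.Series(calls)
    lab = lab[lab != UNCLASSIFIED]
    classes = [c for c in dict.fromkeys(lab) if (lab == c).sum() >= 2]
    if len(classes) < 2:
        raise ValueError("need >= 2 classes with classified samples")
    df = expr.data[list(lab.index)]
    signatures: dict[str, list[str]] = {}
    flagged: list[str] = []
    for cls in classes:
        in_cols = list(lab.index[lab == cls])
        out_cols = [s for s in lab.index if lab[s] != cls]
        a = df[in_cols].to_numpy(dtype=float)
        b = df[out_cols].to_numpy(dtype=float)
        diff = a.mean(axis=1) - b.mean(axis=1)
        fc = np.power(2.0, diff)
        p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        ok = (fc > params.fc_threshold) & (p < params.meta_p)
        if not ok.any():
            flagged.append(cls)
            signatures[cls] = []
            continue
        idx = np.where(ok)[0]
        top = idx[np.argsort(-fc[idx], kind="stable")][: params.meta_top_n]
        signatures[cls] = [expr.feature_ids[i] for i in top]

    out = pd.DataFrame(index=classes, columns=classes, dtype=float)
    for sig_cls in classes:
        genes = signatures[sig_cls]
        if not genes:
            continue
        sample_scores = df.loc[genes].median(axis=0)
        for sample_cls in classes:
            cols = list(lab.index[lab == sample_cls])
            out.loc[sig_cls, sample_cls] = float(sample_scores[cols].median())
    return out, flagged


def cross_cohort_concordance(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame
) -> pd.Series:
    """Per-class Pearson r between two cohorts' mean-score matrices.

    Both inputs are sets-by-classes mean ssGSEA scores over an identical
    set universe and class labels.
    """
    if list(scores_a.columns) != list(scores_b.columns):
        raise ValueError("class labels differ between cohorts")
    shared = [s for s in scores_a.index if s in set(scores_b.index)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared sets for a correlation")
    a = scores_a.loc[shared]
    b = scores_b.loc[shared]
    out = {}
    for cls in scores_a.columns:
        r, _ = scipy.stats.pearsonr(a[cls], b[cls])
        out[cls] = float(r)
    return pd.Series(out, name="pearson_r")
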