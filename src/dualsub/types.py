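"""Shared domain containers.

All containers are thin, validated wrappers around pandas objects so the
rest of the package can rely on their invariants (unique identifiers,
finite values, disjoint template classes) without re-checking them.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_CLASSES = ("CMS1", "CMS2", "CMS3", "CMS4")
UNCLASSIFIED = "unclassified"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} identifier(s): {sorted(set(dups))}")


class ExpressionMatrix:
    """Genes-by-samples (or sets-by-samples) numeric matrix.

    Rows are features (genes or gene-set names), columns are samples.
    Values are normalised log-scale expression or enrichment scores.

    Parameters
    ----------
    data : pandas.DataFrame
        Numeric frame with feature ids as index and sample ids as columns.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("ExpressionMatrix expects a pandas DataFrame")
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("expression matrix needs at least 1 feature and 1 sample")
        _check_unique([str(i) for i in data.index], "feature")
        _check_unique([str(c) for c in data.columns], "sample")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at feature {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        self.data = data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        missing = [f for f in features if f not in self.data.index]
        if missing:
            raise KeyError(f"features absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(features)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} features x {self.shape[1]} samples)"

    def isclose(self, other: "ExpressionMatrix", tol: float = 1e-9) -> bool:
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, atol=tol, rtol=0)
        )


class GeneSetCollection:
    """Named gene sets with optional free-text descriptions."""

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        _check_unique(list(sets.keys()), "gene set")
        clean: dict[str, list[str]] = {}
        for name, members in sets.items():
            dedup = list(dict.fromkeys(members))
            if not dedup:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = dedup
        self.sets = clean
        self.descriptions = dict(descriptions or {})

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


class SubtypeTemplate:
    """Class -> marker feature mapping used by nearest-template prediction.

    ``feature_space`` is ``"gene"`` for gene-level templates (option A) or
    ``"gene_set"`` for pathway-level templates (options B/C) whose features
    are gene-set names scored by ssGSEA.

    A feature may belong to at most one class; this is what makes the
    binary indicator encoding of the template meaningful.
    """

    def __init__(
        self,
        features_by_class: Mapping[str, Sequence[str]],
        feature_space: str = "gene",
        classes: Sequence[str] | None = None,
        allow_empty: bool = False,
    ):
        if feature_space not in ("gene", "gene_set"):
            raise ValueError("feature_space must be 'gene' or 'gene_set'")
        self.classes = list(classes) if classes is not None else list(features_by_class)
        _check_unique(self.classes, "class")
        self.feature_space = feature_space
        self.features_by_class: dict[str, list[str]] = {}
        seen: dict[str, str] = {}
        for cls in self.classes:
            members = list(dict.fromkeys(features_by_class.get(cls, [])))
            if not members and not allow_empty:
                raise ValueError(f"class {cls!r} has no features")
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"feature {m!r} assigned to both {seen[m]!r} and {cls!r}"
                    )
                seen[m] = cls
            self.features_by_class[cls] = members

    @property
    def all_features(self) -> list[str]:
        out: list[str] = []
        for cls in self.classes:
            out.extend(self.features_by_class[cls])
        return out

    def class_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.features_by_class.items()}

    def __repr__(self) -> str:
        sizes = ", ".join(f"{c}={n}" for c, n in self.class_sizes().items())
        return f"SubtypeTemplate({self.feature_space}; {sizes})"


@dataclass(frozen=True)
class OrthologMap:
    """Directed many-to-many symbol mapping between two species.

    ``pairs`` holds unique (source, target) symbol pairs in input order.
    """

    pairs: tuple[tuple[str, str], ...]
    direction: str = "human->mouse"

    def __post_init__(self) -> None:
        seen = set()
        for s, t in self.pairs:
            if not s or not t:
                raise ValueError("ortholog pair with blank symbol")
            if (s, t) in seen:
                raise ValueError(f"duplicate ortholog pair {(s, t)}")
            seen.add((s, t))

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], direction: str = "human->mouse"
    ) -> "OrthologMap":
        """Build a map, silently collapsing exact duplicate rows."""
        uniq = list(dict.fromkeys((str(s), str(t)) for s, t in pairs))
        return cls(tuple(uniq), direction)

    def targets_of(self, source: str) -> list[str]:
        return [t for s, t in self.pairs if s == source]

    @property
    def forward(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, []).append(t)
        return out

    @property
    def reverse(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, t in self.pairs:
            out.setdefault(t, []).append(s)
        return out

    def multiplicity_report(self) -> dict[str, int]:
        fwd, rev = self.forward, self.reverse
        return {
            "n_pairs": len(self.pairs),
            "n_sources": len(fwd),
            "n_targets": len(rev),
            "n_one_to_many": sum(1 for v in fwd.values() if len(v) > 1),
            "n_many_to_one": sum(1 for v in rev.values() if len(v) > 1),
        }

    def __len__(self) -> int:
        return len(self.pairs)


class ClassificationResult:
    """Per-sample nearest-template calls with permutation significance.

    This is the results object returned by
    :meth:`dualsub.ntp.NearestTemplateModel.fit`. For each sample it holds
    the cosine correlation distance to every class template, the predicted
    class (``"unclassified"`` when the BH-adjusted permutation FDR fails
    the cutoff, when the best distance is tied, or when the sample is
    degenerate), the permutation p-value and the BH q-value.
    """

    def __init__(
        self,
        samples: Sequence[str],
        classes: Sequence[str],
        predicted: Sequence[str],
        distances: np.ndarray,
        p_values: Sequence[float],
        fdr: Sequence[float],
        best_class: Sequence[str] | None = None,
        reasons: Mapping[str, str] | None = None,
        params: object | None = None,
    ):
        self.samples = list(samples)
        self.classes = list(classes)
        self.predicted = list(predicted)
        self.distances = np.asarray(distances, dtype=float)
        self.p_values = np.asarray(p_values, dtype=float)
        self.fdr = np.asarray(fdr, dtype=float)
        self.best_class = list(best_class) if best_class is not None else None
        self.reasons = dict(reasons or {})
        self.params = params
        if self.distances.shape != (len(self.samples), len(self.classes)):
            raise ValueError("distance matrix shape mismatch")
        for i, cls in enumerate(self.predicted):
            if cls == UNCLASSIFIED:
                continue
            if cls not in self.classes:
                raise ValueError(f"unknown predicted class {cls!r}")
            if not np.isclose(
                self.distances[i, self.classes.index(cls)],
                self.distances[i].min(),
                atol=1e-12,
            ):
                raise ValueError(
                    f"predicted class for sample {self.samples[i]!r} is not "
                    "the argmin of its distances"
                )

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample": self.samples,
                "predicted_class": self.predicted,
            }
        )
        for j, cls in enumerate(self.classes):
            df[f"d.{cls}"] = self.distances[:, j]
        df["p_value"] = self.p_values
        df["FDR"] = self.fdr
        return df

    def calls(self) -> pd.Series:
        return pd.Series(self.predicted, index=self.samples, name="predicted_class")

    @property
    def n_unclassified(self) -> int:
        return sum(1 for c in self.predicted if c == UNCLASSIFIED)

    def summary(self) -> str:
        """Plain-text summary table of calls and significance."""
        buf = _io.StringIO()
        counts = pd.Series(self.predicted).value_counts()
        buf.write("Nearest-template classification\n")
        buf.write("=" * 47 + "\n")
        buf.write(f"Samples:        {len(self.samples)}\n")
        buf.write(f"Classes:        {', '.join(self.classes)}\n")
        for cls in self.classes + [UNCLASSIFIED]:
            buf.write(f"  {cls:<14}{int(counts.get(cls, 0))}\n")
        if self.params is not None:
            buf.write(f"Params:         {self.params}\n")
        buf.write("-" * 47 + "\n")
        with pd.option_context("display.width", 120, "display.max_rows", 40):
            buf.write(self.frame.to_string(index=False, float_format="%.4f"))
        return buf.getvalue()

    def __repr__(self) -> str:
        return (
            f"ClassificationResult({len(self.samples)} samples, "
            f"{self.n_unclassified} unclassified)"
        )
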