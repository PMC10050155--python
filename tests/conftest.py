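import numpy as np
import pandas as pd
import pytest

from dualsub.types import ExpressionMatrix, GeneSetCollection, SubtypeTemplate
from dualsub.simulate import SimParams, simulate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 2 samples with distinct values."""
    return ExpressionMatrix(
        pd.DataFrame(
            {"s1": [4.0, 3.0, 2.0, 1.0], "s2": [1.0, 2.0, 3.0, 4.0]},
            index=["g1", "g2", "g3", "g4"],
        )
    )


@pytest.fixture
def two_class_template() -> SubtypeTemplate:
    return SubtypeTemplate({"class1": ["f1", "f2"], "class2": ["f3", "f4"]})


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted cohort shared by the heavier tests."""
    return simulate_cohort(SimParams())


@pytest.fixture(scope="session")
def default_template(default_cohort) -> SubtypeTemplate:
    _, _, _, _, truth = default_cohort
    classes = ["CMS1", "CMS2", "CMS3", "CMS4"]
    return SubtypeTemplate(
        {c: [s for s, k in truth["set_truth"].items() if k == c] for c in classes},
        feature_space="gene_set",
        classes=classes,
    )


def naive_ssgsea(df: pd.DataFrame, sets: dict, alpha: float) -> pd.DataFrame:
    """Independent brute-force ssGSEA oracle (explicit double loop).

    Ranks computed by pairwise counting, running sum accumulated gene by
    gene; shares no code with the implementation under test.
    """
    out = pd.DataFrame(index=list(sets), columns=df.columns, dtype=float)
    n = df.shape[0]
    for sample in df.columns:
        x = df[sample].to_numpy(dtype=float)
        ranks = np.empty(n)
        for i in range(n):
            less = sum(1 for j in range(n) if x[j] < x[i])
            equal = sum(1 for j in range(n) if x[j] == x[i])
            ranks[i] = less + (equal + 1) / 2.0
        order = sorted(range(n), key=lambda i: -ranks[i])
        for name, members in sets.items():
            member_set = set(members)
            in_flags = [df.index[i] in member_set for i in order]
            m = sum(in_flags)
            w_total = sum(
                abs(ranks[order[i]]) ** alpha for i in range(n) if in_flags[i]
            )
            p_in = p_out = 0.0
            es = 0.0
            for i in range(n):
                if in_flags[i]:
                    p_in += abs(ranks[order[i]]) ** alpha / w_total
                else:
                    p_out += 1.0 / (n - m)
                es += p_in - p_out
            out.loc[name, sample] = es
    return out
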