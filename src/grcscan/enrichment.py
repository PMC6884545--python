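"""Gonad-expression enrichment of a gene set by randomisation.

Tests whether orthologs of GRC-linked genes are enriched for gonad-maximal
expression in a GRC-lacking species. Each background gene is labelled by its
tissue of maximal expression over a multi-tissue panel (unexpressed genes are
excluded from the background); the query set's testis-max and ovary-max
counts are compared to 10,000 random draws of the same size from the
background, giving one-tailed empirical p-values for enrichment (and
underrepresentation of the "other tissues" category).

The exact hypergeometric tail, computed by direct summation over binomial
coefficients, serves as an independent oracle for the randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "build_background",
    "randomisation_test",
    "hypergeom_oracle",
    "EnrichmentResult",
]


def build_background(
    expr_table: pd.DataFrame,
    annotation_universe: list[str] | set[str] | None = None,
    tissue_order: list[str] | None = None,
) -> pd.Series:
    """Label every expressed background gene by its tissue of maximal
    expression.

    Genes not expressed in any tissue are excluded; genes outside the
    annotation universe (when given) are excluded. Arg-max ties are broken by
    fixed tissue order (``tissue_order`` or the table's column order), so the
    labelling is deterministic.
    """
    table = expr_table
    if tissue_order is not None:
        table = table[tissue_order]
    expressed = table.sum(axis=1) > 0
    table = table[expressed]
    if annotation_universe is not None:
        table = table.loc[table.index.intersection(pd.Index(annotation_universe))]
    return table.idxmax(axis=1)  # first column wins ties


@dataclass
class EnrichmentResult:
    """Observed tissue-of-max counts against a sampling null.

    ``p_enrich`` are raw one-tailed fractions of null draws with a count at
    least as large as observed (testis, ovary); ``p_under`` the analogous
    lower tail for the "other" category. ``*_plus1`` apply the (r+1)/(n+1)
    convention so no empirical p is exactly zero. ``bonferroni_factor`` is
    provided for optional family-wise reporting, not applied.
    """

    query_size: int
    background_size: int
    category_counts: dict[str, int]
    observed: dict[str, int]
    n_reps: int
    seed: int
    p_enrich: dict[str, float]
    p_enrich_plus1: dict[str, float]
    p_under_other: float
    p_under_other_plus1: float
    null_mean: dict[str, float] = field(default_factory=dict)
    bonferroni_factor: int = 1


def randomisation_test(
    background: pd.Series,
    query_ids: list[str],
    n_reps: int = 10_000,
    seed: int = 0,
    gonad_tissues: tuple[str, str] = ("testis", "ovary"),
) -> EnrichmentResult:
    """Randomisation enrichment test on tissue-of-max labels.

    Draws ``n_reps`` samples of the query size without replacement from the
    full background (query genes included in the pool) and counts, per draw,
    genes maximally expressed in each gonad tissue. One-tailed p-values: the
    fraction of draws with a gonad count >= observed (enrichment) and with an
    "other tissues" count <= observed (underrepresentation).
    """
    query_ids = list(query_ids)
    n = len(query_ids)
    N = len(background)
    if n > N:
        raise ValueError("query larger than background")
    missing = set(query_ids) - set(background.index)
    if missing:
        raise ValueError(f"query genes absent from background: {sorted(missing)[:5]}")
    labels = background.to_numpy()
    testis, ovary = gonad_tissues
    codes = np.zeros(N, dtype=np.int8)  # 0 = other
    codes[labels == testis] = 1
    codes[labels == ovary] = 2

    obs_labels = background.loc[query_ids].to_numpy()
    observed = {
        testis: int((obs_labels == testis).sum()),
        ovary: int((obs_labels == ovary).sum()),
    }
    observed["other"] = n - observed[testis] - observed[ovary]

    rng = np.random.default_rng(seed)
    null_t = np.empty(n_reps, dtype=np.int32)
    null_o = np.empty(n_reps, dtype=np.int32)
    for i in range(n_reps):
        draw = codes[rng.choice(N, size=n, replace=False)]
        null_t[i] = (draw == 1).sum()
        null_o[i] = (draw == 2).sum()
    null_other = n - null_t - null_o

    def tail_ge(null, obs):
        return int((null >= obs).sum())

    r_t = tail_ge(null_t, observed[testis])
    r_o = tail_ge(null_o, observed[ovary])
    r_u = int((null_other <= observed["other"]).sum())
    K = {
        testis: int((codes == 1).sum()),
        ovary: int((codes == 2).sum()),
        "other": int((codes == 0).sum()),
    }
    return EnrichmentResult(
        query_size=n,
        background_size=N,
        category_counts=K,
        observed=observed,
        n_reps=n_reps,
        seed=seed,
        p_enrich={testis: r_t / n_reps, ovary: r_o / n_reps},
        p_enrich_plus1={
            testis: (r_t + 1) / (n_reps + 1),
            ovary: (r_o + 1) / (n_reps + 1),
        },
        p_under_other=r_u / n_reps,
        p_under_other_plus1=(r_u + 1) / (n_reps + 1),
        null_mean={
            testis: float(null_t.mean()),
            ovary: float(null_o.mean()),
            "other": float(null_other.mean()),
        },
    )


def hypergeom_oracle(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), by direct
    summation of binomial coefficients in exact integer arithmetic.

    Independent of any library distribution; used to verify the randomisation
    test's convergence.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    hi = min(n, K)
    if k <= max(0, n - (N - K)):
        return 1.0
    if k > hi:
        return 0.0
    total = comb(N, n)
    acc = 0
    for i in range(k, hi + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return acc / total
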