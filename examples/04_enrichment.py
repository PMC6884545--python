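"""Gonad-expression enrichment of a gene set by randomisation.

A background of 7918 genes labelled by tissue of maximal expression (1376
testis-max, 685 ovary-max) is sampled 10,000 times at the query size (65);
the one-tailed p is the fraction of draws with at least the observed count
(22 testis-max). The exact hypergeometric tail is the independent oracle.
"""

import pandas as pd

from grcscan import enrichment

N, K_t, K_o, n, k_t, k_o = 7918, 1376, 685, 65, 22, 6
labels = ["testis"] * K_t + ["ovary"] * K_o + ["other"] * (N - K_t - K_o)
background = pd.Series(labels, index=[f"g{i}" for i in range(N)])
query = ([f"g{i}" for i in range(k_t)] + [f"g{K_t + i}" for i in range(k_o)]
         + [f"g{K_t + K_o + i}" for i in range(n - k_t - k_o)])

res = enrichment.randomisation_test(background, query, n_reps=10_000, seed=1)
exact = enrichment.hypergeom_oracle(N, K_t, n, k_t)
print(f"observed counts:          {res.observed}")
print(f"null mean counts:         { {k: round(v, 2) for k, v in res.null_mean.items()} }")
print(f"p(testis enrichment):     {res.p_enrich['testis']:.4f} "
      f"(+1 convention: {res.p_enrich_plus1['testis']:.4f})")
print(f"exact hypergeometric tail: {exact:.6f}")
print(f"p(other underrepresented): {res.p_under_other:.4f}")
# 22 testis-max genes against a null mean of ~11.3 is a strong enrichment;
# the randomisation p agrees with the exact tail to Monte Carlo error.
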