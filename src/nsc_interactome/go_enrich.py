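"""GO Biological Process over-representation by one-sided Fisher's exact test.

A protein set (here: proteins more abundant under differentiation) is
tested term-by-term against a background (all proteins identified in any
sample).  For a term annotating K of N background proteins and k of the
n test-set proteins, the one-sided enrichment p-value is the
hypergeometric upper tail P(X >= k).  P-values are corrected across the
tested terms with Benjamini-Hochberg; terms with adjusted p strictly
below alpha (default 0.1) are called significantly enriched.

Only terms with at least one test-set protein and at least two background
proteins annotated are tested, so vacuous terms do not inflate the BH
denominator.  Annotations are used as given — no propagation up the GO
hierarchy is attempted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iotables import AnnotationMap


def fisher_enrichment(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher p-value for k of n test proteins in a K-of-N term.

    Equals the hypergeometric upper tail P(X >= k) with population N,
    K successes and n draws.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid 2x2 margins: k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) == 0:
        return np.zeros(0)
    if (pvalues < 0).any() or (pvalues > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def go_enrichment(test_set: Iterable[str],
                  background: Iterable[str],
                  annotations: AnnotationMap,
                  alpha_go: float = 0.1,
                  min_background: int = 2) -> pd.DataFrame:
    """Term-wise over-representation of ``test_set`` within ``background``.

    Returns one row per tested term with columns term, name, k, n, K, N,
    pvalue, qvalue, significant, sorted by (pvalue, term).  The test-set
    must be a subset of the background; terms tested are those annotating
    >= 1 test-set protein and >= ``min_background`` background proteins.
    """
    test = set(test_set)
    bg = set(background)
    stray = test - bg
    if stray:
        raise ValueError("test set proteins missing from background: "
                         + ", ".join(sorted(stray)[:10]))
    n, N = len(test), len(bg)
    rows = []
    for term in sorted(annotations.terms()):
        members = annotations.annotated(term, bg)
        K = len(members)
        k = len(members & test)
        if k < 1 or K < min_background:
            continue
        rows.append({
            "term": term,
            "name": annotations.term_names.get(term, ""),
            "k": k, "n": n, "K": K, "N": N,
            "pvalue": fisher_enrichment(k, n, K, N),
        })
    if not rows:
        return pd.DataFrame(columns=["term", "name", "k", "n", "K", "N",
                                     "pvalue", "qvalue", "significant"])
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["qvalue"] < alpha_go
    return (out.sort_values(["pvalue", "term"], kind="mergesort")
               .reset_index(drop=True))
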