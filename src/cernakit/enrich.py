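"""Hypergeometric over-representation analysis of gene lists.

For a study set of n genes drawn from a background of N, a term annotating
K background genes and hitting k study genes is scored by the upper tail
P(X >= k), X ~ Hypergeometric(N, K, n).  Rows are flagged significant at a
raw p below alpha (0.05 by default); Benjamini-Hochberg adjusted values are
reported alongside for stricter use.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .quantde import adjust_bh

ENRICH_COLUMNS = ["term_id", "k", "K", "n", "N", "p", "padj", "significant"]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    N = background size, K = background genes with the term, n = study size,
    k = study genes with the term.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValidationError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    # survival function is P(X > k-1); scipy computes it in log space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(study: set[str], background: set[str],
           term2genes: dict[str, set[str]], alpha: float = 0.05
           ) -> pd.DataFrame:
    """One row per term with at least one study hit, BH across tested terms."""
    study = set(study)
    background = set(background)
    if not study:
        warnings.warn("empty study set; nothing to test", stacklevel=2)
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    if not study <= background:
        raise ValidationError("study set must be a subset of the background")
    N, n = len(background), len(study)
    rows = []
    for term in sorted(term2genes):
        genes = set(term2genes[term]) & background
        k = len(genes & study)
        if k == 0:
            continue
        rows.append([term, k, len(genes), n, N,
                     hypergeom_upper(k, len(genes), n, N)])
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:6])
    if len(df):
        df["padj"] = adjust_bh(df["p"].to_numpy())
        df["significant"] = df["p"] < alpha
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        df["padj"] = []
        df["significant"] = []
    return df
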