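"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written from first principles (plain Python
loops, explicit formulas) so it shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


# ---------------------------------------------------------------- target scan

def brute_scan(mirna: str, transcript: str) -> list[tuple[int, float]]:
    """Expectation score at every offset, by explicit per-position rules."""
    mirna = mirna.upper().replace("U", "T")
    transcript = transcript.upper().replace("U", "T")
    L = len(mirna)
    out = []
    for off in range(len(transcript) - L + 1):
        total = 0.0
        for i in range(L):
            p = L - i                      # miRNA position (1-based, 5'->3')
            mb = mirna[p - 1]
            tb = transcript[off + i]
            if tb == _COMP.get(mb, "?"):
                pen = 0.0
            elif (mb == "G" and tb == "T") or (mb == "T" and tb == "G"):
                pen = 0.5
            else:
                pen = 1.0
            if 2 <= p <= 13:
                pen *= 2.0
            total += pen
        out.append((off + 1, total))
    return out


# ---------------------------------------------------------------- correlation

def _average_ranks(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def spearman_oracle(x, y) -> float:
    return pearson_oracle(_average_ranks(list(x)), _average_ranks(list(y)))


# ---------------------------------------------------------------- BH

def bh_oracle(p) -> np.ndarray:
    """Step-up adjustment computed literally from the definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running_min = min(running_min, p[i] * m / rank_from_end)
        adj[i] = running_min
    return np.array(adj)


# ---------------------------------------------------------------- hypergeom

def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every n-subset of an N-element universe."""
    universe = list(range(N))
    marked = set(range(K))
    hits = 0
    total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(marked.intersection(subset)) >= k:
            hits += 1
    return hits / total


# ---------------------------------------------------------------- intervals

def cis_oracle(lncs, genes, window):
    """All-pairs same-chromosome proximity by explicit interval arithmetic.

    Items are (id, chrom, start, end); returns {(lnc_id, gene_id): gap}.
    """
    out = {}
    for lid, lc, ls, le in lncs:
        for gid, gc, gs, ge in genes:
            if lc != gc or lid == gid:
                continue
            if le < gs:
                gap = gs - le - 1
            elif ge < ls:
                gap = ls - ge - 1
            else:
                gap = 0
            if gap <= window:
                out[(lid, gid)] = gap
    return out


# ---------------------------------------------------------------- ORF

def longest_orf_oracle(seq: str) -> int:
    """Longest ATG..stop ORF length in nt (incl. both codons), 3 frames."""
    seq = seq.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        j = start + 3
        while j + 3 <= len(seq):
            if seq[j:j + 3] in stops:
                best = max(best, j + 3 - start)
                break
            j += 3
    return best


# ---------------------------------------------------------------- network

def network_counts_oracle(triplets):
    """Node/edge counts by explicit set construction from (l, m, g) tuples."""
    nodes = set()
    edges = set()
    for l, m, g in triplets:
        nodes |= {l, m, g}
        edges |= {(m, l), (m, g)}
    return len(nodes), len(edges)
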