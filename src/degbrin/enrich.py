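"""Hypergeometric gene-set enrichment of DEG sets against a background universe.

With N background genes, K members of a term, and n DEGs drawn, the overlap k
follows a hypergeometric distribution; enrichment evidence is the upper-tail
probability P(X >= k).  The pmf is evaluated exactly in log space via
log-gamma, and p-values across terms are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dge import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe."""

    sets: dict  # term name -> set of gene ids
    universe: set

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: {sorted(extra)[:5]}"
                )

    @property
    def background_size(self) -> int:
        return len(self.universe)


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X = k) = C(K,k) C(N-K, n-k) / C(N,n), log-space evaluation."""
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if k < 0 or k > min(K, n):
        raise ValueError(f"k={k} outside [0, min(K, n)={min(K, n)}]")
    if n - k > N - K:
        return 0.0
    logp = _log_choose(K, k) + _log_choose(N - K, n - k) - _log_choose(N, n)
    return float(np.exp(logp))


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) by summing the exact pmf over the support."""
    kmax = min(K, n)
    if k <= max(0, n - (N - K)):
        return 1.0
    total = sum(hypergeom_pmf(N, K, n, j) for j in range(k, kmax + 1))
    return float(min(1.0, total))


def enrich(deg_set, collection: GeneSetCollection, background: set | None = None) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``deg_set`` against each term.

    Returns a frame with columns term, N, K, n, k, p, adj_p sorted by
    adjusted then raw p-value.  Genes outside the universe are dropped from
    the DEG set before testing.
    """
    universe = background if background is not None else collection.universe
    degs = set(deg_set) & universe
    if not degs:
        warnings.warn("empty DEG set (after restriction to the universe); no enrichment")
        return pd.DataFrame(columns=["term", "N", "K", "n", "k", "p", "adj_p"])
    N = len(universe)
    n = len(degs)
    rows = []
    for term, genes in collection.sets.items():
        members = set(genes) & universe
        K = len(members)
        k = len(members & degs)
        rows.append({"term": term, "N": N, "K": K, "n": n, "k": k, "p": hypergeom_tail(N, K, n, k)})
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["adj_p", "p", "term"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT input/output

def read_gmt(path, universe) -> GeneSetCollection:
    """Read a GMT file (term, description, members...), restricted to the universe."""
    universe = set(universe)
    sets: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            continue
        term, _desc, *genes = parts
        members = set(genes) & universe
        if members:
            sets[term] = members
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(path, sets: dict, description: str = "na") -> None:
    lines = [
        "\t".join([term, description] + sorted(genes)) for term, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
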