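"""Model interpretation: gene/region importances, gradient statistics, triads.

Gene and region importances are read from the trained multiplicative gates,
``softplus(gamma)`` per gene and ``softplus(rho)`` per region; an optional
gradient-weighted variant multiplies each gate by the mean absolute input
gradient.  Training-stability statistics (mean, sd, range, Pearson kurtosis)
summarize the pooled per-epoch parameter-update samples.  The triad report
links each top-ranked region to its top-ranked genes and to the enriched
pathways containing them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import RegionDEGSets
from .gcnmodel import GCNParams, softplus
from .traineval import TrainRecord


@dataclass
class ImportanceReport:
    """Ranked nonnegative importance scores for regions and genes."""

    region_scores: pd.Series  # index region label, sorted descending
    gene_scores: pd.Series  # index gene id, sorted descending
    method: str = "gate"

    def top_genes(self, n: int) -> list:
        return list(self.gene_scores.index[:n])

    def top_regions(self, n: int) -> list:
        return list(self.region_scores.index[:n])


def _ranked(scores: pd.Series) -> pd.Series:
    # sort by score descending, ties broken lexicographically by label
    frame = scores.rename("score").rename_axis("label").reset_index()
    frame = frame.sort_values(["score", "label"], ascending=[False, True], kind="mergesort")
    return frame.set_index("label")["score"]


def importance_report(
    params: GCNParams,
    region_labels,
    gene_labels,
    mode: str = "gate",
    input_gradients: np.ndarray | None = None,
) -> ImportanceReport:
    """Gate-based (optionally gradient-weighted) importance rankings.

    ``input_gradients`` is a (n_samples, |G|) array of d(loss)/d(x) values;
    in ``gate_x_gradient`` mode gene scores are gate * mean |gradient|.
    """
    gene = softplus(params.gamma)
    region = softplus(params.rho)
    if mode == "gate_x_gradient":
        if input_gradients is None:
            raise ValueError("gate_x_gradient mode requires input_gradients")
        gene = gene * np.abs(input_gradients).mean(axis=0)
    elif mode != "gate":
        raise ValueError(f"unknown importance mode {mode!r}")
    if np.allclose(gene, gene[0]) and np.allclose(region, region[0]):
        warnings.warn("gates appear untrained (uniform scores); ranking is lexicographic")
    return ImportanceReport(
        region_scores=_ranked(pd.Series(region, index=list(region_labels))),
        gene_scores=_ranked(pd.Series(gene, index=list(gene_labels))),
        method=mode,
    )


@dataclass
class GradientStats:
    mean: float
    sd: float
    minimum: float
    maximum: float
    kurtosis: float  # Pearson (non-excess): m4 / m2^2, 3 for a normal

    def to_dict(self) -> dict:
        return {
            "mean": self.mean, "sd": self.sd, "min": self.minimum,
            "max": self.maximum, "kurtosis": self.kurtosis,
        }


def gradient_stats(values) -> GradientStats:
    """Moment summary of parameter-update values (pooled over epochs)."""
    if isinstance(values, TrainRecord):
        values = values.pooled_updates()
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty gradient sample")
    m = float(x.mean())
    centered = x - m
    m2 = float((centered**2).mean())
    if m2 == 0.0:
        warnings.warn("constant gradient sample; kurtosis undefined")
        kurt = float("nan")
    else:
        kurt = float((centered**4).mean() / m2**2)
    return GradientStats(
        mean=m,
        sd=float(np.sqrt(m2)),
        minimum=float(x.min()),
        maximum=float(x.max()),
        kurtosis=kurt,
    )


@dataclass
class TriadRow:
    region: str
    genes: list
    pathways: list
    key_genes: list


def triad_table(
    importance: ImportanceReport,
    region_sets: RegionDEGSets,
    enrichment: dict,
    top_k: int = 5,
    top_genes: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Region-gene-pathway triads for the ``top_k`` most important regions.

    ``enrichment`` maps region -> enrichment frame (columns term, k, adj_p and
    a ``members`` column listing each term's overlapping genes, as produced by
    :func:`region_enrichment`).  A region's genes are the globally top-ranked
    genes intersected with its own DEG set; its pathways are the significant
    terms (adj_p < alpha) containing at least one of those genes.
    """
    global_top = importance.top_genes(top_genes)
    rows = []
    for region in importance.top_regions(top_k):
        region_degs = region_sets.region_sets.get(region, set())
        genes = [g for g in global_top if g in region_degs]
        pathways: list = []
        key_genes: list = []
        table = enrichment.get(region)
        if table is not None and len(table):
            sig = table[table["adj_p"] < alpha]
            for _, row in sig.iterrows():
                members = set(row.get("members", ()))
                hit = members & set(genes)
                if hit:
                    pathways.append(row["term"])
                    key_genes.extend(sorted(hit))
        seen: set = set()
        key_genes = [g for g in key_genes if not (g in seen or seen.add(g))]
        rows.append(
            {
                "region": region,
                "genes": ";".join(genes),
                "pathways": ";".join(pathways),
                "key_genes": ";".join(key_genes),
            }
        )
    return pd.DataFrame(rows, columns=["region", "genes", "pathways", "key_genes"])


def region_enrichment(region_sets: RegionDEGSets, collection, background=None) -> dict:
    """Per-region enrichment tables with a ``members`` column for triads."""
    from .enrich import enrich

    out = {}
    for region, degs in region_sets.region_sets.items():
        if not degs:
            out[region] = pd.DataFrame(
                columns=["term", "N", "K", "n", "k", "p", "adj_p", "members"]
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = enrich(degs, collection, background=background)
        universe = background if background is not None else collection.universe
        restricted = set(degs) & set(universe)
        table["members"] = [
            sorted(set(collection.sets.get(t, set())) & restricted) for t in table["term"]
        ]
        out[region] = table
    return out


def overlap_with_hubs(importance: ImportanceReport, hubs, top_n: int = 20) -> float:
    """Fraction of the top-n important genes also called as PPI hubs."""
    if top_n > len(importance.gene_scores):
        raise ValueError(
            f"top_n={top_n} exceeds the {len(importance.gene_scores)} ranked genes"
        )
    top = set(importance.top_genes(top_n))
    return len(top & set(hubs)) / top_n
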