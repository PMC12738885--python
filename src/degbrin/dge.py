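"""Per-region differential expression with empirical-Bayes variance moderation.

For each brain region the expression of each gene is modelled by an ordinary
linear model on diagnostic group, ``y = X b + e`` with ``e ~ N(0, s^2 I)``.
Gene-wise residual variances ``s_g^2`` are assumed exchangeable draws from a
scaled inverse-chi-square prior with hyperparameters ``(d0, s0^2)``; the
moderated variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

shrinks each gene's variance toward the prior, and the moderated statistic

    t~_g = beta_g / (s~_g * sqrt(v_g))

is referred to a t distribution on ``d0 + d_g`` degrees of freedom.  The
hyperparameters are estimated by moment matching on ``log s_g^2``: under the
prior, ``log s_g^2`` is a location-shifted log-F variate whose mean and
variance have closed forms in digamma/trigamma functions, so ``d0`` is
obtained by inverting the trigamma function (Newton iteration) and ``s0^2``
from the matched mean.

Differentially expressed genes (DEGs) pass |log2FC| > 0.585 (a 1.5-fold
change) AND Benjamini-Hochberg adjusted p < 0.05, both strict.  Per-region
DEG sets are unions over the three group contrasts (MCI-CON, AD-CON, MCI-AD);
the universal cross-region list G keeps genes differentially expressed in at
least ``min_regions`` (default 2) regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .simdata import CONTRASTS, GROUPS

logger = logging.getLogger(__name__)

#: |log2FC| bound corresponding to a 1.5-fold change
LFC_THRESHOLD = 0.585
ALPHA = 0.05
#: cap representing d0 -> +infinity (no gene-wise variance information)
D0_CAP = 1e6

GROUP_OF_DIAGNOSIS = {
    "Normal": "CON",
    "Possible AD": "MCI",
    "Probable AD": "MCI",
    "Definite AD": "AD",
}


class EmptyResultError(RuntimeError):
    """All genes (or all regions) were filtered away."""


def consolidate_groups(diagnosis: pd.Series) -> pd.Series:
    """Map diagnostic labels onto the three analytical groups CON/MCI/AD."""
    unknown = set(diagnosis.unique()) - set(GROUP_OF_DIAGNOSIS)
    if unknown:
        raise ValueError(f"unknown diagnosis labels: {sorted(unknown)}")
    return diagnosis.map(GROUP_OF_DIAGNOSIS)


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(
    expr: pd.DataFrame,
    detection_threshold: float | None = None,
    max_below_fraction: float = 0.6,
) -> pd.DataFrame:
    """Detection filter, missing-value removal, duplicate-gene averaging.

    Genes whose expression falls below ``detection_threshold`` in more than
    ``max_below_fraction`` of samples are removed, as are genes with any
    missing value; rows sharing a gene id are collapsed by their mean.  When
    no threshold is supplied the 20th percentile of all finite values is used.
    """
    if expr.empty:
        raise ValueError("expression matrix is empty")
    out = expr[~expr.isna().any(axis=1)]
    if out.index.has_duplicates:
        out = out.groupby(level=0, sort=False).mean()
    if detection_threshold is None:
        detection_threshold = float(np.nanpercentile(expr.values, 20))
    below = (out.values < detection_threshold).mean(axis=1)
    out = out.loc[below <= max_below_fraction]
    if out.empty:
        raise EmptyResultError("all genes removed by preprocessing filters")
    return out


# ---------------------------------------------------------------------------
# gene-wise linear models

@dataclass
class GeneFit:
    """Per-gene OLS summaries for one contrast.

    coef
        contrast of group means, log2FC units.
    sigma
        residual standard deviation s_g.
    df_residual
        residual degrees of freedom (n - rank(X); shared across genes).
    stdev_unscaled_sq
        unscaled coefficient variance v_g = c' (X'X)^-1 c, so that
        Var(coef) = sigma^2 * v_g.
    """

    gene_ids: list
    coef: np.ndarray
    sigma: np.ndarray
    df_residual: float
    stdev_unscaled_sq: float
    contrast: str = ""


def fit_linear_models(expr: pd.DataFrame, groups: pd.Series, contrast: str) -> GeneFit:
    """Per-gene OLS of expression on group membership for one two-group contrast.

    ``contrast`` is "A-B": coef = mean(A) - mean(B).  Fit on the samples of
    the two groups only (pairwise subsetting).
    """
    a, b = contrast.split("-")
    groups = groups.reindex(expr.columns)
    in_a = (groups == a).to_numpy()
    in_b = (groups == b).to_numpy()
    n1, n2 = int(in_a.sum()), int(in_b.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"contrast {contrast}: need >= 2 samples per group, got {a}:{n1}, {b}:{n2}"
        )
    ya = expr.values[:, in_a]
    yb = expr.values[:, in_b]
    coef = ya.mean(axis=1) - yb.mean(axis=1)
    rss = ((ya - ya.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    rss += ((yb - yb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    sigma = np.sqrt(rss / df)
    return GeneFit(
        gene_ids=list(expr.index),
        coef=coef,
        sigma=sigma,
        df_residual=float(df),
        stdev_unscaled_sq=1.0 / n1 + 1.0 / n2,
        contrast=contrast,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the asymptotic start 1/x)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(sigma_sq: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from gene-wise variances.

    Matches the empirical mean and variance of ``log sigma_sq`` to the
    log scaled-F distribution implied by the inverse-chi-square prior.
    Returns d0 capped at ``D0_CAP`` (representing +infinity) when the
    observed dispersion of log variances is no larger than the sampling
    dispersion, and falls back to d0 = 0 (no moderation) when the moment
    estimates are non-finite.
    """
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    ok = np.isfinite(sigma_sq) & (sigma_sq > 0) & (df > 0)
    z = np.log(sigma_sq[ok])
    if z.size < 2:
        logger.warning("fewer than 2 usable variances; falling back to d0 = 0")
        return 0.0, float(np.median(sigma_sq[ok])) if ok.any() else 1.0
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if not np.isfinite(emean) or not np.isfinite(evar):
        logger.warning("non-finite moment estimates; falling back to d0 = 0")
        return 0.0, float(np.exp(np.median(z)))
    if evar <= 0:
        # observed dispersion no larger than sampling dispersion: the prior is
        # effectively a point mass at the (geometric) common variance
        return D0_CAP, float(np.exp(z.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    d0 = min(d0, D0_CAP)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


@dataclass
class ModeratedFit:
    """Moderated statistics for one contrast (the shrunken-t analogue of GeneFit)."""

    gene_ids: list
    coef: np.ndarray  # log2FC
    d0: float
    s0_sq: float
    sigma_tilde_sq: np.ndarray
    t: np.ndarray
    df_total: float
    p_value: np.ndarray
    adj_p_value: np.ndarray
    contrast: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "log2FC": self.coef,
                "t": self.t,
                "p": self.p_value,
                "adj_p": self.adj_p_value,
                "contrast": self.contrast,
            }
        )


def moderate(fit: GeneFit, d0: float | None = None, s0_sq: float | None = None) -> ModeratedFit:
    """Empirical-Bayes moderated t-statistics for a :class:`GeneFit`.

    When (d0, s0_sq) are not supplied they are estimated from the gene-wise
    residual variances by :func:`estimate_prior`.  d0 = 0 reproduces the
    ordinary t-statistic exactly.
    """
    sigma_sq = fit.sigma**2
    if d0 is None or s0_sq is None:
        d0, s0_sq = estimate_prior(sigma_sq, fit.df_residual)
    dg = fit.df_residual
    if d0 >= D0_CAP:
        sig2 = np.full_like(sigma_sq, s0_sq)
        df_total = np.inf
    else:
        sig2 = (d0 * s0_sq + dg * sigma_sq) / (d0 + dg)
        df_total = d0 + dg
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coef / (np.sqrt(sig2) * np.sqrt(fit.stdev_unscaled_sq))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)
    return ModeratedFit(
        gene_ids=fit.gene_ids,
        coef=fit.coef,
        d0=float(d0),
        s0_sq=float(s0_sq),
        sigma_tilde_sq=sig2,
        t=np.where(np.isnan(t), 0.0, t),
        df_total=float(df_total),
        p_value=p,
        adj_p_value=bh_adjust(p),
        contrast=fit.contrast,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_degs(mod: ModeratedFit, lfc_threshold: float = LFC_THRESHOLD, alpha: float = ALPHA) -> pd.DataFrame:
    """Rows of the moderated fit passing both DEG thresholds (strict)."""
    frame = mod.to_frame()
    keep = (np.abs(frame["log2FC"]) > lfc_threshold) & (frame["adj_p"] < alpha)
    return frame.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-region assembly

@dataclass
class RegionDEGSets:
    """Per-region DEG sets, per-gene region frequency, and the universal list G."""

    region_sets: dict  # region -> set of genes (union over contrasts)
    region_frequency: pd.Series  # gene -> number of regions where DE
    universal: set  # genes DE in >= min_regions regions
    min_regions: int = 2
    deg_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def restricted(self) -> dict:
        """Region sets intersected with the universal list G (graph input)."""
        return {r: s & self.universal for r, s in self.region_sets.items()}

    def to_json_dict(self) -> dict:
        return {
            "min_regions": self.min_regions,
            "region_sets": {r: sorted(s) for r, s in self.region_sets.items()},
            "universal": sorted(self.universal),
            "region_frequency": {g: int(c) for g, c in self.region_frequency.items()},
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "RegionDEGSets":
        return cls(
            region_sets={r: set(s) for r, s in payload["region_sets"].items()},
            region_frequency=pd.Series(payload["region_frequency"], dtype=int),
            universal=set(payload["universal"]),
            min_regions=int(payload.get("min_regions", 2)),
        )


def degs_per_region(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    contrasts=CONTRASTS,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
    min_regions: int = 2,
) -> RegionDEGSets:
    """Run moderated-t DEG calling per region and assemble cross-region sets.

    Each region is analysed independently; contrasts whose groups have fewer
    than 2 samples in a region are skipped with a warning.  The per-region DEG
    set is the union over its valid contrasts.
    """
    if "group" not in samples.columns:
        samples = samples.assign(group=consolidate_groups(samples["diagnosis"]))
    sample_group = samples.set_index("sample_id")["group"]
    region_sets: dict = {}
    tables = []
    any_contrast = False
    for region, meta in samples.groupby("region", sort=True):
        cols = [c for c in meta["sample_id"] if c in expr.columns]
        sub = expr[cols]
        groups = sample_group.loc[cols]
        degs: set = set()
        for contrast in contrasts:
            a, b = contrast.split("-")
            counts = groups.value_counts()
            if counts.get(a, 0) < 2 or counts.get(b, 0) < 2:
                warnings.warn(
                    f"region {region}: skipping contrast {contrast} (insufficient samples)"
                )
                continue
            any_contrast = True
            fit = fit_linear_models(sub, groups, contrast)
            mod = moderate(fit)
            table = call_degs(mod, lfc_threshold, alpha)
            table.insert(0, "region", region)
            tables.append(table)
            degs |= set(table["gene"])
        region_sets[region] = degs
    if not any_contrast:
        raise EmptyResultError("no region had a valid contrast")
    freq = pd.Series(
        np.zeros(len(expr.index), dtype=int), index=expr.index, name="n_regions"
    )
    for genes in region_sets.values():
        if genes:
            freq.loc[list(genes)] += 1
    universal = set(freq.index[freq >= min_regions])
    deg_table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["region", "gene", "log2FC", "t", "p", "adj_p", "contrast"])
    )
    return RegionDEGSets(
        region_sets=region_sets,
        region_frequency=freq[freq > 0],
        universal=universal,
        min_regions=min_regions,
        deg_table=deg_table,
    )


# ---------------------------------------------------------------------------
# statsmodels-style model facade

class RegionalDGE:
    """Per-region moderated-t differential expression model.

    Parameters
    ----------
    expr : pandas.DataFrame
        Preprocessed genes x samples log2 expression.
    samples : pandas.DataFrame
        Sample metadata with sample_id, region and group (or diagnosis).

    ``fit()`` returns a :class:`RegionalDGEResults` holding the per-contrast
    DEG tables and the cross-region set assembly.
    """

    def __init__(self, expr: pd.DataFrame, samples: pd.DataFrame, contrasts=CONTRASTS):
        self.expr = expr
        self.samples = samples
        self.contrasts = tuple(contrasts)

    @classmethod
    def from_files(cls, expr_path, meta_path, **kwargs) -> "RegionalDGE":
        from .simdata import read_expression, read_metadata

        return cls(read_expression(expr_path), read_metadata(meta_path), **kwargs)

    def fit(
        self,
        lfc_threshold: float = LFC_THRESHOLD,
        alpha: float = ALPHA,
        min_regions: int = 2,
    ) -> "RegionalDGEResults":
        sets = degs_per_region(
            self.expr,
            self.samples,
            contrasts=self.contrasts,
            lfc_threshold=lfc_threshold,
            alpha=alpha,
            min_regions=min_regions,
        )
        return RegionalDGEResults(self, sets, lfc_threshold, alpha)


class RegionalDGEResults:
    """Fitted differential-expression results with a summary table."""

    def __init__(self, model: RegionalDGE, sets: RegionDEGSets, lfc_threshold: float, alpha: float):
        self.model = model
        self.region_sets = sets
        self.lfc_threshold = lfc_threshold
        self.alpha = alpha

    @property
    def universal(self) -> set:
        return self.region_sets.universal

    @property
    def deg_table(self) -> pd.DataFrame:
        return self.region_sets.deg_table

    def summary(self) -> pd.DataFrame:
        """Per-region DEG counts by contrast plus the union column."""
        rows = []
        table = self.deg_table
        for region, genes in sorted(self.region_sets.region_sets.items()):
            row = {"region": region}
            for contrast in self.model.contrasts:
                sub = table[(table["region"] == region) & (table["contrast"] == contrast)]
                row[contrast] = int(sub["gene"].nunique())
            row["union"] = len(genes)
            rows.append(row)
        out = pd.DataFrame(rows)
        out.attrs["n_universal"] = len(self.universal)
        return out
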