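"""Synthetic multi-region expression cohorts with planted differential expression.

Every downstream stage of the pipeline (per-region moderated-t differential
expression, the cross-region co-occurrence network, the GCN classifier and the
interpretability reports) is exercised against cohorts produced here, for which
the ground truth — which genes were shifted, in which regions, for which group
contrast, and with what residual variance — is known exactly.

The generative model mirrors the assumptions of the downstream analysis:

* one sample per (subject, region) pair, each subject contributing one sample
  to every region;
* log2-scale expression, gene baseline ``mu_g ~ Normal(8, 1.5^2)``;
* gene-wise residual variances drawn from a scaled inverse-chi-square prior
  ``sigma_g^2 ~ d0 * s0^2 / chisq(d0)`` so the empirical-Bayes variance
  moderation of :mod:`degbrin.dge` has a recoverable ground truth;
* planted differentially expressed genes receive additive group-dependent mean
  shifts of magnitude ``effect_size_log2fc`` (random sign) in their region.

A fraction of each region's planted genes is drawn from one common
cross-region pool, producing the multifocal co-occurrence structure that the
DEG-BRIN graph is built from; the remainder are region-private.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("CON", "MCI", "AD")
#: diagnosis labels feeding the three analytical groups
DIAGNOSIS_OF_GROUP = {
    "CON": ("Normal",),
    "MCI": ("Possible AD", "Probable AD"),
    "AD": ("Definite AD",),
}
CONTRASTS = ("MCI-CON", "AD-CON", "MCI-AD")
#: group whose regional mean is shifted when a gene is planted for a contrast
_SHIFTED_GROUP = {"MCI-CON": "MCI", "AD-CON": "AD", "MCI-AD": "MCI"}


class ConfigurationError(ValueError):
    """Raised when a :class:`SyntheticConfig` field is invalid."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic cohort.

    Defaults emulate a multi-region postmortem brain study: 19 anatomical
    regions, three diagnostic groups, moderate per-region DEG counts with half
    of them drawn from a shared cross-region pool, 1.5-fold-change-scale
    effects, and an inverse-chi-square variance prior with 4 prior degrees of
    freedom and prior variance 0.25 (residual sd ~ 0.5 on the log2 scale).
    """

    n_genes: int = 2000
    n_regions: int = 19
    subjects_per_group: dict = field(
        default_factory=lambda: {"CON": 20, "MCI": 20, "AD": 20}
    )
    deg_per_region: int = 30
    shared_fraction: float = 0.5
    effect_size_log2fc: float = 1.0
    prior_df_d0: float = 4.0
    prior_var_s0sq: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    subject_severity_sd: float = 0.4
    n_stage_blocks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_regions"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if set(self.subjects_per_group) != set(GROUPS):
            raise ConfigurationError(
                f"subjects_per_group must have keys {GROUPS}, got {sorted(self.subjects_per_group)}"
            )
        for g, n in self.subjects_per_group.items():
            if int(n) < 1:
                raise ConfigurationError(f"subjects_per_group[{g}] must be >= 1, got {n}")
        if self.deg_per_region < 0:
            raise ConfigurationError(f"deg_per_region must be >= 0, got {self.deg_per_region}")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigurationError(f"shared_fraction must be in [0, 1], got {self.shared_fraction}")
        if self.effect_size_log2fc <= 0:
            raise ConfigurationError(
                f"effect_size_log2fc must be > 0, got {self.effect_size_log2fc}"
            )
        if self.prior_df_d0 <= 0:
            raise ConfigurationError(f"prior_df_d0 must be > 0, got {self.prior_df_d0}")
        if self.prior_var_s0sq <= 0:
            raise ConfigurationError(f"prior_var_s0sq must be > 0, got {self.prior_var_s0sq}")
        if self.subject_severity_sd < 0:
            raise ConfigurationError(
                f"subject_severity_sd must be >= 0, got {self.subject_severity_sd}"
            )
        if self.n_stage_blocks < 1:
            raise ConfigurationError(
                f"n_stage_blocks must be >= 1, got {self.n_stage_blocks}"
            )

    @property
    def n_shared_per_contrast(self) -> int:
        return int(round(self.shared_fraction * self.deg_per_region))

    @property
    def shared_pool_size(self) -> int:
        """Size of the common cross-region pool (>= 2 whenever it is used)."""
        if self.deg_per_region == 0 or self.shared_fraction == 0:
            return 0
        return max(2, 2 * self.n_shared_per_contrast)


@dataclass
class GroundTruth:
    """What was planted: per (region, contrast) gene sets, true variances, labels."""

    planted_degs: dict  # region -> contrast -> set of gene ids
    gene_variances: pd.Series  # per-gene true residual variance
    group_labels: pd.Series  # per-sample group
    shared_pool: set  # union of all stage-block pools of planted genes
    block_pools: dict = field(default_factory=dict)  # block index -> pool gene set
    region_block: dict = field(default_factory=dict)  # region -> block index

    def planted_union(self) -> set:
        out: set = set()
        for per_contrast in self.planted_degs.values():
            for genes in per_contrast.values():
                out |= set(genes)
        return out

    def cross_region_genes(self, min_regions: int = 2) -> set:
        """Genes planted (any contrast) in at least ``min_regions`` regions."""
        count: dict = {}
        for per_contrast in self.planted_degs.values():
            region_genes: set = set()
            for genes in per_contrast.values():
                region_genes |= set(genes)
            for g in region_genes:
                count[g] = count.get(g, 0) + 1
        return {g for g, c in count.items() if c >= min_regions}


def _region_labels(n_regions: int) -> list:
    return [f"R{i + 1:02d}" for i in range(n_regions)]


def generate_cohort(config: SyntheticConfig):
    """Generate an expression matrix, sample table and ground truth.

    Returns
    -------
    expr : pandas.DataFrame
        genes x samples, log2 scale; index gene ids, columns sample ids.
    samples : pandas.DataFrame
        columns sample_id, subject_id, region, diagnosis, group.
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    regions = _region_labels(config.n_regions)

    # subjects and their groups / diagnoses
    subject_rows = []
    idx = 0
    for group in GROUPS:
        diags = DIAGNOSIS_OF_GROUP[group]
        for j in range(int(config.subjects_per_group[group])):
            idx += 1
            subject_rows.append(
                (f"S{idx:04d}", group, diags[j % len(diags)])
            )
    sample_rows = []
    for subj, group, diag in subject_rows:
        for region in regions:
            sample_rows.append(
                {
                    "sample_id": f"{subj}_{region}",
                    "subject_id": subj,
                    "region": region,
                    "diagnosis": diag,
                    "group": group,
                }
            )
    samples = pd.DataFrame(sample_rows)

    # gene-level parameters
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    # scaled inverse-chi-square: d0 * s0^2 / chisq_d0
    sigma2 = config.prior_df_d0 * config.prior_var_s0sq / rng.chisquare(
        config.prior_df_d0, size=config.n_genes
    )
    gene_variances = pd.Series(sigma2, index=genes, name="variance")

    # planted DEG bookkeeping; regions fall into contiguous pathology-stage
    # blocks, each with its own shared pool, so DEG sharing concentrates
    # among regions at a similar stage of regional propagation
    planted: dict = {r: {c: set() for c in CONTRASTS} for r in regions}
    # each stage block needs several regions for within-block sharing to exist
    n_blocks = max(1, min(config.n_stage_blocks, config.n_regions // 3))
    region_block = {r: i * n_blocks // config.n_regions for i, r in enumerate(regions)}
    block_pools: dict = {b: [] for b in range(n_blocks)}
    if config.deg_per_region > 0 and config.shared_fraction > 0:
        want = min(config.shared_pool_size * n_blocks, config.n_genes)
        drawn = list(rng.choice(genes, size=want, replace=False))
        for b in range(n_blocks):
            block_pools[b] = drawn[
                b * config.shared_pool_size : (b + 1) * config.shared_pool_size
            ]
    all_pool = {g for pool in block_pools.values() for g in pool}
    non_pool = [g for g in genes if g not in all_pool]
    gene_pos = {g: i for i, g in enumerate(genes)}

    # effect matrix: gene x group additive shift, per region
    n_samples = len(samples)
    values = rng.normal(0.0, 1.0, size=(config.n_genes, n_samples))
    values *= np.sqrt(sigma2)[:, None]
    values += mu[:, None]

    # direction of dysregulation is a gene-level property, shared across regions
    gene_sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    # subject-level disease severity (mean 1) scales that subject's shifts:
    # the MCI group in particular merges heterogeneous diagnostic strata
    sev_sd = config.subject_severity_sd
    if sev_sd > 0:
        severity = {
            subj: rng.gamma(1.0 / sev_sd**2, sev_sd**2) for subj, _, _ in subject_rows
        }
    else:
        severity = {subj: 1.0 for subj, _, _ in subject_rows}

    n_shared = config.n_shared_per_contrast
    n_private = config.deg_per_region - n_shared
    col_of = {s: j for j, s in enumerate(samples["sample_id"])}
    group_col = {g: k for k, g in enumerate(GROUPS)}
    for region in regions:
        pool = block_pools[region_block[region]]
        shift = np.zeros((config.n_genes, len(GROUPS)))  # per-group additive shift
        for contrast in CONTRASTS:
            chosen: list = []
            if n_shared and pool:
                chosen += list(rng.choice(pool, size=min(n_shared, len(pool)), replace=False))
            if n_private:
                chosen += list(
                    rng.choice(non_pool, size=min(n_private, len(non_pool)), replace=False)
                )
            planted[region][contrast] = set(chosen)
            target = _SHIFTED_GROUP[contrast]
            for g in chosen:
                shift[gene_pos[g], group_col[target]] += (
                    gene_sign[gene_pos[g]] * config.effect_size_log2fc
                )
        in_region = samples["region"] == region
        for _, row in samples.loc[in_region].iterrows():
            j = col_of[row["sample_id"]]
            values[:, j] += shift[:, group_col[row["group"]]] * severity[row["subject_id"]]

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples["sample_id"])
    truth = GroundTruth(
        planted_degs=planted,
        gene_variances=gene_variances,
        group_labels=samples.set_index("sample_id")["group"],
        shared_pool=all_pool,
        block_pools={b: set(p) for b, p in block_pools.items()},
        region_block=region_block,
    )
    return expr, samples, truth


def generate_ppi(genes, edge_density: float, score_range=(0.0, 1.0), seed: int = 0) -> pd.DataFrame:
    """Random undirected PPI edge list with uniform confidence scores.

    Each unordered gene pair becomes an edge independently with probability
    ``edge_density``; scores are uniform on ``score_range``.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    if not 0.0 < edge_density <= 1.0:
        raise ValueError(f"edge_density must be in (0, 1], got {edge_density}")
    lo, hi = score_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"score_range must be within [0, 1], got {score_range}")
    rng = np.random.default_rng(seed)
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    keep = rng.random(iu[0].size) < edge_density
    a_idx, b_idx = iu[0][keep], iu[1][keep]
    scores = rng.uniform(lo, hi, size=a_idx.size)
    return pd.DataFrame(
        {
            "gene_a": [genes[i] for i in a_idx],
            "gene_b": [genes[j] for j in b_idx],
            "score": scores,
        }
    )


# ---------------------------------------------------------------------------
# plain-text serialization (TSV / JSON), the pipeline's on-disk interchange

def write_cohort(outdir, expr: pd.DataFrame, samples: pd.DataFrame, truth: GroundTruth) -> dict:
    """Write expression TSV, metadata TSV and ground-truth JSON; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = outdir / "expression.tsv"
    meta_path = outdir / "metadata.tsv"
    truth_path = outdir / "ground_truth.json"
    expr.to_csv(expr_path, sep="\t")
    samples.to_csv(meta_path, sep="\t", index=False)
    payload = {
        "planted_degs": {
            r: {c: sorted(s) for c, s in per.items()} for r, per in truth.planted_degs.items()
        },
        "gene_variances": truth.gene_variances.round(8).to_dict(),
        "group_labels": truth.group_labels.to_dict(),
        "shared_pool": sorted(truth.shared_pool),
    }
    truth_path.write_text(json.dumps(payload, indent=1))
    return {"expression": str(expr_path), "metadata": str(meta_path), "ground_truth": str(truth_path)}


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index.name = "gene"
    return expr


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_ppi(path, edges: pd.DataFrame) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_ppi(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    edges["score"] = edges["score"].astype(float)
    return edges
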