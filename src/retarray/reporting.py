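"""Heatmap-matrix construction and end-to-end two-cohort comparison runs.

The heatmap follows the conventions of the study's expression figure: only
genes whose regularized t-statistic exceeds the threshold (|d| > 1 by
default) are included; cell values are log2 expression relative to a
reference computed per gene as the mid-point between the two compared group
means, so over- and under-expression are symmetric around zero; rows are
ordered by hierarchical clustering of genes and columns by donor time of
death within each cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from . import diffexp, normalization
from .enrichment import RankSetEnrichment
from .genesets import GeneSetCollection
from .setcluster import cluster_sets

__all__ = ["HeatmapSpec", "heatmap_matrix", "ComparisonConfig",
           "ComparisonReport", "run_comparison"]


@dataclass
class HeatmapSpec:
    """Gene x sample matrix of midpoint-centered log2 values plus orders."""

    values: pd.DataFrame        # rows already ordered by clustering
    genes: list                 # row order
    samples: list               # column order (cohort A then cohort B, by TOD)
    t_threshold: float
    two_sided: bool


def _cluster_row_order(values: np.ndarray) -> np.ndarray:
    if values.shape[0] < 3:
        return np.arange(values.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = pdist(values, metric="correlation")
    dist = np.nan_to_num(dist, nan=0.0)     # constant rows: treat as identical
    return leaves_list(average(dist))


def heatmap_matrix(norm: pd.DataFrame, gene_table: pd.DataFrame,
                   meta: pd.DataFrame, mask_a, mask_b,
                   t_threshold: float = 1.0, two_sided: bool = True) -> HeatmapSpec:
    """Build the heatmap matrix for genes passing the |d| threshold.

    ``gene_table`` is the collapsed per-gene DE table (columns probe_id, d,
    s, q, f); ``mask_a``/``mask_b`` are boolean masks over the columns of
    ``norm`` naming the two cohorts (A drawn first/left).  ``two_sided``
    applies |d| > t; set False for the one-sided d > t reading.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    stat = gene_table["d"].abs() if two_sided else gene_table["d"]
    selected = gene_table[stat > t_threshold]
    if selected.empty:
        raise ValueError(f"no gene passes the t-statistic threshold {t_threshold}")

    sub = norm.loc[selected["probe_id"].to_numpy()]
    vals = sub.to_numpy(dtype=float)
    mean_a = vals[:, mask_a].mean(axis=1)
    mean_b = vals[:, mask_b].mean(axis=1)
    centered = vals - ((mean_a + mean_b) / 2.0)[:, None]

    tod = meta.loc[norm.columns, "tod"].to_numpy(dtype=float)
    cols_a = np.flatnonzero(mask_a)[np.argsort(tod[mask_a], kind="stable")]
    cols_b = np.flatnonzero(mask_b)[np.argsort(tod[mask_b], kind="stable")]
    col_order = np.concatenate([cols_a, cols_b])

    row_order = _cluster_row_order(centered[:, col_order])
    genes = [selected.index[i] for i in row_order]
    samples = [norm.columns[j] for j in col_order]
    values = pd.DataFrame(centered[np.ix_(row_order, col_order)],
                          index=genes, columns=samples)
    return HeatmapSpec(values=values, genes=genes, samples=samples,
                       t_threshold=t_threshold, two_sided=two_sided)


@dataclass
class ComparisonConfig:
    """Everything needed to run one two-cohort comparison.

    ``test_query``/``control_query`` are pandas query strings evaluated on
    the metadata table (e.g. ``"group == 'pos'"``).
    """

    test_query: str
    control_query: str
    threshold_method: str = "valley"
    manual_threshold: float | None = None
    quantile: float = 0.15
    span: float = 0.4
    max_iter: int = 10
    tol: float = 1e-3
    s0_percentile: float = 75.0
    n_perm: int = 200
    seed: int = 0
    alpha: float = 0.01
    t_threshold: float = 1.0
    two_sided_heatmap: bool = True
    filter_before_normalize: bool = True


@dataclass
class ComparisonReport:
    """Artifacts of a full comparison run plus a stage-count manifest."""

    threshold: normalization.DetectionThreshold
    normalized: pd.DataFrame
    norm_report: normalization.NormalizationReport
    de: diffexp.SamDEResults
    gene_table: pd.DataFrame
    ranked_genes: list
    enrichment: object                 # EnrichmentResults or None
    vi: object                         # VIDistanceMatrix or None
    heatmap: HeatmapSpec | None
    manifest: dict = field(default_factory=dict)


def run_comparison(matrix: pd.DataFrame, meta: pd.DataFrame,
                   mapping: pd.Series, collection: GeneSetCollection | None,
                   config: ComparisonConfig) -> ComparisonReport:
    """filter -> normalize -> DE -> collapse -> rank -> enrich -> cluster
    -> heatmap, with a manifest of counts at every stage."""
    index_name = meta.index.name or "sample"
    meta = meta.loc[matrix.columns]
    meta.index.name = index_name    # .loc with a nameless Index drops the name
    test_samples = meta.query(config.test_query).index
    control_samples = meta.query(config.control_query).index
    for name, cohort in (("test", test_samples), ("control", control_samples)):
        if len(cohort) < 2:
            raise ValueError(
                f"{name} cohort predicate matches {len(cohort)} sample(s); "
                "need at least 2")
    cohort_cols = list(control_samples) + list(test_samples)
    sub = matrix[cohort_cols]
    submeta = meta.loc[cohort_cols]

    threshold = normalization.estimate_detection_threshold(
        sub, method=config.threshold_method,
        manual_value=config.manual_threshold, quantile=config.quantile)
    if config.filter_before_normalize:
        detected = normalization.filter_detected(sub, threshold)
        normalized, norm_report = normalization.multiloess_normalize(
            detected, span=config.span, max_iter=config.max_iter, tol=config.tol)
    else:
        normalized, norm_report = normalization.multiloess_normalize(
            sub, span=config.span, max_iter=config.max_iter, tol=config.tol)
        normalized = normalization.filter_detected(normalized, threshold)

    test_mask = np.asarray([s in set(test_samples) for s in normalized.columns])
    de = diffexp.SamDifferentialExpression(
        normalized, test_mask, s0_percentile=config.s0_percentile,
    ).fit(n_perm=config.n_perm, seed=config.seed)
    gene_table = de.collapse(mapping)
    ranked = diffexp.rank_genes(gene_table)

    enrichment = vi = None
    if collection is not None and len(collection):
        enrichment = RankSetEnrichment(ranked, collection).fit(alpha=config.alpha)
        sig = enrichment.significant_sets
        if len(sig) >= 2:
            vi = cluster_sets({s.name: collection[s.name] for s in sig},
                              universe=ranked)

    heatmap = None
    mask_b = ~test_mask
    try:
        heatmap = heatmap_matrix(normalized, gene_table, submeta,
                                 mask_a=mask_b, mask_b=test_mask,
                                 t_threshold=config.t_threshold,
                                 two_sided=config.two_sided_heatmap)
    except ValueError:
        pass    # no gene passed the display threshold; manifest records 0

    manifest = {
        "config": asdict(config),
        "n_samples_test": int(len(test_samples)),
        "n_samples_control": int(len(control_samples)),
        "n_probes_input": int(matrix.shape[0]),
        "detection_threshold": threshold.value,
        "n_probes_detected": int(normalized.shape[0]),
        "normalization_iterations": norm_report.iterations,
        "normalization_max_residual": norm_report.max_residual(),
        "s0": de.s0,
        "pi0": de.pi0,
        "n_permutations": de.n_perm,
        "n_genes_after_collapse": int(len(gene_table)),
        "n_called_q_05": int((gene_table["q"] < 0.05).sum()),
        "n_called_q_01": int((gene_table["q"] < 0.01).sum()),
        "n_sets_tested": enrichment.n_tested if enrichment else 0,
        "n_sets_significant": len(enrichment.significant_sets) if enrichment else 0,
        "n_heatmap_genes": len(heatmap.genes) if heatmap else 0,
    }
    return ComparisonReport(threshold=threshold, normalized=normalized,
                            norm_report=norm_report, de=de,
                            gene_table=gene_table, ranked_genes=ranked,
                            enrichment=enrichment, vi=vi, heatmap=heatmap,
                            manifest=manifest)
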