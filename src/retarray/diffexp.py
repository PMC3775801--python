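"""SAM-style regularized-t differential expression with permutation q-values.

The test statistic for probe i between two groups is

    d_i = (mean1_i - mean2_i) / (s_i + s0)

with the pooled standard error
``s_i = sqrt((1/n1 + 1/n2) * (SS1_i + SS2_i) / (n1 + n2 - 2))`` and a shared
exchangeability factor ``s0`` set at a percentile (default 75) of the s_i —
the regularization that keeps accidentally tiny variances from dominating
the ranking.  False discovery rates come from label permutations: at each
candidate cutoff on |d| the FDR is the median permuted exceedance count,
scaled by an estimate of the null proportion pi0, divided by the observed
count; a probe's q-value is the smallest FDR over all cutoffs at which it
is called.

Signed fold changes use the convention |f| >= 1: the linear-scale ratio of
group means when >= 1, else its negated reciprocal.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "regularized_t",
    "fold_change",
    "permutation_qvalues",
    "collapse_probes",
    "rank_genes",
    "SamDifferentialExpression",
    "SamDEResults",
]


def _as_mask(matrix: pd.DataFrame, groups) -> np.ndarray:
    mask = np.asarray(groups)
    if mask.dtype != bool:
        raise TypeError("groups must be a boolean mask (True = test group)")
    if mask.size != matrix.shape[1]:
        raise ValueError("groups length must match the number of samples")
    return mask


def _d_stat(values: np.ndarray, mask: np.ndarray, s0: float):
    n1, n2 = int(mask.sum()), int((~mask).sum())
    g1, g2 = values[:, mask], values[:, ~mask]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    ss1 = ((g1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((g2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    denom = s + s0
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    return d, s


def regularized_t(matrix: pd.DataFrame, groups, s0_percentile: float = 75.0,
                  s0: float | None = None):
    """Per-probe (d, s) plus the shared s0.

    ``groups`` is a boolean mask over samples, True marking the test group
    (group 1).  ``s0`` overrides the percentile rule when given.  Returns
    ``(d: Series, s: Series, s0: float)``.
    """
    mask = _as_mask(matrix, groups)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    if not 0 <= s0_percentile <= 100:
        raise ValueError("s0_percentile must be in [0, 100]")
    values = matrix.to_numpy(dtype=float)
    _, s = _d_stat(values, mask, 0.0)
    if s0 is None:
        # linear interpolation between order statistics
        s0 = float(np.percentile(s, s0_percentile))
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    if s0 == 0:
        warnings.warn("s0 is 0 (constant matrix?); d reduces to an ordinary t",
                      stacklevel=2)
    d, s = _d_stat(values, mask, s0)
    return (pd.Series(d, index=matrix.index, name="d"),
            pd.Series(s, index=matrix.index, name="s"), float(s0))


def fold_change(matrix: pd.DataFrame, groups) -> pd.Series:
    """Signed linear fold: ratio of linear-scale group means (test over
    control), reciprocal-negated below 1 so that |f| >= 1."""
    mask = _as_mask(matrix, groups)
    if mask.sum() < 1 or (~mask).sum() < 1:
        raise ValueError("both groups need at least one sample")
    lin = np.exp2(matrix.to_numpy(dtype=float))
    m1 = lin[:, mask].mean(axis=1)
    m2 = lin[:, ~mask].mean(axis=1)
    assert np.all(m1 > 0) and np.all(m2 > 0), "linear group means must be positive"
    ratio = m1 / m2
    f = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    return pd.Series(f, index=matrix.index, name="f")


def _enumerate_masks(n: int, n1: int, n_perm: int, seed: int):
    """Label permutations as boolean masks.  Exhaustive when C(n, n1) fits
    in n_perm, otherwise seeded random assignments."""
    from math import comb
    total = comb(n, n1)
    if total <= n_perm:
        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            masks[i, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n1, replace=False)] = True
    return masks, False


def _fdr_curve(d_obs: np.ndarray, perm_d: list, pi0: float):
    """FDR at every candidate cutoff (the observed |d| values, descending)
    and per-probe q-values (min FDR over cutoffs at which the probe is
    called)."""
    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    sorted_asc = np.sort(abs_obs)
    m = len(abs_obs)
    # observed count called at each cutoff (ties share the larger count)
    obs_counts = m - np.searchsorted(sorted_asc, thresholds, side="left")
    counts = np.empty((len(perm_d), m))
    for p, dstar in enumerate(perm_d):
        counts[p] = m - np.searchsorted(np.sort(np.abs(dstar)), thresholds,
                                        side="left")
    med_counts = np.median(counts, axis=0)
    fdr_raw = med_counts / obs_counts
    fdr = np.clip(pi0 * fdr_raw, 0.0, 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    # tied |d| values must share a q-value
    tie_q = pd.Series(q).groupby(abs_obs).transform("min").to_numpy()
    return fdr, fdr_raw, tie_q


def _pi0_sam(d_obs: np.ndarray, perm_d: list) -> float:
    pooled = np.concatenate(perm_d)
    q25, q75 = np.percentile(pooled, [25, 75])
    frac = np.mean((d_obs > q25) & (d_obs < q75))
    return float(np.clip(frac / 0.5, 0.0, 1.0))


def permutation_qvalues(matrix: pd.DataFrame, groups, n_perm: int = 200,
                        seed: int = 0, s0_percentile: float = 75.0,
                        s0: float | None = None, pi0: float | str = "sam",
                        permutations=None) -> pd.Series:
    """Per-probe q-values; see :class:`SamDifferentialExpression` for the
    full results object."""
    res = SamDifferentialExpression(
        matrix, groups, s0_percentile=s0_percentile, s0=s0,
    ).fit(n_perm=n_perm, seed=seed, pi0=pi0, permutations=permutations)
    return res.table["q"]


class SamDifferentialExpression:
    """Two-group regularized-t model for a probes x samples log2 matrix.

    Parameters
    ----------
    matrix : DataFrame, probes x samples, log2 scale.
    groups : boolean mask over samples; True = test group (group 1).
    s0_percentile : percentile of the per-probe standard errors used for
        the exchangeability factor (default 75).
    s0 : explicit exchangeability factor overriding the percentile rule.
    """

    def __init__(self, matrix: pd.DataFrame, groups,
                 s0_percentile: float = 75.0, s0: float | None = None):
        self.matrix = matrix
        self.mask = _as_mask(matrix, groups)
        self.s0_percentile = s0_percentile
        self._s0_fixed = s0

    def fit(self, n_perm: int = 200, seed: int = 0, pi0: float | str = "sam",
            permutations=None) -> "SamDEResults":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        d, s, s0 = regularized_t(self.matrix, self.mask,
                                 self.s0_percentile, self._s0_fixed)
        f = fold_change(self.matrix, self.mask)
        values = self.matrix.to_numpy(dtype=float)
        n, n1 = self.mask.size, int(self.mask.sum())
        if permutations is None:
            masks, exhaustive = _enumerate_masks(n, n1, n_perm, seed)
        else:
            masks = np.asarray(permutations, dtype=bool)
            exhaustive = False
        if len(masks) < 20 and permutations is None and not exhaustive:
            warnings.warn(f"only {len(masks)} permutations; q-value resolution "
                          "is coarse", stacklevel=2)
        perm_d = [_d_stat(values, m_, s0)[0] for m_ in masks]
        d_arr = d.to_numpy()
        pi0_val = _pi0_sam(d_arr, perm_d) if pi0 == "sam" else float(pi0)
        fdr, fdr_raw, q = _fdr_curve(d_arr, perm_d, pi0_val)
        table = pd.DataFrame({"d": d, "s": s, "q": q, "f": f},
                             index=self.matrix.index)
        return SamDEResults(table=table, s0=s0, pi0=pi0_val,
                            n_perm=len(masks), exhaustive=exhaustive,
                            fdr_curve=fdr, fdr_curve_raw=fdr_raw)


class SamDEResults:
    """Fitted differential-expression results.

    Attributes
    ----------
    table : DataFrame indexed by probe id with columns d, s, q, f.
    s0, pi0 : the exchangeability factor and estimated null proportion.
    n_perm : permutations actually used; ``exhaustive`` marks full
        enumeration of the label assignments.
    fdr_curve / fdr_curve_raw : FDR at each candidate |d| cutoff
        (descending), with and without the pi0 scaling.
    """

    def __init__(self, table, s0, pi0, n_perm, exhaustive,
                 fdr_curve, fdr_curve_raw):
        self.table = table
        self.s0 = s0
        self.pi0 = pi0
        self.n_perm = n_perm
        self.exhaustive = exhaustive
        self.fdr_curve = fdr_curve
        self.fdr_curve_raw = fdr_curve_raw

    def called(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]

    def collapse(self, mapping: pd.Series) -> pd.DataFrame:
        """Collapse probes to genes; see :func:`collapse_probes`."""
        return collapse_probes(self.table, mapping)

    def summary(self) -> str:
        t = self.table
        lines = [
            "SAM-style regularized-t differential expression",
            f"  probes            : {len(t)}",
            f"  s0 (exchangeability): {self.s0:.5g}",
            f"  pi0 estimate      : {self.pi0:.3f}",
            f"  permutations      : {self.n_perm}"
            + (" (exhaustive)" if self.exhaustive else ""),
            f"  called at q < 0.01: {(t['q'] < 0.01).sum()}",
            f"  called at q < 0.05: {(t['q'] < 0.05).sum()}",
        ]
        return "\n".join(lines)


def collapse_probes(table: pd.DataFrame, mapping: pd.Series) -> pd.DataFrame:
    """One row per gene: the probe with the smallest q represents the gene;
    ties broken by larger |d|, then lexicographically smaller probe id.
    Probes missing from the mapping are dropped with a warning."""
    if len(mapping) == 0:
        raise ValueError("empty probe-to-gene mapping")
    mapped = table.index.intersection(mapping.index)
    if len(mapped) < len(table):
        warnings.warn(f"dropping {len(table) - len(mapped)} unmapped probes",
                      stacklevel=2)
    sub = table.loc[mapped].copy()
    sub["gene_id"] = mapping.loc[mapped].to_numpy()
    sub = sub.reset_index().rename(columns={sub.index.name or "index": "probe_id"})
    sub["_absd"] = sub["d"].abs()
    sub = sub.sort_values(["q", "_absd", "probe_id"],
                          ascending=[True, False, True], kind="stable")
    best = sub.drop_duplicates("gene_id", keep="first").drop(columns="_absd")
    return best.set_index("gene_id")[["probe_id", "d", "s", "q", "f"]]


def rank_genes(gene_table: pd.DataFrame) -> list:
    """Gene ids ordered best-first: ascending q, ties by descending |d|,
    then gene id — a strict order for the rank enrichment."""
    t = gene_table.copy()
    t["_absd"] = t["d"].abs()
    t = t.sort_values(["q", "_absd"], ascending=[True, False], kind="stable")
    # final lexicographic tie-break on gene id for exact ties in (q, |d|)
    t = (t.reset_index()
          .sort_values(["q", "_absd", "gene_id"], ascending=[True, False, True],
                       kind="stable"))
    return t["gene_id"].tolist()
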