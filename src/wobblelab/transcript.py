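"""RNA-seq count filtering, TMM normalization, DE testing and p/RTS ranking.

The stages mirror a standard edgeR-style workflow for a two-group embryonic
brain comparison with sex as a batch covariate, followed by a TRIAGE-style
re-ranking: genes are ordered by ``p / RTS`` where RTS (repressive tendency
score) quantifies a gene's breadth of H3K27me3 coverage, so that regulatory
genes with modest p-values outrank housekeeping genes with tiny ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .proteome import PeptideMatrix, fit_moderated_model


class DesignError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Nonnegative integer counts (genes x samples) with a group+sex design."""

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.design.index.equals(self.counts.columns):
            raise ValueError("design rows must match count columns")
        if (self.library_sizes <= 0).any():
            raise ValueError("every sample needs a positive library size")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class RankedGeneTable:
    """Genes ordered by the p/RTS metric, with the top-N head split out."""

    table: pd.DataFrame  # gene_id idx: p, sign, rts, metric, rank, rts_flag
    top: pd.DataFrame
    n_missing_rts: int


def cpm(counts: pd.DataFrame, norm_factors: pd.Series | None = None,
        log: bool = False, prior_count: float = 0.5) -> pd.DataFrame:
    """Counts per million over (TMM-adjusted, if factors given) effective
    library sizes; ``log=True`` returns log2-CPM with a prior count."""
    lib = counts.sum(axis=0).astype(float)
    if norm_factors is not None:
        lib = lib * norm_factors
    if log:
        return np.log2((counts + prior_count).div(lib + 2 * prior_count,
                                                  axis=1) * 1e6)
    return counts.div(lib, axis=1) * 1e6


def filter_counts(cm: CountMatrix, cpm_cutoff: float = 0.5,
                  min_samples: int = 6, literal: bool = False
                  ) -> tuple[CountMatrix, dict]:
    """Remove weakly expressed genes by a CPM rule.

    Default (conventional) rule: keep genes with CPM >= ``cpm_cutoff`` in at
    least ``min_samples`` samples.  ``literal=True`` applies the removal
    phrasing instead — drop genes whose CPM falls below the cutoff in at
    least ``min_samples`` samples — which differs on boundary genes when the
    two sample thresholds do not sum to the sample count.  Raw library sizes
    are used (filtering precedes normalization).  Idempotent.
    """
    if min_samples > cm.counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    c = cpm(cm.counts)
    if literal:
        keep = (c < cpm_cutoff).sum(axis=1) < min_samples
    else:
        keep = (c >= cpm_cutoff).sum(axis=1) >= min_samples
    filtered = CountMatrix(counts=cm.counts.loc[keep], design=cm.design)
    report = {"kept": int(keep.sum()), "removed": int((~keep).sum())}
    return filtered, report


def tmm_normalize(cm: CountMatrix, logratio_trim: float = 0.30,
                  abundance_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the column whose upper-quartile count fraction
    is closest to the mean upper quartile.  For each sample, genes with zero
    counts in either member of the pair are excluded, M-values are trimmed
    30% from each tail (5% on A), and the factor is the precision-weighted
    mean M.  Factors are rescaled to geometric mean 1.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                   for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    yr = counts[:, ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        ys = counts[:, j]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(
                f"sample {cm.counts.columns[j]!r} shares no expressed genes "
                "with the reference")
        ps = ys[ok] / lib[j]
        pr = yr[ok] / lib[ref]
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (lib[j] - ys[ok]) / (lib[j] * ys[ok]) + \
            (lib[ref] - yr[ok]) / (lib[ref] * yr[ok])
        n = m.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abundance_trim) + 1, n - np.floor(n * abundance_trim)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
               (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any() or np.sum(1.0 / w[keep]) == 0:
            f = 0.0
        else:
            f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        if not np.isfinite(f) or abs(f) < 1e-10:
            f = 0.0
        factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="tmm_factor")


def gene_de_test(cm: CountMatrix, norm_factors: pd.Series | None = None,
                 include_sex: bool = True, prior_count: float = 0.5
                 ) -> pd.DataFrame:
    """Moderated two-group test on log2-CPM with an optional sex covariate.

    log2-CPM (prior count 0.5, TMM-effective library sizes) is modeled
    linearly with group + sex terms; the group coefficient is tested with
    the same empirical-Bayes moderation machinery used for peptides.
    Returns a per-gene table with ``log2fc`` (signed, mutant vs control),
    ``t`` and ``p``.
    """
    design = cm.design.copy()
    if include_sex:
        if "sex" not in design.columns:
            raise DesignError("design has no 'sex' column")
        by_group = design.groupby("group")["sex"].nunique()
        if (by_group == 1).all() and design["sex"].nunique() > 1:
            raise DesignError(
                "sex is aliased with group (each group has a single sex); "
                "the group effect is not estimable")
    else:
        design = design[["group"]]
    logcpm = cpm(cm.counts, norm_factors=norm_factors, log=True,
                 prior_count=prior_count)
    matrix = PeptideMatrix(
        intensities=logcpm,
        proteins=pd.Series(logcpm.index, index=logcpm.index),
        is_spike=pd.Series(False, index=logcpm.index),
        design=design,
    )
    fit = fit_moderated_model(matrix, sigma2_tech=0.0)
    out = fit.table.loc[:, ["log2fc", "t", "p"]].copy()
    out.index.name = "gene_id"
    return out


def triage_rerank(gene_p: pd.Series, signs: pd.Series, rts: pd.Series,
                  top_n: int = 50, rts_threshold: float = 0.03
                  ) -> RankedGeneTable:
    """Re-rank genes by ``p / RTS`` (ascending; small = high priority).

    ``signs`` carry the regulation direction (+1 up, -1 down).  Genes
    without an RTS entry are excluded and counted; RTS values must be
    strictly positive.  Ties in the metric break by gene id, so the ranking
    is a stable permutation.
    """
    if not isinstance(signs, pd.Series):
        signs = pd.Series(np.asarray(signs), index=gene_p.index)
    rts = rts.dropna()
    if (rts <= 0).any():
        raise ValueError("RTS values must be > 0")
    common = gene_p.index.intersection(rts.index)
    n_missing = len(gene_p.index) - len(common)
    tab = pd.DataFrame({
        "p": gene_p.loc[common],
        "sign": signs.loc[common],
        "rts": rts.loc[common],
    })
    tab["metric"] = tab["p"] / tab["rts"]
    # stable metric sort; pre-sorting by gene id makes ties break by id
    tab = tab.sort_index(kind="mergesort").sort_values("metric",
                                                       kind="mergesort")
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab["rts_flag"] = tab["rts"] >= rts_threshold
    tab.index.name = "gene_id"
    return RankedGeneTable(table=tab, top=tab.head(top_n),
                           n_missing_rts=n_missing)
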