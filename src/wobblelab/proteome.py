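"""Peptide-level differential expression with protein-level roll-up.

The workflow mirrors standard label-free proteomics practice for a two-group
comparison:

1. cyclic-loess normalization of log2 peptide intensities
   (:func:`normalize_peptides`);
2. estimation of purely technical variance from spike-in peptides and its
   subtraction from each peptide's residual variance
   (:func:`estimate_technical_variance`, :func:`fit_moderated_model`);
3. empirical-Bayes moderated t-tests per peptide (limma-style variance
   shrinkage, hyperparameters by method of moments on log variances);
4. roll-up to proteins: Simes-combined p-values, 20%-trimmed-mean log2
   fold-changes, Benjamini-Hochberg FDR, and up/down calls at FDR < 0.1
   (:func:`rollup_proteins`, :func:`classify_de`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: floor for technical-variance-corrected residual variances (log2^2 units)
VARIANCE_FLOOR = 1e-8


class NormalizationError(ValueError):
    pass


class SpikeInError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass
class PeptideMatrix:
    """Log2 peptide intensities with protein mapping and sample design.

    ``intensities`` is peptides x samples (NaN = missing, never silent zero);
    ``proteins`` maps each peptide to exactly one protein id; ``is_spike``
    flags spike-in peptides; ``design`` holds one row per sample with a
    ``group`` column (two levels) and optional covariate columns.
    """

    intensities: pd.DataFrame
    proteins: pd.Series
    is_spike: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            raise ValueError("duplicate peptide ids")
        if not (self.proteins.index.equals(idx) and self.is_spike.index.equals(idx)):
            raise ValueError("protein map / spike flags must match peptide index")
        if "group" not in self.design.columns:
            raise ValueError("design must contain a 'group' column")
        if not self.design.index.equals(self.intensities.columns):
            raise ValueError("design rows must match sample columns")
        if self.design["group"].isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def groups(self) -> list:
        return sorted(self.design["group"].unique())

    @classmethod
    def from_tables(cls, peptide_table: pd.DataFrame,
                    design: pd.DataFrame) -> "PeptideMatrix":
        """Build from the on-disk schema: ``peptide_id``, ``protein_id``,
        ``is_spike`` then one column per sample."""
        tab = peptide_table.set_index("peptide_id")
        samples = [c for c in tab.columns if c not in ("protein_id", "is_spike")]
        design = design.set_index("sample") if "sample" in design.columns else design
        return cls(
            intensities=tab[samples].astype(float),
            proteins=tab["protein_id"],
            is_spike=tab["is_spike"].astype(bool),
            design=design.loc[samples],
        )

    def to_table(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "peptide_id": self.intensities.index,
            "protein_id": self.proteins.values,
            "is_spike": self.is_spike.astype(int).values,
        })
        for col in self.intensities.columns:
            out[col] = self.intensities[col].values
        return out


@dataclass
class ModeratedStats:
    """Per-peptide moderated test results plus the global EB hyperparameters."""

    table: pd.DataFrame  # log2fc, s2, df, s2_corr, s2_post, t, p, tested
    sigma2_tech: float
    s0_squared: float
    d0: float
    proteins: pd.Series = field(repr=False)
    is_spike: pd.Series | None = field(default=None, repr=False)


@dataclass
class ProteinDETable:
    table: pd.DataFrame  # protein_id idx: n_peptides, log2fc, simes_p, q, call
    fdr_threshold: float = 0.1


# ---------------------------------------------------------------------------
# statistical primitives (also used by the transcript module)


def simes_p(pvalues: np.ndarray) -> float:
    """Simes-combined p-value: ``min_k n * p_(k) / k`` over sorted p's."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = p.size
    if n == 0:
        raise ValueError("no p-values to combine")
    return float(np.min(n * p / np.arange(1, n + 1)))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def trimmed_mean_fc(log2fcs: np.ndarray, trim: float = 0.20) -> float:
    """Mean log2 fold-change after discarding ``floor(trim*n)`` values from
    each tail; for n <= 4 at the default trim this is the plain mean."""
    x = np.sort(np.asarray(log2fcs, dtype=float))
    k = int(np.floor(trim * x.size))
    if k > 0:
        x = x[k:-k]
    return float(np.mean(x))


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def squeeze_variances(s2: np.ndarray, df: np.ndarray,
                      d0: float | None = None
                      ) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of sample variances.

    Fits a scaled inverse-chi-square prior ``(s0^2, d0)`` by method of
    moments on log variances and returns posterior variances
    ``(d0*s0^2 + df*s2) / (d0 + df)`` together with the hyperparameters.
    ``d0`` may be forced (0 disables moderation; inf pools completely).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (df > 0) & np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise ValueError("no positive-df variances to moderate")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2) + np.log(df[ok] / 2)
    emean = float(np.mean(e))
    if d0 is None:
        evar = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
        target = evar - float(np.mean(special.polygamma(1, df[ok] / 2)))
        if target > 0:
            d0 = float(2 * _trigamma_inverse(np.array(target))[()])
        else:
            d0 = np.inf
    if d0 == 0:
        s0_sq = float(np.exp(emean))
        return s2.copy(), s0_sq, 0.0
    if np.isinf(d0):
        s0_sq = float(np.exp(emean))
        return np.full_like(s2, s0_sq), s0_sq, float(d0)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    post = np.where(ok, post, s0_sq)
    return post, s0_sq, float(d0)


# ---------------------------------------------------------------------------
# normalization


def normalize_peptides(matrix: PeptideMatrix, *, already_log2: bool = True,
                       n_cycles: int = 3, span: float = 0.7,
                       min_finite: int = 10
                       ) -> tuple[PeptideMatrix, pd.DataFrame]:
    """Cyclic-loess normalization over all sample pairs.

    For every ordered pair of samples the M = x_i - x_j vs A = (x_i + x_j)/2
    trend is estimated by loess (span 0.7) and half of it is subtracted from
    each sample; the sweep over all pairs is repeated ``n_cycles`` times.
    Removes both constant log2 offsets and intensity-dependent distortions.

    Returns the normalized matrix and a diagnostics table with the median M
    per pair per cycle.
    """
    x = matrix.intensities.to_numpy(dtype=float).copy()
    if not already_log2:
        if np.nanmin(x) <= 0:
            raise NormalizationError("raw-scale intensities must be positive")
        x = np.log2(x)
    n_samples = x.shape[1]
    if n_samples < 2:
        raise NormalizationError("need at least 2 samples")
    finite_per_sample = np.isfinite(x).sum(axis=0)
    if (finite_per_sample < min_finite).any():
        bad = matrix.intensities.columns[finite_per_sample < min_finite]
        raise NormalizationError(
            f"samples with < {min_finite} finite intensities: {list(bad)}"
        )
    diag = []
    for cycle in range(n_cycles):
        for i in range(n_samples - 1):
            for j in range(i + 1, n_samples):
                both = np.isfinite(x[:, i]) & np.isfinite(x[:, j])
                m = x[both, i] - x[both, j]
                a = (x[both, i] + x[both, j]) / 2.0
                diag.append({"cycle": cycle + 1,
                             "pair": f"{matrix.intensities.columns[i]}:"
                                     f"{matrix.intensities.columns[j]}",
                             "median_m": float(np.median(m))})
                if np.ptp(a) == 0:  # flat A axis: remove the constant offset
                    fit = np.full(m.size, np.mean(m))
                else:
                    fit = lowess(m, a, frac=span, return_sorted=False,
                                 delta=0.01 * np.ptp(a))
                x[both, i] -= fit / 2.0
                x[both, j] += fit / 2.0
    normalized = PeptideMatrix(
        intensities=pd.DataFrame(x, index=matrix.intensities.index,
                                 columns=matrix.intensities.columns),
        proteins=matrix.proteins, is_spike=matrix.is_spike,
        design=matrix.design,
    )
    return normalized, pd.DataFrame(diag)


# ---------------------------------------------------------------------------
# technical variance from spike-ins


def estimate_technical_variance(matrix: PeptideMatrix) -> float:
    """Pooled within-spike variance across samples (group labels ignored:
    spike-ins carry no biological signal by construction)."""
    spikes = matrix.intensities.loc[matrix.is_spike.values]
    if spikes.empty:
        raise SpikeInError(
            "no spike-in peptides flagged; pass sigma2_tech=0.0 explicitly "
            "to fit_moderated_model to skip the correction"
        )
    ss = 0.0
    dof = 0
    for _, row in spikes.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size >= 2:
            ss += float(np.sum((vals - vals.mean()) ** 2))
            dof += vals.size - 1
    if dof < 2:
        raise SpikeInError("need >= 1 spike-in with >= 3 finite observations")
    return ss / dof


# ---------------------------------------------------------------------------
# moderated linear model


def _design_matrix(design: pd.DataFrame, groups: list) -> np.ndarray:
    """Intercept + mutant-vs-control indicator + dummy-coded covariates.

    The group coefficient is the log2FC of ``groups[1]`` relative to
    ``groups[0]`` (sorted labels: with labels 'control'/'mutant' the sign is
    mutant minus control).
    """
    cols = [np.ones(len(design)),
            (design["group"] == groups[1]).to_numpy(dtype=float)]
    for cov in design.columns:
        if cov == "group":
            continue
        vals = design[cov]
        if vals.dtype.kind in "fiu":
            cols.append(vals.to_numpy(dtype=float))
        else:
            levels = sorted(vals.unique())
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_moderated_model(matrix: PeptideMatrix, sigma2_tech: float | None = None,
                        *, d0: float | None = None,
                        min_per_group: int = 2) -> ModeratedStats:
    """Per-peptide group-difference linear model with EB moderation.

    The technical variance (estimated from spike-ins unless given) is
    subtracted from each peptide's residual variance before shrinkage:
    ``s2_corr = max(s2 - sigma2_tech, 1e-8)``.  The moderated t uses
    posterior variance ``(d0*s0^2 + d*s2_corr)/(d0 + d)`` on ``d0 + d``
    degrees of freedom.  Spike-in peptides are excluded from testing.
    Peptides with fewer than ``min_per_group`` finite observations in either
    group are flagged untested.
    """
    if sigma2_tech is None:
        sigma2_tech = estimate_technical_variance(matrix)
    if sigma2_tech < 0:
        raise ValueError("sigma2_tech must be >= 0")

    groups = matrix.groups
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    X_full = _design_matrix(matrix.design, groups)
    y_all = matrix.intensities.to_numpy(dtype=float)
    group_idx = 1  # column of the group coefficient
    in_g = [(matrix.design["group"] == g).to_numpy() for g in groups]

    n_pep = y_all.shape[0]
    b = np.full(n_pep, np.nan)
    s2 = np.full(n_pep, np.nan)
    dfree = np.zeros(n_pep)
    vb = np.full(n_pep, np.nan)
    tested = np.zeros(n_pep, dtype=bool)

    finite = np.isfinite(y_all)
    eligible = (~matrix.is_spike.to_numpy()) & \
        (finite[:, in_g[0]].sum(axis=1) >= min_per_group) & \
        (finite[:, in_g[1]].sum(axis=1) >= min_per_group)

    # group peptides by missingness pattern so each pattern is solved once
    patterns: dict[bytes, list[int]] = {}
    for i in np.nonzero(eligible)[0]:
        patterns.setdefault(finite[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        X = X_full[mask]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            continue  # aliased design on this pattern: leave untested
        xtx_inv = np.linalg.inv(X.T @ X)
        hat = xtx_inv @ X.T
        Y = y_all[np.ix_(rows, np.nonzero(mask)[0])]
        beta = Y @ hat.T
        resid = Y - beta @ X.T
        d = mask.sum() - X.shape[1]
        b[rows] = beta[:, group_idx]
        vb[rows] = xtx_inv[group_idx, group_idx]
        dfree[rows] = d
        if d > 0:
            s2[rows] = np.sum(resid ** 2, axis=1) / d
            tested[rows] = True

    if not tested.any():
        raise ValueError("all peptides excluded from testing")

    s2_corr = np.where(tested, np.maximum(s2 - sigma2_tech, VARIANCE_FLOOR),
                       np.nan)
    post, s0_sq, d0_hat = squeeze_variances(s2_corr[tested], dfree[tested],
                                            d0=d0)
    s2_post = np.full(n_pep, np.nan)
    s2_post[tested] = post

    t = np.full(n_pep, np.nan)
    p = np.full(n_pep, np.nan)
    t[tested] = b[tested] / np.sqrt(s2_post[tested] * vb[tested])
    total_df = d0_hat + dfree[tested]
    if np.isinf(d0_hat):
        p[tested] = 2 * stats.norm.sf(np.abs(t[tested]))
    else:
        p[tested] = 2 * stats.t.sf(np.abs(t[tested]), total_df)

    table = pd.DataFrame({
        "log2fc": b, "s2": s2, "df": dfree, "s2_corr": s2_corr,
        "s2_post": s2_post, "t": t, "p": p, "tested": tested,
    }, index=matrix.intensities.index)
    return ModeratedStats(table=table, sigma2_tech=float(sigma2_tech),
                          s0_squared=s0_sq, d0=d0_hat,
                          proteins=matrix.proteins,
                          is_spike=matrix.is_spike)


# ---------------------------------------------------------------------------
# protein roll-up


def rollup_proteins(mod: ModeratedStats, trim: float = 0.20,
                    fdr_threshold: float = 0.1) -> ProteinDETable:
    """Roll peptide statistics up to proteins.

    Per protein: Simes-combined p over its tested peptides, trimmed-mean
    log2FC (20% of peptides discarded from each tail), then BH q-values
    across proteins and up/down/ns calls at q < ``fdr_threshold``.
    Proteins with zero tested peptides are dropped with a warning.
    """
    tab = mod.table[mod.table["tested"]]
    if tab.empty:
        raise ValueError("no tested peptides to roll up")
    prot = mod.proteins.loc[tab.index]
    real = (mod.proteins if mod.is_spike is None
            else mod.proteins[~mod.is_spike])  # spike carriers never roll up
    n_dropped = len(set(real) - set(prot))
    if n_dropped > 0:
        logger.warning("%d proteins had no tested peptides and were dropped",
                       n_dropped)
    rows = []
    for protein_id, sub in tab.groupby(prot, sort=True):
        rows.append({
            "protein_id": protein_id,
            "n_peptides": len(sub),
            "log2fc": trimmed_mean_fc(sub["log2fc"].to_numpy(), trim),
            "simes_p": simes_p(sub["p"].to_numpy()),
        })
    out = pd.DataFrame(rows).set_index("protein_id")
    out["q"] = bh_adjust(out["simes_p"].to_numpy())
    out["call"] = "ns"
    sig = out["q"] < fdr_threshold
    out.loc[sig & (out["log2fc"] > 0), "call"] = "up"
    out.loc[sig & (out["log2fc"] < 0), "call"] = "down"
    n_zero = int((sig & (out["log2fc"] == 0)).sum())
    if n_zero:
        logger.warning("%d significant proteins with log2FC == 0 left 'ns'",
                       n_zero)
    return ProteinDETable(table=out, fdr_threshold=fdr_threshold)


def classify_de(de: ProteinDETable,
                fdr_threshold: float | None = None) -> tuple[set, set]:
    """Up- and down-regulated protein id sets at strict q < threshold."""
    thr = de.fdr_threshold if fdr_threshold is None else fdr_threshold
    tab = de.table
    sig = tab["q"] < thr
    up = set(tab.index[sig & (tab["log2fc"] > 0)])
    down = set(tab.index[sig & (tab["log2fc"] < 0)])
    return up, down
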