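"""tRNA-modification quantification: internal-standard normalization and
genotype comparison.

LC-MS peak areas for the wobble-uridine modifications (ncm5U, mcm5U,
mcm5s2U) and Elongator-independent controls (m1A, m7G, t6A) are divided by
the pseudouridine (Psi) area of the same sample — Psi is abundant and
Elongator-independent, so it absorbs per-sample loading and instrument
response.  Genotypes are then compared to the control group by one-way
ANOVA with a Dunnett-style many-to-one comparison whose family-wise
adjustment is computed by seeded permutation of the maximum |t|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class SchemaError(ValueError):
    pass


@dataclass
class NormalizedModLevels:
    """Per-sample Psi-normalized levels and per-genotype relative means."""

    levels: pd.DataFrame       # sample rows: genotype + one column per mod
    relative: pd.DataFrame     # genotype rows: mean level / control mean
    control: str

    @property
    def modifications(self) -> list[str]:
        return [c for c in self.levels.columns if c != "genotype"]


def normalize_modifications(table: pd.DataFrame, control: str = "control",
                            psi_column: str = "Psi") -> NormalizedModLevels:
    """Divide every modification's peak area by the sample's Psi area.

    Relative levels are each genotype's mean level divided by the control
    genotype's mean, so the control row is exactly 1.  Scale-invariant:
    multiplying all areas of one sample by a constant changes nothing.
    """
    if psi_column not in table.columns:
        raise SchemaError(f"missing internal-standard column {psi_column!r}")
    for col in ("sample", "genotype"):
        if col not in table.columns:
            raise SchemaError(f"missing column {col!r}")
    if control not in set(table["genotype"]):
        raise SchemaError(f"control genotype {control!r} not present")
    psi = table[psi_column].to_numpy(dtype=float)
    bad = ~(psi > 0)
    if bad.any():
        names = table.loc[bad, "sample"].tolist()
        raise SchemaError(f"Psi area missing or <= 0 in sample(s): {names}")
    mods = [c for c in table.columns
            if c not in ("sample", "genotype", psi_column)]
    levels = table[mods].astype(float).div(psi, axis=0)
    levels.insert(0, "genotype", table["genotype"].values)
    levels.index = pd.Index(table["sample"], name="sample")
    means = levels.groupby("genotype")[mods].mean()
    relative = means / means.loc[control]
    return NormalizedModLevels(levels=levels, relative=relative,
                               control=control)


def compare_to_control(norm: NormalizedModLevels, n_perm: int = 2000,
                       seed: int | None = None) -> pd.DataFrame:
    """Many-to-one genotype comparison per modification.

    For each modification: a one-way ANOVA p across genotypes, and per
    mutant genotype a Dunnett-style t against control (pooled within-group
    variance) whose family-wise adjusted p is the permutation tail
    probability of the maximum |t| over comparisons under shuffled genotype
    labels.  Requires >= 2 genotypes with >= 3 samples each.
    """
    levels = norm.levels
    genotypes = sorted(levels["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    sizes = levels.groupby("genotype").size()
    if (sizes < 3).any():
        raise ValueError("need >= 3 samples per genotype")
    others = [g for g in genotypes if g != norm.control]
    labels = levels["genotype"].to_numpy()
    masks = {g: labels == g for g in genotypes}
    n_total = labels.size
    df_within = n_total - len(genotypes)
    rng = np.random.default_rng(seed)
    perm_idx = np.stack([rng.permutation(n_total) for _ in range(n_perm)])

    def dunnett_t(values_2d: np.ndarray) -> np.ndarray:
        """Dunnett-style t per comparison, rows = (permuted) datasets."""
        means = {g: values_2d[:, masks[g]].mean(axis=1) for g in genotypes}
        ss = sum(((values_2d[:, masks[g]] - means[g][:, None]) ** 2).sum(axis=1)
                 for g in genotypes)
        s2 = ss / df_within
        n_ctrl = masks[norm.control].sum()
        cols = []
        for g in others:
            se = np.sqrt(s2 * (1.0 / masks[g].sum() + 1.0 / n_ctrl))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (means[g] - means[norm.control]) / se
            cols.append(np.where(se > 0, t, 0.0))
        return np.column_stack(cols)  # (rows, comparisons)

    rows = []
    for mod in norm.modifications:
        y = levels[mod].to_numpy(dtype=float)
        by_geno = [y[masks[g]] for g in genotypes]
        anova_p = float(stats.f_oneway(*by_geno).pvalue)
        t_obs = dunnett_t(y[None, :])[0]
        null_max = np.abs(dunnett_t(y[perm_idx])).max(axis=1)
        for g, t in zip(others, t_obs):
            adj_p = float((1 + (null_max >= abs(t)).sum()) / (n_perm + 1))
            rows.append({"modification": mod, "genotype": g,
                         "t": float(t), "anova_p": anova_p,
                         "adjusted_p": adj_p})
    return pd.DataFrame(rows)
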