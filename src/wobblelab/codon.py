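"""Relative synonymous codon usage (RSCU) and codon-bias statistics.

Loss of Elongator-dependent wobble-uridine (U34) modifications slows decoding
of A-ending codons read by the affected tRNAs (Lys AAA, Gln CAA, Glu GAA),
while their G-ending synonyms (AAG, CAG, GAG) are decoded normally.  This
module quantifies the resulting bias: per-gene RSCU profiles, per-codon
median RSCU differences (dRSCU) between up- and down-regulated protein sets
with Mann-Whitney tests, AA- vs AG-ending codon-class enrichment, and
protein-length bias tests.

RSCU(c) = observed count of codon c divided by the mean count over its
synonymous family; 1 means unbiased usage.  Stop codons are excluded; the
single-codon families ATG (Met) and TGG (Trp) have RSCU = 1 whenever
observed.  Families absent from a gene are flagged absent, not scored 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .proteome import bh_adjust

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: codon -> amino acid for the 61 sense codons of the standard code
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
#: amino acid -> tuple of synonymous codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)

SENSE_CODONS = tuple(sorted(CODON_TO_AA))


class CodonError(ValueError):
    pass


@dataclass
class RSCUVector:
    """Per-codon RSCU values for one coding sequence.

    ``rscu`` holds values only for codons whose synonymous family was
    observed at least once; ``family_counts`` holds raw codon counts per
    family.
    """

    gene_id: str
    rscu: dict[str, float]
    family_counts: dict[str, dict[str, int]]

    def __getitem__(self, codon: str) -> float:
        return self.rscu[codon]

    def get(self, codon: str) -> float | None:
        return self.rscu.get(codon)


@dataclass
class CodonClassSpec:
    """Two disjoint sense-codon sets to contrast (default AA- vs AG-ending)."""

    class_a: frozenset = frozenset({"AAA", "CAA", "GAA"})
    class_b: frozenset = frozenset({"AAG", "CAG", "GAG"})
    label: str = "AA-ending vs AG-ending"

    def __post_init__(self) -> None:
        a, b = frozenset(self.class_a), frozenset(self.class_b)
        if a & b:
            raise CodonError("codon classes must be disjoint")
        bad = (a | b) - set(SENSE_CODONS)
        if bad:
            raise CodonError(f"non-sense codons in class spec: {sorted(bad)}")
        object.__setattr__(self, "class_a", a)
        object.__setattr__(self, "class_b", b)


@dataclass
class CodonBiasResult:
    per_codon: pd.DataFrame  # codon idx: family, delta_rscu, u, p, q, n_up, n_down
    skipped: list[str] = field(default_factory=list)


def rscu_profile(sequence: str, gene_id: str = "") -> RSCUVector:
    """RSCU vector of one CDS (standard genetic code, stops excluded).

    An internal stop codon triggers a warning but the profile is still
    computed over all sense codons; non-ACGT characters are rejected.
    """
    seq = str(sequence).upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise CodonError(f"{gene_id or 'CDS'}: length {len(seq)} not a "
                         "multiple of 3")
    if set(seq) - set("ACGT"):
        raise CodonError(f"{gene_id or 'CDS'}: ambiguous/non-ACGT characters")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    internal_stops = sum(c in STOP_CODONS for c in codons[:-1])
    if internal_stops:
        logger.warning("%s: %d internal stop codon(s)", gene_id, internal_stops)
    counts: dict[str, int] = {}
    for c in codons:
        if c not in STOP_CODONS:
            counts[c] = counts.get(c, 0) + 1
    rscu: dict[str, float] = {}
    family_counts: dict[str, dict[str, int]] = {}
    for aa, fam in FAMILIES.items():
        fam_counts = {c: counts.get(c, 0) for c in fam}
        total = sum(fam_counts.values())
        if total == 0:
            continue  # family absent: flagged by omission
        family_counts[aa] = fam_counts
        mean = total / len(fam)
        for c in fam:
            rscu[c] = fam_counts[c] / mean
    return RSCUVector(gene_id=gene_id, rscu=rscu, family_counts=family_counts)


def mann_whitney(x: np.ndarray, y: np.ndarray,
                 exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for small samples,
    tie-corrected normal approximation otherwise.  Returns (U, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # complete tie: no evidence either way
        return float(x.size * y.size / 2), 1.0
    if x.size <= exact_max_n and y.size <= exact_max_n:
        if np.unique(pooled).size == pooled.size:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact")
            return float(res.statistic), float(min(res.pvalue, 1.0))
        return _exact_mwu_with_ties(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _exact_mwu_with_ties(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p under ties: enumerate every group-label
    assignment of the pooled sample (feasible for the small-n path only)."""
    import itertools

    pooled = np.concatenate([x, y])
    n1, n = x.size, pooled.size
    # U via the rank formulation, 0.5 per tie
    gt = pooled[:, None] > pooled[None, :]
    eq = pooled[:, None] == pooled[None, :]
    half = gt + 0.5 * eq
    np.fill_diagonal(half, 0.0)

    def u_of(idx: tuple[int, ...]) -> float:
        rest = np.setdiff1d(np.arange(n), idx)
        return float(half[np.ix_(idx, rest)].sum())

    u_obs = u_of(tuple(range(n1)))
    us = np.array([u_of(c)
                   for c in itertools.combinations(range(n), n1)])
    lo = float((us <= u_obs).mean())
    hi = float((us >= u_obs).mean())
    return u_obs, min(1.0, 2 * min(lo, hi))


def compare_codon_usage(up: list[RSCUVector], down: list[RSCUVector],
                        min_genes: int = 3) -> CodonBiasResult:
    """Per-codon dRSCU (median up - median down) with Mann-Whitney tests.

    Codons observed in fewer than ``min_genes`` genes on either side are
    skipped and listed in ``skipped``.  BH q-values run across tested codons.
    """
    if not up:
        raise ValueError("up set is empty")
    if not down:
        raise ValueError("down set is empty")
    rows, skipped = [], []
    for codon in SENSE_CODONS:
        uv = np.array([v.rscu[codon] for v in up if codon in v.rscu])
        dv = np.array([v.rscu[codon] for v in down if codon in v.rscu])
        if uv.size < min_genes or dv.size < min_genes:
            skipped.append(codon)
            continue
        u_stat, p = mann_whitney(uv, dv)
        rows.append({
            "codon": codon, "family": CODON_TO_AA[codon],
            "delta_rscu": float(np.median(uv) - np.median(dv)),
            "u": u_stat, "p": p, "n_up": uv.size, "n_down": dv.size,
        })
    per_codon = pd.DataFrame(rows).set_index("codon") if rows else \
        pd.DataFrame(columns=["family", "delta_rscu", "u", "p",
                              "n_up", "n_down"])
    if len(per_codon):
        per_codon["q"] = bh_adjust(per_codon["p"].to_numpy())
    return CodonBiasResult(per_codon=per_codon, skipped=skipped)


def class_scores(profiles: list[RSCUVector],
                 spec: CodonClassSpec) -> pd.Series:
    """Per-gene codon-class score: mean RSCU over class A minus mean RSCU
    over class B, over observed codons only; positive = A-biased.
    Genes observing no codon of either class are excluded."""
    scores = {}
    for prof in profiles:
        a = [prof.rscu[c] for c in spec.class_a if c in prof.rscu]
        b = [prof.rscu[c] for c in spec.class_b if c in prof.rscu]
        if not a and not b:
            continue
        score_a = float(np.mean(a)) if a else 0.0
        score_b = float(np.mean(b)) if b else 0.0
        scores[prof.gene_id] = score_a - score_b
    return pd.Series(scores, dtype=float)


def codon_class_enrichment(up: list[RSCUVector], down: list[RSCUVector],
                           spec: CodonClassSpec | None = None) -> dict:
    """Compare per-gene codon-class scores between up and down sets
    (two-sided Mann-Whitney)."""
    spec = spec or CodonClassSpec()
    up_scores = class_scores(up, spec)
    down_scores = class_scores(down, spec)
    if up_scores.empty or down_scores.empty:
        side = "up" if up_scores.empty else "down"
        raise ValueError(f"no scorable genes in the {side} set")
    u_stat, p = mann_whitney(up_scores.to_numpy(), down_scores.to_numpy())
    return {
        "label": spec.label,
        "up_median_score": float(up_scores.median()),
        "down_median_score": float(down_scores.median()),
        "u": u_stat,
        "p": p,
        "n_up": len(up_scores),
        "n_down": len(down_scores),
        "n_excluded": (len(up) - len(up_scores)) + (len(down) - len(down_scores)),
    }


def length_bias_test(set_lengths: np.ndarray,
                     reference_lengths: np.ndarray) -> dict:
    """Length bias of a protein set against all quantified proteins.

    Dichotomizes the set at the reference median into short (< median) and
    long (> median) members and compares the two subsets by two-sided
    Wilcoxon rank-sum; also reports a sign-test p for the set median
    differing from the reference median.  A split with an empty side is
    degenerate: p = 1 with a flag.
    """
    set_lengths = np.asarray(set_lengths, dtype=float)
    reference_lengths = np.asarray(reference_lengths, dtype=float)
    if set_lengths.size < 2:
        raise ValueError("need at least 2 proteins in the set")
    ref_median = float(np.median(reference_lengths))
    short = set_lengths[set_lengths < ref_median]
    long_ = set_lengths[set_lengths > ref_median]
    degenerate = short.size == 0 or long_.size == 0
    if degenerate:
        split_p = 1.0
    else:
        _, split_p = mann_whitney(short, long_)
    n_informative = short.size + long_.size
    if n_informative == 0:
        sign_p = 1.0
    else:
        sign_p = float(stats.binomtest(int(short.size), n_informative,
                                       0.5).pvalue)
    return {
        "reference_median": ref_median,
        "n_short": int(short.size),
        "n_long": int(long_.size),
        "split_p": float(split_p),
        "sign_p": sign_p,
        "degenerate": degenerate,
    }
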