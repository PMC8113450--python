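"""Network-based statistic (NBS) on structural connectomes.

Given per-subject symmetric streamline-count matrices and a two-group design,
the NBS thresholds edge-wise two-sample t statistics at a primary threshold,
extracts connected components of the supra-threshold graph, scores each
component by its *extent* (edge count), and assigns family-wise-error-
corrected p-values from the permutation null distribution of the maximum
component extent.  A threshold scan reports the primary threshold with the
lowest corrected p, run separately for increased and decreased connectivity.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ConnectomeSet:
    """Subject connectivity matrices (symmetric, zero diagonal) + groups."""

    matrices: dict[str, np.ndarray]
    groups: pd.Series  # subject -> group label
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        dims = {m.shape for m in self.matrices.values()}
        if len(dims) != 1:
            raise ValueError(f"matrix dimension mismatch across subjects: {dims}")
        (dim,) = dims
        if dim[0] != dim[1]:
            raise ValueError("matrices must be square")
        for subj, m in self.matrices.items():
            if not np.allclose(m, m.T, atol=1e-6):
                raise ValueError(f"matrix for {subj!r} is not symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"matrix for {subj!r} has nonzero diagonal")
            if (m < 0).any():
                raise ValueError(f"matrix for {subj!r} has negative weights")
        if set(self.groups.index) != set(self.matrices):
            raise ValueError("group labels must cover exactly the subjects")
        if not self.node_labels:
            self.node_labels = [f"node_{i:03d}" for i in range(dim[0])]

    @property
    def n_nodes(self) -> int:
        return next(iter(self.matrices.values())).shape[0]

    def edge_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(subjects x edges) matrix over the upper triangle, plus (i, j)."""
        n = self.n_nodes
        iu = np.triu_indices(n, k=1)
        subjects = sorted(self.matrices)
        x = np.stack([self.matrices[s][iu] for s in subjects])
        return x, iu[0], iu[1]

    def group_indicator(self, mutant_label: str) -> np.ndarray:
        subjects = sorted(self.matrices)
        return np.array([self.groups[s] == mutant_label for s in subjects])


@dataclass
class NBSComponent:
    edges: list[tuple[int, int]]
    extent: int
    fwer_p: float


@dataclass
class NBSResult:
    t_primary: float
    direction: str
    components: list[NBSComponent]
    n_perm: int
    seed: int | None

    @property
    def min_fwer_p(self) -> float:
        return min((c.fwer_p for c in self.components), default=1.0)

    @property
    def largest(self) -> NBSComponent | None:
        return max(self.components, key=lambda c: c.extent, default=None)


# ---------------------------------------------------------------------------
# edge statistics


def _pooled_t(x: np.ndarray, in_g1: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column of ``x`` (group1 - group2).

    Edges with zero pooled variance get 0 when the means agree and +/-inf
    otherwise.
    """
    n1 = int(in_g1.sum())
    n2 = x.shape[0] - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 subjects per group")
    x1, x2 = x[in_g1], x[~in_g1]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    ss = ((x1 - m1) ** 2).sum(axis=0) + ((x2 - m2) ** 2).sum(axis=0)
    s2 = ss / (n1 + n2 - 2)
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where(se == 0, np.where(diff == 0, 0.0,
                                       np.sign(diff) * np.inf), t)
    return t


def edge_statistics(conn: ConnectomeSet, direction: str = "increase",
                    mutant_label: str = "mutant") -> np.ndarray:
    """Symmetric matrix of one-sided edge t statistics.

    ``direction='increase'`` scores mutant > control; ``'decrease'`` scores
    mutant < control (the two are exact negatives).
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    x, rows, cols = conn.edge_table()
    t = _pooled_t(x, conn.group_indicator(mutant_label))
    if direction == "decrease":
        t = -t
    n = conn.n_nodes
    out = np.zeros((n, n))
    out[rows, cols] = t
    out = out + out.T
    return out


# ---------------------------------------------------------------------------
# components


def extract_components(stat_matrix: np.ndarray, t_primary: float
                       ) -> list[tuple[list[tuple[int, int]], int]]:
    """Connected components of the supra-threshold graph.

    Edges with statistic strictly above ``t_primary`` form the graph;
    each returned component is (sorted edge list, extent = edge count).
    Components are edge-disjoint by construction.
    """
    if not np.isfinite(t_primary):
        raise ValueError("t_primary must be finite")
    iu = np.triu_indices(stat_matrix.shape[0], k=1)
    supra = stat_matrix[iu] > t_primary
    g = nx.Graph()
    g.add_edges_from(zip(iu[0][supra], iu[1][supra]))
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        edges = sorted((min(a, b), max(a, b)) for a, b in sub.edges)
        comps.append((edges, len(edges)))
    comps.sort(key=lambda c: (-c[1], c[0]))
    return comps


def _max_extent_per_perm(t_null: np.ndarray, rows: np.ndarray,
                         cols: np.ndarray, t_primary: float) -> np.ndarray:
    """Maximum component extent per permutation (union-find on the few
    supra-threshold edges)."""
    out = np.zeros(t_null.shape[0], dtype=int)
    supra_all = t_null > t_primary
    for k in range(t_null.shape[0]):
        idx = np.nonzero(supra_all[k])[0]
        if idx.size == 0:
            continue
        parent: dict[int, int] = {}
        size: dict[int, int] = {}

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        count: dict[int, int] = {}
        for e in idx:
            a, b = int(rows[e]), int(cols[e])
            for v in (a, b):
                if v not in parent:
                    parent[v] = v
                    count[v] = 0
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
                count[ra] += count.pop(rb)
            count[ra] = count.get(ra, 0) + 1
        out[k] = max(count[find(r)] for r in count)
    return out


# ---------------------------------------------------------------------------
# permutation machinery


def _relabelings(n_subjects: int, n_group1: int, observed: tuple[int, ...],
                 n_perm: int, seed: int | None) -> list[tuple[int, ...]]:
    """Distinct group-label assignments excluding the observed one: full
    enumeration when few exist, else uniform sampling without replacement."""
    total = math.comb(n_subjects, n_group1)
    if total - 1 <= n_perm:
        if total - 1 < 100:
            logger.warning(
                "only %d distinct relabelings exist; using full enumeration",
                total - 1)
        return [c for c in itertools.combinations(range(n_subjects), n_group1)
                if c != observed]
    rng = np.random.default_rng(seed)
    seen = {observed}
    out: list[tuple[int, ...]] = []
    while len(out) < n_perm:
        c = tuple(sorted(rng.choice(n_subjects, size=n_group1,
                                    replace=False).tolist()))
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def _null_t(x: np.ndarray, relabelings: list[tuple[int, ...]],
            chunk: int = 500):
    """Yield pooled-t arrays (chunk x edges) for permuted group labels."""
    n_subj, _ = x.shape
    for start in range(0, len(relabelings), chunk):
        block = relabelings[start:start + chunk]
        g = np.zeros((len(block), n_subj), dtype=bool)
        for i, comb in enumerate(block):
            g[i, list(comb)] = True
        n1 = g[0].sum()
        n2 = n_subj - n1
        tot = x.sum(axis=0)
        tot_sq = (x ** 2).sum(axis=0)
        s1 = g @ x
        s1_sq = g @ (x ** 2)
        m1 = s1 / n1
        m2 = (tot - s1) / n2
        ss = (s1_sq - n1 * m1 ** 2) + ((tot_sq - s1_sq) - n2 * m2 ** 2)
        s2 = ss / (n_subj - 2)
        se = np.sqrt(np.maximum(s2, 0) * (1.0 / n1 + 1.0 / n2))
        diff = m1 - m2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
            t = np.where(se == 0, np.where(diff == 0, 0.0,
                                           np.sign(diff) * np.inf), t)
        yield t


def nbs_test(conn: ConnectomeSet, direction: str = "increase",
             t_primary: float = 3.0, n_perm: int = 5000,
             seed: int | None = None,
             mutant_label: str = "mutant") -> NBSResult:
    """Network-based statistic with permutation FWER correction.

    The null distribution is the maximum component extent over group-label
    permutations (full enumeration when the design admits no more than
    ``n_perm`` distinct relabelings, else seeded uniform sampling without
    replacement).  Each observed component's corrected p is
    ``(1 + #{null max >= extent}) / (n_used + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    res = scan_thresholds(conn, direction=direction, t_range=(t_primary,),
                          n_perm=n_perm, seed=seed, mutant_label=mutant_label)
    return res[0][0]


def scan_thresholds(conn: ConnectomeSet, direction: str = "increase",
                    t_range: tuple[float, ...] | None = None,
                    n_perm: int = 5000, seed: int | None = None,
                    mutant_label: str = "mutant"
                    ) -> tuple[tuple[NBSResult, ...], NBSResult]:
    """Run the NBS at each primary threshold with one shared permutation
    schedule; return (per-threshold results, best result).

    The default range is t = 2.5 to 3.5 in steps of 0.1.  The best result is
    the threshold with the smallest component FWER p, ties broken toward the
    lower threshold.
    """
    if t_range is None:
        t_range = tuple(np.round(np.arange(2.5, 3.5001, 0.1), 1))
    if len(t_range) == 0:
        raise ValueError("t_range must be nonempty")
    x, rows, cols = conn.edge_table()
    in_g1 = conn.group_indicator(mutant_label)
    sign = -1.0 if direction == "decrease" else 1.0
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    t_obs = sign * _pooled_t(x, in_g1)

    observed = tuple(int(i) for i in np.nonzero(in_g1)[0])
    relabelings = _relabelings(x.shape[0], int(in_g1.sum()), observed,
                               n_perm, seed)
    n_used = len(relabelings)

    null_max = np.zeros((len(t_range), n_used), dtype=int)
    done = 0
    for t_block in _null_t(x, relabelings):
        t_block = sign * t_block
        for ti, t_primary in enumerate(t_range):
            null_max[ti, done:done + t_block.shape[0]] = \
                _max_extent_per_perm(t_block, rows, cols, t_primary)
        done += t_block.shape[0]

    n = conn.n_nodes
    stat = np.zeros((n, n))
    stat[rows, cols] = t_obs
    stat = stat + stat.T

    results = []
    for ti, t_primary in enumerate(t_range):
        comps = extract_components(stat, t_primary)
        components = [
            NBSComponent(
                edges=edges, extent=extent,
                fwer_p=float((1 + int((null_max[ti] >= extent).sum()))
                             / (n_used + 1)),
            )
            for edges, extent in comps
        ]
        results.append(NBSResult(t_primary=float(t_primary),
                                 direction=direction, components=components,
                                 n_perm=n_used, seed=seed))
    best = min(results, key=lambda r: (r.min_fwer_p, r.t_primary))
    return tuple(results), best


def result_table(results: tuple[NBSResult, ...]) -> pd.DataFrame:
    rows = []
    for r in results:
        largest = r.largest
        rows.append({
            "t_primary": r.t_primary,
            "direction": r.direction,
            "n_components": len(r.components),
            "max_extent": largest.extent if largest else 0,
            "min_fwer_p": r.min_fwer_p,
            "n_perm": r.n_perm,
        })
    return pd.DataFrame(rows)
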