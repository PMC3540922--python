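"""Two-step cluster analysis for de novo syllable category discovery.

The procedure compresses the data into cluster-feature (CF) entries with a
sequential BIRCH-style pass, agglomerates those entries by minimum
log-likelihood distance, selects the number of clusters with a BIC-based
two-stage rule, and finally assigns every original row to its nearest
cluster.  Cluster quality is summarized by the average silhouette of
cohesion on standardized variables.

Formulas follow the Chiu et al. (2001) formulation used by mainstream
statistics packages: each entry ``v`` has tightness

    xi(v) = -n_v * sum_k 0.5 * log(g_k + s2_{v,k})

where ``g_k`` is the global (whole-data) variance of variable ``k`` acting
as a regularizer and ``s2_{v,k}`` the within-entry variance, and the merge
cost is ``d(a, b) = xi(a) + xi(b) - xi(a+b) >= 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CFEntry",
    "CFTreeParams",
    "ClusterModel",
    "CollinearityReport",
    "MergeTree",
    "check_collinearity",
    "log_likelihood_distance",
    "precluster",
    "agglomerate",
    "choose_k",
    "silhouette_cohesion",
    "fit",
    "DEFAULT_VARIABLES",
]

DEFAULT_VARIABLES = ("n_steps", "start_khz", "middle_khz", "end_khz")


# ---------------------------------------------------------------------------
# Cluster features


@dataclass
class CFEntry:
    """Sufficient statistics of a (sub-)cluster: count, sums, sums of squares."""

    n: int
    linear_sum: np.ndarray
    square_sum: np.ndarray

    @classmethod
    def from_row(cls, x: Sequence[float]) -> "CFEntry":
        x = np.asarray(x, dtype=float)
        return cls(1, x.copy(), x**2)

    def merge(self, other: "CFEntry") -> "CFEntry":
        return CFEntry(
            self.n + other.n,
            self.linear_sum + other.linear_sum,
            self.square_sum + other.square_sum,
        )

    @property
    def mean(self) -> np.ndarray:
        return self.linear_sum / self.n

    @property
    def variance(self) -> np.ndarray:
        """Per-variable maximum-likelihood variance, clipped at zero."""
        v = self.square_sum / self.n - (self.linear_sum / self.n) ** 2
        return np.maximum(v, 0.0)


@dataclass(frozen=True)
class CFTreeParams:
    """Pre-clustering settings.

    ``max_branches`` and ``max_depth`` bound the CF tree as in the SPSS
    defaults (8 and 3), giving a leaf-entry capacity of
    ``max_branches ** max_depth``.  ``disable=True`` skips compression and
    yields one singleton entry per row (used by the oracle tests).
    """

    max_branches: int = 8
    max_depth: int = 3
    distance_threshold: float = 0.0
    disable: bool = False

    def __post_init__(self) -> None:
        if self.max_branches < 2:
            raise ValueError("max_branches must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")

    @property
    def capacity(self) -> int:
        return self.max_branches**self.max_depth


def _xi(n: np.ndarray, var: np.ndarray, global_var: np.ndarray) -> np.ndarray:
    """Tightness of entries given as arrays of counts and variances.

    ``n`` has shape (E,), ``var`` shape (E, V); returns shape (E,).
    """
    return -np.asarray(n) * 0.5 * np.sum(np.log(global_var + var), axis=-1)


def _xi_single(entry: CFEntry, global_var: np.ndarray) -> float:
    return float(-entry.n * 0.5 * np.sum(np.log(global_var + entry.variance)))


def log_likelihood_distance(
    a: CFEntry, b: CFEntry, global_variances: Sequence[float]
) -> float:
    """Log-likelihood merge cost between two cluster-feature entries.

    ``d(a, b) = xi(a) + xi(b) - xi(a+b)``; symmetric and non-negative.  The
    global per-variable variances regularize the within-entry variances so
    singleton entries have finite tightness.
    """
    g = np.asarray(global_variances, dtype=float)
    if a.linear_sum.shape != b.linear_sum.shape or a.linear_sum.shape != g.shape:
        raise ValueError("entries and global variances must share the variable set")
    d = _xi_single(a, g) + _xi_single(b, g) - _xi_single(a.merge(b), g)
    return float(max(d, 0.0))


# ---------------------------------------------------------------------------
# Step 1: sequential pre-clustering


class _EntryStore:
    """Flat array-backed store of CF entries supporting vectorized queries."""

    def __init__(self, n_vars: int, capacity_hint: int = 64):
        self.size = 0
        self.N = np.zeros(capacity_hint)
        self.LS = np.zeros((capacity_hint, n_vars))
        self.SS = np.zeros((capacity_hint, n_vars))

    def _grow(self) -> None:
        self.N = np.concatenate([self.N, np.zeros_like(self.N)])
        self.LS = np.concatenate([self.LS, np.zeros_like(self.LS)])
        self.SS = np.concatenate([self.SS, np.zeros_like(self.SS)])

    def append(self, n: float, ls: np.ndarray, ss: np.ndarray) -> None:
        if self.size == self.N.size:
            self._grow()
        self.N[self.size] = n
        self.LS[self.size] = ls
        self.SS[self.size] = ss
        self.size += 1

    def variances(self) -> np.ndarray:
        n = self.N[: self.size, None]
        return np.maximum(self.SS[: self.size] / n - (self.LS[: self.size] / n) ** 2, 0.0)

    def entries(self) -> list[CFEntry]:
        return [
            CFEntry(int(round(self.N[i])), self.LS[i].copy(), self.SS[i].copy())
            for i in range(self.size)
        ]


def _distances_to_entries(
    store: _EntryStore, n: float, ls: np.ndarray, ss: np.ndarray, g: np.ndarray
) -> np.ndarray:
    """Merge cost between one candidate entry and every stored entry."""
    s = store.size
    N, LS, SS = store.N[:s], store.LS[:s], store.SS[:s]
    var_e = store.variances()
    xi_e = _xi(N, var_e, g)
    var_x = np.maximum(ss / n - (ls / n) ** 2, 0.0)
    xi_x = float(_xi(np.array(n), var_x, g))
    nm = N + n
    lsm = LS + ls
    ssm = SS + ss
    var_m = np.maximum(ssm / nm[:, None] - (lsm / nm[:, None]) ** 2, 0.0)
    xi_m = _xi(nm, var_m, g)
    return np.maximum(xi_e + xi_x - xi_m, 0.0)


def precluster(
    data: np.ndarray,
    params: CFTreeParams | None = None,
    global_variances: np.ndarray | None = None,
) -> list[CFEntry]:
    """Compress rows into CF entries with a sequential threshold pass.

    Each row is absorbed into its nearest existing entry when the merge cost
    is at or below the current distance threshold, otherwise it seeds a new
    entry.  When the number of entries exceeds the tree capacity
    (``max_branches ** max_depth``), the threshold is raised to the smallest
    observed inter-entry distance (at least doubling) and the entries are
    re-inserted — the BIRCH rebuild strategy.  Exact duplicates always merge
    (cost 0).  The sum of entry counts equals the number of rows.
    """
    params = params or CFTreeParams()
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("data must be a non-empty 2-D array")
    if params.disable:
        return [CFEntry.from_row(x) for x in X]
    g = (
        np.asarray(global_variances, dtype=float)
        if global_variances is not None
        else X.var(axis=0)
    )
    g = np.where(g > 0, g, 1.0)  # constant variables carry no distance signal

    store = _EntryStore(X.shape[1])
    threshold = float(params.distance_threshold)
    capacity = params.capacity

    def rebuild(current: _EntryStore, thr: float) -> _EntryStore:
        new = _EntryStore(X.shape[1], capacity_hint=max(64, current.size))
        for i in range(current.size):
            n, ls, ss = current.N[i], current.LS[i], current.SS[i]
            if new.size:
                d = _distances_to_entries(new, n, ls, ss, g)
                j = int(np.argmin(d))
                if d[j] <= thr:
                    new.N[j] += n
                    new.LS[j] += ls
                    new.SS[j] += ss
                    continue
            new.append(n, ls, ss)
        return new

    for x in X:
        ss_x = x**2
        if store.size:
            d = _distances_to_entries(store, 1.0, x, ss_x, g)
            j = int(np.argmin(d))
            if d[j] <= threshold:
                store.N[j] += 1.0
                store.LS[j] += x
                store.SS[j] += ss_x
                continue
        store.append(1.0, x, ss_x)
        while store.size > capacity:
            # Smallest inter-entry distance sets the new threshold.
            dmin = np.inf
            for i in range(store.size):
                di = _distances_to_entries(store, store.N[i], store.LS[i], store.SS[i], g)
                di[i] = np.inf
                dmin = min(dmin, float(di.min()))
            threshold = max(dmin, threshold * 2.0, 1e-12)
            store = rebuild(store, threshold)
    return store.entries()


# ---------------------------------------------------------------------------
# Step 2: agglomeration, model selection, assignment


@dataclass
class MergeTree:
    """Record of a greedy agglomeration of CF entries.

    ``labels_by_k[k]`` maps each input entry to a cluster index in
    ``0..k-1`` (indices ordered by first entry appearance);
    ``merge_distance_to[k]`` is the cost of the merge that produced the
    ``k``-cluster partition from ``k+1`` clusters.
    """

    n_entries: int
    labels_by_k: dict[int, np.ndarray]
    merge_distance_to: dict[int, float]


def _pairwise_distance_matrix(
    N: np.ndarray, LS: np.ndarray, SS: np.ndarray, g: np.ndarray, active: np.ndarray
) -> np.ndarray:
    E = N.size
    var = np.maximum(SS / N[:, None] - (LS / N[:, None]) ** 2, 0.0)
    xi = _xi(N, var, g)
    M = np.full((E, E), np.inf)
    for i in range(E):
        if not active[i]:
            continue
        idx = np.flatnonzero(active[i + 1 :]) + i + 1
        if idx.size == 0:
            continue
        nm = N[i] + N[idx]
        lsm = LS[i] + LS[idx]
        ssm = SS[i] + SS[idx]
        var_m = np.maximum(ssm / nm[:, None] - (lsm / nm[:, None]) ** 2, 0.0)
        xi_m = _xi(nm, var_m, g)
        d = np.maximum(xi[i] + xi[idx] - xi_m, 0.0)
        M[i, idx] = d
        M[idx, i] = d
    return M


def agglomerate(
    entries: Sequence[CFEntry],
    global_variances: Sequence[float],
    k_max: int = 15,
) -> MergeTree:
    """Greedy agglomeration of entries by minimum log-likelihood distance.

    At each step the pair with the smallest merge cost is joined (ties
    broken toward the lowest index pair, scanning row-major), down to a
    single cluster.  Partitions for every ``k <= k_max`` are recorded.
    """
    E = len(entries)
    if E < 1:
        raise ValueError("at least one entry required")
    g = np.asarray(global_variances, dtype=float)
    N = np.array([float(e.n) for e in entries])
    LS = np.array([e.linear_sum for e in entries], dtype=float)
    SS = np.array([e.square_sum for e in entries], dtype=float)
    active = np.ones(E, dtype=bool)
    owner = np.arange(E)  # entry -> representative entry index

    labels_by_k: dict[int, np.ndarray] = {}
    merge_distance_to: dict[int, float] = {}

    def snapshot(k: int) -> None:
        reps = owner.copy()
        _, labels = np.unique(reps, return_inverse=True)
        # Renumber by first appearance for deterministic labels.
        order: dict[int, int] = {}
        out = np.empty(E, dtype=int)
        for i, lab in enumerate(labels):
            if lab not in order:
                order[lab] = len(order)
            out[i] = order[lab]
        labels_by_k[k] = out

    if E <= k_max:
        snapshot(E)
    if E == 1:
        return MergeTree(1, labels_by_k, merge_distance_to)

    M = _pairwise_distance_matrix(N, LS, SS, g, active)
    var = np.maximum(SS / N[:, None] - (LS / N[:, None]) ** 2, 0.0)
    xi = _xi(N, var, g)

    for k_current in range(E, 1, -1):
        flat = int(np.argmin(M))  # first minimum row-major: lowest (i, j)
        i, j = divmod(flat, E)
        if i > j:
            i, j = j, i
        dist = float(M[i, j])
        # Merge j into i.
        N[i] += N[j]
        LS[i] += LS[j]
        SS[i] += SS[j]
        active[j] = False
        owner[owner == owner[j]] = owner[i]
        M[j, :] = np.inf
        M[:, j] = np.inf
        var_i = np.maximum(SS[i] / N[i] - (LS[i] / N[i]) ** 2, 0.0)
        xi[i] = float(_xi(np.array(N[i]), var_i, g))
        idx = np.flatnonzero(active)
        idx = idx[idx != i]
        if idx.size:
            nm = N[i] + N[idx]
            lsm = LS[i] + LS[idx]
            ssm = SS[i] + SS[idx]
            var_m = np.maximum(ssm / nm[:, None] - (lsm / nm[:, None]) ** 2, 0.0)
            xi_m = _xi(nm, var_m, g)
            d = np.maximum(xi[i] + xi[idx] - xi_m, 0.0)
            M[i, idx] = d
            M[idx, i] = d
        else:
            M[i, :] = np.inf
            M[:, i] = np.inf
        k_new = k_current - 1
        merge_distance_to[k_new] = dist
        if k_new <= k_max:
            snapshot(k_new)
    return MergeTree(E, labels_by_k, merge_distance_to)


def _bic_curve(
    entries: Sequence[CFEntry],
    tree: MergeTree,
    global_variances: np.ndarray,
    n_total: int,
) -> dict[int, float]:
    """BIC(k) = -2 * sum_clusters xi + 2 k V log(n) for each recorded k."""
    g = np.asarray(global_variances, dtype=float)
    V = g.size
    curve: dict[int, float] = {}
    for k, labels in sorted(tree.labels_by_k.items()):
        total_xi = 0.0
        for c in range(k):
            members = [entries[i] for i in np.flatnonzero(labels == c)]
            agg = members[0]
            for m in members[1:]:
                agg = agg.merge(m)
            total_xi += _xi_single(agg, g)
        curve[k] = -2.0 * total_xi + 2.0 * k * V * np.log(n_total)
    return curve


def choose_k(
    bic_curve: dict[int, float],
    merge_distance_to: dict[int, float],
    bic_ratio_threshold: float = 0.04,
    distance_ratio_threshold: float = 1.15,
    min_distance_jump: float = 2.0,
) -> int:
    """Two-stage selection of the cluster count.

    Stage 1 scans the BIC curve: the candidate ceiling ``k1`` is the first
    ``k`` whose improvement ``BIC(k+1) - BIC(k)`` falls below
    ``bic_ratio_threshold`` times the first improvement (or ``k = 1``
    immediately if BIC does not improve at all).  Stage 2 examines the
    merge-distance ratios ``R(k) = d(k-1 <- k) / d(k <- k+1)`` for
    ``2 <= k <= k1``: a large ratio marks the last merge before genuinely
    distinct groups are joined.  The ``k`` with the largest ratio wins if it
    beats the runner-up by ``distance_ratio_threshold``; otherwise the
    larger of the two candidate ``k`` is taken.  If no ratio reaches
    ``min_distance_jump`` the merge sequence is judged structureless and a
    single cluster is returned.
    """
    ks = sorted(bic_curve)
    k_hi = ks[-1]
    if k_hi == 1:
        return 1
    dbic = {k: bic_curve[k + 1] - bic_curve[k] for k in ks[:-1]}
    if dbic[1] >= 0:
        return 1
    k1 = k_hi
    for k in ks[:-1]:
        if dbic[k] / dbic[1] < bic_ratio_threshold:
            k1 = k
            break
    if k1 == 1:
        return 1

    def ratio(k: int) -> float:
        num = merge_distance_to.get(k - 1, np.nan)
        den = merge_distance_to.get(k, np.nan)
        if not np.isfinite(num) or not np.isfinite(den):
            return 0.0
        if den <= 0.0:
            return np.inf if num > 0 else 1.0
        return num / den

    candidates = list(range(2, k1 + 1))
    ratios = {k: ratio(k) for k in candidates}
    best = max(candidates, key=lambda k: (ratios[k], -k))
    if ratios[best] < min_distance_jump:
        return 1
    rest = [k for k in candidates if k != best]
    if not rest:
        return best
    second = max(rest, key=lambda k: (ratios[k], -k))
    if ratios[second] <= 0 or ratios[best] / ratios[second] > distance_ratio_threshold:
        return best
    return max(best, second)


def silhouette_cohesion(data: np.ndarray, assignments: Sequence[int]) -> float:
    """Average silhouette of cohesion on standardized variables.

    For each point, ``(b - a) / max(a, b)`` with ``a`` the mean Euclidean
    distance to its own cluster's other members and ``b`` the smallest mean
    distance to another cluster; averaged over all points.  Variables are
    z-scored first.  Requires at least two non-empty clusters; singleton
    clusters contribute 0 for their lone member.
    """
    X = np.asarray(data, dtype=float)
    labels = np.asarray(assignments)
    if X.shape[0] != labels.size:
        raise ValueError("data and assignments length mismatch")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = Z.shape[0]
    sums = np.zeros((n, uniq.size))
    counts = np.array([(labels == u).sum() for u in uniq])
    chunk = max(1, int(2**25 // max(n, 1)))
    for start in range(0, n, chunk):
        block = Z[start : start + chunk]
        d = np.sqrt(
            np.maximum(
                (block**2).sum(1)[:, None] + (Z**2).sum(1)[None, :] - 2.0 * block @ Z.T,
                0.0,
            )
        )
        for ui, u in enumerate(uniq):
            sums[start : start + chunk, ui] = d[:, labels == u].sum(axis=1)
    own = np.searchsorted(uniq, labels)
    s = np.zeros(n)
    for i in range(n):
        ui = own[i]
        if counts[ui] > 1:
            a = sums[i, ui] / (counts[ui] - 1)
        else:
            s[i] = 0.0
            continue
        other = [sums[i, uj] / counts[uj] for uj in range(uniq.size) if uj != ui]
        b = min(other)
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


# ---------------------------------------------------------------------------
# Collinearity screen


@dataclass
class CollinearityReport:
    """Pairwise Pearson correlations with |r| > 0.9 pairs flagged."""

    variables: list[str]
    pairwise_r: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    undefined: list[str] = field(default_factory=list)


def check_collinearity(data: pd.DataFrame, r_threshold: float = 0.9) -> CollinearityReport:
    """Screen clustering variables for confounding correlations.

    Pairs with ``|r| > r_threshold`` are flagged with a warning (not an
    error).  Constant variables have undefined correlations and are flagged
    separately.
    """
    if data.shape[1] < 2 or data.shape[0] < 3:
        raise ValueError("collinearity check requires >= 2 variables and >= 3 rows")
    variables = list(data.columns)
    corr = data.corr()
    np.fill_diagonal(corr.values, 1.0)
    undefined = [v for v in variables if data[v].nunique() <= 1]
    flagged = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > r_threshold:
                flagged.append((a, b, float(r)))
    if flagged:
        warnings.warn(
            "highly correlated variable pairs (|r| > "
            f"{r_threshold}): {[(a, b) for a, b, _ in flagged]}",
            stacklevel=2,
        )
    if undefined:
        warnings.warn(f"constant variables with undefined correlations: {undefined}", stacklevel=2)
    return CollinearityReport(variables, corr, flagged, undefined)


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class ClusterModel:
    """Fitted two-step clustering result."""

    k: int
    variables: list[str]
    sizes: np.ndarray
    means: np.ndarray  # (k, V)
    variances: np.ndarray  # (k, V)
    assignments: np.ndarray  # per accepted row, cluster index 0..k-1
    bic_curve: dict[int, float]
    merge_distance_to: dict[int, float]
    silhouette: float | None
    rejected_rows: np.ndarray  # positional indices of rejected input rows
    labels_by_k: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "variables": list(self.variables),
            "sizes": [int(s) for s in self.sizes],
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "bic_curve": {str(k): float(v) for k, v in sorted(self.bic_curve.items())},
            "silhouette": None if self.silhouette is None else float(self.silhouette),
            "n_rejected": int(self.rejected_rows.size),
        }


def _assign_rows(
    X: np.ndarray, sizes: np.ndarray, means: np.ndarray, variances: np.ndarray, g: np.ndarray
) -> np.ndarray:
    """Nearest-cluster assignment of rows by log-likelihood merge cost."""
    n, V = X.shape
    k = sizes.size
    cost = np.empty((n, k))
    xi_x = -0.5 * np.sum(np.log(g), axis=-1)  # singleton rows: zero variance
    for c in range(k):
        nc = sizes[c]
        ls = means[c] * nc
        ss = (variances[c] + means[c] ** 2) * nc
        xi_c = float(-nc * 0.5 * np.sum(np.log(g + variances[c])))
        nm = nc + 1.0
        lsm = ls + X
        ssm = ss + X**2
        var_m = np.maximum(ssm / nm - (lsm / nm) ** 2, 0.0)
        xi_m = -nm * 0.5 * np.sum(np.log(g + var_m), axis=1)
        cost[:, c] = xi_c + xi_x - xi_m
    return np.argmin(cost, axis=1)


def fit(
    features: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    params: CFTreeParams | None = None,
    k_max: int = 15,
    bic_ratio_threshold: float = 0.04,
    distance_ratio_threshold: float = 1.15,
    min_distance_jump: float = 2.0,
) -> ClusterModel:
    """Run the full two-step clustering pipeline on a features table.

    Rows with missing or non-finite values in the clustering variables are
    rejected and reported in ``rejected_rows``.  Constant variables are
    dropped with a warning (they carry no distance signal).  Variables are
    used unstandardized for the log-likelihood distance; the silhouette is
    computed on standardized variables.
    """
    params = params or CFTreeParams()
    missing = [v for v in variables if v not in features.columns]
    if missing:
        raise ValueError(f"features table is missing variables: {missing}")
    raw = features[list(variables)].apply(pd.to_numeric, errors="coerce")
    ok = np.isfinite(raw.to_numpy(dtype=float)).all(axis=1)
    rejected = np.flatnonzero(~ok)
    if rejected.size:
        warnings.warn(
            f"rejected {rejected.size} row(s) with missing or non-numeric values",
            stacklevel=2,
        )
    X_full = raw.to_numpy(dtype=float)[ok]
    n = X_full.shape[0]
    if n < 1:
        raise ValueError("no valid rows to cluster")
    if n < 100:
        warnings.warn(
            f"only {n} rows; two-step clustering is designed for large samples "
            "and defaults may need adjustment below ~1000 syllables",
            stacklevel=2,
        )
    use = [v for v in variables]
    g_all = X_full.var(axis=0)
    const = [v for v, gv in zip(use, g_all) if gv == 0.0]
    if const:
        warnings.warn(f"dropping constant clustering variables: {const}", stacklevel=2)
        keep = [i for i, v in enumerate(use) if v not in const]
        use = [use[i] for i in keep]
        X = X_full[:, keep]
    else:
        X = X_full
    if X.shape[1] == 0:
        # All variables constant: a single degenerate cluster.
        return ClusterModel(
            k=1,
            variables=list(variables),
            sizes=np.array([n]),
            means=X_full.mean(axis=0, keepdims=True),
            variances=X_full.var(axis=0, keepdims=True),
            assignments=np.zeros(n, dtype=int),
            bic_curve={1: 0.0},
            merge_distance_to={},
            silhouette=None,
            rejected_rows=rejected,
        )
    g = X.var(axis=0)

    entries = precluster(X, params, global_variances=g)
    k_max_eff = min(k_max, len(entries))
    tree = agglomerate(entries, g, k_max=k_max_eff)
    bic = _bic_curve(entries, tree, g, n_total=n)
    k = choose_k(
        bic,
        tree.merge_distance_to,
        bic_ratio_threshold=bic_ratio_threshold,
        distance_ratio_threshold=distance_ratio_threshold,
        min_distance_jump=min_distance_jump,
    )

    labels_e = tree.labels_by_k[k]
    sizes = np.zeros(k)
    LS = np.zeros((k, X.shape[1]))
    SS = np.zeros((k, X.shape[1]))
    for e, lab in zip(entries, labels_e):
        sizes[lab] += e.n
        LS[lab] += e.linear_sum
        SS[lab] += e.square_sum
    means = LS / sizes[:, None]
    variances = np.maximum(SS / sizes[:, None] - means**2, 0.0)

    if k > 1:
        assignments = _assign_rows(X, sizes, means, variances, g)
        # Recompute cluster summaries from the final assignments.
        sizes = np.array([(assignments == c).sum() for c in range(k)], dtype=float)
        if (sizes == 0).any():
            nonempty = np.flatnonzero(sizes > 0)
            remap = {int(c): i for i, c in enumerate(nonempty)}
            assignments = np.array([remap[int(c)] for c in assignments])
            k = nonempty.size
            sizes = np.array([(assignments == c).sum() for c in range(k)], dtype=float)
        means = np.array([X[assignments == c].mean(axis=0) for c in range(k)])
        variances = np.array([X[assignments == c].var(axis=0) for c in range(k)])
        sil = silhouette_cohesion(X, assignments) if k > 1 else None
    else:
        assignments = np.zeros(n, dtype=int)
        sil = None

    return ClusterModel(
        k=int(k),
        variables=use,
        sizes=sizes.astype(int),
        means=means,
        variances=variances,
        assignments=assignments,
        bic_curve=bic,
        merge_distance_to=tree.merge_distance_to,
        silhouette=sil,
        rejected_rows=rejected,
        labels_by_k=tree.labels_by_k,
    )
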