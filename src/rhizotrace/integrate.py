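"""Cross-dataset screening and causal-path summarization.

Links the hotspot (Cd migration) response to metabolite, microbial and
soil blocks: Spearman screens at the study's thresholds, Mantel tests on
distance matrices, Boruta-style all-relevant feature confirmation against
shadow features, a piecewise path model (one standardized regression per
endogenous node of a DAG), and variance partitioning by inclusion-
exclusion over subset fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance

from .errors import DegenerateInputError, InsufficientDataError, InvalidConfigError

__all__ = [
    "ScreenResult",
    "BorutaResult",
    "PathModel",
    "VpaResult",
    "spearman_screen",
    "mantel",
    "boruta_screen",
    "fit_path_model",
    "variance_partition",
]


# ---------------------------------------------------------------------------
# Spearman screen


@dataclass
class ScreenResult:
    edges: pd.DataFrame          # x_var, y_var, r, p, passed
    r_min: float
    p_max: float

    @property
    def passed(self) -> pd.DataFrame:
        return self.edges[self.edges["passed"]]


def spearman_screen(x_table: pd.DataFrame, y_table: pd.DataFrame,
                    r_min: float = 0.6, p_max: float = 0.05,
                    use_absolute: bool = True) -> ScreenResult:
    """All-pairs Spearman screen between two sample-aligned tables.

    An edge passes when |r| > r_min (signed r if ``use_absolute`` is off)
    and p < p_max.  Constant variables yield undefined r and are flagged
    failed.  Ties are handled by average ranks (scipy).
    """
    x_table, y_table = x_table.align(y_table, join="inner", axis=0)
    if len(x_table) < 5:
        raise InsufficientDataError("need >= 5 shared samples for the screen")
    rows = []
    for xv in x_table.columns:
        for yv in y_table.columns:
            x = x_table[xv].to_numpy(dtype=float)
            y = y_table[yv].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((xv, yv, np.nan, np.nan, False))
                continue
            r, p = stats.spearmanr(x, y)
            eff = abs(r) if use_absolute else r
            rows.append((xv, yv, float(r), float(p),
                         bool(eff > r_min and p < p_max)))
    edges = pd.DataFrame(rows, columns=["x_var", "y_var", "r", "p", "passed"])
    return ScreenResult(edges, r_min, p_max)


# ---------------------------------------------------------------------------
# Mantel


def _as_square(d) -> tuple[np.ndarray, list]:
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        arr = d.to_numpy(dtype=float)
    else:
        arr = np.asarray(d, dtype=float)
        labels = list(range(arr.shape[0]))
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise DegenerateInputError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise DegenerateInputError("distance matrix must be symmetric")
    return arr, labels


def mantel(dist_a, dist_b, method: str = "spearman", n_perm: int = 999,
           seed: int | None = 0,
           exhaustive: bool = False) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    The statistic is the (Spearman by default) correlation over the
    strictly-lower-triangle entries; the null permutes rows and columns
    of the second matrix jointly; p uses the add-one rule for the
    one-sided (r_perm >= r_obs) tail, so p is never 0.  ``exhaustive``
    enumerates all n! permutations (feasible for n <= 7; the identity is
    included, so again p > 0).
    """
    a, la = _as_square(dist_a)
    b, lb = _as_square(dist_b)
    if a.shape != b.shape:
        raise DegenerateInputError("matrices differ in size")
    if isinstance(dist_a, pd.DataFrame) and isinstance(dist_b, pd.DataFrame):
        if la != lb:
            b = dist_b.loc[la, la].to_numpy(dtype=float)
    n = a.shape[0]
    if n < 4:
        raise InsufficientDataError("Mantel needs >= 4 objects")

    tri = np.tril_indices(n, k=-1)

    def corr(x, y):
        if method == "spearman":
            return stats.spearmanr(x, y).statistic
        if method == "pearson":
            return stats.pearsonr(x, y).statistic
        raise InvalidConfigError(f"unknown method {method!r}")

    r_obs = float(corr(a[tri], b[tri]))
    if exhaustive:
        from itertools import permutations as all_perms
        if n > 7:
            raise InvalidConfigError("exhaustive Mantel limited to n <= 7")
        perms = [np.array(p) for p in all_perms(range(n))]
        n_ge = sum(
            corr(a[tri], b[np.ix_(p, p)][tri]) >= r_obs - 1e-12 for p in perms
        )
        return r_obs, n_ge / len(perms)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if corr(a[tri], bp[tri]) >= r_obs:
            n_ge += 1
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return r_obs, p


# ---------------------------------------------------------------------------
# Boruta


@dataclass
class BorutaResult:
    decisions: pd.DataFrame      # feature, importance_mean, hits, decision
    shadow_max: np.ndarray       # per-round ShadowMax importance
    n_rounds: int

    def confirmed(self) -> list[str]:
        d = self.decisions
        return d.loc[d["decision"] == "confirmed", "feature"].tolist()


def boruta_screen(features: pd.DataFrame, target, n_rounds: int = 100,
                  alpha: float = 0.05, seed: int | None = 0,
                  n_trees: int = 500,
                  importance: str = "permutation") -> BorutaResult:
    """All-relevant feature selection against shadow features.

    Each round appends a column-shuffled copy of every feature, fits a
    random forest (regressor for numeric targets, classifier otherwise —
    the forest is a numeric primitive whose importances are consumed),
    and scores a "hit" for every real feature whose importance exceeds
    the round's maximum shadow importance (ShadowMax).  Decisions come
    from a binomial test of the hit count against chance (p = 0.5) at
    ``alpha``: significantly many hits -> confirmed, significantly few ->
    rejected, otherwise tentative.
    """
    if n_rounds < 1:
        raise InvalidConfigError("n_rounds must be >= 1")
    if features.shape[1] < 2:
        raise InsufficientDataError("need >= 2 candidate features")
    if len(features) < 10:
        raise InsufficientDataError("need >= 10 samples")
    y = np.asarray(target)
    numeric = np.issubdtype(y.dtype, np.number)
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)

    hits = np.zeros(p, dtype=int)
    imp_sum = np.zeros(p)
    shadow_max = np.zeros(n_rounds)
    for rd in range(n_rounds):
        shadow = np.column_stack([rng.permutation(X[:, j]) for j in range(p)])
        Xa = np.hstack([X, shadow])
        forest_cls = RandomForestRegressor if numeric else RandomForestClassifier
        forest = forest_cls(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(Xa, y)
        if importance == "permutation":
            imp = permutation_importance(
                forest, Xa, y, n_repeats=3,
                random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
            ).importances_mean
        elif importance == "impurity":
            imp = forest.feature_importances_
        else:
            raise InvalidConfigError(f"unknown importance type {importance!r}")
        real, sh = imp[:p], imp[p:]
        shadow_max[rd] = sh.max()
        hits += real > shadow_max[rd]
        imp_sum += real

    decisions = []
    for j in range(p):
        p_hi = stats.binomtest(int(hits[j]), n_rounds, 0.5,
                               alternative="greater").pvalue
        p_lo = stats.binomtest(int(hits[j]), n_rounds, 0.5,
                               alternative="less").pvalue
        if p_hi < alpha:
            decision = "confirmed"
        elif p_lo < alpha:
            decision = "rejected"
        else:
            decision = "tentative"
        decisions.append((features.columns[j], imp_sum[j] / n_rounds,
                          int(hits[j]), decision))
    frame = pd.DataFrame(
        decisions, columns=["feature", "importance_mean", "hits", "decision"]
    )
    return BorutaResult(frame, shadow_max, n_rounds)


# ---------------------------------------------------------------------------
# piecewise path model


@dataclass
class PathModel:
    paths: pd.DataFrame          # parent, child, coefficient, p
    r2: dict                     # endogenous node -> equation R^2
    effects: pd.DataFrame        # source, target, direct, indirect, total

    def coefficient(self, parent: str, child: str) -> float:
        sel = self.paths[(self.paths["parent"] == parent)
                         & (self.paths["child"] == child)]
        if sel.empty:
            raise KeyError((parent, child))
        return float(sel["coefficient"].iloc[0])


def _dag_edges(dag_spec) -> list[tuple[str, str]]:
    if isinstance(dag_spec, dict):
        edges = [tuple(e) for e in dag_spec.get("paths", dag_spec)]
    else:
        edges = [tuple(e) for e in dag_spec]
    graph: dict[str, set] = {}
    for a, b in edges:
        graph.setdefault(a, set())
        graph.setdefault(b, set()).add(a)
    try:
        list(TopologicalSorter(graph).static_order())
    except CycleError as exc:
        raise InvalidConfigError(f"path specification is cyclic: {exc}") from exc
    return edges


def fit_path_model(data: pd.DataFrame, dag_spec) -> PathModel:
    """Piecewise path analysis: one standardized OLS per endogenous node.

    Every variable is z-scored; each node with parents is regressed on
    them, giving standardized path coefficients with two-sided p and an
    equation R^2.  Indirect effects are products of coefficients along
    directed chains; total effect = direct + sum of indirect chains.
    """
    edges = _dag_edges(dag_spec)
    variables = sorted({v for e in edges for v in e})
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise InvalidConfigError(f"variables absent from data: {missing}")
    parents = {v: [a for a, b in edges if b == v] for v in variables}
    max_parents = max(len(p) for p in parents.values())
    if len(data) < 3 + max_parents:
        raise InsufficientDataError("too few samples for the path model")

    z = (data[variables] - data[variables].mean()) / data[variables].std(ddof=1)
    rows, r2 = [], {}
    for child, pars in parents.items():
        if not pars:
            continue
        X = z[pars].to_numpy()
        if np.linalg.cond(X.T @ X) > 1e8:
            raise DegenerateInputError(
                f"collinear parents for {child!r}: {pars}"
            )
        model = sm.OLS(z[child].to_numpy(), sm.add_constant(X)).fit()
        r2[child] = float(model.rsquared)
        for k, par in enumerate(pars):
            rows.append((par, child, float(model.params[k + 1]),
                         float(model.pvalues[k + 1])))
    paths = pd.DataFrame(rows, columns=["parent", "child", "coefficient", "p"])

    coef = {(a, b): c for a, b, c, _ in paths.itertuples(index=False)}
    children = {v: [b for a, b in edges if a == v] for v in variables}

    def chains(src, dst, prefix):
        if src == dst and len(prefix) > 1:
            yield prefix
            return
        for nxt in children.get(src, []):
            yield from chains(nxt, dst, prefix + [nxt])

    eff_rows = []
    for src in variables:
        for dst in variables:
            if src == dst:
                continue
            all_chains = list(chains(src, dst, [src]))
            if not all_chains:
                continue
            direct = coef.get((src, dst), 0.0)
            indirect = sum(
                float(np.prod([coef[(c[i], c[i + 1])]
                               for i in range(len(c) - 1)]))
                for c in all_chains if len(c) > 2
            )
            eff_rows.append((src, dst, direct, indirect, direct + indirect))
    effects = pd.DataFrame(
        eff_rows, columns=["source", "target", "direct", "indirect", "total"]
    )
    return PathModel(paths, r2, effects)


# ---------------------------------------------------------------------------
# variance partitioning


@dataclass
class VpaResult:
    """Unique/shared explained-variance fractions of a response.

    Fractions follow the standard three-block inclusion-exclusion over
    subset fits; shared fractions can be negative (suppression) and are
    reported as-is.  In unadjusted mode the fractions plus the residual
    sum to exactly 1.
    """

    fractions: dict
    total_r2: float
    residual: float
    adjusted: bool
    block_names: tuple


def _fit_r2(y: np.ndarray, X: np.ndarray, adjusted: bool) -> float:
    n = len(y)
    model = sm.OLS(y, sm.add_constant(X)).fit()
    if not adjusted:
        return float(model.rsquared)
    p = X.shape[1]
    return float(1.0 - (1.0 - model.rsquared) * (n - 1) / (n - p - 1))


def _block(b) -> np.ndarray | None:
    if b is None:
        return None
    arr = np.asarray(b, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr if arr.shape[1] else None


def variance_partition(y, block_a, block_b, block_c=None,
                       adjusted: bool = False,
                       names: tuple = ("a", "b", "c")) -> VpaResult:
    """Partition explained variance of ``y`` over 2 or 3 predictor blocks.

    Fits the response on every non-empty subset of blocks (7 fits for 3
    blocks) and decomposes R^2 (adjusted R^2 when ``adjusted``) into
    unique and shared fractions by inclusion-exclusion.
    """
    y = np.asarray(y, dtype=float).ravel()
    blocks = [_block(block_a), _block(block_b), _block(block_c)]
    keep = [i for i, b in enumerate(blocks) if b is not None]
    if not keep:
        raise InvalidConfigError("all predictor blocks are empty")
    total_p = sum(blocks[i].shape[1] for i in keep)
    if len(y) <= total_p + 1:
        raise InsufficientDataError("n must exceed total predictors + 1")

    def r2_of(subset):
        X = np.hstack([blocks[i] for i in subset])
        return _fit_r2(y, X, adjusted)

    if len(keep) == 2:
        i, j = keep
        ni, nj = names[i], names[j]
        r2i, r2j, r2ij = r2_of([i]), r2_of([j]), r2_of([i, j])
        fractions = {
            f"unique_{ni}": r2ij - r2j,
            f"unique_{nj}": r2ij - r2i,
            f"shared_{ni}_{nj}": r2i + r2j - r2ij,
        }
        total = r2ij
    else:
        i, j, k = keep
        ni, nj, nk = (names[m] for m in keep)
        r2 = {s: r2_of(list(s)) for s in
              [(i,), (j,), (k,), (i, j), (i, k), (j, k), (i, j, k)]}
        total = r2[(i, j, k)]
        g = (r2[(i,)] + r2[(j,)] + r2[(k,)]
             - r2[(i, j)] - r2[(i, k)] - r2[(j, k)] + total)
        fractions = {
            f"unique_{ni}": total - r2[(j, k)],
            f"unique_{nj}": total - r2[(i, k)],
            f"unique_{nk}": total - r2[(i, j)],
            f"shared_{ni}_{nj}": r2[(i,)] + r2[(j,)] - r2[(i, j)] - g,
            f"shared_{ni}_{nk}": r2[(i,)] + r2[(k,)] - r2[(i, k)] - g,
            f"shared_{nj}_{nk}": r2[(j,)] + r2[(k,)] - r2[(j, k)] - g,
            "shared_all": g,
        }
    return VpaResult(
        fractions=fractions,
        total_r2=total,
        residual=1.0 - total,
        adjusted=adjusted,
        block_names=tuple(names[m] for m in keep),
    )
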