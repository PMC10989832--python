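"""Community-level statistics for samples x taxa count tables.

Alpha diversity, rarefaction, Bray-Curtis dissimilarity, nonmetric
multidimensional scaling, ANOSIM, SIMPER and per-taxon difference tests
(Welch t, simplified LDA effect size) are implemented directly from their
defining formulas; permutation procedures use the add-one rule so p
values are reproducible under a fixed seed and never exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.isotonic import IsotonicRegression

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "alpha_diversity",
    "rarefaction_curve",
    "bray_curtis",
    "relative_abundance",
    "aggregate_taxonomy",
    "nmds",
    "NmdsResult",
    "anosim",
    "simper",
    "welch_t_table",
    "lefse_lite",
]


def _counts(table: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise DegenerateInputError("negative counts in community table")
    return arr


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    arr = _counts(table)
    totals = arr.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise DegenerateInputError("sample with zero total count")
    return pd.DataFrame(arr / totals, index=table.index, columns=table.columns)


def aggregate_taxonomy(table: pd.DataFrame, taxonomy: pd.Series,
                       level: int) -> pd.DataFrame:
    """Sum taxon columns by lineage prefix truncated at ``level`` ranks.

    Lineages are ";"-separated strings (rank prefixes like ``p__`` are
    kept verbatim); taxa without a lineage or with fewer resolved ranks
    fall into "unclassified".
    """
    def key(taxon):
        lineage = taxonomy.get(taxon)
        if not isinstance(lineage, str) or not lineage.strip():
            return "unclassified"
        parts = [p.strip() for p in lineage.split(";")]
        if len(parts) < level or not parts[level - 1]:
            return "unclassified"
        return ";".join(parts[:level])

    grouped = table.T.groupby([key(t) for t in table.columns]).sum().T
    return grouped


# ---------------------------------------------------------------------------
# alpha diversity & rarefaction


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon, Simpson (1 - sum p^2), Chao1 and observed taxa.

    Chao1 = S_obs + F1^2 / (2 F2); with no doubletons the bias-corrected
    form S_obs + F1 (F1 - 1) / 2 is used.  Empty samples are excluded
    with a warning.
    """
    arr = _counts(table)
    rows = {}
    for sid, x in zip(table.index, arr):
        total = x.sum()
        if total == 0:
            warnings.warn(f"sample {sid!r} is empty; excluded from alpha diversity")
            continue
        p = x[x > 0] / total
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        s_obs = int((x > 0).sum())
        chao1 = s_obs + (f1**2 / (2 * f2) if f2 > 0 else f1 * (f1 - 1) / 2)
        rows[sid] = {
            "shannon": float(-(p * np.log(p)).sum()),
            "simpson": float(1.0 - (p**2).sum()),
            "chao1": float(chao1),
            "observed": s_obs,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefaction_curve(table: pd.DataFrame, depths, reps: int = 100,
                      seed: int | None = 0) -> pd.DataFrame:
    """Mean observed taxa after subsampling without replacement.

    Returns samples x depths; depths exceeding a sample's total are
    skipped (NaN) with a warning.
    """
    arr = _counts(table).astype(np.int64)
    rng = np.random.default_rng(seed)
    depths = [int(d) for d in depths]
    out = pd.DataFrame(np.nan, index=table.index, columns=depths, dtype=float)
    for sid, x in zip(table.index, arr):
        total = int(x.sum())
        for d in depths:
            if d > total:
                warnings.warn(
                    f"depth {d} exceeds total {total} for sample {sid!r}; skipped"
                )
                continue
            obs = [
                int((rng.multivariate_hypergeometric(x, d) > 0).sum())
                for _ in range(reps)
            ]
            out.loc[sid, d] = float(np.mean(obs))
    return out


# ---------------------------------------------------------------------------
# Bray-Curtis


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis: d(a,b) = sum|x_a - x_b| / sum(x_a + x_b)."""
    arr = _counts(table)
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(arr[i] - arr[i + 1:]).sum(axis=1)
        denom = (arr[i] + arr[i + 1:]).sum(axis=1)
        if (denom == 0).any():
            j = int(np.flatnonzero(denom == 0)[0]) + i + 1
            raise DegenerateInputError(
                f"Bray-Curtis undefined for all-zero samples "
                f"{table.index[i]!r}, {table.index[j]!r}"
            )
        d[i, i + 1:] = d[i + 1:, i] = diff / denom
    return pd.DataFrame(d, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float               # Kruskal stress-1
    converged: bool
    n_iter: int


def _nmds_single(delta: np.ndarray, k: int, rng, max_iter: int,
                 tol: float) -> tuple[np.ndarray, float, bool, int]:
    n = delta.shape[0]
    tri = np.triu_indices(n, k=1)
    order = np.argsort(delta[tri], kind="stable")
    X = rng.normal(size=(n, k))
    iso = IsotonicRegression(increasing=True)
    last = np.inf
    stress = np.inf
    for it in range(1, max_iter + 1):
        diff = X[:, None, :] - X[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        dv = d[tri]
        # monotone regression of configuration distances on dissimilarity rank
        dhat = np.empty_like(dv)
        dhat[order] = iso.fit_transform(np.arange(dv.size), dv[order])
        denom = float((dv**2).sum())
        stress = np.sqrt(float(((dv - dhat) ** 2).sum()) / denom) if denom else 0.0
        if last - stress < tol:
            return X, stress, True, it
        last = stress
        # Guttman transform toward the disparities
        dh = np.zeros((n, n))
        dh[tri] = dhat
        dh += dh.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dh / np.where(d > 0, d, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
    return X, stress, False, max_iter


def nmds(dist, k: int = 2, n_starts: int = 4, max_iter: int = 300,
         seed: int | None = 0, tol: float = 1e-7) -> NmdsResult:
    """Nonmetric MDS by iterative majorization with monotone regression.

    Minimizes Kruskal stress-1 over ``n_starts`` random configurations
    and returns the best; with a fixed seed the embedding is fully
    reproducible.  Non-convergence returns the best configuration found,
    flagged.
    """
    if isinstance(dist, pd.DataFrame):
        labels, delta = list(dist.index), dist.to_numpy(dtype=float)
    else:
        delta = np.asarray(dist, dtype=float)
        labels = list(range(delta.shape[0]))
    n = delta.shape[0]
    if n < k + 2:
        raise InsufficientDataError(f"NMDS in {k}-D needs >= {k + 2} points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        X, stress, conv, it = _nmds_single(delta, k, rng, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, conv, it)
    X, stress, conv, it = best
    coords = pd.DataFrame(
        X - X.mean(axis=0), index=labels,
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return NmdsResult(coords, float(stress), conv, it)


# ---------------------------------------------------------------------------
# ANOSIM


def _group_arrays(labels, index) -> np.ndarray:
    if isinstance(labels, pd.Series):
        return labels.reindex(index).to_numpy()
    return np.asarray(labels)


def anosim(dist, groups, n_perm: int = 999, seed: int | None = 0,
           exhaustive: bool = False) -> tuple[float, float]:
    """Analysis of similarities on ranked pairwise distances.

    R = (mean between-group rank - mean within-group rank) / (M / 2) with
    M = n(n-1)/2; p from label permutations with the add-one rule.
    ``exhaustive`` enumerates every label permutation instead (n <= 7;
    the identity is among them, so p > 0).
    """
    if isinstance(dist, pd.DataFrame):
        g = _group_arrays(groups, dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        g = np.asarray(groups)
    n = d.shape[0]
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise InsufficientDataError("ANOSIM needs >= 2 groups with >= 2 members")

    tri = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d[tri])
    m = n * (n - 1) / 2

    def r_stat(gv):
        between = gv[tri[0]] != gv[tri[1]]
        return (ranks[between].mean() - ranks[~between].mean()) / (m / 2)

    r_obs = float(r_stat(g))
    if exhaustive:
        from itertools import permutations as all_perms
        if n > 7:
            raise InsufficientDataError("exhaustive ANOSIM limited to n <= 7")
        perms = [np.array(pp) for pp in all_perms(range(n))]
        n_ge = sum(r_stat(g[pp]) >= r_obs - 1e-12 for pp in perms)
        return r_obs, n_ge / len(perms)
    rng = np.random.default_rng(seed)
    n_ge = sum(
        r_stat(rng.permutation(g)) >= r_obs for _ in range(n_perm)
    )
    return r_obs, (1.0 + n_ge) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# SIMPER


def simper(table: pd.DataFrame, groups, pair: tuple | None = None) -> pd.DataFrame:
    """Per-taxon decomposition of mean between-group Bray-Curtis.

    For every between-group sample pair the Bray-Curtis numerator term of
    each taxon, |x_a - x_b| / sum(x_a + x_b), is averaged; contributions
    sum exactly to the mean between-group dissimilarity.  Returns taxa
    sorted by contribution with percent and cumulative percent columns.
    """
    g = _group_arrays(groups, table.index)
    uniq = list(pd.unique(g))
    if pair is None:
        if len(uniq) != 2:
            raise DegenerateInputError(
                "SIMPER needs exactly 2 groups (or an explicit pair)"
            )
        pair = (uniq[0], uniq[1])
    a_idx = np.flatnonzero(g == pair[0])
    b_idx = np.flatnonzero(g == pair[1])
    if a_idx.size < 1 or b_idx.size < 1:
        raise DegenerateInputError(f"empty group in pair {pair}")
    arr = _counts(table)
    contrib = np.zeros(arr.shape[1])
    n_pairs = 0
    for i in a_idx:
        for j in b_idx:
            denom = (arr[i] + arr[j]).sum()
            if denom == 0:
                raise DegenerateInputError("pair of all-zero samples")
            contrib += np.abs(arr[i] - arr[j]) / denom
            n_pairs += 1
    contrib /= n_pairs
    total = contrib.sum()
    out = pd.DataFrame({
        "taxon": table.columns,
        "contribution": contrib,
        f"mean_{pair[0]}": arr[a_idx].mean(axis=0),
        f"mean_{pair[1]}": arr[b_idx].mean(axis=0),
    }).sort_values("contribution", ascending=False, kind="stable")
    out["contribution_percent"] = 100.0 * out["contribution"] / total if total else 0.0
    out["cumulative_percent"] = out["contribution_percent"].cumsum()
    out.attrs["mean_dissimilarity"] = float(total)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-taxon tests


def welch_t_table(table: pd.DataFrame, groups, pair: tuple | None = None,
                  transform: str = "relative", bh: bool = False) -> pd.DataFrame:
    """Welch's t (Satterthwaite df) per taxon between two groups.

    Defaults to per-sample relative abundances (``transform="none"`` for
    raw counts).  Taxa with zero variance in both groups and equal means
    get t = 0, p = 1.  Optional Benjamini-Hochberg column.
    """
    g = _group_arrays(groups, table.index)
    uniq = list(pd.unique(g))
    if pair is None:
        if len(uniq) != 2:
            raise DegenerateInputError("need exactly 2 groups (or explicit pair)")
        pair = (uniq[0], uniq[1])
    data = relative_abundance(table) if transform == "relative" else table
    a = data.loc[np.asarray(g) == pair[0]].to_numpy(dtype=float)
    b = data.loc[np.asarray(g) == pair[1]].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InsufficientDataError("Welch test needs >= 2 samples per group")
    rows = []
    for j, taxon in enumerate(table.columns):
        x, y = a[:, j], b[:, j]
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            if x.mean() == y.mean():
                rows.append((taxon, 0.0, float(len(x) + len(y) - 2), 1.0))
                continue
        res = stats.ttest_ind(x, y, equal_var=False)
        rows.append((taxon, float(res.statistic), float(res.df), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["taxon", "t", "df", "p"])
    if bh:
        out["p_bh"] = stats.false_discovery_control(out["p"].fillna(1.0))
    return out


def lefse_lite(table: pd.DataFrame, groups, lda_threshold: float = 3.5,
               kw_alpha: float = 0.05, n_boot: int = 30,
               seed: int | None = 0) -> pd.DataFrame:
    """Two-stage biomarker discovery (simplified LDA effect size).

    Stage 1 keeps taxa whose Kruskal-Wallis p across groups is below
    ``kw_alpha`` (relative abundances scaled to 1e6, the conventional
    LDA-score scale).  Stage 2 averages, over ``n_boot`` bootstrap
    rounds, an LDA-scaled between-class difference per surviving taxon:
    0.5 x (|raw class-mean difference| + |unit LDA loading x projected
    class-mean difference|) for the most separated class pair; effect =
    log10 of that (floored at 1).  Biomarkers are survivors with effect
    >= ``lda_threshold``, assigned to their group of highest mean
    abundance.  The subclass/one-against-all grid of the full recipe is
    intentionally omitted (no subclass design here).
    """
    g = _group_arrays(groups, table.index)
    uniq = list(pd.unique(g))
    if len(uniq) < 2:
        raise InsufficientDataError("LEfSe needs >= 2 groups")
    X = relative_abundance(table).to_numpy(dtype=float) * 1e6
    taxa = list(table.columns)

    keep = []
    for j in range(X.shape[1]):
        samples = [X[np.asarray(g) == grp, j] for grp in uniq]
        if np.ptp(np.concatenate(samples)) == 0:
            continue
        try:
            p = stats.kruskal(*samples).pvalue
        except ValueError:  # all values identical
            continue
        if p < kw_alpha:
            keep.append(j)
    if not keep:
        return pd.DataFrame(
            columns=["taxon", "effect_size", "group", "kw_p"]
        )

    rng = np.random.default_rng(seed)
    Xk = X[:, keep]
    g_arr = np.asarray(g)
    effects = np.zeros(len(keep))
    for _ in range(n_boot):
        idx = np.concatenate([
            rng.choice(np.flatnonzero(g_arr == grp),
                       size=(g_arr == grp).sum(), replace=True)
            for grp in uniq
        ])
        Xb, gb = Xk[idx], g_arr[idx]
        raw_diff = _max_pair_diff(Xb, gb, uniq)
        try:
            lda = LinearDiscriminantAnalysis(n_components=1)
            proj = lda.fit_transform(Xb, gb).ravel()
            w = lda.scalings_[:, 0]
            w = np.abs(w) / (np.linalg.norm(w) or 1.0)
            proj_diff = max(
                abs(proj[gb == c1].mean() - proj[gb == c2].mean())
                for c1, c2 in _pairs(uniq)
            )
            lda_term = w * proj_diff
        except np.linalg.LinAlgError:
            lda_term = np.zeros(len(keep))
        effects += np.log10(np.maximum(1.0, 0.5 * (raw_diff + lda_term)))
    effects /= n_boot

    rows = []
    for e, j in zip(effects, keep):
        if e >= lda_threshold:
            means = {grp: X[g_arr == grp, j].mean() for grp in uniq}
            rows.append((taxa[j], float(e), max(means, key=means.get)))
    out = pd.DataFrame(rows, columns=["taxon", "effect_size", "group"])
    return out.sort_values("effect_size", ascending=False).reset_index(drop=True)


def _pairs(items):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]


def _max_pair_diff(X, g, uniq) -> np.ndarray:
    means = np.stack([X[g == grp].mean(axis=0) for grp in uniq])
    diff = np.zeros(X.shape[1])
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            diff = np.maximum(diff, np.abs(means[i] - means[j]))
    return diff
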