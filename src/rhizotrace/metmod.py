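"""Weighted metabolite coexpression modules.

The workflow mirrors weighted coexpression network analysis applied to
chromatographic peak areas: low-signal filtering and log2 transform,
soft-threshold power selection by scale-free fit, adjacency raised to
that power and converted to a topological overlap matrix (TOM),
average-linkage clustering of dissTOM = 1 - TOM with a minimum module
size (default 28), first-principal-component eigenmetabolites with
merging of modules whose eigenprofiles correlate at or above 0.8,
Bonferroni-corrected module-trait correlation, and per-module hub
metabolites ranked by module membership (kME).

The pipeline contains no randomness: fixed inputs give identical modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "ModuleSet",
    "EigenProfile",
    "preprocess",
    "pick_soft_threshold",
    "adjacency_tom",
    "tom_from_adjacency",
    "detect_modules",
    "eigenmetabolites",
    "module_trait",
    "hub_metabolites",
    "UNASSIGNED",
]

UNASSIGNED = "grey"

# WGCNA-style module color names, assigned largest module first
_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)


def preprocess(matrix: pd.DataFrame, min_level: float = 5.0) -> pd.DataFrame:
    """Drop metabolites never reaching ``min_level`` and log2-transform.

    A metabolite is kept when its maximum peak area across samples is at
    least ``min_level``; surviving values become log2(x + 1).
    """
    arr = matrix.to_numpy(dtype=float)
    if (arr < 0).any():
        raise DegenerateInputError("peak areas must be non-negative")
    keep = matrix.columns[arr.max(axis=0) >= min_level]
    if len(keep) == 0:
        raise DegenerateInputError("all metabolites fall below min_level")
    out = np.log2(matrix[keep].to_numpy(dtype=float) + 1.0)
    result = pd.DataFrame(out, index=matrix.index, columns=keep)
    result.attrs["transformed"] = True
    return result


def _abs_corr(matrix: pd.DataFrame) -> np.ndarray:
    arr = matrix.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    if (sd == 0).any():
        offender = matrix.columns[sd == 0][0]
        raise DegenerateInputError(
            f"constant metabolite {offender!r} has undefined correlation"
        )
    return np.abs(np.corrcoef(arr, rowvar=False))


def pick_soft_threshold(matrix: pd.DataFrame, candidate_powers=range(1, 21),
                        target_r2: float = 0.8, n_bins: int = 10,
                        min_mean_connectivity: float = 5.0):
    """Smallest power giving an approximately scale-free network.

    For each candidate power the adjacency is |cor|^power; connectivity
    k_i is binned and log10 p(k) is regressed on log10 mean(k) per bin.
    The chosen power is the smallest whose fit R^2 (with negative slope)
    reaches ``target_r2`` while mean connectivity stays above
    ``min_mean_connectivity`` (default 5, the usual rule of thumb) —
    high powers can look scale-free only because they annihilate the
    adjacency.  Small or block-structured
    networks often never look scale-free at any usable power; then the
    conventional sample-size-based default for unsigned networks (9
    below 20 samples, 8 below 30, 7 below 40, else 6) is returned with a
    warning.  Returns (power, diagnostics frame).
    """
    if len(matrix) < 8:
        raise InsufficientDataError("soft-threshold selection needs >= 8 samples")
    corr = _abs_corr(matrix)
    np.fill_diagonal(corr, 0.0)
    rows = []
    for beta in candidate_powers:
        k = (corr**beta).sum(axis=0)
        r2, slope = _scale_free_fit(k, n_bins)
        rows.append((int(beta), r2, slope, float(k.mean())))
    diag = pd.DataFrame(
        rows, columns=["power", "scale_free_r2", "slope", "mean_connectivity"]
    )
    ok = diag[(diag["scale_free_r2"] >= target_r2) & (diag["slope"] < 0)
              & (diag["mean_connectivity"] >= min_mean_connectivity)]
    if not ok.empty:
        return int(ok["power"].iloc[0]), diag
    n = len(matrix)
    fallback = 9 if n < 20 else 8 if n < 30 else 7 if n < 40 else 6
    fallback = int(np.clip(fallback, min(candidate_powers), max(candidate_powers)))
    warnings.warn(
        f"no power reached scale-free R^2 >= {target_r2}; "
        f"falling back to the sample-size default {fallback}"
    )
    return fallback, diag


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = k[k > 0]
    if k.size < n_bins:
        raise DegenerateInputError("too few connected nodes for scale-free fit")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    centers, freqs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (k >= lo) & (k < hi)
        if sel.sum() > 0:
            centers.append(k[sel].mean())
            freqs.append(sel.mean())
    if len(centers) < 4:
        raise DegenerateInputError("fewer than 4 occupied connectivity bins")
    x = np.log10(np.asarray(centers))
    y = np.log10(np.asarray(freqs))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - fitted) ** 2).sum()) / ss_tot if ss_tot else 0.0
    return r2, float(slope)


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap of a symmetric adjacency in [0, 1].

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu;
    TOM_ii = 1.
    """
    a_off = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a_off, 0.0)
    k = a_off.sum(axis=0)
    # zero diagonal makes a_off @ a_off skip u = i and u = j automatically
    l = a_off @ a_off
    num = l + a_off
    den = np.minimum.outer(k, k) + 1.0 - a_off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return (tom + tom.T) / 2.0


def adjacency_tom(matrix: pd.DataFrame, beta: int):
    """Adjacency |cor|^beta and its topological overlap matrix.

    dissTOM = 1 - TOM (see :func:`tom_from_adjacency` for the overlap
    formula).  Returns (adjacency, tom, diss_tom) frames.
    """
    if beta < 1:
        raise DegenerateInputError("beta must be >= 1")
    a = _abs_corr(matrix) ** beta
    np.fill_diagonal(a, 1.0)
    ids = matrix.columns
    tom = tom_from_adjacency(a)
    wrap = lambda m: pd.DataFrame(m, index=ids, columns=ids)
    return wrap(a), wrap(tom), wrap(1.0 - tom)


@dataclass
class ModuleSet:
    labels: pd.Series          # metabolite -> module name (UNASSIGNED bucket)
    min_module_size: int

    @property
    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for met, mod in self.labels.items():
            if mod != UNASSIGNED:
                out.setdefault(mod, []).append(met)
        return out


def detect_modules(diss_tom: pd.DataFrame, min_module_size: int = 28,
                   cut_height: float | None = None) -> ModuleSet:
    """Average-linkage clustering of dissTOM with a static tree cut.

    The tree is cut at ``cut_height`` (default 0.95 of the maximum merge
    height — cutting at the root's doorstep lets unrelated background
    leaves ride into modules); clusters smaller than ``min_module_size``
    go to the unassigned bucket.  Modules are named by size (largest
    first) with the conventional color labels; the procedure is
    deterministic.
    """
    arr = diss_tom.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise DegenerateInputError("dissTOM must be square")
    if np.abs(arr - arr.T).max() > 1e-9:
        raise DegenerateInputError("dissTOM asymmetric beyond 1e-9")
    condensed = squareform(arr, checks=False)
    link = average(condensed)
    max_h = link[:, 2].max()
    h = 0.95 * max_h if cut_height is None else cut_height
    raw = fcluster(link, t=h, criterion="distance")

    ids = list(diss_tom.index)
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size].index.tolist()
    big.sort(key=lambda c: (-sizes[c], c))
    name = {c: (_COLORS[i] if i < len(_COLORS) else f"module{i + 1}")
            for i, c in enumerate(big)}
    labels = pd.Series(
        [name.get(c, UNASSIGNED) for c in raw], index=ids, name="module"
    )
    return ModuleSet(labels, min_module_size)


@dataclass
class EigenProfile:
    scores: pd.DataFrame            # samples x modules, unit-norm columns
    variance_explained: pd.Series   # per module
    fallback_mean: list[str]        # modules where PC1 fell back to the mean


def _module_pc1(block: np.ndarray):
    """Unit-norm PC1 of standardized member profiles, oriented positively
    with the module mean profile; returns (scores, variance explained)."""
    std = block.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    z = (block - block.mean(axis=0)) / std
    try:
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        score = u[:, 0]
        var_exp = float(s[0] ** 2 / (s**2).sum())
    except np.linalg.LinAlgError:
        score = z.mean(axis=1)
        norm = np.linalg.norm(score)
        score = score / norm if norm else score
        return score, np.nan
    mean_profile = z.mean(axis=1)
    if np.dot(score, mean_profile) < 0:
        score = -score
    return score, var_exp


def eigenmetabolites(matrix: pd.DataFrame, modules: ModuleSet,
                     merge_threshold: float = 0.8):
    """Per-module eigenmetabolites with iterative correlated-module merging.

    Each module's eigenmetabolite is the unit-norm first principal
    component of its standardized member profiles, sign-oriented along
    the module mean.  Module pairs whose eigenprofiles correlate at or
    above ``merge_threshold`` are merged (most correlated pair first) and
    profiles recomputed until no pair qualifies.  Returns
    (EigenProfile, merged ModuleSet).
    """
    labels = modules.labels.copy()

    def profiles(lbls):
        mods = sorted(set(lbls) - {UNASSIGNED})
        scores, var_exp, fb = {}, {}, []
        for m in mods:
            members = lbls.index[lbls == m]
            sc, ve = _module_pc1(matrix[members].to_numpy(dtype=float))
            scores[m] = sc
            var_exp[m] = ve
            if np.isnan(ve):
                fb.append(m)
        return scores, var_exp, fb

    scores, var_exp, fb = profiles(labels)
    while len(scores) > 1:
        mods = sorted(scores)
        best = None
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                r = float(np.corrcoef(scores[a], scores[b])[0, 1])
                if r >= merge_threshold and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        labels[labels == b] = a   # absorb b into a; name of the larger kept
        scores, var_exp, fb = profiles(labels)

    frame = pd.DataFrame(scores, index=matrix.index)
    profile = EigenProfile(frame, pd.Series(var_exp), fb)
    return profile, ModuleSet(labels, modules.min_module_size)


def module_trait(eigenprofiles: EigenProfile | pd.DataFrame,
                 traits: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Pearson correlation of each eigenmetabolite with each trait.

    Returns long format (module, trait, r, p, p_bonferroni) with the
    Bonferroni factor equal to the number of module x trait cells.
    """
    scores = (eigenprofiles.scores
              if isinstance(eigenprofiles, EigenProfile) else eigenprofiles)
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    if not scores.index.equals(traits.index):
        if set(scores.index) != set(traits.index):
            raise DegenerateInputError(
                "eigenprofiles and traits cover different samples"
            )
        traits = traits.loc[scores.index]
    n_cells = scores.shape[1] * traits.shape[1]
    rows = []
    for mod in scores.columns:
        for tr in traits.columns:
            r, p = stats.pearsonr(scores[mod], traits[tr])
            rows.append((mod, tr, float(r), float(p),
                         float(min(1.0, p * n_cells))))
    return pd.DataFrame(
        rows, columns=["module", "trait", "r", "p", "p_bonferroni"]
    )


def hub_metabolites(matrix: pd.DataFrame, modules: ModuleSet,
                    eigenprofiles: EigenProfile, top_k: int = 5) -> pd.DataFrame:
    """Top-``top_k`` metabolites per module by module membership.

    Membership (kME) is |cor(metabolite profile, module eigenmetabolite)|.
    """
    rows = []
    for mod, members in modules.modules.items():
        if mod not in eigenprofiles.scores.columns:
            continue
        es = eigenprofiles.scores[mod].to_numpy()
        kme = {
            met: abs(float(np.corrcoef(matrix[met].to_numpy(dtype=float), es)[0, 1]))
            for met in members
        }
        ranked = sorted(kme.items(), key=lambda kv: (-kv[1], kv[0]))
        for rank, (met, val) in enumerate(ranked[:top_k], start=1):
            rows.append((mod, met, val, rank))
    return pd.DataFrame(rows, columns=["module", "metabolite", "kme", "rank"])
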