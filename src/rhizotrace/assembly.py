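"""Null-model phylogenetic community assembly.

Implements the standard ecological-process partition: beta mean nearest
taxon distance (betaMNTD) between sample pairs, its tip-shuffled null
standardization betaNTI, the Raup-Crick metric on Bray-Curtis (RCbray),
and the threshold classification into variable selection, homogeneous
selection, dispersal limitation, homogenizing dispersal and drift.

|betaNTI| > 2 marks deterministic (selection-driven) turnover, the sign
separating variable (+) from homogeneous (-) selection; stochastic pairs
are split by RCbray at +/-0.95.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidConfigError, ParseError
from .io import patristic_matrix

__all__ = [
    "AssemblyResult",
    "bmntd",
    "beta_nti",
    "raup_crick_bray",
    "classify_processes",
    "PROCESSES",
]

PROCESSES = (
    "heterogeneous-selection",
    "homogeneous-selection",
    "dispersal-limitation",
    "homogenizing-dispersal",
    "drift",
)


def _tip_distances(table: pd.DataFrame, tree) -> np.ndarray:
    """taxa x taxa patristic matrix aligned to the table's columns."""
    if isinstance(tree, pd.DataFrame):
        missing = [t for t in table.columns if t not in tree.index]
        if missing:
            raise ParseError(f"taxa absent from distance matrix: {missing}")
        return tree.loc[table.columns, table.columns].to_numpy(dtype=float)
    if isinstance(tree, dendropy.Tree):
        return patristic_matrix(tree, list(table.columns)).to_numpy()
    raise InvalidConfigError("tree must be a dendropy.Tree or a distance DataFrame")


def _bmntd_all_pairs(freq: np.ndarray, present: list[np.ndarray],
                     dist: np.ndarray, weighted: bool) -> np.ndarray:
    """betaMNTD for every sample pair given one tip-distance matrix."""
    n = freq.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        ia = present[i]
        for j in range(i + 1, n):
            jb = present[j]
            sub = dist[np.ix_(ia, jb)]
            mins_i = sub.min(axis=1)
            mins_j = sub.min(axis=0)
            if weighted:
                wi = freq[i, ia] / freq[i, ia].sum()
                wj = freq[j, jb] / freq[j, jb].sum()
                val = 0.5 * (wi @ mins_i + wj @ mins_j)
            else:
                val = 0.5 * (mins_i.mean() + mins_j.mean())
            out[i, j] = out[j, i] = val
    return out


def _prepare(table: pd.DataFrame):
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise DegenerateInputError("negative counts")
    totals = arr.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise DegenerateInputError("sample with zero total count")
    freq = arr / totals
    present = [np.flatnonzero(row > 0) for row in arr]
    return arr, freq, present


def bmntd(table: pd.DataFrame, tree,
          abundance_weighted: bool = True) -> pd.DataFrame:
    """Beta mean nearest taxon distance between all sample pairs.

    For each pair, every taxon in one sample contributes its patristic
    distance to the nearest taxon of the other sample (itself, if
    shared); contributions are abundance-weighted by default and the two
    directions are averaged.
    """
    dist = _tip_distances(table, tree)
    _, freq, present = _prepare(table)
    out = _bmntd_all_pairs(freq, present, dist, abundance_weighted)
    return pd.DataFrame(out, index=table.index, columns=table.index)


def beta_nti(table: pd.DataFrame, tree, n_null: int = 999,
             seed: int | None = 0, abundance_weighted: bool = True,
             exhaustive: bool = False) -> pd.DataFrame:
    """Standardized betaMNTD deviation from a tip-shuffle null.

    The null randomizes taxa across the phylogeny by permuting tip labels
    (equivalently, rows/columns of the patristic matrix) while keeping
    abundances intact; betaNTI = (obs - null mean) / null sd per pair.
    With ``exhaustive`` every tip relabeling is enumerated (feasible for
    <= 8 taxa) instead of ``n_null`` sampled shuffles.  Pairs whose null
    sd is 0 report 0 when the observation equals the (constant) null —
    e.g. a perfect star phylogeny — and NaN otherwise; NaN pairs are
    excluded from downstream fractions.
    """
    dist = _tip_distances(table, tree)
    _, freq, present = _prepare(table)
    obs = _bmntd_all_pairs(freq, present, dist, abundance_weighted)

    n_taxa = dist.shape[0]
    if exhaustive:
        from itertools import permutations
        if n_taxa > 8:
            raise InvalidConfigError("exhaustive null is limited to <= 8 taxa")
        perms = [np.array(p) for p in permutations(range(n_taxa))]
    else:
        if n_null < 99:
            raise InvalidConfigError("n_null must be >= 99")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n_taxa) for _ in range(n_null)]
    nulls = np.empty((len(perms), obs.shape[0], obs.shape[0]))
    for b, perm in enumerate(perms):
        nulls[b] = _bmntd_all_pairs(freq, present, dist[np.ix_(perm, perm)],
                                    abundance_weighted)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    # a numerically-zero null spread (all shuffles equivalent) is degenerate:
    # report 0 when the observation sits on the (constant) null, NaN otherwise
    scale = np.maximum(1.0, np.abs(mean))
    tiny = sd <= 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(~tiny, (obs - mean) / np.where(~tiny, sd, 1.0), np.nan)
    degenerate_match = tiny & (np.abs(obs - mean) <= 1e-9 * scale)
    z = np.where(degenerate_match, 0.0, z)
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=table.index, columns=table.index)


def raup_crick_bray(table: pd.DataFrame, n_null: int = 999,
                    seed: int | None = 0) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis, rescaled to [-1, 1].

    Null communities preserve each sample's richness and total
    abundance: taxa are drawn without replacement with probability
    proportional to regional occupancy, then individuals fill to the
    observed total with probability proportional to regional relative
    abundance among the drawn taxa.  RC = 2 x ((#null < obs) + 0.5 x
    (#null = obs)) / n_null - 1, so identical pairs under a diverse null
    approach -1 and unusually dissimilar pairs approach +1.
    """
    if n_null < 99:
        raise InvalidConfigError("n_null must be >= 99")
    arr, _, present = _prepare(table)
    n_samp, n_taxa = arr.shape
    pool = np.flatnonzero(arr.sum(axis=0) > 0)
    if pool.size < 2:
        raise DegenerateInputError("single-taxon metacommunity is degenerate")
    occupancy = (arr[:, pool] > 0).sum(axis=0).astype(float)
    occupancy /= occupancy.sum()
    regional = arr[:, pool].sum(axis=0).astype(float)
    regional /= regional.sum()
    richness = [(arr[s] > 0).sum() for s in range(n_samp)]
    totals = arr.sum(axis=1).astype(int)

    def bc(x, y):
        return np.abs(x - y).sum() / (x + y).sum()

    rng = np.random.default_rng(seed)

    def null_sample(s):
        k = min(richness[s], pool.size)
        chosen = rng.choice(pool.size, size=k, replace=False, p=occupancy)
        counts = np.ones(k, dtype=float)
        fill = int(totals[s]) - k
        if fill > 0:
            w = regional[chosen] / regional[chosen].sum()
            counts += rng.multinomial(fill, w)
        vec = np.zeros(n_taxa)
        vec[pool[chosen]] = counts
        return vec

    out = np.zeros((n_samp, n_samp))
    for i in range(n_samp):
        for j in range(i + 1, n_samp):
            obs = bc(arr[i], arr[j])
            less = equal = 0
            for _ in range(n_null):
                d = bc(null_sample(i), null_sample(j))
                if d < obs - 1e-12:
                    less += 1
                elif abs(d - obs) <= 1e-12:
                    equal += 1
            rc = 2.0 * ((less + 0.5 * equal) / n_null) - 1.0
            out[i, j] = out[j, i] = rc
    return pd.DataFrame(out, index=table.index, columns=table.index)


@dataclass
class AssemblyResult:
    bnti: pd.DataFrame
    rc_bray: pd.DataFrame | None
    pair_process: pd.DataFrame        # sample_a, sample_b, bnti, rc, process
    process_fractions: pd.Series      # over PROCESSES, sums to 1


def classify_processes(bnti: pd.DataFrame, rc_bray: pd.DataFrame | None = None,
                       bnti_threshold: float = 2.0,
                       rc_threshold: float = 0.95) -> AssemblyResult:
    """Stegen-style partition of sample pairs into assembly processes.

    betaNTI > +2 -> heterogeneous (variable) selection; < -2 ->
    homogeneous selection; otherwise RCbray > +0.95 -> dispersal
    limitation, < -0.95 -> homogenizing dispersal, else drift.  Pairs
    with NaN betaNTI (degenerate null) are excluded from the fractions; a
    missing RC value for a stochastic pair is an error.
    """
    samples = list(bnti.index)
    rows = []
    for i, a in enumerate(samples):
        for j in range(i + 1, len(samples)):
            b = samples[j]
            z = float(bnti.loc[a, b])
            if np.isnan(z):
                rows.append((a, b, z, np.nan, "undefined"))
                continue
            if z > bnti_threshold:
                proc, rc = "heterogeneous-selection", np.nan
            elif z < -bnti_threshold:
                proc, rc = "homogeneous-selection", np.nan
            else:
                if rc_bray is None or np.isnan(rc_bray.loc[a, b]):
                    raise DegenerateInputError(
                        f"missing RCbray for stochastic pair ({a}, {b})"
                    )
                rc = float(rc_bray.loc[a, b])
                if rc > rc_threshold:
                    proc = "dispersal-limitation"
                elif rc < -rc_threshold:
                    proc = "homogenizing-dispersal"
                else:
                    proc = "drift"
            rows.append((a, b, z, rc, proc))
    pair_process = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "bnti", "rc", "process"]
    )
    valid = pair_process[pair_process["process"] != "undefined"]
    if valid.empty:
        raise DegenerateInputError("no classifiable pairs")
    fractions = (
        valid["process"].value_counts(normalize=True)
        .reindex(PROCESSES, fill_value=0.0)
    )
    return AssemblyResult(bnti, rc_bray, pair_process, fractions)
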