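"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a root-box
rhizosphere experiment with four treatments x five replicates, a membrane
fluorescence imprint of Cd mobility, a 16S-style community table with
phylogenetically conserved habitat preference, block-correlated metabolite
modules, and a hotspot response wired to metabolite/microbe/soil composites
by known path coefficients.  Every product carries its truth alongside so
downstream estimators can be scored against what was planted.

Randomness: each generator draws from an independent substream of the
config seed (``default_rng([seed, stream_id])``), so the imprint, the
community, the metabolome and the integrated block are individually
reproducible and mutually independent.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.ndimage import distance_transform_edt

from .errors import InvalidConfigError

__all__ = [
    "SimulationConfig",
    "ImprintSimulation",
    "CommunitySimulation",
    "MetabolomeSimulation",
    "IntegratedSimulation",
    "simulate_imprint",
    "simulate_community",
    "simulate_metabolome",
    "simulate_integrated",
]

# substream ids, one per generator
_IMPRINT, _COMMUNITY, _METABOLOME, _INTEGRATED = 1, 2, 3, 4

_DEFAULT_PATHS = {
    ("metabolite", "microbe"): 0.6,
    ("metabolite", "soil"): 0.3,
    ("microbe", "soil"): 0.4,
    ("metabolite", "Cd"): -0.25,
    ("microbe", "Cd"): -0.35,
    ("soil", "Cd"): -0.3,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    n_samples_per_group: int = 5
    n_groups: int = 4
    n_taxa: int = 150
    n_metabolites: int = 120
    image_shape: tuple[int, int] = (128, 128)
    filtering_strength: float = 20.0
    module_spec: tuple[tuple[int, float], ...] = ((30, 0.8), (30, 0.8), (30, 0.8))
    path_coefficients: dict = field(default_factory=lambda: dict(_DEFAULT_PATHS))
    noise_sd: float = 2.0
    colocalization_strength: float = 3.0
    sequencing_depth: int = 10_000

    def __post_init__(self):
        for name in ("n_samples_per_group", "n_groups", "n_taxa",
                     "n_metabolites", "sequencing_depth"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if len(self.image_shape) != 2 or min(self.image_shape) < 1:
            raise InvalidConfigError("image_shape must be two positive ints")
        if self.filtering_strength < 0:
            raise InvalidConfigError("filtering_strength must be >= 0")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        for size, r in self.module_spec:
            if not 0 <= r < 1:
                raise InvalidConfigError("within-module correlation must be in [0, 1)")
            if size < 3:
                raise InvalidConfigError("module sizes must be >= 3")

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_group * self.n_groups


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# imprint


@dataclass
class ImprintSimulation:
    gray: np.ndarray                 # [0, 256] raster
    root_mask: np.ndarray            # binary, same shape
    calibration: list[tuple[float, float]]   # (mg/kg, mean gray) per film
    truth_concentration: np.ndarray  # mg/kg
    gray_per_mg_kg: float            # slope of the planted monotone map
    gray_offset: float


def _grow_root(shape, rng) -> np.ndarray:
    """A connected branching path entering from the top edge."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=np.uint8)

    def walk(r0, c, length, drift):
        for r in range(r0, min(r0 + length, rows)):
            step = int(np.clip(rng.integers(-1, 2) + drift, -1, 1))
            c = int(np.clip(c + step, 0, cols - 1))
            mask[r, c] = 1

    c0 = int(rng.integers(cols // 3, 2 * cols // 3))
    mask[0, c0] = 1
    # main axis plus two laterals branching partway down
    walk(0, c0, rows, 0)
    for frac, drift in ((0.3, 1), (0.55, -1)):
        r_branch = int(rows * frac)
        on_path = np.flatnonzero(mask[r_branch])
        if on_path.size:
            walk(r_branch, int(on_path[0]), rows - r_branch, drift)
    return mask


def simulate_imprint(config: SimulationConfig,
                     noise_sd: float | None = None) -> ImprintSimulation:
    """Plant a Cd concentration field around a synthetic root.

    Truth concentration = background + root-proximal enrichment (amplitude
    ``colocalization_strength``, exponential decay with distance to the
    root) + pixel noise.  The gray raster is a fixed affine map of the
    truth into [20, 230]; calibration films sample the same map at known
    concentrations.  ``noise_sd`` (gray units; default ``config.noise_sd``)
    may be set to 0 for noiseless fields.
    """
    if min(config.image_shape) < 8:
        raise InvalidConfigError("image_shape must be at least 8x8")
    rng = _rng(config, _IMPRINT)
    noise = config.noise_sd if noise_sd is None else noise_sd
    if noise < 0:
        raise InvalidConfigError("noise_sd must be >= 0")

    mask = _grow_root(config.image_shape, rng)
    background = 1.0
    strength = config.colocalization_strength
    dist = distance_transform_edt(1 - mask)
    enrich = strength * np.exp(-dist / 8.0)

    # planted monotone map: gray = offset + slope * conc, spanning [20, 230]
    c_max = background + max(strength, 1.0) * 1.2
    slope = 210.0 / c_max
    offset = 20.0
    conc_noise_sd = noise / slope  # pixel noise expressed in mg/kg
    truth = background + enrich
    if conc_noise_sd > 0:
        truth = truth + rng.normal(0.0, conc_noise_sd, size=truth.shape)
    truth = np.clip(truth, 0.0, None)
    gray = np.clip(offset + slope * truth, 0.0, 256.0)

    concs = np.linspace(0.0, c_max, 6)
    calibration = [(float(c), float(offset + slope * c)) for c in concs]
    return ImprintSimulation(gray, mask, calibration, truth, slope, offset)


# ---------------------------------------------------------------------------
# community


@dataclass
class CommunitySimulation:
    table: pd.DataFrame          # samples x taxa integer counts
    tree: dendropy.Tree
    groups: pd.Series            # sample id -> group label
    regime: str                  # "neutral" or "filtered"
    habitat_optima: pd.Series    # planted trait per taxon
    environments: pd.Series      # group label -> environment value


def _yule_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Pure-birth tree, branch lengths rescaled to height 1."""
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i:04d}"
    height = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return tree


def _brownian_tip_traits(tree: dendropy.Tree, rng) -> dict[str, float]:
    """Evolve a habitat-preference trait by Brownian motion along branches."""
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            bl = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, np.sqrt(bl) if bl > 0 else 0.0
            )
    return {
        leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()
    }


def simulate_community(config: SimulationConfig,
                       regime: str = "filtered",
                       environments=None) -> CommunitySimulation:
    """Sample group-structured communities on a simulated phylogeny.

    "neutral": every sample is a multinomial draw from one shared regional
    pool (lognormal base abundances).  "filtered": taxon weights are the
    base abundances times a Gaussian match between each taxon's habitat
    optimum (Brownian trait on the tree) and the group's environment,
    sharpness = ``filtering_strength``; strength 0 recovers the neutral
    law exactly.  Group environments default to quantiles of the realized
    optima spanning the 10th-90th percentile, so every group has
    well-matched taxa regardless of the trait scale the tree produced and
    extreme groups select genuinely contrasting clades.
    """
    if config.n_taxa < 2:
        raise InvalidConfigError("n_taxa must be >= 2")
    if regime not in ("neutral", "filtered"):
        raise InvalidConfigError(f"unknown regime {regime!r}")
    rng = _rng(config, _COMMUNITY)
    tree = _yule_tree(config.n_taxa, int(rng.integers(2**31 - 1)))
    optima = pd.Series(_brownian_tip_traits(tree, rng)).sort_index()
    taxa = list(optima.index)

    # steep (sigma = 1.5) lognormal rank-abundance: a realistic long tail of
    # rare taxa, so finite-depth samples show compositional turnover
    base = rng.lognormal(mean=0.0, sigma=1.5, size=len(taxa))
    base /= base.sum()

    group_labels = [f"G{g + 1}" for g in range(config.n_groups)]
    if environments is None:
        if config.n_groups == 1:
            probs = np.array([0.5])
        else:
            probs = np.linspace(0.1, 0.9, config.n_groups)
        env_values = np.quantile(optima.to_numpy(), probs)
    else:
        env_values = np.asarray(environments, dtype=float)
        if env_values.size != config.n_groups:
            raise InvalidConfigError("need one environment value per group")
    environments = pd.Series(env_values, index=group_labels)

    rows, sample_ids, groups = [], [], []
    strength = config.filtering_strength if regime == "filtered" else 0.0
    for g, label in enumerate(group_labels):
        w = base * np.exp(-strength * (optima.to_numpy() - env_values[g]) ** 2)
        w /= w.sum()
        for rep in range(config.n_samples_per_group):
            rows.append(rng.multinomial(config.sequencing_depth, w))
            sample_ids.append(f"{label}_r{rep + 1}")
            groups.append(label)

    table = pd.DataFrame(np.array(rows), index=sample_ids, columns=taxa)
    return CommunitySimulation(
        table=table,
        tree=tree,
        groups=pd.Series(groups, index=sample_ids, name="group"),
        regime=regime,
        habitat_optima=optima,
        environments=environments,
    )


# ---------------------------------------------------------------------------
# metabolome


@dataclass
class MetabolomeSimulation:
    matrix: pd.DataFrame        # samples x metabolites, peak areas > 0
    module_labels: pd.Series    # metabolite -> module index (-1 = noise)
    trait: pd.Series            # per-sample trait tied to module 0
    latent_factors: pd.DataFrame  # samples x modules


def simulate_metabolome(config: SimulationConfig) -> MetabolomeSimulation:
    """Block-correlated metabolite peak areas.

    Module ``m`` metabolites load on a shared latent factor so that any
    two members correlate at the requested within-module level (on the
    log2 scale); leftover metabolites are independent noise.  Module 0's
    latent factor is returned (plus small noise) as the tied trait.  Peak
    areas are ``2**(2*z + 10)``, i.e. log-normal and strictly positive,
    so the standard log2 transform recovers the planted linear structure.
    """
    sizes = [s for s, _ in config.module_spec]
    if sum(sizes) > config.n_metabolites:
        raise InvalidConfigError(
            f"module sizes sum to {sum(sizes)} > n_metabolites={config.n_metabolites}"
        )
    rng = _rng(config, _METABOLOME)
    n = config.n_samples
    n_modules = len(config.module_spec)
    factors = rng.normal(size=(n, n_modules))

    cols, labels = [], []
    for m, (size, r) in enumerate(config.module_spec):
        load = np.sqrt(r)
        resid = np.sqrt(1.0 - r)
        for _ in range(size):
            cols.append(load * factors[:, m] + resid * rng.normal(size=n))
            labels.append(m)
    for _ in range(config.n_metabolites - sum(sizes)):
        cols.append(rng.normal(size=n))
        labels.append(-1)

    z = np.column_stack(cols)
    areas = np.power(2.0, 2.0 * z + 10.0)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    met_ids = [f"m{j + 1:04d}" for j in range(config.n_metabolites)]
    matrix = pd.DataFrame(areas, index=sample_ids, columns=met_ids)
    trait = pd.Series(
        factors[:, 0] + 0.3 * rng.normal(size=n), index=sample_ids,
        name="trait",
    )
    return MetabolomeSimulation(
        matrix=matrix,
        module_labels=pd.Series(labels, index=met_ids, name="module"),
        trait=trait,
        latent_factors=pd.DataFrame(
            factors, index=sample_ids,
            columns=[f"module_{m}" for m in range(n_modules)],
        ),
    )


# ---------------------------------------------------------------------------
# integrated multi-omic block


@dataclass
class IntegratedSimulation:
    data: pd.DataFrame            # samples x {metabolite, microbe, soil, Cd}
    truth_coefficients: dict      # directed edge -> planted coefficient
    covariance: pd.DataFrame      # implied population covariance
    truth_vpa: dict               # analytic variance fractions for Cd

    @property
    def response(self) -> pd.Series:
        return self.data["Cd"]


_NODES = ("metabolite", "microbe", "soil", "Cd")


def _implied_covariance(coeffs: dict) -> tuple[pd.DataFrame, list[str]]:
    """Population covariance of the standardized linear DAG (unit variances)."""
    nodes = [n for n in _NODES]
    for a, b in coeffs:
        for v in (a, b):
            if v not in nodes:
                raise InvalidConfigError(f"unknown path node {v!r}")
    graph = {n: set() for n in nodes}
    for (a, b) in coeffs:
        graph[b].add(a)
    try:
        order = list(TopologicalSorter(graph).static_order())
    except CycleError as exc:
        raise InvalidConfigError(f"path_coefficients graph is cyclic: {exc}") from exc

    sigma = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for v in order:
        parents = sorted(graph[v])
        b = np.array([coeffs[(p, v)] for p in parents])
        if parents:
            spp = sigma.loc[parents, parents].to_numpy()
            explained = float(b @ spp @ b)
        else:
            explained = 0.0
        noise_var = 1.0 - explained
        if noise_var <= 0:
            raise InvalidConfigError(
                f"path coefficients into {v!r} imply variance >= 1"
            )
        for u in order:
            if u == v:
                continue
            cov = sum(
                coeffs[(p, v)] * sigma.loc[p, u] for p in parents
            )
            sigma.loc[v, u] = sigma.loc[u, v] = cov
        sigma.loc[v, v] = 1.0
    return sigma, order


def _subset_r2(sigma: pd.DataFrame, y: str, predictors: list[str]) -> float:
    if not predictors:
        return 0.0
    s_xy = sigma.loc[predictors, y].to_numpy()
    s_xx = sigma.loc[predictors, predictors].to_numpy()
    return float(s_xy @ np.linalg.solve(s_xx, s_xy))


def analytic_vpa(sigma: pd.DataFrame, y: str = "Cd",
                 blocks: tuple[str, ...] = ("metabolite", "microbe", "soil")) -> dict:
    """Closed-form unique/shared explained-variance fractions of ``y``."""
    a, b, c = blocks
    r2 = {
        frozenset(s): _subset_r2(sigma, y, sorted(s))
        for s in ([a], [b], [c], [a, b], [a, c], [b, c], [a, b, c])
    }
    total = r2[frozenset([a, b, c])]
    out = {
        f"unique_{a}": total - r2[frozenset([b, c])],
        f"unique_{b}": total - r2[frozenset([a, c])],
        f"unique_{c}": total - r2[frozenset([a, b])],
    }
    g = (r2[frozenset([a])] + r2[frozenset([b])] + r2[frozenset([c])]
         - r2[frozenset([a, b])] - r2[frozenset([a, c])] - r2[frozenset([b, c])]
         + total)
    out[f"shared_{a}_{b}"] = (r2[frozenset([a])] + r2[frozenset([b])]
                              - r2[frozenset([a, b])] - g)
    out[f"shared_{a}_{c}"] = (r2[frozenset([a])] + r2[frozenset([c])]
                              - r2[frozenset([a, c])] - g)
    out[f"shared_{b}_{c}"] = (r2[frozenset([b])] + r2[frozenset([c])]
                              - r2[frozenset([b, c])] - g)
    out["shared_all"] = g
    out["residual"] = 1.0 - total
    out["total_r2"] = total
    return out


def simulate_integrated(config: SimulationConfig,
                        n_samples: int | None = None) -> IntegratedSimulation:
    """Standardized composite scores wired by the configured DAG.

    Variables are generated in topological order as linear combinations of
    their parents plus Gaussian noise scaled so every node has unit
    population variance.  The analytic covariance and the implied VPA
    fractions for the Cd (hotspot) response are returned as truth.
    """
    coeffs = {tuple(k): float(v) for k, v in config.path_coefficients.items()}
    sigma, order = _implied_covariance(coeffs)
    graph = {n: sorted({a for (a, b) in coeffs if b == n}) for n in _NODES}

    rng = _rng(config, _INTEGRATED)
    n = config.n_samples if n_samples is None else int(n_samples)
    data = {}
    for v in order:
        parents = graph[v]
        b = np.array([coeffs[(p, v)] for p in parents])
        if parents:
            spp = sigma.loc[parents, parents].to_numpy()
            noise_sd = np.sqrt(1.0 - float(b @ spp @ b))
            mean = sum(coeffs[(p, v)] * data[p] for p in parents)
        else:
            noise_sd, mean = 1.0, 0.0
        data[v] = mean + rng.normal(0.0, noise_sd, size=n)

    frame = pd.DataFrame(
        {v: data[v] for v in _NODES},
        index=[f"S{i + 1:03d}" for i in range(n)],
    )
    return IntegratedSimulation(
        data=frame,
        truth_coefficients=coeffs,
        covariance=sigma,
        truth_vpa=analytic_vpa(sigma),
    )
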