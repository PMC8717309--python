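"""Synthetic data with the statistical structure the analysis assumes.

Every stage of the pipeline is testable without the original field data:

* pure-birth (Yule) trees with exponential waiting times,
* Brownian-motion trait evolution along those trees (tip covariance equals
  the trait rate times the shared root-path matrix),
* germination generated from the inverse of the fitted model —
  log(SGS + 1) = X b + a + e with a phylogenetically correlated a — then
  discretized to integer feces seedling counts,
* jittered-grid landscape mosaics with configurable mean patch area
  (the two study landscapes contrast ~27.5 ha vs ~2.9 ha mean field size),
* hourly correlated-random-walk hare tracks (gamma step lengths,
  wrapped-Cauchy turning angles, optional grassland attraction).

All generators are deterministic for a fixed seed; a single integer seed per
call drives every random draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import ValidationError
from .mobility import LANDUSE_TYPES, Patch
from .phylo import PhyloCovariance, phylo_vcv, vcv_to_correlation

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_trait_table",
    "simulate_germination",
    "simulate_landscape",
    "simulate_track",
    "DEFAULT_TYPE_PROPORTIONS",
]

#: Land-use composition of the simulated mosaics: arable-dominated
#: agricultural landscapes (~2/3 arable) with grassland, forest and minor types.
DEFAULT_TYPE_PROPORTIONS: dict[str, float] = {
    "field": 0.64,
    "grassland": 0.18,
    "forest": 0.12,
    "wetland": 0.03,
    "urban": 0.02,
    "quarry": 0.01,
}


@dataclass
class SimulationConfig:
    """Study-condition defaults for the end-to-end synthetic pipeline.

    Trait effects and variances are on the model scale (log(SGS+1) response):
    ``beta`` holds (intercept, log density, log EI, log area) effects, and
    ``sigma2_p``/``sigma2_e`` the phylogenetic and residual variances
    (defaults give phylogenetic heritability 0.4). The default intercept
    offsets the trait scales (log density of ~0.001 mg/mm^3 contributes about
    -4 through its effect) so the linear predictor sits well above the zero
    floor of SGS: the back-transformed generator then stays within the model
    family it inverts, which is what parameter-recovery tests require. Lower
    intercepts yield the censored low-success regime real data occupy.
    Landscape areas are in hectares; movement steps are hourly with a gamma
    step-length distribution whose mean (~150 m/h) sits between the ~110 and
    ~185 m/h implied by the two study landscapes.
    """

    seed: int = 0
    n_tips: int = 44
    birth_rate: float = 1.0
    beta: tuple[float, ...] = (7.2, 0.6, 0.5, -0.4)
    sigma2_p: float = 0.2
    sigma2_e: float = 0.3
    seeds_fed: int = 800
    control_germ_pct: float = 70.0
    extent_m: tuple[float, float] = (3000.0, 3000.0)
    mean_patch_area_ha: float = 27.5
    type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    step_shape: float = 1.5
    step_scale_m: float = 100.0
    turn_concentration: float = 0.5
    habitat_bias: float = 0.0
    n_steps: int = 240
    n_individuals: int = 5

    def __post_init__(self) -> None:
        if self.sigma2_p < 0 or self.sigma2_e <= 0 or self.birth_rate <= 0:
            raise ValidationError("rates and variances must be positive")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError("type proportions must sum to 1")


def simulate_yule_tree(
    n_tips: int, birth_rate: float, seed: int
) -> dendropy.Tree:
    """Pure-birth tree: exponential waiting times, uniformly chosen splits.

    Ultrametric by construction (all tips end at the present). Tips are
    labelled sp01, sp02, ... in birth order.
    """
    if n_tips < 2:
        raise ValidationError("need at least two tips")
    if birth_rate <= 0:
        raise ValidationError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.edge.length = 0.0
    # Active lineages with the time their edge started.
    active: list[tuple[dendropy.Node, float]] = []
    now = 0.0
    left, right = dendropy.Node(), dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    active = [(left, now), (right, now)]
    while len(active) < n_tips:
        k = len(active)
        now += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = now - born
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active.extend([(a, now), (b, now)])
    now += rng.exponential(1.0 / (birth_rate * n_tips))
    width = int(math.ceil(math.log10(n_tips + 1)))
    for j, (node, born) in enumerate(active):
        node.edge.length = now - born
        node.taxon = taxa.new_taxon(label=f"sp{j + 1:0{width}d}")
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree, root_value: float, rate: float, seed: int
) -> dict[str, float]:
    """Brownian motion along branches: tip covariance = rate * shared path length."""
    if rate < 0:
        raise ValidationError("BM rate must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[dendropy.Node, float] = {tree.seed_node: root_value}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[node.parent_node]
        length = node.edge.length or 0.0
        values[node] = parent + math.sqrt(rate * length) * rng.standard_normal()
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out


def simulate_trait_table(
    tree: dendropy.Tree,
    seed: int,
    bm_rate: float = 0.3,
    trait_means: dict[str, float] | None = None,
    phylo_signal: bool = True,
) -> pd.DataFrame:
    """Positive seed traits per tip: independent BM on the log scale, exponentiated.

    Default log-scale root values roughly match the magnitudes of the feeding
    experiment's density (mg/mm^3), EI and area (mm^2) columns.

    With ``phylo_signal=False`` the log traits are instead drawn iid normal
    with the same marginal variance (``bm_rate`` times the mean tip depth).
    Tree-structured covariates overlap the deep-split directions of the
    phylogenetic covariance that identify the random-effect variance, so
    recovery studies of heritability use signal-free traits to keep all
    phylogenetic structure in the random effect.
    """
    means = trait_means or {"density": math.log(0.001), "ei": math.log(2.0),
                            "area": math.log(10.0)}
    rng = np.random.default_rng(seed)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    cols: dict[str, dict[str, float]] = {}
    if phylo_signal:
        for name, mu in means.items():
            sub = int(rng.integers(2**31))
            cols[name] = simulate_bm_traits(tree, mu, bm_rate, sub)
    else:
        depths = {
            leaf.taxon.label: sum(
                node.edge.length or 0.0 for node in leaf.ancestor_iter(inclusive=False)
            ) + (leaf.edge.length or 0.0)
            for leaf in tree.leaf_node_iter()
        }
        sd = math.sqrt(bm_rate * float(np.mean(list(depths.values()))))
        for name, mu in means.items():
            draws = mu + sd * rng.standard_normal(len(labels))
            cols[name] = dict(zip(labels, draws))
    df = pd.DataFrame({"species": labels})
    for name, tips in cols.items():
        df[name] = [math.exp(tips[lab]) for lab in labels]
    return df


def simulate_germination(
    tree: dendropy.Tree,
    trait_table: pd.DataFrame,
    beta: tuple[float, ...],
    sigma2_p: float,
    sigma2_e: float,
    seeds_fed: int,
    capacity_pct: float,
    seed: int,
    count_model: str = "round",
) -> pd.DataFrame:
    """Germination outcomes from the inverse of the mixed model.

    eta = X b + a + e with a ~ N(0, sigma2_p * R) (R the tree's correlation
    matrix) and e ~ N(0, sigma2_e * I); SGS_true = max(exp(eta) - 1, 0).
    Seedling counts are either the nearest consistent integer
    (``count_model="round"``) or binomial draws (``count_model="binomial"``,
    a deliberate misspecification stress test). The returned table carries
    species, traits, counts and the realized (re-discretized) SGS, ready for
    the trait and mixed-model stages.
    """
    if seeds_fed <= 0:
        raise ValidationError("seeds_fed must be positive")
    if not 0.0 < capacity_pct <= 100.0:
        raise ValidationError("capacity_pct must lie in (0, 100]")
    if count_model not in ("round", "binomial"):
        raise ValidationError("count_model must be 'round' or 'binomial'")
    predictors = [c for c in trait_table.columns if c != "species"]
    if len(beta) != len(predictors) + 1:
        raise ValidationError(
            f"beta needs {len(predictors) + 1} entries (intercept + {predictors})"
        )
    rng = np.random.default_rng(seed)
    R = vcv_to_correlation(phylo_vcv(tree))
    order = [R.labels.index(sp) for sp in trait_table["species"]]
    Rm = R.matrix[np.ix_(order, order)]
    n = len(trait_table)
    X = np.column_stack(
        [np.ones(n)] + [np.log(trait_table[p].to_numpy(dtype=float)) for p in predictors]
    )
    L = np.linalg.cholesky(Rm + 1e-10 * np.eye(n))
    a = math.sqrt(sigma2_p) * (L @ rng.standard_normal(n))
    e = math.sqrt(sigma2_e) * rng.standard_normal(n)
    eta = X @ np.asarray(beta, dtype=float) + a + e
    sgs_true = np.clip(np.expm1(eta), 0.0, None)

    germinable = capacity_pct / 100.0 * seeds_fed
    expected = sgs_true / 100.0 * germinable
    if count_model == "round":
        counts = np.rint(expected).astype(int)
    else:
        p_germ = np.clip(expected / seeds_fed, 0.0, 1.0)
        counts = rng.binomial(seeds_fed, p_germ)
    counts = np.minimum(counts, seeds_fed)
    sgs = 100.0 * counts / germinable

    out = trait_table.copy()
    out["seeds_fed"] = seeds_fed
    out["control_germ_pct"] = capacity_pct
    out["feces_germ"] = counts
    out["sgs_true"] = sgs_true
    out["sgs"] = sgs
    return out


def simulate_landscape(
    extent_m: tuple[float, float],
    mean_patch_area_ha: float,
    type_proportions: dict[str, float],
    seed: int,
    jitter: float = 0.35,
) -> list[Patch]:
    """Jittered rectangular-grid mosaic tiling the extent exactly.

    Cell count is chosen so the mean cell area approximates the target
    (mean area = extent area / n cells exactly); interior grid lines are
    jittered by up to ``jitter`` of a cell, keeping polygons valid and
    non-overlapping. Land-use types are drawn per cell from the proportions.
    """
    W, H = extent_m
    target_m2 = mean_patch_area_ha * 1e4
    if W * H < 4 * target_m2:
        raise ValidationError("extent must be much larger than the mean patch area")
    total = sum(type_proportions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError("type proportions must sum to 1")
    unknown = set(type_proportions) - set(LANDUSE_TYPES)
    if unknown:
        raise ValidationError(f"unknown land-use types: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    s = math.sqrt(target_m2)
    nx = max(2, round(W / s))
    ny = max(2, round(H / s))

    def edges(total_len: float, k: int) -> np.ndarray:
        e = np.linspace(0.0, total_len, k + 1)
        cell = total_len / k
        e[1:-1] += rng.uniform(-jitter * cell / 2, jitter * cell / 2, size=k - 1)
        return e

    xs = edges(W, nx)
    ys = edges(H, ny)
    types = list(type_proportions)
    probs = np.array([type_proportions[t] for t in types])
    patches = []
    k = 0
    for iy in range(ny):
        for ix in range(nx):
            k += 1
            landuse = types[int(rng.choice(len(types), p=probs))]
            patches.append(
                Patch(
                    patch_id=f"P{k:04d}",
                    landuse=landuse,
                    polygon=box(xs[ix], ys[iy], xs[ix + 1], ys[iy + 1]),
                )
            )
    return patches


def _wrapped_cauchy(rng: np.random.Generator, rho: float) -> float:
    """Wrapped-Cauchy turning angle with mean 0 and concentration rho in [0, 1)."""
    if rho <= 0:
        return float(rng.uniform(-math.pi, math.pi))
    u = rng.uniform()
    return float(2.0 * math.atan((1.0 - rho) / (1.0 + rho) * math.tan(math.pi * (u - 0.5))))


def simulate_track(
    patches: list[Patch],
    extent_m: tuple[float, float],
    n_steps: int,
    seed: int,
    step_shape: float = 1.5,
    step_scale_m: float = 100.0,
    turn_concentration: float = 0.5,
    habitat_bias: float = 0.0,
    individual_id: str = "hare01",
    start: tuple[float, float] | None = None,
    start_time: str = "2020-04-01T00:00:00",
) -> pd.DataFrame:
    """Hourly correlated random walk inside the landscape extent.

    Step lengths are gamma(shape, scale); headings accumulate wrapped-Cauchy
    turns with concentration ``turn_concentration``. Positions reflect at the
    extent borders. With ``habitat_bias`` > 0, each step picks among a handful
    of candidate headings with weights exp(bias) for candidates landing in
    grassland (a soft foraging preference).
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be positive")
    W, H = extent_m
    rng = np.random.default_rng(seed)
    if start is None:
        pos = np.array([rng.uniform(0.2 * W, 0.8 * W), rng.uniform(0.2 * H, 0.8 * H)])
    else:
        pos = np.array(start, dtype=float)
        if not (0 <= pos[0] <= W and 0 <= pos[1] <= H):
            raise ValidationError("start must lie inside the extent")
    heading = rng.uniform(-math.pi, math.pi)

    from shapely.geometry import Point
    from shapely.strtree import STRtree

    grass = [p.polygon for p in patches if p.landuse == "grassland"]
    grass_tree = STRtree(grass) if (grass and habitat_bias > 0) else None

    def reflect(v: float, lo: float, hi: float) -> float:
        span = hi - lo
        v = (v - lo) % (2 * span)
        return lo + (v if v <= span else 2 * span - v)

    times = pd.date_range(start_time, periods=n_steps + 1, freq="h")
    xs, ys = [pos[0]], [pos[1]]
    for _ in range(n_steps):
        step = rng.gamma(step_shape, step_scale_m)
        if grass_tree is not None:
            cands = [heading + _wrapped_cauchy(rng, turn_concentration) for _ in range(5)]
            weights = []
            for h in cands:
                nx = reflect(pos[0] + step * math.cos(h), 0.0, W)
                ny = reflect(pos[1] + step * math.sin(h), 0.0, H)
                pt = Point(nx, ny)
                in_grass = any(
                    grass[int(g)].covers(pt) for g in grass_tree.query(pt)
                )
                weights.append(math.exp(habitat_bias if in_grass else 0.0))
            w = np.array(weights) / sum(weights)
            heading = cands[int(rng.choice(len(cands), p=w))]
        else:
            heading += _wrapped_cauchy(rng, turn_concentration)
        pos[0] = reflect(pos[0] + step * math.cos(heading), 0.0, W)
        pos[1] = reflect(pos[1] + step * math.sin(heading), 0.0, H)
        xs.append(pos[0])
        ys.append(pos[1])
    return pd.DataFrame(
        {"individual_id": individual_id, "t": times, "x": xs, "y": ys}
    )
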