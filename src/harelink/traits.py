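"""Seed morphology indices and germination statistics.

A feeding experiment measures, for each plant species, how many seeds were fed
to captive hares, how many seedlings later emerged from collected feces, and a
control germination capacity (percent of 100 untreated seeds that germinated).
This module derives the morphological indices used as candidate predictors of
gut-passage survival — eccentricity, flatness, density, dimensional shape
variance, surface area and the area-to-mass ratio — and the *standardized
germination success* (SGS), which expresses feces germination relative to the
number of germinable seeds actually fed:

    SGS [%] = 100 * feces_seedlings / (capacity/100 * seeds_fed)

SGS can exceed 100% when more seedlings emerge from feces than the control
capacity predicts (observed for very low-capacity species).

It also implements the predictor-screening steps used ahead of the mixed model:
pairwise Pearson collinearity filtering and an exploratory PCA, plus group
summaries of SGS by neophyte / red-list status.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

from .errors import (
    ExcludedSpeciesError,
    InvalidDimensionError,
    MissingTraitError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "SeedTraitRecord",
    "SurfaceAreaResult",
    "eccentricity_index",
    "flatness_index",
    "seed_density",
    "shape_variance",
    "surface_area",
    "area_mass_ratio",
    "standardized_germination",
    "build_trait_table",
    "collinearity_filter",
    "CollinearityResult",
    "pca_summary",
    "PcaResult",
    "group_summary",
    "VS_UPPER_BOUND",
    "THOMSEN_P",
]

#: Upper bound of the dimensional shape variance when length is the longest
#: dimension (attained in the limit width = height = 0).
VS_UPPER_BOUND = 2.0 / 9.0

#: Exponent of the Thomsen approximation to the ellipsoid surface area.
THOMSEN_P = 1.6075


@dataclass
class SeedTraitRecord:
    """One plant species in the feeding experiment.

    Raw dimensions (``length``, ``width``, ``height`` in mm) are optional:
    when present, all indices are derived from them; when absent, printed
    index values (``ei``, ``fi``, ``density``, ``area``, ``area_mass``) may be
    supplied directly (as in the packaged experiment table, whose raw
    dimensions live in supplementary sources). Missing heights are flagged,
    never imputed.
    """

    species: str
    seeds_fed: int
    control_germ_pct: float
    feces_germ: int
    length: float | None = None
    width: float | None = None
    height: float | None = None
    mass: float | None = None
    volume: float | None = None
    neophyte: bool = False
    red_list: str = "-"
    germ_temp: str = "15/25"
    # Pre-computed indices for records without raw dimensions.
    ei: float | None = None
    fi: float | None = None
    density: float | None = None
    area: float | None = None
    area_mass: float | None = None

    def __post_init__(self) -> None:
        if self.seeds_fed <= 0:
            raise ValidationError(f"{self.species}: seeds_fed must be positive")
        if not 0.0 <= self.control_germ_pct <= 100.0:
            raise ValidationError(
                f"{self.species}: control_germ_pct must lie in [0, 100]"
            )
        if self.feces_germ < 0 or self.feces_germ > self.seeds_fed:
            raise ValidationError(
                f"{self.species}: feces_germ must lie in [0, seeds_fed]"
            )
        for name in ("length", "width", "height", "mass", "volume"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise InvalidDimensionError(
                    f"{self.species}: {name} must be positive, got {value!r}"
                )

    @property
    def has_dimensions(self) -> bool:
        return self.length is not None and self.width is not None

    @property
    def height_missing(self) -> bool:
        return self.height is None


def eccentricity_index(length: float, width: float) -> float:
    """Seed elongation: length / width. 1 for an equant (round) seed."""
    if length <= 0 or width <= 0:
        raise InvalidDimensionError("eccentricity_index requires positive length and width")
    return length / width


def flatness_index(length: float, width: float, height: float | None) -> float:
    """Seed flatness: (length + width) / (2 * height). 1 for a sphere."""
    if height is None:
        raise MissingTraitError("flatness_index requires seed height")
    if length <= 0 or width <= 0 or height <= 0:
        raise InvalidDimensionError("flatness_index requires positive dimensions")
    return (length + width) / (2.0 * height)


def seed_density(mass: float, volume: float) -> float:
    """Mass per volume (units as given, typically mg/mm^3)."""
    if mass <= 0 or volume <= 0:
        raise InvalidDimensionError("seed_density requires positive mass and volume")
    return mass / volume


def shape_variance(length: float, width: float, height: float | None) -> float:
    """Dimensional shape variance Vs (Bekker-style shape type).

    The three dimensions are scaled by length, x = (1, width/length,
    height/length), and Vs is their population variance, sum((x - mean(x))^2)/3.
    A sphere has Vs = 0; when length is the longest dimension Vs <= 2/9.
    """
    if height is None:
        raise MissingTraitError("shape_variance requires seed height")
    if length <= 0 or width <= 0 or height <= 0:
        raise InvalidDimensionError("shape_variance requires positive dimensions")
    x = np.array([1.0, width / length, height / length])
    return float(np.mean((x - x.mean()) ** 2))


class SurfaceAreaResult(NamedTuple):
    area: float
    branch: str  # "ellipsoid" | "cylinder"
    method: str  # "thomsen" | "quadrature" (cylinder branch is closed-form)


def _ellipsoid_area_thomsen(a: float, b: float, c: float, p: float = THOMSEN_P) -> float:
    return 4.0 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def _ellipsoid_area_quadrature(a: float, b: float, c: float) -> float:
    """Exact ellipsoid surface area by numerical quadrature of the surface integral."""

    def integrand(theta: float, phi: float) -> float:
        st, ct = math.sin(theta), math.cos(theta)
        sp, cp = math.sin(phi), math.cos(phi)
        # |r_theta x r_phi| for r = (a st cp, b st sp, c ct)
        ex = b * c * st * st * cp
        ey = a * c * st * st * sp
        ez = a * b * st * ct
        return math.sqrt(ex * ex + ey * ey + ez * ez)

    area, _ = integrate.dblquad(integrand, 0.0, 2.0 * math.pi, 0.0, math.pi,
                                epsabs=1e-10, epsrel=1e-10)
    return area


_DEAD_BRANCH_WARNED = False


def surface_area(
    length: float,
    width: float,
    height: float | None,
    vs_threshold: float = 1.0,
    ellipsoid: str = "thomsen",
    cylinder_radius: str = "mean",
    warn_dead_branch: bool = True,
) -> SurfaceAreaResult:
    """Seed surface area in mm^2, switching on shape variance.

    Rather spheric seeds (Vs below ``vs_threshold``) are treated as ellipsoids
    with semi-axes (length/2, width/2, height/2); slender elongated seeds
    (Vs above it) as cylinders, area 2*pi*r^2 + 2*pi*r*L with L = length and
    r = (width + height)/4 by default (``cylinder_radius="mean"``) or width/2
    (``cylinder_radius="width"``).

    Note: whenever length is the longest dimension, Vs <= 2/9 < 1, so the
    default (literal) threshold of 1.0 leaves the cylinder branch dead; a
    warning is emitted once per process. Pass e.g. ``vs_threshold=0.1`` to
    make the branch reachable.
    """
    vs = shape_variance(length, width, height)  # validates inputs
    assert height is not None

    global _DEAD_BRANCH_WARNED
    if (
        warn_dead_branch
        and vs_threshold >= 1.0
        and length >= max(width, height)
        and not _DEAD_BRANCH_WARNED
    ):
        warnings.warn(
            "vs_threshold >= 1.0: shape variance is bounded by 2/9 when length "
            "is the longest dimension, so the cylinder branch can never be "
            "taken; consider a threshold below 2/9 (e.g. 0.1).",
            UserWarning,
            stacklevel=2,
        )
        _DEAD_BRANCH_WARNED = True

    if vs < vs_threshold:
        a, b, c = length / 2.0, width / 2.0, height / 2.0
        if ellipsoid == "thomsen":
            return SurfaceAreaResult(_ellipsoid_area_thomsen(a, b, c), "ellipsoid", "thomsen")
        if ellipsoid == "quadrature":
            return SurfaceAreaResult(_ellipsoid_area_quadrature(a, b, c), "ellipsoid", "quadrature")
        raise ValidationError(f"unknown ellipsoid method {ellipsoid!r}")
    if cylinder_radius == "mean":
        r = (width + height) / 4.0
    elif cylinder_radius == "width":
        r = width / 2.0
    else:
        raise ValidationError(f"unknown cylinder_radius rule {cylinder_radius!r}")
    area = 2.0 * math.pi * r * r + 2.0 * math.pi * r * length
    return SurfaceAreaResult(area, "cylinder", "closed-form")


def area_mass_ratio(area: float, mass: float) -> float:
    """Surface area per unit mass (mm^2 per mass unit)."""
    if mass <= 0:
        raise InvalidDimensionError("area_mass_ratio requires positive mass")
    if area <= 0:
        raise InvalidDimensionError("area_mass_ratio requires positive area")
    return area / mass


def standardized_germination(
    feces_germ: int | float, control_germ_pct: float, seeds_fed: int
) -> float:
    """Standardized germination success in percent.

    100 * feces_germ / (control_germ_pct/100 * seeds_fed); may exceed 100 when
    feces germination outperforms the control capacity.
    """
    if seeds_fed <= 0:
        raise ValidationError("seeds_fed must be positive")
    if control_germ_pct <= 0:
        raise ExcludedSpeciesError(
            "species with zero control germination capacity are excluded "
            "from standardized germination"
        )
    if feces_germ < 0:
        raise ValidationError("feces_germ must be non-negative")
    return 100.0 * feces_germ / ((control_germ_pct / 100.0) * seeds_fed)


def build_trait_table(
    records: Iterable[SeedTraitRecord],
    vs_threshold: float = 1.0,
    ellipsoid: str = "thomsen",
    cylinder_radius: str = "mean",
) -> pd.DataFrame:
    """Assemble one row per species with every derived index.

    Indices are computed from raw dimensions when available, otherwise taken
    from the record's pre-computed fields. Rows lacking the data for an index
    carry NaN plus a ``height_missing`` flag; SGS is NaN for zero-capacity
    species (kept representable via ``group_summary``'s na_policy).
    """
    records = list(records)
    names = [r.species for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate species in trait table: {dupes}")

    rows = []
    for r in records:
        ei = fi = vs = area = density = am = np.nan
        branch = None
        if r.has_dimensions:
            assert r.length is not None and r.width is not None
            ei = eccentricity_index(r.length, r.width)
            if not r.height_missing:
                fi = flatness_index(r.length, r.width, r.height)
                vs = shape_variance(r.length, r.width, r.height)
                sa = surface_area(
                    r.length, r.width, r.height,
                    vs_threshold=vs_threshold,
                    ellipsoid=ellipsoid,
                    cylinder_radius=cylinder_radius,
                )
                area, branch = sa.area, sa.branch
        else:
            ei = r.ei if r.ei is not None else np.nan
            fi = r.fi if r.fi is not None else np.nan
            area = r.area if r.area is not None else np.nan
        if r.mass is not None and r.volume is not None:
            density = seed_density(r.mass, r.volume)
        elif r.density is not None:
            density = r.density
        if r.mass is not None and not np.isnan(area):
            am = area_mass_ratio(area, r.mass)
        elif r.area_mass is not None:
            am = r.area_mass
        if r.control_germ_pct > 0:
            sgs = standardized_germination(r.feces_germ, r.control_germ_pct, r.seeds_fed)
        else:
            sgs = np.nan
        rows.append(
            {
                "species": r.species,
                "seeds_fed": r.seeds_fed,
                "germ_temp": r.germ_temp,
                "control_germ_pct": r.control_germ_pct,
                "feces_germ": r.feces_germ,
                "sgs": sgs,
                "ei": ei,
                "fi": fi,
                "vs": vs,
                "mass": r.mass if r.mass is not None else np.nan,
                "volume": r.volume if r.volume is not None else np.nan,
                "density": density,
                "area": area,
                "area_mass": am,
                "area_branch": branch,
                "neophyte": r.neophyte,
                "red_list": r.red_list,
                "height_missing": r.height_missing,
            }
        )
    columns = [
        "species", "seeds_fed", "germ_temp", "control_germ_pct", "feces_germ",
        "sgs", "ei", "fi", "vs", "mass", "volume", "density", "area",
        "area_mass", "area_branch", "neophyte", "red_list", "height_missing",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class CollinearityResult:
    retained: list[str]
    dropped: list[str]
    correlations: pd.DataFrame
    threshold: float


def collinearity_filter(
    table: pd.DataFrame,
    predictors: Sequence[str],
    threshold: float = 0.7,
    priority: Sequence[str] = ("density", "ei", "area"),
    log: bool = True,
) -> CollinearityResult:
    """Drop one member of every predictor pair with |Pearson r| > threshold.

    Predictors are ordered by the configured ``priority`` list (unlisted
    columns follow in their given order); pairs are scanned greedily in that
    order and the lower-priority member of each offending pair is dropped.
    Correlations are computed on log-transformed values by default, matching
    the transform later used in the model. The result is independent of row
    order by construction (Pearson r is permutation-invariant).
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("collinearity threshold must lie in (0, 1)")
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValidationError("need at least two predictors")
    ordered = [p for p in priority if p in predictors]
    ordered += [p for p in predictors if p not in ordered]

    mat = table.loc[:, ordered].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValidationError("collinearity_filter: predictors contain missing values")
    if log:
        if (mat <= 0).any():
            raise ValidationError("log transform requires positive predictor values")
        mat = np.log(mat)
    if np.any(np.std(mat, axis=0) == 0.0):
        const = [ordered[i] for i in np.where(np.std(mat, axis=0) == 0.0)[0]]
        raise UndefinedCorrelationError(f"constant predictor column(s): {const}")

    corr = np.corrcoef(mat, rowvar=False)
    corr_df = pd.DataFrame(corr, index=ordered, columns=ordered)

    dropped: set[str] = set()
    for i, left in enumerate(ordered):
        if left in dropped:
            continue
        for j in range(i + 1, len(ordered)):
            right = ordered[j]
            if right in dropped:
                continue
            if abs(corr[i, j]) > threshold:
                dropped.add(right)
    retained = [p for p in ordered if p not in dropped]
    return CollinearityResult(
        retained=retained,
        dropped=[p for p in ordered if p in dropped],
        correlations=corr_df,
        threshold=threshold,
    )


@dataclass
class PcaResult:
    loadings: pd.DataFrame          # predictors x components, orthonormal columns
    eigenvalues: np.ndarray         # descending, sums to n predictors
    explained_variance_ratio: np.ndarray
    rank_warning: bool = False


def pca_summary(
    table: pd.DataFrame, predictors: Sequence[str], log: bool = True
) -> PcaResult:
    """Exploratory PCA of the standardized (correlation-matrix) predictors."""
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValidationError("PCA needs at least two predictors")
    mat = table.loc[:, predictors].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValidationError("pca_summary: predictors contain missing values")
    if log:
        if (mat <= 0).any():
            raise ValidationError("log transform requires positive predictor values")
        mat = np.log(mat)
    rank_warning = mat.shape[0] < len(predictors)
    if rank_warning:
        warnings.warn("fewer rows than predictors: trailing eigenvalues are zero",
                      UserWarning, stacklevel=2)
    corr = np.corrcoef(mat, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    comp_names = [f"PC{i + 1}" for i in range(len(predictors))]
    return PcaResult(
        loadings=pd.DataFrame(eigvec, index=predictors, columns=comp_names),
        eigenvalues=eigval,
        explained_variance_ratio=eigval / eigval.sum(),
        rank_warning=rank_warning,
    )


def group_summary(
    table: pd.DataFrame,
    grouping: str = "neophyte",
    exclude: Sequence[str] = (),
    na_policy: str = "zero",
) -> pd.DataFrame:
    """Mean SGS per group (neophyte status or red-list class).

    ``exclude`` removes species entirely (e.g. the extreme outlier Poa annua).
    ``na_policy`` controls species whose SGS is undefined because the control
    capacity was zero: "zero" counts them as SGS = 0 (the convention that
    reproduces the experiment's printed non-neophyte mean), "drop" removes
    them. Empty groups yield an explicit row with n = 0 and NaN mean.
    """
    if grouping not in table.columns:
        raise ValidationError(f"unknown grouping column {grouping!r}")
    if na_policy not in ("zero", "drop"):
        raise ValidationError("na_policy must be 'zero' or 'drop'")
    unknown = [s for s in exclude if s not in set(table["species"])]
    if unknown:
        raise ValidationError(f"exclusions not found in table: {unknown}")

    sub = table.loc[~table["species"].isin(exclude)].copy()
    if na_policy == "zero":
        sub["sgs"] = sub["sgs"].fillna(0.0)
    else:
        sub = sub.dropna(subset=["sgs"])

    out = (
        sub.groupby(grouping, dropna=False)["sgs"]
        .agg(mean_sgs="mean", n="size")
        .reset_index()
    )
    return out
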