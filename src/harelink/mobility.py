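"""Mobile-link analysis of GPS-tracked hares.

Hares retain ingested seeds for roughly 7 +/- 1.4 h; any habitat patches an
individual visits within that window are candidates to receive dispersed
seeds. Given hourly GPS fixes in a projected planar frame (meters) and a
polygonal land-use map, this module:

* resamples raw fixes to an hourly resolution,
* assigns each fix a patch id and land-use type (point-in-polygon; fixes
  outside all patches are "matrix" and excluded from counts),
* slides retention-time windows (5.6 / 7 / 8.4 h) fix by fix along each
  track, counting distinct land-use types and unique patches per type,
* computes per-window travel distances and centroid distance matrices of
  the visited patches, classified by land-use pair.

Windows use the closed interval [t0, t0 + T]: with hourly fixes a 5.6 h
window therefore holds up to 6 fixes (hours 0..5) and a 7 h window up to 8.
Windows are truncated at gaps larger than 1.5x the nominal fix interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from .errors import ValidationError

__all__ = [
    "Patch",
    "RetentionWindow",
    "LANDUSE_TYPES",
    "MATRIX_LABEL",
    "RETENTION_HOURS",
    "resample_hourly",
    "assign_patches",
    "centroid_distance_matrix",
    "sliding_windows",
    "window_connectivity",
    "window_travel_distance",
    "connectivity_summary",
]

LANDUSE_TYPES = ("grassland", "forest", "field", "wetland", "quarry", "urban")
MATRIX_LABEL = "matrix"
#: Retention-time windows in hours: mean - CI, mean, mean + CI.
RETENTION_HOURS = (5.6, 7.0, 8.4)
#: A time step larger than this multiple of the nominal fix interval truncates windows.
GAP_FACTOR = 1.5


@dataclass
class Patch:
    """A land-use polygon with stable id."""

    patch_id: str
    landuse: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.landuse not in LANDUSE_TYPES:
            raise ValidationError(
                f"patch {self.patch_id!r}: unknown land-use {self.landuse!r}"
            )
        if not self.polygon.is_valid:
            raise ValidationError(f"patch {self.patch_id!r}: invalid polygon")

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


@dataclass
class RetentionWindow:
    """Indices [start, stop) of consecutive fixes spanning at most T hours."""

    start: int
    stop: int
    duration_hours: float
    truncated: bool = False

    @property
    def n_fixes(self) -> int:
        return self.stop - self.start


def _check_track(track: pd.DataFrame) -> None:
    for col in ("t", "x", "y"):
        if col not in track.columns:
            raise ValidationError(f"track lacks column {col!r}")
    t = pd.to_datetime(track["t"]).astype("int64").to_numpy()
    if len(t) > 1 and not (np.diff(t) > 0).all():
        raise ValidationError("track timestamps must be strictly increasing")
    if not np.isfinite(track[["x", "y"]].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite coordinates in track")


def resample_hourly(track: pd.DataFrame, tolerance_min: float = 10.0) -> pd.DataFrame:
    """Keep, per whole hour, the fix nearest the hour mark within tolerance.

    Hours without a fix inside the tolerance are simply absent — gaps are
    preserved, never interpolated.
    """
    _check_track(track)
    if len(track) == 0:
        return track.copy()
    t = pd.to_datetime(track["t"])
    hour = t.dt.round("h")
    offset = (t - hour).abs()
    ok = offset <= pd.Timedelta(minutes=tolerance_min)
    cand = track.loc[ok].copy()
    cand["_hour"] = hour[ok]
    cand["_off"] = offset[ok]
    picked = cand.sort_values(["_hour", "_off"], kind="mergesort").groupby("_hour").head(1)
    return (
        picked.sort_values("t", kind="mergesort")
        .drop(columns=["_hour", "_off"])
        .reset_index(drop=True)
    )


def _check_no_overlap(patches: list[Patch]) -> None:
    tree = STRtree([p.polygon for p in patches])
    offenders = []
    for i, p in enumerate(patches):
        for j in tree.query(p.polygon.buffer(-1e-9)):
            j = int(j)
            if j <= i:
                continue
            q = patches[j]
            inter = p.polygon.intersection(q.polygon)
            if inter.area > 1e-6:
                offenders.append((p.patch_id, q.patch_id))
    if offenders:
        raise ValidationError(f"overlapping patches: {offenders}")


def assign_patches(
    track: pd.DataFrame, patches: list[Patch], check_overlap: bool = True
) -> pd.DataFrame:
    """Point-in-polygon assignment of every fix.

    Boundary points count as inside (inclusive-edge rule); a point on a
    shared boundary goes to the lexicographically smallest patch_id. Fixes
    outside all patches are labelled "matrix". Returns the track with added
    ``patch_id`` and ``landuse`` columns.
    """
    _check_track(track)
    if check_overlap:
        _check_no_overlap(patches)
    tree = STRtree([p.polygon for p in patches])
    pts = [Point(xy) for xy in track[["x", "y"]].to_numpy(dtype=float)]
    patch_ids = []
    landuses = []
    for pt in pts:
        hits = [
            patches[int(j)]
            for j in tree.query(pt)
            if patches[int(j)].polygon.covers(pt)
        ]
        if hits:
            best = min(hits, key=lambda p: p.patch_id)
            patch_ids.append(best.patch_id)
            landuses.append(best.landuse)
        else:
            patch_ids.append(MATRIX_LABEL)
            landuses.append(MATRIX_LABEL)
    out = track.copy()
    out["patch_id"] = patch_ids
    out["landuse"] = landuses
    return out


def centroid_distance_matrix(
    patches: list[Patch],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Euclidean centroid distances between visited patches, plus class means.

    Classes summarize pairs as: differing land-use types, field-field,
    grassland-grassland, forest-forest. Returns (matrix, class summary).
    """
    if len(patches) < 2:
        raise ValidationError("need at least two visited patches for a distance matrix")
    ids = [p.patch_id for p in patches]
    cents = np.array([p.centroid for p in patches])
    diff = cents[:, None, :] - cents[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    matrix = pd.DataFrame(D, index=ids, columns=ids)

    classes: dict[str, list[float]] = {
        "differing": [], "field-field": [], "grassland-grassland": [], "forest-forest": []
    }
    for i, j in combinations(range(len(patches)), 2):
        a, b = patches[i].landuse, patches[j].landuse
        if a != b:
            classes["differing"].append(D[i, j])
        elif f"{a}-{b}" in classes:
            classes[f"{a}-{b}"].append(D[i, j])
    rows = []
    for name, vals in classes.items():
        rows.append(
            {
                "pair_class": name,
                "n_pairs": len(vals),
                "mean_m": float(np.mean(vals)) if vals else np.nan,
                "sd_m": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return matrix, pd.DataFrame(rows)


def sliding_windows(
    track: pd.DataFrame, T: float, nominal_interval_hours: float = 1.0
) -> list[RetentionWindow]:
    """All retention windows of duration T hours, one per start fix.

    Each window is the maximal run of consecutive fixes with timestamps in
    the closed interval [t0, t0 + T], truncated at any step larger than
    ``GAP_FACTOR`` times the nominal fix interval. A track shorter than T
    yields a single truncated window.
    """
    if T <= 0:
        raise ValidationError("retention time must be positive")
    _check_track(track)
    t = pd.to_datetime(track["t"]).astype("int64").to_numpy() / 3.6e12  # hours
    n = len(t)
    if n == 0:
        return []
    max_gap = GAP_FACTOR * nominal_interval_hours
    windows = []
    for i in range(n):
        j = i
        truncated = False
        while j + 1 < n:
            if t[j + 1] - t[i] > T + 1e-9:
                break
            if t[j + 1] - t[j] > max_gap + 1e-9:
                truncated = True
                break
            j += 1
        else:
            if t[n - 1] - t[i] < T - 1e-9:
                truncated = True  # ran out of track before spanning T
        windows.append(
            RetentionWindow(start=i, stop=j + 1, duration_hours=T, truncated=truncated)
        )
    return windows


def window_connectivity(
    window: RetentionWindow, assigned: pd.DataFrame
) -> tuple[int, dict[str, int]]:
    """Counts of land-use types and unique patches per type inside a window.

    Matrix fixes are excluded. An all-matrix window returns (0, {}).
    """
    if "landuse" not in assigned.columns:
        raise ValidationError("run assign_patches first")
    sub = assigned.iloc[window.start: window.stop]
    sub = sub[sub["landuse"] != MATRIX_LABEL]
    if len(sub) == 0:
        return 0, {}
    per_type = sub.groupby("landuse")["patch_id"].nunique().to_dict()
    return len(per_type), {str(k): int(v) for k, v in per_type.items()}


def window_travel_distance(
    window: RetentionWindow, track: pd.DataFrame, mode: str = "path"
) -> float:
    """Distance traveled inside a window, in kilometers.

    ``mode="path"`` (default) sums consecutive-step Euclidean lengths;
    ``mode="net"`` is the start-to-end displacement. A single-fix window
    yields 0.
    """
    if mode not in ("path", "net"):
        raise ValidationError("mode must be 'path' or 'net'")
    xy = track[["x", "y"]].to_numpy(dtype=float)[window.start: window.stop]
    if len(xy) < 2:
        return 0.0
    if mode == "path":
        steps = np.sqrt((np.diff(xy, axis=0) ** 2).sum(axis=1))
        return float(steps.sum()) / 1000.0
    return float(np.hypot(*(xy[-1] - xy[0]))) / 1000.0


def _transition_composition(assigned: pd.DataFrame) -> dict[str, int]:
    """Counts of between-patch transitions by unordered land-use pair.

    A transition is a pair of consecutive non-matrix fixes in different
    patches; self-transitions (same patch) are not connections.
    """
    counts: dict[str, int] = {}
    pid = assigned["patch_id"].to_numpy()
    lu = assigned["landuse"].to_numpy()
    for k in range(len(assigned) - 1):
        if MATRIX_LABEL in (lu[k], lu[k + 1]):
            continue
        if pid[k] == pid[k + 1]:
            continue
        key = "-".join(sorted((lu[k], lu[k + 1])))
        counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class ConnectivitySummary:
    """Per-individual window means and the landscape-level aggregate."""

    per_individual: pd.DataFrame  # individual, T, mean_types, mean patches per type, travel km
    aggregate: pd.DataFrame       # T, metric, mean, sd across individuals
    composition: pd.DataFrame     # pair, count, percent (pooled over individuals)
    excluded: list[str] = field(default_factory=list)


def connectivity_summary(
    tracks: pd.DataFrame,
    patches: list[Patch],
    retention_hours: tuple[float, ...] = RETENTION_HOURS,
    min_days: float = 10.0,
    distance_mode: str = "path",
) -> ConnectivitySummary:
    """Moving-window connectivity per individual and landscape aggregate.

    ``tracks`` holds hourly fixes for all individuals (columns individual_id,
    t, x, y). Individuals observed for fewer than ``min_days`` are excluded
    (and listed). For each retention time T the per-individual mean number of
    land-use types per window, mean unique patches per type, and mean travel
    distance are averaged across windows; the aggregate reports mean +/- SD
    across individuals. Connection composition pools consecutive between-patch
    transitions over individuals.
    """
    if "individual_id" not in tracks.columns:
        raise ValidationError("tracks need an individual_id column")
    per_rows = []
    comp_total: dict[str, int] = {}
    excluded = []
    for ind, sub in tracks.groupby("individual_id", sort=True):
        sub = sub.sort_values("t", kind="mergesort").reset_index(drop=True)
        span_days = (
            pd.to_datetime(sub["t"]).iloc[-1] - pd.to_datetime(sub["t"]).iloc[0]
        ) / pd.Timedelta(days=1)
        if span_days < min_days:
            excluded.append(str(ind))
            continue
        assigned = assign_patches(sub, patches, check_overlap=False)
        for key, cnt in _transition_composition(assigned).items():
            comp_total[key] = comp_total.get(key, 0) + cnt
        for T in retention_hours:
            wins = sliding_windows(assigned, T)
            n_types = []
            per_type_counts: dict[str, list[int]] = {}
            travel = []
            for w in wins:
                k, per_type = window_connectivity(w, assigned)
                n_types.append(k)
                for lu, c in per_type.items():
                    per_type_counts.setdefault(lu, []).append(c)
                travel.append(window_travel_distance(w, assigned, mode=distance_mode))
            row = {
                "individual_id": str(ind),
                "T": T,
                "n_windows": len(wins),
                "mean_types": float(np.mean(n_types)) if n_types else np.nan,
                "mean_travel_km": float(np.mean(travel)) if travel else np.nan,
            }
            for lu in LANDUSE_TYPES:
                vals = per_type_counts.get(lu, [])
                # Mean unique patches of this type over the windows that visit it.
                row[f"patches_{lu}"] = float(np.mean(vals)) if vals else np.nan
            per_rows.append(row)

    per_df = pd.DataFrame(per_rows)
    agg_rows = []
    if len(per_df):
        metrics = ["mean_types", "mean_travel_km"] + [f"patches_{lu}" for lu in LANDUSE_TYPES]
        for T in retention_hours:
            subT = per_df[per_df["T"] == T]
            for m in metrics:
                vals = subT[m].dropna()
                agg_rows.append(
                    {
                        "T": T,
                        "metric": m,
                        "mean": float(vals.mean()) if len(vals) else np.nan,
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                        "n_individuals": int(len(vals)),
                    }
                )
    total = sum(comp_total.values())
    comp_rows = [
        {"pair": k, "count": v, "percent": 100.0 * v / total}
        for k, v in sorted(comp_total.items(), key=lambda kv: -kv[1])
    ] if total else []
    return ConnectivitySummary(
        per_individual=per_df,
        aggregate=pd.DataFrame(agg_rows),
        composition=pd.DataFrame(comp_rows, columns=["pair", "count", "percent"]),
        excluded=excluded,
    )
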