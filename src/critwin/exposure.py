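"""Nearest-source exposure assignment and gestational-week aggregation.

Each birth is matched, on every day of the pregnancy, to the closest
pollution source active that day. Births with any pregnancy day lacking an
active source within the eligibility radius (default 8.49 km, the
half-diagonal of a 12 km square grid cell) are excluded. Daily values are
averaged into pregnancy-week (7-day blocks after conception) and trimester
averages, and the person-week matrix is standardized to a pooled one-SD
scale so a weekly effect reads "per SD of weekly ozone".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic import N_WEEKS, MAX_PREGNANCY_DAYS, PollutionPanel, SourceSet

#: eligibility radius, km: half-diagonal of a 12 km grid cell, as printed
#: at two decimals (12 * sqrt(2) / 2 = 8.4852...).
DEFAULT_RADIUS_KM = 8.49
KM_PER_MILE = 1.609344


class AssignmentError(RuntimeError):
    """A pregnancy day had no in-radius active source (birth not eligible)."""


def max_cell_distance(cell_side: float) -> float:
    """Farthest distance from the center of a square cell to any point in it.

    For a ``cell_side`` x ``cell_side`` cell this is the half-diagonal
    ``cell_side * sqrt(2) / 2``; at 12 km it gives the 8.49 km eligibility
    radius (5.28 miles).
    """
    if cell_side < 0:
        raise ValueError("cell side must be non-negative")
    return float(cell_side) * np.sqrt(2.0) / 2.0


def km_to_miles(km: float) -> float:
    return km / KM_PER_MILE


def nearest_source(location, sources: SourceSet, day: int) -> tuple[int, float]:
    """Closest source active on ``day``; ties broken by smallest source_id.

    Returns ``(-1, inf)`` when no source is active that day.
    """
    active = sources.active[:, day]
    if not active.any():
        return -1, np.inf
    coords = sources.coords[active]
    ids = sources.frame["source_id"].to_numpy()[active]
    d = np.hypot(coords[:, 0] - location[0], coords[:, 1] - location[1])
    best = np.lexsort((ids, d))[0]  # distance first, then id
    return int(ids[best]), float(d[best])


def _split_activity(sources: SourceSet):
    """Rows that are active every day vs. rows with gaps."""
    always = sources.active.all(axis=1)
    return np.flatnonzero(always), np.flatnonzero(~always)


def eligibility_filter(cohort: pd.DataFrame, sources: SourceSet,
                       radius: float = DEFAULT_RADIUS_KM,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep births with an active in-radius source on every pregnancy day.

    Returns ``(eligible_cohort, exclusions)`` where exclusions records each
    excluded birth and its first failing pregnancy day (1-based).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(cohort)
    if n == 0:
        return cohort.copy(), pd.DataFrame(
            columns=["birth_id", "first_failing_day", "reason"])

    locs = cohort[["x_km", "y_km"]].to_numpy(dtype=float)
    conception = cohort["conception_day"].to_numpy(dtype=int)
    birth_day = cohort["birth_day"].to_numpy(dtype=int)
    rows_a, rows_b = _split_activity(sources)

    dist_a = np.full(n, np.inf)
    if rows_a.size:
        tree = cKDTree(sources.coords[rows_a])
        dist_a, _ = tree.query(locs)

    first_fail = np.zeros(n, dtype=int)  # 0 = eligible
    covered_by_a = dist_a <= radius
    if rows_b.size == 0:
        first_fail[~covered_by_a] = 1  # every day fails identically
    else:
        coords_b = sources.coords[rows_b]
        active_b = sources.active[rows_b]
        chunk = max(1, int(2e7 // max(active_b.shape[1], 1)))
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            idx = np.flatnonzero(~covered_by_a[lo:hi]) + lo
            if idx.size == 0:
                continue
            d_b = np.sqrt(((locs[idx, None, :] - coords_b[None, :, :]) ** 2).sum(-1))
            inrad = (d_b <= radius).astype(np.float32)
            cov = (inrad @ active_b.astype(np.float32)) > 0.5  # (idx, n_days)
            for k, i in enumerate(idx):
                window = cov[k, conception[i] + 1: birth_day[i] + 1]
                fails = ~window
                if fails.any():
                    first_fail[i] = int(np.argmax(fails)) + 1

    eligible = cohort.loc[first_fail == 0].reset_index(drop=True)
    excl = cohort.loc[first_fail > 0, ["birth_id"]].copy()
    excl["first_failing_day"] = first_fail[first_fail > 0]
    excl["reason"] = "no active source within radius"
    return eligible, excl.reset_index(drop=True)


def _daily_values(cohort: pd.DataFrame, sources: SourceSet,
                  panel: PollutionPanel, radius: float) -> np.ndarray:
    """Nearest-active-source daily ozone for each pregnancy day.

    Output is (n, 308); entries beyond 7*ga are left as NaN and masked by
    the weekly validity mask downstream.
    """
    n = len(cohort)
    locs = cohort[["x_km", "y_km"]].to_numpy(dtype=float)
    conception = cohort["conception_day"].to_numpy(dtype=int)
    ga = cohort["gestational_age"].to_numpy(dtype=int)
    n_days = panel.values.shape[1]

    day = conception[:, None] + 1 + np.arange(MAX_PREGNANCY_DAYS)[None, :]
    preg = np.arange(MAX_PREGNANCY_DAYS)[None, :] < (7 * ga)[:, None]
    day_clipped = np.clip(day, 0, n_days - 1)
    if (day[preg] < 0).any() or (day[preg] >= n_days).any():
        raise AssignmentError("pregnancy days fall outside the panel date range")

    rows_a, rows_b = _split_activity(sources)
    vals = np.full((n, MAX_PREGNANCY_DAYS), np.nan)
    dist = np.full((n, MAX_PREGNANCY_DAYS), np.inf)

    best_a_val = None
    if rows_a.size:
        tree = cKDTree(sources.coords[rows_a])
        dist_a, idx_a = tree.query(locs)
        best_a_val = panel.values[rows_a[idx_a][:, None], day_clipped]

    if rows_b.size:
        coords_b = sources.coords[rows_b]
        d_b = np.sqrt(((locs[:, None, :] - coords_b[None, :, :]) ** 2).sum(-1))
        order = np.argsort(d_b, axis=1, kind="stable")
        filled = np.zeros((n, MAX_PREGNANCY_DAYS), dtype=bool)
        active_b = sources.active[rows_b]
        for r in range(rows_b.size):
            cand = order[:, r]
            dcand = d_b[np.arange(n), cand]
            if best_a_val is not None:
                sel = ~filled & (dist_a[:, None] <= dcand[:, None])
                vals[sel] = best_a_val[sel]
                dist[sel] = np.broadcast_to(dist_a[:, None], sel.shape)[sel]
                filled |= sel
            actv = active_b[cand[:, None], day_clipped]
            selm = ~filled & actv
            vals[selm] = panel.values[rows_b[cand][:, None], day_clipped][selm]
            dist[selm] = np.broadcast_to(dcand[:, None], selm.shape)[selm]
            filled |= selm
        if best_a_val is not None:
            sel = ~filled
            vals[sel] = best_a_val[sel]
            dist[sel] = np.broadcast_to(dist_a[:, None], sel.shape)[sel]
            filled |= sel
        if not filled[preg].all():
            raise AssignmentError("a pregnancy day has no active source")
    elif best_a_val is not None:
        vals[:] = best_a_val
        dist[:] = dist_a[:, None]
    else:
        raise AssignmentError("source set is empty")

    if (dist[preg] > radius).any():
        raise AssignmentError(
            "a pregnancy day has no in-radius active source; "
            "the birth should have been excluded by the eligibility filter")
    vals[~preg] = np.nan
    return vals


def weekly_exposure(birth: pd.Series, sources: SourceSet, panel: PollutionPanel,
                    radius: float = DEFAULT_RADIUS_KM) -> tuple[np.ndarray, np.ndarray]:
    """Raw weekly ozone averages for one (eligible) birth.

    Pregnancy week j covers days 7(j-1)+1 .. 7j after conception; the week-j
    value is the mean of the nearest-active-source daily values over those
    7 days. Weeks beyond the gestational age are invalid (zero).
    Reference implementation: loops over days and calls :func:`nearest_source`.
    """
    ga = int(birth["gestational_age"])
    conception = int(birth["conception_day"])
    daily = np.zeros(7 * ga)
    id_lookup = pd.Series(np.arange(len(sources.frame)),
                          index=sources.frame["source_id"]).to_dict()
    for d in range(1, 7 * ga + 1):
        sid, dd = nearest_source((birth["x_km"], birth["y_km"]), sources,
                                 conception + d)
        if sid < 0 or dd > radius:
            raise AssignmentError(f"no in-radius active source on pregnancy day {d}")
        daily[d - 1] = panel.values[id_lookup[sid], conception + d]
    raw = np.zeros(N_WEEKS)
    raw[:ga] = daily.reshape(ga, 7).mean(axis=1)
    valid = np.arange(1, N_WEEKS + 1) <= ga
    return raw, valid


@dataclass
class ScalingRecord:
    """Pooled center/scale (ppm) used to standardize person-week exposures."""
    center: float
    scale: float

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")


@dataclass
class ExposureMatrix:
    """n x 44 weekly exposures with a per-woman validity mask.

    ``values`` are standardized; invalid entries (week beyond gestational
    age) are exactly zero so the probit linear predictor's sum over weeks
    self-truncates at each gestational age. ``raw`` keeps the ppm-scale
    averages for trimester aggregation and back-transformation.
    """
    values: np.ndarray
    raw: np.ndarray
    valid: np.ndarray
    scaling: ScalingRecord

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self, birth_ids) -> pd.DataFrame:
        n, w = self.values.shape
        return pd.DataFrame({
            "birth_id": np.repeat(np.asarray(birth_ids), w),
            "week": np.tile(np.arange(1, w + 1), n),
            "raw": self.raw.ravel(),
            "standardized": self.values.ravel(),
            "valid": self.valid.astype(int).ravel(),
        })


def standardize(raw: np.ndarray, valid: np.ndarray,
                per_week: bool = False) -> ExposureMatrix:
    """Pooled (or optionally per-week) standardization of valid entries."""
    raw = np.asarray(raw, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid entries to standardize")
    out = np.zeros_like(raw)
    if per_week:
        center = np.zeros(raw.shape[1])
        scale = np.ones(raw.shape[1])
        for j in range(raw.shape[1]):
            vj = valid[:, j]
            if vj.sum() < 2:
                continue
            c, s = raw[vj, j].mean(), raw[vj, j].std(ddof=1)
            if s <= 0:
                raise ValueError(f"zero variance in week {j + 1}")
            out[vj, j] = (raw[vj, j] - c) / s
            center[j], scale[j] = c, s
        rec = ScalingRecord(float(center[valid.any(axis=0)].mean()),
                            float(scale[valid.any(axis=0)].mean()))
    else:
        pooled = raw[valid]
        c, s = float(pooled.mean()), float(pooled.std(ddof=1))
        if s <= 1e-12 * max(1.0, abs(c)):
            raise ValueError("zero variance among valid exposure entries")
        out[valid] = (raw[valid] - c) / s
        rec = ScalingRecord(c, s)
    raw_masked = np.where(valid, raw, 0.0)
    return ExposureMatrix(out, raw_masked, valid, rec)


def build_exposure_matrix(cohort: pd.DataFrame, sources: SourceSet,
                          panel: PollutionPanel,
                          radius: float = DEFAULT_RADIUS_KM,
                          per_week: bool = False) -> ExposureMatrix:
    """Vectorized daily assignment + weekly averaging + standardization."""
    daily = _daily_values(cohort, sources, panel, radius)
    weekly = daily.reshape(len(cohort), N_WEEKS, 7).mean(axis=2)
    ga = cohort["gestational_age"].to_numpy(dtype=int)
    valid = np.arange(1, N_WEEKS + 1)[None, :] <= ga[:, None]
    weekly = np.where(valid, weekly, 0.0)
    return standardize(weekly, valid, per_week=per_week)


def trimester_average(weekly_raw: np.ndarray, ga: int) -> np.ndarray:
    """Trimester means: weeks 1-13, 14-26, 27-ga (term births, ga >= 37)."""
    if ga < 27:
        raise ValueError("trimester averaging requires gestational age >= 27")
    w = np.asarray(weekly_raw, dtype=float)
    return np.array([w[0:13].mean(), w[13:26].mean(), w[26:ga].mean()])


def trimester_matrix(exposure: ExposureMatrix) -> np.ndarray:
    """(n, 3) raw trimester averages derived from the weekly matrix."""
    ga = exposure.valid.sum(axis=1).astype(int)
    return np.vstack([trimester_average(exposure.raw[i], ga[i])
                      for i in range(exposure.n)])


def write_exposure(exposure: ExposureMatrix, birth_ids, path) -> None:
    exposure.to_frame(birth_ids).to_csv(path, index=False)


def write_exclusions(exclusions: pd.DataFrame, path) -> None:
    exclusions.to_csv(path, index=False)
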