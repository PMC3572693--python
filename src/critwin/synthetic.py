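"""Synthetic birth cohort and ambient-ozone data generation.

Emulates the data structures of a term-birth / low-birth-weight critical-window
study: a geocoded cohort of term singleton births (gestational age 37-44
completed weeks, ~2.3% low birth weight), daily maximum 8-hour-average ozone
series (ppm) with seasonality and temporal autocorrelation, and three
co-registered pollution "metric" layouts --

* ``monitor``: a sparse network of ground monitors with possible inactive
  days (the directly observed product);
* ``grid``: a complete regular lattice (default 12 km spacing) carrying a
  smoothed, biased transform of the latent ozone field, emulating
  deterministic chemistry-model error;
* ``dense``: a dense point set carrying the latent field plus small noise,
  emulating a statistically calibrated (downscaled) product.

Median nearest-source distances are ordered dense < grid < monitor, matching
the qualitative ordering of real monitor / grid / census-tract products.

Outcomes are generated forward from the probit model

    p_i = Phi( x_i' beta + sum_{j<=ga_i} z_ij theta_j )

with the intercept calibrated by bisection so the marginal low-birth-weight
rate hits a target prevalence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import ndtr

N_WEEKS = 44
MAX_PREGNANCY_DAYS = 7 * N_WEEKS

SEX_LEVELS = ["male", "female"]
SEASON_LEVELS = ["winter", "spring", "summer", "fall"]
PARITY_LEVELS = ["0", "1", "2+"]
AGE_LEVELS = ["10-19", "20-24", "25-29", "30-34", "35-39", "40+"]
RACE_LEVELS = ["NH-white", "NH-black", "Hispanic", "NH-other"]
EDU_LEVELS = ["<HS", "HS", ">HS"]

# Default categorical frequencies, loosely matching a South Texas birth
# population (Hispanic-majority region).
DEFAULT_COVARIATE_PROBS = {
    "sex": {"male": 0.51, "female": 0.49},
    "parity": {"0": 0.38, "1": 0.30, "2+": 0.32},
    "maternal_age_group": {
        "10-19": 0.18, "20-24": 0.28, "25-29": 0.24,
        "30-34": 0.17, "35-39": 0.10, "40+": 0.03,
    },
    "race_ethnicity": {
        "NH-white": 0.14, "NH-black": 0.02, "Hispanic": 0.81, "NH-other": 0.03,
    },
    "education": {"<HS": 0.36, "HS": 0.34, ">HS": 0.30},
}

DEFAULT_GA_PROBS = {37: 0.07, 38: 0.16, 39: 0.27, 40: 0.27,
                    41: 0.15, 42: 0.05, 43: 0.02, 44: 0.01}


class ConfigurationError(ValueError):
    """Raised for inconsistent generator settings."""


@dataclass
class GeneratorConfig:
    """Settings for one synthetic realization.

    Distances are planar km on a square region ``[0, region_extent]^2``;
    ozone values are ppm (daily maximum 8-hour average); dates are calendar
    days in ``[date_start, date_end]``.
    """

    n_births: int = 10_000
    region_extent: float = 120.0
    date_start: str = "2001-01-01"
    date_end: str = "2004-12-31"
    monitor_count: int = 6
    monitor_missing_rate: float = 0.0
    grid_spacing: float = 12.0
    dense_spacing: float = 2.0
    ozone_mean: float = 0.040
    ozone_seasonal_amplitude: float = 0.010
    ozone_ar_coefficient: float = 0.7
    ozone_noise_sd: float = 0.005
    spatial_range: float = 100.0
    grid_bias_ppm: float = 0.003
    grid_bias_factor: float = 1.10
    grid_smooth_days: int = 7
    dense_noise_sd: float = 0.001
    true_beta: np.ndarray | None = None
    true_theta: np.ndarray | None = None
    true_window: tuple[int, ...] = (20, 21, 22, 23)
    window_effect: float = 0.15
    target_prevalence: float = 0.023
    population_centers: tuple[tuple[float, float], ...] | None = None
    population_sd: float | None = None
    ga_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_GA_PROBS))
    covariate_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_PROBS.items()})
    seed: int = 0

    def __post_init__(self):
        if self.n_births < 1:
            raise ConfigurationError("n_births must be positive")
        if self.region_extent <= 0:
            raise ConfigurationError("region_extent must be positive")
        if self.monitor_count < 1:
            raise ConfigurationError("monitor_count must be >= 1")
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be positive")
        if not self.dense_spacing < self.grid_spacing:
            raise ConfigurationError(
                "dense_spacing must be smaller than grid_spacing "
                "(dense product must sit closer than the coarse grid)")
        if not 0.0 <= self.ozone_ar_coefficient < 1.0:
            raise ConfigurationError("ozone_ar_coefficient must lie in [0, 1)")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigurationError("target_prevalence must lie in (0, 1)")
        if self.n_days < MAX_PREGNANCY_DAYS + 1:
            raise ConfigurationError(
                f"date range must span at least {MAX_PREGNANCY_DAYS + 1} days "
                "so a full 44-week pregnancy fits")

    @property
    def origin(self) -> pd.Timestamp:
        return pd.Timestamp(self.date_start)

    @property
    def n_days(self) -> int:
        return (pd.Timestamp(self.date_end) - pd.Timestamp(self.date_start)).days + 1

    def centers(self) -> np.ndarray:
        if self.population_centers is not None:
            return np.asarray(self.population_centers, dtype=float)
        L = self.region_extent
        return np.array([[0.32 * L, 0.38 * L], [0.68 * L, 0.62 * L]])

    def resolve_true_theta(self) -> np.ndarray:
        """Weekly effect vector: zero outside the designated window."""
        if self.true_theta is not None:
            theta = np.asarray(self.true_theta, dtype=float)
            if theta.shape != (N_WEEKS,):
                raise ConfigurationError(f"true_theta must have length {N_WEEKS}")
            return theta
        theta = np.zeros(N_WEEKS)
        for j in self.true_window:
            if not 1 <= j <= N_WEEKS:
                raise ConfigurationError(f"window week {j} outside 1..{N_WEEKS}")
            theta[j - 1] = self.window_effect
        return theta

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class SourceSet:
    """Pollution sources of one or more metric regimes.

    ``frame`` has columns source_id, regime, x_km, y_km; ``active`` is a
    boolean (n_sources, n_days) matrix. Grid and dense sources are active
    every day; monitors may have inactive days.
    """

    frame: pd.DataFrame
    active: np.ndarray
    origin: pd.Timestamp

    def regime(self, name: str) -> "SourceSet":
        keep = (self.frame["regime"] == name).to_numpy()
        if not keep.any():
            raise ConfigurationError(f"no sources of regime {name!r}")
        return SourceSet(self.frame.loc[keep].reset_index(drop=True),
                         self.active[keep], self.origin)

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x_km", "y_km"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class PollutionPanel:
    """Daily ozone values per source; NaN where the source is inactive."""

    values: np.ndarray          # (n_sources, n_days), ppm
    source_ids: np.ndarray
    origin: pd.Timestamp

    def to_long(self) -> pd.DataFrame:
        n_src, n_days = self.values.shape
        dates = self.origin + pd.to_timedelta(np.arange(n_days), unit="D")
        df = pd.DataFrame({
            "source_id": np.repeat(self.source_ids, n_days),
            "date": np.tile(dates, n_src),
            "value": self.values.ravel(),
        })
        return df.dropna(subset=["value"]).reset_index(drop=True)


def _lattice(extent: float, spacing: float) -> np.ndarray:
    """Cell-center lattice covering [0, extent]^2 at the given spacing."""
    n = int(np.floor(extent / spacing))
    n = max(n, 1)
    coords1d = (np.arange(n) + 0.5) * spacing
    xx, yy = np.meshgrid(coords1d, coords1d)
    return np.column_stack([xx.ravel(), yy.ravel()])


def gen_sources(config: GeneratorConfig,
                regimes: tuple[str, ...] = ("monitor", "grid", "dense")) -> SourceSet:
    """Lay out pollution sources for the requested metric regimes.

    Grid and dense regimes are regular lattices at their respective spacings
    (active every day). Monitors are placed preferentially near the
    population centers and may be inactive on random days at
    ``monitor_missing_rate``.
    """
    rng = config.rng(1)
    rows, actives = [], []
    sid = 0
    for regime in regimes:
        if regime == "monitor":
            centers = config.centers()
            sd = config.population_sd or config.region_extent / 8.0
            which = rng.integers(0, len(centers), size=config.monitor_count)
            pts = centers[which] + rng.normal(0.0, sd, size=(config.monitor_count, 2))
            pts = np.clip(pts, 0.0, config.region_extent)
            act = rng.random((config.monitor_count, config.n_days)) >= config.monitor_missing_rate
        elif regime == "grid":
            pts = _lattice(config.region_extent, config.grid_spacing)
            act = np.ones((len(pts), config.n_days), dtype=bool)
        elif regime == "dense":
            pts = _lattice(config.region_extent, config.dense_spacing)
            act = np.ones((len(pts), config.n_days), dtype=bool)
        else:
            raise ConfigurationError(f"unknown regime {regime!r}")
        for (x, y) in pts:
            rows.append((sid, regime, float(x), float(y)))
            sid += 1
        actives.append(act)
    frame = pd.DataFrame(rows, columns=["source_id", "regime", "x_km", "y_km"])
    return SourceSet(frame, np.vstack(actives), config.origin)


def _seasonal(day_index: np.ndarray, origin: pd.Timestamp,
              amplitude: float, peak_doy: float = 196.0) -> np.ndarray:
    doy = (origin.dayofyear - 1 + day_index) % 365.25
    return amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def _latent_field(coords: np.ndarray, config: GeneratorConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Latent daily ozone at each source: mean + seasonal + spatial AR(1)."""
    n_src = len(coords)
    T = config.n_days
    days = np.arange(T)
    series = config.ozone_mean + _seasonal(days, config.origin,
                                           config.ozone_seasonal_amplitude)
    latent = np.broadcast_to(series, (n_src, T)).copy()
    if config.ozone_noise_sd > 0:
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        R = np.exp(-d / config.spatial_range)
        # jitter keeps the Cholesky stable for co-located lattice points
        L = np.linalg.cholesky(R + 1e-10 * np.eye(n_src))
        innov = config.ozone_noise_sd * (L @ rng.standard_normal((n_src, T)))
        rho = config.ozone_ar_coefficient
        if rho > 0:
            innov[:, 0] /= np.sqrt(1.0 - rho**2)  # stationary start
            innov = lfilter([1.0], [1.0, -rho], innov, axis=1)
        latent += innov
    return latent


def _smooth_time(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, ((0, 0), (pad, pad)), mode="edge")
    out = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="valid"), 1, padded)
    return out[:, :values.shape[1]]


def gen_ozone_panel(sources: SourceSet, config: GeneratorConfig) -> PollutionPanel:
    """Simulate daily maximum 8-hour ozone for every source.

    All regimes share one latent spatially correlated AR(1) field. Monitor
    series report the latent field (masked on inactive days); grid series are
    a temporally smoothed, multiplicatively and additively biased transform
    (deterministic-model error); dense series are the latent field plus small
    calibration noise. Values are clipped to the physical band (0, 0.5) ppm.
    """
    rng = config.rng(2)
    coords = sources.coords
    latent = _latent_field(coords, config, rng)
    values = latent.copy()

    regimes = sources.frame["regime"].to_numpy()
    grid_rows = np.flatnonzero(regimes == "grid")
    if grid_rows.size:
        smoothed = _smooth_time(latent[grid_rows], config.grid_smooth_days)
        x = coords[grid_rows, 0]
        y = coords[grid_rows, 1]
        L = config.region_extent
        bias = config.grid_bias_ppm * np.sin(2 * np.pi * x / L) * np.cos(2 * np.pi * y / L)
        values[grid_rows] = config.grid_bias_factor * smoothed + bias[:, None]
    dense_rows = np.flatnonzero(regimes == "dense")
    if dense_rows.size and config.dense_noise_sd > 0:
        values[dense_rows] += rng.normal(0.0, config.dense_noise_sd,
                                         size=values[dense_rows].shape)

    np.clip(values, 1e-4, 0.5 - 1e-4, out=values)
    values[~sources.active] = np.nan
    return PollutionPanel(values, sources.frame["source_id"].to_numpy(), config.origin)


def _draw_categorical(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    levels = np.array(list(probs.keys()), dtype=object)
    p = np.asarray(list(probs.values()), dtype=float)
    p = p / p.sum()
    return levels[rng.choice(len(levels), size=n, p=p)]


def _season_of(dates: pd.DatetimeIndex) -> np.ndarray:
    month = dates.month.to_numpy()
    season = np.full(len(dates), "winter", dtype=object)
    season[np.isin(month, (3, 4, 5))] = "spring"
    season[np.isin(month, (6, 7, 8))] = "summer"
    season[np.isin(month, (9, 10, 11))] = "fall"
    return season


def regional_weather(config: GeneratorConfig) -> pd.DataFrame:
    """One region-wide temperature/dewpoint value per calendar day (deg C)."""
    rng = config.rng(3)
    days = np.arange(config.n_days)
    temp = 22.0 + 8.0 * _seasonal(days, config.origin, 1.0) + rng.normal(0, 2.0, config.n_days)
    dew = temp - 5.0 + rng.normal(0, 1.5, config.n_days)
    return pd.DataFrame({"day": days, "temperature": temp, "dewpoint": dew})


def gen_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic term-birth cohort (outcomes unset).

    Gestational ages are drawn from a term distribution on 37..44 completed
    weeks; conception day = birth day - 7*ga, and birth dates are uniform
    over the days for which the whole pregnancy fits inside the date range.
    Residences cluster around the population centers.
    """
    rng = config.rng(4)
    n = config.n_births
    ga = _draw_categorical(rng, config.ga_probs, n).astype(int)
    lo = 7 * ga  # earliest birth day with conception inside the range
    birth_day = (lo + rng.random(n) * (config.n_days - lo)).astype(int)
    birth_day = np.minimum(birth_day, config.n_days - 1)

    centers = config.centers()
    sd = config.population_sd or config.region_extent / 10.0
    which = rng.integers(0, len(centers), size=n)
    loc = centers[which] + rng.normal(0.0, sd, size=(n, 2))
    loc = np.clip(loc, 0.0, config.region_extent)

    dates = config.origin + pd.to_timedelta(birth_day, unit="D")
    dates = pd.DatetimeIndex(dates)
    weather = regional_weather(config)
    cohort = pd.DataFrame({
        "birth_id": np.arange(n),
        "x_km": loc[:, 0],
        "y_km": loc[:, 1],
        "birth_day": birth_day,
        "gestational_age": ga,
        "sex": _draw_categorical(rng, config.covariate_probs["sex"], n),
        "season_of_birth": _season_of(dates),
        "birth_year": dates.year.to_numpy(),
        "parity": _draw_categorical(rng, config.covariate_probs["parity"], n),
        "maternal_age_group": _draw_categorical(
            rng, config.covariate_probs["maternal_age_group"], n),
        "race_ethnicity": _draw_categorical(
            rng, config.covariate_probs["race_ethnicity"], n),
        "education": _draw_categorical(rng, config.covariate_probs["education"], n),
        "temperature": weather["temperature"].to_numpy()[birth_day],
        "dewpoint": weather["dewpoint"].to_numpy()[birth_day],
    })
    cohort["conception_day"] = cohort["birth_day"] - 7 * cohort["gestational_age"]
    return cohort


def calibrate_intercept(eta: np.ndarray, target: float,
                        lo: float = -12.0, hi: float = 12.0) -> float:
    """Bisection for the intercept shift a with mean(Phi(a + eta)) = target."""
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    f = lambda a: float(np.mean(ndtr(a + eta))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target prevalence unreachable within intercept bounds")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_outcomes(cohort: pd.DataFrame, exposure_values: np.ndarray,
                 design_matrix: np.ndarray, config: GeneratorConfig,
                 ) -> tuple[pd.DataFrame, dict]:
    """Generate binary low-birth-weight outcomes from the probit model.

    ``exposure_values`` is the standardized, validity-masked n x 44 weekly
    matrix (invalid weeks exactly zero, so the sum over weeks self-truncates
    at each woman's gestational age). The intercept is auto-calibrated by
    bisection so the expected marginal rate equals ``target_prevalence``.
    Returns the cohort with an ``lbw`` column and the ground-truth parameters.
    """
    n = len(cohort)
    X = np.asarray(design_matrix, dtype=float)
    Z = np.asarray(exposure_values, dtype=float)
    if Z.shape != (n, N_WEEKS):
        raise ValueError(f"exposure matrix must be n x {N_WEEKS}")
    beta = (np.zeros(X.shape[1]) if config.true_beta is None
            else np.asarray(config.true_beta, dtype=float))
    if beta.shape != (X.shape[1],):
        raise ValueError("true_beta not conformable with the design matrix")
    theta = config.resolve_true_theta()
    eta = X @ beta + Z @ theta
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    intercept = calibrate_intercept(eta, config.target_prevalence)
    p = ndtr(intercept + eta)
    rng = config.rng(5)
    y = (rng.random(n) < p).astype(int)
    out = cohort.copy()
    out["lbw"] = y
    truth = {"intercept": intercept, "beta": beta, "theta": theta,
             "probabilities": p}
    return out, truth


# ----------------------------------------------------------------------
# delimited-text output

def write_cohort(cohort: pd.DataFrame, path, origin: pd.Timestamp) -> None:
    df = cohort.copy()
    df["birth_date"] = (origin + pd.to_timedelta(df["birth_day"], unit="D")).dt.date
    df.to_csv(path, index=False)


def write_sources(sources: SourceSet, path) -> None:
    df = sources.frame.copy()
    df["n_active_days"] = sources.active.sum(axis=1)
    df.to_csv(path, index=False)


def write_panel(panel: PollutionPanel, path) -> None:
    panel.to_long().to_csv(path, index=False)


def write_config(config: GeneratorConfig, path) -> None:
    import yaml
    d = dataclasses.asdict(config)
    for key, val in d.items():
        if isinstance(val, np.ndarray):
            d[key] = val.tolist()
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
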