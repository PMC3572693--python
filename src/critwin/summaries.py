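"""Posterior window summaries, DIC model comparison and diagnostics.

Per-week posterior medians and 95% equal-tailed credible intervals define
the critical-window calls: a week is flagged significant when its interval
excludes zero, and contiguous significant weeks of common sign form a
window. Model fit is compared through the deviance information criterion
DIC = D_bar + p_D with p_D = D_bar - D_hat (plug-in at the posterior means),
and posterior-mean precision is reported as batch-means Monte-Carlo errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .sampler import PosteriorDraws

_PCLIP = 1e-12


@dataclass
class WindowSummaries:
    """Per-week posterior summary table plus the average interval length."""
    table: pd.DataFrame          # week, median, lower95, upper95, significant, width
    average_width: float
    level: float

    def significant_weeks(self) -> np.ndarray:
        t = self.table
        return t.loc[t["significant"], "week"].to_numpy()


@dataclass
class WindowRun:
    start: int
    end: int
    sign: int   # +1 or -1

    def weeks(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class FitMetrics:
    dic: float
    p_d: float
    d_bar: float
    d_hat: float


def summarize_windows(draws: PosteriorDraws, level: float = 0.95,
                      max_display_week: int | None = None) -> WindowSummaries:
    """Medians, equal-tailed intervals and significance flags per week.

    ``max_display_week`` truncates the report (not the fit); useful when a
    variant's late-pregnancy intervals are too wide to display.
    """
    if draws.n_draws < 100:
        raise ValueError("need at least 100 posterior draws to summarize")
    theta = draws.theta
    weeks = (draws.week_ids if draws.week_ids is not None
             else np.arange(1, theta.shape[1] + 1))
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(theta, alpha, axis=0)
    upper = np.quantile(theta, 1.0 - alpha, axis=0)
    median = np.quantile(theta, 0.5, axis=0)
    table = pd.DataFrame({
        "week": np.asarray(weeks, dtype=int),
        "median": median,
        "lower95": lower,
        "upper95": upper,
    })
    table["significant"] = (table["lower95"] > 0) | (table["upper95"] < 0)
    table["width"] = table["upper95"] - table["lower95"]
    if max_display_week is not None:
        table = table.loc[table["week"] <= max_display_week].reset_index(drop=True)
    return WindowSummaries(table, float(table["width"].mean()), level)


def identify_windows(summaries: WindowSummaries) -> list[WindowRun]:
    """Maximal runs of consecutive significant weeks with common sign."""
    t = summaries.table.sort_values("week")
    runs: list[WindowRun] = []
    current: WindowRun | None = None
    for _, row in t.iterrows():
        if not row["significant"]:
            current = None
            continue
        sign = 1 if row["lower95"] > 0 else -1
        week = int(row["week"])
        if (current is not None and sign == current.sign
                and week == current.end + 1):
            current.end = week
        else:
            current = WindowRun(week, week, sign)
            runs.append(current)
    return runs


def deviance(beta: np.ndarray, theta: np.ndarray | None,
             design: np.ndarray, exposure_block: np.ndarray | None,
             y: np.ndarray) -> float:
    """-2 log Bernoulli likelihood at (beta, theta), probabilities clamped."""
    eta = np.asarray(design, dtype=float) @ np.asarray(beta, dtype=float)
    if exposure_block is not None and theta is not None and np.size(theta):
        eta = eta + exposure_block @ np.asarray(theta, dtype=float)
    p = np.clip(ndtr(eta), _PCLIP, 1.0 - _PCLIP)
    y = np.asarray(y)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def compute_dic(draws: PosteriorDraws, design: np.ndarray,
                exposure_block: np.ndarray | None, y: np.ndarray,
                chunk: int = 250) -> FitMetrics:
    """Deviance information criterion from the posterior draws.

    D_bar is the posterior mean deviance; D_hat plugs in the posterior means
    of (beta, theta); p_D = D_bar - D_hat and DIC = D_bar + p_D.
    """
    X = np.asarray(design, dtype=float)
    Z = None if exposure_block is None else np.asarray(exposure_block, dtype=float)
    y = np.asarray(y)
    n_draws = draws.n_draws
    dev_sum = 0.0
    for lo in range(0, n_draws, chunk):
        hi = min(lo + chunk, n_draws)
        eta = draws.beta[lo:hi] @ X.T
        if Z is not None and draws.theta.shape[1]:
            eta += draws.theta[lo:hi] @ Z.T
        p = np.clip(ndtr(eta), _PCLIP, 1.0 - _PCLIP)
        dev_sum += float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    d_bar = dev_sum / n_draws
    d_hat = deviance(draws.beta.mean(axis=0),
                     draws.theta.mean(axis=0) if draws.theta.shape[1] else None,
                     X, Z, y)
    p_d = d_bar - d_hat
    return FitMetrics(dic=d_bar + p_d, p_d=p_d, d_bar=d_bar, d_hat=d_hat)


def mc_error(x: np.ndarray) -> float:
    """Batch-means standard error of the posterior mean (~sqrt(n) batches)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 400:
        raise ValueError("need at least 400 draws for a batch-means MC error")
    n_batches = int(round(np.sqrt(n)))
    batch_size = n // n_batches
    trimmed = x[: n_batches * batch_size].reshape(n_batches, batch_size)
    means = trimmed.mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


@dataclass
class MetricComparison:
    summary: pd.DataFrame             # per metric: average width, Jaccard, ...
    weekly_differences: pd.DataFrame  # per week: median diff vs reference
    reference: str


def compare_metrics(summaries: dict[str, WindowSummaries],
                    reference: str | None = None) -> MetricComparison:
    """Cross-metric comparison of window summaries on a common week grid."""
    names = list(summaries)
    if not names:
        raise ValueError("no summaries to compare")
    reference = reference or names[0]
    ref = summaries[reference]
    ref_weeks = ref.table["week"].to_numpy()
    ref_sig = set(ref.significant_weeks().tolist())
    ref_median = ref.table.set_index("week")["median"]

    rows = []
    diffs = pd.DataFrame({"week": ref_weeks})
    for name in names:
        ws = summaries[name]
        weeks = ws.table["week"].to_numpy()
        if not np.array_equal(weeks, ref_weeks):
            raise ValueError(f"metric {name!r} is on a different week grid")
        sig = set(ws.significant_weeks().tolist())
        union = ref_sig | sig
        jaccard = (len(ref_sig & sig) / len(union)) if union else 1.0
        diff = (ws.table.set_index("week")["median"] - ref_median)
        diffs[name] = diff.to_numpy()
        rows.append({
            "metric": name,
            "average_interval_width": ws.average_width,
            "n_significant_weeks": len(sig),
            "jaccard_vs_reference": jaccard,
            "mean_abs_median_diff": float(np.abs(diff).mean()),
        })
    return MetricComparison(pd.DataFrame(rows), diffs, reference)


def plot_windows(summaries: WindowSummaries, path, title: str = "") -> None:
    """Median + interval per week; significant weeks marked with filled dots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = summaries.table
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.vlines(t["week"], t["lower95"], t["upper95"], color="0.6", lw=1)
    sig = t["significant"]
    ax.plot(t.loc[~sig, "week"], t.loc[~sig, "median"], "o",
            mfc="white", mec="black", ms=4)
    ax.plot(t.loc[sig, "week"], t.loc[sig, "median"], "o", color="black", ms=4)
    ax.axhline(0.0, color="red", lw=0.8, ls="--")
    ax.set_xlabel("pregnancy week")
    ax.set_ylabel("effect per SD of weekly ozone (probit scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def draws_to_long(draws: PosteriorDraws) -> pd.DataFrame:
    """Long-format (iteration, parameter, value) table of all draws."""
    frames = []
    it = np.arange(draws.n_draws)
    for j, lab in enumerate(draws.beta_labels):
        frames.append(pd.DataFrame({"iteration": it, "parameter": lab,
                                    "value": draws.beta[:, j]}))
    for j, lab in enumerate(draws.theta_labels):
        frames.append(pd.DataFrame({"iteration": it, "parameter": lab,
                                    "value": draws.theta[:, j]}))
    if draws.sigma2_theta is not None:
        frames.append(pd.DataFrame({"iteration": it, "parameter": "sigma2_theta",
                                    "value": draws.sigma2_theta}))
    if draws.phi is not None:
        frames.append(pd.DataFrame({"iteration": it, "parameter": "phi",
                                    "value": draws.phi}))
    return pd.concat(frames, ignore_index=True)
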