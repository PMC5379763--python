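"""Single-cell and colony growth analytics.

Model fits used throughout:

* single-cell length growth  l(t) = l0 · e^{k t}  (nonlinear least squares,
  log-linear initialization); the elongation E = ln(l_f / l_0) = k·T links the
  fitted rate to the division time T,
* colony cell counts by the Baranyi–Roberts primary growth model with the
  curvature parameters fixed (m = 0, n = 20) for an abrupt lag-to-exponential
  transition, yielding the lag time λ and maximum specific growth rate μ_max,
* gamma distributions (maximum likelihood) for life-attribute variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellLifeAttributes",
    "BaranyiFit",
    "GammaFit",
    "fit_exponential_growth",
    "baranyi_roberts",
    "fit_baranyi_roberts",
    "life_attributes",
    "fit_gamma",
    "pearson_corr",
    "life_attribute_table",
]


@dataclass
class CellLifeAttributes:
    cell_id: int
    T_div: float | None          # min; None for censored lives
    l0: float                    # um, birth length
    lf: float                    # um, last observed length
    k: float | None              # 1/min fitted elongation rate
    E: float | None              # ln(lf/l0)
    censored: bool
    length_stats: dict = field(default_factory=dict)
    area_stats: dict = field(default_factory=dict)


@dataclass
class BaranyiFit:
    lambda_lag: float            # min
    mu_max: float                # 1/min
    y0: float                    # log-count at t=0
    m: float = 0.0               # fixed
    n: float = 20.0              # fixed
    rss: float = 0.0
    flagged: bool = False        # gross non-monotonicity in the input


@dataclass
class GammaFit:
    shape: float
    scale: float
    n_obs: int
    log_likelihood: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def fit_exponential_growth(lengths, times) -> tuple[float, float, float]:
    """Fit l(t) = l0·e^{kt}; returns (l0, k, rss).

    Nonlinear least squares on the lengths themselves, initialized from the
    log-linear regression (which is exact for noiseless data).
    """
    from scipy.optimize import curve_fit

    lengths = np.asarray(lengths, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(lengths) != len(times) or len(lengths) < 2:
        raise ValueError("need matching length/time series with >= 2 points")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    slope, intercept = np.polyfit(times, np.log(lengths), 1)
    p0 = (math.exp(intercept), slope)
    try:
        popt, _ = curve_fit(lambda t, l0, k: l0 * np.exp(k * t), times,
                            lengths, p0=p0, maxfev=2000)
    except RuntimeError:
        popt = p0
    l0, k = float(popt[0]), float(popt[1])
    rss = float(((l0 * np.exp(k * times) - lengths) ** 2).sum())
    return l0, k, rss


def baranyi_roberts(t, y0, mu_max, lambda_lag, n=20.0):
    """Log-count growth y(t) = y0 + mu_max·A(t) with the curvature-n lag term

        A(t) = t + (1/(n·mu)) · ln(e^{-n·mu·t} + e^{-n·mu·λ} − e^{-n·mu·(t+λ)}).

    With the stationary-phase parameter m fixed to 0 there is no saturation
    term; n = 20 makes the lag-to-exponential transition nearly a kink at λ.
    """
    t = np.asarray(t, dtype=float)
    nm = n * mu_max
    if nm <= 0:
        return y0 + mu_max * t
    a = nm * t
    b = nm * lambda_lag
    # ln(e^-a + e^-b - e^-(a+b)) computed stably via the dominant term
    m = np.logaddexp(-a, -b)
    inner = -(a + b) - m
    with np.errstate(over="ignore"):
        corr = np.log1p(-np.exp(np.minimum(inner, 0.0)))
    big_a = t + (m + corr) / nm
    return y0 + mu_max * big_a


def fit_baranyi_roberts(times, log_counts, m: float = 0.0,
                        n: float = 20.0) -> BaranyiFit:
    """Least-squares fit of (y0, mu_max, lambda) on log counts; m, n fixed."""
    from scipy.optimize import least_squares

    times = np.asarray(times, dtype=float)
    y = np.asarray(log_counts, dtype=float)
    if len(times) != len(y) or len(times) < 8:
        raise ValueError("need >= 8 time points")
    if m != 0.0:
        raise NotImplementedError("only the m = 0 (no stationary phase) form")
    flagged = bool(np.any(np.diff(y) < -math.log(1.5)))
    # initialization: slope of the steep half for mu, elbow for lambda
    slope0 = max((y[-1] - y[0]) / max(times[-1] - times[0], 1e-9), 1e-4)
    lam0 = float(times[max(int(len(times) * 0.2) - 1, 0)])

    def resid(p):
        y0, mu, lam = p
        return baranyi_roberts(times, y0, mu, lam, n) - y

    best = None
    for lam_try in {0.0, lam0, float(times[len(times) // 3])}:
        sol = least_squares(resid, x0=[y[0], slope0, lam_try],
                            bounds=([-np.inf, 1e-9, 0.0],
                                    [np.inf, np.inf, float(times[-1])]))
        if best is None or sol.cost < best.cost:
            best = sol
    y0, mu, lam = best.x
    return BaranyiFit(lambda_lag=float(lam), mu_max=float(mu), y0=float(y0),
                      m=m, n=n, rss=float(2 * best.cost), flagged=flagged)


def _stats(values: np.ndarray) -> dict:
    return {"min": float(values.min()), "max": float(values.max()),
            "mean": float(values.mean()), "median": float(np.median(values)),
            "std": float(values.std(ddof=1)) if len(values) > 1 else 0.0}


def life_attributes(node, instants_df, sampling_period: float) -> CellLifeAttributes:
    """Life attributes of one lineage node.

    ``instants_df`` is a DataFrame of this cell's instants with columns
    ``frame`` (0-based), ``length_um``, ``area_um2``.  Division time is
    (division_frame − birth_frame)·sampling_period; E = ln(l_f/l_0) (natural
    log, so that E = k·T holds for exponential growth); k comes from the
    per-cell exponential fit.  Lives truncated by the movie (fate not
    "divided") are flagged censored and excluded from life-attribute
    distributions downstream.
    """
    df = instants_df.sort_values("frame")
    lengths = df["length_um"].to_numpy(dtype=float)
    times = df["frame"].to_numpy(dtype=float) * sampling_period
    censored = node.fate != "divided"
    l0, lf = float(lengths[0]), float(lengths[-1])
    T_div = None
    if node.division_frame is not None:
        T_div = (node.division_frame - node.birth_frame) * sampling_period
    k = E = None
    if len(lengths) >= 4 and np.all(lengths > 0):
        _, k, _ = fit_exponential_growth(lengths, times - times[0])
    if l0 > 0 and lf > 0:
        E = math.log(lf / l0)
    return CellLifeAttributes(
        cell_id=node.cell_id, T_div=T_div, l0=l0, lf=lf, k=k, E=E,
        censored=censored, length_stats=_stats(lengths),
        area_stats=_stats(df["area_um2"].to_numpy(dtype=float)))


def fit_gamma(values) -> GammaFit:
    """Maximum-likelihood gamma fit (location fixed at zero)."""
    from scipy import stats

    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise ValueError("need >= 20 observations")
    if np.any(values <= 0):
        raise ValueError("gamma fit needs positive values")
    if np.ptp(values) < 1e-12 * abs(values[0]):
        raise ValueError("degenerate (constant) sample")
    shape, _, scale = stats.gamma.fit(values, floc=0)
    loglik = float(stats.gamma.logpdf(values, shape, 0, scale).sum())
    return GammaFit(shape=float(shape), scale=float(scale),
                    n_obs=len(values), log_likelihood=loglik)


def pearson_corr(x, y) -> float:
    """Product-moment correlation; NaN flag when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series with >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    from scipy import stats

    return float(stats.pearsonr(x, y).statistic)


def life_attribute_table(forest, instant_df, sampling_period: float):
    """Life attributes for every lineage node, as a DataFrame.

    ``instant_df`` holds all cell instants with a ``cell_id`` column linking
    them to lineage nodes.
    """
    import pandas as pd

    rows = []
    for node in sorted(forest.nodes.values(), key=lambda n: n.cell_id):
        sub = instant_df[instant_df["cell_id"] == node.cell_id]
        if sub.empty:
            continue
        la = life_attributes(node, sub, sampling_period)
        rows.append({
            "cell_id": la.cell_id, "colony_track_id": node.colony_track_id,
            "generation": forest.generation(node.cell_id),
            "T_div_min": la.T_div, "l0_um": la.l0, "lf_um": la.lf,
            "k_per_min": la.k, "elongation_E": la.E, "censored": la.censored,
            "mean_length_um": la.length_stats["mean"],
            "max_area_um2": la.area_stats["max"],
        })
    return pd.DataFrame(rows)
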