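"""Developmental-rate (DVR) phenology model for rice heading date.

Development stage (DVS) runs from 0 at emergence to 1 at heading and
accumulates a daily developmental rate driven by temperature and day
length:

    DVR_i = f(T_i)^α · g(P_i)^β / G    inside the photoperiod-sensitive
                                       window  0.145+0.005G ≤ DVS ≤ 0.345+0.005G
    DVR_i = f(T_i)^α / G               outside it

where f is a beta-type temperature response peaking at the optimum
temperature and g a decreasing day-length response equal to 1 below the
optimal photoperiod.  The cardinal points (T_b=8, T_o=30, T_c=42 °C;
P_b=0, P_o=10, P_c=24 h) are fixed across lines; (α, β_P, G) are
line-specific and fitted from multi-environment heading-date records by
particle swarm optimization.  An extreme learning machine then maps the
marker genotypes of six heading-date genes to (α, β_P, G) so the
parameters can be predicted for unphenotyped lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DVRCardinals, ELMSettings, PSOSettings
from .growth import WeatherSeries

_DVS_TOL = 1e-9  # absorbs float accumulation when DVR is an exact reciprocal


@dataclass
class DVRParams:
    """Line-specific DVR parameters.

    alpha: sensitivity to temperature (exponent, dimensionless).
    beta_p: sensitivity to day length (exponent, dimensionless).
    g: growth period, days-equivalent divisor (> 0).
    """

    alpha: float
    beta_p: float
    g: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta_p < 0:
            raise ValueError("alpha and beta_p must be >= 0")
        if self.g <= 0:
            raise ValueError("g must be > 0")


@dataclass
class METRecord:
    """One line × trial observation from a multi-environment trial."""

    line_id: str
    trial_id: str
    latitude: float
    sowing_date: pd.Timestamp
    heading_date: pd.Timestamp | None
    weather: WeatherSeries

    @property
    def days_to_heading(self) -> int | None:
        if self.heading_date is None:
            return None
        return int((pd.Timestamp(self.heading_date)
                    - pd.Timestamp(self.sowing_date)).days) + 1


@dataclass
class METData:
    """Heading-date records of a panel of lines across site-years."""

    records: list[METRecord]

    def for_line(self, line_id: str) -> list[METRecord]:
        return [r for r in self.records if r.line_id == line_id]

    @property
    def line_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.line_id, None)
        return list(seen)


@dataclass
class HeadingResult:
    """Outcome of a DVS simulation.

    heading_day: 1-based day count after emergence at which DVS first
        reaches 1, or None if the weather series ends first ("no heading").
    dvs: the DVS trajectory up to (and including) the heading day.
    """

    heading_day: int | None
    dvs: np.ndarray

    @property
    def headed(self) -> bool:
        return self.heading_day is not None


def day_length(latitude: float, day_of_year, twilight_angle: float = -0.833):
    """Theoretical day length (hours) from latitude and day of year.

    Uses the standard solar-declination formula and a configurable sun
    elevation threshold (default −0.833°, geometric sunrise/sunset with
    refraction).  Latitudes poleward of 66.5° are rejected: polar day and
    night are out of scope.
    """
    if abs(latitude) >= 66.5:
        raise ValueError("polar latitudes (|lat| >= 66.5) are not supported")
    doy = np.asarray(day_of_year, dtype=float)
    decl = np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.25))
    lat = np.deg2rad(latitude)
    h = np.deg2rad(twilight_angle)
    cos_omega = ((np.sin(h) - np.sin(lat) * np.sin(decl))
                 / (np.cos(lat) * np.cos(decl)))
    omega = np.arccos(np.clip(cos_omega, -1.0, 1.0))
    hours = 2.0 * np.rad2deg(omega) / 15.0
    return float(hours) if np.isscalar(day_of_year) else hours


def f_temp(t, cardinals: DVRCardinals = DVRCardinals()):
    """Beta-type temperature response in [0, 1]; 1 at T_o, 0 outside [T_b, T_c]."""
    t = np.asarray(t, dtype=float)
    tb, to, tc = cardinals.t_b, cardinals.t_o, cardinals.t_c
    exp = (tc - to) / (to - tb)
    with np.errstate(invalid="ignore"):
        inside = ((t - tb) / (to - tb)) * ((tc - t) / (tc - to)) ** exp
    out = np.where((t >= tb) & (t <= tc), inside, 0.0)
    return float(out) if out.ndim == 0 else out


def g_photo(p, cardinals: DVRCardinals = DVRCardinals()):
    """Day-length response in [0, 1]; 1 below P_o, decreasing to 0 at P_c."""
    p = np.asarray(p, dtype=float)
    pb, po, pc = cardinals.p_b, cardinals.p_o, cardinals.p_c
    exp = (pc - po) / (po - pb)
    with np.errstate(invalid="ignore"):
        long_day = ((p - pb) / (po - pb)) * \
            (np.clip(pc - p, 0.0, None) / (pc - po)) ** exp
    out = np.where(p < po, 1.0, np.clip(long_day, 0.0, None))
    return float(out) if out.ndim == 0 else out


def _dvs_window(g: float | np.ndarray) -> tuple:
    return 0.145 + 0.005 * np.asarray(g), 0.345 + 0.005 * np.asarray(g)


def simulate_dvs_heading(params: DVRParams, weather: WeatherSeries,
                         emergence_date,
                         cardinals: DVRCardinals = DVRCardinals()
                         ) -> HeadingResult:
    """Accumulate daily DVR from emergence; heading when DVS reaches 1.

    The photoperiod term applies only while the start-of-day DVS lies in
    the window [0.145+0.005G, 0.345+0.005G].  Day 1 is the emergence day;
    the returned heading_day n corresponds to calendar date
    emergence_date + (n−1) days.
    """
    w = weather.slice_from(emergence_date)
    if w.day_length is None:
        raise ValueError("weather series has no day_length; attach it first")
    ft = f_temp(w.t_mean, cardinals) ** params.alpha
    gp = g_photo(w.day_length, cardinals) ** params.beta_p
    lo, hi = _dvs_window(params.g)
    dvs = 0.0
    traj = np.empty(len(w))
    heading = None
    for i in range(len(w)):
        rate = ft[i] * gp[i] if lo <= dvs <= hi else ft[i]
        dvs += rate / params.g
        traj[i] = dvs
        if dvs >= 1.0 - _DVS_TOL:
            heading = i + 1
            break
    n = len(traj) if heading is None else heading
    return HeadingResult(heading, traj[:n])


def _heading_batch_loop(ft_pow: np.ndarray, gp_pow: np.ndarray,
                        g: np.ndarray, fractional: bool = False
                        ) -> np.ndarray:
    """Day-by-day reference implementation of the batch heading computation.

    Kept as the independent oracle for `_heading_batch`; both share only
    the model definition, not the traversal strategy.
    """
    n_p, n_d = ft_pow.shape
    dvs = np.zeros(n_p)
    heading = np.full(n_p, np.nan)
    lo, hi = _dvs_window(g)
    active = np.ones(n_p, dtype=bool)
    for i in range(n_d):
        in_win = (dvs >= lo) & (dvs <= hi)
        rate = np.where(in_win, ft_pow[:, i] * gp_pow[:, i], ft_pow[:, i]) / g
        new = np.where(active, dvs + rate, dvs)
        done = active & (new >= 1.0 - _DVS_TOL)
        if fractional:
            frac = np.divide(1.0 - dvs, rate, out=np.ones_like(dvs),
                             where=rate > 0)
            heading[done] = i + np.minimum(frac, 1.0)[done]
        else:
            heading[done] = i + 1
        dvs = new
        active &= ~done
        if not active.any():
            break
    return heading


def _heading_one(a: np.ndarray, b: np.ndarray, ftp: np.ndarray,
                 fgp: np.ndarray, g: float, lo: float, hi: float,
                 fractional: bool) -> float:
    """Heading day for one particle from cumulative daily rates.

    a = cumsum(f^α), b = cumsum(f^α·g^β).  The trajectory has three
    phases — pre-window (full rate), in-window (photoperiod-reduced rate),
    post-window (full rate) — whose boundaries are located by binary
    search on the cumulative sums; within-window membership is decided by
    the start-of-day DVS, matching the daily simulation exactly.
    """
    n = len(a)
    tol = _DVS_TOL * g

    def frac_day(idx: int, prev_cum: float, target: float,
                 rate: np.ndarray) -> float:
        if not fractional:
            return idx + 1.0
        r = rate[idx]
        return idx + (min((target - prev_cum) / r, 1.0) if r > 0 else 1.0)

    head_target = (1.0 - _DVS_TOL) * g
    # phase 1: full rate until the window's start-of-day threshold
    t_win = int(np.searchsorted(a, lo * g - tol, side="left"))
    t_head = int(np.searchsorted(a, head_target, side="left"))
    if t_head <= t_win:
        if t_head >= n:
            return np.nan
        prev = a[t_head - 1] if t_head else 0.0
        return frac_day(t_head, prev, g, ftp)
    if t_win >= n:
        return np.nan
    if a[t_win] > hi * g + tol:  # window jumped over within one day
        if t_head >= n:
            return np.nan
        prev = a[t_head - 1] if t_head else 0.0
        return frac_day(t_head, prev, g, ftp)

    # phase 2: in-window from day s, photoperiod-reduced rate
    s = t_win + 1
    dvs0 = a[t_win]  # cumsum units (dvs·g)
    b0 = b[s - 1]
    bt = b - b0  # cumulative in-window progress from day s on
    exit_target = (hi * g - dvs0) + tol
    head2_target = head_target - dvs0
    t_exit = int(np.searchsorted(bt[s - 1:], exit_target, side="right")) \
        + s - 1 + 1  # first day whose start DVS exceeds hi
    t_head2 = int(np.searchsorted(bt[s - 1:], head2_target, side="left")) \
        + s - 1
    if t_head2 < t_exit:
        if t_head2 >= n:
            return np.nan
        prev = dvs0 + bt[t_head2 - 1]
        return frac_day(t_head2, prev, g, fgp)
    if t_exit >= n:
        return np.nan

    # phase 3: full rate after leaving the window
    dvs_j = dvs0 + bt[t_exit - 1]
    a0 = a[t_exit - 1]
    t_head3 = int(np.searchsorted(a[t_exit:], head_target - dvs_j + a0,
                                  side="left")) + t_exit
    if t_head3 >= n:
        return np.nan
    prev = dvs_j + (a[t_head3 - 1] - a0 if t_head3 > t_exit else 0.0)
    return frac_day(t_head3, prev, g, ftp)


def _heading_batch(ft_pow: np.ndarray, gp_pow: np.ndarray, g: np.ndarray,
                   fractional: bool = False) -> np.ndarray:
    """Vectorized heading day over a particle batch.

    ft_pow, gp_pow: (n_particles, n_days) daily f(T)^α and g(P)^β.
    Returns float array of heading days (NaN where DVS never reaches 1).
    With ``fractional=True`` the within-day crossing time of DVS = 1 is
    interpolated, giving a continuous objective surface for the optimizer
    (the integer day is its ceiling).
    """
    prod = ft_pow * gp_pow
    a = np.cumsum(ft_pow, axis=1)
    b = np.cumsum(prod, axis=1)
    lo, hi = _dvs_window(g)
    out = np.empty(len(g))
    for p in range(len(g)):
        out[p] = _heading_one(a[p], b[p], ft_pow[p], prod[p],
                              float(g[p]), float(lo[p]), float(hi[p]),
                              fractional)
    return out


@dataclass
class FittedDVR:
    """PSO fit result for one line."""

    params: DVRParams
    objective_rmse: float
    history: np.ndarray  # best-so-far objective per iteration


def fit_dvr_pso(records: list[METRecord], settings: PSOSettings,
                rng: np.random.Generator,
                cardinals: DVRCardinals = DVRCardinals(),
                emergence_offset_days: int = 0) -> FittedDVR:
    """Fit (α, β_P, G) for one line by global-best particle swarm.

    Minimizes the RMSE (days) between simulated and observed heading dates
    over the configured bounds box.  Trials where a particle never reaches
    heading contribute a penalized pseudo-observation (series length + 50
    days), which keeps the objective finite and monotone-improvable.
    """
    usable = [r for r in records if r.heading_date is not None]
    if len(usable) < 3:
        raise ValueError("need >=3 trials with observed heading dates")

    trials = []
    for r in usable:
        emergence = pd.Timestamp(r.sowing_date) + \
            pd.Timedelta(days=emergence_offset_days)
        w = r.weather.slice_from(emergence)
        if w.day_length is None:
            raise ValueError("MET weather has no day_length attached")
        obs = (pd.Timestamp(r.heading_date) - emergence).days + 1
        trials.append((f_temp(w.t_mean, cardinals),
                       g_photo(w.day_length, cardinals), float(obs)))

    lb = np.array([settings.alpha_bounds[0], settings.beta_bounds[0],
                   settings.g_bounds[0]])
    ub = np.array([settings.alpha_bounds[1], settings.beta_bounds[1],
                   settings.g_bounds[1]])
    span = ub - lb
    n_p = settings.swarm_size

    def objective(x: np.ndarray, tie_break: float = 0.05) -> np.ndarray:
        # primary term: RMSE of integer heading days (what is observed);
        # secondary term: fractional crossing times, giving the swarm a
        # gradient across the integer plateaus
        alpha, beta, g = x[:, 0], x[:, 1], x[:, 2]
        sq_int = np.zeros(len(x))
        sq_frac = np.zeros(len(x))
        for ft, gp, obs in trials:
            ft_pow = np.power(ft[None, :], alpha[:, None])
            gp_pow = np.power(gp[None, :], beta[:, None])
            sim = _heading_batch(ft_pow, gp_pow, g, fractional=True)
            sim = np.where(np.isnan(sim), len(ft) + 50.0, sim)
            sq_int += (np.ceil(sim - _DVS_TOL) - obs) ** 2
            sq_frac += (sim + 0.5 - obs) ** 2
        return (np.sqrt(sq_int / len(trials))
                + tie_break * np.sqrt(sq_frac / len(trials)))

    penalty_floor = min(len(ft) + 50.0 - obs for ft, gp, obs in trials)
    for attempt in range(settings.retry_cap + 1):
        x = lb + rng.random((n_p, 3)) * span
        v = (rng.random((n_p, 3)) - 0.5) * span * 0.1
        f = objective(x)
        if np.min(f) < abs(penalty_floor):
            break
    else:
        raise RuntimeError("PSO initialization failed: no particle produced "
                           f"a heading date after {settings.retry_cap} retries")

    pbest_x, pbest_f = x.copy(), f.copy()
    g_idx = int(np.argmin(f))
    gbest_x, gbest_f = x[g_idx].copy(), float(f[g_idx])
    history = np.empty(settings.iterations)
    for it in range(settings.iterations):
        r1 = rng.random((n_p, 3))
        r2 = rng.random((n_p, 3))
        v = (settings.inertia * v
             + settings.c1 * r1 * (pbest_x - x)
             + settings.c2 * r2 * (gbest_x[None, :] - x))
        v = np.clip(v, -span, span)
        x = np.clip(x + v, lb, ub)
        # random immigrants: resample the worst tenth of the swarm to keep
        # exploring — the integer-day landscape is multimodal.  The current
        # best particle is never resampled.
        k = max(1, n_p // 10)
        order = np.argsort(pbest_f)
        worst = order[-k:][order[-k:] != order[0]]
        if len(worst):
            x[worst] = lb + rng.random((len(worst), 3)) * span
            v[worst] = 0.0
        f = objective(x)
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g_idx = int(np.argmin(pbest_f))
        if pbest_f[g_idx] < gbest_f:
            gbest_f = float(pbest_f[g_idx])
            gbest_x = pbest_x[g_idx].copy()
        history[it] = gbest_f
    pure_rmse = float(objective(gbest_x[None, :], tie_break=0.0)[0])
    return FittedDVR(DVRParams(*gbest_x), pure_rmse, history)


@dataclass
class ELMModel:
    """Extreme learning machine mapping gene genotypes to (α, β_P, G).

    A single random hidden layer (seeded, reproducible) with sigmoid
    activation; output weights solved by ridge least squares with an
    unpenalized intercept.
    """

    seed: int
    hidden_nodes: int
    ridge: float
    x_mean: np.ndarray
    x_std: np.ndarray
    w_in: np.ndarray   # (n_features, hidden)
    b_in: np.ndarray   # (hidden,)
    w_out: np.ndarray  # (hidden + 1, 3), last row is the intercept
    target_names: tuple[str, ...] = ("alpha", "beta_p", "g")

    def hidden(self, x: np.ndarray) -> np.ndarray:
        z = (x - self.x_mean) / self.x_std
        a = z @ self.w_in + self.b_in
        return 1.0 / (1.0 + np.exp(-a))

    def predict(self, x: np.ndarray) -> np.ndarray:
        h = self.hidden(np.asarray(x, dtype=float))
        hb = np.hstack([h, np.ones((len(h), 1))])
        return hb @ self.w_out


def elm_fit(genotypes: np.ndarray, params: np.ndarray,
            settings: ELMSettings, seed: int) -> ELMModel:
    """Fit the ELM genotype→parameter map on a training panel.

    genotypes: (n_lines, n_genes) coded genotypes; params: (n_lines, 3)
    fitted (α, β_P, G).  Hidden weights are drawn from a seeded generator,
    so refitting with the same seed reproduces them exactly.
    """
    x = np.asarray(genotypes, dtype=float)
    y = np.asarray(params, dtype=float)
    if x.ndim != 2 or y.shape != (len(x), 3):
        raise ValueError("genotypes must be (n, n_genes) and params (n, 3)")
    if settings.hidden_nodes < 1:
        raise ValueError("hidden_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    x_mean = x.mean(axis=0)
    x_std = x.std(axis=0)
    x_std[x_std == 0] = 1.0
    w_in = rng.standard_normal((x.shape[1], settings.hidden_nodes))
    b_in = rng.standard_normal(settings.hidden_nodes)
    model = ELMModel(seed, settings.hidden_nodes, settings.ridge,
                     x_mean, x_std, w_in, b_in,
                     np.zeros((settings.hidden_nodes + 1, 3)))
    h = model.hidden(x)
    hb = np.hstack([h, np.ones((len(h), 1))])
    pen = np.full(hb.shape[1], settings.ridge)
    pen[-1] = 0.0  # intercept unpenalized
    model.w_out = np.linalg.solve(hb.T @ hb + np.diag(pen), hb.T @ y)
    return model


def resolve_gene_markers(marker_ids: list[str],
                         gene_marker_map: dict[str, str]) -> list[int]:
    """Column indices of the nearest-SNP proxy for each heading-date gene."""
    idx = []
    lookup = {m: i for i, m in enumerate(marker_ids)}
    for gene, snp in gene_marker_map.items():
        if snp not in lookup:
            raise KeyError(f"gene {gene}: proxy SNP {snp!r} not in marker set")
        idx.append(lookup[snp])
    return idx


def elm_predict(model: ELMModel, markers, gene_marker_map: dict[str, str],
                settings: PSOSettings = PSOSettings()) -> pd.DataFrame:
    """Predict per-line (α, β_P, G) from heading-gene proxy SNP genotypes.

    Predictions falling outside the PSO bounds box are clamped onto the
    bounds (with a warning), keeping downstream DVS simulation in the
    regime the optimizer was constrained to.
    """
    cols = resolve_gene_markers(list(markers.marker_ids), gene_marker_map)
    x = markers.codes[:, cols]
    raw = model.predict(x)
    lb = np.array([settings.alpha_bounds[0], settings.beta_bounds[0],
                   settings.g_bounds[0]])
    ub = np.array([settings.alpha_bounds[1], settings.beta_bounds[1],
                   settings.g_bounds[1]])
    clamped = np.clip(raw, lb, ub)
    if np.any(clamped != raw):
        n_out = int(np.sum(np.any(clamped != raw, axis=1)))
        warnings.warn(f"ELM predictions clamped to PSO bounds for {n_out} "
                      "line(s)")
    return pd.DataFrame(clamped, index=list(markers.line_ids),
                        columns=["alpha", "beta_p", "g"])
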