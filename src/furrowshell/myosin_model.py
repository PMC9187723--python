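"""MyoII intensity kinetics: the double-exponential model, its fit, and the
mapping from fitted excess fluorescence to the mechanical pre-stress ramp.

Background-subtracted apical MyoII fluorescence at the ventral midline rises
as a double exponential,

    I_myo(t) = I_c + I * (exp(exp((t - t0)/T) - 1) - 1),

where I_c is the constant (background plus baseline) signal, I an amplitude
in the same arbitrary fluorescence units, t0 the onset of the progressive
MyoII increase and T its characteristic time (T = 20 min for confocal-rate
movies; light-sheet movies develop twice as fast).  At t = t0 the inner
exponent is zero, so I_myo(t0) = I_c exactly: the onset time marks the
departure from baseline.

The full spatio-temporal MyoII signal separates into a row-dependent profile
times a time-dependent function; the fitted excess fluorescence
(I_myo(t) - I_c), scaled by a stress-per-intensity calibration factor,
prescribes the active pre-stress sigma_a and hence the pre-strain ramp
eps_a = sigma_a / chi_2d used by the shell solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "IntensityModelParams",
    "RowProfile",
    "eval_intensity",
    "fit_intensity",
    "decompose_signal",
    "prestress_schedule",
    "synchronize_time",
    "CONFOCAL_RATE_FACTOR",
]

# confocal movies develop at half the light-sheet rate; confocal times are
# divided by this factor after the t = 0 offset to share a common clock
CONFOCAL_RATE_FACTOR = 2.0

# guard: exp argument above which the double exponential overflows float64
_MAX_INNER = float(np.log(700.0))


@dataclass(frozen=True)
class IntensityModelParams:
    """Parameters of the double-exponential MyoII intensity model."""

    i_c: float = 4.0  # constant signal (arb)
    amplitude: float = 1.0  # I (arb)
    t_onset: float = 0.0  # t0 (min)
    tau: float = 20.0  # T, characteristic time (min)

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("characteristic time T must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.i_c, self.amplitude, self.t_onset, self.tau])


@dataclass(frozen=True)
class RowProfile:
    """Multiplicative per-row factor of the MyoII excess signal, row 0 = 1."""

    values: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) < 2:
            raise ValueError("profile needs at least two rows")
        if not np.isclose(v[0], 1.0):
            raise ValueError("profile must be normalised to 1 at row 0")

    def __call__(self, row) -> np.ndarray:
        rows = np.arange(len(self.values), dtype=float)
        return np.interp(np.abs(np.asarray(row, dtype=float)), rows, self.values, right=0.0)


def eval_intensity(params: IntensityModelParams, t) -> np.ndarray:
    """Evaluate I_myo(t) = I_c + I (exp(exp((t - t0)/T) - 1) - 1).

    Rejects times far enough beyond the onset that the double exponential
    would overflow double precision.
    """
    t = np.asarray(t, dtype=float)
    inner = (t - params.t_onset) / params.tau
    if np.any(inner > _MAX_INNER):
        bound = params.t_onset + params.tau * _MAX_INNER
        raise ValueError(f"intensity model overflows for t > {bound:.3g} min")
    return params.i_c + params.amplitude * (np.exp(np.exp(inner) - 1.0) - 1.0)


def _model_vec(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    # clipped harder than eval_intensity: wild trial parameters during the
    # fit must produce large-but-finite residuals, not overflow
    i_c, amp, t0, tau = theta
    inner = np.clip((t - t0) / tau, None, np.log(50.0))
    return i_c + amp * (np.exp(np.exp(inner) - 1.0) - 1.0)


def fit_intensity(
    t,
    intensity,
    n_starts: int = 5,
) -> tuple[IntensityModelParams, float]:
    """Fit the double-exponential model by bounded multi-start least squares.

    The fit is deterministic: starting points are taken from a fixed coarse
    grid of onset times (quantiles of the sampled interval) crossed with a
    fixed grid of characteristic times.  Returns the best-fit parameters and
    the residual sum of squares.

    Raises
    ------
    ValueError
        For fewer than 8 samples or a fit that fails to converge.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if t.ndim != 1 or len(t) < 8:
        raise ValueError("need at least 8 samples spanning the intensity rise")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    span = t[-1] - t[0]
    y_exc = max(y.max() - y.min(), 1e-12)
    t0_grid = np.quantile(t, np.linspace(0.1, 0.9, n_starts))
    tau_grid = span * np.array([0.15, 0.4, 1.0])

    best = None
    lower = [y.min() - 10 * y_exc, 0.0, t[0] - 5 * span, 1e-3 * span]
    upper = [y.max() + 10 * y_exc, 1e3 * y_exc, t[-1] + 5 * span, 1e2 * span]
    for t0 in t0_grid:
        for tau in tau_grid:
            theta0 = np.array([y.min(), 0.5 * y_exc, t0, tau])
            try:
                res = scipy.optimize.least_squares(
                    lambda th: _model_vec(th, t) - y,
                    theta0,
                    bounds=(lower, upper),
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                    max_nfev=2000,
                )
            except Exception:
                continue
            cost = 2.0 * res.cost
            if best is None or cost < best[0] - 1e-15:
                best = (cost, res.x)
    if best is None:
        raise ValueError("double-exponential fit failed from every start")
    cost, th = best
    params = IntensityModelParams(i_c=th[0], amplitude=th[1], t_onset=th[2], tau=th[3])
    return params, cost


def decompose_signal(table: pd.DataFrame, i_c: float = 4.0):
    """Rank-1 factorisation of the excess MyoII signal into profile x time.

    ``table`` must carry columns (row_index, time, intensity); intensities are
    averaged per (row, time), the constant signal ``i_c`` is subtracted, and
    the excess matrix M[row, time] is factorised as profile(row) * g(time) in
    the least-squares sense (leading SVD pair), normalised so profile(0) = 1.

    Returns (RowProfile, g as pd.Series indexed by time, relative residual).
    """
    piv = table.pivot_table(index="row_index", columns="time", values="intensity")
    if piv.shape[0] < 2 or piv.shape[1] < 2:
        raise ValueError("need at least 2 rows x 2 time points")
    if piv.isna().any().any():
        piv = piv.interpolate(axis=1, limit_direction="both")
    m = piv.to_numpy() - i_c
    norm = np.linalg.norm(m)
    if norm < 1e-12:
        raise ValueError("excess signal is identically zero")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    profile = u[:, 0] * s[0]
    g = vt[0]
    # fix sign and normalise to row 0
    if profile[0] < 0:
        profile, g = -profile, -g
    g = g * profile[0]
    profile = profile / profile[0]
    resid = np.linalg.norm(m - np.outer(profile, g)) / norm
    g_series = pd.Series(g, index=piv.columns, name="excess_time_function")
    return RowProfile(tuple(profile)), g_series, float(resid)


def prestress_schedule(
    params: IntensityModelParams,
    profile,
    scale: float,
    times,
    chi_2d: float = 50.0,
    rows=None,
):
    """Map fitted excess fluorescence onto the mechanical pre-stress ramp.

    sigma_a(row, t) = scale * profile(row) * (I_myo(t) - I_c), and the areal
    pre-strain prescribed to the solver is eps_a = sigma_a / chi_2d.

    Returns a DataFrame of eps_a with one column per row index plus an
    ``eps_midline`` column suitable for building a solver RampSchedule.
    """
    if scale <= 0:
        raise ValueError("stress-per-intensity scale must be positive")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("time grid must be non-decreasing")
    rows = np.arange(9) if rows is None else np.asarray(rows)
    excess = eval_intensity(params, times) - params.i_c
    eps_mid = scale * excess / chi_2d
    data = {"time": times, "eps_midline": eps_mid}
    prof = np.asarray(profile(rows), dtype=float)
    for r, pr in zip(rows, prof):
        data[f"eps_row_{int(r)}"] = eps_mid * pr
    return pd.DataFrame(data)


def synchronize_time(table: pd.DataFrame, modality: str = "lightsheet"):
    """Set t = 0 at 20% apical-area reduction of the five midline rows.

    The mean apical area of rows 0-4, normalised to its initial value, is
    interpolated to find the time at which it crosses 0.8; all times are
    offset by that instant.  Confocal movies develop at half the light-sheet
    rate, so their offset times are additionally divided by 2.

    Returns (t_zero, table copy with a ``time_sync`` column).
    """
    if modality not in ("lightsheet", "confocal"):
        raise ValueError("modality must be 'lightsheet' or 'confocal'")
    sel = table[table["row_index"] <= 4]
    if sel.empty:
        raise ValueError("table has no cells in rows 0-4")
    mean_area = sel.groupby("time")["apical_area"].mean().sort_index()
    rel = mean_area / mean_area.iloc[0]
    below = np.nonzero(rel.to_numpy() <= 0.8)[0]
    if len(below) == 0 or below[0] == 0:
        raise ValueError("midline area never crosses the 20% reduction mark")
    j = below[0]
    t_hi, t_lo = rel.index[j], rel.index[j - 1]
    r_hi, r_lo = rel.iloc[j], rel.iloc[j - 1]
    t_zero = t_lo + (0.8 - r_lo) * (t_hi - t_lo) / (r_hi - r_lo)

    out = table.copy()
    out["time_sync"] = out["time"] - t_zero
    if modality == "confocal":
        out["time_sync"] /= CONFOCAL_RATE_FACTOR
    return float(t_zero), out
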