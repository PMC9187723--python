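"""Seeded generators for synthetic observations.

These emulate the structure of confocal cell-tracking output during ventral
furrow formation — per-cell time series of apical area, AP/DV lengths of the
best-fit ellipse, DV distance from the ventral midline (pooled into cell
rows) and mean apical MyoII intensity — together with recoil traces for
ablation-style analyses and circle point sets for curvature oracles.  Every
generator is deterministic given its seed, and ships its ground truth so the
quantification stages can be tested against known inputs.

Default study conditions: nine cell rows on each side of the midline, cells
imaged every 30 s over ~16 min around gastrulation onset, MyoII kinetics
following the double-exponential model (I_c = 4 arb, T = 20 min confocal),
midline rows contracting while rows 6-9 expand with DV stretch beyond row 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .myosin_model import IntensityModelParams, RowProfile, eval_intensity

__all__ = [
    "GeneratorSpec",
    "default_row_profile_values",
    "generate_tracking_table",
    "generate_recoil_trace",
    "generate_circle_points",
]

# graded MyoII row profile used when none is supplied: matches the shell
# model's Gaussian profile exp(-(row/4)^2) sampled at integer rows
def default_row_profile_values(n_rows: int = 9) -> tuple:
    rows = np.arange(n_rows, dtype=float)
    return tuple(np.exp(-((rows / 4.0) ** 2)))


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions for the synthetic tracking-table generator."""

    intensity: IntensityModelParams = field(
        default_factory=lambda: IntensityModelParams(i_c=4.0, amplitude=1.0, t_onset=-8.0, tau=20.0)
    )
    profile: RowProfile = field(
        default_factory=lambda: RowProfile(default_row_profile_values())
    )
    n_rows: int = 9
    cells_per_row: int = 12
    t_start: float = -10.0  # min
    t_stop: float = 6.0
    dt: float = 0.5  # confocal stacks every 30 s
    cell_diameter_um: float = 7.0
    mean_area_um2: float = 36.0
    contraction: float = 0.55  # midline area fold-change deficit at late times
    expansion: float = 0.22  # ventro-lateral area gain at late times
    dv_stretch: float = 0.25  # DV length gain for rows >= 3
    noise_intensity: float = 0.0  # sigma of multiplicative log-normal noise
    noise_geometry: float = 0.0  # sigma (um / um^2) of additive Gaussian noise
    dropout: float = 0.0  # probability a cell's track ends early
    seed: int = 0
    area_response: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.cells_per_row < 1:
            raise ValueError("need at least 2 rows with at least 1 cell each")
        if self.noise_intensity < 0 or self.noise_geometry < 0:
            raise ValueError("noise levels must be non-negative")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


def _area_fold(spec: GeneratorSpec, rows: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Late-time contraction of midline rows, expansion around rows 6-9.

    Smooth logistic time course keyed to the MyoII onset; broadcasting over
    (rows, t) arrays of equal shape.
    """
    if spec.area_response is not None:
        return spec.area_response(rows, t)
    prof = spec.profile(rows)
    f_inf = (
        1.0
        - spec.contraction * prof
        + spec.expansion * np.exp(-(((rows - 7.0) / 2.0) ** 2))
    )
    ramp = 1.0 / (1.0 + np.exp(-(t - (spec.intensity.t_onset + 4.0)) / 2.0))
    return 1.0 + (f_inf - 1.0) * ramp


def _dv_fold(spec: GeneratorSpec, rows: np.ndarray, t: np.ndarray) -> np.ndarray:
    gain = spec.dv_stretch * np.exp(-(((rows - 6.0) / 2.5) ** 2)) * (rows >= 3)
    ramp = 1.0 / (1.0 + np.exp(-(t - (spec.intensity.t_onset + 4.0)) / 2.0))
    return 1.0 + gain * ramp


def generate_tracking_table(spec: GeneratorSpec | None = None):
    """Generate a synthetic per-cell tracking table.

    Returns ``(table, ground_truth)`` where the table has columns
    (cell_id, time, row_index, dv_distance, apical_area, len_AP, len_DV,
    intensity) and ``ground_truth`` records the seed, the injected intensity
    parameters and row profile, and the noiseless response curves.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.t_start, spec.t_stop + 0.5 * spec.dt, spec.dt)
    n_t = len(times)

    records = []
    cell_id = 0
    for row in range(spec.n_rows):
        for _ in range(spec.cells_per_row):
            base_area = spec.mean_area_um2 * rng.lognormal(0.0, 0.08)
            dv = (row + rng.uniform(-0.3, 0.3)) * spec.cell_diameter_um
            n_keep = n_t
            if spec.dropout > 0 and rng.uniform() < spec.dropout:
                n_keep = rng.integers(max(3, n_t // 2), n_t)
            tt = times[:n_keep]
            rr = np.full_like(tt, float(row))
            a_fold = _area_fold(spec, rr, tt)
            dv_fold = _dv_fold(spec, rr, tt)
            area = base_area * a_fold
            len_dv = np.sqrt(base_area) * dv_fold
            len_ap = area / len_dv
            inten = spec.intensity.i_c + spec.profile(rr) * (
                eval_intensity(spec.intensity, tt) - spec.intensity.i_c
            )
            if spec.noise_intensity > 0:
                inten = inten * rng.lognormal(0.0, spec.noise_intensity, size=n_keep)
            if spec.noise_geometry > 0:
                area = np.maximum(area + rng.normal(0, spec.noise_geometry, n_keep), 1e-3)
                len_dv = np.maximum(len_dv + rng.normal(0, 0.1 * spec.noise_geometry, n_keep), 1e-3)
                len_ap = np.maximum(len_ap + rng.normal(0, 0.1 * spec.noise_geometry, n_keep), 1e-3)
            records.append(
                pd.DataFrame(
                    dict(
                        cell_id=cell_id,
                        time=tt,
                        row_index=row,
                        dv_distance=dv,
                        apical_area=area,
                        len_AP=len_ap,
                        len_DV=len_dv,
                        intensity=inten,
                    )
                )
            )
            cell_id += 1
    table = pd.concat(records, ignore_index=True)

    rows = np.arange(spec.n_rows, dtype=float)
    ground_truth = dict(
        seed=spec.seed,
        intensity_params=dict(
            i_c=spec.intensity.i_c,
            amplitude=spec.intensity.amplitude,
            t_onset=spec.intensity.t_onset,
            tau=spec.intensity.tau,
        ),
        row_profile=list(np.asarray(spec.profile(rows))),
        area_fold_final=list(_area_fold(spec, rows, np.full_like(rows, times[-1]))),
    )
    return table, ground_truth


def generate_recoil_trace(
    d0: float,
    tau: float,
    noise: float = 0.0,
    seed: int = 0,
    t_stop: float | None = None,
    n_samples: int = 60,
):
    """Saturating-exponential recoil trace d(t) = d0 (1 - exp(-t/tau)).

    Emulates the displacement of a severed actomyosin network edge after
    ablation.  Returns ``(DataFrame(time, displacement), ground_truth)`` with
    the true initial recoil velocity d0/tau recorded.
    """
    if d0 <= 0 or tau <= 0:
        raise ValueError("d0 and tau must be positive")
    rng = np.random.default_rng(seed)
    t_stop = 5.0 * tau if t_stop is None else t_stop
    t = np.linspace(0.0, t_stop, n_samples)
    d = d0 * (1.0 - np.exp(-t / tau))
    if noise > 0:
        d = d + rng.normal(0.0, noise * d0, size=t.shape)
    trace = pd.DataFrame(dict(time=t, displacement=d))
    return trace, dict(seed=seed, d0=d0, tau=tau, max_velocity=d0 / tau)


def generate_circle_points(
    radius: float,
    arc: float = np.pi / 2,
    jitter: float = 0.0,
    seed: int = 0,
    n_points: int = 3,
):
    """Planar points on a circular arc of given radius, with optional jitter.

    Ground-truth curvature 1/radius is attached for three-point curvature
    oracles; the points are returned in arc order, centred on the bottom of
    the circle (outward reference pointing down).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    ang = np.linspace(-arc / 2, arc / 2, n_points) - np.pi / 2
    pts = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    if jitter > 0:
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    return pts, dict(seed=seed, radius=radius, curvature=1.0 / radius)
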