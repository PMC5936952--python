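"""Electrogram feature extraction and vector feature maps.

Each electrode's voltage series is reduced to twelve waveform
statistics; the nine electrodes of a multiprobe are then combined into
a fixed-length feature vector holding the per-electrode statistics,
mean spatial gradients of every statistic along x and y across the 3x3
grid, and the wavefront propagation direction estimated from relative
activation times.  Vector feature maps (VFMs) aggregate a statistic by
displacement from a known driver centre across many simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .electrogram import PROBE_SPACING, ElectrogramRecord

SCHEMA_VERSION = 2

#: Per-electrode waveform statistics, in canonical order.
ELECTRODE_FEATURE_NAMES: tuple[str, ...] = (
    "v_max",
    "v_min",
    "v_mean",
    "v_var",
    "skewness",
    "kurtosis",
    "first_stationary_idx",
    "max_abs_dvdt",
    "intensity",
    "dom_freq",
    "dom_freq_mag",
    "n_deflections",
)

#: Fraction of the window's peak |V| a sample must exceed to count as an
#: activation (used for deflection counting and activation times).
ACTIVATION_THRESHOLD = 0.25

N_ELECTRODES = 9
_GRID_STEPS = (-1, 0, 1)  # electrode grid indices, row-major (dy, dx)


def electrode_features(series: np.ndarray) -> np.ndarray:
    """Twelve waveform statistics of one electrode's voltage series.

    Skewness and kurtosis are standardized central moments (kurtosis is
    the plain fourth moment, 3 for a Gaussian); both are defined as 0
    for a constant series.  dom_freq is the index (cycles per window)
    of the largest nonzero-frequency Fourier magnitude.
    """
    v = np.asarray(series, dtype=float)
    if v.ndim != 1 or v.size < 8:
        raise ValueError("electrode series must be 1-D with at least 8 samples")
    n = v.size
    mean = v.mean()
    centred = v - mean
    var = float(np.mean(centred**2))
    if var > 1e-24:
        skew = float(np.mean(centred**3)) / var**1.5
        kurt = float(np.mean(centred**4)) / var**2
    else:
        skew = 0.0
        kurt = 0.0

    d = np.diff(v)
    max_abs_dvdt = float(np.abs(d).max())
    intensity = float(np.abs(v).sum())

    mags = np.abs(np.fft.rfft(v))
    k = int(np.argmax(mags[1:])) + 1
    dom_mag = float(mags[k])
    dom_freq = float(k) if dom_mag > 1e-12 else 0.0

    first_stat = _first_stationary_index(d)
    n_defl = _count_deflections(v)

    return np.array(
        [
            v.max(),
            v.min(),
            mean,
            var,
            skew,
            kurt,
            first_stat,
            max_abs_dvdt,
            intensity,
            dom_freq,
            dom_mag,
            n_defl,
        ]
    )


def _first_stationary_index(d: np.ndarray) -> float:
    """Index of the first local extremum (sign change or plateau of the
    first difference); 0 when the series has no interior extremum."""
    prod = d[:-1] * d[1:]
    informative = (d[:-1] != 0) | (d[1:] != 0)
    hits = np.nonzero((prod <= 0) & informative)[0]
    return float(hits[0] + 1) if hits.size else 0.0


def _count_deflections(v: np.ndarray) -> float:
    """Number of excursions of |V| above the activation threshold."""
    peak = np.abs(v).max()
    if peak <= 0:
        return 0.0
    active = np.abs(v) >= ACTIVATION_THRESHOLD * peak
    rises = int(active[0]) + int(np.count_nonzero(active[1:] & ~active[:-1]))
    return float(rises)


def activation_times(voltages: np.ndarray) -> np.ndarray:
    """First step each electrode's |V| reaches the activation threshold
    of its own window peak; NaN for a silent electrode.

    voltages has shape (duration, n_electrodes).
    """
    v = np.abs(np.asarray(voltages, dtype=float))
    peaks = v.max(axis=0)
    times = np.full(v.shape[1], np.nan)
    for e in range(v.shape[1]):
        if peaks[e] > 0:
            times[e] = float(np.argmax(v[:, e] >= ACTIVATION_THRESHOLD * peaks[e]))
    return times


def feature_gradients(feature_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean gradient of each statistic along x and y across the 3x3 grid.

    feature_grid has shape (9, n_features) in row-major (dy, dx)
    electrode order.  The gradient along x is the mean over the six
    x-adjacent electrode pairs of (right - left) / spacing; analogously
    for y, so values are per cell and zig-zag noise is averaged out.
    """
    g = np.asarray(feature_grid, dtype=float).reshape(3, 3, -1)
    grad_x = (g[:, 1:, :] - g[:, :-1, :]).mean(axis=(0, 1)) / PROBE_SPACING
    grad_y = (g[1:, :, :] - g[:-1, :, :]).mean(axis=(0, 1)) / PROBE_SPACING
    return grad_x, grad_y


def wavefront_direction(
    times: np.ndarray,
) -> tuple[float, tuple[float, float], bool]:
    """Propagation direction from a least-squares plane fit of the nine
    activation times over the electrode offsets.

    Fits t(x, y) = a x + b y + c; the wave travels towards increasing
    time, so the direction is (a, b) normalized.  Returns (angle,
    (ux, uy), ok).  ok is False (and the direction zero) when fewer
    than three electrodes activated or the times are all equal.
    """
    angle, unit, _resid, ok = _wavefront_fit(times)
    return angle, unit, ok


def _wavefront_fit(
    times: np.ndarray,
) -> tuple[float, tuple[float, float], float, bool]:
    """Plane fit of activation times: (angle, unit vector, RMS residual, ok)."""
    times = np.asarray(times, dtype=float)
    offs = np.array(
        [(dx * PROBE_SPACING, dy * PROBE_SPACING) for dy in _GRID_STEPS for dx in _GRID_STEPS],
        dtype=float,
    )
    good = np.isfinite(times)
    if good.sum() < 3 or np.ptp(times[good]) == 0:
        return 0.0, (0.0, 0.0), 0.0, False
    A = np.column_stack([offs[good, 0], offs[good, 1], np.ones(int(good.sum()))])
    coef, *_ = np.linalg.lstsq(A, times[good], rcond=None)
    resid = float(np.sqrt(np.mean((A @ coef - times[good]) ** 2)))
    a, b = float(coef[0]), float(coef[1])
    norm = np.hypot(a, b)
    if norm == 0:
        return 0.0, (0.0, 0.0), resid, False
    return float(np.arctan2(b, a)), (a / norm, b / norm), resid, True


def feature_vector_names() -> list[str]:
    names = [
        f"e{e}_{f}" for e in range(N_ELECTRODES) for f in ELECTRODE_FEATURE_NAMES
    ]
    names += [f"grad_x_{f}" for f in ELECTRODE_FEATURE_NAMES]
    names += [f"grad_y_{f}" for f in ELECTRODE_FEATURE_NAMES]
    names += ["wavefront_angle", "wavefront_ux", "wavefront_uy"]
    # cross-probe activation-time statistics: waves radiating from a
    # driver under the probe arrive non-planarly (high plane-fit
    # residual) and with a wide spread of arrival times
    names += ["wavefront_fit_residual", "activation_time_range"]
    return names


FEATURE_VECTOR_NAMES: tuple[str, ...] = tuple(feature_vector_names())


def feature_vector(record: ElectrogramRecord | np.ndarray) -> np.ndarray:
    """Fixed-length feature vector for one multiprobe recording.

    Layout (schema version 1): 9 x 12 per-electrode statistics, 12
    x-gradients, 12 y-gradients, then wavefront angle and unit vector.
    """
    volts = record.voltages if isinstance(record, ElectrogramRecord) else np.asarray(record)
    if volts.ndim != 2 or volts.shape[1] != N_ELECTRODES:
        raise ValueError("expected a (duration, 9) voltage array")
    per_elec = np.stack([electrode_features(volts[:, e]) for e in range(N_ELECTRODES)])
    grad_x, grad_y = feature_gradients(per_elec)
    times = activation_times(volts)
    angle, (ux, uy), resid, _ok = _wavefront_fit(times)
    good = np.isfinite(times)
    t_range = float(np.ptp(times[good])) if good.any() else 0.0
    return np.concatenate(
        [per_elec.ravel(), grad_x, grad_y, [angle, ux, uy, resid, t_range]]
    )


@dataclass
class VectorFeatureMap:
    """Mean of one statistic binned by displacement from the driver centre.

    means[iy, ix] is the mean feature value at displacement
    (dx, dy) = (ix - x_extent, iy - y_extent); bins with count 0 are NaN.
    """

    feature: str
    means: np.ndarray
    counts: np.ndarray
    x_extent: int
    y_extent: int

    def value_at(self, dx: int, dy: int) -> float:
        return float(self.means[dy + self.y_extent, dx + self.x_extent])

    def folded(self) -> "VectorFeatureMap":
        """Average the four mirror images so the map is symmetric across
        both axes (count-weighted; a fixed point for symmetric input)."""
        c = np.nan_to_num(self.counts)
        s = np.nan_to_num(self.means) * c
        s_sym = s + s[::-1, :] + s[:, ::-1] + s[::-1, ::-1]
        c_sym = c + c[::-1, :] + c[:, ::-1] + c[::-1, ::-1]
        with np.errstate(invalid="ignore"):
            means = np.where(c_sym > 0, s_sym / np.maximum(c_sym, 1e-300), np.nan)
        return VectorFeatureMap(
            feature=self.feature,
            means=means,
            counts=c_sym,
            x_extent=self.x_extent,
            y_extent=self.y_extent,
        )

    def to_frame(self):
        import pandas as pd

        ys, xs = np.nonzero(self.counts > 0)
        return pd.DataFrame(
            {
                "dx": xs - self.x_extent,
                "dy": ys - self.y_extent,
                "mean": self.means[ys, xs],
                "count": self.counts[ys, xs].astype(int),
            }
        )


def build_vfm(
    samples,
    feature: str,
    x_extent: int = 100,
    y_extent: int = 100,
) -> VectorFeatureMap:
    """Aggregate (displacement, features) samples into a vector feature map.

    ``samples`` yields ((dx, dy), values) pairs where values is either a
    per-electrode feature array in canonical order or a mapping with the
    named feature; displacements outside the extents are dropped.
    """
    try:
        fi = ELECTRODE_FEATURE_NAMES.index(feature)
    except ValueError:
        raise ValueError(f"unknown feature {feature!r}") from None
    shape = (2 * y_extent + 1, 2 * x_extent + 1)
    total = np.zeros(shape)
    counts = np.zeros(shape)
    n = 0
    for (dx, dy), values in samples:
        n += 1
        ix = int(round(dx)) + x_extent
        iy = int(round(dy)) + y_extent
        if not (0 <= ix < shape[1] and 0 <= iy < shape[0]):
            continue
        value = values[fi] if not isinstance(values, dict) else values[feature]
        total[iy, ix] += float(value)
        counts[iy, ix] += 1
    if n == 0:
        raise ValueError("build_vfm requires at least one sample")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, total / np.maximum(counts, 1e-300), np.nan)
    return VectorFeatureMap(
        feature=feature, means=means, counts=counts, x_extent=x_extent, y_extent=y_extent
    )
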