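"""Tabularizations of sequence tensors for MLP models.

Three schemes summarize each time-dynamic channel of an imputed tensor:

* ``TAB_P`` — 10th/50th/90th percentiles per channel, plus the end-of-window
  cumulative total for medication channels;
* ``TAB_F`` — the three Hjorth parameters (activity, mobility, complexity)
  plus the full-depth orthonormal Haar wavelet coefficients;
* ``TAB_T`` — the raw time steps vectorized channel-major, time-minor.

Static features are appended without aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .preprocess import CUMULATIVE_SUFFIX, SequenceTensor, StaticMatrix

__all__ = ["TabularMatrix", "haar_coeffs", "hjorth", "tab_f", "tab_p", "tab_t"]


@dataclass
class TabularMatrix:
    values: np.ndarray  # (m, d)
    column_names: list[str]
    surgery_ids: list

    def __post_init__(self):
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column count mismatch")
        if np.isnan(self.values).any():
            raise ValueError("tabular matrix must be computed post-imputation")


def _check_imputed(tensor: SequenceTensor) -> None:
    if np.isnan(tensor.values).any():
        raise ValueError("tensor contains missing values; impute first")
    if tensor.n_steps < 1:
        raise ValueError("tensor has no time steps")


def _append_statics(values, names, statics: StaticMatrix | None):
    if statics is None or not statics.feature_names:
        return values, names
    return (
        np.concatenate([values, statics.values], axis=1),
        names + list(statics.feature_names),
    )


def tab_p(tensor: SequenceTensor, statics: StaticMatrix | None = None) -> TabularMatrix:
    """Percentile aggregation; linear interpolation between order statistics."""
    _check_imputed(tensor)
    cols, names = [], []
    for j, name in enumerate(tensor.channel_names):
        series = tensor.values[:, j, :]
        for q in (10, 50, 90):
            cols.append(np.percentile(series, q, axis=1))
            names.append(f"{name}__p{q}")
        if name.endswith(CUMULATIVE_SUFFIX):
            cols.append(series[:, -1])  # administered total over the window
            names.append(f"{name}__total")
    values, names = _append_statics(np.column_stack(cols), names, statics)
    return TabularMatrix(values, names, list(tensor.surgery_ids))


def hjorth(series: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity of a 1-D series.

    Activity is the population variance; mobility is
    ``sqrt(var(diff(x)) / var(x))``; complexity is the mobility of the first
    difference divided by the mobility of the series.  A zero-variance
    series returns (0, 0, 0).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("hjorth requires a 1-D series of length >= 3")
    var_x = x.var()
    if var_x == 0:
        return (0.0, 0.0, 0.0)
    d1 = np.diff(x)
    var_d1 = d1.var()
    mobility = np.sqrt(var_d1 / var_x)
    if var_d1 == 0:
        return (float(var_x), float(mobility), 0.0)
    d2 = np.diff(d1)
    mobility_d1 = np.sqrt(d2.var() / var_d1)
    return (float(var_x), float(mobility), float(mobility_d1 / mobility))


def _pad_pow2(x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    target = 1 << (n - 1).bit_length()
    if target == n:
        return x
    pad = np.repeat(x[..., -1:], target - n, axis=-1)
    return np.concatenate([x, pad], axis=-1)


def haar_coeffs(series: np.ndarray) -> np.ndarray:
    """Full-depth orthonormal Haar transform, level order (approximation
    first, then details coarse to fine).

    The series is padded to the next power of two by repeating its last
    value, so the transform is orthonormal and energy-preserving on the
    padded samples.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if x.size == 1:
        return x.copy()
    x = _pad_pow2(x)
    coeffs = pywt.wavedec(x, "haar", mode="periodization")
    return np.concatenate(coeffs)


def tab_f(tensor: SequenceTensor, statics: StaticMatrix | None = None) -> TabularMatrix:
    """Signal-feature aggregation: Hjorth parameters + Haar coefficients."""
    _check_imputed(tensor)
    n = tensor.n_steps
    n_pad = 1 << (n - 1).bit_length() if n > 1 else 1
    cols, names = [], []
    for j, name in enumerate(tensor.channel_names):
        series = tensor.values[:, j, :]
        hj = np.array([hjorth(row) for row in series])
        cols.append(hj)
        names += [f"{name}__activity", f"{name}__mobility", f"{name}__complexity"]
        hc = np.array([haar_coeffs(row) for row in series])
        cols.append(hc)
        names += [f"{name}__haar{i}" for i in range(n_pad)]
    values, names = _append_statics(np.concatenate(cols, axis=1), names, statics)
    return TabularMatrix(values, names, list(tensor.surgery_ids))


def tab_t(tensor: SequenceTensor, statics: StaticMatrix | None = None) -> TabularMatrix:
    """Vectorize the grid channel-major, time-minor: k x n -> k*n columns."""
    _check_imputed(tensor)
    m, k, n = tensor.values.shape
    values = tensor.values.reshape(m, k * n)
    names = [f"{name}__t{t}" for name in tensor.channel_names for t in range(n)]
    values, names = _append_statics(values, names, statics)
    return TabularMatrix(values, names, list(tensor.surgery_ids))
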