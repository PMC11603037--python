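"""From event tables to model-ready tensors.

The fixed pipeline order is: range cleaning (in :mod:`trapod.data`) ->
composite merging -> resampling to the grid -> cumulative dose channels ->
missingness indicators -> LOCF/mean imputation -> z-scaling on training
statistics.  The observation mask is computed at resampling time and never
altered by imputation.

Windows follow the intraoperative timing convention: endpoints in minutes
relative to anesthesia begin (T_begin = 0) or anesthesia end (T_end), e.g.
``[T_begin, 30]`` is the first intraoperative 30 minutes and ``[-30, T_end]``
the last 30.  Bins are left-closed half-open intervals anchored at the
window start; observations in a bin are mean-aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import FeatureSpec, validate_specs

__all__ = [
    "ObservationWindow",
    "ScalerStats",
    "SequenceTensor",
    "StaticMatrix",
    "add_missing_indicators",
    "apply_scaler",
    "assemble_inputs",
    "broadcast_static",
    "cumulative_doses",
    "fit_scaler",
    "impute",
    "merge_composites",
    "parse_window",
    "resample_to_grid",
    "resolve_window",
]

INDICATOR_SUFFIX = "__missing"
CUMULATIVE_SUFFIX = "__cum"


# ---------------------------------------------------------------------------
# Windows


@dataclass(frozen=True)
class ObservationWindow:
    """W = [Tx, Ty]: endpoints in minutes anchored at anesthesia begin
    (``from_begin``) or anesthesia end (``from_end``)."""

    anchor_x: str
    t_x: float
    anchor_y: str
    t_y: float

    def __post_init__(self):
        for a in (self.anchor_x, self.anchor_y):
            if a not in ("from_begin", "from_end"):
                raise ValueError(f"bad anchor {a!r}")

    def __str__(self):
        def fmt(anchor, t):
            return f"{t:g}" if anchor == "from_begin" else f"end{t:+g}" if t else "end"

        return f"[{fmt(self.anchor_x, self.t_x)},{fmt(self.anchor_y, self.t_y)}]"


def parse_window(text: str) -> ObservationWindow:
    """Parse ``"0:30"``, ``"-30:end"``, ``"begin:end"`` or ``"full"``.

    Bare numbers are minutes from T_begin; per the timing convention a
    negative number anchors to T_end; the tokens ``begin`` and ``end`` name
    the phase boundaries themselves.
    """
    text = text.strip()
    if text == "full":
        return ObservationWindow("from_begin", 0.0, "from_end", 0.0)

    def tok(s: str) -> tuple[str, float]:
        s = s.strip()
        if s == "begin":
            return "from_begin", 0.0
        if s == "end":
            return "from_end", 0.0
        v = float(s)
        return ("from_end", v) if v < 0 else ("from_begin", v)

    try:
        a, b = text.split(":")
    except ValueError as e:
        raise ValueError(f"cannot parse window {text!r}") from e
    ax, tx = tok(a)
    ay, ty = tok(b)
    return ObservationWindow(ax, tx, ay, ty)


def resolve_window(window: ObservationWindow, t_end: float) -> tuple[float, float]:
    """Resolve to a concrete half-open ``[start, end)`` for one surgery."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    start = window.t_x + (t_end if window.anchor_x == "from_end" else 0.0)
    end = window.t_y + (t_end if window.anchor_y == "from_end" else 0.0)
    if start >= end:
        raise ValueError(f"window {window} resolves to empty [{start}, {end}) "
                         f"for t_end={t_end}")
    return start, end


# ---------------------------------------------------------------------------
# Containers


@dataclass
class SequenceTensor:
    """Surgeries x channels x time-steps values with an observation mask.

    ``mask`` is 1 where the bin held no observation.  Before imputation,
    such bins are NaN in ``values``; after imputation no NaN remains but the
    mask is untouched.
    """

    values: np.ndarray  # (m, k, n)
    mask: np.ndarray  # (m, k, n), 1 = no observation
    channel_names: list[str]
    surgery_ids: list
    interval_min: float

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length mismatch")

    @property
    def n_surgeries(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[2]

    def channel(self, name: str) -> int:
        return self.channel_names.index(name)

    def copy(self) -> "SequenceTensor":
        return SequenceTensor(
            self.values.copy(), self.mask.copy(), list(self.channel_names),
            list(self.surgery_ids), self.interval_min,
        )


@dataclass
class StaticMatrix:
    values: np.ndarray  # (m, k)
    feature_names: list[str]
    surgery_ids: list

    def copy(self) -> "StaticMatrix":
        return StaticMatrix(self.values.copy(), list(self.feature_names),
                            list(self.surgery_ids))


@dataclass
class ScalerStats:
    """Per-channel mean/sd for z-scaling and per-channel training means for
    imputation; computed from training surgeries only."""

    mean: dict = field(default_factory=dict)  # channel -> float
    sd: dict = field(default_factory=dict)
    impute_mean: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Resampling


def resample_to_grid(
    events: pd.DataFrame,
    window: ObservationWindow,
    interval_min: float,
    channels: list[str],
    surgery_ids: list,
    t_end: dict,
) -> SequenceTensor:
    """Mean-aggregate observations into ``interval_min`` bins over the window.

    The number of steps is ``floor(window_length / interval)`` using the
    *shortest* resolved window across surgeries when anchors mix begin/end;
    with consistent anchors every surgery resolves to the same length except
    the full-phase window, where the per-surgery window is truncated to the
    common grid.  Empty bins are NaN with mask 1.
    """
    lengths = [resolve_window(window, t_end[s])[1] - resolve_window(window, t_end[s])[0]
               for s in surgery_ids]
    n = int(np.floor(min(lengths) / interval_min))
    if n < 1:
        raise ValueError("window shorter than one sampling interval")
    m, k = len(surgery_ids), len(channels)
    sums = np.zeros((m, k, n))
    counts = np.zeros((m, k, n))
    sid_index = {s: i for i, s in enumerate(surgery_ids)}
    ch_index = {c: j for j, c in enumerate(channels)}

    ev = events[
        events["surgery_id"].isin(sid_index)
        & events["feature_name"].isin(ch_index)
        & events["value"].notna()
    ]
    starts = {s: resolve_window(window, t_end[s])[0] for s in surgery_ids}
    srs = ev["surgery_id"].map(sid_index).to_numpy()
    chs = ev["feature_name"].map(ch_index).to_numpy()
    t0 = ev["surgery_id"].map(starts).to_numpy(dtype=float)
    rel = ev["t_offset_min"].to_numpy(dtype=float) - t0
    bins = np.floor(rel / interval_min).astype(int)
    ok = (bins >= 0) & (bins < n)
    vals = ev["value"].to_numpy(dtype=float)
    np.add.at(sums, (srs[ok], chs[ok], bins[ok]), vals[ok])
    np.add.at(counts, (srs[ok], chs[ok], bins[ok]), 1.0)

    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mask = (counts == 0).astype(np.int8)
    return SequenceTensor(values, mask, list(channels), list(surgery_ids), interval_min)


# ---------------------------------------------------------------------------
# Composites, cumulative doses, indicators


def merge_composites(events: pd.DataFrame, specs: list[FeatureSpec]) -> pd.DataFrame:
    """Append composite event streams (concatenation of member rows).

    Member streams are retained alongside the composite, so models can still
    distinguish the sources."""
    by_name = validate_specs(specs)
    extra = []
    for spec in specs:
        if not spec.composite_of:
            continue
        members = events[events["feature_name"].isin(spec.composite_of)]
        if members.empty:
            continue
        comp = members.copy()
        comp["feature_name"] = spec.name
        extra.append(comp)
    if not extra:
        return events.copy()
    return pd.concat([events, *extra], ignore_index=True)


def cumulative_doses(tensor: SequenceTensor, specs: list[FeatureSpec]) -> SequenceTensor:
    """Append a running-sum channel for each cumulative (medication) feature.

    Empty bins contribute 0; the cumulative channel is never missing and
    restarts at 0 at the window start."""
    by_name = {s.name: s for s in specs}
    out = tensor.copy()
    for name in list(tensor.channel_names):
        spec = by_name.get(name)
        if spec is None or not spec.cumulative:
            continue
        j = out.channel(name)
        per_bin = np.where(out.mask[:, j, :] == 1, 0.0, out.values[:, j, :])
        if (per_bin < 0).any():
            raise ValueError(f"negative dose in cumulative feature {name!r}")
        cum = np.cumsum(per_bin, axis=1)
        out.values = np.concatenate([out.values, cum[:, None, :]], axis=1)
        out.mask = np.concatenate(
            [out.mask, np.zeros_like(cum[:, None, :], dtype=np.int8)], axis=1
        )
        out.channel_names.append(name + CUMULATIVE_SUFFIX)
    return out


def add_missing_indicators(
    tensor: SequenceTensor, specs: list[FeatureSpec]
) -> SequenceTensor:
    """Append a binary channel equal to the observation mask for each feature
    flagged ``missing_indicator`` (1 = value missing in that bin)."""
    by_name = {s.name: s for s in specs}
    out = tensor.copy()
    for name in list(tensor.channel_names):
        spec = by_name.get(name)
        if spec is None or not spec.missing_indicator:
            continue
        j = out.channel(name)
        ind = out.mask[:, j, :].astype(float)
        out.values = np.concatenate([out.values, ind[:, None, :]], axis=1)
        out.mask = np.concatenate(
            [out.mask, np.zeros_like(ind[:, None, :], dtype=np.int8)], axis=1
        )
        out.channel_names.append(name + INDICATOR_SUFFIX)
    return out


# ---------------------------------------------------------------------------
# Imputation and scaling


def fit_scaler(tensor: SequenceTensor, statics: StaticMatrix | None = None) -> ScalerStats:
    """Channel means/SDs from training surgeries (observed bins only for the
    imputation means; all post-imputation values would bias toward LOCF)."""
    stats = ScalerStats()
    for j, name in enumerate(tensor.channel_names):
        vals = tensor.values[:, j, :]
        obs = vals[~np.isnan(vals)]
        stats.impute_mean[name] = float(obs.mean()) if obs.size else 0.0
    # scaling statistics are computed on the imputed training tensor
    imputed = impute(tensor, stats)
    for j, name in enumerate(imputed.channel_names):
        vals = imputed.values[:, j, :]
        stats.mean[name] = float(vals.mean())
        stats.sd[name] = float(vals.std())
    if statics is not None:
        for j, name in enumerate(statics.feature_names):
            col = statics.values[:, j]
            obs = col[~np.isnan(col)]
            mu = float(obs.mean()) if obs.size else 0.0
            stats.impute_mean[name] = mu
            filled = np.where(np.isnan(col), mu, col)
            stats.mean[name] = float(filled.mean())
            stats.sd[name] = float(filled.std())
    return stats


def impute(tensor: SequenceTensor, scaler: ScalerStats) -> SequenceTensor:
    """LOCF within each surgery x channel series; bins before the first
    observation (and all-missing series) get the training-set channel mean.
    LOCF does not carry values in from outside the window."""
    out = tensor.copy()
    m, k, n = out.values.shape
    for j, name in enumerate(out.channel_names):
        if name not in scaler.impute_mean:
            raise KeyError(f"scaler has no statistics for channel {name!r}")
        vals = out.values[:, j, :]
        missing = np.isnan(vals)
        if not missing.any():
            continue
        # vectorized LOCF: index of last observed bin at or before each bin
        idx = np.where(~missing, np.arange(n)[None, :], -1)
        idx = np.maximum.accumulate(idx, axis=1)
        filled = np.where(
            idx >= 0,
            np.take_along_axis(
                np.where(missing, 0.0, vals), np.maximum(idx, 0), axis=1
            ),
            scaler.impute_mean[name],
        )
        out.values[:, j, :] = filled
    return out


def apply_scaler(data: SequenceTensor | StaticMatrix, scaler: ScalerStats):
    """z-transform with training statistics; zero-SD channels map to 0."""
    if not scaler.mean:
        raise RuntimeError("scaler has not been fitted")
    out = data.copy()
    names = out.channel_names if isinstance(out, SequenceTensor) else out.feature_names
    for j, name in enumerate(names):
        if name not in scaler.mean:
            raise KeyError(f"scaler has no statistics for channel {name!r}")
        mu, sd = scaler.mean[name], scaler.sd[name]
        if isinstance(out, SequenceTensor):
            col = out.values[:, j, :]
        else:
            col = out.values[:, j]
        col = np.where(np.isnan(col), scaler.impute_mean[name], col)
        scaled = (col - mu) / sd if sd > 0 else np.zeros_like(col)
        if isinstance(out, SequenceTensor):
            out.values[:, j, :] = scaled
        else:
            out.values[:, j] = scaled
    return out


def broadcast_static(statics: StaticMatrix, n_steps: int) -> SequenceTensor:
    """Turn each static feature into a constant-in-time channel."""
    vals = np.repeat(statics.values[:, :, None], n_steps, axis=2)
    mask = np.zeros_like(vals, dtype=np.int8)
    return SequenceTensor(vals, mask, list(statics.feature_names),
                          list(statics.surgery_ids), np.nan)


def concat_tensors(a: SequenceTensor, b: SequenceTensor) -> SequenceTensor:
    if a.surgery_ids != b.surgery_ids or a.n_steps != b.n_steps:
        raise ValueError("tensors are not aligned")
    return SequenceTensor(
        np.concatenate([a.values, b.values], axis=1),
        np.concatenate([a.mask, b.mask], axis=1),
        a.channel_names + b.channel_names,
        list(a.surgery_ids),
        a.interval_min,
    )


# ---------------------------------------------------------------------------
# End-to-end assembly


def statics_matrix(statics: pd.DataFrame, surgery_ids: list,
                   feature_names: list[str]) -> StaticMatrix:
    df = statics.set_index("surgery_id").loc[surgery_ids]
    return StaticMatrix(
        df[feature_names].to_numpy(dtype=float), list(feature_names), list(surgery_ids)
    )


def assemble_inputs(
    events: pd.DataFrame,
    statics: pd.DataFrame,
    specs: list[FeatureSpec],
    window: ObservationWindow,
    interval_min: float,
    surgery_ids: list,
    t_end: dict,
    scaler: ScalerStats | None = None,
    include_statics_as_channels: bool = False,
    scale: bool = True,
) -> tuple[SequenceTensor, StaticMatrix, ScalerStats]:
    """Run composites -> resample -> cumulative -> indicators -> impute ->
    scale and return the sequence tensor, the static matrix, and the scaler.

    When ``scaler`` is None it is fitted on the given surgeries, which must
    then be the training split.
    """
    by_name = validate_specs(specs)
    dynamic = [s.name for s in specs if s.is_dynamic]
    static_names = [
        s.name for s in specs
        if not s.is_dynamic and s.name in statics.columns
    ]
    ev = merge_composites(events, specs)
    tensor = resample_to_grid(ev, window, interval_min, dynamic, surgery_ids, t_end)
    tensor = cumulative_doses(tensor, specs)
    tensor = add_missing_indicators(tensor, specs)
    stat = statics_matrix(statics, surgery_ids, static_names)
    if scaler is None:
        scaler = fit_scaler(tensor, stat)
    tensor = impute(tensor, scaler)
    if scale:
        tensor = apply_scaler(tensor, scaler)
        stat = apply_scaler(stat, scaler)
    if include_statics_as_channels and static_names:
        tensor = concat_tensors(tensor, broadcast_static(stat, tensor.n_steps))
    return tensor, stat, scaler
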