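"""Flow-cytometry quantification of a fluorescent recombination reporter.

The readout is the fraction of cells whose reporter fluorescence exceeds
a negative-control-derived threshold, restricted to a scatter gate that
encloses a fixed fraction of events:

1. a 2-D kernel density estimate over (FSC-H, SSC-H) gates the densest
   40% of events of each sample;
2. samples whose gate centroid is far from the rest of the experiment
   (median/MAD screen) are flagged as outliers;
3. the ON/OFF threshold is the 99.9th percentile of the gated
   fluorescence of an empty-vector negative control;
4. fraction-ON = gated events strictly above the threshold / gated events.

Event tables are plain CSV with columns FSC-H, SSC-H and one
fluorescence channel (default FL1-H); no compensation or transformation
is applied — thresholds act on raw intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EventTable",
    "GateRegion",
    "SwitchResult",
    "DEFAULT_CHANNELS",
    "kde_gate",
    "flag_outlier_samples",
    "negative_threshold",
    "fraction_on",
    "summarize_groups",
    "compare_conditions",
    "read_events_csv",
]

DEFAULT_CHANNELS: Mapping[str, str] = {"fsc": "FSC-H", "ssc": "SSC-H", "fl": "FL1-H"}


@dataclass
class EventTable:
    """List-mode events for one sample plus its metadata."""

    data: pd.DataFrame
    sample_id: str = "sample"
    experiment_id: Optional[str] = None
    role: str = "test"  # "test" or "negative_control"
    channels: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNELS))

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("event table is empty")
        for key in ("fsc", "ssc", "fl"):
            col = self.channels[key]
            if col not in self.data.columns:
                raise ValueError(f"channel {key!r} -> {col!r} not in event table columns")
            if not np.all(np.isfinite(self.data[col].to_numpy(dtype=float))):
                raise ValueError(f"non-finite values in channel {col!r}")

    @property
    def fsc(self) -> np.ndarray:
        return self.data[self.channels["fsc"]].to_numpy(dtype=float)

    @property
    def ssc(self) -> np.ndarray:
        return self.data[self.channels["ssc"]].to_numpy(dtype=float)

    @property
    def fl(self) -> np.ndarray:
        return self.data[self.channels["fl"]].to_numpy(dtype=float)


@dataclass
class GateRegion:
    """Density gate over scatter space for one sample."""

    in_gate: np.ndarray
    density_threshold: float
    centroid: tuple[float, float]
    polygon: Optional[np.ndarray]
    sample_id: str = "sample"
    experiment_id: Optional[str] = None

    @property
    def n_gated(self) -> int:
        return int(self.in_gate.sum())


@dataclass
class SwitchResult:
    sample_id: str
    threshold: float
    fraction_on: float
    n_gated: int
    outlier_flag: bool = False


def _silverman_bandwidths(fsc: np.ndarray, ssc: np.ndarray) -> tuple[float, float]:
    # per-axis Silverman rule for a 2-D product kernel: h_j = sigma_j * n^(-1/6)
    n = fsc.size
    h = np.array([fsc.std(ddof=1), ssc.std(ddof=1)]) * n ** (-1.0 / 6.0)
    if np.any(h <= 0) or not np.all(np.isfinite(h)):
        raise ValueError("degenerate scatter: zero variance on an axis")
    return float(h[0]), float(h[1])


def _product_kde(
    qx: np.ndarray, qy: np.ndarray, fsc: np.ndarray, ssc: np.ndarray, hx: float, hy: float
) -> np.ndarray:
    """Gaussian product-kernel density of (fsc, ssc) at query points, chunked."""
    n = fsc.size
    norm = 1.0 / (n * 2.0 * math.pi * hx * hy)
    out = np.empty(qx.size)
    chunk = max(1, int(4e6 // max(n, 1)) + 1)
    for start in range(0, qx.size, chunk):
        sl = slice(start, start + chunk)
        dx = (qx[sl, None] - fsc[None, :]) / hx
        dy = (qy[sl, None] - ssc[None, :]) / hy
        out[sl] = np.exp(-0.5 * (dx * dx + dy * dy)).sum(axis=1)
    return out * norm


def kde_gate(
    events: EventTable,
    target_fraction: float = 0.40,
    bandwidth_rule: str = "silverman",
    grid_resolution: int = 64,
) -> GateRegion:
    """Gate the densest ``target_fraction`` of events in scatter space.

    A Gaussian product-kernel density over (FSC-H, SSC-H) is evaluated at
    every event; exactly ``ceil(target_fraction * n)`` highest-density
    events are gated (ties broken by input order).  The density contour
    at the resulting threshold is returned as a display polygon.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    fsc, ssc = events.fsc, events.ssc
    n = fsc.size
    if n < 10:
        raise ValueError("need at least 10 events to gate")
    if bandwidth_rule != "silverman":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    hx, hy = _silverman_bandwidths(fsc, ssc)

    density = _product_kde(fsc, ssc, fsc, ssc, hx, hy)
    m = math.ceil(target_fraction * n)
    order = np.argsort(-density, kind="stable")  # stable: ties keep input order
    gated_idx = order[:m]
    d_star = float(density[order[m - 1]])
    in_gate = np.zeros(n, dtype=bool)
    in_gate[gated_idx] = True

    centroid = (float(fsc[in_gate].mean()), float(ssc[in_gate].mean()))
    polygon = _contour_polygon(fsc, ssc, hx, hy, d_star, grid_resolution)
    return GateRegion(
        in_gate=in_gate,
        density_threshold=d_star,
        centroid=centroid,
        polygon=polygon,
        sample_id=events.sample_id,
        experiment_id=events.experiment_id,
    )


def _contour_polygon(fsc, ssc, hx, hy, level, grid_resolution):
    """Display-only gate perimeter: the KDE contour at the gate threshold."""
    from skimage import measure

    pad_x, pad_y = 3 * hx, 3 * hy
    gx = np.linspace(fsc.min() - pad_x, fsc.max() + pad_x, grid_resolution)
    gy = np.linspace(ssc.min() - pad_y, ssc.max() + pad_y, grid_resolution)
    gxx, gyy = np.meshgrid(gx, gy)
    dens = _product_kde(gxx.ravel(), gyy.ravel(), fsc, ssc, hx, hy).reshape(gxx.shape)
    contours = measure.find_contours(dens, level)
    if not contours:
        return None
    longest = max(contours, key=len)
    # map (row, col) grid indices back to data coordinates
    xs = np.interp(longest[:, 1], np.arange(grid_resolution), gx)
    ys = np.interp(longest[:, 0], np.arange(grid_resolution), gy)
    return np.column_stack([xs, ys])


def flag_outlier_samples(
    gates: Sequence[GateRegion], mad_cutoff: float = 5.0
) -> dict[str, bool]:
    """Screen gate centroids per experiment with a median/MAD rule.

    Within each experiment the median and MAD of the centroids are taken
    per scatter axis; a sample deviating by more than ``mad_cutoff`` MADs
    on either axis is flagged.  A zero MAD flags nothing on that axis.
    Automates the study's by-eye screen for gates of unexpected position.
    """
    by_expt: dict = {}
    for g in gates:
        by_expt.setdefault(g.experiment_id, []).append(g)
    flags: dict[str, bool] = {}
    for expt, group in by_expt.items():
        if len(group) < 3:
            raise ValueError(
                f"experiment {expt!r} has {len(group)} samples; need >= 3 for outlier screening"
            )
        cent = np.array([g.centroid for g in group])
        flagged = np.zeros(len(group), dtype=bool)
        for axis in range(2):
            med = np.median(cent[:, axis])
            mad = np.median(np.abs(cent[:, axis] - med))
            if mad == 0:
                continue
            flagged |= np.abs(cent[:, axis] - med) > mad_cutoff * mad
        for g, f in zip(group, flagged):
            flags[g.sample_id] = bool(f)
    return flags


def negative_threshold(
    negative: EventTable, gate: GateRegion, percentile: float = 99.9
) -> float:
    """ON/OFF threshold: empirical percentile of gated negative-control FL.

    Linear interpolation between closest order statistics (the numpy
    default).  Requires the sample to carry the negative-control role
    and at least 100 gated events.
    """
    if negative.role != "negative_control":
        raise ValueError(
            f"sample {negative.sample_id!r} in experiment {negative.experiment_id!r} "
            "is not a negative control"
        )
    values = negative.fl[gate.in_gate]
    if values.size < 100:
        raise ValueError(f"only {values.size} gated events; need >= 100")
    return float(np.percentile(values, percentile))


def fraction_on(sample: EventTable, gate: GateRegion, threshold: float) -> SwitchResult:
    """Fraction of gated events with fluorescence strictly above threshold."""
    fl = sample.fl[gate.in_gate]
    return SwitchResult(
        sample_id=sample.sample_id,
        threshold=float(threshold),
        fraction_on=float((fl > threshold).mean()),
        n_gated=int(fl.size),
    )


def summarize_groups(groups: Mapping[str, Sequence]) -> pd.DataFrame:
    """Per-condition mean, s.e.m. (sd/sqrt(n), sample sd) and n.

    Values may be floats or :class:`SwitchResult`; a single-value group
    gets NaN s.e.m.
    """
    rows = []
    for condition, values in groups.items():
        vals = np.asarray(
            [v.fraction_on if isinstance(v, SwitchResult) else float(v) for v in values]
        )
        if vals.size == 0:
            raise ValueError(f"empty group {condition!r}")
        sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else float("nan")
        rows.append({"condition": condition, "mean": float(vals.mean()), "sem": sem, "n": vals.size})
    return pd.DataFrame(rows)


def compare_conditions(
    group_a: Sequence[float], group_b: Sequence[float], method: str = "t_test"
) -> tuple[float, float]:
    """Two-sided comparison of two groups: Welch t-test or rank-sum.

    The rank-sum test is exact (full enumeration) for combined n <= 20
    and uses the normal approximation above that.  Two zero-variance
    groups with equal means give (0, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if method == "t_test":
        if a.size < 2 or b.size < 2:
            raise ValueError("t_test needs >= 2 values per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            return 0.0, 1.0
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if method == "wilcoxon":
        if a.size < 1 or b.size < 1:
            raise ValueError("wilcoxon needs >= 1 value per group")
        mode = "exact" if a.size + b.size <= 20 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=mode)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def read_events_csv(
    path,
    sample_id: str = "sample",
    experiment_id: Optional[str] = None,
    role: str = "test",
    channels: Optional[Mapping[str, str]] = None,
) -> EventTable:
    """Load a CSV event table (columns named per the channel map)."""
    data = pd.read_csv(path)
    return EventTable(
        data=data,
        sample_id=sample_id,
        experiment_id=experiment_id,
        role=role,
        channels=dict(channels) if channels else dict(DEFAULT_CHANNELS),
    )
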