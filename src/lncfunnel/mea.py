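"""Multielectrode-array activity metrics.

Implements the per-well analysis chain for extracellular recordings:
spike detection with an adaptive threshold of six standard deviations of
the per-electrode noise (noise estimated as MAD / 0.6745, robust to the
spikes themselves), single-electrode burst detection (>= 5 spikes with
all inter-spike intervals <= 100 ms), network-burst detection on the
pooled trains of active electrodes (>= 50 pooled spikes, pooled ISIs
<= 100 ms, participation strictly above 35% of active electrodes), a
pairwise cross-correlogram synchrony index (area within a +/- 10 ms
central window of the unit-normalized correlogram over a 1 s lag span),
and a composite neural activity score (NAS) formed as the unweighted
mean of five batch min-max-normalized metrics.

"Active electrode" (>= 5 spikes per minute) and the correlogram span,
bin and NAS weighting are not standardized by MEA vendors; the defaults
here are explicit, documented choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeRaster",
    "Burst",
    "NetworkBurst",
    "WellMetrics",
    "detect_spikes",
    "mean_firing_rate",
    "detect_bursts",
    "detect_network_bursts",
    "synchrony_index",
    "neural_activity_score",
    "compute_well_metrics",
]


@dataclass
class SpikeRaster:
    """Per-electrode sorted spike times over one recording."""

    electrode_ids: list[str]
    spikes: dict[str, np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for e in self.electrode_ids:
            t = np.asarray(self.spikes.get(e, ()), dtype=float)
            if t.size and ((t < 0).any() or (t > self.duration).any()):
                raise ValueError(f"electrode {e!r} has spikes outside [0, duration]")
            if t.size > 1 and not (np.diff(t) > 0).all():
                raise ValueError(f"electrode {e!r} spike times not strictly increasing")
            self.spikes[e] = t

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    def total_spikes(self) -> int:
        return int(sum(self.spikes[e].size for e in self.electrode_ids))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# duration_s={self.duration}\n")
            fh.write("electrode_id,spike_time_s\n")
            for e in self.electrode_ids:
                for t in self.spikes[e]:
                    fh.write(f"{e},{t:.6f}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpikeRaster":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# duration_s="):
                raise ValueError("raster CSV must start with '# duration_s=' line")
            duration = float(header.split("=", 1)[1])
            df = pd.read_csv(fh)
        spikes = {
            str(e): np.sort(g["spike_time_s"].to_numpy())
            for e, g in df.groupby("electrode_id")
        }
        return cls(sorted(spikes), spikes, duration)


@dataclass(frozen=True)
class Burst:
    electrode: str
    start: float
    end: float
    n_spikes: int


@dataclass(frozen=True)
class NetworkBurst:
    start: float
    end: float
    n_spikes: int
    participating: frozenset[str]


@dataclass(frozen=True)
class WellMetrics:
    mean_firing_rate: float
    burst_frequency: float
    network_burst_frequency: float
    synchrony_index: float
    active_fraction: float


METRIC_NAMES = [
    "mean_firing_rate",
    "burst_frequency",
    "network_burst_frequency",
    "synchrony_index",
    "active_fraction",
]


def detect_spikes(
    traces: Mapping[str, np.ndarray], fs: float, k: float = 6.0
) -> SpikeRaster:
    """Threshold-crossing spike detection on voltage traces.

    Per electrode the noise scale is estimated as MAD/0.6745 after median
    subtraction; samples with |v - median| strictly above k * sigma are
    spike candidates, and candidates within a 1 ms refractory window
    collapse to the absolute peak.  Electrodes with sigma below 1e-12
    (e.g. an all-constant trace) yield no spikes.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    refractory = max(1, int(round(1e-3 * fs)))
    spikes: dict[str, np.ndarray] = {}
    duration = 0.0
    for e, v in traces.items():
        v = np.asarray(v, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite sample in trace {e!r}")
        duration = max(duration, v.size / fs)
        med = np.median(v)
        dev = np.abs(v - med)
        sigma = np.median(dev) / 0.6745
        if sigma < 1e-12:
            spikes[e] = np.empty(0)
            continue
        above = np.nonzero(dev > k * sigma)[0]
        times = []
        i = 0
        while i < above.size:
            j = i
            while j + 1 < above.size and above[j + 1] - above[j] <= refractory:
                j += 1
            group = above[i : j + 1]
            peak = group[np.argmax(dev[group])]
            times.append(peak / fs)
            i = j + 1
        spikes[e] = np.asarray(times)
    return SpikeRaster(list(traces), spikes, duration if duration > 0 else 1.0)


def mean_firing_rate(raster: SpikeRaster) -> tuple[pd.Series, float]:
    """Per-electrode firing rate (Hz) and the well mean over all
    electrodes, silent ones included."""
    rates = pd.Series(
        {e: raster.spikes[e].size / raster.duration for e in raster.electrode_ids},
        dtype=float,
    )
    return rates, float(rates.mean()) if len(rates) else 0.0


def _isi_runs(times: np.ndarray, isi_max: float) -> list[tuple[int, int]]:
    """Maximal runs [i, j] (inclusive) of consecutive spikes with every
    successive ISI <= isi_max."""
    if times.size == 0:
        return []
    breaks = np.nonzero(np.diff(times) > isi_max)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [times.size - 1]])
    return list(zip(starts, ends))


def detect_bursts(
    train: Sequence[float] | np.ndarray,
    min_spikes: int = 5,
    isi_max: float = 0.1,
    electrode: str = "",
) -> list[Burst]:
    """Single-electrode bursts: maximal runs of >= min_spikes spikes whose
    successive ISIs are all <= isi_max (inclusive)."""
    t = np.asarray(train, dtype=float)
    if t.size > 1 and not (np.diff(t) > 0).all():
        raise ValueError("spike train must be sorted strictly increasing")
    return [
        Burst(electrode, float(t[i]), float(t[j]), int(j - i + 1))
        for i, j in _isi_runs(t, isi_max)
        if j - i + 1 >= min_spikes
    ]


def active_electrodes(
    raster: SpikeRaster, active_rule: float = 5.0
) -> list[str]:
    """Electrodes firing at >= active_rule spikes per minute."""
    per_min = 60.0 / raster.duration
    return [
        e
        for e in raster.electrode_ids
        if raster.spikes[e].size * per_min >= active_rule
    ]


def detect_network_bursts(
    raster: SpikeRaster,
    min_spikes: int = 50,
    isi_max: float = 0.1,
    participation_min: float = 0.35,
    active_rule: float = 5.0,
) -> list[NetworkBurst]:
    """Network bursts on the pooled spike train of active electrodes.

    A maximal pooled run with ISIs <= isi_max qualifies when it contains
    >= min_spikes spikes and the electrodes contributing to it are
    strictly more than participation_min of the active electrodes.
    """
    active = active_electrodes(raster, active_rule)
    if not active:
        logger.warning("no active electrodes; no network bursts")
        return []
    times = np.concatenate([raster.spikes[e] for e in active])
    labels = np.concatenate(
        [np.full(raster.spikes[e].size, i) for i, e in enumerate(active)]
    )
    order = np.argsort(times, kind="stable")
    times, labels = times[order], labels[order]
    out: list[NetworkBurst] = []
    for i, j in _isi_runs(times, isi_max):
        n = j - i + 1
        if n < min_spikes:
            continue
        members = np.unique(labels[i : j + 1])
        if members.size > participation_min * len(active):
            out.append(
                NetworkBurst(
                    float(times[i]),
                    float(times[j]),
                    int(n),
                    frozenset(active[m] for m in members),
                )
            )
    return out


def synchrony_index(
    raster: SpikeRaster,
    window: float = 0.020,
    span: float = 1.0,
    bin: float = 0.001,
) -> float:
    """Mean over electrode pairs of the central area of the unit-
    normalized pairwise cross-correlogram.

    For each pair, all spike-time differences within +/- span/2 are
    histogrammed at the given bin; the pair's index is the fraction of
    that mass within +/- window/2.  1.0 for identical trains, ~window/span
    for independent Poisson trains.
    """
    nonempty = [e for e in raster.electrode_ids if raster.spikes[e].size > 0]
    if len(nonempty) < 2:
        raise ValueError("synchrony index needs >= 2 electrodes with spikes")
    half_span, half_win = span / 2, window / 2
    indices = []
    for i in range(len(nonempty)):
        ta = raster.spikes[nonempty[i]]
        for j in range(i + 1, len(nonempty)):
            tb = raster.spikes[nonempty[j]]
            lo = np.searchsorted(tb, ta - half_span, side="left")
            hi = np.searchsorted(tb, ta + half_span, side="right")
            total = 0
            central = 0
            for a, l, h in zip(ta, lo, hi):
                if h <= l:
                    continue
                diffs = tb[l:h] - a
                # assign to 1 ms lag bins; count the central window bins
                bins = np.floor(diffs / bin)
                total += diffs.size
                central += int(
                    np.count_nonzero((bins >= -half_win / bin) & (bins < half_win / bin))
                )
            if total > 0:
                indices.append(central / total)
    if not indices:
        return 0.0
    return float(np.mean(indices))


def neural_activity_score(metrics: pd.DataFrame) -> pd.Series:
    """Composite NAS per well: unweighted mean of the five metrics after
    min-max normalization across the wells of the batch (a metric that is
    constant across wells contributes 0)."""
    if metrics.empty:
        raise ValueError("need at least one well")
    missing = set(METRIC_NAMES) - set(metrics.columns)
    if missing:
        raise ValueError(f"missing metric columns: {sorted(missing)}")
    normed = pd.DataFrame(index=metrics.index)
    for name in METRIC_NAMES:
        col = metrics[name].astype(float)
        span = col.max() - col.min()
        normed[name] = 0.0 if span == 0 else (col - col.min()) / span
    return normed.mean(axis=1).rename("nas")


def compute_well_metrics(
    raster: SpikeRaster,
    min_spikes: int = 5,
    isi_max: float = 0.1,
    nb_min_spikes: int = 50,
    participation_min: float = 0.35,
    active_rule: float = 5.0,
) -> WellMetrics:
    """All five raw well-level metrics from one raster."""
    _, mfr = mean_firing_rate(raster)
    n_bursts = sum(
        len(detect_bursts(raster.spikes[e], min_spikes, isi_max, electrode=e))
        for e in raster.electrode_ids
    )
    n_nb = len(
        detect_network_bursts(
            raster, nb_min_spikes, isi_max, participation_min, active_rule
        )
    )
    try:
        sync = synchrony_index(raster)
    except ValueError:
        sync = 0.0
    n_active = len(active_electrodes(raster, active_rule))
    return WellMetrics(
        mean_firing_rate=mfr,
        burst_frequency=n_bursts / raster.duration,
        network_burst_frequency=n_nb / raster.duration,
        synchrony_index=sync,
        active_fraction=n_active / max(raster.n_electrodes, 1),
    )
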