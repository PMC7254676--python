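"""Collective-activity observables.

Network bursts are detected from the population-activity signal (number of
unique neurons spiking within the trailing 1 s window) with a Schmitt
trigger: a burst opens when the signal reaches 10% of the active-neuron
count and closes when it falls below 5%.  Bursts closer than 0.5 s are
merged and bursts with fewer than 10 participants are discarded.  A culture
is deemed bursty when its mean inter-burst interval (onset-to-onset) is
below 45 s.

An *active* neuron is a neuron-labelled ROI with at least ``theta_active``
(default 2) reconstructed spikes per recording; the percentage-active
denominator is all cell ROIs (neuron or silent labels, i.e. glia excluded).

An *independent* spike is more than one frame (50 ms at 20 fps) away from
any other spike anywhere in the system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkBurst",
    "ActivitySummary",
    "activity_signal",
    "schmitt_trigger",
    "detect_network_bursts",
    "activity_summary",
    "independent_spike_fraction",
    "count_active",
    "BURSTY_IBI_CUTOFF_S",
]

BURSTY_IBI_CUTOFF_S = 45.0


@dataclass
class NetworkBurst:
    onset_frame: int
    offset_frame: int
    participants: frozenset
    spikes_per_participant: float
    duration_s: float

    @property
    def n_participants(self) -> int:
        return len(self.participants)


def activity_signal(raster: np.ndarray, window_frames: int) -> np.ndarray:
    """Per frame, the number of unique neurons spiking in the trailing window
    (current frame inclusive)."""
    raster = np.atleast_2d(raster).astype(bool)
    n, T = raster.shape
    t_idx = np.arange(T)
    last = np.where(raster, t_idx[None, :], -window_frames - 1)
    last = np.maximum.accumulate(last, axis=1)
    covered = last >= (t_idx[None, :] - (window_frames - 1))
    return covered.sum(axis=0)


def schmitt_trigger(signal: np.ndarray, hi: float, lo: float) -> list[tuple[int, int]]:
    """Hysteresis segmentation: open at signal >= hi, close at signal < lo.

    Returns [onset, offset] frame pairs, offset = last frame with
    signal >= lo in the episode.
    """
    episodes = []
    open_ = False
    onset = 0
    for t, v in enumerate(signal):
        if not open_ and v >= hi:
            open_ = True
            onset = t
        elif open_ and v < lo:
            episodes.append((onset, t - 1))
            open_ = False
    if open_:
        episodes.append((onset, len(signal) - 1))
    return episodes


def count_active(raster: np.ndarray, theta_active: int = 2) -> int:
    return int((np.atleast_2d(raster).sum(axis=1) >= theta_active).sum())


def _participants(raster: np.ndarray, onset: int, offset: int) -> frozenset:
    return frozenset(np.flatnonzero(raster[:, onset : offset + 1].any(axis=1)).tolist())


def detect_network_bursts(
    raster: np.ndarray,
    frame_rate: float,
    n_active: int | None = None,
    window_s: float = 1.0,
    hi_frac: float = 0.10,
    lo_frac: float = 0.05,
    merge_gap_s: float = 0.5,
    min_participants: int = 10,
    theta_active: int = 2,
) -> list[NetworkBurst]:
    """Schmitt-trigger network-burst detection on a spike raster.

    Threshold percentages are relative to the recording's active-neuron
    count (``n_active``; computed from the raster if not given).
    """
    raster = np.atleast_2d(raster).astype(bool)
    if raster.size == 0 or not raster.any():
        return []
    if n_active is None:
        n_active = count_active(raster, theta_active)
    if n_active == 0:
        return []
    window_frames = max(1, round(window_s * frame_rate))
    signal = activity_signal(raster, window_frames)
    episodes = schmitt_trigger(signal, hi_frac * n_active, lo_frac * n_active)
    # the burst interval includes the trailing window that raised the signal
    # over threshold, so the spikes that ignited the burst are inside it
    episodes = [
        (max(0, onset - (window_frames - 1)), offset) for onset, offset in episodes
    ]
    # merge bursts whose intervals are separated by less than merge_gap_s
    merge_gap = merge_gap_s * frame_rate
    merged: list[list[int]] = []
    for onset, offset in episodes:
        if merged and onset - merged[-1][1] < merge_gap:
            merged[-1][1] = max(offset, merged[-1][1])
        else:
            merged.append([onset, offset])
    bursts = []
    for onset, offset in merged:
        parts = _participants(raster, onset, offset)
        if len(parts) < min_participants:
            continue
        n_spikes = int(raster[sorted(parts), onset : offset + 1].sum())
        bursts.append(
            NetworkBurst(
                onset_frame=onset,
                offset_frame=offset,
                participants=parts,
                spikes_per_participant=n_spikes / len(parts),
                duration_s=(offset - onset + 1) / frame_rate,
            )
        )
    return bursts


def independent_spike_fraction(raster: np.ndarray) -> float:
    """Fraction of spikes with no other spike within +/- 1 frame system-wide.

    Same-neuron coincidences on adjacent frames count like any other spike;
    a neuron cannot spike twice in one frame (binary raster), so no
    same-neuron exclusion is needed on the centre frame.
    """
    raster = np.atleast_2d(raster).astype(bool)
    total = int(raster.sum())
    if total == 0:
        return math.nan
    per_frame = raster.sum(axis=0)
    window = per_frame.copy()
    window[:-1] += per_frame[1:]
    window[1:] += per_frame[:-1]
    # a spike is independent iff the 3-frame window holds only itself
    independent = int(per_frame[(window == 1) & (per_frame == 1)].sum())
    return independent / total


@dataclass
class ActivitySummary:
    percent_active: float
    percent_in_bursts: float  # per-burst mean of 100 * participants / active
    mean_ibi: float  # onset-to-onset, s; NaN when < 2 bursts
    burst_duration: float  # mean detected burst duration, s
    burst_amplitude: float  # mean spikes per participating neuron per burst
    global_rate: float  # total spikes / duration, spikes/s
    independent_fraction: float  # percent
    bursty: bool
    n_bursts: int
    n_active: int
    n_cells: int
    per_neuron_rate: np.ndarray = field(repr=False, default=None)
    per_neuron_isi: np.ndarray = field(repr=False, default=None)
    per_neuron_burst_rate: np.ndarray = field(repr=False, default=None)
    per_neuron_burst_ibi: np.ndarray = field(repr=False, default=None)


def _single_cell_bursts(
    spike_frames: np.ndarray, frame_rate: float, max_gap_s: float = 1.0
) -> tuple[int, float]:
    """Group a neuron's spikes into events (gaps <= max_gap_s); events with
    >= 2 spikes are single-cell bursts.  Returns (n_bursts, mean IBI)."""
    if spike_frames.size < 2:
        return 0, math.nan
    gaps = np.diff(spike_frames) / frame_rate
    starts = np.flatnonzero(np.concatenate([[True], gaps > max_gap_s]))
    sizes = np.diff(np.concatenate([starts, [spike_frames.size]]))
    burst_starts = spike_frames[starts[sizes >= 2]]
    if burst_starts.size < 2:
        return int((sizes >= 2).sum()), math.nan
    return int((sizes >= 2).sum()), float(np.mean(np.diff(burst_starts)) / frame_rate)


def activity_summary(
    raster: np.ndarray,
    labels: np.ndarray,
    bursts: list[NetworkBurst],
    frame_rate: float,
    theta_active: int = 2,
) -> ActivitySummary:
    """Fig.-1-style observables from a reconstructed raster.

    ``raster`` has one row per ROI (rows of non-neuron ROIs all zero);
    ``labels`` holds the per-ROI class (neuron/glia/silent).
    """
    raster = np.atleast_2d(raster).astype(bool)
    labels = np.asarray(labels).astype(str)
    n_rois, T = raster.shape
    duration = T / frame_rate

    is_neuron = labels == "neuron"
    is_cell = is_neuron | (labels == "silent")
    spike_counts = raster.sum(axis=1)
    active_mask = is_neuron & (spike_counts >= theta_active)
    n_active = int(active_mask.sum())
    n_cells = int(is_cell.sum())
    percent_active = 100.0 * n_active / n_cells if n_cells else math.nan

    if len(bursts) >= 1 and n_active > 0:
        pct_in = float(
            np.mean([100.0 * b.n_participants / n_active for b in bursts])
        )
        amp = float(np.mean([b.spikes_per_participant for b in bursts]))
        dur = float(np.mean([b.duration_s for b in bursts]))
    else:
        pct_in = math.nan
        amp = math.nan
        dur = math.nan
    if len(bursts) >= 2:
        onsets = np.array([b.onset_frame for b in bursts]) / frame_rate
        mean_ibi = float(np.mean(np.diff(onsets)))
    else:
        mean_ibi = math.nan

    total_spikes = int(raster.sum())
    indep = independent_spike_fraction(raster)

    rates = spike_counts / duration
    isi = np.full(n_rois, math.nan)
    burst_rate = np.full(n_rois, math.nan)
    burst_ibi = np.full(n_rois, math.nan)
    for i in np.flatnonzero(active_mask):
        frames = np.flatnonzero(raster[i])
        if frames.size >= 2:
            isi[i] = float(np.mean(np.diff(frames)) / frame_rate)
        nb, ibi = _single_cell_bursts(frames, frame_rate)
        burst_rate[i] = nb / duration
        burst_ibi[i] = ibi

    return ActivitySummary(
        percent_active=percent_active,
        percent_in_bursts=pct_in,
        mean_ibi=mean_ibi,
        burst_duration=dur,
        burst_amplitude=amp,
        global_rate=total_spikes / duration,
        independent_fraction=100.0 * indep if not math.isnan(indep) else math.nan,
        bursty=bool(not math.isnan(mean_ibi) and mean_ibi < BURSTY_IBI_CUTOFF_S),
        n_bursts=len(bursts),
        n_active=n_active,
        n_cells=n_cells,
        per_neuron_rate=rates,
        per_neuron_isi=isi,
        per_neuron_burst_rate=burst_rate,
        per_neuron_burst_ibi=burst_ibi,
    )
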