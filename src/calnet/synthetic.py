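"""Ground-truth culture generator.

Generates everything the analysis chain consumes, with known ground truth:

* a planted modular directed network over the active neurons,
* a spike raster containing scheduled network bursts plus an out-of-burst
  background of isolated spikes,
* calcium fluorescence traces (normalized and raw, with baseline drift), and
* optionally a rendered fluorescence movie for the ROI-detection stage.

Burst model
-----------
Burst onsets follow a renewal process with gamma-distributed inter-onset
intervals (shape ``ibi_shape``, mean ``mean_ibi``), giving a unimodal IBI
distribution.  Each burst opens with a synchronous *ignition volley* --
``ceil(0.1 * n_active) + ignition_margin`` participants spiking on the onset
frame -- which guarantees that a 10%-threshold trigger opens exactly at the
onset; the remaining participants spike within the following
``burst_duration`` seconds.  Participants are drawn with probability weighted
3:1 (``intra_weight``) towards the burst's home module, so co-bursting carries
the planted community structure into the inferred effective network.

Background model
----------------
Out-of-burst spikes are a time-homogeneous point process: the spike *count*
is Poisson with rate ``independent_rate`` per active neuron, but spike frames
are placed with a minimum spacing of 3 frames from each other and from burst
windows, so that background spikes are genuinely isolated (no other spike
within +/-1 frame anywhere in the system).  A plain Poisson placement cannot
reach high isolated fractions at realistic global rates: isolated spikes need
pairwise separation >= 2 frames, so their number is hard-bounded by half the
frame count, and chance coincidences at a few spikes/s would otherwise
reclassify most of the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import GeneratorParams

__all__ = [
    "GroundTruthCulture",
    "make_ground_truth_network",
    "simulate_raster",
    "render_traces",
    "render_movie",
    "disk_layout",
    "RenderedTraces",
]

ROLE_NEURON = "neuron"
ROLE_SILENT = "silent"
ROLE_GLIA = "glia"


def make_ground_truth_network(
    n_neurons: int,
    n_modules: int,
    p_intra: float,
    p_inter: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted-partition directed graph.

    Returns ``(adjacency, module_labels)`` where ``adjacency[i, j]`` is True
    for an edge i -> j (no self-loops) and module labels are balanced within
    one neuron.
    """
    if n_neurons < 1 or n_modules < 1:
        raise ValueError("n_neurons and n_modules must be >= 1")
    if n_modules > n_neurons:
        raise ValueError("n_modules cannot exceed n_neurons")
    for p in (p_intra, p_inter):
        if not 0.0 <= p <= 1.0:
            raise ValueError("edge probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = np.sort(np.arange(n_neurons) % n_modules)
    same = labels[:, None] == labels[None, :]
    p_matrix = np.where(same, p_intra, p_inter)
    adj = rng.random((n_neurons, n_neurons)) < p_matrix
    np.fill_diagonal(adj, False)
    return adj, labels


@dataclass
class GroundTruthCulture:
    """A generated culture with full ground truth."""

    params: GeneratorParams
    roles: np.ndarray  # per-ROI role: neuron / silent / glia
    active_ids: np.ndarray  # ROI indices of active (spiking) neurons
    network: np.ndarray  # directed adjacency over active neurons
    module_labels: np.ndarray  # module label per active neuron
    raster: np.ndarray  # bool (n_rois, n_frames); spikes on active rows only
    burst_schedule: list[tuple[float, float, frozenset]] = field(
        default_factory=list
    )  # (onset s, offset s, participant ROI ids)
    n_burst_spikes: int = 0
    n_background_spikes: int = 0
    trace_seed: int = 0

    @property
    def n_frames(self) -> int:
        return self.raster.shape[1]


def _burst_onsets(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Gamma-renewal burst onset times (s), clear of the recording edges."""
    if not np.isfinite(params.mean_ibi) or params.mean_ibi <= 0:
        return np.empty(0)
    shape = params.ibi_shape
    scale = params.mean_ibi / shape
    onsets = []
    t = rng.uniform(0.0, params.mean_ibi)
    margin = params.burst_duration + 2.0 / params.frame_rate
    while t < params.duration - margin:
        onsets.append(t)
        t += rng.gamma(shape, scale)
    return np.asarray(onsets)


def _place_background(
    n_spikes: int,
    n_frames: int,
    forbidden: np.ndarray,
    rng: np.random.Generator,
    spacing: int = 3,
) -> np.ndarray:
    """Place ``n_spikes`` frames with pairwise spacing >= ``spacing``.

    Falls back to spacing 2, then to arbitrary free frames, if the request
    saturates the hard-core packing limit.
    """
    occupied = forbidden.copy()
    chosen: list[int] = []
    for gap in range(spacing - 1, -1, -1):
        if len(chosen) >= n_spikes:
            break
        candidates = rng.permutation(np.flatnonzero(~occupied))
        for f in candidates:
            if len(chosen) >= n_spikes:
                break
            lo, hi = max(0, f - gap), min(n_frames, f + gap + 1)
            if occupied[lo:hi].any():
                continue
            chosen.append(int(f))
            occupied[f] = True
    return np.asarray(sorted(chosen), dtype=np.int64)


def simulate_raster(
    params: GeneratorParams,
    network: np.ndarray | None = None,
    seed: int | None = None,
) -> GroundTruthCulture:
    """Generate a ground-truth culture (network, burst schedule, raster)."""
    if seed is not None:
        params = params.with_seed(seed)
    rng = np.random.default_rng(params.seed)
    n_frames = params.n_frames
    fr = params.frame_rate
    n_active = params.n_active

    # per-culture variability (optional): jitter rate-like parameters
    if params.culture_cv > 0:
        from dataclasses import replace

        jitter = rng.normal(1.0, params.culture_cv, size=3).clip(0.2, 3.0)
        params = replace(
            params,
            mean_ibi=params.mean_ibi * jitter[0],
            independent_rate=params.independent_rate * jitter[1],
            burst_participation=min(1.0, params.burst_participation * jitter[2]),
        )

    # role assignment over ROIs
    order = rng.permutation(params.n_rois)
    roles = np.empty(params.n_rois, dtype=object)
    roles[order[: params.n_glia]] = ROLE_GLIA
    active_ids = np.sort(order[params.n_glia : params.n_glia + n_active])
    roles[active_ids] = ROLE_NEURON
    silent_ids = order[params.n_glia + n_active :]
    roles[silent_ids] = ROLE_SILENT

    # planted network over active neurons
    if network is None:
        net_seed = int(rng.integers(2**31 - 1))
        network, module_labels = make_ground_truth_network(
            n_active, max(1, params.n_modules), params.p_intra, params.p_inter, net_seed
        )
    else:
        network = np.asarray(network, dtype=bool)
        if network.shape != (n_active, n_active):
            raise ValueError(
                f"network shape {network.shape} does not match the "
                f"{n_active} active neurons implied by the parameters"
            )
        module_labels = np.sort(np.arange(n_active) % max(1, params.n_modules))

    raster = np.zeros((params.n_rois, n_frames), dtype=bool)
    burst_frames_mask = np.zeros(n_frames, dtype=bool)
    schedule: list[tuple[float, float, frozenset]] = []
    n_burst_spikes = 0

    n_participants = round(params.burst_participation * n_active)
    onsets = _burst_onsets(params, rng) if n_participants > 0 else np.empty(0)
    w_frames = max(1, round(params.burst_duration * fr))
    volley = min(
        n_participants, int(np.ceil(0.1 * n_active)) + params.ignition_margin
    )
    module_weight = np.ones(n_active)

    for onset_s in onsets:
        f0 = round(onset_s * fr)
        if f0 + w_frames + 1 >= n_frames:
            continue
        home = int(rng.integers(max(1, params.n_modules)))
        weights = np.where(module_labels == home, params.intra_weight, module_weight)
        p = weights / weights.sum()
        part_local = rng.choice(n_active, size=n_participants, replace=False, p=p)
        part_rois = active_ids[part_local]
        # ignition volley on the onset frame, followers within the window
        raster[part_rois[:volley], f0] = True
        n_spikes_each = np.ones(n_participants, dtype=int)
        if params.spikes_per_burst_neuron > 1:
            extra = params.spikes_per_burst_neuron - 1.0
            n_spikes_each += rng.binomial(2, min(1.0, extra / 2.0), n_participants)
        for j, roi in enumerate(part_rois):
            k = n_spikes_each[j] - (1 if j < volley else 0)
            if k <= 0:
                continue
            offs = rng.integers(1, w_frames + 1, size=k)
            raster[roi, f0 + offs] = True
        n_burst = int(raster[part_rois, f0 : f0 + w_frames + 1].sum())
        n_burst_spikes += n_burst
        lo = max(0, f0 - 2)
        hi = min(n_frames, f0 + w_frames + 3)
        burst_frames_mask[lo:hi] = True
        schedule.append(
            (float(onset_s), float(onset_s + params.burst_duration), frozenset(part_rois))
        )

    # isolated background spikes
    n_background = 0
    if params.independent_rate > 0 and n_active > 0:
        target = params.independent_rate * n_active * params.duration
        n_bg = int(rng.poisson(target))
        frames = _place_background(n_bg, n_frames, burst_frames_mask, rng)
        neurons = active_ids[rng.integers(0, n_active, size=frames.size)]
        raster[neurons, frames] = True
        n_background = frames.size

    return GroundTruthCulture(
        params=params,
        roles=roles,
        active_ids=active_ids,
        network=network,
        module_labels=module_labels,
        raster=raster,
        burst_schedule=schedule,
        n_burst_spikes=n_burst_spikes,
        n_background_spikes=n_background,
        trace_seed=int(rng.integers(2**31 - 1)),
    )


@dataclass
class RenderedTraces:
    """Fluorescence traces of a culture, raw and normalized scale."""

    raw: np.ndarray  # camera units, includes baseline, drift and noise
    normalized: np.ndarray  # %dF/F0, signal + noise (ideal baseline removal)
    clean: np.ndarray  # %dF/F0, noiseless signal
    f0_true: np.ndarray  # true baseline (camera units), per ROI x frame
    frame_rate: float


def render_traces(
    culture: GroundTruthCulture, noiseless: bool = False
) -> RenderedTraces:
    """Render per-ROI fluorescence from the spike raster.

    Each spike adds ``A * exp(-t / tau)`` (%dF/F0) by linear superposition.
    Glia get slow large-amplitude waves, silent ROIs only noise.  The raw
    trace is ``baseline * (1 + (signal + drift + noise) / 100)`` with a slow
    two-sinusoid plus reflected-random-walk drift.
    """
    p = culture.params
    rng = np.random.default_rng(culture.trace_seed)
    n, T = culture.raster.shape
    fr = p.frame_rate
    t = np.arange(T) / fr

    clean = np.zeros((n, T), dtype=np.float64)
    # calcium kernel via a first-order AR filter: exact A * g^k superposition
    g = np.exp(-1.0 / (p.kernel_decay * fr))
    from scipy.signal import lfilter

    spiking = np.flatnonzero(culture.raster.any(axis=1))
    if spiking.size:
        clean[spiking] = lfilter(
            [p.kernel_amplitude], [1.0, -g], culture.raster[spiking].astype(np.float64), axis=1
        )

    glia_rows = np.flatnonzero(culture.roles == ROLE_GLIA)
    for i in glia_rows:
        amp = rng.uniform(5.0, 20.0)
        period = rng.uniform(25.0, 35.0)
        phase = rng.uniform(0, 2 * np.pi)
        wave = 0.5 * amp * (1.0 + np.sin(2 * np.pi * t / period + phase))
        clean[i] = wave

    # slow drift: two sinusoids (120 s, 300 s) + reflected random walk
    phases = rng.uniform(0, 2 * np.pi, size=(n, 2))
    drift = p.drift_amplitude * (
        0.5 * np.sin(2 * np.pi * t[None, :] / 120.0 + phases[:, :1])
        + 0.3 * np.sin(2 * np.pi * t[None, :] / 300.0 + phases[:, 1:])
    )
    if p.drift_amplitude > 0:
        walk = np.cumsum(
            rng.normal(0.0, p.drift_amplitude / np.sqrt(T) / 4, (n, T)), axis=1
        )
        half = p.drift_amplitude / 2
        walk = half - np.abs(np.mod(walk + half, 4 * half) - 2 * half)  # reflect
        drift = drift + walk

    sd = 0.0 if noiseless else p.noise_sd
    noise = rng.normal(0.0, sd, size=(n, T)) if sd > 0 else np.zeros((n, T))

    baseline = p.baseline_level * rng.uniform(0.8, 1.2, size=(n, 1))
    f0_true = baseline * (1.0 + drift / 100.0)
    raw = baseline * (1.0 + (clean + drift + noise) / 100.0)
    normalized = clean + noise
    return RenderedTraces(
        raw=raw, normalized=normalized, clean=clean, f0_true=f0_true, frame_rate=fr
    )


def disk_layout(
    n_rois: int,
    image_size: tuple[int, int],
    radius: int = 4,
    seed: int = 0,
    jitter: int = 1,
) -> list[np.ndarray]:
    """Jittered-grid layout of disk footprints; each entry is (k, 2) pixel coords."""
    h, w = image_size
    pitch = int(np.ceil(np.sqrt(h * w / max(1, n_rois))))
    pitch = max(pitch, 2 * radius + 3)
    rng = np.random.default_rng(seed)
    centers = []
    for r in range(radius + 1, h - radius - 1, pitch):
        for c in range(radius + 1, w - radius - 1, pitch):
            centers.append((r, c))
    if len(centers) < n_rois:
        raise ValueError(
            f"image {image_size} too small for {n_rois} footprints of radius {radius}"
        )
    centers = [centers[i] for i in rng.permutation(len(centers))[:n_rois]]
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = np.argwhere(dy**2 + dx**2 <= radius**2) - radius
    footprints = []
    for r, c in centers:
        rr = r + int(rng.integers(-jitter, jitter + 1))
        cc = c + int(rng.integers(-jitter, jitter + 1))
        pix = disk + (rr, cc)
        if (pix < 0).any() or (pix[:, 0] >= h).any() or (pix[:, 1] >= w).any():
            pix = disk + (r, c)
        footprints.append(pix)
    return footprints


def vignette_field(
    image_size: tuple[int, int], base: float = 100.0, amplitude: float = 60.0
) -> np.ndarray:
    """Smooth illumination field rising radially from the (0, 0) corner.

    Camera fields of view are never flat; the detector's 20-30 percentile
    normalization expects the image intensity spread to be dominated by such
    smooth structure (a flat noise-only background clips to a near-binary
    image and defeats it).  Somas placed in the dim portion of the field sit
    below the normalization band and segment cleanly.
    """
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r2 = (yy**2 + xx**2) / (h**2 + w**2)
    return base + amplitude * r2


def render_movie(
    traces_raw: np.ndarray,
    layout: list[np.ndarray],
    image_size: tuple[int, int],
    seed: int = 0,
    background: float | np.ndarray = 100.0,
    pixel_noise_sd: float = 2.0,
) -> np.ndarray:
    """Render a movie (frames, h, w) from raw traces and ROI footprints.

    Each frame is background + footprint x trace + pixel noise; the
    background may be a scalar or a 2-D illumination field (see
    :func:`vignette_field`).  Footprints must lie inside the image.
    """
    n, T = traces_raw.shape
    if len(layout) != n:
        raise ValueError("one footprint per trace is required")
    h, w = image_size
    for pix in layout:
        if (pix < 0).any() or (pix[:, 0] >= h).any() or (pix[:, 1] >= w).any():
            raise ValueError("footprint outside image bounds")
    rng = np.random.default_rng(seed)
    bg = np.broadcast_to(np.asarray(background, dtype=np.float32), (h, w))
    movie = bg[None, :, :] + rng.normal(
        0.0, pixel_noise_sd, size=(T, h, w)
    ).astype(np.float32)
    for i, pix in enumerate(layout):
        movie[:, pix[:, 0], pix[:, 1]] += traces_raw[i][:, None].astype(np.float32)
    np.clip(movie, 0.0, None, out=movie)
    return movie
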