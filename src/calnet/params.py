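"""Generator parameters and named culture presets.

A :class:`GeneratorParams` bundles everything the synthetic-culture generator
needs: field-of-view composition (ROIs, glia fraction, active fraction),
recording geometry (duration, frame rate), burst scheduling (mean inter-burst
interval, participation, burst duration), the out-of-burst background rate,
the planted modular network, and the calcium-transient kernel used to render
fluorescence.

Presets (``WT-STR``, ``HD-STR``, ``WT-CTX``, ``HD-CTX``, ``BIC-like``,
``NMDA-like``) live in ``presets.toml`` next to this module and are calibrated
so that the *measured* observables of the full analysis chain (active %, IBI,
global rate, independent-spike fraction, per-burst participation) land on the
documented target values. Each preset also carries a ``targets`` table with
the expected mean and SEM of every observable, used by recovery tests.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any

__all__ = ["GeneratorParams", "get_preset", "preset_targets", "list_presets"]


@dataclass
class GeneratorParams:
    """Parameters of one synthetic culture.

    Fractions are in [0, 1]; times in seconds; rates in spikes/s;
    fluorescence amplitudes in %dF/F0.
    """

    n_rois: int = 800
    frac_active: float = 0.14
    frac_glia: float = 0.10
    duration: float = 600.0
    frame_rate: float = 20.0
    mean_ibi: float = 17.0
    burst_participation: float = 0.22
    burst_duration: float = 0.2
    spikes_per_burst_neuron: float = 1.0
    independent_rate: float = 0.05
    n_modules: int = 4
    p_intra: float = 0.30
    p_inter: float = 0.01
    kernel_amplitude: float = 1.0
    kernel_decay: float = 3.0
    noise_sd: float = 0.2
    drift_amplitude: float = 2.0
    seed: int = 0
    # shape of the gamma-distributed inter-onset intervals (renewal process)
    ibi_shape: float = 4.0
    # weight ratio for drawing burst participants from the burst's home module
    intra_weight: float = 3.0
    # ignition volley = ceil(0.1 * n_active) + ignition_margin synchronous
    # spikes at burst onset, guaranteeing the trigger opens on the onset frame
    ignition_margin: int = 4
    # culture-level variability multiplier (0 = identical cultures per preset)
    culture_cv: float = 0.0
    # mean resting fluorescence, arbitrary camera units
    baseline_level: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("frac_active", "frac_glia", "burst_participation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        n_frames = self.duration * self.frame_rate
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("duration * frame_rate must be an integer frame count")
        if self.kernel_amplitude <= 0 or self.kernel_decay <= 0:
            raise ValueError("calcium kernel amplitude and decay must be positive")

    # -- derived counts -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return round(self.duration * self.frame_rate)

    @property
    def n_glia(self) -> int:
        return round(self.frac_glia * self.n_rois)

    @property
    def n_cells(self) -> int:
        """ROIs that are cells (neuron or silent), i.e. everything but glia."""
        return self.n_rois - self.n_glia

    @property
    def n_active(self) -> int:
        return round(self.frac_active * self.n_cells)

    def with_seed(self, seed: int) -> "GeneratorParams":
        return replace(self, seed=int(seed))


def _load_preset_file() -> dict[str, Any]:
    text = resources.files("calnet").joinpath("presets.toml").read_text()
    return tomllib.loads(text)


_PRESET_CACHE: dict[str, Any] | None = None


def _presets() -> dict[str, Any]:
    global _PRESET_CACHE
    if _PRESET_CACHE is None:
        _PRESET_CACHE = _load_preset_file()
    return _PRESET_CACHE


def list_presets() -> list[str]:
    return sorted(_presets().keys())


def get_preset(name: str) -> GeneratorParams:
    """Return the generator parameters of a named preset.

    Raises ``KeyError`` for unknown names.
    """
    presets = _presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    entry = dict(presets[name])
    entry.pop("targets", None)
    entry.pop("notes", None)
    if entry.get("mean_ibi") == "inf":
        entry["mean_ibi"] = math.inf
    return GeneratorParams(**entry)


def preset_targets(name: str) -> dict[str, dict[str, float]]:
    """Target observable means/SEMs for a preset (empty dict if undocumented)."""
    presets = _presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}")
    return {k: dict(v) for k, v in presets[name].get("targets", {}).items()}
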