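"""End-to-end orchestration: simulate -> traces -> classify -> peel ->
bursts -> effective network -> topology, plus multi-culture reports.

`analyze_culture` runs the full chain on one generated culture and returns a
flat observable dict (one row of the group table).  `run_preset_study` maps
it over seeds; `run_pipeline` drives everything from a config dictionary
(see ``defaults.toml`` for the reference parameter set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classification import classify_traces, default_classifier, featurize_traces
from .dynamics import activity_summary, detect_network_bursts
from .gte import InferenceRefused, infer_effective_network
from .imaging import normalize_traces
from .params import GeneratorParams, get_preset
from .spikes import CalciumKernel, reconstruct_raster
from .synthetic import render_traces, simulate_raster
from .topology import summarize_topology

__all__ = ["analyze_culture", "run_preset_study", "run_pipeline", "CultureResult"]


@dataclass
class CultureResult:
    summary: dict
    raster: np.ndarray
    labels: np.ndarray
    network: object | None  # EffectiveNetwork or None when refused
    inference_status: str


def analyze_culture(
    params: GeneratorParams,
    seed: int,
    infer_network: bool = True,
    theta_active: int = 2,
    from_normalized: bool = False,
    classifier=None,
) -> CultureResult:
    """Generate one culture and run the full analysis chain on it.

    The chain re-measures everything from the rendered fluorescence: baseline
    normalization of the raw traces, trace classification, spike peeling,
    burst detection, activity statistics and (optionally) GTE + topology.
    Set ``from_normalized`` to skip the baseline-estimation stage and use the
    generator's ideal normalized traces (useful for noiseless checks).
    """
    params = params.with_seed(seed)
    culture = simulate_raster(params)
    rendered = render_traces(culture)
    fr = params.frame_rate

    if from_normalized:
        r = rendered.normalized
        valid = np.ones(r.shape[0], dtype=bool)
    else:
        tm = normalize_traces(rendered.raw, fr)
        r = tm.r
        valid = tm.valid

    if classifier is None:
        classifier = default_classifier(params.duration, fr, seed=0)
    feats = featurize_traces(r, fr)
    labels, _ = classify_traces(classifier, feats)
    labels = np.where(valid, labels, "silent")

    kernel = CalciumKernel(params.kernel_amplitude, params.kernel_decay)
    neuron_rows = np.flatnonzero(labels == "neuron")
    raster = np.zeros(r.shape, dtype=bool)
    if neuron_rows.size:
        sub, _flagged = reconstruct_raster(r[neuron_rows], fr, kernel)
        raster[neuron_rows] = sub

    n_active = int(
        ((raster.sum(axis=1) >= theta_active) & (labels == "neuron")).sum()
    )
    bursts = detect_network_bursts(
        raster, fr, n_active=n_active, theta_active=theta_active
    )
    summ = activity_summary(raster, labels, bursts, fr, theta_active=theta_active)

    row = {
        "seed": seed,
        "percent_active": summ.percent_active,
        "percent_in_bursts": summ.percent_in_bursts,
        "mean_ibi": summ.mean_ibi,
        "burst_duration": summ.burst_duration,
        "burst_amplitude": summ.burst_amplitude,
        "global_rate": summ.global_rate,
        "independent_fraction": summ.independent_fraction,
        "bursty": summ.bursty,
        "n_bursts": summ.n_bursts,
        "n_active": summ.n_active,
        "n_cells": summ.n_cells,
        "global_efficiency": math.nan,
        "community_q": math.nan,
        "community_size": math.nan,
        "n_connector_hubs": math.nan,
        "n_edges": math.nan,
    }

    net = None
    status = "skipped"
    if infer_network:
        active_rows = np.flatnonzero(
            (raster.sum(axis=1) >= theta_active) & (labels == "neuron")
        )
        try:
            net = infer_effective_network(
                raster[active_rows], neuron_ids=active_rows
            )
            topo = summarize_topology(net.adjacency, seed=seed)
            row.update(
                global_efficiency=topo.global_efficiency,
                community_q=topo.q,
                community_size=topo.mean_community_size,
                n_connector_hubs=topo.n_connector_hubs,
                n_edges=net.n_edges,
            )
            status = "ok"
        except InferenceRefused as exc:
            status = f"refused: {exc.n_active} active neurons (<= 25)"
    row["inference_status"] = status
    return CultureResult(
        summary=row, raster=raster, labels=labels, network=net,
        inference_status=status,
    )


def run_preset_study(
    preset: str | GeneratorParams,
    seeds: list[int],
    infer_network: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Analyze one culture per seed; returns the one-row-per-culture table."""
    params = get_preset(preset) if isinstance(preset, str) else preset
    classifier = default_classifier(params.duration, params.frame_rate, seed=0)
    rows = []
    for s in seeds:
        res = analyze_culture(
            params, seed=s, infer_network=infer_network,
            classifier=classifier, **kwargs,
        )
        rows.append(res.summary)
    return pd.DataFrame(rows)


def run_pipeline(config: dict) -> dict:
    """Drive a multi-group study from a config dict.

    Config keys: ``groups`` (mapping of group name -> {preset, seeds}),
    ``infer_network`` (bool), ``output_dir`` (optional; write CSV tables).
    Returns {group: DataFrame} plus a pooled table under "_all".
    """
    groups = config.get("groups", {})
    infer = bool(config.get("infer_network", True))
    out = {}
    pooled = []
    for name, spec in groups.items():
        preset = spec.get("preset", name)
        seeds = list(spec.get("seeds", range(1, 11)))
        if "overrides" in spec:
            params = replace(get_preset(preset), **spec["overrides"])
        else:
            params = get_preset(preset)
        df = run_preset_study(params, seeds, infer_network=infer)
        df.insert(0, "group", name)
        out[name] = df
        pooled.append(df)
    out["_all"] = pd.concat(pooled, ignore_index=True) if pooled else pd.DataFrame()
    outdir = config.get("output_dir")
    if outdir:
        import pathlib

        p = pathlib.Path(outdir)
        p.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(p / f"{name.strip('_') or 'all'}.csv", index=False)
    return out
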