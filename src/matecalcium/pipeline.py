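"""End-to-end orchestration: simulate -> extract -> align/correlate ->
metrics -> spurious screen -> cohort summaries.

Every run writes a manifest (parameters, seed, software version) whose hash
is embedded in all outputs, so identical manifests yield byte-identical
results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import align_to_events, average_response, concatenate_matrices, lag_correlation
from .config import RunConfig
from .ethogram import Ethogram
from .extraction import compute_activity_trace, extract_roi_signals
from .io import (
    write_ethogram_csv,
    write_results_json,
    write_traces_csv,
    write_volumes_h5,
    write_tracks_csv,
)
from .metrics import MEASURES, cohort_success_percent, mating_metrics
from .spurious import classify_male, cohort_spurious_fraction, detect_pulses
from .synthetic import make_tracks, render_volumes, simulate_ethogram, simulate_traces

logger = logging.getLogger(__name__)


def manifest_for(config: RunConfig) -> tuple[dict, str]:
    manifest = {
        "software": "matecalcium",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    digest = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    return manifest, digest


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages and write the result bundle under ``outdir``.

    Produces ``manifest.json``, per-male ethogram/trace CSVs, a demo
    rendered volume (HDF5) with its round-trip extraction check,
    ``metrics.csv``, ``correlations.json`` and ``spurious.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest, digest = manifest_for(config)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    stage = "simulate"
    try:
        ethograms: dict[str, Ethogram] = {}
        activities = {}
        truths = {}
        for i in range(config.n_males):
            rid = f"male{i:02d}"
            e = simulate_ethogram(config.simulation, seed=config.seed + i, recording_id=rid)
            raw, truth = simulate_traces(e, config.simulation, seed=config.seed + i)
            ethograms[rid] = e
            truths[rid] = truth
            write_ethogram_csv(e, outdir / f"ethogram_{rid}.csv")
            stage = "extract"
            activities[rid] = compute_activity_trace(
                raw,
                camera_offset=config.simulation.camera_offset,
                window=config.sg_window,
                order=config.sg_order,
                downsample_factor=config.downsample_factor,
            )
            write_traces_csv(None, outdir / f"activity_{rid}.csv", activity=activities[rid])
            stage = "simulate"

        demo_pearson = {}
        if config.render_demo_volumes:
            stage = "render"
            demo_rid = "demo"
            sim = dataclasses.replace(
                config.simulation, recording_duration_s=config.demo_duration_s
            )
            e_demo = simulate_ethogram(sim, seed=config.seed, recording_id=demo_rid)
            raw_demo, truth_demo = simulate_traces(e_demo, sim, seed=config.seed)
            tracks = make_tracks(raw_demo.neuron_ids, raw_demo.n_samples, config.geometry)
            vols = render_volumes(
                raw_demo, tracks, config.geometry, seed=config.seed,
                camera_offset=sim.camera_offset,
            )
            write_volumes_h5(vols, outdir / "volumes_demo.h5")
            write_tracks_csv(tracks, outdir / "tracks_demo.csv")
            stage = "extract"
            raw_rt = extract_roi_signals(vols, tracks, config.roi_um, recording_id=demo_rid)
            act_rt = compute_activity_trace(
                raw_rt,
                camera_offset=sim.camera_offset,
                window=config.sg_window,
                order=config.sg_order,
                downsample_factor=config.downsample_factor,
            )
            factor = config.downsample_factor
            for nid in act_rt.neuron_ids:
                truth_a = 1.0 + truth_demo.activity[nid]
                n = (len(truth_a) // factor) * factor
                truth_ds = truth_a[:n].reshape(-1, factor).mean(axis=1)
                rec = act_rt.activity[nid]
                m = min(len(rec), len(truth_ds))
                if np.ptp(truth_ds[:m]) == 0 or np.ptp(rec[:m]) == 0:
                    # neuron without events in the demo window: correlation
                    # undefined, skipped
                    continue
                demo_pearson[nid] = float(np.corrcoef(rec[:m], truth_ds[:m])[0, 1])

        stage = "align"
        correlations = {}
        for nid, motif in config.correlation_pairs:
            mats = []
            for rid, act in activities.items():
                onsets = ethograms[rid].onsets_of(motif)
                if not onsets:
                    continue
                try:
                    mats.append(
                        align_to_events(act, onsets, nid, motif, config.window_s)
                    )
                except ValueError:
                    continue
            if not mats:
                continue
            pooled = concatenate_matrices(mats)
            curve = average_response(pooled)
            res = lag_correlation(pooled, ethograms, motif, config.max_lag_samples)
            correlations[f"{nid}:{motif}"] = {
                "n_animals": pooled.n_animals,
                "n_instances": res.n_instances,
                "n_dropped": res.n_dropped,
                "lag_samples": res.lag_samples,
                "lag_s": res.lag_s,
                "mean_correlation": res.mean_correlation,
                "t_statistic": res.t_statistic,
                "p_value": res.p_value,
                "curve_constant": curve.constant,
                "lag_convention": res.lag_convention,
            }

        stage = "metrics"
        perf_rows = []
        for rid, e in ethograms.items():
            p = mating_metrics(e)
            row = {"recording_id": rid}
            row.update({m: getattr(p, m) for m in MEASURES})
            perf_rows.append(row)
        metrics_df = pd.DataFrame(perf_rows).set_index("recording_id").sort_index()
        with open(outdir / "metrics.csv", "w", encoding="utf-8") as fh:
            fh.write(f"# manifest_hash={digest}\n")
            metrics_df.to_csv(fh)
        n_succ, n_tot, pct = cohort_success_percent(list(ethograms.values()))

        stage = "spurious"
        labels = []
        call_rows = []
        for rid, act in activities.items():
            vulva = ethograms[rid].intervals_of("vulva_contact")
            calls = []
            for nid in act.neuron_ids:
                call = detect_pulses(act, nid, vulva, config.detector)
                calls.append(call)
                for (on, off), peak in zip(call.pulses, call.peaks):
                    call_rows.append((rid, nid, on, off, peak))
            labels.append(classify_male(calls))
        n_pos, n_total, pct_spur = cohort_spurious_fraction(labels)
        calls_df = pd.DataFrame(
            call_rows,
            columns=["recording_id", "neuron_id", "pulse_onset_s", "pulse_offset_s", "peak"],
        )
        with open(outdir / "spurious_calls.csv", "w", encoding="utf-8") as fh:
            fh.write(f"# manifest_hash={digest}\n")
            calls_df.to_csv(fh, index=False)

        write_results_json(correlations, outdir / "correlations.json", digest)
        write_results_json(
            {
                "mating_success": {"n_success": n_succ, "n_total": n_tot, "percent": pct},
                "spurious": {
                    "n_positive": n_pos,
                    "n_total": n_total,
                    "percent": pct_spur,
                    "detector": dataclasses.asdict(config.detector),
                },
                "demo_pearson_r": demo_pearson,
            },
            outdir / "spurious.json",
            digest,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "manifest_hash": digest,
        "n_males": config.n_males,
        "success_percent": pct,
        "spurious_percent": pct_spur,
        "demo_pearson_r": demo_pearson,
        "correlations": correlations,
    }
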