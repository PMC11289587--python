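"""End-to-end analysis: raw traces or spike lists through every stage.

Stages: (optional) spike detection → recording QC → per-compartment
network bursts → circuitry/intermediate bursts with plate classification →
the eight burst output parameters per level → surrogate randomness test →
(optional, raw input only) CorSE functional connectivity.  Every
intermediate is written next to the report so a run is fully auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as tb_io
from .bursts import detect_network_bursts
from .circuitry import detect_circuitry
from .config import PipelineConfig
from .connectivity import connectivity_matrix
from .layout import RawRecording, SpikeListSet
from .metrics import compute_parameters
from .spikes import detect_spikes
from .surrogate import run_test

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(
    config: PipelineConfig,
    spikes: SpikeListSet | None = None,
    raw: RawRecording | None = None,
    out_dir: str | Path = ".",
    run_connectivity: bool | None = None,
) -> dict:
    """Run every stage and return (and write) the machine-readable report.

    Provide either ``raw`` (spike detection runs first) or ``spikes``.
    Connectivity runs by default when raw traces are available.
    """
    if spikes is None and raw is None:
        raise ValueError("provide raw traces or a spike list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    if spikes is None:
        log.info("stage: spike detection")
        spikes = detect_spikes(raw, config.spike_detection)
        tb_io.write_spike_csv(spikes, out_dir / "spikes.csv")
        report["stages"].append("spike_detection")
        report["spike_counts"] = spikes.counts()

    log.info("stage: recording QC")
    flagged = tb_io.flag_noisy_recording(
        spikes,
        bin_width=config.qc.bin_width,
        rate_limit=config.qc.rate_limit,
        min_channels_fraction=config.qc.min_channels_fraction,
    )
    report["stages"].append("qc")
    report["qc_flagged_intervals"] = flagged

    log.info("stage: network bursts")
    nbs = {
        c: detect_network_bursts(spikes, c, config.network_bursts)
        for c in spikes.layout.compartments
    }
    with open(out_dir / "bursts.json", "w") as f:
        json.dump(
            {c: [nb.to_dict() for nb in lst] for c, lst in nbs.items()},
            f, indent=1, default=_jsonable,
        )
    report["stages"].append("network_bursts")
    report["nb_counts"] = {c: len(lst) for c, lst in nbs.items()}

    log.info("stage: circuitry bursts")
    cbs, icbs, labels = detect_circuitry(nbs)
    with open(out_dir / "circuitry.json", "w") as f:
        json.dump(
            {
                "cb": [ev.to_dict() for ev in cbs],
                "icb": [ev.to_dict() for ev in icbs],
                "labels": sorted(labels),
            },
            f, indent=1, default=_jsonable,
        )
    report["stages"].append("circuitry_bursts")
    report["cb_count"] = len(cbs)
    report["icb_counts"] = {
        pair: sum(1 for ev in icbs if ev.pair_label == pair) for pair in ("AB", "AC", "BC")
    }
    report["synchrony_labels"] = sorted(labels)

    log.info("stage: burst metrics")
    frac = config.network_bursts.min_contribution_fraction
    nb_params = {
        c: compute_parameters(nbs[c], spikes, scope=c, min_contribution_fraction=frac)
        for c in spikes.layout.compartments
    }
    cb_params = compute_parameters(cbs, spikes, scope=None, min_contribution_fraction=frac)
    report["stages"].append("burst_metrics")
    report["nb_parameters"] = {c: p.as_dict() for c, p in nb_params.items()}
    report["cb_parameters"] = cb_params.as_dict()

    log.info("stage: surrogate test")
    if any(len(lst) for lst in nbs.values()):
        result = run_test(nbs, spikes.duration, config.surrogate)
        report["surrogate_test"] = result.to_dict()
    else:
        report["surrogate_test"] = None
    report["stages"].append("surrogate_test")

    if run_connectivity is None:
        run_connectivity = raw is not None
    if run_connectivity:
        if raw is None:
            raise ValueError("connectivity requires raw traces")
        log.info("stage: connectivity")
        conn = connectivity_matrix(raw, config.connectivity)
        np.savetxt(out_dir / "corse_matrix.csv", conn.pair_matrix, delimiter=",")
        report["stages"].append("connectivity")
        report["connectivity"] = conn.to_dict()

    with open(out_dir / "report.json", "w") as f:
        json.dump(report, f, indent=1, default=_jsonable)
    return report
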