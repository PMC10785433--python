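"""End-to-end orchestration: convert -> gate -> count -> fit -> test -> compare.

Given a validated :class:`~meioflow.config.PipelineConfig`, :func:`run_pipeline`
reads every sample file (FCS or per-event CSV), writes the converted CSV
event tables, applies the selected gate variant, tabulates the three
category counts, fits the misclassification-adjusted model, runs the Wald
detectability test per spiked sample, and — when a paired reference table is
configured — fits the recovery regression.  All numeric outputs are
deterministic under a fixed config and seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import load_paired_csv, recovery_regression
from .config import PipelineConfig, build_thresholds
from .errors import MeioflowError
from .fcs import read_csv_events, read_fcs, write_csv
from .gating import apply_quality_filter, tabulate_counts
from .model import ExperimentSeries, fit_experiment, wald_test

__all__ = ["PipelineStageError", "run_pipeline"]


class PipelineStageError(MeioflowError):
    """A pipeline stage failed; names the stage and the offending sample."""

    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on sample {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample


def _read_sample(entry, aliases):
    if entry.path.suffix.lower() == ".fcs":
        return read_fcs(entry.path, sample_id=entry.sample_id, aliases=aliases)
    table = read_csv_events(entry.path, sample_id=entry.sample_id)
    return table.rename_channels(aliases)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full pipeline; returns a map of output names to paths."""
    out = Path(config.output_dir)
    (out / "events").mkdir(parents=True, exist_ok=True)
    thresholds = build_thresholds(config.gate_variant, config.threshold_overrides)

    counts_rows = []
    series_entries = []
    outputs: dict[str, Path] = {}
    for entry in config.samples:
        try:
            table = _read_sample(entry, config.channel_aliases)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineStageError("convert", entry.sample_id, exc) from exc
        csv_path = out / "events" / f"{entry.sample_id}.csv"
        write_csv(table, csv_path)
        outputs[f"events/{entry.sample_id}"] = csv_path
        try:
            kept = apply_quality_filter(table, thresholds)
            counts = tabulate_counts(kept, thresholds)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("gate", entry.sample_id, exc) from exc
        counts_rows.append({
            "experiment": config.experiment_id,
            "sample": entry.sample_id,
            "role": entry.role.value,
            "n_events_raw": len(table),
            "n_events_gated": counts.n_total,
            "y_rfp": counts.y1,
            "y_gfp_combined": counts.y2,
            "y_wt": counts.y3,
        })
        series_entries.append((counts, entry.role))

    counts_path = out / "counts.csv"
    pd.DataFrame(counts_rows).to_csv(counts_path, index=False)
    outputs["counts"] = counts_path

    series = ExperimentSeries(config.experiment_id, tuple(series_entries))
    try:
        fit = fit_experiment(series, config.optimizer)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("fit", config.experiment_id, exc) from exc
    fit_rows = []
    for m, sid in enumerate(fit.sample_ids):
        try:
            wald = wald_test(fit, m)
            z, p = wald.statistic, wald.p_value
        except MeioflowError:
            z, p = np.nan, np.nan
        fit_rows.append({
            "experiment": config.experiment_id,
            "sample": sid,
            "s_hat": fit.s_hat[m],
            "se": fit.se_s[m],
            "z": z,
            "p_value": p,
            "boundary": bool(fit.boundary[m]),
        })
    fit_path = out / "fit_results.csv"
    pd.DataFrame(fit_rows).to_csv(fit_path, index=False)
    outputs["fit_results"] = fit_path

    if config.comparison_path is not None:
        paired = load_paired_csv(config.comparison_path, percent=config.comparison_percent)
        reg = recovery_regression(paired, remove_influential=True)
        reg_path = out / "recovery_regression.csv"
        pd.DataFrame([{
            "slope": reg.slope,
            "slope_percent": reg.slope_percent,
            "se_slope": reg.se_slope,
            "intercept": reg.intercept,
            "removed_label": reg.removed_label,
            "n_used": reg.n_used,
        }]).to_csv(reg_path, index=False)
        outputs["recovery_regression"] = reg_path

    log_path = out / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"meioflow version: {__version__}\n")
        fh.write(f"experiment: {config.experiment_id}\n")
        fh.write(f"gate variant: {config.gate_variant.value}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"optimizer: {config.optimizer}\n")
        fh.write("thresholds:\n")
        for block_name, block in (("fluorescence", thresholds.fluorescence),
                                  ("quality", thresholds.quality)):
            for ch, (lo, hi) in block.items():
                fh.write(f"  {block_name} {ch}: min={lo} max={hi}\n")
        fh.write(f"loglik: {fit.loglik:.6f}\n")
        fh.write(f"converged: {fit.converged}\n")
    outputs["run_log"] = log_path
    return outputs
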