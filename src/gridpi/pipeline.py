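"""End-to-end pipeline: simulate -> score -> gridfit -> cohort.

Each stage writes its outputs under the run directory; a manifest records
package/library versions, the seed, and SHA-256 hashes of every produced
file so identical seeds yield identical result hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bold_sim import simulate_grid_bold
from .cohort_sim import simulate_cohort
from .config import RunConfig
from .grid import GridDirectionModel, control_symmetries
from .io import (
    FLOAT_FMT,
    load_roi_timeseries,
    write_bold_nifti,
    write_events,
    write_mask_nifti,
    write_orientation_map,
    write_trajectory,
)
from .risk import (
    ChangeRegressionResults,
    compare_nested,
    double_risk_label,
    elasticnet_risk_auc,
    fit_change_regression,
    fit_trial_mixed,
)
from .scoring import condition_deltas, score_trials, summarize

__all__ = ["run_pipeline"]

log = logging.getLogger("gridpi")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Execute the full pipeline described by ``config``.

    Returns the output directory. Any stage failure aborts with the stage
    name in the exception; partial outputs and the resolved config are left
    on disk for inspection.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    config.to_yaml(out / "config.yaml")
    manifest = {
        "gridpi_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "stages": {},
        "files": {},
    }
    stage = "simulate"
    try:
        cohort, trajectories = simulate_cohort(
            config.cohort, config.agent, config.arena
        )
        traj_dir = out / "trials"
        traj_dir.mkdir(exist_ok=True)
        for traj in trajectories:
            name = f"{traj.meta['pid']}_t{traj.meta['trial']:02d}.csv"
            write_trajectory(traj, traj_dir / name)
        cohort.to_csv(out / "cohort.csv", index=False)
        manifest["stages"][stage] = {"n_participants": len(cohort),
                                     "n_trials": len(trajectories)}
        log.info("simulate: %d participants, %d trials", len(cohort),
                 len(trajectories))

        stage = "score"
        trials = score_trials(trajectories)
        trials.to_csv(out / "trials.csv", index=False, float_format=FLOAT_FMT)
        summary = summarize(trials)
        summary.to_csv(out / "summary.csv", index=False, float_format=FLOAT_FMT)
        manifest["stages"][stage] = {
            "included_pct": float(100 * trials["included"].mean())
        }

        stage = "gridfit"
        if config.grid is not None:
            series, events, mask = simulate_grid_bold(config.grid)
            write_bold_nifti(series.data, out / "bold.nii.gz", config.grid.tr)
            write_mask_nifti(mask, out / "mask.nii.gz")
            write_events(events, out / "events.tsv")
            # refit from the files just written (exercises the IO contract)
            roi = load_roi_timeseries(out / "bold.nii.gz", out / "mask.nii.gz")
            results = GridDirectionModel(roi, events, n_fold=config.grid.n_fold).fit()
            metrics = {6: results.metrics()}
            for fold, res in control_symmetries(roi, events).items():
                metrics[fold] = res.metrics()
            pd.DataFrame(metrics.values()).to_csv(
                out / "grid_metrics.csv", index=False, float_format=FLOAT_FMT
            )
            write_orientation_map(
                results.orientations_deg, mask, out / "orientations.nii.gz"
            )
            manifest["stages"][stage] = {"magnitude": results.magnitude}
        else:
            log.info("gridfit: no grid spec, stage skipped")
            manifest["stages"][stage] = "skipped"

        stage = "cohort"
        deltas = condition_deltas(summary, "location_error")
        table = cohort.join(deltas, on="pid")
        stats_out = {}
        for outcome in ("delta_BA", "delta_CA"):
            if outcome in table and table[outcome].notna().sum() >= 20:
                res = fit_change_regression(table, outcome)
                res.anova.to_csv(out / f"anova_{outcome}.csv", float_format=FLOAT_FMT)
                res.contrasts.to_csv(
                    out / f"contrasts_{outcome}.csv", index=False,
                    float_format=FLOAT_FMT,
                )
                stats_out[outcome] = float(res.adj_r2)
        mixed = fit_trial_mixed(trials.merge(cohort, on="pid"))
        mixed.anova.to_csv(out / "mixed_anova.csv", float_format=FLOAT_FMT)
        if config.n_elasticnet_permutations > 0 and "delta_CA" in table:
            feats = table[["delta_CA", "age_y", "edu_y", "sex"]].dropna()
            label = double_risk_label(table.loc[feats.index])
            if label.sum() >= 8:
                en = elasticnet_risk_auc(
                    feats,
                    label,
                    n_permutations=config.n_elasticnet_permutations,
                    seed=config.stage_seeds()["cohort"],
                )
                en.selection_frequency.to_frame("pct_nonzero").to_csv(
                    out / "elasticnet_selection.csv", float_format=FLOAT_FMT
                )
                stats_out["elasticnet_mean_auc"] = en.mean_auc
            else:
                log.warning(
                    "elastic net skipped: only %d double-risk positives",
                    int(label.sum()),
                )
        manifest["stages"][stage] = stats_out
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
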