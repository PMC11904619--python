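"""End-to-end orchestration: generate -> postprocess -> QC -> fit ->
cross-validate -> variability analysis, with manifests for
reproducibility.

A run is fully determined by its configuration and master seed: every
stage derives its randomness from the seed, and the manifest records a
hash of the configuration plus a content hash of every artifact
written.  A fit that fails for one sweep is recorded as a failed row
rather than aborting the batch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import variability as vstats
from .fitting import FitConfig, FitResult, fit_sweep
from .metrics import cross_validation_table, e_fit, e_predict
from .models import build_model
from .postprocess import QCCriteria, postprocess_pair, qc_filter
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("ikrfit.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    model_names: tuple[str, ...] = ("Beattie",)
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    qc: QCCriteria = field(default_factory=QCCriteria)
    seed: int = 1
    out_dir: str = "ikrfit_run"

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            return obj

        d = {k: enc(getattr(self, k)) for k in
             ("model_names", "synth", "fit", "qc", "seed", "out_dir")}
        # protocols are regenerated from config, not serialised
        if isinstance(d["synth"], dict):
            d["synth"].pop("protocols", None)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land must not change them
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, header_note: str, index=True) -> str:
    with open(path, "w") as fh:
        fh.write(f"# {header_note}\n")
        df.to_csv(fh, index=index)
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    note = f"config_hash={config.config_hash()} seed={config.seed}"
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "config": config.to_dict(), "files": {}, "stages": []}

    def _abort(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- generate ------------------------------------------------------
    try:
        log.info("generating synthetic dataset")
        dataset = generate_dataset(config.synth, config.seed)
        manifest["stages"].append("generate")
        manifest["dataset_hash"] = dataset.content_hash()
        (out / "ground_truth.json").write_text(dataset.ground_truth_json())
        _write_csv(dataset.design.to_frame(), out / "design.csv", note, index=False)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _abort("generate", exc)

    # -- postprocess + QC ---------------------------------------------
    try:
        log.info("postprocessing %d wells", len(dataset.design.wells))
        corrected = {}
        annot_rows = []
        for well in dataset.design.wells:
            for entry in dataset.design.sweeps("pre"):
                pre = dataset.trace(well, entry.protocol, entry.sweep, "pre")
                post = dataset.trace(well, entry.protocol, entry.sweep, "post")
                proto = dataset.protocols[entry.protocol]
                tr = postprocess_pair(pre, post, proto, dataset.E_Kr)
                corrected[(well, entry.protocol, entry.sweep)] = tr
                annot_rows.append({
                    "well": well, "protocol": entry.protocol, "sweep": entry.sweep,
                    "g_L": tr.leak.g_L, "E_L": tr.leak.E_L, "E_obs": tr.E_obs,
                    "V_off": tr.V_off, "sigma_hat": tr.sigma_hat,
                    "flags": ";".join(tr.qc_flags),
                })
        annotations = pd.DataFrame(annot_rows)
        manifest["files"]["annotations.csv"] = _write_csv(
            annotations, out / "annotations.csv", note, index=False)
        raw_pre = {
            (well, e.protocol, e.sweep): dataset.trace(well, e.protocol,
                                                       e.sweep, "pre")
            for well in dataset.design.wells
            for e in dataset.design.sweeps("pre")
        }
        passing, flags = qc_filter(corrected, dataset.E_Kr, config.qc,
                                   raw=raw_pre)
        manifest["files"]["qc_report.csv"] = _write_csv(flags, out / "qc_report.csv", note)
        manifest["passing_wells"] = passing
        manifest["stages"].append("postprocess")
        log.info("QC passed %d/%d wells", len(passing), len(dataset.design.wells))
    except Exception as exc:  # noqa: BLE001
        _abort("postprocess", exc)

    # -- fit -----------------------------------------------------------
    fits: dict[str, list[FitResult]] = {m: [] for m in config.model_names}
    fit_rows = []
    try:
        for model_name in config.model_names:
            model = build_model(model_name)
            for well in passing:
                for entry in dataset.design.fitting_sweeps():
                    tr = corrected[(well, entry.protocol, entry.sweep)]
                    proto = dataset.protocols[entry.protocol]
                    try:
                        fr = fit_sweep(model, tr, proto, config.fit,
                                       E_Kr=dataset.E_Kr)
                        fits[model_name].append(fr)
                        row = {"model": model_name, "well": well,
                               "protocol": entry.protocol, "sweep": entry.sweep,
                               "sse": fr.sse, "rmse": fr.rmse,
                               "n_repeats_within_1pct": fr.n_repeats_within_1pct,
                               "failed": False}
                        row.update({f"param_{i + 1}": v
                                    for i, v in enumerate(fr.params)})
                    except Exception as exc:  # noqa: BLE001 - keep batch alive
                        log.warning("fit failed for %s/%s/%s: %s", well,
                                    entry.protocol, entry.sweep, exc)
                        row = {"model": model_name, "well": well,
                               "protocol": entry.protocol, "sweep": entry.sweep,
                               "failed": True}
                    fit_rows.append(row)
        fits_df = pd.DataFrame(fit_rows)
        manifest["files"]["fits.csv"] = _write_csv(fits_df, out / "fits.csv",
                                                   note, index=False)
        manifest["stages"].append("fit")
    except Exception as exc:  # noqa: BLE001
        _abort("fit", exc)

    # -- cross-validation ---------------------------------------------
    try:
        summary_rows = []
        for model_name in config.model_names:
            model = build_model(model_name)
            for well in passing:
                well_fits = [f for f in fits[model_name] if f.well == well]
                if not well_fits:
                    continue
                validation = {
                    (e.protocol, e.sweep): corrected[(well, e.protocol, e.sweep)]
                    for e in dataset.design.validation_sweeps()
                }
                table = cross_validation_table(well_fits, validation,
                                               dataset.protocols, model)
                fname = f"crossval_{model_name}_{well}.csv"
                manifest["files"][fname] = _write_csv(table, out / fname, note)
                summary_rows.append({
                    "model": model_name, "well": well,
                    "E_fit": e_fit(table), "E_predict": e_predict(table),
                })
        summary = pd.DataFrame(summary_rows)
        manifest["files"]["crossval_summary.csv"] = _write_csv(
            summary, out / "crossval_summary.csv", note, index=False)
        manifest["stages"].append("crossval")
    except Exception as exc:  # noqa: BLE001
        _abort("crossval", exc)

    # -- variability ---------------------------------------------------
    try:
        var_rows = []
        for model_name in config.model_names:
            ok = [f for f in fits[model_name]]
            wells_used = {f.well for f in ok}
            protos_used = {f.protocol for f in ok}
            if len(wells_used) < 2 or len(protos_used) < 2:
                log.warning("variability analysis for %s skipped "
                            "(needs >= 2 wells and >= 2 protocols)", model_name)
                continue
            table = vstats.transform_estimates(ok, build_model(model_name))
            stats = vstats.lld_table(table)
            var_rows.append({"model": model_name, **stats.to_dict()})
        if var_rows:
            var_df = pd.DataFrame(var_rows)
            manifest["files"]["variability.csv"] = _write_csv(
                var_df, out / "variability.csv", note, index=False)
        manifest["stages"].append("variability")
    except Exception as exc:  # noqa: BLE001
        _abort("variability", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
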