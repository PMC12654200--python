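"""Full-experiment orchestration and consolidated reporting.

``run_full_experiment`` executes the whole workflow on a spectra CSV or a
synthetic-cohort recipe: replicate aggregation, the four QC metrics and
their exact group comparison, the 2 regions × 6 pipelines × 2 models
evaluation grid (24 LOOCV cells), and the unsupervised exploration
artifacts (cosine distances, MDS, Ward linkage, 2D-COS). A failure in one
grid cell is recorded as a structured per-cell error and never aborts the
run. The JSON report payload is deterministic for a fixed input and seed
(the timestamp lives in a separate field).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import EvalConfig, EvalResult, loocv_evaluate
from .explore import cosine_distance_matrix, mds_embed, twodcos_maps, ward_cluster
from .fcbf import FCBFConfig
from .preprocess import PIPELINE_LABELS, PIPELINE_NAMES, PipelineSpec, apply_pipeline
from .qc import QCConfig, qc_group_compare, qc_group_frame, qc_records_frame, qc_table
from .spectra import (
    SpectraSet,
    aggregate_replicates,
    read_spectra_csv,
    write_spectra_csv,
)
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RunReport", "run_full_experiment", "evaluation_grid"]

log = logging.getLogger("ftirfp")

REGIONS = ("fingerprint", "amide_i")
MODELS = ("svm", "naive_bayes")
REPORT_SCHEMA_VERSION = 1


@dataclass
class GridCell:
    region: str
    pipeline: str
    model: str
    status: str  # "ok" | "error"
    result: EvalResult | None = None
    error: str | None = None


@dataclass
class RunReport:
    seed: int
    config: dict
    qc_records: pd.DataFrame
    qc_group_stats: pd.DataFrame | None
    grid: list[GridCell]
    exploration: dict
    version: str = __version__
    schema_version: int = REPORT_SCHEMA_VERSION
    timestamp: str = ""

    def grid_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.grid:
            row = {
                "region": c.region,
                "pipeline": c.pipeline,
                "pipeline_label": PIPELINE_LABELS[c.pipeline],
                "model": c.model,
                "status": c.status,
            }
            if c.result is not None:
                r = c.result
                row.update(
                    auc=r.auc,
                    accuracy=r.accuracy,
                    ci_lo=r.accuracy_ci[0],
                    ci_hi=r.accuracy_ci[1],
                    sensitivity=r.sensitivity,
                    specificity=r.specificity,
                    selected_features=";".join(
                        sorted(
                            {f"{w:.0f}" for feats in (r.fold_features or {}).values() for w in feats}
                        )
                    ),
                )
            else:
                row["error"] = c.error
            rows.append(row)
        return pd.DataFrame(rows)

    def payload(self) -> dict:
        """Deterministic JSON-ready payload (timestamp excluded)."""
        return {
            "schema_version": self.schema_version,
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "qc_records": self.qc_records.to_dict(orient="records"),
            "qc_group_stats": (
                None
                if self.qc_group_stats is None
                else self.qc_group_stats.to_dict(orient="records")
            ),
            "grid": self.grid_frame().fillna("").to_dict(orient="records"),
            "exploration": self.exploration,
        }

    def to_json(self) -> str:
        data = dict(self.payload())
        data["timestamp"] = self.timestamp
        return json.dumps(data, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def evaluation_grid(
    donor_set: SpectraSet,
    seed: int = 0,
    fs_mode: str = "per_fold",
    fcbf_config: FCBFConfig | None = None,
) -> list[GridCell]:
    """Run every region × pipeline × model combination with per-cell errors."""
    fcbf_config = fcbf_config or FCBFConfig()
    cells: list[GridCell] = []
    for region in REGIONS:
        for pname in PIPELINE_NAMES:
            spec = PipelineSpec.from_name(pname, region)
            try:
                processed = apply_pipeline(donor_set, spec)
            except Exception as exc:
                for model in MODELS:
                    cells.append(GridCell(region, pname, model, "error", error=str(exc)))
                continue
            for model in MODELS:
                cfg = EvalConfig(
                    model=model,
                    fs_mode=fs_mode if spec.fcbf else "none",
                    seed=seed,
                    fcbf=fcbf_config,
                )
                try:
                    res = loocv_evaluate(processed, spec, cfg)
                    cells.append(GridCell(region, pname, model, "ok", result=res))
                    log.info(
                        "%s / %s / %s: AUC=%.2f acc=%.2f",
                        region, pname, model, res.auc, res.accuracy,
                    )
                except Exception as exc:
                    cells.append(GridCell(region, pname, model, "error", error=str(exc)))
                    log.warning("%s / %s / %s failed: %s", region, pname, model, exc)
    return cells


def _exploration_artifacts(donor_set: SpectraSet, seed: int) -> dict:
    out: dict = {}
    try:
        d2 = apply_pipeline(donor_set, PipelineSpec.from_name("d2", "fingerprint"))
        dm = cosine_distance_matrix(d2)
        mds = mds_embed(dm, seed=seed)
        Z = ward_cluster(dm)
        out["cosine_distance"] = {"ids": dm.ids, "d": dm.d}
        out["mds"] = {"coords": mds.coords, "stress": mds.stress}
        out["ward_linkage"] = Z
        for region in REGIONS:
            proc = apply_pipeline(donor_set, PipelineSpec.from_name("d2", region))
            maps = twodcos_maps(proc)
            out[f"twodcos_{region}"] = {
                "grid": maps.grid,
                "sync": maps.sync,
                "async": maps.async_,
                "order": maps.order,
            }
    except Exception as exc:  # exploration failures are non-fatal
        out["error"] = str(exc)
    return out


def run_full_experiment(
    source: SyntheticConfig | str | Path,
    out_dir: str | Path | None = None,
    seed: int = 0,
    fs_mode: str = "per_fold",
    qc_config: QCConfig | None = None,
) -> RunReport:
    """Simulate or load spectra, then run QC, the 24-cell grid, and exploration.

    ``source`` is either a :class:`SyntheticConfig` (cohort is generated and,
    when ``out_dir`` is given, written alongside its truth JSON) or a path to
    a wide spectra CSV. Artifacts (QC tables, grid CSV, exploration CSVs,
    report JSON) are written to ``out_dir`` when provided.
    """
    qc_config = qc_config or QCConfig()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    if isinstance(source, SyntheticConfig):
        spectra_set, truth = generate_cohort(source)
        config_echo = {
            "input": "synthetic",
            "synthetic": _config_dict(source),
            "fs_mode": fs_mode,
        }
        if out_path is not None:
            write_spectra_csv(spectra_set, out_path / "spectra.csv")
            (out_path / "truth.json").write_text(
                json.dumps(
                    {
                        "config": _config_dict(source),
                        "donors": [dataclasses.asdict(d) for d in truth.donors],
                    },
                    indent=2,
                    default=_json_default,
                )
            )
    else:
        spectra_set = read_spectra_csv(source)
        config_echo = {"input": str(source), "fs_mode": fs_mode}

    donor_set = aggregate_replicates(spectra_set)
    records = qc_table(donor_set, qc_config)
    qc_df = qc_records_frame(records)
    try:
        group_df = qc_group_frame(qc_group_compare(records))
    except Exception as exc:
        log.warning("QC group comparison skipped: %s", exc)
        group_df = None

    cells = evaluation_grid(donor_set, seed=seed, fs_mode=fs_mode)
    exploration = _exploration_artifacts(donor_set, seed)

    report = RunReport(
        seed=seed,
        config=config_echo,
        qc_records=qc_df,
        qc_group_stats=group_df,
        grid=cells,
        exploration=exploration,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    if out_path is not None:
        qc_df.to_csv(out_path / "qc_records.csv", index=False)
        if group_df is not None:
            group_df.to_csv(out_path / "qc_group_stats.csv", index=False)
        report.grid_frame().to_csv(out_path / "evaluation_grid.csv", index=False)
        _write_exploration_csvs(exploration, out_path)
        (out_path / "report.json").write_text(report.to_json())
    return report


def _write_exploration_csvs(exploration: dict, out_path: Path) -> None:
    if "cosine_distance" in exploration:
        ids = exploration["cosine_distance"]["ids"]
        pd.DataFrame(exploration["cosine_distance"]["d"], index=ids, columns=ids).to_csv(
            out_path / "cosine_distance.csv"
        )
    if "mds" in exploration:
        pd.DataFrame(exploration["mds"]["coords"], columns=["dim1", "dim2"]).to_csv(
            out_path / "mds_coords.csv", index=False
        )
    if "ward_linkage" in exploration:
        pd.DataFrame(
            exploration["ward_linkage"], columns=["left", "right", "height", "size"]
        ).to_csv(out_path / "ward_linkage.csv", index=False)
    for region in REGIONS:
        key = f"twodcos_{region}"
        if key in exploration:
            grid = exploration[key]["grid"]
            for kind in ("sync", "async"):
                pd.DataFrame(exploration[key][kind], index=grid, columns=grid).to_csv(
                    out_path / f"{key}_{kind}.csv"
                )


def _config_dict(cfg: SyntheticConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["bands"] = [dataclasses.asdict(b) for b in cfg.bands]
    d["baseline_poly_coeffs_sd"] = list(cfg.baseline_poly_coeffs_sd)
    return d
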