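"""Case orchestration: registration -> vessel index -> lesion metrics.

`run_case_objects` drives the whole analysis on in-memory volumes and is
the single code path used by the CLI, the cohort runner and the test
phantoms.  `run_case` wraps it with NIfTI I/O, provenance capture and the
JSON report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import pandas as pd

from . import __version__
from .config import config_hash, load_config
from .core import (
    BinaryMask,
    PerfusionSeries,
    ScalarMap,
    read_volume,
    split_hemispheres,
    write_volume,
)
from .errors import ConfigurationError, CviError
from .lesion_metrics import (
    LesionReport,
    compartments,
    cortical_volume,
    mismatch_ratios,
    segment_core,
    ttp_delay,
    ttp_map,
)
from .registration import apply_transform, coregister, motion_correct
from .vessel_index import CviResult, compute_cvi, extract_highcv, leptomeningeal_mask

REPORT_SCHEMA_VERSION = 1

_REQUIRED_INPUTS = ("pwi", "adc", "brain", "ventricles", "atlas", "sinus")

_REPORT_REQUIRED_KEYS = (
    "schema_version", "cvi", "lesion", "dichotomized_collaterals", "provenance",
)


@dataclass
class CaseReport:
    """Scalar results of one case plus provenance."""

    cvi_result: CviResult
    lesion_report: LesionReport
    dichotomized_collaterals: str
    cvi_cutoff: float
    provenance: Dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, Any]:
        cr, lr = self.cvi_result, self.lesion_report
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "cvi": {
                "cvi": cr.cvi,
                "highcv_affected_mm3": cr.highcv_affected_mm3,
                "highcv_unaffected_mm3": cr.highcv_unaffected_mm3,
                "cv_threshold": cr.threshold_used,
                "bolus_peak_index": cr.bolus_peak_index,
                "cutoff": self.cvi_cutoff,
            },
            "lesion": {
                "core_mm3": lr.core_mm3,
                "core_cortical_mm3": lr.core_cortical_mm3,
                "perfusion_lesion_mm3": lr.perfusion_lesion_mm3,
                "at_risk_mm3": lr.at_risk_mm3,
                "severe_mm3": lr.severe_mm3,
                "mismatch_entire": lr.mismatch_entire,
                "mismatch_at_risk": lr.mismatch_at_risk,
                "hir": lr.hir,
                "contralesional_median_ttp_s": lr.contralesional_median_ttp_s,
            },
            "dichotomized_collaterals": self.dichotomized_collaterals,
            "provenance": self.provenance,
        }


def validate_report(doc: Dict[str, Any]) -> None:
    missing = [k for k in _REPORT_REQUIRED_KEYS if k not in doc]
    if missing:
        raise CviError(f"report schema violation, missing keys: {missing}")
    if doc["schema_version"] != REPORT_SCHEMA_VERSION:
        raise CviError(f"unsupported report schema {doc['schema_version']}")


def run_case_objects(
    series: PerfusionSeries,
    adc: ScalarMap,
    brain: BinaryMask,
    ventricles: BinaryMask,
    atlas_density: ScalarMap,
    sinus: BinaryMask,
    cortex: Optional[BinaryMask] = None,
    cfg: Optional[Dict[str, Any]] = None,
    dwi_lesion_mm3: Optional[float] = None,
) -> CaseReport:
    """Run the full analysis on in-memory volumes.

    The acute DWI lesion volume defaults to the ADC-derived core volume
    when no separately traced lesion is supplied.
    """
    cfg = dict(load_config() if cfg is None else cfg)
    side = cfg.get("affected_side")
    if side not in ("left", "right"):
        raise ConfigurationError(
            "affected_side must be declared as 'left' or 'right'"
        )

    if cfg["motion_correction"]:
        series, _ = motion_correct(series, metric=cfg["registration_metric"])

    if not cfg["assume_registered"]:
        tfm = coregister(adc, series.volume(0), metric=cfg["registration_metric"])
        adc = apply_transform(adc, tfm, series.geometry)

    # --- collateral vessel index ---
    highcv, cv, thr, t_star = extract_highcv(
        series, brain, ventricles,
        range_fraction=cfg["highcv_range_fraction"],
        lower_pct=cfg["robust_lower_pct"],
        upper_pct=cfg["robust_upper_pct"],
        strip_fraction=cfg["strip_fraction"],
        strip_scope=cfg["strip_scope"],
    )
    lepto = leptomeningeal_mask(atlas_density, sinus)
    lepto_split = split_hemispheres(lepto, side)
    cvi_result = compute_cvi(
        highcv, lepto_split, series.geometry, cv=cv,
        threshold_used=thr, t_star=t_star,
    )

    # --- lesion metrics ---
    core = segment_core(
        adc, brain, threshold=cfg["adc_core_threshold"],
        units=cfg["adc_units"], min_component_mm3=cfg["min_component_mm3"],
    )
    tissue = brain.subtract(ventricles, label="brain_tissue")
    tissue_split = split_hemispheres(tissue, side)
    ttp = ttp_map(series, brain)
    delay, ref_median = ttp_delay(ttp, tissue_split.unaffected)
    restrict = tissue_split.affected if cfg["restrict_perfusion_to_affected"] else None
    comps = compartments(
        delay, core, tissue,
        at_risk_s=cfg["delay_at_risk_s"], severe_s=cfg["delay_severe_s"],
        min_component_mm3=cfg["min_component_mm3"], restrict_to=restrict,
    )
    lesion_mm3, at_risk_mm3, severe_mm3 = comps.volumes_mm3()
    core_mm3 = core.volume_mm3
    dwi_mm3 = core_mm3 if dwi_lesion_mm3 is None else dwi_lesion_mm3
    entire, at_risk_ratio = mismatch_ratios(lesion_mm3, at_risk_mm3, dwi_mm3)
    cortical = None
    if cortex is not None:
        cortical, _ = cortical_volume(core, cortex, series.geometry)

    lesion_report = LesionReport(
        core_mm3=core_mm3,
        core_cortical_mm3=cortical,
        perfusion_lesion_mm3=lesion_mm3,
        at_risk_mm3=at_risk_mm3,
        severe_mm3=severe_mm3,
        mismatch_entire=entire,
        mismatch_at_risk=at_risk_ratio,
        hir=comps.hir,
        contralesional_median_ttp_s=ref_median,
    )
    cutoff = cfg["cvi_cutoff"]
    report = CaseReport(
        cvi_result=cvi_result,
        lesion_report=lesion_report,
        dichotomized_collaterals=cvi_result.dichotomize(cutoff),
        cvi_cutoff=cutoff,
        provenance={
            "software": f"cvipwi {__version__}",
            "config_hash": config_hash(cfg),
            "affected_side": side,
        },
    )
    report._intermediates = {  # type: ignore[attr-defined]
        "cv_map": cv, "highcv": highcv, "core": core, "ttp": ttp,
        "ttp_delay": delay, "perfusion_lesion": comps.perfusion_lesion,
        "at_risk": comps.at_risk, "severe": comps.severe,
    }
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_case(
    inputs: Dict[str, Any],
    config_path=None,
    out_dir=None,
    write_intermediates: bool = True,
    **overrides,
) -> CaseReport:
    """Run one case from NIfTI files and write the JSON report.

    ``inputs`` maps input names (pwi, adc, brain, ventricles, atlas, sinus,
    optionally cortex) to file paths.
    """
    cfg = load_config(config_path, **overrides)
    missing = [k for k in _REQUIRED_INPUTS if not inputs.get(k)]
    if missing:
        raise ConfigurationError(f"missing required input(s): {', '.join(missing)}")
    axis = cfg["left_right_axis"]
    series = read_volume(inputs["pwi"], 4, tr=cfg["tr"], left_right_axis=axis)
    adc = read_volume(inputs["adc"], 3, left_right_axis=axis)

    def mask(name):
        m = read_volume(inputs[name], 3, left_right_axis=axis)
        return BinaryMask(m.data, m.geometry, label=name)

    brain, ventricles, sinus = mask("brain"), mask("ventricles"), mask("sinus")
    atlas = read_volume(inputs["atlas"], 3, left_right_axis=axis)
    cortex = mask("cortex") if inputs.get("cortex") else None

    report = run_case_objects(
        series, adc, brain, ventricles, atlas, sinus, cortex=cortex, cfg=cfg,
    )
    report.provenance["inputs"] = {
        k: {"path": str(v), "sha256": _sha256(Path(v))}
        for k, v in inputs.items() if v
    }
    report.provenance["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        doc = report.to_dict()
        validate_report(doc)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if write_intermediates:
            for name, obj in report._intermediates.items():  # type: ignore[attr-defined]
                write_volume(obj, out_dir / f"{name}.nii.gz")
    return report


#: fixed column order of the cohort CSV
COHORT_COLUMNS = [
    "case", "status", "cvi", "highcv_affected_mm3", "highcv_unaffected_mm3",
    "dichotomized_collaterals", "core_mm3", "core_cortical_mm3",
    "perfusion_lesion_mm3", "at_risk_mm3", "severe_mm3",
    "mismatch_entire", "mismatch_at_risk", "hir",
    "contralesional_median_ttp_s", "error",
]

_CASE_FILES = {
    "pwi": "pwi.nii.gz", "adc": "adc.nii.gz", "brain": "brain.nii.gz",
    "ventricles": "ventricles.nii.gz", "atlas": "atlas.nii.gz",
    "sinus": "sinus.nii.gz", "cortex": "cortex.nii.gz",
}


def run_cohort(cohort_dir, out_csv=None) -> pd.DataFrame:
    """Run every case subdirectory of ``cohort_dir``; one CSV row per case.

    A case directory holds the standard file names (pwi.nii.gz, adc.nii.gz,
    brain/ventricles/atlas/sinus masks, optional cortex.nii.gz) and a
    case.yaml config declaring at least the affected side.  Failing cases
    are logged and marked failed; they never abort the cohort.
    """
    cohort_dir = Path(cohort_dir)
    rows: List[Dict[str, Any]] = []
    for case_dir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        row: Dict[str, Any] = {c: None for c in COHORT_COLUMNS}
        row["case"] = case_dir.name
        try:
            inputs = {
                k: (case_dir / fn if (case_dir / fn).exists() else None)
                for k, fn in _CASE_FILES.items()
            }
            cfg_file = case_dir / "case.yaml"
            report = run_case(
                inputs, config_path=cfg_file if cfg_file.exists() else None,
                out_dir=case_dir / "results", write_intermediates=False,
            )
            d = report.to_dict()
            row.update(
                status="ok",
                cvi=d["cvi"]["cvi"],
                highcv_affected_mm3=d["cvi"]["highcv_affected_mm3"],
                highcv_unaffected_mm3=d["cvi"]["highcv_unaffected_mm3"],
                dichotomized_collaterals=d["dichotomized_collaterals"],
                **d["lesion"],
            )
        except (CviError, OSError) as exc:
            row.update(status="failed", error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
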