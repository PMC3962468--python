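"""Cohort orchestration: run every configured eye, apply inclusion rules,
aggregate, and leave an auditable manifest.

Config file (YAML or JSON)::

    seed: 1
    min_lesions: 50          # eyes with fewer included lesions are skipped
    pixel_size_um: 10
    analysis:                # optional AnalysisConfig overrides
      vessel_threshold: 60
      mark_threshold: 128
      connectivity: 8
    eyes:
      - id: eye01
        marked_ir: eye01/marked_ir.png
        cscan: eye01/cscan.png
        exclusion: eye01/exclusion.png   # optional

Relative paths resolve against the config file's directory. Outputs are
written atomically (temp file + rename) so a failed eye never corrupts
another eye's results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .cohort_stats import CohortSummary, summarize_cohort
from .colocalization import EyeResult, analyze_eye
from .errors import ChoropointError, InsufficientDataError
from .imaging_io import read_grayscale, read_mask
from .preprocess import AnalysisConfig

log = logging.getLogger(__name__)

DEFAULT_MIN_LESIONS = 50


@dataclass
class EyeStatus:
    eye_id: str
    inputs: dict[str, str]
    status: str  # "ok" or "skipped"
    reason: str = ""


@dataclass
class RunManifest:
    config: dict[str, Any]
    master_seed: int
    version: str
    eyes: list[EyeStatus] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": self.config,
            "master_seed": self.master_seed,
            "version": self.version,
            "eyes": [dataclasses.asdict(e) for e in self.eyes],
        }


def _atomic_write_json(obj: Any, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=2)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_config(config_path: str | Path) -> dict[str, Any]:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or not cfg.get("eyes"):
        raise ChoropointError(f"{config_path}: config must define at least one eye")
    return cfg


def run_cohort(config_path: str | Path, out_dir: str | Path | None = None,
               ) -> tuple[list[EyeResult], CohortSummary | None, RunManifest]:
    """Analyze every eye in the config, skip ineligible ones, summarize the rest.

    Eyes failing per-eye analysis, or with fewer than ``min_lesions``
    included points, are recorded as skipped with a reason; the cohort
    summary needs >= 2 surviving eyes (None otherwise).
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    base = config_path.parent
    seed = int(cfg.get("seed", 0))
    min_lesions = int(cfg.get("min_lesions", DEFAULT_MIN_LESIONS))
    pixel_size_um = float(cfg.get("pixel_size_um", 10.0))
    analysis_cfg = AnalysisConfig(**cfg.get("analysis", {}))
    out = Path(out_dir) if out_dir is not None else base / cfg.get("out_dir", "results")

    manifest = RunManifest(config=cfg, master_seed=seed, version=__version__)
    results: list[EyeResult] = []
    for i, eye_cfg in enumerate(cfg["eyes"]):
        eye_id = str(eye_cfg.get("id", f"eye{i:02d}"))
        inputs = {k: str(eye_cfg[k]) for k in ("marked_ir", "cscan", "exclusion") if k in eye_cfg}
        status = EyeStatus(eye_id=eye_id, inputs=inputs, status="ok")
        manifest.eyes.append(status)
        try:
            marked = read_grayscale(base / eye_cfg["marked_ir"], pixel_size_um)
            cscan = read_grayscale(base / eye_cfg["cscan"], pixel_size_um)
            exclusion = (read_mask(base / eye_cfg["exclusion"], "exclusion")
                         if "exclusion" in eye_cfg else None)
            result = analyze_eye(eye_id, marked, cscan, exclusion, analysis_cfg,
                                 seed=seed + i)
        except (ChoropointError, OSError, KeyError, ValueError) as exc:
            status.status = "skipped"
            status.reason = f"analysis failed: {exc}"
            log.warning("eye %s skipped: %s", eye_id, exc)
            continue
        if result.n_included < min_lesions:
            status.status = "skipped"
            status.reason = f"below min_lesions ({result.n_included} < {min_lesions})"
            log.info("eye %s skipped: %s", eye_id, status.reason)
            continue
        results.append(result)
        _atomic_write_json(result.to_dict(), out / f"{eye_id}.json")

    summary: CohortSummary | None = None
    if len(results) >= 2:
        try:
            summary = summarize_cohort(results)
            _atomic_write_json(summary.to_dict(), out / "cohort_summary.json")
        except InsufficientDataError as exc:
            log.warning("cohort summary unavailable: %s", exc)
    else:
        log.warning("only %d eligible eye(s); cohort summary requires 2", len(results))

    if results:
        _write_cohort_csv(results, out / "cohort.csv")
    _atomic_write_json(manifest.to_dict(), out / "manifest.json")
    return results, summary, manifest


def _write_cohort_csv(results: list[EyeResult], path: Path) -> None:
    import csv

    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["pct_vessel", "pct_near_1_3", "pct_mid_4_6", "pct_far_ge7"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["eye_id", "n_marked", "n_excluded", "n_included",
                         "vessel_area_fraction"]
                        + [f"obs_{c}" for c in cols] + [f"ctl_{c}" for c in cols])
        for r in results:
            writer.writerow([r.eye_id, r.n_marked, r.n_excluded, r.n_included,
                             f"{r.vessel_area_fraction:.6f}"]
                            + [f"{getattr(r.observed, c):.6f}" for c in cols]
                            + [f"{getattr(r.control, c):.6f}" for c in cols])
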