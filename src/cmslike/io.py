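"""Table schemas, run manifests and the stage pipeline.

CSV (UTF-8, comma, "." decimal) is the canonical tabular format; JSON
for summaries.  Every output table carries the tool version and the
config hash in a leading comment line, and every pipeline run emits one
manifest recording the config snapshot, all seeds, and the SHA-256 of
each file it read or wrote, so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import table1_report
from .classifier import ClassifierModel, classify_cohort, cohort_classification_report
from .quant import quantify_spot
from .survival import cox_fit, km_estimate, logrank_test
from .synthetic import (
    CohortConfig,
    ImageSpec,
    SurvivalParams,
    generate_cohort,
    generate_spot_image,
    perturb_annotation,
)
from .validation import ValidationRegion, validation_report

logger = logging.getLogger("cmslike")

__all__ = [
    "SchemaError",
    "TABLE_SCHEMAS",
    "validate_table",
    "read_table",
    "write_table",
    "RunManifest",
    "run_pipeline",
    "load_config",
]


class SchemaError(ValueError):
    """A table failed schema validation."""


def _score_range(lo, hi):
    return lambda s: s.isna() | ((s >= lo) & (s <= hi))


#: Required columns and row validators per table kind.  Optional columns
#: (e.g. htr2b_pct) may be absent or empty; unknown columns are preserved.
TABLE_SCHEMAS = {
    "patients": {
        "required": ["patient_id", "mmr_deficient"],
        "checks": {},
    },
    "spots": {
        "required": [
            "patient_id", "spot_index", "cdx2_intensity", "cdx2_pct",
            "frmd6_intensity", "frmd6_pct", "htr2b_intensity",
            "ker_intensity", "ker_pct", "zeb1_pct",
        ],
        "checks": {
            "spot_index": _score_range(1, 4),
            "cdx2_intensity": _score_range(0, 3),
            "frmd6_intensity": _score_range(0, 3),
            "htr2b_intensity": _score_range(0, 3),
            "ker_intensity": _score_range(0, 3),
            "cdx2_pct": _score_range(0, 100),
            "frmd6_pct": _score_range(0, 100),
            "ker_pct": _score_range(0, 100),
            "zeb1_pct": _score_range(0, 100),
        },
    },
    "bcat": {
        "required": ["patient_id", "spot_index", "nuclear_intensity",
                     "nuclear_pct_category"],
        "checks": {
            "nuclear_intensity": _score_range(0, 3),
            "nuclear_pct_category": _score_range(0, 4),
        },
    },
    "calls": {
        "required": ["patient_id", "cms_label", "stage_provenance"],
        "checks": {},
    },
}


def validate_table(df, kind):
    """Validate a table against its declared schema; raise SchemaError."""
    schema = TABLE_SCHEMAS[kind]
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind}: missing required column(s) {missing}")
    bad_rows = {}
    for col, check in schema["checks"].items():
        if col not in df.columns:
            continue
        ok = check(pd.to_numeric(df[col], errors="coerce"))
        # values that fail to parse count as out of range unless empty
        ok |= df[col].isna()
        if not ok.all():
            bad_rows[col] = df.index[~ok].tolist()
    if bad_rows:
        lines = "; ".join(f"{c}: rows {r}" for c, r in bad_rows.items())
        raise SchemaError(f"{kind}: out-of-range values ({lines})")
    return df


def _file_sha256(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def save_image(rgb, path):
    """Write an 8-bit RGB spot image as PNG (or TIFF by extension)."""
    from PIL import Image

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)
    return path


def load_image(path):
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def save_mask(mask, path):
    """Write a binary mask as a single-channel 0/255 PNG."""
    from PIL import Image

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    return path


def load_mask(path):
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("L")) >= 128


def write_table(df, path, kind=None, config_hash=""):
    """Write a CSV with a comment header carrying version and config hash."""
    if kind is not None:
        validate_table(df, kind)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# cmslike {__version__} config={config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path, kind=None):
    """Read a CSV written by :func:`write_table` (or any plain CSV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    if kind is not None:
        validate_table(df, kind)
    return df


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record emitted by every pipeline run."""

    config: dict
    seed: int
    stages: list
    version: str = __version__
    inputs: dict = dataclasses.field(default_factory=dict)
    outputs: dict = dataclasses.field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def write(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=str))
        return path


_DEFAULT_CONFIG = {
    "cohort": {},            # CohortConfig field overrides
    "survival": {},          # SurvivalParams overrides
    "image": {},             # ImageSpec overrides
    "model": {},             # ClassifierModel overrides
    "association": {"ordering": "pearson", "reps": 100000},
    "quantify": {"n_images": 3, "markers": ["CDX2", "KER"]},
    "survive": {"endpoint": "os"},
    "validate": {"n_regions": 5, "n_validators": 2, "jitter": 2.0},
}


def load_config(path=None):
    """Load a YAML/JSON config file, merged over the defaults."""
    cfg = json.loads(json.dumps(_DEFAULT_CONFIG))
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise SchemaError(f"config {path}: expected a mapping at top level")
        for key, val in user.items():
            if key not in cfg:
                raise SchemaError(f"config {path}: unknown section {key!r}")
            if isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _config_hash(cfg):
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


ALL_STAGES = ("simulate", "quantify", "classify", "associate", "survive",
              "validate")


def run_pipeline(config=None, outdir="cmslike_out", stages=ALL_STAGES, seed=0):
    """Run the pipeline stages in dependency order and emit a manifest.

    ``config`` may be a path to a YAML/JSON file, a dict, or ``None``
    for the defaults.  Returns the :class:`RunManifest`.
    """
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = load_config(None)
        for key, val in config.items():
            if isinstance(val, dict):
                cfg.setdefault(key, {}).update(val)
            else:
                cfg[key] = val
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    manifest = RunManifest(config=cfg, seed=seed, stages=list(stages),
                           started=time.time())
    rng = np.random.default_rng(seed)

    def record(path):
        manifest.outputs[str(path)] = _file_sha256(path)

    stages = list(stages)
    if "simulate" in stages:
        logger.info("stage simulate")
        sp = SurvivalParams(**cfg["survival"])
        cc = CohortConfig(seed=seed, survival_params=sp, **cfg["cohort"])
        patients, spots, bcat = generate_cohort(cc)
        record(write_table(patients, outdir / "patients.csv",
                           "patients", chash))
        record(write_table(spots, outdir / "spots.csv", "spots", chash))
        record(write_table(bcat, outdir / "bcat.csv", "bcat", chash))

    if "quantify" in stages:
        logger.info("stage quantify")
        rows = []
        qc = cfg["quantify"]
        for i in range(int(qc["n_images"])):
            spec = ImageSpec(seed=int(rng.integers(2**31)), **cfg["image"])
            img, _, gt = generate_spot_image(spec)
            for marker in qc["markers"]:
                res = quantify_spot(img, marker)
                rows.append(
                    {
                        "image_index": i,
                        "marker": marker,
                        "continuous_intensity": res.continuous_intensity,
                        "rounded_intensity": res.rounded_intensity,
                        "percent_positive": res.percent_positive,
                        "truth_intensity": gt["continuous_intensity"],
                        "truth_percent": gt["percent_positive"],
                    }
                )
        record(write_table(pd.DataFrame(rows), outdir / "quant.csv",
                           config_hash=chash))

    if "classify" in stages:
        logger.info("stage classify")
        patients = read_table(outdir / "patients.csv", "patients")
        spots = read_table(outdir / "spots.csv", "spots")
        bcat = read_table(outdir / "bcat.csv", "bcat")
        model = ClassifierModel(**cfg["model"])
        calls = classify_cohort(patients, spots, bcat, model)
        record(write_table(calls, outdir / "calls.csv", "calls", chash))
        report = cohort_classification_report(calls)
        rpath = outdir / "classification_summary.json"
        rpath.write_text(json.dumps(report, indent=2))
        record(rpath)

    if "associate" in stages:
        logger.info("stage associate")
        patients = read_table(outdir / "patients.csv", "patients")
        calls = read_table(outdir / "calls.csv", "calls")
        merged = patients.merge(calls[["patient_id", "cms_label"]],
                                on="patient_id")
        ac = cfg["association"]
        assoc = table1_report(merged, ordering=ac["ordering"],
                              reps=int(ac["reps"]), seed=seed)
        record(write_table(assoc, outdir / "associations.csv",
                           config_hash=chash))

    if "survive" in stages:
        logger.info("stage survive")
        patients = read_table(outdir / "patients.csv", "patients")
        calls = read_table(outdir / "calls.csv", "calls")
        merged = patients.merge(calls[["patient_id", "cms_label"]],
                                on="patient_id")
        merged = merged[merged["cms_label"] != "unclassified"]
        endpoint = cfg["survive"]["endpoint"]
        if endpoint not in ("os", "dss"):
            raise SchemaError("survive.endpoint must be 'os' or 'dss'")
        event_col = "os_event" if endpoint == "os" else "dss_event"
        groups = sorted(merged["cms_label"].unique())
        km_rows = []
        gts, ges = [], []
        for g in groups:
            sub = merged[merged["cms_label"] == g]
            t = sub["os_time"].to_numpy(float)
            e = sub[event_col].to_numpy(bool)
            gts.append(t)
            ges.append(e)
            if e.any():
                curve = km_estimate(t, e)
                for i in range(curve.times.size):
                    km_rows.append(
                        {
                            "group": g, "time": curve.times[i],
                            "survival": curve.survival[i],
                            "ci_low": curve.ci_low[i],
                            "ci_high": curve.ci_high[i],
                            "at_risk": curve.at_risk[i],
                        }
                    )
        record(write_table(pd.DataFrame(km_rows), outdir / "km_curves.csv",
                           config_hash=chash))
        results = {}
        if len(groups) >= 2:
            chi2, df, p = logrank_test(gts, ges)
            results["logrank"] = {"chi2": chi2, "df": df, "p": p}
            if "CMS2-like" in groups:
                ref = "CMS2-like"
                cols = {
                    f"cms[{g}]": (merged["cms_label"] == g).to_numpy(float)
                    for g in groups if g != ref
                }
                fit = cox_fit(
                    np.column_stack(list(cols.values())),
                    merged["os_time"].to_numpy(float),
                    merged[event_col].to_numpy(bool),
                    names=list(cols.keys()),
                )
                results["cox_univariable_subtype"] = json.loads(
                    fit.summary().to_json(orient="index")
                )
        spath = outdir / "survival_results.json"
        spath.write_text(json.dumps(results, indent=2))
        record(spath)

    if "validate" in stages:
        logger.info("stage validate")
        vc = cfg["validate"]
        regions = []
        for i in range(int(vc["n_regions"])):
            spec = ImageSpec(seed=int(rng.integers(2**31)), **cfg["image"])
            _, mask, gt = generate_spot_image(spec)
            validators = [
                perturb_annotation(mask, vc["jitter"],
                                   seed=int(rng.integers(2**31)))
                for _ in range(int(vc["n_validators"]))
            ]
            regions.append(
                ValidationRegion(
                    model_mask=mask,
                    validator_masks=validators,
                    model_score=gt["rounded_intensity"],
                    validator_scores=[gt["rounded_intensity"]] * len(validators),
                )
            )
        rep = validation_report(regions)
        record(write_table(rep, outdir / "validation_report.csv",
                           config_hash=chash))

    manifest.finished = time.time()
    manifest.write(outdir / "manifest.json")
    return manifest
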