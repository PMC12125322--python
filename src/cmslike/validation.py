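"""Model-vs-annotator validation arithmetic for segmentation and scoring.

Area-overlap precision and sensitivity between a model's analysis mask
and a human annotation mask, their harmonic mean (F1), and the
percentage of regions where the model's rounded intensity score matches
a validator's score.  Summaries average unweighted over regions, then
over validators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationRegion",
    "area_precision",
    "area_sensitivity",
    "f1",
    "matching_intensity",
    "validation_report",
]

logger = logging.getLogger(__name__)


def _as_mask(m):
    return np.asarray(m).astype(bool)


def area_precision(model, annot):
    """|model ∩ annot| / |model| — fraction of the model's area confirmed.

    Returns ``nan`` (undefined) for an empty model mask.
    """
    model, annot = _as_mask(model), _as_mask(annot)
    if model.shape != annot.shape:
        raise ValueError("mask dimensions differ")
    denom = model.sum()
    if denom == 0:
        return float("nan")
    return float(np.count_nonzero(model & annot) / denom)


def area_sensitivity(model, annot):
    """|model ∩ annot| / |annot| — fraction of the annotation recovered.

    Returns ``nan`` (undefined) for an empty annotation mask.
    """
    model, annot = _as_mask(model), _as_mask(annot)
    if model.shape != annot.shape:
        raise ValueError("mask dimensions differ")
    denom = annot.sum()
    if denom == 0:
        return float("nan")
    return float(np.count_nonzero(model & annot) / denom)


def f1(precision, sensitivity):
    """Harmonic mean of precision and sensitivity; 0 when both are 0."""
    p, s = float(precision), float(sensitivity)
    if not (0.0 <= p <= 1.0 and 0.0 <= s <= 1.0):
        raise ValueError("precision and sensitivity must be in [0,1]")
    if p + s == 0.0:
        return 0.0
    return 2.0 * p * s / (p + s)


def matching_intensity(model_scores, validator_scores):
    """Percentage of positions where the rounded scores agree exactly."""
    m = np.asarray(model_scores)
    v = np.asarray(validator_scores)
    if m.shape != v.shape or m.size == 0:
        raise ValueError("score sequences must be nonempty and equal length")
    return float(100.0 * np.count_nonzero(m == v) / m.size)


@dataclass
class ValidationRegion:
    """One validation region: model output vs one or more human validators."""

    model_mask: np.ndarray
    validator_masks: list = field(default_factory=list)
    model_score: int | None = None
    validator_scores: list = field(default_factory=list)

    def __post_init__(self):
        for vm in self.validator_masks:
            if np.asarray(vm).shape != np.asarray(self.model_mask).shape:
                raise ValueError("all masks must share dimensions")


def validation_report(regions):
    """Summarize model-vs-validator and validator-vs-validator agreement.

    Returns a data frame with one row per comparison pair: mean
    precision, sensitivity and F1 over regions (undefined regions
    dropped with a warning) plus the matching-intensity percentage when
    scores are present.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("need at least one region")
    n_val = len(regions[0].validator_masks)
    if n_val == 0:
        raise ValueError("need at least one validator")

    rows = []

    def summarize(kind, label, pairs, score_pairs):
        ps, ss, fs = [], [], []
        dropped = 0
        for a, b in pairs:
            p, s = area_precision(a, b), area_sensitivity(a, b)
            if np.isnan(p) or np.isnan(s):
                dropped += 1
                continue
            ps.append(p)
            ss.append(s)
            fs.append(f1(p, s))
        if dropped:
            logger.warning("%s %s: dropped %d empty-mask region(s)", kind, label, dropped)
        match = None
        if score_pairs:
            a, b = zip(*score_pairs)
            match = matching_intensity(a, b)
        rows.append(
            {
                "comparison": kind,
                "pair": label,
                "mean_precision": float(np.mean(ps)) if ps else float("nan"),
                "mean_sensitivity": float(np.mean(ss)) if ss else float("nan"),
                "mean_f1": float(np.mean(fs)) if fs else float("nan"),
                "matching_intensity_pct": match,
                "n_regions": len(ps),
            }
        )

    for v in range(n_val):
        pairs = [(r.model_mask, r.validator_masks[v]) for r in regions]
        score_pairs = [
            (r.model_score, r.validator_scores[v])
            for r in regions
            if r.model_score is not None and len(r.validator_scores) > v
        ]
        summarize("model-vs-validator", f"model|v{v + 1}", pairs, score_pairs)
    for v1 in range(n_val):
        for v2 in range(v1 + 1, n_val):
            pairs = [(r.validator_masks[v1], r.validator_masks[v2]) for r in regions]
            score_pairs = [
                (r.validator_scores[v1], r.validator_scores[v2])
                for r in regions
                if len(r.validator_scores) > v2
            ]
            summarize("validator-vs-validator", f"v{v1 + 1}|v{v2 + 1}", pairs, score_pairs)

    report = pd.DataFrame(rows)
    # averaged-across-validators summary for the model
    mv = report[report["comparison"] == "model-vs-validator"]
    summary = {
        "comparison": "model-averaged",
        "pair": "model|all",
        "mean_precision": mv["mean_precision"].mean(),
        "mean_sensitivity": mv["mean_sensitivity"].mean(),
        "mean_f1": mv["mean_f1"].mean(),
        "matching_intensity_pct": mv["matching_intensity_pct"].mean(),
        "n_regions": int(mv["n_regions"].sum()),
    }
    return pd.concat([report, pd.DataFrame([summary])], ignore_index=True)
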