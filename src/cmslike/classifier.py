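"""Hierarchical CMS-resembling classification of colorectal tumors.

Three stages, applied per patient:

1. **MMR gate** — mismatch-repair-deficient tumors are CMS1-like,
   regardless of marker scores.
2. **Five-marker spot classifier** — each evaluable TMA spot's panel
   (CDX2, FRMD6, HTR2B, ZEB1, KER) yields a probability of being
   epithelial; spots are called E or M and the majority over 1-4 spots
   decides CMS2/3-like (E) vs CMS4-like (M).  An exact tie is
   inconclusive and the patient is left unclassified.
3. **Beta-catenin split** — CMS2/3-like tumors with a positive nuclear
   beta-catenin consensus (score >= 2 in intensity or percentage
   category, majority over spots) are CMS2-like, negative ones
   CMS3-like; a tied consensus is inconclusive.

The spot classifier is a pluggable logistic model over the panel
features with ZEB1 entered as a presence indicator (>= 2% cutoff).  The
default coefficients fix the biological signs (CDX2 and KER epithelial,
FRMD6/HTR2B/ZEB1 mesenchymal) with magnitudes calibrated once on the
synthetic generator's well-separated phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import round_intensity

__all__ = [
    "LABELS",
    "ZEB1_PRESENCE_CUTOFF",
    "SpotMarkerPanel",
    "BetaCateninScore",
    "ClassifierModel",
    "SubtypeCall",
    "zeb1_presence",
    "spot_epithelial_probability",
    "classify_spot",
    "aggregate_spot_calls",
    "beta_catenin_call",
    "aggregate_bcat",
    "classify_patient",
    "classify_cohort",
    "cohort_classification_report",
]

LABELS = ("CMS1-like", "CMS2-like", "CMS3-like", "CMS4-like", "unclassified")

#: ZEB1 percent-positive cutoff below which staining counts as absent,
#: suppressing potential false positives.
ZEB1_PRESENCE_CUTOFF = 2.0


@dataclass(frozen=True)
class SpotMarkerPanel:
    """One TMA spot's five-marker scores (the classifier feature vector)."""

    cdx2_intensity: int
    cdx2_pct: float
    frmd6_intensity: int
    frmd6_pct: float
    htr2b_intensity: int
    ker_intensity: int
    ker_pct: float
    zeb1_pct: float

    def __post_init__(self):
        for name in ("cdx2_intensity", "frmd6_intensity", "htr2b_intensity",
                     "ker_intensity"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3):
                raise ValueError(f"{name}={v!r} not an integer score 0-3")
        for name in ("cdx2_pct", "frmd6_pct", "ker_pct", "zeb1_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v!r} outside [0,100]")


@dataclass(frozen=True)
class BetaCateninScore:
    """Nuclear beta-catenin spot score.

    intensity: 0 negative, 1 low, 2 moderate, 3 high.
    pct_category: 0 negative, 1 = 1-10%, 2 = 11-50%, 3 = 51-90%,
    4 = >= 90% of cells.
    """

    nuclear_intensity: int
    nuclear_pct_category: int

    def __post_init__(self):
        if self.nuclear_intensity not in (0, 1, 2, 3):
            raise ValueError("nuclear_intensity must be in 0..3")
        if self.nuclear_pct_category not in (0, 1, 2, 3, 4):
            raise ValueError("nuclear_pct_category must be in 0..4")


@dataclass(frozen=True)
class ClassifierModel:
    """Logistic spot model: P(epithelial) = logistic(intercept + coef . x).

    Features: the four integer intensities, the three percentages, and
    the ZEB1 presence indicator.  Positive coefficients push toward the
    epithelial (CMS2/3-like) call.
    """

    intercept: float = 0.0
    coefficients: dict = field(
        default_factory=lambda: {
            "cdx2_intensity": 1.2,
            "cdx2_pct": 0.03,
            "ker_intensity": 0.8,
            "ker_pct": 0.02,
            "frmd6_intensity": -1.2,
            "frmd6_pct": -0.03,
            "htr2b_intensity": -1.0,
            "zeb1_present": -2.0,
        }
    )
    threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0,1)")
        for k, v in self.coefficients.items():
            if not np.isfinite(v):
                raise ValueError(f"coefficient {k} is not finite")


@dataclass
class SubtypeCall:
    """A patient's final label with per-stage provenance."""

    patient_id: str
    label: str
    stage_provenance: str
    spot_probabilities: list = field(default_factory=list)
    spot_calls: list = field(default_factory=list)
    bcat_consensus: str | None = None


def zeb1_presence(zeb1_pct):
    """ZEB1 present iff percent positive >= the 2% cutoff."""
    p = float(zeb1_pct)
    if not 0.0 <= p <= 100.0:
        raise ValueError("zeb1_pct outside [0,100]")
    return p >= ZEB1_PRESENCE_CUTOFF


def spot_epithelial_probability(panel: SpotMarkerPanel, model: ClassifierModel):
    """Probability that one spot is epithelial (CMS2/3-like) type."""
    feats = {
        "cdx2_intensity": panel.cdx2_intensity,
        "cdx2_pct": panel.cdx2_pct,
        "frmd6_intensity": panel.frmd6_intensity,
        "frmd6_pct": panel.frmd6_pct,
        "htr2b_intensity": panel.htr2b_intensity,
        "ker_intensity": panel.ker_intensity,
        "ker_pct": panel.ker_pct,
        "zeb1_present": 1.0 if zeb1_presence(panel.zeb1_pct) else 0.0,
    }
    score = model.intercept + sum(
        coef * feats[name] for name, coef in model.coefficients.items()
    )
    return float(1.0 / (1.0 + np.exp(-score)))


def classify_spot(prob, threshold=0.5):
    """E (epithelial) if prob >= threshold else M; ties break to E."""
    return "E" if prob >= threshold else "M"


def aggregate_spot_calls(calls):
    """Majority vote over 1-4 spot calls; an exact tie is inconclusive."""
    calls = list(calls)
    if not calls:
        raise ValueError("no spot calls to aggregate")
    e = calls.count("E")
    m = calls.count("M")
    if e > m:
        return "CMS2/3-like"
    if m > e:
        return "CMS4-like"
    return "inconclusive"


def beta_catenin_call(score: BetaCateninScore):
    """Positive iff nuclear score >= 2 in either intensity or percentage."""
    return score.nuclear_intensity >= 2 or score.nuclear_pct_category >= 2


def aggregate_bcat(calls):
    """Majority beta-catenin status over spots; an exact tie is inconclusive."""
    calls = list(calls)
    if not calls:
        raise ValueError("no beta-catenin calls to aggregate")
    pos = sum(bool(c) for c in calls)
    neg = len(calls) - pos
    if pos > neg:
        return "positive"
    if neg > pos:
        return "negative"
    return "inconclusive"


def classify_patient(patient_id, mmr_deficient, panels, bcat_scores,
                     model: ClassifierModel | None = None):
    """Run the full three-stage classification for one patient.

    ``panels`` is a sequence of :class:`SpotMarkerPanel` (may be empty for
    mismatch-repair-deficient patients); ``bcat_scores`` a sequence of
    :class:`BetaCateninScore`.
    """
    if model is None:
        model = ClassifierModel()
    if mmr_deficient:
        return SubtypeCall(patient_id, "CMS1-like", "MMR gate")
    panels = list(panels)
    if not panels:
        return SubtypeCall(patient_id, "unclassified", "missing-data")
    probs = [spot_epithelial_probability(p, model) for p in panels]
    calls = [classify_spot(p, model.threshold) for p in probs]
    vote = aggregate_spot_calls(calls)
    if vote == "inconclusive":
        return SubtypeCall(patient_id, "unclassified", "inconclusive-at-vote",
                           probs, calls)
    if vote == "CMS4-like":
        return SubtypeCall(patient_id, "CMS4-like", "spot vote", probs, calls)
    # CMS2/3-like: split on the beta-catenin consensus
    bcat_scores = list(bcat_scores)
    if not bcat_scores:
        return SubtypeCall(patient_id, "unclassified", "missing-data",
                           probs, calls)
    consensus = aggregate_bcat(beta_catenin_call(s) for s in bcat_scores)
    if consensus == "inconclusive":
        return SubtypeCall(patient_id, "unclassified", "inconclusive-at-bcat",
                           probs, calls, consensus)
    label = "CMS2-like" if consensus == "positive" else "CMS3-like"
    return SubtypeCall(patient_id, label, "beta-catenin split", probs, calls,
                       consensus)


_PANEL_COLS = {
    "cdx2_intensity": True, "cdx2_pct": False, "frmd6_intensity": True,
    "frmd6_pct": False, "htr2b_intensity": True, "ker_intensity": True,
    "ker_pct": False, "zeb1_pct": False,
}


def _panel_from_row(row):
    kwargs = {}
    for col, is_intensity in _PANEL_COLS.items():
        v = row[col]
        if pd.isna(v):
            raise ValueError(f"missing feature {col}")
        kwargs[col] = round_intensity(float(v)) if is_intensity else float(v)
    return SpotMarkerPanel(**kwargs)


def classify_cohort(patients, spots, bcat, model: ClassifierModel | None = None):
    """Classify every patient of a cohort from tabular inputs.

    ``patients`` needs ``patient_id`` and ``mmr_deficient``; ``spots``
    one row per spot with the panel columns (continuous intensities are
    rounded to integer scores here, mirroring the regression-then-round
    scoring flow); ``bcat`` one row per spot with the nuclear
    beta-catenin scores.  Returns a data frame with one row per patient
    (label + provenance) in the input patient order.
    """
    if model is None:
        model = ClassifierModel()
    spot_groups = dict(tuple(spots.groupby("patient_id"))) if len(spots) else {}
    bcat_groups = dict(tuple(bcat.groupby("patient_id"))) if len(bcat) else {}
    rows = []
    for _, prow in patients.iterrows():
        pid = prow["patient_id"]
        panels = []
        if pid in spot_groups:
            for _, srow in spot_groups[pid].iterrows():
                try:
                    panels.append(_panel_from_row(srow))
                except ValueError:
                    continue  # spot skipped: incomplete panel
        scores = []
        if pid in bcat_groups:
            scores = [
                BetaCateninScore(int(r["nuclear_intensity"]),
                                 int(r["nuclear_pct_category"]))
                for _, r in bcat_groups[pid].iterrows()
            ]
        call = classify_patient(pid, bool(prow["mmr_deficient"]), panels,
                                scores, model)
        rows.append(
            {
                "patient_id": pid,
                "cms_label": call.label,
                "stage_provenance": call.stage_provenance,
                "n_spots": len(call.spot_calls),
                "bcat_consensus": call.bcat_consensus,
            }
        )
    return pd.DataFrame(rows)


def cohort_classification_report(calls):
    """Counts and percentages per label plus the classified fraction.

    ``calls`` is either a data frame with a ``cms_label`` column or a
    sequence of labels.  Percentages are reported both over classified
    patients and over the whole cohort (the two denominators differ and
    both are meaningful).
    """
    if isinstance(calls, pd.DataFrame):
        labels = calls["cms_label"]
    else:
        labels = pd.Series([getattr(c, "label", c) for c in calls])
    if len(labels) == 0:
        raise ValueError("no calls")
    counts = {lab: int((labels == lab).sum()) for lab in LABELS}
    n = int(len(labels))
    n_classified = n - counts["unclassified"]
    report = {
        "n_patients": n,
        "n_classified": n_classified,
        "classified_fraction_pct": 100.0 * n_classified / n,
        "counts": counts,
        "pct_of_classified": {
            lab: (100.0 * counts[lab] / n_classified if n_classified else 0.0)
            for lab in LABELS[:4]
        },
        "pct_of_cohort": {lab: 100.0 * counts[lab] / n for lab in LABELS[:4]},
    }
    return report
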