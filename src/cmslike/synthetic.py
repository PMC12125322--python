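"""Synthetic cohorts and synthetic TMA spot images with ground truth.

Every downstream stage of the pipeline (spot quantification, subtype
classification, association testing, survival analysis, validation metrics)
is exercised on data produced here, since no patient-level data are
publicly deposited.  The generator emulates:

* four latent CMS-resembling subtypes with configurable prevalence,
* per-subtype marker distributions for the five-marker panel
  (CDX2, FRMD6, HTR2B, ZEB1, cytokeratin/KER) with epithelial vs
  mesenchymal directionality,
* up to four 1-mm TMA spots per tumor with independent inter-spot noise
  and spot dropout,
* beta-catenin nuclear scores concentrated on the CMS2-like subtype,
* mismatch-repair deficiency concentrated on the CMS1-like subtype,
* proportional-hazards survival with subtype-specific log hazard ratios,
  independent censoring and administrative censoring at a follow-up
  horizon,
* synthetic DAB/hematoxylin spot images with exact epithelium masks and
  known intensity / percent-positive ground truth (two-stain
  Beer-Lambert synthesis, invertible by :mod:`cmslike.quant`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.stats import truncnorm

__all__ = [
    "SUBTYPES",
    "MARKERS",
    "MarkerDist",
    "SurvivalParams",
    "CohortConfig",
    "ImageSpec",
    "ConfigurationError",
    "generate_cohort",
    "generate_survival",
    "generate_spot_image",
    "perturb_annotation",
    "default_marker_params",
    "default_bcat_params",
]

#: Latent subtype labels, in fixed order (CMS1-like .. CMS4-like).
SUBTYPES = ("CMS1L", "CMS2L", "CMS3L", "CMS4L")

#: Marker panel, in the column order used throughout the package.
MARKERS = ("CDX2", "FRMD6", "HTR2B", "ZEB1", "KER")

# ---------------------------------------------------------------------------
# Stain model shared with cmslike.quant (Beer-Lambert, H-DAB)
# ---------------------------------------------------------------------------

#: Unit optical-density vector of hematoxylin in RGB (Ruifrok-Johnston).
STAIN_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
#: Unit optical-density vector of DAB in RGB (Ruifrok-Johnston).
STAIN_DAB = np.array([0.268, 0.570, 0.776])
#: DAB optical density produced by one unit of the 0-3 intensity scale.
DAB_OD_PER_UNIT = 0.35
#: Hematoxylin OD of non-epithelial tissue / of epithelium.
_H_OD_STROMA = 0.25
_H_OD_EPITHELIUM = 0.70


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class MarkerDist:
    """Truncated-normal parameters for one marker in one subtype.

    Intensity lives on the continuous 0-3 scale; percent positive on
    0-100.  ``pct_mean is None`` marks markers whose percentage is never
    scored (HTR2B).
    """

    intensity_mean: float
    intensity_sd: float
    pct_mean: float | None = None
    pct_sd: float | None = None


def default_marker_params() -> dict[str, dict[str, MarkerDist]]:
    """Well-separated epithelial vs mesenchymal marker distributions.

    CMS1/2/3-like tumors share the epithelial phenotype (high CDX2 and
    KER, low FRMD6/HTR2B, ZEB1 essentially absent); CMS4-like is the
    converse, mesenchymal phenotype.
    """
    epithelial = {
        "CDX2": MarkerDist(2.4, 0.35, 82.0, 8.0),
        "FRMD6": MarkerDist(0.6, 0.35, 15.0, 8.0),
        "HTR2B": MarkerDist(0.5, 0.30),
        "ZEB1": MarkerDist(0.0, 0.0, 0.5, 0.5),
        "KER": MarkerDist(2.3, 0.35, 80.0, 8.0),
    }
    mesenchymal = {
        "CDX2": MarkerDist(0.7, 0.35, 20.0, 8.0),
        "FRMD6": MarkerDist(2.3, 0.40, 70.0, 10.0),
        "HTR2B": MarkerDist(2.2, 0.40),
        "ZEB1": MarkerDist(0.0, 0.0, 12.0, 6.0),
        "KER": MarkerDist(1.2, 0.40, 40.0, 10.0),
    }
    return {
        "CMS1L": epithelial,
        "CMS2L": epithelial,
        "CMS3L": epithelial,
        "CMS4L": mesenchymal,
    }


def default_bcat_params() -> dict[str, tuple[tuple[float, ...], tuple[float, ...]]]:
    """Per-subtype (intensity 0-3 probs, percent-category 0-4 probs).

    Nuclear beta-catenin positivity (score >= 2 in either axis) is
    concentrated in CMS2-like and rare elsewhere.
    """
    positive = ((0.05, 0.15, 0.45, 0.35), (0.05, 0.15, 0.30, 0.30, 0.20))
    negative = ((0.60, 0.35, 0.04, 0.01), (0.60, 0.35, 0.03, 0.015, 0.005))
    return {
        "CMS1L": negative,
        "CMS2L": positive,
        "CMS3L": negative,
        "CMS4L": negative,
    }


@dataclass(frozen=True)
class SurvivalParams:
    """Weibull proportional-hazards generator settings.

    baseline_hazard is the scale-rate of the baseline (CMS2-like) group
    per year; shape=1 gives exponential event times.  log_hrs are the
    per-subtype log hazard ratios in SUBTYPES order (CMS2-like = 0 by
    convention).  censoring_rate is the target marginal fraction of
    subjects randomly censored before their event (implemented as
    independent exponential censoring whose rate is solved numerically);
    a value >= 1 withdraws every subject before any event occurs.
    dss_attribution is the probability that a death is attributed to the
    disease (so disease-specific events are a subset of overall-survival
    events).
    """

    baseline_hazard: float = 0.08
    shape: float = 1.0
    log_hrs: tuple[float, float, float, float] = (0.45, 0.0, 0.37, 0.37)
    censoring_rate: float = 0.15
    horizon: float = 15.0
    dss_attribution: float = 0.7

    def validate(self) -> None:
        if self.baseline_hazard <= 0 or self.shape <= 0:
            raise ConfigurationError("hazard parameters must be positive")
        if not 0.0 <= self.censoring_rate:
            raise ConfigurationError("censoring_rate must be >= 0")
        if self.horizon <= 0:
            raise ConfigurationError("follow-up horizon must be positive")
        if not 0.0 <= self.dss_attribution <= 1.0:
            raise ConfigurationError("dss_attribution must be a probability")


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort."""

    n_patients: int = 538
    subtype_prevalence: tuple[float, float, float, float] = (0.158, 0.349, 0.385, 0.108)
    spots_per_patient: int = 4
    spot_dropout_prob: float = 0.05
    marker_params: dict = field(default_factory=default_marker_params)
    bcat_params: dict = field(default_factory=default_bcat_params)
    mmr_deficiency_prob: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    # independent per-spot noise around the patient-level phenotype
    spot_intensity_sd: float = 0.20
    spot_pct_sd: float = 4.0
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        prev = np.asarray(self.subtype_prevalence, dtype=float)
        if prev.shape != (4,) or np.any(prev < 0) or abs(prev.sum() - 1.0) > 1e-9:
            raise ConfigurationError("subtype_prevalence must be a 4-simplex vector")
        if self.spots_per_patient not in (1, 2, 3, 4):
            raise ConfigurationError("spots_per_patient must be in 1..4")
        if not 0.0 <= self.spot_dropout_prob < 1.0:
            raise ConfigurationError("spot_dropout_prob must be in [0,1)")
        for p in self.mmr_deficiency_prob:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("mmr_deficiency_prob entries must be in [0,1]")
        self.survival_params.validate()


# ---------------------------------------------------------------------------
# Clinicopathological covariates (marginals of a stage I-IV surgical cohort;
# independent of the latent subtype so association scans are null by default)
# ---------------------------------------------------------------------------

_COVARIATE_LEVELS = {
    "age_group": (("<69", ">=69"), (0.485, 0.515)),
    "sex": (("female", "male"), (0.47, 0.53)),
    "stage": (("I", "II", "III", "IV"), (0.187, 0.297, 0.351, 0.165)),
    "pT": (("1", "2", "3", "4"), (0.042, 0.202, 0.645, 0.111)),
    "pN": (("0", "1", "2"), (0.513, 0.279, 0.208)),
    "grade": (("low", "high"), (0.883, 0.117)),
    "location": (("right colon", "left colon", "rectum"), (0.293, 0.239, 0.468)),
    "histology": (("non-mucinous", "mucinous"), (0.938, 0.062)),
}


def _trunc_normal(rng, mean, sd, low, high, size=None):
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    if size is None:
        size = np.broadcast_shapes(mean.shape, sd.shape)
    if np.all(sd <= 0):
        return np.broadcast_to(np.clip(mean, low, high), size).copy()
    sd = np.maximum(sd, 1e-12)
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig):
    """Draw a cohort of patients with spot-level marker panels.

    Returns ``(patients, spots, bcat)`` as three data frames.

    * ``patients`` -- one row per patient: latent subtype (ground truth,
      hidden from the classifier), clinicopathological covariates,
      mismatch-repair status, and survival columns.
    * ``spots`` -- one row per evaluable TMA spot with continuous marker
      intensities (0-3) and percent-positive values (0-100); rounding to
      integer scores happens downstream in the classifier, mirroring the
      regression-then-round scoring flow.
    * ``bcat`` -- one row per spot with ordinal nuclear beta-catenin
      scores (intensity 0-3, percent category 0-4).

    Deterministic under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    subtype_idx = rng.choice(4, size=n, p=np.asarray(config.subtype_prevalence, float))
    subtypes = np.array(SUBTYPES)[subtype_idx]
    patient_ids = np.array([f"P{i:05d}" for i in range(n)])

    patients = pd.DataFrame({"patient_id": patient_ids, "latent_subtype": subtypes})
    for name, (levels, probs) in _COVARIATE_LEVELS.items():
        patients[name] = rng.choice(levels, size=n, p=np.asarray(probs))
    # pM = 1 iff stage IV (metastatic at diagnosis)
    patients["pM"] = np.where(patients["stage"] == "IV", "1", "0")
    mmr_p = np.asarray(config.mmr_deficiency_prob, float)[subtype_idx]
    patients["mmr_deficient"] = rng.random(n) < mmr_p

    # --- spot panels (vectorized: patient-level latent phenotype, then
    # independent per-spot noise) -------------------------------------------
    mp = config.marker_params
    S = config.spots_per_patient
    latent_int = {}
    latent_pct = {}
    for m in MARKERS:
        i_mean = np.empty(n)
        i_sd = np.empty(n)
        p_mean = np.full(n, np.nan)
        p_sd = np.full(n, np.nan)
        has_pct = mp[SUBTYPES[0]][m].pct_mean is not None
        for k, st in enumerate(SUBTYPES):
            d: MarkerDist = mp[st][m]
            sel = subtype_idx == k
            i_mean[sel], i_sd[sel] = d.intensity_mean, d.intensity_sd
            if d.pct_mean is not None:
                p_mean[sel], p_sd[sel] = d.pct_mean, d.pct_sd
        latent_int[m] = _trunc_normal(rng, i_mean, i_sd, 0, 3)
        latent_pct[m] = (
            _trunc_normal(rng, p_mean, p_sd, 0, 100) if has_pct else p_mean
        )

    keep = rng.random((n, S)) >= config.spot_dropout_prob
    empty = ~keep.any(axis=1)
    if empty.any():  # always leave at least one evaluable spot
        keep[np.flatnonzero(empty), rng.integers(0, S, empty.sum())] = True

    spot_cols = {
        "patient_id": np.repeat(patient_ids, S)[keep.ravel()],
        "spot_index": np.tile(np.arange(1, S + 1), n)[keep.ravel()],
    }
    for m in MARKERS:
        key = m.lower()
        if m != "ZEB1":
            vals = _trunc_normal(
                rng,
                np.repeat(latent_int[m], S),
                config.spot_intensity_sd,
                0,
                3,
                size=n * S,
            )
            spot_cols[f"{key}_intensity"] = vals[keep.ravel()]
        if m != "HTR2B":
            vals = _trunc_normal(
                rng,
                np.repeat(latent_pct[m], S),
                config.spot_pct_sd,
                0,
                100,
                size=n * S,
            )
            spot_cols[f"{key}_pct"] = vals[keep.ravel()]
    spots = pd.DataFrame(spot_cols)

    # --- beta-catenin scores ----------------------------------------------
    b_int = np.empty(n * S, dtype=np.int64)
    b_pct = np.empty(n * S, dtype=np.int64)
    sub_rep = np.repeat(subtype_idx, S)
    for k, st in enumerate(SUBTYPES):
        ip, pp = config.bcat_params[st]
        sel = np.flatnonzero(sub_rep == k)
        b_int[sel] = rng.choice(4, size=sel.size, p=np.asarray(ip, float))
        b_pct[sel] = rng.choice(5, size=sel.size, p=np.asarray(pp, float))
    bcat = pd.DataFrame(
        {
            "patient_id": np.repeat(patient_ids, S),
            "spot_index": np.tile(np.arange(1, S + 1), n),
            "nuclear_intensity": b_int,
            "nuclear_pct_category": b_pct,
        }
    )

    patients = generate_survival(
        patients, config.survival_params, rng=rng
    )
    return patients, spots, bcat


def _censoring_rate_for_fraction(frac, hazards, shape, horizon):
    """Exponential censoring rate giving a marginal censored fraction ~frac.

    ``hazards`` are the per-subject Weibull rate parameters.  The censored
    fraction counts subjects censored (randomly or administratively)
    before their event.
    """
    hazards = np.asarray(hazards, float)

    def frac_censored(lam):
        # P(min(C, horizon) < T) for T ~ Weibull(shape, rate h), C ~ Exp(lam)
        out = np.empty_like(hazards)
        for i, h in enumerate(np.unique(hazards)):
            # numerically integrate P(T > c) lam e^{-lam c} dc over (0, horizon)
            from scipy.integrate import quad

            surv = lambda t: np.exp(-h * t**shape)
            val, _ = quad(lambda c: surv(c) * lam * np.exp(-lam * c), 0, horizon)
            val += surv(horizon) * np.exp(-lam * horizon)  # admin censoring
            out[hazards == h] = val
        return out.mean()

    admin_only = frac_censored(1e-12)
    if frac <= admin_only:
        return 0.0
    try:
        return optimize.brentq(lambda lam: frac_censored(lam) - frac, 1e-9, 1e3)
    except ValueError:
        return 1e3


def generate_survival(patients, params: SurvivalParams, seed=None, rng=None,
                      extra_loghr=None):
    """Fill os_time / os_event / dss_event via a Weibull PH model.

    Event times follow h(t|subtype) = baseline_hazard * shape * t^(shape-1)
    * exp(log_hr).  ``extra_loghr`` optionally adds a per-patient log
    hazard contribution (for simulating covariate effects).  Censoring is
    independent exponential (rate solved to match ``censoring_rate`` as a
    marginal censored fraction) plus administrative censoring at the
    horizon.  Disease-specific events are a Bernoulli(dss_attribution)
    subset of overall-survival events.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    patients = patients.copy()
    n = len(patients)
    sub_idx = np.searchsorted(
        np.array(SUBTYPES), patients["latent_subtype"].to_numpy()
    )
    loghr = np.asarray(params.log_hrs, float)[sub_idx]
    if extra_loghr is not None:
        loghr = loghr + np.asarray(extra_loghr, float)
    rate = params.baseline_hazard * np.exp(loghr)

    if params.censoring_rate >= 1.0:
        # every subject withdrawn before any event can be observed
        patients["os_time"] = rng.uniform(0, params.horizon, n)
        patients["os_event"] = False
        patients["dss_event"] = False
        return patients

    u = rng.random(n)
    t_event = (-np.log(u) / rate) ** (1.0 / params.shape)
    if params.censoring_rate > 0:
        lam = _censoring_rate_for_fraction(
            params.censoring_rate, rate, params.shape, params.horizon
        )
    else:
        lam = 0.0
    t_cens = (
        rng.exponential(1.0 / lam, n) if lam > 0 else np.full(n, np.inf)
    )
    t_cens = np.minimum(t_cens, params.horizon)
    os_time = np.minimum(t_event, t_cens)
    os_event = t_event <= t_cens
    dss_event = os_event & (rng.random(n) < params.dss_attribution)
    patients["os_time"] = os_time
    patients["os_event"] = os_event
    patients["dss_event"] = dss_event
    return patients


# ---------------------------------------------------------------------------
# Synthetic spot images
# ---------------------------------------------------------------------------


@dataclass
class ImageSpec:
    """Specification of one synthetic TMA spot image."""

    width: int = 256
    height: int = 256
    pixel_size: float = 200.0  # nm / pixel
    tissue_radius_fraction: float = 0.9
    epithelium_blob_count: int = 6
    blob_radius_range: tuple[float, float] = (0.10, 0.22)  # fraction of min dim
    dab_intensity_level: float = 2.0
    positive_fraction: float = 0.5
    noise_sd: float = 2.0  # 8-bit RGB units
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if not 0.0 <= self.dab_intensity_level <= 3.0:
            raise ConfigurationError("dab_intensity_level must be in [0,3]")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ConfigurationError("positive_fraction must be in [0,1]")
        if self.epithelium_blob_count <= 0 and self.positive_fraction > 0:
            raise ConfigurationError(
                "zero-area epithelium requested with positive_fraction > 0"
            )


def generate_spot_image(spec: ImageSpec):
    """Render one synthetic TMA spot.

    Returns ``(rgb, epithelium_mask, ground_truth)`` where ``rgb`` is an
    8-bit HxWx3 array, ``epithelium_mask`` a boolean raster marking the
    epithelium exactly, and ``ground_truth`` a dict with the intended
    continuous intensity, its rounded value and the realized percent of
    epithelial area that is DAB positive.

    The image is a circular tissue disc on a white background: the disc
    carries light hematoxylin, epithelial blobs carry strong
    hematoxylin, and a smooth random sub-region of the epithelium
    (targeting ``positive_fraction`` of its area) carries DAB at an
    optical density proportional to ``dab_intensity_level``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_disc = spec.tissue_radius_fraction * min(h, w) / 2.0
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_disc**2

    epi = np.zeros((h, w), dtype=bool)
    if spec.epithelium_blob_count > 0:
        rmin, rmax = spec.blob_radius_range
        for _ in range(spec.epithelium_blob_count):
            br = rng.uniform(rmin, rmax) * min(h, w)
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, max(r_disc - br, 0))
            by, bx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            epi |= (yy - by) ** 2 + (xx - bx) ** 2 <= br**2
        epi &= disc
    if epi.sum() == 0 and spec.positive_fraction > 0:
        raise ConfigurationError(
            "zero-area epithelium realized with positive_fraction > 0"
        )

    # DAB-positive sub-region: threshold a smooth random field at the
    # quantile that yields the target area fraction exactly (in pixels).
    positive = np.zeros((h, w), dtype=bool)
    if spec.positive_fraction > 0 and epi.any():
        if spec.positive_fraction >= 1.0:
            positive = epi.copy()
        else:
            fld = ndimage.gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 16)
            vals = fld[epi]
            thr = np.quantile(vals, 1.0 - spec.positive_fraction)
            positive = epi & (fld > thr)

    h_od = np.where(epi, _H_OD_EPITHELIUM, np.where(disc, _H_OD_STROMA, 0.0))
    d_od = np.where(positive, spec.dab_intensity_level * DAB_OD_PER_UNIT, 0.0)

    od = h_od[..., None] * STAIN_HEMATOXYLIN + d_od[..., None] * STAIN_DAB
    rgb = 255.0 * np.power(10.0, -od)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    pct = 100.0 * positive.sum() / epi.sum() if epi.any() else 0.0
    from .quant import round_intensity  # local import avoids a cycle

    ground_truth = {
        "continuous_intensity": float(spec.dab_intensity_level),
        "rounded_intensity": round_intensity(spec.dab_intensity_level),
        "percent_positive": float(pct),
        "epithelium_area": int(epi.sum()),
    }
    return rgb, epi, ground_truth


def perturb_annotation(mask, boundary_jitter, seed=0):
    """Jitter a binary mask's boundary, emulating inter-annotator variation.

    Adds a smooth random field scaled by ``boundary_jitter`` (pixels) to
    the mask's signed Euclidean distance and re-thresholds at zero.
    ``boundary_jitter=0`` is the identity.
    """
    if boundary_jitter < 0:
        raise ValueError("boundary_jitter must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if boundary_jitter == 0:
        return mask.copy()
    rng = np.random.default_rng(seed)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = inside - outside  # >0 strictly inside, <0 strictly outside
    noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), 4.0)
    noise /= max(noise.std(), 1e-12)
    return (signed + boundary_jitter * noise) > 0
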