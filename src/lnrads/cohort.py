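"""Synthetic lymph-node cohort generator.

The study cohort this package targets (398 B-mode ultrasound images of
superficial lymph nodes with LN-RADS grades and histopathological malignancy
labels) is not publicly available.  This module generates seeded synthetic
cohorts whose statistical structure matches the published description of
that dataset:

* the LN-RADS level × malignancy joint distribution (level marginals
  21/28/58/83/89/119 of 398; per-level malignancy 0/21, 0/28, 1/58, 30/83,
  77/89, 118/119);
* class-conditional short-axis-diameter (SAD) distributions calibrated so
  the classical "SAD > 10 mm" rule attains TPR ≈ 0.611 / FPR ≈ 0.145 and the
  "> 8 mm" rule attains sensitivity ≈ 0.77 / specificity ≈ 0.66, the two
  operating points the source study reports;
* LN-RADS-graded morphology (cortex thickness, L/S ratio, hilum presence,
  echogenicity) drawn uniformly inside the clinical bounds that define each
  level;
* optional speckle-textured ellipse images emulating B-mode appearance.

Randomness discipline: :func:`sample_cohort` uses a single
``numpy.random.Generator`` seeded from ``config.seed`` and draws all fields
in a fixed vectorised order, so cohorts are bit-reproducible across runs and
platforms.  Images are seeded per record from ``(config.seed, crc32(id))``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .coding import LEVELS, InvalidLevelError, level_index

# --------------------------------------------------------------------------
# Published cohort structure (level marginals and per-level malignancy)
# --------------------------------------------------------------------------

#: Number of nodes per LN-RADS level in the source cohort (total 398).
LEVEL_COUNTS = np.array([21, 28, 58, 83, 89, 119], dtype=float)

#: Malignant nodes per level in the source cohort.
MALIGNANT_COUNTS = np.array([0, 0, 1, 30, 77, 118], dtype=float)

#: Node-location counts (axilla, neck, groin, other) in the source cohort.
LOCATION_COUNTS = np.array([153, 148, 79, 18], dtype=float)
LOCATIONS = ("axilla", "neck", "groin", "other")

DEFAULT_CATEGORY_WEIGHTS = LEVEL_COUNTS / LEVEL_COUNTS.sum()
DEFAULT_P_MALIGNANT = MALIGNANT_COUNTS / LEVEL_COUNTS

#: Operating points of the SAD rule reported for the real cohort:
#: (TPR, FPR) of "SAD > 10 mm" and "SAD > 8 mm".
OP_POINT_10MM = (138 / 226, 25 / 172)
OP_POINT_8MM = (0.77, 1 - 0.66)

# Per-level morphology bounds (uniform draws).  Cortex follows the clinical
# definitions: regular <= 3 mm for levels 1-2, > 3 mm for level 3, up to
# 4 mm for 4a, > 4 mm with irregularity for 4b/5.  L/S ratio > 2 (oval) for
# normal nodes, <= 2 (round) increasingly for suspicious ones.
_CORTEX_RANGES = [(0.5, 3.0), (0.8, 3.0), (3.0, 3.8), (3.0, 4.0), (4.0, 7.0), (4.0, 9.0)]
_LS_RANGES = [(2.0, 3.5), (1.6, 3.0), (1.2, 2.0), (1.2, 2.2), (1.0, 2.0), (1.0, 1.8)]
_HILUM_P = [0.99, 1.0, 0.95, 0.70, 0.25, 0.05]
_ECHO_CENTERS = [0.85, 0.80, 0.65, 0.55, 0.35, 0.20]
_ECHO_HALFWIDTH = 0.10


class CalibrationError(ValueError):
    """Raised when SAD-model calibration inputs are degenerate."""


class SchemaError(ValueError):
    """Raised when a cohort table does not match the documented schema."""


@dataclass(frozen=True)
class SADModel:
    """Class-conditional lognormal model of short-axis diameter (mm).

    ``SAD | class ~ LogNormal(mu, sigma)`` with log-scale location/scale per
    class.  Fixed by matching two survival quantiles per class (the 10 mm and
    8 mm operating points), which determines the lognormal uniquely.
    """

    mu_benign: float
    sigma_benign: float
    mu_malignant: float
    sigma_malignant: float

    def __post_init__(self):
        if self.sigma_benign <= 0 or self.sigma_malignant <= 0:
            raise CalibrationError("sigma must be positive")

    def survival(self, threshold_mm: float, malignant: bool) -> float:
        """P(SAD > threshold | class)."""
        mu = self.mu_malignant if malignant else self.mu_benign
        sigma = self.sigma_malignant if malignant else self.sigma_benign
        return float(norm.sf((np.log(threshold_mm) - mu) / sigma))

    def implied_auc(self) -> float:
        """AUC of SAD as a malignancy score under this model.

        For two normals on the log scale the probability that a malignant
        draw exceeds a benign one is Phi(dmu / sqrt(s_m^2 + s_b^2)).
        """
        d = self.mu_malignant - self.mu_benign
        s = np.hypot(self.sigma_malignant, self.sigma_benign)
        return float(norm.cdf(d / s))


def calibrate_sad_model(
    op_point_10mm: tuple[float, float] = OP_POINT_10MM,
    op_point_8mm: tuple[float, float] = OP_POINT_8MM,
) -> SADModel:
    """Fit the class-conditional lognormal SAD model to two ROC points.

    Each operating point ``(tpr, fpr)`` states the survival probability of
    each class past the corresponding threshold: P(SAD > 10 | malignant) =
    tpr10, P(SAD > 10 | benign) = fpr10, and likewise at 8 mm.  Two survival
    constraints per class give a 2x2 linear system in (mu, sigma) via the
    inverse standard-normal CDF:

        log t = mu + sigma * Phi^{-1}(1 - p)

    solved in closed form.
    """
    tpr10, fpr10 = op_point_10mm
    tpr8, fpr8 = op_point_8mm
    for p in (tpr10, fpr10, tpr8, fpr8):
        if not 0.0 < p < 1.0:
            raise CalibrationError(f"operating-point probability {p} not in (0,1)")
    if not (tpr8 > tpr10 and fpr8 > fpr10):
        raise CalibrationError("the 8 mm point must dominate the 10 mm point")

    def _solve(p10: float, p8: float) -> tuple[float, float]:
        z10 = norm.ppf(1.0 - p10)
        z8 = norm.ppf(1.0 - p8)
        if abs(z10 - z8) < 1e-12:
            raise CalibrationError("equal quantiles within a class")
        sigma = (np.log(10.0) - np.log(8.0)) / (z10 - z8)
        if sigma <= 0:
            raise CalibrationError("inconsistent operating points (sigma <= 0)")
        mu = np.log(10.0) - sigma * z10
        return float(mu), float(sigma)

    mu_b, sig_b = _solve(fpr10, fpr8)
    mu_m, sig_m = _solve(tpr10, tpr8)
    return SADModel(mu_b, sig_b, mu_m, sig_m)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the published cohort structure; ``image_mode`` adds
    rendered B-mode-like images.  ``mm_per_pixel`` of 0.1 on a 224x224
    canvas gives a 22.4 mm field of view; tests use a coarser 64x64 fast
    mode.
    """

    n: int = 398
    seed: int = 0
    category_weights: tuple = tuple(DEFAULT_CATEGORY_WEIGHTS)
    p_malignant_given_level: tuple = tuple(DEFAULT_P_MALIGNANT)
    sad_model: SADModel = field(default_factory=calibrate_sad_model)
    image_mode: bool = False
    mm_per_pixel: float = 0.1
    image_size: tuple[int, int] = (224, 224)

    def __post_init__(self):
        w = np.asarray(self.category_weights, float)
        if w.shape != (6,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("category_weights must be 6 non-negatives summing to 1")
        p = np.asarray(self.p_malignant_given_level, float)
        if p.shape != (6,) or (p < 0).any() or (p > 1).any():
            raise ValueError("p_malignant_given_level must be 6 probabilities")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")


@dataclass
class LNRecord:
    """One (synthetic or real) lymph node."""

    id: str
    location: str
    sad_mm: float
    lad_mm: float
    ls_ratio: float
    cortex_mm: float
    hilum_present: bool
    echogenicity: float
    lnrads: str
    malignant: bool
    latent: float = float("nan")


COHORT_COLUMNS = [
    "id", "location", "sad_mm", "lad_mm", "ls_ratio", "cortex_mm",
    "hilum_present", "echogenicity", "lnrads", "malignant",
]


def sample_cohort(config: GeneratorConfig) -> list[LNRecord]:
    """Draw ``config.n`` i.i.d. synthetic lymph nodes.

    The hidden severity ``latent`` is a Uniform(0,1) draw; the LN-RADS level
    is its bucket under the cumulative category weights, so level marginals
    match the configured weights exactly in expectation and mean severity
    strictly increases with level.  Malignancy is drawn from the level (not
    the latent) so the per-level conditionals hold exactly in expectation.
    """
    if config.n < 0:
        raise ValueError("n must be non-negative")
    n = config.n
    if n == 0:
        return []
    rng = np.random.default_rng(config.seed)

    latent = rng.uniform(0.0, 1.0, size=n)
    cuts = np.cumsum(np.asarray(config.category_weights, float))[:-1]
    level_idx = np.searchsorted(cuts, latent, side="right")

    p_mal = np.asarray(config.p_malignant_given_level, float)[level_idx]
    malignant = rng.uniform(size=n) < p_mal

    m = config.sad_model
    mu = np.where(malignant, m.mu_malignant, m.mu_benign)
    sigma = np.where(malignant, m.sigma_malignant, m.sigma_benign)
    sad = np.exp(mu + sigma * rng.standard_normal(n))

    cortex_lo, cortex_hi = np.array(_CORTEX_RANGES).T[:, level_idx]
    cortex = rng.uniform(cortex_lo, cortex_hi)
    ls_lo, ls_hi = np.array(_LS_RANGES).T[:, level_idx]
    ls = rng.uniform(ls_lo, ls_hi)
    hilum = rng.uniform(size=n) < np.asarray(_HILUM_P)[level_idx]
    echo_c = np.asarray(_ECHO_CENTERS)[level_idx]
    echo = np.clip(rng.uniform(echo_c - _ECHO_HALFWIDTH, echo_c + _ECHO_HALFWIDTH), 0.0, 1.0)
    loc_idx = rng.choice(len(LOCATIONS), size=n, p=LOCATION_COUNTS / LOCATION_COUNTS.sum())

    records = []
    for i in range(n):
        records.append(
            LNRecord(
                id=f"LN{i:06d}",
                location=LOCATIONS[loc_idx[i]],
                sad_mm=float(sad[i]),
                lad_mm=float(sad[i] * ls[i]),
                ls_ratio=float(ls[i]),
                cortex_mm=float(cortex[i]),
                hilum_present=bool(hilum[i]),
                echogenicity=float(echo[i]),
                lnrads=LEVELS[level_idx[i]],
                malignant=bool(malignant[i]),
                latent=float(latent[i]),
            )
        )
    return records


# --------------------------------------------------------------------------
# Image rendering (speckle-textured ellipse phantom)
# --------------------------------------------------------------------------

# Intensity bands (before speckle): interior tissue stays strictly below the
# hilum band so hilum presence is recoverable from pixel values.
_HILUM_LO = 0.85
_INTERIOR_CAP = 0.78
_HILUM_FRACTION = 0.35  # normalised radius of the central hilum region


def render_image(record: LNRecord, config: GeneratorConfig) -> np.ndarray:
    """Render one node as a speckle-textured grayscale image in [0, 1].

    An ellipse with axes ``lad_mm x sad_mm`` (at ``mm_per_pixel`` scale) on a
    darker fat-texture background: an outer cortex band of ``cortex_mm``, a
    bright central hilum iff ``hilum_present``, interior intensity scaled by
    ``echogenicity``, all modulated by multiplicative speckle.  Deterministic
    given the record and ``config.seed``.
    """
    h, w = config.image_size
    a_px = record.lad_mm / 2.0 / config.mm_per_pixel  # semi-major, pixels
    b_px = record.sad_mm / 2.0 / config.mm_per_pixel  # semi-minor, pixels
    if 2 * a_px >= min(h, w) - 2 or 2 * b_px >= min(h, w) - 2:
        raise ValueError(
            f"node ({record.lad_mm:.1f} x {record.sad_mm:.1f} mm) does not fit a "
            f"{h}x{w} canvas at {config.mm_per_pixel} mm/px"
        )

    rng = np.random.default_rng([config.seed, zlib.crc32(record.id.encode()) & 0x7FFFFFFF])
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # normalised elliptical radius: <= 1 inside the node
    r = np.sqrt(((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2)

    img = np.full((h, w), 0.45)  # fatty background
    inside = r <= 1.0
    cortex_frac = min(record.cortex_mm / max(record.sad_mm / 2.0, 1e-9), 1.0)
    in_cortex = inside & (r >= 1.0 - cortex_frac)
    in_medulla = inside & ~in_cortex
    img[in_cortex] = 0.15 + 0.55 * record.echogenicity
    img[in_medulla] = 0.30 + 0.45 * record.echogenicity

    speckle = rng.gamma(shape=8.0, scale=1.0 / 8.0, size=(h, w))
    img = img * speckle
    # cap non-hilum tissue below the hilum band, then paint the hilum
    img = np.clip(img, 0.0, _INTERIOR_CAP)
    if record.hilum_present:
        hilum = r <= _HILUM_FRACTION
        img[hilum] = np.clip(_HILUM_LO + 0.1 * (speckle[hilum] - 1.0), _HILUM_LO, 1.0)
    return np.clip(img, 0.0, 1.0)


def save_image_png(img: np.ndarray, path) -> None:
    """Write a [0,1] float image as 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray((np.clip(img, 0, 1) * 255).round().astype(np.uint8), mode="L").save(path)


# --------------------------------------------------------------------------
# Table I/O
# --------------------------------------------------------------------------


def cohort_to_frame(records: list[LNRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame with the documented column order."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in COHORT_COLUMNS} for r in records],
        columns=COHORT_COLUMNS,
    )


def write_cohort(records: list[LNRecord], path) -> None:
    """Write a cohort as comma-separated text (floats at full precision)."""
    # %.17g guarantees float round-trip through text
    cohort_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> list[LNRecord]:
    """Read a cohort table written by :func:`write_cohort`.

    Raises :class:`SchemaError` on missing/unknown columns or invalid
    LN-RADS values.  ``read(write(x)) == x`` on all fields (``latent`` is
    generator-internal and not serialised).
    """
    df = pd.read_csv(path, dtype={"lnrads": str}, float_precision="round_trip")
    if list(df.columns) != COHORT_COLUMNS:
        raise SchemaError(
            f"bad cohort header {list(df.columns)}; expected {COHORT_COLUMNS}"
        )
    records = []
    for row in df.itertuples(index=False):
        lvl = str(row.lnrads)
        try:
            level_index(lvl)
        except InvalidLevelError as e:
            raise SchemaError(str(e)) from None
        if row.location not in LOCATIONS:
            raise SchemaError(f"unknown location {row.location!r}")
        records.append(
            LNRecord(
                id=str(row.id),
                location=str(row.location),
                sad_mm=float(row.sad_mm),
                lad_mm=float(row.lad_mm),
                ls_ratio=float(row.ls_ratio),
                cortex_mm=float(row.cortex_mm),
                hilum_present=bool(row.hilum_present),
                echogenicity=float(row.echogenicity),
                lnrads=lvl,
                malignant=bool(row.malignant),
            )
        )
    return records


# --------------------------------------------------------------------------
# Fast feature-vector path
# --------------------------------------------------------------------------

#: Dimension of the feature vectors the classification heads consume.
N_FEATURES = 10


def features_from_records(records: list[LNRecord], seed: int = 0) -> np.ndarray:
    """Emit 10-d feature vectors directly from records, bypassing images.

    The first six dimensions carry the node's measurable structure (log-SAD,
    L/S ratio, cortex thickness, hilum flag, echogenicity, latent severity)
    with additive Gaussian noise so classes are not perfectly separable; the
    remaining four are pure noise.  This stands in for backbone features when
    exercising the head/training/evaluation stack at desk scale.
    """
    rng = np.random.default_rng([seed, 0x5EED])
    n = len(records)
    X = np.empty((n, N_FEATURES))
    X[:, 0] = [np.log(r.sad_mm) - 2.2 for r in records]
    X[:, 1] = [r.ls_ratio - 1.8 for r in records]
    X[:, 2] = [(r.cortex_mm - 3.5) / 2.0 for r in records]
    X[:, 3] = [1.0 if r.hilum_present else -1.0 for r in records]
    X[:, 4] = [(r.echogenicity - 0.5) * 2.0 for r in records]
    X[:, 5] = [r.latent - 0.5 for r in records]
    X[:, :6] += 0.35 * rng.standard_normal((n, 6))
    X[:, 6:] = rng.standard_normal((n, N_FEATURES - 6))
    return X


def summarize_cohort(records: list[LNRecord]) -> pd.DataFrame:
    """Counts per LN-RADS level x malignancy, matching the published layout."""
    df = cohort_to_frame(records)
    rows = []
    for lvl in LEVELS:
        sub = df[df["lnrads"] == lvl]
        rows.append(
            {
                "lnrads": lvl,
                "benign": int((~sub["malignant"]).sum()),
                "malignant": int(sub["malignant"].sum()),
                "total": len(sub),
            }
        )
    rows.append(
        {
            "lnrads": "total",
            "benign": int((~df["malignant"]).sum()),
            "malignant": int(df["malignant"].sum()),
            "total": len(df),
        }
    )
    return pd.DataFrame(rows)
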