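"""Synthetic two-channel multiphoton phantoms and simulated patient cohorts.

Real acquisitions of prostate tissue pair an SHG channel, bright only over
fibrillar collagen, with an autofluorescence channel showing overall tissue.
The phantom generator reproduces the aspects of such images the downstream
analysis depends on: SHG-bright collagen fibers with controllable width,
brightness, count and orientation concentration, drawn over diffuse green
stroma, plus gland-shaped regions that are autofluorescent but SHG-dark.
Every phantom comes with exact ground truth (fiber centerlines, widths,
orientations, masks, true area fraction), which is what makes the feature
extractors testable without any real tissue.

The cohort simulator produces per-patient collagen feature vectors (several
tissue cores per patient, drawn around a patient-level mean) and
proportional-hazards recurrence times driven by chosen features, with
administrative censoring at the end of follow-up.

All randomness flows from explicit integer seeds; a fixed seed reproduces
images bit-for-bit (quantization to 8 bits is the last step).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.draw import ellipse

from ._angles import principal_axis_deg, wrap_axial
from .content import FeatureVector
from .prep import DEFAULT_PIXEL_SIZE_UM, MPMImage
from .survival import PatientRecord

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = factor * sigma


@dataclass(frozen=True)
class FiberSpec:
    """Ground-truth description of one rendered collagen fiber."""

    centerline: np.ndarray          # (n, 2) float (row, col) pixel coordinates
    width_um: float                 # full width (FWHM of the rendered profile)
    peak_intensity: float           # SHG amplitude before quantization, (0, 255]
    orientation_deg: float          # principal-axis orientation, [0, 180)

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline, dtype=float).reshape(-1, 2)
        if len(pts) < 2:
            raise ValueError("centerline needs >= 2 points")
        if self.width_um <= 0:
            raise ValueError("width_um must be positive")
        if not (0 < self.peak_intensity <= 255):
            raise ValueError("peak_intensity must be in (0, 255]")
        object.__setattr__(self, "centerline", pts)

    @property
    def length_px(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)))

    def length_um(self, pixel_size_um: float) -> float:
        return self.length_px * pixel_size_um

    @property
    def straightness(self) -> float:
        chord = float(np.linalg.norm(self.centerline[-1] - self.centerline[0]))
        return min(chord / self.length_px, 1.0) if self.length_px > 0 else 1.0


@dataclass(frozen=True)
class Ellipse:
    """Gland-shaped region: center (row, col), semi-axes (px), rotation (deg)."""

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation_deg: float = 0.0


@dataclass
class PhantomConfig:
    """Parameters of one synthetic two-channel phantom.

    Intensity parameters are on the 0-255 scale; widths and lengths in
    micrometres. ``kappa`` is the von Mises concentration of fiber
    orientations applied on the doubled (axial) angle: 0 gives isotropic
    fibers, large values near-parallel ones. ``fiber_curviness`` bounds the
    per-step angular drift of the centerline random walk, in degrees.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_fibers: int = 40
    width_mean_um: float = 3.0
    width_sd_um: float = 0.8
    length_mean_um: float = 60.0
    length_sd_um: float = 15.0
    kappa: float = 0.0
    mu_deg: float = 0.0
    fiber_curviness: float = 3.0
    shg_intensity_mean: float = 120.0
    shg_intensity_sd: float = 20.0
    green_background_level: float = 100.0
    gland_fill_level: float = 150.0
    gland_spec: list[Ellipse] = field(default_factory=list)
    tissue_spec: Ellipse | None = None    # None: auto-inscribed ellipse
    tissue_full_frame: bool = False       # True: the whole frame is tissue
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        for name in ("shg_intensity_mean", "green_background_level",
                     "gland_fill_level"):
            if not (0 <= getattr(self, name) <= 255):
                raise ValueError(f"{name} must be within [0, 255]")


@dataclass
class GroundTruth:
    """Exact per-phantom ground truth for validating the extractors."""

    fibers: list[FiberSpec]
    gland_mask: np.ndarray
    stroma_mask: np.ndarray
    tissue_mask: np.ndarray
    fiber_mask: np.ndarray    # noiseless half-maximum binary fiber rendering
    true_af: float

    def to_frame(self, pixel_size_um: float) -> pd.DataFrame:
        rows = [{
            "fiber_id": i,
            "length_um": f.length_um(pixel_size_um),
            "width_um": f.width_um,
            "straightness": f.straightness,
            "orientation_deg": f.orientation_deg,
        } for i, f in enumerate(self.fibers)]
        return pd.DataFrame(rows, columns=["fiber_id", "length_um", "width_um",
                                           "straightness", "orientation_deg"])


def gland_mask_from_spec(glands: list[Ellipse], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for g in glands:
        rr, cc = ellipse(g.center[0], g.center[1], g.axes[0], g.axes[1],
                         shape=shape, rotation=np.deg2rad(g.rotation_deg))
        mask[rr, cc] = True
    return mask


def tissue_mask_from_config(config: PhantomConfig) -> np.ndarray:
    """Tissue footprint: the whole frame, or an (auto-)inscribed ellipse.

    The default inscribed ellipse emulates a roughly round tissue core on
    a dark (glass) background, which is what makes autofluorescence-based
    tissue masking meaningful downstream.
    """
    shape = config.image_size_px
    if config.tissue_full_frame:
        return np.ones(shape, dtype=bool)
    spec = config.tissue_spec or Ellipse(
        center=((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0),
        axes=(0.47 * shape[0], 0.47 * shape[1]))
    return gland_mask_from_spec([spec], shape)


def _sample_axial_angles(rng: np.random.Generator, n: int,
                         mu_deg: float, kappa: float) -> np.ndarray:
    """Draw axial orientations in [0, 180): von Mises on the doubled angle."""
    doubled = rng.vonmises(np.deg2rad(2.0 * mu_deg), kappa, size=n)
    return wrap_axial(np.rad2deg(doubled) / 2.0)


def sample_fibers(config: PhantomConfig,
                  region: np.ndarray | None = None) -> list[FiberSpec]:
    """Sample fiber ground truth: seed points uniform on ``region``,
    centerlines as unit-step random walks with bounded angular drift,
    widths and brightness from truncated normals.

    The walk's initial orientation is von Mises(mu, kappa) on the doubled
    angle; with ``fiber_curviness = 0`` fibers are perfectly straight.
    """
    if region is None:
        region = (tissue_mask_from_config(config)
                  & ~gland_mask_from_spec(config.gland_spec, config.image_size_px))
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty stroma region")
    # Seed midpoints uniformly over the frame expanded by half a fiber
    # length, so coverage of the stromal region stays uniform up to its
    # edges; rendering clips fibers to the stroma, the way sectioning cuts
    # real fibers at a tissue or gland boundary.
    halflen_px = 0.5 * config.length_mean_um / config.pixel_size_um
    nrows, ncols = config.image_size_px

    rng = np.random.default_rng([config.seed, 1])
    fibers: list[FiberSpec] = []
    for _ in range(config.n_fibers):
        start = np.array([rng.uniform(-halflen_px, nrows + halflen_px),
                          rng.uniform(-halflen_px, ncols + halflen_px)])
        axis_deg = float(_sample_axial_angles(rng, 1, config.mu_deg, config.kappa)[0])
        length_px = max(config.length_mean_um + config.length_sd_um * rng.standard_normal(),
                        4.0 * config.pixel_size_um) / config.pixel_size_um
        n_steps = max(int(round(length_px)), 2)
        # the axis is undirected; pick the walking direction at random
        theta = np.deg2rad(axis_deg + (180.0 if rng.random() < 0.5 else 0.0))
        pts = [start]
        for _ in range(n_steps):
            theta += np.deg2rad(rng.uniform(-config.fiber_curviness,
                                            config.fiber_curviness))
            pts.append(pts[-1] + np.array([np.sin(theta), np.cos(theta)]))
        centerline = np.array(pts)

        width_um = max(config.width_mean_um + config.width_sd_um * rng.standard_normal(),
                       config.pixel_size_um)  # truncated at one pixel
        peak = float(np.clip(
            config.shg_intensity_mean + config.shg_intensity_sd * rng.standard_normal(),
            1.0, 255.0))
        fibers.append(FiberSpec(centerline=centerline, width_um=width_um,
                                peak_intensity=peak,
                                orientation_deg=principal_axis_deg(centerline)))
    return fibers


def _render_fiber(canvas: np.ndarray, binary: np.ndarray, fiber: FiberSpec,
                  pixel_size_um: float) -> None:
    """Add one fiber's Gaussian-profile ridge to ``canvas`` (in place)."""
    fwhm_px = max(fiber.width_um / pixel_size_um, 1.0)
    sigma = fwhm_px / GAUSSIAN_FWHM_FACTOR
    # densify the centerline so distance-to-polyline is accurate to ~0.15 px
    pts = fiber.centerline
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    dense = [pts[0]]
    for p0, p1, sl in zip(pts[:-1], pts[1:], seglen):
        k = max(int(np.ceil(sl / 0.3)), 1)
        for t in np.linspace(0, 1, k + 1)[1:]:
            dense.append(p0 + t * (p1 - p0))
    dense = np.array(dense)

    reach = 3.0 * sigma + 2.0
    r0 = max(int(np.floor(dense[:, 0].min() - reach)), 0)
    r1 = min(int(np.ceil(dense[:, 0].max() + reach)) + 1, canvas.shape[0])
    c0 = max(int(np.floor(dense[:, 1].min() - reach)), 0)
    c1 = min(int(np.ceil(dense[:, 1].max() + reach)) + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, _ = cKDTree(dense).query(grid, workers=1)
    dist = dist.reshape(rr.shape)
    canvas[r0:r1, c0:c1] += fiber.peak_intensity * np.exp(-dist**2 / (2 * sigma**2))
    binary[r0:r1, c0:c1] |= dist <= fwhm_px / 2.0


def render_phantom(fibers: list[FiberSpec],
                   config: PhantomConfig) -> tuple[MPMImage, GroundTruth]:
    """Render fibers into the SHG channel and tissue into the green channel.

    The SHG channel is the sum of per-fiber Gaussian ridges (cross-section
    FWHM equal to the fiber's nominal width), zeroed inside glands, plus
    additive Gaussian noise, clipped and quantized to 0-255 as the final
    step. The green channel is the diffuse stroma level with brighter
    gland fill. ``true_af`` is the fraction of tissue pixels covered by the
    noiseless half-maximum fiber rendering.
    """
    shape = config.image_size_px
    tissue = tissue_mask_from_config(config)
    gland = gland_mask_from_spec(config.gland_spec, shape) & tissue
    stroma = tissue & ~gland

    shg = np.zeros(shape, dtype=float)
    fiber_binary = np.zeros(shape, dtype=bool)
    for f in fibers:
        _render_fiber(shg, fiber_binary, f, config.pixel_size_um)
    shg[~stroma] = 0.0        # collagen lives in the stroma only
    fiber_binary &= stroma
    true_af = float(fiber_binary[tissue].mean()) if tissue.any() else 0.0

    green = np.zeros(shape, dtype=float)
    green[stroma] = config.green_background_level
    green[gland] = config.gland_fill_level

    rng = np.random.default_rng([config.seed, 2])
    if config.noise_sd > 0:
        shg = shg + rng.normal(0.0, config.noise_sd, shape)
        green = green + rng.normal(0.0, config.noise_sd, shape)
    quantize = lambda x: np.clip(np.rint(x), 0, 255).astype(np.uint8)
    image = MPMImage(channel_r=quantize(shg), channel_g=quantize(green),
                     pixel_size_um=config.pixel_size_um)
    truth = GroundTruth(fibers=fibers, gland_mask=gland, stroma_mask=stroma,
                        tissue_mask=tissue, fiber_mask=fiber_binary,
                        true_af=true_af)
    return image, truth


def generate_phantom(config: PhantomConfig) -> tuple[MPMImage, GroundTruth]:
    """Sample fibers on the stromal region and render them."""
    tissue = tissue_mask_from_config(config)
    stroma = tissue & ~gland_mask_from_spec(config.gland_spec, config.image_size_px)
    fibers = sample_fibers(config, stroma) if config.n_fibers > 0 else []
    return render_phantom(fibers, config)


def write_phantom(path_prefix, image: MPMImage, truth: GroundTruth,
                  config: PhantomConfig) -> None:
    """Write image (2-page TIFF), masks (TIFF), ground-truth CSV and config JSON."""
    import tifffile

    image.to_tiff(f"{path_prefix}.tif")
    tifffile.imwrite(f"{path_prefix}_gland_mask.tif",
                     truth.gland_mask.astype(np.uint8) * 255)
    tifffile.imwrite(f"{path_prefix}_tissue_mask.tif",
                     truth.tissue_mask.astype(np.uint8) * 255)
    truth.to_frame(config.pixel_size_um).to_csv(f"{path_prefix}_fibers.csv",
                                                index=False)
    cfg = dataclasses.asdict(config)
    cfg["true_af"] = truth.true_af
    with open(f"{path_prefix}_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Population distribution of each simulated collagen feature:
#: (population mean, between-patient SD, within-patient/between-core SD).
#: Scales follow the field's conventions: fractions in [0, 1], intensities
#: on the 8-bit 0-255 scale, widths/lengths in micrometres, angles in
#: degrees from the tumor-gland boundary.
DEFAULT_FEATURE_DISTRIBUTIONS: dict[str, tuple[float, float, float]] = {
    "af": (0.25, 0.08, 0.04),
    "i_r": (80.0, 20.0, 8.0),
    "i_g": (90.0, 15.0, 6.0),
    "norm_intensity": (0.45, 0.10, 0.04),
    "coherence": (0.30, 0.10, 0.05),
    "fiber_width_um": (3.0, 0.8, 0.3),
    "fiber_length_um": (60.0, 15.0, 6.0),
    "fiber_straightness": (0.85, 0.05, 0.02),
    "fiber_angle_deg": (45.0, 12.0, 5.0),
}

_FEATURE_BOUNDS = {
    "af": (0.0, 1.0),
    "i_r": (0.0, 255.0),
    "i_g": (0.0, 255.0),
    "norm_intensity": (0.0, 1.0),
    "coherence": (0.0, 1.0),
    "fiber_width_um": (0.1, None),
    "fiber_length_um": (1.0, None),
    "fiber_straightness": (0.01, 1.0),
    "fiber_angle_deg": (0.0, 90.0),
}


@dataclass
class CohortConfig:
    """Parameters of a simulated patient cohort.

    ``feature_effects`` maps collagen feature names to log-hazard
    coefficients (per unit of the feature); recurrence times are
    exponential with rate ``baseline_hazard * exp(sum beta * (x - mu))``
    where ``x`` is the patient's mean feature value and ``mu`` the
    population mean (centering keeps ``baseline_hazard`` the event rate of
    a typical patient). Follow-up ends at ``follow_up_months``
    (administrative censoring only; the three-year biochemical-recurrence
    window is 36 months).
    """

    n_patients: int = 60
    cores_per_patient: int = 3
    feature_effects: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.02
    follow_up_months: float = 36.0
    group_shift: float = 0.0
    seed: int = 0
    feature_distributions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_DISTRIBUTIONS))

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.follow_up_months <= 0:
            raise ValueError("follow_up_months must be positive")
        unknown = set(self.feature_effects) - set(self.feature_distributions)
        if unknown:
            raise ValueError(f"unknown feature(s) in feature_effects: {sorted(unknown)}")


def simulate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Simulate per-core collagen features and proportional-hazards outcomes.

    Each patient has a latent feature mean drawn from the population
    distribution; cores scatter around it with the within-patient SD.
    The hazard acts on the patient's across-core mean feature values.
    When ``group_shift`` is nonzero, a random half of the patients form a
    high-risk generative group whose latent means for every effect feature
    are shifted up by ``group_shift``.
    """
    rng = np.random.default_rng([config.seed, 3])
    names = list(config.feature_distributions)
    records: list[PatientRecord] = []
    high_risk = rng.permutation(config.n_patients) < config.n_patients // 2

    for i in range(config.n_patients):
        latent = {}
        for name in names:
            mu, bsd, _ = config.feature_distributions[name]
            if config.group_shift != 0.0 and name in config.feature_effects and high_risk[i]:
                mu = mu + config.group_shift
            latent[name] = mu + bsd * rng.standard_normal()
        cores = []
        for _ in range(config.cores_per_patient):
            vals = {}
            for name in names:
                _, _, wsd = config.feature_distributions[name]
                lo, hi = _FEATURE_BOUNDS.get(name, (None, None))
                vals[name] = float(np.clip(latent[name] + wsd * rng.standard_normal(),
                                           lo, hi))
            cores.append(FeatureVector(**vals))
        mean_features = FeatureVector.mean(cores)

        log_rr = sum(beta * (getattr(mean_features, name)
                             - config.feature_distributions[name][0])
                     for name, beta in config.feature_effects.items())
        rate = config.baseline_hazard * np.exp(log_rr)
        t = rng.exponential(1.0 / rate)
        event = int(t <= config.follow_up_months)
        time_months = float(min(t, config.follow_up_months))
        records.append(PatientRecord(
            patient_id=f"P{i + 1:04d}", core_features=cores,
            mean_features=mean_features, time_months=max(time_months, 1e-6),
            event=event,
            covariates={"risk_group": int(high_risk[i])} if config.group_shift else {}))
    return records


def cohort_to_frames(records: list[PatientRecord]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into a per-core feature table and an outcomes table."""
    feat_rows, out_rows = [], []
    for rec in records:
        for j, fv in enumerate(rec.core_features):
            row = {"patient_id": rec.patient_id, "core_id": f"core{j + 1}"}
            row.update(fv.as_dict())
            feat_rows.append(row)
        out = {"patient_id": rec.patient_id, "time_months": rec.time_months,
               "event": rec.event}
        out.update(rec.covariates)
        out_rows.append(out)
    return pd.DataFrame(feat_rows), pd.DataFrame(out_rows)


def write_cohort(features_path, outcomes_path, records: list[PatientRecord]) -> None:
    features, outcomes = cohort_to_frames(records)
    features.to_csv(features_path, index=False)
    outcomes.to_csv(outcomes_path, index=False)
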