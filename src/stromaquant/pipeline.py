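"""End-to-end orchestration: simulate, extract, screen.

Files are the only interface between stages: the extract stage writes a
feature CSV (per-core rows plus per-patient mean rows), the screen stage
reads that CSV together with an outcomes CSV and writes a report
directory. A single integer seed reproduces a full simulated run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .content import (ContentConfig, FeatureVector, FEATURE_COLUMNS,
                      compute_content_features)
from .fibers import (GlandSegmentationConfig, TracerParams, compute_coherence,
                     fiber_boundary_angle, segment_glands, summarize_fibers,
                     trace_fibers)
from .prep import MPMImage
from .survival import (PatientRecord, covariate_scale, cox_fit, km_logrank,
                       lr_test, ph_check, dichotomize_at_mean,
                       univariable_screen)
from .synthetic import PhantomConfig, generate_phantom

log = logging.getLogger("stromaquant")

PATIENT_MEAN_CORE_ID = "patient_mean"


@dataclass
class ExtractConfig:
    """Feature-extraction settings shared by all images of a run."""

    content: ContentConfig = field(default_factory=ContentConfig)
    tracer: TracerParams = field(default_factory=TracerParams)
    gland: GlandSegmentationConfig = field(default_factory=GlandSegmentationConfig)
    coherence_sigma_px: float = 2.0
    pixel_size_um: float | None = None      # None: trust the TIFF metadata
    background_radius_px: int | None = None  # None: no background subtraction
    roi_csv: str | None = None              # ROI list; None: whole image
    roi_size_um: float = 500.0              # default ROI size for size-less lists
    emit_overlays: bool = True


def extract_image_features(image: MPMImage,
                           config: ExtractConfig = ExtractConfig()
                           ) -> tuple[FeatureVector, dict]:
    """Compute the full feature vector for one two-channel image.

    Composition of the stages: gland/stroma segmentation, content features
    on the stroma, fiber tracing with per-fiber boundary angles, and
    structure-tensor coherence. Returns the vector and a dict of
    intermediates (masks, fibers, boundaries) for QC.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        boundaries = segment_glands(image, config.gland)
    fv, masks = compute_content_features(image, boundaries.stroma_mask,
                                         config.content)
    fibers = trace_fibers(image.channel_r, masks["analysis"], config.tracer,
                          image.pixel_size_um)
    try:
        coherence = compute_coherence(image.channel_r, masks["analysis"],
                                      config.coherence_sigma_px)
    except ValueError:
        coherence = math.nan
    angles = [fiber_boundary_angle(f, boundaries) for f in fibers]
    morph = summarize_fibers(fibers, angles)
    fv = fv.merged(coherence=coherence, fiber_width_um=morph.fiber_width_um,
                   fiber_length_um=morph.fiber_length_um,
                   fiber_straightness=morph.fiber_straightness,
                   fiber_angle_deg=morph.fiber_angle_deg)
    return fv, {"masks": masks, "fibers": fibers, "boundaries": boundaries}


def _write_overlay(path: Path, image: MPMImage, intermediates: dict) -> None:
    import imageio.v3 as iio

    rgb = np.zeros((*image.shape, 3), dtype=np.uint8)
    rgb[..., 0] = np.clip(image.channel_r, 0, 255).astype(np.uint8)
    rgb[..., 1] = np.clip(image.channel_g, 0, 255).astype(np.uint8)
    for fiber in intermediates["fibers"]:
        rr = fiber.points[:, 0].astype(int)
        cc = fiber.points[:, 1].astype(int)
        rgb[rr, cc] = (255, 255, 255)
    iio.imwrite(path, rgb)


def run_extract(input_dir, out_dir, config: ExtractConfig = ExtractConfig()
                ) -> Path:
    """Extract features from every ``<patient>_<core>.tif`` in a directory.

    Writes ``features.csv`` with one row per core and one ``patient_mean``
    row per patient, QC overlays, and a run manifest. Unreadable images
    are logged and skipped; the run continues.
    """
    from .prep import extract_rois, read_roi_csv, subtract_background

    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(p for p in input_dir.glob("*.tif")
                   if "_mask" not in p.stem)
    if config.roi_csv:
        from .prep import DEFAULT_PIXEL_SIZE_UM, roi_size_px
        default_px = roi_size_px(config.roi_size_um,
                                 config.pixel_size_um or DEFAULT_PIXEL_SIZE_UM)
        roi_map = read_roi_csv(config.roi_csv, default_size_px=default_px)
    else:
        roi_map = {}
    rows, failures = [], []
    for path in paths:
        try:
            image = MPMImage.from_tiff(path, pixel_size_um=config.pixel_size_um)
            if config.background_radius_px:
                image = MPMImage(
                    channel_r=subtract_background(image.channel_r,
                                                  config.background_radius_px),
                    channel_g=subtract_background(image.channel_g,
                                                  config.background_radius_px),
                    pixel_size_um=image.pixel_size_um, label=image.label)
            rois = roi_map.get(path.name, []) + roi_map.get("*", [])
            crops = extract_rois(image, rois) if rois else [image]
            extracted = [(crop, *extract_image_features(crop, config))
                         for crop in crops]
        except Exception as exc:   # per-file isolation is the contract
            log.error("failed to process %s: %s", path.name, exc)
            failures.append({"file": path.name, "error": str(exc)})
            continue
        stem = path.stem
        patient_id, _, core_id = stem.rpartition("_")
        if not patient_id:
            patient_id, core_id = stem, "core1"
        for crop, fv, inter in extracted:
            rows.append({"patient_id": patient_id, "core_id": core_id,
                         "roi_label": crop.label, **fv.as_dict()})
        if config.emit_overlays:
            _write_overlay(out_dir / f"{stem}_overlay.png", image,
                           extracted[0][2] if not rois else
                           {"fibers": []})

    frame = pd.DataFrame(rows)
    mean_rows = []
    for pid, grp in frame.groupby("patient_id", sort=True):
        cores = [FeatureVector(**{k: r[k] for k in FEATURE_COLUMNS})
                 for _, r in grp.iterrows()]
        mean_rows.append({"patient_id": pid, "core_id": PATIENT_MEAN_CORE_ID,
                          "roi_label": "", **FeatureVector.mean(cores).as_dict()})
    frame = pd.concat([frame, pd.DataFrame(mean_rows)], ignore_index=True)
    features_csv = out_dir / "features.csv"
    frame.to_csv(features_csv, index=False, float_format="%.10g")
    _write_manifest(out_dir, {"stage": "extract", "n_images": len(paths),
                              "n_failed": len(failures), "failures": failures,
                              "config": dataclasses.asdict(config)})
    return features_csv


def load_patients(features_csv, outcomes_csv) -> list[PatientRecord]:
    """Join a features CSV with an outcomes CSV into patient records."""
    feats = pd.read_csv(features_csv)
    outcomes = pd.read_csv(outcomes_csv)
    ids = sorted(set(feats["patient_id"].astype(str))
                 & set(outcomes["patient_id"].astype(str)))
    if not ids:
        raise ValueError("no patient_id overlap between features and outcomes")
    outcomes = outcomes.set_index(outcomes["patient_id"].astype(str))
    records = []
    for pid in ids:
        sub = feats[feats["patient_id"].astype(str) == pid]
        core_rows = sub[sub.get("core_id", "core1") != PATIENT_MEAN_CORE_ID]
        cores = [FeatureVector(**{k: r[k] for k in FEATURE_COLUMNS})
                 for _, r in core_rows.iterrows()]
        if not cores:
            continue
        out = outcomes.loc[pid]
        covs = {c: float(out[c]) for c in outcomes.columns
                if c not in ("patient_id", "time_months", "event")
                and np.isreal(out[c])}
        records.append(PatientRecord(
            patient_id=pid, core_features=cores,
            mean_features=FeatureVector.mean(cores),
            time_months=float(out["time_months"]), event=int(out["event"]),
            covariates=covs))
    return records


def run_screen(features_csv, outcomes_csv, out_dir,
               clinical_covariates: list[str] | None = None,
               alpha: float = 0.05, make_plots: bool = True) -> Path:
    """Run the full statistical screen and write a report directory.

    Contents: the univariable table, one multivariable model per
    collinearity group of flagged features (plus any clinical
    covariates), an AIC / likelihood-ratio comparison of those models,
    a proportional-hazards check, and mean-cutoff Kaplan-Meier plots with
    log-rank p-values for each flagged feature.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients = load_patients(features_csv, outcomes_csv)
    if len(patients) < 4:
        warnings.warn("very small cohort; estimates will be unstable",
                      RuntimeWarning, stacklevel=2)
    n_events = sum(p.event for p in patients)
    if n_events == 0:
        raise ValueError("no events")

    screen = univariable_screen(patients, alpha=alpha)
    screen.table.to_csv(out_dir / "univariable.csv", index=False,
                        float_format="%.6g")

    time = np.array([p.time_months for p in patients])
    event = np.array([p.event for p in patients])
    base = pd.DataFrame({c: [p.covariates.get(c, np.nan) for p in patients]
                         for c in (clinical_covariates or [])})

    comparison_rows, ph_frames = [], []
    base_fit = None
    if len(base.columns):
        keep_base = ~base.isna().any(axis=1)
        try:
            base_fit = cox_fit(time[keep_base.to_numpy()],
                               event[keep_base.to_numpy()], base[keep_base])
        except (ValueError, RuntimeError) as exc:
            log.warning("clinical base model failed: %s", exc)
    for k, group in enumerate(screen.model_groups, start=1):
        X = pd.DataFrame({f: [getattr(p.mean_features, f) * covariate_scale(f)
                              for p in patients]
                          for f in group})
        X = pd.concat([X, base], axis=1)
        keep = ~X.isna().any(axis=1)
        try:
            results = cox_fit(time[keep.to_numpy()], event[keep.to_numpy()],
                              X[keep])
        except (ValueError, RuntimeError) as exc:
            log.error("multivariable model %d failed: %s", k, exc)
            continue
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out_dir / f"multivariable_model{k}.csv", index=False,
            float_format="%.6g")
        row = {"model": k, "features": "+".join(group),
               "k_params": len(results),
               "log_likelihood": results[0].log_likelihood,
               "aic": results[0].aic,
               "lr_vs_base_chi2": math.nan, "lr_vs_base_p": math.nan}
        if base_fit is not None and len(results) > len(base_fit) \
                and results[0].n == base_fit[0].n:
            # collagen model nested over the clinical-only base
            try:
                chi2, _, p = lr_test(base_fit, results)
                row["lr_vs_base_chi2"], row["lr_vs_base_p"] = chi2, p
            except ValueError as exc:
                log.warning("LR test failed for model %d: %s", k, exc)
        comparison_rows.append(row)
        try:
            phc = ph_check(time[keep.to_numpy()], event[keep.to_numpy()], X[keep])
            phc.insert(0, "model", k)
            ph_frames.append(phc.reset_index(names="covariate"))
        except (ValueError, RuntimeError) as exc:
            log.warning("PH check failed for model %d: %s", k, exc)

    if comparison_rows:
        comp = pd.DataFrame(comparison_rows).sort_values("aic")
        comp.to_csv(out_dir / "model_comparison.csv", index=False,
                    float_format="%.6g")
    if ph_frames:
        pd.concat(ph_frames, ignore_index=True).to_csv(
            out_dir / "ph_check.csv", index=False, float_format="%.6g")

    km_rows = []
    for f in screen.flagged:
        x = np.array([getattr(p.mean_features, f) for p in patients])
        ok = np.isfinite(x)
        try:
            labels = dichotomize_at_mean(x[ok])
            km = km_logrank(time[ok], event[ok], labels)
        except ValueError as exc:
            log.warning("KM split failed for %s: %s", f, exc)
            continue
        km_rows.append({"variable": f, "logrank_chi2": km.logrank_chi2,
                        "logrank_p": km.logrank_p,
                        "n_high": int((labels == "High").sum()),
                        "n_low": int((labels == "Low").sum())})
        if make_plots:
            _plot_km(out_dir / f"km_{f}.png", f, km)
    pd.DataFrame(km_rows, columns=["variable", "logrank_chi2", "logrank_p",
                                   "n_high", "n_low"]).to_csv(
        out_dir / "km_logrank.csv", index=False, float_format="%.6g")

    _write_report_text(out_dir, patients, screen, comparison_rows, km_rows)
    _write_manifest(out_dir, {"stage": "screen", "n_patients": len(patients),
                              "n_events": int(n_events), "alpha": alpha,
                              "flagged": screen.flagged,
                              "model_groups": screen.model_groups})
    return out_dir


def _plot_km(path: Path, feature: str, km) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    colors = {"High": "tab:blue", "Low": "tab:red"}
    for lab in km.groups:
        ax.step(km.times[lab], km.survival[lab], where="post",
                label=lab, color=colors.get(lab))
    ax.set_xlabel("months")
    ax.set_ylabel("recurrence-free survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{feature} (log-rank p = {km.logrank_p:.3g})", fontsize=9)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _write_report_text(out_dir: Path, patients, screen, comparison_rows,
                       km_rows) -> None:
    lines = [f"stromaquant v{__version__} screen report",
             f"patients: {len(patients)}, events: {sum(p.event for p in patients)}",
             "", "univariable Cox screen (HR per unit, 95% CI, raw p):"]
    for _, r in screen.table.iterrows():
        flag = " *" if r["variable"] in screen.flagged else ""
        lines.append(f"  {r['variable']:<20} HR {r['hr']:.3f} "
                     f"({r['ci_low']:.3f}-{r['ci_high']:.3f}) p={r['p']:.4f}{flag}")
    lines.append("")
    lines.append(f"flagged at p<0.05: {', '.join(screen.flagged) or 'none'}")
    if screen.model_groups:
        lines.append("multivariable model groups (collinearity-partitioned):")
        for k, g in enumerate(screen.model_groups, 1):
            lines.append(f"  model {k}: {', '.join(g)}")
    for row in sorted(comparison_rows, key=lambda r: r["aic"]):
        lines.append(f"  model {row['model']} AIC {row['aic']:.2f}")
    if km_rows:
        lines.append("mean-cutoff Kaplan-Meier log-rank:")
        for r in km_rows:
            lines.append(f"  {r['variable']:<20} chi2={r['logrank_chi2']:.3f} "
                         f"p={r['logrank_p']:.4f}")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")


def _write_manifest(out_dir: Path, payload: dict) -> None:
    payload = {"software": f"stromaquant {__version__}", **payload}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Image-level cohort simulation and the end-to-end demo
# ---------------------------------------------------------------------------

@dataclass
class EndToEndConfig:
    """Conditions of the simulated end-to-end experiment.

    Each patient gets latent fiber-brightness and fiber-width levels drawn
    around the phantom defaults; cores are rendered phantoms at those
    levels, and recurrence times follow a proportional-hazards model on
    the latent levels (log-hazard ``beta_intensity`` per intensity unit
    and ``beta_width`` per micrometre). The defaults give strong,
    detectable effects on fiber intensity and width only, mirroring the
    direction of the clinical findings the screen is designed around.
    """

    n_patients: int = 60
    cores_per_patient: int = 3
    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(
        image_size_px=(200, 200), n_fibers=30, noise_sd=6.0))
    intensity_between_sd: float = 20.0
    width_between_sd: float = 0.8
    beta_intensity: float = 0.05
    beta_width: float = 1.2
    baseline_hazard: float = 0.02
    follow_up_months: float = 36.0
    seed: int = 0


def simulate_image_cohort(config: EndToEndConfig, out_dir) -> Path:
    """Render per-core phantom TIFFs plus an outcomes CSV for a cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 4])
    base = config.phantom
    out_rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        intensity = float(np.clip(
            base.shg_intensity_mean + config.intensity_between_sd * rng.standard_normal(),
            20.0, 240.0))
        width = float(max(
            base.width_mean_um + config.width_between_sd * rng.standard_normal(),
            0.8))
        log_rr = (config.beta_intensity * (intensity - base.shg_intensity_mean)
                  + config.beta_width * (width - base.width_mean_um))
        rate = config.baseline_hazard * np.exp(log_rr)
        t = rng.exponential(1.0 / rate)
        event = int(t <= config.follow_up_months)
        out_rows.append({"patient_id": pid,
                         "time_months": float(max(min(t, config.follow_up_months),
                                                  1e-6)),
                         "event": event})
        for j in range(config.cores_per_patient):
            cfg = replace(base, shg_intensity_mean=intensity, width_mean_um=width,
                          seed=int(rng.integers(2**31 - 1)))
            image, _ = generate_phantom(cfg)
            image.to_tiff(out_dir / f"{pid}_core{j + 1}.tif")
    outcomes_csv = out_dir / "outcomes.csv"
    pd.DataFrame(out_rows).to_csv(outcomes_csv, index=False)
    return outcomes_csv


def run_end_to_end(config: EndToEndConfig, out_dir,
                   extract_config: ExtractConfig | None = None) -> Path:
    """simulate -> extract -> screen, driven by one seed.

    Returns the report directory. The same config and seed reproduce the
    full report.
    """
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    log.info("stage 1/3: simulating %d patients x %d cores",
             config.n_patients, config.cores_per_patient)
    outcomes_csv = simulate_image_cohort(config, images_dir)
    if extract_config is None:
        extract_config = ExtractConfig(emit_overlays=False)
    log.info("stage 2/3: extracting features")
    features_csv = run_extract(images_dir, out_dir / "extract", extract_config)
    log.info("stage 3/3: screening")
    report_dir = run_screen(features_csv, outcomes_csv, out_dir / "report")
    return report_dir
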