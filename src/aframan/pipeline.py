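"""End-to-end orchestration: phantom -> screening -> plan -> Raman -> report.

Each stage is wrapped so a failure aborts the run with the stage name; a
manifest ties together the configuration, per-stage seeds, package
version and SHA-256 checksums of every file written, making a run with a
fixed seed byte-reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__, afimage, calibration, classify, io, phantom, ramanproc, sampler
from .config import RunConfig

log = logging.getLogger("aframan")

STAGES = ("phantom", "af-process", "plan", "raman-process", "classify")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig, outdir: Path) -> Path:
    """Execute the full simulated pipeline into a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def _write(name: str, writer, *args) -> Path:
        path = outdir / name
        writer(path, *args)
        files[name] = io.sha256_of(path)
        return path

    # -- stage 0: phantom -------------------------------------------------
    try:
        pc = config.phantom
        seed0 = config.stage_seed(0)
        tmap = phantom.demo_tissue_map(
            shape=pc.shape,
            tumour_radius_px=pc.tumour_radius_px,
            stroma_halo_px=pc.stroma_halo_px,
            seed=seed0,
            pixel_size_um=pc.pixel_size_um,
            fibrosis=pc.fibrosis,
        )
        rng = np.random.default_rng(seed0)
        blood = contact = None
        if pc.blood_contact_fields:
            blood = phantom.smooth_random_field(tmap.shape, rng, 0.6, 1.0)
            contact = phantom.smooth_random_field(tmap.shape, rng, 0.7, 1.0)
        pair = phantom.render_af_pair(
            tmap,
            filter1_nm=config.af.filter1_nm,
            filter2_nm=config.af.filter2_nm,
            noise_sd=pc.af_noise_sd,
            blood_field=blood,
            contact_field=contact,
            seed=seed0,
        )
        _write("filter1.tif", io.write_af_channel, pair.filter1)
        _write("filter2.tif", io.write_af_channel, pair.filter2)
        _write("truth_labels.png", io.write_label_png, tmap.labels, outdir / "truth_legend.json")
        files["truth_legend.json"] = io.sha256_of(outdir / "truth_legend.json")
        log.info("phantom: %s px, classes %s", tmap.shape, tmap.class_fractions())
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("phantom", exc) from exc

    # -- stage 1: af-process ----------------------------------------------
    try:
        ac = config.af
        threshold = ac.mask_threshold_counts
        if threshold is None:
            threshold = afimage.auto_mask_threshold(pair.filter2)
        mask = afimage.mask_background(pair.filter2, threshold)
        rimg = afimage.ratiometric(pair, mask, epsilon=ac.epsilon_counts)
        bands = afimage.ThresholdBands(
            adipose=ac.adipose_band,
            retained=ac.retained_band,
            fibrosis_mode=ac.fibrosis_mode,
        )
        screen = afimage.screen_adipose(rimg, bands, median_filter_3x3=ac.median_filter_3x3)
        _write("ratio.tif", io.write_ratio_image, rimg.ratio)
        _write("screen_labels.png", io.write_label_png, screen)
        retained_frac = float((screen == afimage.ScreenLabel.RETAINED).sum()) / max(
            int(mask.sum()), 1
        )
        log.info("af-process: mask threshold %.1f, retained fraction %.3f", threshold, retained_frac)
    except Exception as exc:  # noqa: BLE001
        raise StageError("af-process", exc) from exc

    # -- stage 2: plan -----------------------------------------------------
    try:
        sc = config.sampler
        seed2 = config.stage_seed(2)
        retained = screen == afimage.ScreenLabel.RETAINED
        seg = sampler.segment(
            retained,
            target_segment_px=sc.target_segment_px,
            seed=seed2,
            ratio=rimg.ratio,
            features=sc.features,
        )
        plan = sampler.plan_sampling(
            seg,
            min_points=sc.min_points,
            t_acq_s=sc.t_acq_s,
            budget_s=sc.budget_s,
            seed=seed2,
        )
        _write("segments.png", io.write_label_png, np.clip(seg.segment_id, 0, 255))
        plan_lines = ["point_id,row,col,segment_id"] + [
            f"{i},{r},{c},{sid}" for i, (r, c, sid) in enumerate(plan.points)
        ]
        (outdir / "plan.csv").write_text("\n".join(plan_lines) + "\n")
        files["plan.csv"] = io.sha256_of(outdir / "plan.csv")
        log.info("plan: K=%d segments, %d points (%.0f s)", seg.K, len(plan.points), plan.total_time_s)
    except Exception as exc:  # noqa: BLE001
        raise StageError("plan", exc) from exc

    # -- stage 3: raman-process -------------------------------------------
    try:
        rc = config.raman
        seed3 = config.stage_seed(3)
        refs = calibration.default_refs()
        instrument = phantom.InstrumentModel()
        measured_std = instrument.distort(calibration.render_intensity_standard(refs))
        measured_ps = instrument.distort(calibration.render_polystyrene())
        models = phantom.default_band_models(
            noise_sd=config.phantom.raman_noise_sd,
            cosmic_ray_rate=config.phantom.cosmic_ray_rate,
        )
        spectra_dir = outdir / "spectra"
        spectra_dir.mkdir(exist_ok=True)
        processed: dict[tuple[int, int], ramanproc.RamanSpectrum] = {}
        qc_rows = []
        for i, (r, c, sid) in enumerate(plan.points):
            raw = phantom.render_raman(
                (r, c), tmap, model_set=models, seed=(seed3 + i) % 2**31,
                acquisition_s=sc.t_acq_s,
            )
            raw = instrument.distort(raw)
            out = ramanproc.process_all(
                raw,
                refs,
                measured_std,
                measured_ps,
                z_threshold=rc.z_threshold,
                calibration_model=rc.calibration_model,
                background_order=rc.background_order,
                smooth_window=rc.smooth_window,
                smooth_polyorder=rc.smooth_polyorder,
                max_counts_780=rc.max_counts_780,
                min_snr=rc.min_snr,
                qc_before_smoothing=rc.qc_before_smoothing,
            )
            name = f"spectra/point_{i:04d}.csv"
            _write(name, io.write_spectrum_csv, out)
            qc_rows.append(
                {
                    "point_id": i,
                    "row": r,
                    "col": c,
                    "segment_id": sid,
                    "snr": out.qc.snr,
                    "i780": out.qc.i780,
                    "passed": out.qc.passed,
                    "reasons": list(out.qc.reasons),
                }
            )
            if out.qc.passed:
                processed[(r, c)] = out
        io.write_manifest(outdir / "qc.json", {"spectra": qc_rows})
        files["qc.json"] = io.sha256_of(outdir / "qc.json")
        log.info("raman-process: %d/%d spectra passed QC", len(processed), len(plan.points))
    except Exception as exc:  # noqa: BLE001
        raise StageError("raman-process", exc) from exc

    # -- stage 4: classify -------------------------------------------------
    try:
        cc = config.classifier
        thresholds = classify.BandScoreThresholds(
            adipose_ratio=cc.adipose_ratio_threshold,
            collagen_ratio=cc.collagen_ratio_threshold,
        )
        scores = {
            pt: classify.band_scores(s, thresholds, half_width_cm1=cc.band_half_width_cm1)
            for pt, s in processed.items()
        }
        screen_summary = {
            "adipose_area_fraction": float(
                (screen == afimage.ScreenLabel.ADIPOSE).sum()
            )
            / max(int(mask.sum()), 1),
            "n_points_planned": len(plan.points),
        }
        report = classify.margin_report(
            plan,
            scores,
            tmap.specimen_mask,
            pixel_size_um=config.phantom.pixel_size_um,
            segment_id=seg.segment_id,
            screening_summary=screen_summary,
        )
        report.to_json(outdir / "report.json")
        files["report.json"] = io.sha256_of(outdir / "report.json")
        _write("overlay.png", _write_overlay, tmap, screen, plan, report)
        log.info(
            "classify: %d tumour points, margin %s mm",
            report.summary["n_tumour_points"],
            report.min_margin_mm,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc

    config.save(outdir / "config.json")
    files["config.json"] = io.sha256_of(outdir / "config.json")
    manifest = {
        "package_version": __version__,
        "schema_version": config.schema_version,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(i) for i, s in enumerate(STAGES)},
        "retained_band": list(config.af.retained_band),
        "files": files,
    }
    io.write_manifest(outdir / "manifest.json", manifest)
    return outdir


def _write_overlay(
    path: Path,
    tmap,
    screen: np.ndarray,
    plan,
    report,
) -> None:
    """Annotated RGB overlay: screening labels with sampling points on top."""
    import imageio.v3 as iio

    rgb = np.zeros((*screen.shape, 3), dtype=np.uint8)
    rgb[screen == afimage.ScreenLabel.ADIPOSE] = (70, 160, 70)
    rgb[screen == afimage.ScreenLabel.RETAINED] = (170, 170, 190)
    rgb[screen == afimage.ScreenLabel.OUT_OF_RANGE] = (60, 60, 60)
    labels = {(r, c): lab for r, c, _, lab in report.point_labels}
    colors = {"adipose": (0, 255, 0), "stroma": (60, 120, 255), "tumour": (255, 40, 40)}
    for r, c, _sid in plan.points:
        color = colors.get(labels.get((r, c), ""), (255, 255, 0))
        rr = slice(max(r - 1, 0), min(r + 2, screen.shape[0]))
        cc = slice(max(c - 1, 0), min(c + 2, screen.shape[1]))
        rgb[rr, cc] = color
    iio.imwrite(path, rgb)
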