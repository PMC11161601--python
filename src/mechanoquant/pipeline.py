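"""Orchestration: run the analysis stages in dependency order and write
CSV/JSON outputs. Every output row carries the image id and the config
hash; re-running with an identical config and seed is bit-identical."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import beadtrack, fiberorder, morphometrics, segmentation, yapquant
from .config import PipelineConfig
from .image import ImageStack, MultichannelImage

logger = logging.getLogger(__name__)

UNITS_HEADER = "# lengths in um; angles in degrees, CCW from x-axis, in [-90, 90)\n"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(UNITS_HEADER)
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest dict.

    segment -> yap -> fibers run on ``config.image``; beads runs on
    ``config.stack``; the protrusive index on ``config.border_mask``. A
    failure in one stage preserves the outputs already written and re-raises.
    """
    out = config.ensure_output_dir()
    chash = config.config_hash()
    manifest: dict = {
        "config_hash": chash,
        "image_id": config.image_id,
        "outputs": [],
        "timings_s": {},
    }

    def _stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)

        return done

    if config.image is not None:
        done = _stage("segment+yap")
        img = MultichannelImage.load(config.image, pixel_size_um=config.pixel_size_um)
        img = MultichannelImage(
            channels={config.channels.get(k, k): v for k, v in img.channels.items()},
            pixel_size_um=img.pixel_size_um,
        )
        seg = config.segmentation
        organoids = segmentation.segment_organoid(
            img, smooth_sigma_px=seg.smooth_sigma_px, min_area_px=seg.min_area_px
        )
        rows = []
        for oi, org in enumerate(organoids):
            nuclei = segmentation.detect_nuclei(
                img["DAPI"], org, min_area_px=seg.nucleus_min_area_px
            )
            if nuclei.max() == 0:
                logger.warning("organoid %d: no nuclei detected; skipped", oi)
                continue
            cells = segmentation.segment_cells(
                nuclei, img, org, hessian_sigmas=tuple(seg.hessian_sigmas)
            )
            tifffile.imwrite(
                out / f"{config.image_id}_organoid{oi}_cells.tif",
                cells.cell_labels.astype(np.uint16),
            )
            records = yapquant.quantify_cells(
                img,
                cells,
                org,
                background=config.yap.background,
                e_min=config.yap.e_min,
                p_min_um=config.yap.p_min_um,
                measure_lengths=config.yap.measure_lengths,
            )
            for r in records:
                rows.append(
                    {
                        "image_id": config.image_id,
                        "config_hash": chash,
                        "organoid_id": oi,
                        "cell_id": r.cell_id,
                        "layer": r.layer,
                        "role": r.role,
                        "k14_class": r.k14_class,
                        "nuc_mean": r.nuc_mean,
                        "cyto_mean": r.cyto_mean,
                        "background": r.background,
                        "ratio": r.nuc_cyto_ratio,
                        "valid": r.valid,
                        "length_um": r.length_um,
                    }
                )
        cells_csv = out / f"{config.image_id}_cells.csv"
        _write_csv(pd.DataFrame(rows), cells_csv)
        manifest["outputs"].append(str(cells_csv))
        done()

        if config.fibers.channel in img:
            done = _stage("fibers")
            fp = config.fibers
            ofield = fiberorder.structure_tensor_orientation(
                img[fp.channel], sigma_grad=fp.sigma_grad_px, sigma_window=fp.sigma_window_px
            )
            frows = []
            for oi, org in enumerate(organoids):
                rois = fiberorder.extract_rim_rois(
                    org, fp.roi_spacing_um, width_um=fp.roi_width_um, length_um=fp.roi_length_um
                )
                profile = fiberorder.rim_order_profile(
                    ofield,
                    rois,
                    img.pixel_size_um,
                    max_distance_um=fp.max_distance_um,
                    weight_by_coherency=fp.weight_by_coherency,
                    coherency_power=fp.coherency_power,
                )
                for ri, (res, dang) in enumerate(
                    zip(profile.per_roi, profile.mean_angle_vs_normal_deg)
                ):
                    frows.append(
                        {
                            "image_id": config.image_id,
                            "config_hash": chash,
                            "organoid_id": oi,
                            "roi_id": ri,
                            "n_valid": res.n_angles if res else 0,
                            "S": res.S if res else np.nan,
                            "mean_angle_vs_normal_deg": dang,
                        }
                    )
                if profile.pooled is not None:
                    frows.append(
                        {
                            "image_id": config.image_id,
                            "config_hash": chash,
                            "organoid_id": oi,
                            "roi_id": -1,  # pooled over all ROIs
                            "n_valid": profile.pooled.n_angles,
                            "S": profile.pooled.S,
                            "mean_angle_vs_normal_deg": np.nan,
                        }
                    )
            fibers_csv = out / f"{config.image_id}_fibers.csv"
            _write_csv(pd.DataFrame(frows), fibers_csv)
            manifest["outputs"].append(str(fibers_csv))
            done()

    if config.stack is not None:
        done = _stage("beads")
        stack = ImageStack.load(
            config.stack,
            pixel_size_um=config.pixel_size_um,
            frame_interval_min=config.beads.frame_interval_min,
        )
        drift = beadtrack.estimate_drift(stack)
        tracks = beadtrack.detect_and_link(
            stack,
            drift,
            max_step_px=config.beads.max_step_px,
            spot_sigma_px=config.beads.spot_sigma_px,
            threshold_rel=config.beads.threshold_rel,
        )
        if config.image is not None and organoids:
            beadtrack.select_beads(tracks, organoids, mode=config.beads.mode)
            for tr in tracks:
                if tr.included:
                    beadtrack.displacement_toward_organoid(tr, organoids[0])
        brows = []
        for tr in tracks:
            for t in range(stack.n_frames):
                brows.append(
                    {
                        "image_id": config.image_id,
                        "config_hash": chash,
                        "bead_id": tr.bead_id,
                        "frame": t,
                        "row": tr.positions_px[t, 0],
                        "col": tr.positions_px[t, 1],
                        "corrected_row": tr.corrected_px[t, 0],
                        "corrected_col": tr.corrected_px[t, 1],
                        "included": tr.included,
                        "displacement_um": tr.displacement_um,
                    }
                )
        beads_csv = out / f"{config.image_id}_beads.csv"
        _write_csv(pd.DataFrame(brows), beads_csv)
        manifest["outputs"].append(str(beads_csv))
        done()

    if config.border_mask is not None:
        done = _stage("morph")
        mask = tifffile.imread(config.border_mask)
        shape = morphometrics.protrusive_index(
            mask,
            pixel_size_um=config.pixel_size_um or 1.0,
            blur_sigma_px=config.morph.blur_sigma_px,
            erosion_iter=config.morph.erosion_iter,
        )
        morph_csv = out / f"{config.image_id}_morph.csv"
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "image_id": config.image_id,
                        "config_hash": chash,
                        "perimeter_um": shape.perimeter_um,
                        "hull_perimeter_um": shape.hull_perimeter_um,
                        "protrusive_index": shape.protrusive_index,
                    }
                ]
            ),
            morph_csv,
        )
        manifest["outputs"].append(str(morph_csv))
        done()

    with open(out / f"{config.image_id}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
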