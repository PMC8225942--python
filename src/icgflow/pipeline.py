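"""End-to-end orchestration: segment -> register -> flow -> perfusion.

``run_pipeline`` ties the stages together for a preoperative/postoperative
video pair: segment both stable frames, register the preoperative vessel
map onto the postoperative one, classify the blood-flow direction in each
video, decide whether the direction changed, and render perfusion maps and
ROI curves. All intermediate artifacts land in a run directory with a JSON
report; no hidden state passes between stages.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from icgflow import io as icgio
from icgflow.io import ICGVideo
from icgflow.opticalflow import HSParams, direction_change, vessel_flow_direction
from icgflow.perfusion import ROI, delay_time, luminance_curve, perfusion_color_map
from icgflow.registration import register_masks, warp_mask
from icgflow.segmentation import select_stable_frame
from icgflow.segmentation.metrics import dice, jaccard

__all__ = ["PipelineConfig", "run_pipeline", "threshold_segment"]

log = logging.getLogger(__name__)


def threshold_segment(frame: np.ndarray) -> np.ndarray:
    """Otsu-threshold segmentation of a stable frame (model-free fallback)."""
    from skimage.filters import threshold_otsu
    from skimage.morphology import remove_small_objects

    t = threshold_otsu(np.asarray(frame, float))
    return remove_small_objects(frame > t, max_size=16)


@dataclass
class PipelineConfig:
    """Inputs, stage parameters and output directory for one run."""

    pre_video: str
    post_video: str
    out_dir: str
    rois: str | None = None
    model_checkpoint: str | None = None  # None -> threshold segmentation
    mask_pre: str | None = None  # precomputed masks override segmentation
    mask_post: str | None = None
    hs: HSParams = field(default_factory=HSParams)
    ratio: float = 0.8
    seed: int = 0
    use_tta: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        if "hs" in d:
            d["hs"] = HSParams(**d["hs"])
        return cls(**d)


def _segment(video: ICGVideo, cfg: PipelineConfig) -> tuple[np.ndarray, int]:
    idx = select_stable_frame(video)
    frame = video.frames[idx]
    if cfg.model_checkpoint:
        from icgflow.segmentation import MultiTaskUNet, predict, predict_with_tta

        model = MultiTaskUNet.load(cfg.model_checkpoint)
        pred = (predict_with_tta if cfg.use_tta else predict)(model, frame)
        return pred.mask_all, idx
    return threshold_segment(frame), idx


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return (and write) the run report.

    Stage failures are recorded in the report (``report["errors"]``) and the
    remaining stages that do not depend on the failed one still run.
    """
    from icgflow import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "errors": {},
                    "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
                report["stages"][name] = {"ok": True}
            except Exception as exc:
                log.exception("stage %s failed", name)
                report["errors"][name] = str(exc)
                report["stages"][name] = {"ok": False}
            report["stages"][name]["seconds"] = round(time.perf_counter() - t0, 3)
        return deco

    state: dict = {}

    @stage("read")
    def _read():
        state["pre"] = icgio.read_video(config.pre_video)
        state["post"] = icgio.read_video(config.post_video)

    @stage("segmentation")
    def _seg():
        for tag in ("pre", "post"):
            override = getattr(config, f"mask_{tag}")
            if override:
                mask = icgio.read_mask(override)
                idx = select_stable_frame(state[tag])
            else:
                mask, idx = _segment(state[tag], config)
            state[f"mask_{tag}"] = mask
            report[f"stable_frame_{tag}"] = idx
            icgio.write_mask(mask, out / f"mask_{tag}.png")

    @stage("registration")
    def _reg():
        res = register_masks(state["mask_pre"], state["mask_post"],
                             ratio=config.ratio, seed=config.seed)
        report["registration"] = {
            "success": bool(res["success"]), "overlap": res["overlap"],
            "n_matches": res["n_matches"],
            "n_keypoints_moving": res["n_keypoints_moving"],
            "n_keypoints_fixed": res["n_keypoints_fixed"],
        }
        if res["homography"] is not None:
            (out / "homography.json").write_text(
                json.dumps(np.asarray(res["homography"]).tolist()))
            state["H"] = res["homography"]
            state["warped_pre_mask"] = res["warped_mask"]
            report["registration"]["warped_dice"] = dice(res["warped_mask"],
                                                         state["mask_post"])

    @stage("flow_direction")
    def _flow():
        from scipy.spatial import cKDTree

        from icgflow.opticalflow import order_skeleton

        for tag in ("pre", "post"):
            # direction is read on the recipient (main) vessel: the tube of
            # mask pixels around the skeleton's longest path, so that side
            # branches do not pollute the tangent projections
            mask = state[f"mask_{tag}"]
            centerline = order_skeleton(mask)
            rr, cc = np.nonzero(mask)
            dist, _ = cKDTree(centerline).query(np.column_stack([rr, cc]))
            tube = np.zeros_like(mask)
            tube[rr[dist <= 4.0], cc[dist <= 4.0]] = True
            label = vessel_flow_direction(state[tag], tube,
                                          centerline=centerline,
                                          params=config.hs)
            state[f"dir_{tag}"] = label
            report[f"direction_{tag}"] = {"category": label.category,
                                          "confidence": label.confidence,
                                          "mean_sign": label.mean_sign}
        report["direction_change"] = direction_change(state["dir_pre"], state["dir_post"])

    @stage("perfusion")
    def _perf():
        for tag in ("pre", "post"):
            pmap = perfusion_color_map(state[tag], state[f"mask_{tag}"])
            tifffile.imwrite(out / f"ttp_{tag}.tif", pmap.ttp.astype(np.float32))
            icgio.write_mask((pmap.rgb * 255).astype(np.uint8).max(axis=-1) > 0,
                             out / f"perfusion_{tag}_fg.png")
            import imageio.v3 as iio

            iio.imwrite(out / f"perfusion_{tag}.png",
                        (pmap.rgb * 255).astype(np.uint8))
        if config.rois:
            rows = []
            for d in icgio.read_rois(config.rois):
                roi = ROI.from_dict(d)
                for tag in ("pre", "post"):
                    curve = luminance_curve(state[tag], roi)
                    t, flat = delay_time(curve)
                    rows.append({"roi": roi.id, "video": tag, "delay_s": t,
                                 "flat": flat})
                    curve.to_frame().to_csv(out / f"curve_{roi.id}_{tag}.csv",
                                            index=False)
            report["delay_times"] = rows

    ok = not report["errors"]
    report["ok"] = ok
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    lines = [f"# Run report", "",
             f"- version: {report['version']}", f"- ok: {ok}"]
    for key in ("direction_pre", "direction_post", "direction_change",
                "registration"):
        if key in report:
            lines.append(f"- {key}: {report[key]}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return report
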