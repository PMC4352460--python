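"""End-to-end segmentation pipelines and batch evaluation.

Two routes share a skeleton of green channel -> enhancement ->
smoothing -> global threshold -> morphological cleanup:

* ``clahe`` route: CLAHE on the green channel, one of the four
  smoothing filters, Otsu or ISODATA threshold with *dark* polarity
  (vessels are darker than the retinal background);
* ``phasecong`` route: phase-congruency map of the green channel, 3x3
  average filter, then the IDM, Otsu or ISODATA threshold with
  *bright* polarity (vessels carry the high congruency).

The standard pairings (CLAHE with Otsu/ISODATA, phase congruency
with any of the three) are enforced unless ``allow_cross`` is set.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from vesselthresh import evaluate, imaging_io, phasecong, postprocess, preprocess, threshold

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "batch_evaluate",
    "load_config",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".ppm", ".gif", ".jpg", ".jpeg"}


@dataclass
class PipelineConfig:
    """Everything needed to run one segmentation pipeline."""

    route: str = "phasecong"
    threshold_method: str = "idm"
    clahe: preprocess.CLAHEParams = field(default_factory=preprocess.CLAHEParams)
    filter: preprocess.FilterSpec = field(
        default_factory=lambda: preprocess.FilterSpec(kind="gaussian")
    )
    pc: phasecong.PhaseCongParams = field(default_factory=phasecong.PhaseCongParams)
    post: postprocess.PostprocessSpec = field(
        default_factory=postprocess.PostprocessSpec
    )
    n_bins: int = 256
    idm_distances: tuple[int, ...] = (1, 2, 3, 4)
    idm_levels: int = 16
    idm_denominator: str = "plus"
    allow_cross: bool = False
    fov_threshold_fraction: float = 0.15
    fov_margin: int = 6
    evaluate_in_fov: bool = True

    def __post_init__(self) -> None:
        if self.route not in ("clahe", "phasecong"):
            raise ValueError("route must be 'clahe' or 'phasecong'")
        if self.threshold_method not in ("otsu", "isodata", "idm"):
            raise ValueError("threshold_method must be otsu, isodata or idm")
        if (
            self.route == "clahe"
            and self.threshold_method == "idm"
            and not self.allow_cross
        ):
            raise ValueError(
                "the clahe route pairs with otsu/isodata; "
                "set allow_cross=True to force IDM"
            )


@dataclass
class PipelineResult:
    """Final vessel map plus per-stage intermediates for inspection."""

    vessel_map: np.ndarray
    counts: evaluate.ConfusionCounts | None
    threshold: float
    polarity: str
    stages: dict


def _load_gray(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        image = imaging_io.read_fundus_image(image)
    image = np.asarray(image, dtype=np.float64)
    return imaging_io.extract_green_channel(image) if image.ndim == 3 else image


def _load_mask(mask) -> np.ndarray | None:
    if mask is None:
        return None
    if isinstance(mask, (str, Path)):
        return imaging_io.read_binary_map(mask)
    return np.asarray(mask, dtype=bool)


def run_pipeline(
    image,
    config: PipelineConfig | None = None,
    truth=None,
    fov=None,
    dump_dir: str | Path | None = None,
) -> PipelineResult:
    """Segment one fundus image (array or path) with a configured route.

    The FOV mask is derived from brightness when not supplied.  Metrics
    are computed when ground truth is given.  All intermediates are
    returned in ``stages`` (and written to ``dump_dir`` if set).
    """
    config = config or PipelineConfig()
    green = _load_gray(image)
    truth_map = _load_mask(truth)
    fov_mask = _load_mask(fov)
    if fov_mask is None:
        source = image if not isinstance(image, (str, Path)) else green
        try:
            fov_mask = imaging_io.derive_fov_mask(
                np.asarray(source), config.fov_threshold_fraction
            )
        except ValueError:
            fov_mask = np.ones_like(green, dtype=bool)
    if truth_map is not None and truth_map.shape != green.shape:
        raise ValueError("truth shape does not match the image")
    if fov_mask.shape != green.shape:
        raise ValueError("fov shape does not match the image")

    stages: dict = {"green": green}
    if config.route == "phasecong":
        pc_map = phasecong.phase_congruency_map(green, config.pc)
        filtered = preprocess.smooth(
            pc_map, preprocess.FilterSpec(kind="average", window=(3, 3))
        )
        peak = filtered.max()
        working = filtered / peak if peak > 0 else filtered
        working = np.clip(working, 0.0, 1.0)
        polarity = "bright"
        stages.update(pc=pc_map, working=working)
    else:
        enhanced = preprocess.clahe_equalize(green, config.clahe)
        working = preprocess.smooth(enhanced, config.filter)
        working = np.clip(working, 0.0, 1.0)
        polarity = "dark"
        stages.update(enhanced=enhanced, working=working)

    # the FOV rim is a strong artificial edge (especially in the PC
    # map); binarize only inside a small safety margin
    seg_mask = fov_mask
    if config.fov_margin > 0:
        from scipy import ndimage as _ndi

        seg_mask = _ndi.binary_erosion(fov_mask, iterations=config.fov_margin)
        if not seg_mask.any():
            seg_mask = fov_mask
    t = _select_threshold(working, seg_mask, config)
    if t is None:  # degenerate (constant) working image: no vessels
        raw = np.zeros_like(working, dtype=bool)
        t = float("nan")
    else:
        raw = threshold.binarize(working, t, polarity=polarity)
    raw &= seg_mask
    final = postprocess.run_chain(raw, config.post)
    stages.update(threshold=t, seg_mask=seg_mask, raw_binary=raw,
                  postprocessed=final)

    counts = None
    if truth_map is not None:
        counts = evaluate.confusion(
            final, truth_map, fov_mask if config.evaluate_in_fov else None
        )

    if dump_dir is not None:
        _dump_stages(Path(dump_dir), stages, fov_mask, counts)
    return PipelineResult(
        vessel_map=final, counts=counts, threshold=t, polarity=polarity,
        stages=stages,
    )


def _select_threshold(
    working: np.ndarray, fov_mask: np.ndarray, config: PipelineConfig
) -> float | None:
    if config.threshold_method == "idm":
        res = threshold.idm_threshold(
            working,
            distances=config.idm_distances,
            n_levels=config.idm_levels,
            denominator=config.idm_denominator,
        )
        return res.threshold
    hist = threshold.Histogram.from_image(
        working, n_bins=config.n_bins, value_range=(0.0, 1.0), mask=fov_mask
    )
    if np.count_nonzero(hist.counts) < 2:
        return None
    if config.threshold_method == "otsu":
        return threshold.otsu_threshold(hist)
    return threshold.isodata_threshold(hist)


def _dump_stages(out: Path, stages: dict, fov_mask: np.ndarray, counts) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for name, value in stages.items():
        if isinstance(value, np.ndarray):
            if value.dtype == bool:
                imaging_io.write_binary_map(out / f"{name}.png", value)
            else:
                arr = value
                peak = arr.max()
                imaging_io.write_gray_image(
                    out / f"{name}.png", arr / peak if peak > 1 else arr
                )
    imaging_io.write_binary_map(out / "fov.png", fov_mask)
    meta = {"threshold": stages.get("threshold")}
    if counts is not None:
        meta["metrics"] = counts.as_dict()
    (out / "run.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------- batch

def _file_id(path: Path) -> str | None:
    m = re.search(r"\d+", path.stem)
    return m.group(0).lstrip("0") or "0" if m else None


def _index_dir(directory: Path | None) -> dict:
    if directory is None or not directory.is_dir():
        return {}
    out = {}
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in _IMAGE_SUFFIXES:
            fid = _file_id(p)
            if fid is not None and fid not in out:
                out[fid] = p
    return out


def _resolve_layout(root: Path) -> tuple[dict, dict, dict]:
    """Map image ids to (image, truth, mask) paths for DRIVE/STARE-style
    directory layouts, or a flat directory of ``*_image/_truth/_fov``
    files as written by the phantom generator."""
    sub = {p.name.lower(): p for p in root.iterdir() if p.is_dir()}
    img_dir = next((sub[n] for n in ("images", "image") if n in sub), None)
    if img_dir is not None:
        truth_dir = next(
            (sub[n] for n in ("1st_manual", "manual1", "truth", "labels") if n in sub),
            None,
        )
        mask_dir = next((sub[n] for n in ("mask", "masks", "fov") if n in sub), None)
        return _index_dir(img_dir), _index_dir(truth_dir), _index_dir(mask_dir)

    images, truths, masks = {}, {}, {}
    for p in sorted(root.iterdir()):
        if p.suffix.lower() not in _IMAGE_SUFFIXES:
            continue
        fid = _file_id(p)
        if fid is None:
            continue
        stem = p.stem.lower()
        if "truth" in stem or "manual" in stem:
            truths.setdefault(fid, p)
        elif "fov" in stem or "mask" in stem:
            masks.setdefault(fid, p)
        else:
            images.setdefault(fid, p)
    return images, truths, masks


def batch_evaluate(
    dataset_dir: str | Path,
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
) -> tuple[list[dict], dict]:
    """Segment every image in a dataset directory and tabulate metrics.

    Returns per-image rows and the unweighted averages; writes
    ``metrics.csv`` / ``metrics.json`` plus segmentations when
    ``output_dir`` is given.  Images without ground truth get empty
    metric columns.
    """
    config = config or PipelineConfig()
    root = Path(dataset_dir)
    if not root.is_dir():
        raise ValueError(f"not a directory: {root}")
    images, truths, masks = _resolve_layout(root)
    if not images:
        raise ValueError(f"no images found under {root}")

    rows: list[dict] = []
    counts_list: list[evaluate.ConfusionCounts] = []
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for fid in sorted(images, key=lambda s: (len(s), s)):
        result = run_pipeline(
            images[fid], config, truth=truths.get(fid), fov=masks.get(fid)
        )
        row = {"id": fid, "image": images[fid].name,
               "threshold": result.threshold}
        if result.counts is not None:
            row.update(result.counts.as_dict())
            counts_list.append(result.counts)
        rows.append(row)
        if out is not None:
            imaging_io.write_binary_map(
                out / f"{images[fid].stem}_vessels.png", result.vessel_map
            )
    summary = evaluate.aggregate(counts_list) if counts_list else {}
    if out is not None:
        _write_metrics(out, rows, summary)
    return rows, summary


def _write_metrics(out: Path, rows: list[dict], summary: dict) -> None:
    fieldnames = ["id", "image", "threshold", "tp", "tn", "fp", "fn",
                  "sensitivity", "specificity", "accuracy"]
    with (out / "metrics.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, extrasaction="ignore")
        writer.writeheader()
        writer.writerows(rows)
    (out / "metrics.json").write_text(
        json.dumps({"per_image": rows, "summary": summary}, indent=2)
    )


# ---------------------------------------------------------------- config

def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file.

    The ``pc`` section accepts the conventional parameter names
    verbatim (nscale, norient, minWaveLength, mult, sigmaOnf,
    dThetaOnSigma, k, cutOff, g).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    kwargs = dict(raw)
    if "pc" in kwargs:
        kwargs["pc"] = phasecong.PhaseCongParams.from_config(kwargs["pc"])
    if "clahe" in kwargs:
        sec = dict(kwargs["clahe"])
        if "tile_size" in sec and isinstance(sec["tile_size"], list):
            sec["tile_size"] = tuple(sec["tile_size"])
        if "output_range" in sec and isinstance(sec["output_range"], list):
            sec["output_range"] = tuple(sec["output_range"])
        kwargs["clahe"] = preprocess.CLAHEParams(**sec)
    if "filter" in kwargs:
        sec = dict(kwargs["filter"])
        if "window" in sec and isinstance(sec["window"], list):
            sec["window"] = tuple(sec["window"])
        kwargs["filter"] = preprocess.FilterSpec(**sec)
    if "postprocess" in kwargs:
        sec = dict(kwargs.pop("postprocess"))
        for key in ("median_window", "line_angles"):
            if key in sec and isinstance(sec[key], list):
                sec[key] = tuple(sec[key])
        kwargs["post"] = postprocess.PostprocessSpec(**sec)
    if "idm_distances" in kwargs and isinstance(kwargs["idm_distances"], list):
        kwargs["idm_distances"] = tuple(kwargs["idm_distances"])
    if "threshold" in kwargs:
        kwargs["threshold_method"] = kwargs.pop("threshold")
    return PipelineConfig(**kwargs)
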