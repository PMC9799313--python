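"""File formats, run configuration and the end-to-end pipeline.

Conventions, stated once and applied everywhere: pixel coordinates are
0-based (row, col); masks are raster-ordered; intervals are half-open;
CSV is comma-separated UTF-8 with a header row and '.' decimals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import belief, features, fusion
from .detection import ImageGrid, SpotDetector, compute_response
from .exceptions import ConfigError, UnsupportedFormatError
from .simulate import GroundTruth

logger = logging.getLogger("beliefspot")

__all__ = [
    "read_image",
    "write_image",
    "write_label_map",
    "write_truth",
    "read_truth",
    "RunConfig",
    "run_pipeline",
]


def read_image(path) -> ImageGrid:
    """Read a single-channel 8-/16-bit grayscale TIFF as a float grid."""
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise UnsupportedFormatError(
            f"{path}: expected a single-channel 2D image, got shape {data.shape}"
        )
    if data.dtype == np.uint8:
        depth = 8
    elif data.dtype == np.uint16:
        depth = 16
    else:
        raise UnsupportedFormatError(
            f"{path}: expected uint8 or uint16 pixels, got {data.dtype}"
        )
    return ImageGrid(pixels=data.astype(float), bit_depth=depth)


def write_image(image: np.ndarray | ImageGrid, path, bit_depth: int = 8) -> None:
    """Write an intensity raster as 8- or 16-bit grayscale TIFF."""
    pixels = image.pixels if isinstance(image, ImageGrid) else np.asarray(image)
    if bit_depth == 8:
        tifffile.imwrite(path, np.clip(np.round(pixels), 0, 255).astype(np.uint8))
    elif bit_depth == 16:
        tifffile.imwrite(path, np.clip(np.round(pixels), 0, 65535).astype(np.uint16))
    else:
        raise ValueError("bit_depth must be 8 or 16")


def write_label_map(label_map: np.ndarray, path) -> None:
    """Write a component label map as 16-bit TIFF (0 = background)."""
    if label_map.max() > 65535:
        raise ValueError("more than 65535 components cannot be stored in 16 bits")
    tifffile.imwrite(path, label_map.astype(np.uint16))


def write_truth(truth: GroundTruth, path, width: int) -> None:
    payload = [
        {
            "row": r,
            "col": c,
            "sigma": sigma,
            "amplitude": amp,
            "footprint_rle": features.rle_encode(fp, width),
        }
        for (r, c, sigma, amp), fp in zip(truth.sources, truth.footprints)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"width": width, "sources": payload}, fh, indent=2)


def read_truth(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    width = payload["width"]
    truth = GroundTruth(sources=[], footprints=[])
    for src in payload["sources"]:
        truth.sources.append((src["row"], src["col"], src["sigma"], src["amplitude"]))
        truth.footprints.append(features.rle_decode(src["footprint_rle"], width))
    return truth


@dataclass
class DetectionSettings:
    pre_sigma: float = 0.0
    post_sigma: float = 1.0
    prc: float = 2.0
    connectivity: int = 8
    min_area: int = 1
    prune_local_maxima: bool = False
    kurtosis_fallback: str = "error"
    threshold_mode: str = "geometric"


@dataclass
class RunConfig:
    """One JSON document capturing a full reproducible run.

    ``references`` maps each label to a directory of TIFFs used to fit
    its reference model; ``target`` is the directory of images to
    label.  Unknown keys anywhere in the document are rejected by name.
    """

    references: dict[str, str]
    target: str
    out_dir: str
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    z_scope: str = "image"
    cantelli: str = "literal"
    fusion_log_base: str = "e"
    combine: bool = False
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        payload = dict(payload)
        det = payload.get("detection", {})
        if isinstance(det, dict):
            det_known = {f.name for f in dataclasses.fields(DetectionSettings)}
            det_unknown = set(det) - det_known
            if det_unknown:
                raise ConfigError(
                    f"unknown detection configuration keys: {sorted(det_unknown)}"
                )
            payload["detection"] = DetectionSettings(**det)
        return cls(**payload)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _detect_directory(
    directory: Path, detector: SpotDetector, out_dir: Path | None = None
) -> pd.DataFrame:
    """Detect + featurise every TIFF in a directory; one table out."""
    records: list[features.ObjectRecord] = []
    paths = sorted(directory.glob("*.tif")) + sorted(directory.glob("*.tiff"))
    if not paths:
        raise FileNotFoundError(f"no TIFF images found in {directory}")
    for path in paths:
        grid = read_image(path)
        components = detector.detect(grid)
        response = detector.response_
        logger.info(
            "%s: kurtosis=%.4g z=%.4g threshold=%.4g components=%d",
            path.name,
            detector.kurtosis_,
            detector.z_score_,
            detector.threshold_,
            len(components),
        )
        if out_dir is not None:
            write_label_map(components.label_map, out_dir / f"{path.stem}_labels.tif")
        records.extend(
            features.objects_from_components(components, grid, response, path.stem)
        )
    return features.features_table(records)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Detect -> featurise -> fit reference models -> label -> (combine).

    Writes, under ``config.out_dir``: per-image label maps, object
    feature CSVs, one model JSON per reference label, a labelled CSV
    with a belief triplet per target object per reference label, an
    optional fused CSV, and a run log capturing every parameter.
    Deterministic: identical config (and images) gives byte-identical
    CSV outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    artifacts: dict[str, Path] = {}
    detector = SpotDetector(**dataclasses.asdict(config.detection))

    with open(out_dir / "run_config.json", "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    artifacts["config"] = out_dir / "run_config.json"

    models: dict[str, belief.PlausibilityModel] = {}
    for label, directory in sorted(config.references.items()):
        try:
            table = _detect_directory(Path(directory), detector)
        except Exception as exc:  # pragma: no cover - stage tagging
            raise type(exc)(f"[reference detection: {label}] {exc}") from exc
        ref_csv = out_dir / f"objects_{label}.csv"
        features.write_objects_csv(table, ref_csv)
        artifacts[f"objects_{label}"] = ref_csv
        model = belief.fit_reference_model(table, label)
        model_path = out_dir / f"model_{label}.json"
        belief.save_model(model, model_path)
        artifacts[f"model_{label}"] = model_path
        models[label] = model

    try:
        target_table = _detect_directory(Path(config.target), detector, out_dir)
    except Exception as exc:
        raise type(exc)(f"[target detection] {exc}") from exc
    target_csv = out_dir / "objects_target.csv"
    features.write_objects_csv(target_table, target_csv)
    artifacts["objects_target"] = target_csv

    scored = {
        label: belief.assign_plausibility(
            target_table, model, z_scope=config.z_scope, cantelli=config.cantelli
        )
        for label, model in models.items()
    }
    labelled_frames = []
    labels = sorted(scored)
    for label in labels:
        frame = scored[label].copy()
        if len(labels) == 2:
            other = labels[1] if label == labels[0] else labels[0]
            triplets = [
                belief.bidirectional_triplet(qj, qi)
                for qj, qi in zip(frame["pl"], scored[other]["pl"])
            ]
            frame["p"] = [t.p for t in triplets]
            frame["q"] = [t.q for t in triplets]
            frame["r"] = [t.r for t in triplets]
            frame["clamped"] = [t.clamped for t in triplets]
        else:
            # single reference: vacuous belief, all support is plausibility
            frame["p"] = 0.0
            frame["q"] = 1.0 - frame["pl"]
            frame["r"] = frame["pl"]
            frame["clamped"] = False
        labelled_frames.append(frame)
    labelled = pd.concat(labelled_frames, ignore_index=True)
    labelled_csv = out_dir / "labelled.csv"
    labelled.to_csv(labelled_csv, index=False)
    artifacts["labelled"] = labelled_csv

    if config.combine:
        if len(labels) != 2:
            raise ConfigError("fusion requires exactly two reference labels")
        joint = fusion.combine_labelled_tables(
            labelled[labelled["label"] == labels[0]],
            labelled[labelled["label"] == labels[1]],
            mass_col="p",
            log_base=config.fusion_log_base,
        )
        joint_csv = out_dir / "joint.csv"
        joint.to_csv(joint_csv, index=False)
        artifacts["joint"] = joint_csv
    return artifacts
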