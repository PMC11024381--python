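"""End-to-end orchestration, annotation records and evaluation.

``run_pipeline`` chains detection -> segmentation -> overlap detection ->
interior-exterior classification -> arrangement matching and always
returns an :class:`AnnotationRecord`; when a stage fails the record marks
the failing stage and leaves downstream fields empty.  Records serialize
to JSON, can be edited by file-based manual corrections (point add /
remove / label flip) and re-matched — the same workflow an interactive
correction UI would drive, minus the UI.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .arrangement import (
    ArrangementCatalog,
    load_catalog,
    lr_to_iea,
    match_arrangement,
    order_overlaps_by_angle,
)
from .errors import CorrectionError, InvalidInputError, TepalsError
from .ie_classifier import IEModel, MetaConfig, MetaTask, adapt_and_predict
from .overlaps import OverlapPoint, detect_overlap_points, overlap_f1
from .patches import crop_original_patch, generate_synthetic_patch_set
from .segmentation import (
    BoundingBox,
    SegmentedFlower,
    detect_flower,
    letterbox,
    region_iou,
    segment_flower,
)

__all__ = [
    "PipelineConfig",
    "AnnotationRecord",
    "run_pipeline",
    "apply_corrections",
    "integrated_accuracy_estimate",
    "evaluate",
]

STAGES = ("detect", "segment", "overlaps", "classify", "arrange")


@dataclass
class PipelineConfig:
    """All pipeline knobs in one place (defaults are the reference
    operating point: 5 segmentation iterations, 15 px overlap radius,
    20 px patches, synthesis radii 10 and 15 px with a 50-crop quota)."""

    segmentation_iterations: int = 5
    overlap_radius: float = 15.0
    patch_size: int = 20
    synthesis_radii: tuple[float, float] = (10.0, 15.0)
    synthesis_quota: int = 50
    synthesis_per_class: int = 25
    support_per_class: int = 10
    backend: str = "baseline"  # baseline | maml | oracle
    meta: MetaConfig = field(default_factory=MetaConfig)
    catalog_path: str | None = None
    letterbox_side: int = 256
    seed: int = 0

    def catalog(self) -> ArrangementCatalog:
        return load_catalog(self.catalog_path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        meta = MetaConfig(**data.pop("meta", {}))
        if "synthesis_radii" in data:
            data["synthesis_radii"] = tuple(data["synthesis_radii"])
        return cls(meta=meta, **data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["synthesis_radii"] = list(self.synthesis_radii)
        Path(path).write_text(yaml.safe_dump(data))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class AnnotationRecord:
    """Everything the pipeline decided about one image.

    ``extra`` preserves unknown fields found in serialized records so that
    records written by newer tools round-trip losslessly.
    The segmentation mask is kept in memory (``mask``) for evaluation but
    is not serialized; masks persist as PNG files alongside the record.
    """

    image_path: str = ""
    box: BoundingBox | None = None
    overlap_points: list[OverlapPoint] = field(default_factory=list)
    tepal_sequence: str | None = None
    match_id: str | None = None
    match_distance: int | None = None
    match_ambiguous: bool = False
    runners_up: list[str] = field(default_factory=list)
    failure_stage: str | None = None
    provenance: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)
    mask: np.ndarray | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        d = {
            "image_path": self.image_path,
            "box": list(self.box.as_tuple()) if self.box else None,
            "overlap_points": [
                {
                    "position": [float(v) for v in op.position],
                    "chord_endpoints": [
                        [float(v) for v in e] for e in op.chord_endpoints
                    ],
                    "label": op.label,
                    "confidence": float(op.confidence),
                    "corrected": bool(op.corrected),
                }
                for op in self.overlap_points
            ],
            "tepal_sequence": self.tepal_sequence,
            "match": None
            if self.match_id is None
            else {
                "id": self.match_id,
                "distance": self.match_distance,
                "ambiguous": self.match_ambiguous,
                "runners_up": list(self.runners_up),
            },
            "failure_stage": self.failure_stage,
            "provenance": self.provenance,
        }
        d.update(self.extra)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationRecord":
        known = {
            "image_path", "box", "overlap_points", "tepal_sequence",
            "match", "failure_stage", "provenance",
        }
        box = BoundingBox(*d["box"]) if d.get("box") else None
        points = [
            OverlapPoint(
                position=tuple(op["position"]),
                chord_endpoints=tuple(tuple(e) for e in op["chord_endpoints"]),
                label=op.get("label", "unknown"),
                confidence=op.get("confidence", 0.0),
                corrected=op.get("corrected", False),
            )
            for op in d.get("overlap_points", [])
        ]
        match = d.get("match") or {}
        return cls(
            image_path=d.get("image_path", ""),
            box=box,
            overlap_points=points,
            tepal_sequence=d.get("tepal_sequence"),
            match_id=match.get("id"),
            match_distance=match.get("distance"),
            match_ambiguous=match.get("ambiguous", False),
            runners_up=list(match.get("runners_up", [])),
            failure_stage=d.get("failure_stage"),
            provenance=d.get("provenance", {}),
            extra={k: v for k, v in d.items() if k not in known},
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "AnnotationRecord":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.from_dict(json.loads(text))


def _classify_points(
    flower: SegmentedFlower,
    points: list[OverlapPoint],
    config: PipelineConfig,
    model: IEModel | None,
    truth=None,
) -> None:
    """Assign an L/R label and confidence to every detected point, in place."""
    if config.backend == "oracle":
        if truth is None:
            raise InvalidInputError("oracle backend needs ground truth")
        gt = [(np.asarray(pos, float), lab) for pos, lab in truth.overlap_points]
        for op in points:
            dists = [np.linalg.norm(np.asarray(op.position) - pos) for pos, _ in gt]
            op.label = gt[int(np.argmin(dists))][1]
            op.confidence = 1.0
        return
    synth = generate_synthetic_patch_set(
        flower,
        points,
        seed=config.seed,
        per_class=config.synthesis_per_class,
        quota=config.synthesis_quota,
        radii=config.synthesis_radii,
        size=config.patch_size,
    )
    rng = np.random.default_rng(config.seed + 1)
    support = []
    for lab in ("L", "R"):
        group = [p for p in synth.patches if p.label == lab]
        take = min(config.support_per_class, len(group))
        for i in sorted(rng.choice(len(group), take, replace=False)):
            support.append((group[int(i)], lab))
    query = [
        (crop_original_patch(flower, op, config.patch_size), None) for op in points
    ]
    task = MetaTask(support=support, query=query, flower_id="inference")
    if config.backend == "baseline" or model is None:
        model = IEModel(backend="baseline", params=None, config=config.meta)
    preds = adapt_and_predict(model, task)
    for op, (label, conf) in zip(points, preds):
        op.label = label
        op.confidence = conf


def run_pipeline(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    model: IEModel | None = None,
    *,
    detector=None,
    truth=None,
    image_path: str = "",
) -> AnnotationRecord:
    """Run every stage on one RGB image and return the annotation record.

    ``detector`` is an optional detection backend; it receives the
    letterboxed image and its predictions are mapped back to original
    coordinates.  Without one the color-saliency fallback runs at full
    resolution.  ``truth`` (a renderer :class:`GroundTruth`) is only
    consulted by the non-production ``oracle`` classifier backend.
    Stage failures yield a record with ``failure_stage`` set and all
    downstream fields empty.
    """
    config = config or PipelineConfig()
    record = AnnotationRecord(
        image_path=image_path,
        provenance={
            "config_digest": config.digest(),
            "seed": config.seed,
            "backend": config.backend,
        },
    )
    stage = "detect"
    try:
        if detector is not None:
            small, spec = letterbox(image, config.letterbox_side)
            box_small = detect_flower(small, backend=detector)
            h, w = image.shape[:2]
            box = spec.box_to_original(box_small, w, h)
        else:
            box = detect_flower(image)
        record.box = box

        stage = "segment"
        flower = segment_flower(image, box, config.segmentation_iterations)
        record.mask = flower.mask

        stage = "overlaps"
        points = detect_overlap_points(flower, config.overlap_radius)
        record.overlap_points = points
        if len(points) < 3:
            raise InvalidInputError(
                f"only {len(points)} overlap points; need 3 for a circular sequence"
            )

        stage = "classify"
        _classify_points(flower, points, config, model, truth)

        stage = "arrange"
        seq = order_overlaps_by_angle(points, flower.mask)
        tepal_seq = lr_to_iea(seq)
        record.tepal_sequence = tepal_seq.classes
        m = match_arrangement(tepal_seq, config.catalog())
        record.match_id = m.best.id
        record.match_distance = m.distance
        record.match_ambiguous = m.ambiguous
        record.runners_up = [e.id for e in m.runners_up]
    except TepalsError as exc:
        record.failure_stage = stage
        record.provenance["failure"] = f"{type(exc).__name__}: {exc}"
    return record


def _rematch(record: AnnotationRecord, catalog: ArrangementCatalog) -> None:
    points = record.overlap_points
    if len(points) < 3 or any(op.label not in ("L", "R") for op in points):
        record.tepal_sequence = None
        record.match_id = None
        record.match_distance = None
        record.match_ambiguous = False
        record.runners_up = []
        return
    seq = order_overlaps_by_angle(points, record.mask)
    tepal_seq = lr_to_iea(seq)
    record.tepal_sequence = tepal_seq.classes
    m = match_arrangement(tepal_seq, catalog)
    record.match_id = m.best.id
    record.match_distance = m.distance
    record.match_ambiguous = m.ambiguous
    record.runners_up = [e.id for e in m.runners_up]


def apply_corrections(
    record: AnnotationRecord,
    edits: list[dict],
    catalog: ArrangementCatalog | None = None,
    *,
    tol: float = 3.0,
) -> AnnotationRecord:
    """Apply manual corrections and recompute ordering, conversion and
    matching from the corrected labels.

    Each edit is a mapping with ``op`` in {"add", "remove", "flip"}; adds
    carry ``position`` and ``label``, removes and flips reference an
    existing point by ``position`` (nearest within ``tol`` pixels).
    Returns a new record; corrected flags are set on touched points.
    """
    catalog = catalog if catalog is not None else load_catalog()
    points = [replace_point(op) for op in record.overlap_points]
    for edit in edits:
        kind = edit.get("op")
        if kind == "add":
            x, y = edit["position"]
            points.append(
                OverlapPoint(
                    position=(float(x), float(y)),
                    chord_endpoints=((float(x) - 1, float(y)), (float(x) + 1, float(y))),
                    label=edit.get("label", "unknown"),
                    confidence=1.0,
                    corrected=True,
                )
            )
            continue
        if kind not in ("remove", "flip"):
            raise CorrectionError(f"unknown edit op {kind!r}")
        x, y = edit["position"]
        dists = [
            np.hypot(op.position[0] - x, op.position[1] - y) for op in points
        ]
        if not dists or min(dists) > tol:
            raise CorrectionError(f"no overlap point within {tol} px of ({x}, {y})")
        i = int(np.argmin(dists))
        if kind == "remove":
            points.pop(i)
        else:
            op = points[i]
            if op.label not in ("L", "R"):
                raise CorrectionError("cannot flip an unlabeled point")
            op.label = "R" if op.label == "L" else "L"
            op.corrected = True
    out = AnnotationRecord(
        image_path=record.image_path,
        box=record.box,
        overlap_points=points,
        failure_stage=None,
        provenance={**record.provenance, "corrected": True},
        extra=dict(record.extra),
        mask=record.mask,
    )
    _rematch(out, catalog)
    return out


def replace_point(op: OverlapPoint) -> OverlapPoint:
    return OverlapPoint(
        position=op.position,
        chord_endpoints=op.chord_endpoints,
        label=op.label,
        confidence=op.confidence,
        corrected=op.corrected,
    )


def integrated_accuracy_estimate(
    p_detect: float, p_classify: float, n_overlaps: int
) -> float:
    """Expected fraction of flowers on which every one of ``n_overlaps``
    overlap detections and interior-exterior classifications succeeds,
    assuming independence: ``(p_detect * p_classify) ** n_overlaps``."""
    for name, v in (("p_detect", p_detect), ("p_classify", p_classify)):
        if not 0.0 <= v <= 1.0:
            raise InvalidInputError(f"{name} must be in [0, 1]")
    if n_overlaps < 0:
        raise InvalidInputError("n_overlaps must be non-negative")
    return (p_detect * p_classify) ** n_overlaps


def evaluate(records: list[AnnotationRecord], truths: list) -> dict:
    """Per-stage summary of pipeline records against renderer ground truth.

    Reports mean detection-box IoU, mean segmentation IoU (when records
    carry masks), pooled overlap precision/recall/F1 (10 px tolerance),
    interior-exterior accuracy over matched points, arrangement accuracy,
    and the integrated estimate derived from the measured stage scores at
    the mean overlap count.
    """
    if len(records) != len(truths):
        raise InvalidInputError("records and truths must pair one-to-one")
    det_ious, seg_ious = [], []
    tp = fp = fn = 0
    ie_correct = ie_total = 0
    arr_correct = 0
    n_overlaps = []
    for rec, truth in zip(records, truths):
        if rec.box is not None:
            det_ious.append(region_iou(rec.box, truth.box))
        if rec.mask is not None:
            seg_ious.append(region_iou(rec.mask, truth.mask))
        ev = overlap_f1(rec.overlap_points, truth.positions, tol=10.0)
        tp += ev.tp
        fp += ev.fp
        fn += ev.fn
        n_overlaps.append(len(truth.overlap_points))
        gt = [(np.asarray(pos, float), lab) for pos, lab in truth.overlap_points]
        for op in rec.overlap_points:
            dists = [np.linalg.norm(np.asarray(op.position) - pos) for pos, _ in gt]
            if dists and min(dists) <= 10.0 and op.label in ("L", "R"):
                ie_total += 1
                if gt[int(np.argmin(dists))][1] == op.label:
                    ie_correct += 1
        if rec.match_id is not None and rec.match_id == truth.arrangement_id:
            arr_correct += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    ie_acc = ie_correct / ie_total if ie_total else 0.0
    mean_n = float(np.mean(n_overlaps)) if n_overlaps else 0.0
    return {
        "n_images": len(records),
        "detection_iou_mean": float(np.mean(det_ious)) if det_ious else None,
        "segmentation_iou_mean": float(np.mean(seg_ious)) if seg_ious else None,
        "overlap_precision": precision,
        "overlap_recall": recall,
        "overlap_f1": f1,
        "interior_exterior_accuracy": ie_acc,
        "arrangement_accuracy": arr_correct / len(records) if records else 0.0,
        "integrated_estimate": integrated_accuracy_estimate(
            precision, ie_acc, int(round(mean_n))
        ),
    }
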