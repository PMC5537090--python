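"""Structured bone-age reports and the deployed end-to-end pipeline.

``run_pipeline`` chains the whole system on one radiograph: normalization,
label-map segmentation, vision pipeline, classification, maturity staging —
and returns a structured report carrying the top-k age suggestions (3 to 5,
mirroring the handful of atlas reference images shown to the radiologist)
plus model hashes for auditability.  Repeated runs on the same input and
model files produce identical reports (up to the timestamp).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .classifier import BoneAgeCNN, predict
from .detection import PatchClassifierCNN
from .errors import ConfigError
from .evaluation import maturity_stage
from .io import Radiograph, Sex, read_radiograph
from .pipeline import preprocess

MIN_SUGGESTIONS, MAX_SUGGESTIONS = 3, 5


@dataclass
class StructuredReport:
    source_id: str
    sex: str
    predicted_bone_age: int
    topk_suggestions: tuple  # ((age, probability), ...) descending, 3-5 rows
    maturity_stage: str
    pipeline_versions: dict = field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self):
        if not MIN_SUGGESTIONS <= len(self.topk_suggestions) <= MAX_SUGGESTIONS:
            raise ValueError("topk_suggestions must hold 3 to 5 entries")
        probs = [p for _, p in self.topk_suggestions]
        if sorted(probs, reverse=True) != list(probs):
            raise ValueError("topk_suggestions must be sorted by probability")


def _clamp_k(k: int) -> int:
    if not MIN_SUGGESTIONS <= k <= MAX_SUGGESTIONS:
        clamped = min(MAX_SUGGESTIONS, max(MIN_SUGGESTIONS, k))
        warnings.warn(
            f"requested {k} suggestions; clamped to {clamped} (reports carry "
            f"{MIN_SUGGESTIONS}-{MAX_SUGGESTIONS} reference suggestions)",
            stacklevel=3,
        )
        return clamped
    return k


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(
    input_path,
    detector_path,
    classifier_path,
    sex=None,
    k: int = 5,
    patch_size: int | None = None,
    stride: int = 4,
    timestamp: str | None = None,
) -> StructuredReport:
    """Run the fully automated system on one radiograph file.

    Stages: read -> normalize -> label map -> mask -> vision pipeline ->
    classify -> report.  Errors are re-raised with the failing stage named.
    """
    image = (
        input_path
        if isinstance(input_path, Radiograph)
        else read_radiograph(input_path)
    )
    if sex is not None:
        image.sex = Sex.coerce(sex)
    if image.sex is None:
        raise ConfigError("[input] sex is required (file metadata or --sex)")

    try:
        detector = PatchClassifierCNN.load(detector_path)
    except Exception as exc:
        raise ConfigError(f"[detector] {exc}") from exc
    try:
        model = BoneAgeCNN.load(classifier_path)
    except Exception as exc:
        raise ConfigError(f"[classifier] {exc}") from exc

    psize = patch_size if patch_size is not None else detector.patch_size_
    try:
        result = preprocess(image, detector, patch_size=psize, stride=stride)
    except Exception as exc:
        raise type(exc)(f"[preprocess] {exc}") from exc

    k = _clamp_k(k)
    pred = predict(model, result.preprocessed, k=k)
    stage = maturity_stage(image.sex, pred.top1)

    versions = {
        "autobaa": __version__,
        "patch_size": str(psize),
        "stride": str(stride),
    }
    for name, path in (("detector", detector_path), ("classifier", classifier_path)):
        try:
            versions[f"{name}_sha256"] = _file_hash(path)
        except (OSError, TypeError):
            pass
    return StructuredReport(
        source_id=image.source_id,
        sex=image.sex.value,
        predicted_bone_age=pred.top1,
        topk_suggestions=tuple((int(a), float(p)) for a, p in pred.topk),
        maturity_stage=stage,
        pipeline_versions=versions,
        timestamp=timestamp
        if timestamp is not None
        else _dt.datetime.now(_dt.timezone.utc).isoformat(),
    )


def render_report(report: StructuredReport, format: str = "json") -> str:
    """Serialize a report as schema-stable JSON or a human-readable text block."""
    if format == "json":
        return json.dumps(
            {
                "source_id": report.source_id,
                "sex": report.sex,
                "predicted_bone_age": report.predicted_bone_age,
                "topk_suggestions": [
                    {"age": a, "probability": p} for a, p in report.topk_suggestions
                ],
                "maturity_stage": report.maturity_stage,
                "pipeline_versions": report.pipeline_versions,
                "timestamp": report.timestamp,
            },
            indent=1,
            sort_keys=True,
        )
    if format == "text":
        lines = [
            "BONE AGE ASSESSMENT (automated)",
            f"study:            {report.source_id}",
            f"sex:              {report.sex}",
            f"predicted age:    {report.predicted_bone_age} years",
            f"maturity stage:   {report.maturity_stage.replace('_', '-')}",
            "reference suggestions:",
        ]
        for age, prob in report.topk_suggestions:
            lines.append(f"  {age:>2d} years   p = {prob:.3f}")
        lines.append(f"generated: {report.timestamp}")
        return "\n".join(lines)
    raise ConfigError(f"unknown report format {format!r} (json|text)")


def parse_report(text: str) -> StructuredReport:
    """Inverse of ``render_report(..., 'json')``."""
    d = json.loads(text)
    return StructuredReport(
        source_id=d["source_id"],
        sex=d["sex"],
        predicted_bone_age=int(d["predicted_bone_age"]),
        topk_suggestions=tuple(
            (int(e["age"]), float(e["probability"])) for e in d["topk_suggestions"]
        ),
        maturity_stage=d["maturity_stage"],
        pipeline_versions=dict(d["pipeline_versions"]),
        timestamp=d["timestamp"],
    )
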