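"""End-to-end reading: image -> registration -> segmentation -> result.

Interpretation rules for a line strip: no control line means the sample
never migrated, so the strip is invalid regardless of the test region.
Otherwise the five-level test-line class collapses to the reported result:
the light classes (absent or barely-formed line) read positive, the dark
classes read negative, and the doubtful class follows a configurable
policy (undetermined by default).  Any rejected ("undetermined")
classifier output, control or test, dominates the strip result.  Alcohol
strips report the alcohol classifier's label directly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ReaderConfig
from .errors import RegistrationError, SegmentationError
from .histogram import preprocess_alcohol_strip, preprocess_line_strip
from .mlp import UNDETERMINED, TansigMLPClassifier, load_model
from .registration import TemplateModel, locate_strip_region
from .segmentation import segment_roi
from .synthetic import ALCOHOL_STRIP_ID

REGISTRATION_FAILURE = "registration_failure"
SEGMENTATION_MISMATCH = "segmentation_mismatch"


@dataclass
class PanelConfig:
    """Ordered strip identities of one card side."""

    strips: tuple[str, ...]
    alcohol_strip_id: str = ALCOHOL_STRIP_ID

    @property
    def alcohol_present(self) -> bool:
        return self.alcohol_strip_id in self.strips

    @classmethod
    def parse(cls, text: str) -> "PanelConfig":
        return cls(strips=tuple(s.strip().upper() for s in text.split(",") if s.strip()))


@dataclass
class ReaderModels:
    """The trained classifiers a panel needs."""

    control: TansigMLPClassifier | None = None
    testline: TansigMLPClassifier | None = None
    alcohol: TansigMLPClassifier | None = None

    @classmethod
    def load(cls, directory: str | Path) -> "ReaderModels":
        directory = Path(directory)
        kwargs = {}
        for kind in ("control", "testline", "alcohol"):
            path = directory / f"{kind}.json"
            if path.exists():
                kwargs[kind] = load_model(path)
        return cls(**kwargs)

    def require(self, panel: PanelConfig) -> None:
        needs_lines = any(s != panel.alcohol_strip_id for s in panel.strips)
        if needs_lines and (self.control is None or self.testline is None):
            raise ValueError("panel has line strips but control/testline "
                             "models are missing")
        if panel.alcohol_present and self.alcohol is None:
            raise ValueError("panel has an alcohol strip but no alcohol model")


@dataclass
class StripResult:
    strip_id: str
    final_result: str                      # positive|negative|invalid|undetermined
    control_status: str | None = None      # valid|invalid|undetermined
    testline_class: str | None = None
    alcohol_class: str | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class TestResult:
    image_id: str
    panel: tuple[str, ...]
    strips: list[StripResult] = field(default_factory=list)
    failure: str | None = None
    timestamp: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _collapse_testline(testline_class: str, policy: str) -> str:
    if testline_class == UNDETERMINED:
        return UNDETERMINED
    if testline_class in ("very_positive", "positive"):
        return "positive"
    if testline_class in ("negative", "very_negative"):
        return "negative"
    return policy  # doubtful


def _read_line_strip(window, strip_id, models: ReaderModels,
                     config: ReaderConfig, seed: int) -> StripResult:
    hist = preprocess_line_strip(window, config.histogram, seed=seed,
                                 strip_id=strip_id)
    control_half = hist.values[:31]
    test_half = hist.values[31:]
    control_label = str(models.control.predict([control_half])[0])
    test_label = str(models.testline.predict([test_half])[0])
    control_status = {"valid": "valid", "invalid": "invalid"}.get(
        control_label, UNDETERMINED)

    if control_status == "invalid":
        final = "invalid"
    elif control_status == UNDETERMINED:
        final = UNDETERMINED
    else:
        final = _collapse_testline(test_label, config.pipeline.doubtful_policy)

    return StripResult(
        strip_id=strip_id, final_result=final,
        control_status=control_status, testline_class=test_label,
        provenance={
            "histogram": hist.values.tolist(),
            "baseline": [hist.metadata.get("baseline_slope"),
                         hist.metadata.get("baseline_intercept")],
            "minima": [hist.metadata.get("h_min1"), hist.metadata.get("h_min2")],
            "control_scores": models.control.predict_scores(
                [control_half])[0].tolist(),
            "testline_scores": models.testline.predict_scores(
                [test_half])[0].tolist(),
        })


def _read_alcohol_strip(window, strip_id, models: ReaderModels,
                        config: ReaderConfig, seed: int) -> StripResult:
    hist = preprocess_alcohol_strip(window, config.histogram, seed=seed,
                                    strip_id=strip_id)
    label = str(models.alcohol.predict([hist.values])[0])
    return StripResult(
        strip_id=strip_id, final_result=label, alcohol_class=label,
        provenance={
            "histogram": hist.values.tolist(),
            "alcohol_scores": models.alcohol.predict_scores(
                [hist.values])[0].tolist(),
        })


def read_test(image, template: TemplateModel | str | Path,
              panel: PanelConfig, models: ReaderModels,
              config: ReaderConfig | None = None, seed: int = 0,
              image_id: str | None = None,
              debug_dir: str | Path | None = None) -> TestResult:
    """Run the full chain on one captured image.

    ``image`` may be an array or a path.  Registration or segmentation
    failures are reported through ``TestResult.failure`` rather than
    raised, so batch callers can keep going.
    """
    config = config or ReaderConfig()
    if isinstance(template, (str, Path)):
        template = TemplateModel.load(template)
    if isinstance(image, (str, Path)):
        import imageio.v3 as iio

        image_id = image_id or Path(image).stem
        image = iio.imread(image)
    image_id = image_id or "image"
    models.require(panel)

    result = TestResult(image_id=image_id, panel=panel.strips)
    try:
        roi, hom = locate_strip_region(image, template,
                                       config.registration, seed=seed)
    except RegistrationError:
        result.failure = REGISTRATION_FAILURE
        return result
    try:
        regions = segment_roi(roi, panel.strips, panel.alcohol_present,
                              config.segmentation)
    except SegmentationError:
        result.failure = SEGMENTATION_MISMATCH
        return result

    if debug_dir is not None:
        _dump_debug(debug_dir, image_id, roi, regions, panel, config)

    for region in regions:
        x, y, w, h = region.histogram_window
        window = roi[y:y + h, x:x + w]
        if region.strip_id == panel.alcohol_strip_id:
            strip = _read_alcohol_strip(window, region.strip_id, models,
                                        config, seed)
        else:
            strip = _read_line_strip(window, region.strip_id, models,
                                     config, seed)
        strip.provenance["window"] = list(region.histogram_window)
        strip.provenance["inliers"] = hom.inlier_count
        result.strips.append(strip)
    return result


def _dump_debug(debug_dir, image_id, roi, regions, panel, config):
    import imageio.v3 as iio

    from .segmentation import column_filter, threshold_strips

    debug_dir = Path(debug_dir)
    debug_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(debug_dir / f"{image_id}.roi.png", roi)
    mask = column_filter(
        threshold_strips(roi, panel.alcohol_present, config.segmentation),
        config.segmentation.column_min_fraction)
    iio.imwrite(debug_dir / f"{image_id}.mask.png",
                (mask * 255).astype(np.uint8))
    payload = [dataclasses.asdict(r) for r in regions]
    (debug_dir / f"{image_id}.regions.json").write_text(
        json.dumps(payload, indent=1))


def read_batch(directory: str | Path, template, panel: PanelConfig,
               models: ReaderModels, config: ReaderConfig | None = None,
               seed: int = 0):
    """Read every image in a directory and summarize repeatability.

    Files sharing the stem before a ``__`` separator are treated as repeat
    captures of the same physical card; the summary reports, per card and
    strip, the frequency of the modal result over those repeats.  Unreadable
    files are skipped and counted.
    """
    directory = Path(directory)
    if isinstance(template, (str, Path)):
        template = TemplateModel.load(template)
    results: list[TestResult] = []
    skipped = 0
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    for path in paths:
        try:
            import imageio.v3 as iio

            image = iio.imread(path)
        except Exception:
            skipped += 1
            continue
        results.append(read_test(image, template, panel, models, config,
                                 seed=seed, image_id=path.stem))

    by_card: dict[str, list[TestResult]] = {}
    for res in results:
        by_card.setdefault(res.image_id.split("__")[0], []).append(res)

    repeatability = {}
    for card_id, reads in by_card.items():
        per_strip = {}
        for strip_id in panel.strips:
            outcomes = [s.final_result for r in reads for s in r.strips
                        if s.strip_id == strip_id]
            if outcomes:
                values, counts = np.unique(outcomes, return_counts=True)
                per_strip[strip_id] = {
                    "modal_result": str(values[counts.argmax()]),
                    "frequency_pct": 100.0 * counts.max() / len(outcomes),
                    "n_reads": len(outcomes),
                }
        repeatability[card_id] = per_strip

    summary = {
        "n_images": len(results),
        "n_skipped": skipped,
        "n_failed": sum(1 for r in results if r.failure),
        "repeatability": repeatability,
    }
    return results, summary
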