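"""Seeded generators for synthetic test-card images and histogram datasets.

The physical assay is a multi-strip lateral-flow saliva card photographed
inside a light box.  No public image set exists for it, so this module
renders cards with the features the reader relies on:

* a white card carrying printed fiducial texture (so ORB keypoints exist),
* one colored label region per strip at the top of the strip window,
* transverse control/test lines whose darkness encodes the assay outcome,
* an optional blue alcohol reagent pad,
* a linear illumination ramp, additive Gaussian sensor noise, and a small
  in-plane pose perturbation (translation + rotation) of the card.

Every generator is a pure function of its arguments including the seed.
The card pixel geometry is a package choice (the assay vendor publishes
none); all of it lives in :class:`CardGeometry`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import ProjectiveTransform, warp

from .errors import ConfigurationError, GenerationError

# Ordered from lightest (line absent -> drug above cutoff -> "positive")
# to darkest (strong line -> "negative").
TEST_LINE_CLASSES = (
    "very_positive",
    "positive",
    "doubtful",
    "negative",
    "very_negative",
)

# Line-darkness interval per class, on [0, 1].  Adjacent intervals overlap
# slightly on purpose: faint-line classes are genuinely confusable, and the
# test-line classifier is expected to make only adjacent-class errors.
DARKNESS_INTERVALS: dict[str, tuple[float, float]] = {
    "very_positive": (0.00, 0.05),
    "positive": (0.04, 0.26),
    "doubtful": (0.24, 0.50),
    "negative": (0.48, 0.72),
    "very_negative": (0.70, 1.00),
}

# Strip-label ink colors (all dark in G and in at least one of R/B, so both
# channel-combination rules of the segmenter see every label).
LABEL_PALETTE = (
    (200, 40, 55),   # crimson
    (45, 55, 200),   # royal blue
    (40, 90, 160),   # teal
    (200, 85, 40),   # rust
    (60, 45, 190),   # indigo
    (150, 55, 45),   # maroon
)

ALCOHOL_STRIP_ID = "ALC"

# Relative blood-alcohol level (pad blueness) at and above which the pad is
# considered visibly colored, i.e. a positive alcohol result.
ALCOHOL_POSITIVE_LEVEL = 0.2

# Peak darkness of a fully saturated line / pad, in 8-bit intensity units.
LINE_DEPTH_SCALE = 190.0
PAD_LUMA_DEPTH = 154.0  # luminance drop of a fully blue pad

WHITE = 245.0
BACKGROUND = 70.0


@dataclass(frozen=True)
class CardGeometry:
    """Pixel geometry of the synthetic card within a 640x480 frame.

    Offsets under ``label_*``/``*_line_offset`` are measured from the top of
    the strip region (for the label) or from the label's bottom edge (for
    lines and pad), in pixels.
    """

    frame_size: tuple[int, int] = (640, 480)          # (width, height)
    card_rect: tuple[int, int, int, int] = (60, 50, 580, 430)   # x0,y0,x1,y1
    roi_rect: tuple[int, int, int, int] = (140, 90, 500, 240)   # strip region
    label_top_offset: int = 10
    label_height: int = 34
    label_width_frac: float = 0.6     # of the per-strip pitch
    # line centers sit near the middle of each profile half, so the +-15-bin
    # alignment windows never clamp against the half boundaries
    control_line_offset: int = 26     # label bottom -> line center
    test_line_offset: int = 64
    line_thickness: int = 4
    pad_offsets: tuple[int, int] = (34, 72)  # label bottom -> pad top/bottom
    n_texture_patches: int = 350
    design_seed: int = 20150          # fixes the printed fiducial texture
    max_strips: int = 6

    @property
    def roi_quad(self) -> np.ndarray:
        """Strip-region corners (x, y), ordered tl, tr, br, bl."""
        x0, y0, x1, y1 = self.roi_rect
        return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


@dataclass(frozen=True)
class CardSpec:
    """Full description of one synthetic card to render."""

    panel: tuple[str, ...] = ("AMP", "KET", "COC", "MET")
    control_intensities: tuple[float, ...] = (0.8, 0.8, 0.8, 0.8)
    test_classes: tuple[str, ...] = ("very_negative",) * 4
    alcohol_level: float = 0.0
    illumination_gradient: float = 0.03   # intensity units per pixel, flow axis
    noise_sd: float = 2.0                 # additive Gaussian, 8-bit units
    pose: tuple[float, float, float] = (0.0, 0.0, 0.0)  # tx, ty, rot (deg)
    seed: int = 0

    @property
    def alcohol_present(self) -> bool:
        return ALCOHOL_STRIP_ID in self.panel

    def validate(self) -> None:
        if not self.panel:
            raise ConfigurationError("panel must name at least one strip")
        n = len(self.panel)
        if len(self.control_intensities) != n or len(self.test_classes) != n:
            raise ConfigurationError(
                "control_intensities and test_classes must match the panel length"
            )
        for c in self.control_intensities:
            if not 0.0 <= c <= 1.0:
                raise ConfigurationError(f"control intensity {c} outside [0, 1]")
        for cls in self.test_classes:
            if cls not in TEST_LINE_CLASSES:
                raise ConfigurationError(f"unknown test-line class {cls!r}")
        if not 0.0 <= self.alcohol_level <= 1.0:
            raise ConfigurationError("alcohol_level outside [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class StripTruth:
    strip_id: str
    expected_result: str                  # positive | negative | invalid
    label_box: tuple[int, int, int, int]  # x, y, w, h in card frame
    control_line_y: int | None
    test_line_y: int | None
    is_alcohol: bool = False


@dataclass
class GroundTruth:
    """Everything the generator applied, for downstream verification."""

    strips: list[StripTruth]
    homography: np.ndarray                # card frame -> image frame, 3x3

    def to_json(self) -> str:
        payload = {
            "strips": [dataclasses.asdict(s) for s in self.strips],
            "homography": self.homography.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        strips = []
        for s in payload["strips"]:
            s["label_box"] = tuple(s["label_box"])
            strips.append(StripTruth(**s))
        return cls(strips=strips, homography=np.asarray(payload["homography"]))


def expected_strip_result(control_intensity: float, test_class: str) -> str:
    """Outcome a perfect reader should report for a line strip.

    No control line means the sample never migrated: invalid.  Otherwise any
    visible shade in the test region reads negative; an absent or barely
    formed test line reads positive (competitive-binding assays invert the
    usual intuition).
    """
    if control_intensity == 0.0:
        return "invalid"
    if test_class in ("very_positive", "positive"):
        return "positive"
    return "negative"


def expected_alcohol_result(level: float) -> str:
    return "positive" if level >= ALCOHOL_POSITIVE_LEVEL else "negative"


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _strip_layout(geom: CardGeometry, n_strips: int):
    """Per-strip label boxes [(x, y, w, h)] in card-frame pixels."""
    x0, y0, x1, _ = geom.roi_rect
    pitch = (x1 - x0) / n_strips
    w = int(round(pitch * geom.label_width_frac))
    boxes = []
    for i in range(n_strips):
        cx = x0 + (i + 0.5) * pitch
        bx = int(round(cx - w / 2))
        boxes.append((bx, y0 + geom.label_top_offset, w, geom.label_height))
    return boxes


def _draw_texture(img: np.ndarray, geom: CardGeometry, rng: np.random.Generator):
    """Printed fiducial clutter on the card, kept clear of the strip region."""
    cx0, cy0, cx1, cy1 = geom.card_rect
    rx0, ry0, rx1, ry1 = geom.roi_rect
    margin = 6
    placed = 0
    while placed < geom.n_texture_patches:
        w = int(rng.integers(2, 8))
        h = int(rng.integers(2, 8))
        x = int(rng.integers(cx0 + 3, cx1 - 3 - w))
        y = int(rng.integers(cy0 + 3, cy1 - 3 - h))
        if (x + w > rx0 - margin and x < rx1 + margin
                and y + h > ry0 - margin and y < ry1 + margin):
            placed += 1  # count it anyway: keeps patch count seed-stable
            continue
        color = rng.integers(0, 160, size=3)
        img[y:y + h, x:x + w] = color
        placed += 1


def _render_card(spec: CardSpec, geom: CardGeometry, with_content: bool = True):
    """Noiseless, axis-aligned card render plus per-strip truth entries."""
    w, h = geom.frame_size
    img = np.full((h, w, 3), BACKGROUND, dtype=float)
    cx0, cy0, cx1, cy1 = geom.card_rect
    img[cy0:cy1, cx0:cx1] = WHITE

    design_rng = np.random.default_rng(geom.design_seed)
    _draw_texture(img, geom, design_rng)

    boxes = _strip_layout(geom, len(spec.panel))
    strips: list[StripTruth] = []
    for i, (strip_id, box) in enumerate(zip(spec.panel, boxes)):
        bx, by, bw, bh = box
        img[by:by + bh, bx:bx + bw] = LABEL_PALETTE[i % len(LABEL_PALETTE)]
        bottom = by + bh
        is_alc = strip_id == ALCOHOL_STRIP_ID
        if is_alc:
            if with_content and spec.alcohol_level > 0:
                p0, p1 = geom.pad_offsets
                px = bx + 2
                pw = bw - 4
                level = spec.alcohol_level
                pad = np.array([
                    WHITE - 200.0 * level,   # R
                    WHITE - 160.0 * level,   # G
                    235.0,                   # B stays high: blue pad
                ])
                img[bottom + p0:bottom + p1, px:px + pw] = pad
            strips.append(StripTruth(
                strip_id=strip_id,
                expected_result=expected_alcohol_result(spec.alcohol_level),
                label_box=box, control_line_y=None, test_line_y=None,
                is_alcohol=True,
            ))
            continue

        ctrl = spec.control_intensities[i]
        cls = spec.test_classes[i]
        darkness_lo, darkness_hi = DARKNESS_INTERVALS[cls]
        # midpoint of the class interval: the card is the class prototype
        test_darkness = 0.5 * (darkness_lo + darkness_hi)
        cy = bottom + geom.control_line_offset
        ty = bottom + geom.test_line_offset
        if with_content:
            half = geom.line_thickness // 2
            lx = bx - 3
            lw = bw + 6
            if ctrl > 0:
                img[cy - half:cy - half + geom.line_thickness, lx:lx + lw] = (
                    WHITE - LINE_DEPTH_SCALE * ctrl)
            if test_darkness > 0:
                img[ty - half:ty - half + geom.line_thickness, lx:lx + lw] = (
                    WHITE - LINE_DEPTH_SCALE * test_darkness)
        strips.append(StripTruth(
            strip_id=strip_id,
            expected_result=expected_strip_result(ctrl, cls),
            label_box=box, control_line_y=cy, test_line_y=ty,
        ))
    return img, strips


def _pose_homography(pose, geom: CardGeometry) -> np.ndarray:
    tx, ty, rot_deg = pose
    theta = np.deg2rad(rot_deg)
    c, s = np.cos(theta), np.sin(theta)
    w, h = geom.frame_size
    ctr = np.array([w / 2.0, h / 2.0])
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    T1 = np.array([[1, 0, -ctr[0]], [0, 1, -ctr[1]], [0, 0, 1.0]])
    T2 = np.array([[1, 0, ctr[0] + tx], [0, 1, ctr[1] + ty], [0, 0, 1.0]])
    return T2 @ R @ T1


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_template_image(
    panel: tuple[str, ...],
    seed: int = CardGeometry.design_seed,
    geometry: CardGeometry | None = None,
):
    """Render the clean reference card used for registration.

    Returns ``(image, strip_quad)``: an 8-bit RGB frame with fiducial
    texture and label colors but no assay content (no lines, blank pad),
    and the strip-region quadrilateral as a ``(4, 2)`` array of (x, y)
    corners.  Deterministic in ``(panel, seed)``.
    """
    if not panel:
        raise ConfigurationError("panel must name at least one strip")
    geom = geometry or CardGeometry(design_seed=seed)
    if geom.design_seed != seed:
        geom = dataclasses.replace(geom, design_seed=seed)
    if len(panel) > geom.max_strips:
        raise ConfigurationError(
            f"panel of {len(panel)} strips exceeds the {geom.max_strips}-strip card")
    spec = CardSpec(
        panel=tuple(panel),
        control_intensities=(0.0,) * len(panel),
        test_classes=("very_positive",) * len(panel),
        alcohol_level=0.0,
        seed=seed,
    )
    img, _ = _render_card(spec, geom, with_content=False)
    return img.clip(0, 255).astype(np.uint8), geom.roi_quad


def generate_card_image(spec: CardSpec, geometry: CardGeometry | None = None):
    """Render one captured-card frame and its ground truth.

    The noiseless card is drawn axis-aligned, the illumination ramp is added
    along the flow (vertical) axis, the pose homography is applied, and
    sensor noise is added last.  With a zero pose, zero gradient and zero
    noise the output equals the noiseless render exactly.
    """
    spec.validate()
    geom = geometry or CardGeometry()
    if len(spec.panel) > geom.max_strips:
        raise ConfigurationError(
            f"panel of {len(spec.panel)} strips exceeds the {geom.max_strips}-strip card")

    img, strips = _render_card(spec, geom)

    if spec.illumination_gradient != 0.0:
        _, cy0, _, _ = geom.card_rect
        h = geom.frame_size[1]
        ramp = spec.illumination_gradient * (np.arange(h) - cy0)
        img += ramp[:, None, None]

    H = _pose_homography(spec.pose, geom)

    quad_h = np.column_stack([geom.roi_quad, np.ones(4)]) @ H.T
    quad_img = quad_h[:, :2] / quad_h[:, 2:]
    w, h = geom.frame_size
    margin = 5
    if (quad_img[:, 0].min() < margin or quad_img[:, 0].max() > w - margin
            or quad_img[:, 1].min() < margin or quad_img[:, 1].max() > h - margin):
        raise GenerationError("pose pushes the strip region outside the frame")

    if spec.pose != (0.0, 0.0, 0.0):
        tform = ProjectiveTransform(matrix=np.linalg.inv(H))
        img = warp(img, tform, output_shape=img.shape[:2], order=1,
                   cval=BACKGROUND, preserve_range=True)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    truth = GroundTruth(strips=strips, homography=H)
    return img.clip(0, 255).astype(np.uint8), truth


def random_card_spec(
    panel: tuple[str, ...],
    seed: int,
    unambiguous: bool = True,
    invalid_rate: float = 0.0,
) -> CardSpec:
    """Draw a card spec with the pose/illumination variability of a capture.

    With ``unambiguous=True`` test lines come only from the extreme classes
    and the alcohol pad is either blank or clearly colored, mimicking the
    negative / 3x-cutoff conditions of a validation run.
    """
    rng = np.random.default_rng(seed)
    classes = ("very_positive", "very_negative") if unambiguous else TEST_LINE_CLASSES
    ctrl, cls = [], []
    for _ in panel:
        invalid = rng.random() < invalid_rate
        ctrl.append(0.0 if invalid else float(rng.uniform(0.55, 0.95)))
        cls.append(str(rng.choice(classes)))
    if ALCOHOL_STRIP_ID in panel:
        level = 0.0 if rng.random() < 0.5 else float(rng.uniform(0.45, 1.0))
    else:
        level = 0.0
    return CardSpec(
        panel=tuple(panel),
        control_intensities=tuple(ctrl),
        test_classes=tuple(cls),
        alcohol_level=level,
        illumination_gradient=float(rng.uniform(-0.04, 0.04)),
        noise_sd=2.0,
        pose=(float(rng.uniform(-12, 12)), float(rng.uniform(-12, 12)),
              float(rng.uniform(-6, 6))),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# histogram datasets
# ---------------------------------------------------------------------------

_DATASET_LABELS = {
    "alcohol": ("positive", "negative"),
    "control": ("valid", "invalid"),
    "testline": TEST_LINE_CLASSES,
}

_DEFAULT_MIX = {
    # class proportions matching the published evaluation splits
    "alcohol": (74 / 338, 264 / 338),
    "control": (1982 / 2358, 376 / 2358),
    "testline": (0.335, 0.089, 0.146, 0.189, 0.241),
}

_NOISE_SD = 1.5          # residual profile noise after baseline removal
_DIP_SIGMA = 2.2         # line-dip width (bins) in the 100-bin profile
_CONTROL_DEPTH = (40.0, 170.0)   # valid-control dip depth range


def _gaussian_dip(n: int, center: float, depth: float, sigma: float = _DIP_SIGMA):
    i = np.arange(n)
    return -depth * np.exp(-0.5 * ((i - center) / sigma) ** 2)


def _line_profile(rng, control_depth: float, test_depth: float) -> np.ndarray:
    """Baseline-corrected 100-bin profile with control and test dips."""
    prof = rng.normal(0.0, _NOISE_SD, 100)
    prof += _gaussian_dip(100, rng.uniform(22, 28), control_depth)
    prof += _gaussian_dip(100, rng.uniform(65, 69), test_depth)
    return prof


def _align_62(prof: np.ndarray) -> np.ndarray:
    # local import: histogram module depends on nothing from here
    from .histogram import LateralHistogram, align_peaks
    hist = LateralHistogram(values=prof, stage="baseline_corrected")
    return align_peaks(hist).values


def _alcohol_profile(rng, level: float) -> np.ndarray:
    """Raw-style 62-bin alcohol profile before first-15-bin normalization."""
    base = WHITE + rng.uniform(-10, 10)
    i = np.arange(62)
    rise = 1.0 / (1.0 + np.exp(-(i - 19.5) / 1.5))
    fall = 1.0 / (1.0 + np.exp(-(i - 46.5) / 1.5))
    prof = base - PAD_LUMA_DEPTH * level * (rise - fall)
    return prof + rng.normal(0.0, _NOISE_SD, 62)


def generate_histogram_dataset(
    kind: str,
    n: int,
    class_mix: tuple[float, ...] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled preprocessed-stage histograms for classifier training.

    Rows are 62-bin vectors at the stage each classifier consumes: aligned
    residual profiles for ``control``/``testline`` (control signal in bins
    1-31, test signal in bins 32-62), first-15-bin-normalized profiles for
    ``alcohol``.  Columns ``bin_001..bin_062`` plus ``label``.
    """
    if kind not in _DATASET_LABELS:
        raise ConfigurationError(f"unknown dataset kind {kind!r}")
    if n < 10:
        raise ConfigurationError("n must be at least 10")
    labels = _DATASET_LABELS[kind]
    mix = _DEFAULT_MIX[kind] if class_mix is None else tuple(class_mix)
    if len(mix) != len(labels):
        raise ConfigurationError(
            f"class_mix must have {len(labels)} entries for kind {kind!r}")
    if not np.isclose(sum(mix), 1.0):
        raise ConfigurationError("class_mix must sum to 1")

    # largest-remainder apportioning of n over the classes
    raw = np.asarray(mix) * n
    counts = np.floor(raw).astype(int)
    for idx in np.argsort(raw - counts)[::-1][: n - counts.sum()]:
        counts[idx] += 1

    rng = np.random.default_rng(seed)
    rows, row_labels = [], []
    for label, count in zip(labels, counts):
        for _ in range(count):
            if kind == "alcohol":
                if label == "positive":
                    level = rng.uniform(0.35, 1.0)
                else:
                    level = rng.uniform(0.0, 0.03)
                vec = _alcohol_profile(rng, level)
                vec = vec - vec[:15].mean()
            else:
                if kind == "control":
                    ctrl_depth = (rng.uniform(*_CONTROL_DEPTH)
                                  if label == "valid" else 0.0)
                    test_depth = LINE_DEPTH_SCALE * rng.uniform(0.0, 1.0)
                else:  # testline: control line always present
                    ctrl_depth = rng.uniform(*_CONTROL_DEPTH)
                    lo, hi = DARKNESS_INTERVALS[label]
                    test_depth = LINE_DEPTH_SCALE * rng.uniform(lo, hi)
                vec = _align_62(_line_profile(rng, ctrl_depth, test_depth))
            rows.append(vec)
            row_labels.append(label)

    order = rng.permutation(len(rows))
    data = np.asarray(rows)[order]
    frame = pd.DataFrame(
        data, columns=[f"bin_{i + 1:03d}" for i in range(62)])
    frame["label"] = np.asarray(row_labels, dtype=object)[order]
    return frame


def save_card(directory: str | Path, image: np.ndarray, truth: GroundTruth,
              stem: str = "card") -> None:
    """Write ``<stem>.png`` and its ground-truth JSON sidecar."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{stem}.png", image)
    (directory / f"{stem}.truth.json").write_text(truth.to_json())
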