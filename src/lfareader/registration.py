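"""Locate the strip region of a captured card by ORB matching + homography.

The strip region is defined once, by hand, on a clean template image.  At
read time, oriented-FAST keypoints with rotated-BRIEF binary descriptors
are extracted from both images, matched by Hamming distance with a mutual
nearest-neighbor consistency check, and a RANSAC-estimated homography maps
the template's strip quadrilateral into the captured frame.  The captured
image is then warped back into the template frame so all downstream
geometry (segmentation filters, histogram windows) is pose-invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import ORB
from skimage.feature import match_descriptors as _skimage_match
from skimage.measure import ransac as _skimage_ransac
from skimage.transform import ProjectiveTransform, warp

from .config import OrbParams, RegistrationParams
from .errors import RegistrationError, TemplateError


@dataclass
class TemplateModel:
    """Offline half of the matcher: template keypoints plus the strip quad.

    Keypoints are (x, y) template-pixel coordinates; descriptors are 256-bit
    binary strings stored as a boolean ``(n, 256)`` array.
    """

    keypoints: np.ndarray        # (n, 2) float, x/y order
    orientations: np.ndarray     # (n,) radians
    descriptors: np.ndarray      # (n, 256) bool
    strip_quad: np.ndarray       # (4, 2) float, tl/tr/br/bl
    image_size: tuple[int, int]  # (width, height)

    def __post_init__(self):
        if len(self.keypoints) != len(self.descriptors):
            raise TemplateError("keypoints and descriptors must align")
        if len(self.keypoints) < 4:
            raise TemplateError("template needs at least 4 keypoints")

    def to_json(self) -> str:
        packed = np.packbits(self.descriptors.astype(np.uint8), axis=1)
        return json.dumps({
            "keypoints": np.asarray(self.keypoints).tolist(),
            "orientations": np.asarray(self.orientations).tolist(),
            "descriptors": [row.tobytes().hex() for row in packed],
            "strip_quad": np.asarray(self.strip_quad).tolist(),
            "image_size": list(self.image_size),
        })

    @classmethod
    def from_json(cls, text: str) -> "TemplateModel":
        payload = json.loads(text)
        packed = np.array(
            [np.frombuffer(bytes.fromhex(row), dtype=np.uint8)
             for row in payload["descriptors"]])
        descriptors = np.unpackbits(packed, axis=1).astype(bool)
        return cls(
            keypoints=np.asarray(payload["keypoints"], dtype=float),
            orientations=np.asarray(payload["orientations"], dtype=float),
            descriptors=descriptors,
            strip_quad=np.asarray(payload["strip_quad"], dtype=float),
            image_size=tuple(payload["image_size"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TemplateModel":
        return cls.from_json(Path(path).read_text())


@dataclass
class HomographyResult:
    H: np.ndarray                # 3x3, template -> image
    inlier_count: int
    match_count: int
    projected_quad: np.ndarray   # (4, 2) image-frame corners of strip_quad


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        return rgb2gray(img)
    return img.astype(float) / (255.0 if img.dtype == np.uint8 else 1.0)


def detect_orb(image: np.ndarray, orb_params: OrbParams | None = None):
    """Oriented FAST-9 keypoints and 256-bit rBRIEF descriptors.

    Returns ``(keypoints_xy, orientations, descriptors)``; keypoints are in
    (x, y) order regardless of the detector's internal row/col convention.
    """
    p = orb_params or OrbParams()
    detector = ORB(n_keypoints=p.n_keypoints, fast_n=p.fast_n,
                   fast_threshold=p.fast_threshold, n_scales=p.n_scales,
                   downscale=p.downscale)
    gray = _to_gray(image)
    try:
        detector.detect_and_extract(gray)
    except RuntimeError as exc:   # raised on images without any corner
        raise TemplateError(f"no ORB keypoints found: {exc}") from exc
    kp_xy = detector.keypoints[:, ::-1].astype(float)  # row,col -> x,y
    return kp_xy, detector.orientations, detector.descriptors


def build_template(image: np.ndarray, strip_quad: np.ndarray,
                   orb_params: OrbParams | None = None) -> TemplateModel:
    """Extract and persist the template-side keypoints and strip quad."""
    quad = np.asarray(strip_quad, dtype=float)
    if quad.shape != (4, 2):
        raise TemplateError("strip_quad must be 4 corner points")
    img = np.asarray(image)
    h, w = img.shape[:2]
    if quad[:, 0].min() < 0 or quad[:, 0].max() > w \
            or quad[:, 1].min() < 0 or quad[:, 1].max() > h:
        raise TemplateError("strip_quad outside the template image")
    kp, orient, desc = detect_orb(img, orb_params)
    if len(kp) < 4:
        raise TemplateError(f"only {len(kp)} keypoints; template too plain")
    return TemplateModel(keypoints=kp, orientations=orient, descriptors=desc,
                         strip_quad=quad, image_size=(w, h))


def match_descriptors(d_template: np.ndarray, d_image: np.ndarray) -> np.ndarray:
    """Mutual-nearest-neighbor Hamming matching of binary descriptors.

    Each template descriptor is paired with its minimum-Hamming-distance
    image descriptor; only pairs that are each other's nearest neighbor
    survive.  Distance ties are broken toward the lowest index.  Returns an
    ``(m, 2)`` array of (template_idx, image_idx) pairs.
    """
    if len(d_template) == 0 or len(d_image) == 0:
        raise RegistrationError("descriptor sets must be non-empty")
    return _skimage_match(np.asarray(d_template, dtype=bool),
                          np.asarray(d_image, dtype=bool),
                          metric="hamming", cross_check=True)


def estimate_homography(pairs: np.ndarray, kp_template: np.ndarray,
                        kp_image: np.ndarray,
                        params: RegistrationParams | None = None,
                        seed: int = 0,
                        strip_quad: np.ndarray | None = None) -> HomographyResult:
    """RANSAC projective fit over matched keypoint pairs, refit on inliers.

    Raises :class:`RegistrationError` when fewer than 4 pairs are available
    or fewer than ``params.min_inliers`` correspondences support the model.
    """
    params = params or RegistrationParams()
    pairs = np.asarray(pairs)
    if len(pairs) < 4:
        raise RegistrationError(f"{len(pairs)} matches; need at least 4")
    src = np.asarray(kp_template, dtype=float)[pairs[:, 0]]
    dst = np.asarray(kp_image, dtype=float)[pairs[:, 1]]
    model, inliers = _skimage_ransac(
        (src, dst), ProjectiveTransform, min_samples=4,
        residual_threshold=params.ransac_threshold_px,
        max_trials=params.max_iters, rng=seed)
    if model is None or inliers is None or inliers.sum() < params.min_inliers:
        found = 0 if inliers is None else int(inliers.sum())
        raise RegistrationError(
            f"could not locate test: {found} inliers "
            f"(minimum {params.min_inliers})")
    final = ProjectiveTransform.from_estimate(src[inliers], dst[inliers])
    if not final:
        raise RegistrationError("homography refit on inliers failed")
    quad = None if strip_quad is None else final(np.asarray(strip_quad, float))
    return HomographyResult(H=final.params, inlier_count=int(inliers.sum()),
                            match_count=len(pairs), projected_quad=quad)


def locate_strip_region(image: np.ndarray, template: TemplateModel,
                        params: RegistrationParams | None = None,
                        seed: int = 0):
    """Rectify a captured image into the template frame and crop the strips.

    Returns ``(roi_image, HomographyResult)`` where ``roi_image`` is the
    axis-aligned crop of the template's strip quadrilateral, taken from the
    warped capture, as 8-bit data.  Raises :class:`RegistrationError` when
    matching fails.
    """
    params = params or RegistrationParams()
    kp_img, _, desc_img = detect_orb(image, params.orb)
    if len(kp_img) < 4:
        raise RegistrationError("too few keypoints in the captured image")
    pairs = match_descriptors(template.descriptors, desc_img)
    result = estimate_homography(pairs, template.keypoints, kp_img, params,
                                 seed=seed, strip_quad=template.strip_quad)

    # warp the capture into template coordinates: output pixel (template
    # frame) looked up at H(template -> image)
    tform = ProjectiveTransform(matrix=result.H)
    w, h = template.image_size
    img = np.asarray(image, dtype=float)
    rectified = warp(img, tform, output_shape=(h, w), order=1, cval=0.0,
                     preserve_range=True)

    quad = template.strip_quad
    x0, y0 = np.floor(quad.min(axis=0)).astype(int)
    x1, y1 = np.ceil(quad.max(axis=0)).astype(int)
    roi = rectified[y0:y1, x0:x1]
    return roi.clip(0, 255).astype(np.uint8), result
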