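"""Synthetic face images annotated with a 36-point landmark constellation.

Real inputs to average-face construction are anteroposterior facial
photographs, each annotated with an ordered constellation of 36 feature
points. No published annotation scheme exists for the constellation, so this
module fixes its own documented template (see :data:`TEMPLATE_SCHEME`) and
renders schematic faces from it: smooth shaded regions (head, brows, eyes,
nose ridge and nostrils, philtrum, mouth) anchored entirely on the landmark
geometry. Because every rendered feature's position, orientation and width
are functions of the constellation alone, applying a similarity transform to
the landmarks and re-rendering yields exactly the similarity-transformed
face — the property the averaging pipeline is tested against.

Image coordinates: origin top-left, x rightward, y downward, landmarks as
floating-point (x, y). Intensities are floats in [0, 1]; grayscale by
default, RGB by rendering channels identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: index ranges of the fixed 36-point template, in file order
TEMPLATE_SCHEME = {
    "jaw_outline": range(0, 13),  # left temple -> chin -> right temple
    "left_brow": range(13, 16),
    "right_brow": range(16, 19),
    "left_eye": range(19, 23),  # outer, top, inner, bottom
    "right_eye": range(23, 27),  # inner, top, outer, bottom
    "nose": range(27, 31),  # bridge, tip, left nostril, right nostril
    "mouth": range(31, 36),  # left corner, upper mid, right corner, lower mid, philtrum base
}


def default_template(size: int = 256) -> np.ndarray:
    """The canonical 36-point constellation, scaled to an image of ``size`` px."""
    cx, cy, rx, ry = 128.0, 140.0, 78.0, 95.0
    theta = np.deg2rad(180.0 - 15.0 * np.arange(13))
    outline = np.stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)], axis=1)
    pts = np.concatenate(
        [
            outline,
            [[88, 100], [103, 95], [118, 100]],  # left brow
            [[138, 100], [153, 95], [168, 100]],  # right brow
            [[88, 118], [103, 112], [118, 118], [103, 124]],  # left eye
            [[138, 118], [153, 112], [168, 118], [153, 124]],  # right eye
            [[128, 125], [128, 160], [114, 165], [142, 165]],  # nose
            [[103, 190], [128, 184], [153, 190], [128, 197], [128, 172]],  # mouth
        ]
    ).astype(float)
    return pts * (size / 256.0)


def centroid_size(points: np.ndarray) -> float:
    """Root summed squared distance of landmarks from their centroid."""
    c = points.mean(axis=0)
    return float(np.sqrt(((points - c) ** 2).sum()))


def _gauss(X, Y, center, axis, s_major, s_minor, amp):
    """Anisotropic Gaussian blob; ``axis`` is the (possibly unnormalised) major axis."""
    ux, uy = axis
    norm = np.hypot(ux, uy)
    ux, uy = ux / norm, uy / norm
    dx, dy = X - center[0], Y - center[1]
    a = dx * ux + dy * uy
    b = -dx * uy + dy * ux
    return amp * np.exp(-0.5 * ((a / s_major) ** 2 + (b / s_minor) ** 2))


def render_face(
    landmarks: np.ndarray,
    size: int | tuple[int, int] = 256,
    feature_gains: np.ndarray | None = None,
    illumination: float = 1.0,
) -> np.ndarray:
    """Render a schematic face from a 36-point constellation.

    ``feature_gains`` multiplies the amplitude of each shaded component in
    order (per-individual texture variation); ``illumination`` scales the
    whole image. All geometry derives from the landmarks, so rendering is
    exactly covariant with similarity transforms of the constellation.
    """
    lm = np.asarray(landmarks, dtype=float)
    if lm.shape != (36, 2):
        raise ValueError(f"expected a (36, 2) constellation, got {lm.shape}")
    h, w = (size, size) if isinstance(size, int) else size
    X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    u = centroid_size(lm) / 6.0  # scale unit ~ RMS landmark radius

    outline = lm[0:13]
    lbrow, rbrow = lm[13:16], lm[16:19]
    leye, reye = lm[19:23], lm[23:27]
    bridge, tip, lnost, rnost = lm[27], lm[28], lm[29], lm[30]
    mouth = lm[31:35]
    philtrum = lm[35]

    comps = []  # (center, axis, s_major, s_minor, amp)

    # head: broad blob spanning the jaw outline
    head_c = outline.mean(axis=0) - np.array([0.0, 0.22 * u])
    span_x = np.ptp(outline[:, 0]) / 2.0
    span_y = np.ptp(outline[:, 1])
    comps.append((head_c, (1.0, 0.0), 0.72 * span_x, 0.80 * span_y, 0.85))
    # brows: dark strokes along their three points
    for brow in (lbrow, rbrow):
        for p, q in zip(brow[:-1], brow[1:]):
            mid, ax = (p + q) / 2.0, q - p
            comps.append((mid, ax, np.hypot(*(q - p)) / 1.6, 0.035 * u, -0.30))
    # eyes: dark ellipse from the four eye points
    for eye in (leye, reye):
        c = eye.mean(axis=0)
        ax = eye[2] - eye[0]  # inner-outer corner axis
        s_maj = np.hypot(*ax) / 2.2
        s_min = np.hypot(*(eye[1] - eye[3])) / 2.4
        comps.append((c, ax, s_maj, s_min, -0.45))
    # nose ridge highlight along bridge -> tip
    for t in (0.25, 0.5, 0.75, 1.0):
        comps.append((bridge + t * (tip - bridge), tip - bridge, 0.10 * u, 0.045 * u, 0.12))
    # nostrils
    for nost in (lnost, rnost):
        comps.append((nost, rnost - lnost, 0.045 * u, 0.035 * u, -0.28))
    # philtrum ridge between nose base and upper lip
    phil_ax = mouth[1] - philtrum
    comps.append(((philtrum + mouth[1]) / 2.0, phil_ax, 0.10 * u, 0.04 * u, 0.08))
    # mouth: dark band through corners and lip mids
    mc = mouth.mean(axis=0)
    m_ax = mouth[2] - mouth[0]
    comps.append((mc, m_ax, np.hypot(*m_ax) / 2.2, np.hypot(*(mouth[3] - mouth[1])) / 2.0, -0.40))

    if feature_gains is None:
        feature_gains = np.ones(len(comps))
    if len(feature_gains) != len(comps):
        raise ValueError(f"feature_gains must have length {len(comps)}")

    img = np.zeros((h, w), dtype=float)
    for gain, (c, ax, sa, sb, amp) in zip(feature_gains, comps):
        img += _gauss(X, Y, c, ax, sa, sb, amp * gain)
    return np.clip(img * illumination, 0.0, 1.0)


def n_render_components() -> int:
    """Number of shaded components (length expected for feature_gains)."""
    # head + 4 brow strokes + 2 eyes + 4 nose-ridge blobs + 2 nostrils
    # + philtrum + mouth
    return 15


@dataclass
class SimilarityTransform2D:
    """p' = s * R(theta) @ (p - pivot) + pivot + t, y-down convention."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)
    pivot: tuple[float, float] = (0.0, 0.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        piv = np.asarray(self.pivot, dtype=float)
        return (points - piv) @ (self.scale * R).T + piv + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform2D":
        th = np.deg2rad(self.rotation_deg)
        R_inv = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        t = np.asarray(self.translation, dtype=float)
        return SimilarityTransform2D(
            rotation_deg=-self.rotation_deg,
            scale=1.0 / self.scale,
            translation=tuple((R_inv / self.scale) @ (-t)),
            pivot=self.pivot,
        )


@dataclass
class FaceSimConfig:
    """Face-image simulation settings.

    Per-individual landmark noise is isotropic Gaussian in pixels; group
    offsets shift the template per landmark before noise; the similarity
    transform (rotation, scale, translation, drawn uniformly from the stated
    ranges about the image centre) is applied consistently to landmarks and
    rendering. ``on_out_of_bounds`` controls what happens if a transformed
    landmark leaves the image: redraw the transform ("resample") or raise.
    """

    template: np.ndarray | None = None  # default: canonical template at image_size
    image_size: int = 256
    group_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    landmark_noise_sd: float = 2.0
    texture_jitter: float = 0.05
    illumination_jitter: float = 0.05
    rotation_range: tuple[float, float] = (-8.0, 8.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_range: tuple[float, float] = (-8.0, 8.0)
    on_out_of_bounds: str = "resample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template is None:
            self.template = default_template(self.image_size)
        self.template = np.asarray(self.template, dtype=float)
        if self.template.shape != (36, 2):
            raise ValueError("template must have exactly 36 (x, y) points")
        if (self.template < 0).any() or (self.template >= self.image_size).any():
            raise ValueError("template points must lie inside the image bounds")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be >= 0")
        if self.on_out_of_bounds not in ("resample", "error"):
            raise ValueError("on_out_of_bounds must be 'resample' or 'error'")


@dataclass
class FaceSample:
    """One generated face: raster, its landmarks, group label and applied transform."""

    image: np.ndarray
    landmarks: np.ndarray
    group: str
    transform: SimilarityTransform2D
    pre_transform_landmarks: np.ndarray


def generate_faces(
    config: FaceSimConfig, n_per_group: dict[str, int]
) -> list[FaceSample]:
    """Generate labelled faces: template + group offset + noise, then similarity.

    Reproducible under the config seed. The raster is rendered from the
    final (transformed) landmarks, so image and constellation are consistent
    by construction.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    samples: list[FaceSample] = []
    for group, n in n_per_group.items():
        offset = config.group_offsets.get(group)
        offset = np.zeros((36, 2)) if offset is None else np.asarray(offset, float)
        if offset.shape != (36, 2):
            raise ValueError(f"group offset for {group!r} must be (36, 2)")
        for _ in range(n):
            lm0 = (
                config.template
                + offset
                + rng.normal(0.0, config.landmark_noise_sd, size=(36, 2))
            )
            for attempt in range(50):
                tf = SimilarityTransform2D(
                    rotation_deg=float(rng.uniform(*config.rotation_range)),
                    scale=float(rng.uniform(*config.scale_range)),
                    translation=(
                        float(rng.uniform(*config.translation_range)),
                        float(rng.uniform(*config.translation_range)),
                    ),
                    pivot=(size / 2.0, size / 2.0),
                )
                lm = tf.apply(lm0)
                if (lm >= 0).all() and (lm < size).all():
                    break
                if config.on_out_of_bounds == "error":
                    raise ValueError("landmark transformed outside image bounds")
            else:
                raise ValueError(
                    "could not place face inside image bounds after 50 resamples"
                )
            gains = 1.0 + rng.normal(0.0, config.texture_jitter, n_render_components())
            illum = 1.0 + float(rng.normal(0.0, config.illumination_jitter))
            img = render_face(lm, size, feature_gains=gains, illumination=illum)
            samples.append(
                FaceSample(
                    image=img,
                    landmarks=lm,
                    group=group,
                    transform=tf,
                    pre_transform_landmarks=lm0,
                )
            )
    return samples


# ---------------------------------------------------------------------------
# landmark-file and PNG I/O

def write_landmarks(points: np.ndarray, path) -> None:
    """36 lines of "x<TAB>y", template index order."""
    pts = np.asarray(points, dtype=float)
    with open(path, "w", encoding="utf-8") as fh:
        for x, y in pts:
            fh.write(f"{float(x)!r}\t{float(y)!r}\n")


def read_landmarks(path) -> np.ndarray:
    pts = np.loadtxt(path, delimiter="\t", dtype=float)
    if pts.shape != (36, 2):
        raise ValueError(f"{path}: expected 36 'x<TAB>y' lines, got shape {pts.shape}")
    return pts


def write_png(image: np.ndarray, path) -> None:
    """Write a float [0,1] grayscale or RGB raster as 8-bit PNG."""
    from PIL import Image

    arr = (np.clip(image, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_png(path) -> np.ndarray:
    """Read a PNG as float [0,1] (grayscale stays 2-D, RGB keeps channels)."""
    from PIL import Image

    arr = np.asarray(Image.open(path), dtype=float) / 255.0
    return arr
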