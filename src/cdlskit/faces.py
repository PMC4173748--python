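"""Average-face construction from landmark-annotated photographs.

The pipeline mirrors standard appearance-averaging morphometrics: within a
group, all 36-point constellations are registered to each other by
generalized Procrustes analysis (translation, scale and rotation — full
Procrustes, reflections disallowed) and averaged to give a mean shape; a
reference mesh is built on the mean shape by Delaunay triangulation; each
face's appearance is mapped onto that mesh by piecewise affine warping
(per-triangle affine maps defined by the landmark correspondences, bilinear
sampling); and the mapped appearances are averaged pixel-wise.

Pixels outside the landmark convex hull (hair, background) carry no landmark
correspondence and are excluded from averaging; a per-pixel coverage count is
recorded. The mean shape, computed at unit centroid size, is placed on the
output raster by a fixed similarity mapping its bounding box into a central
80% box, preserving aspect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError


@dataclass
class ProcrustesTransform:
    """aligned = scale * source @ rotation.T + translation (rotation proper, det=+1)."""

    scale: float
    rotation: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, float) @ self.rotation.T + self.translation


def _cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z-component of the cross product of stacked 2-D vectors."""
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def _check_constellation(points: np.ndarray, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"{name} must be an (n, 2) point array")
    if not np.isfinite(pts).all():
        raise ValueError(f"{name} contains non-finite coordinates")
    return pts


def procrustes_align(
    source, target, allow_reflection: bool = False
) -> tuple[np.ndarray, ProcrustesTransform, float]:
    """Least-squares similarity superimposition of ``source`` onto ``target``.

    Finds the translation, isotropic scale and proper rotation minimising the
    summed squared distances between corresponding points (reflections are
    never chosen: mirrored faces are not valid superimpositions). Returns the
    aligned points, the transform, and the root-mean-square residual per
    point after alignment.
    """
    src = _check_constellation(source, "source")
    tgt = _check_constellation(target, "target")
    if src.shape != tgt.shape:
        raise ValueError("source and target must have the same number of points")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    Xc, Yc = src - mu_s, tgt - mu_t
    norm_x = np.sqrt((Xc**2).sum())
    if norm_x < 1e-12 or np.linalg.matrix_rank(Xc, tol=1e-9 * max(norm_x, 1.0)) < 2:
        raise ValueError("degenerate source constellation (collinear or coincident)")
    M = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    if allow_reflection:
        d = 1.0
    D = np.diag([1.0, d])
    R = (U @ D @ Vt).T  # maps source -> target orientation
    scale = float((S * np.diag(D)).sum() / (Xc**2).sum())
    translation = mu_t - scale * mu_s @ R.T
    tf = ProcrustesTransform(scale=scale, rotation=R, translation=translation)
    aligned = tf.apply(src)
    distance = float(np.sqrt(((aligned - tgt) ** 2).sum(axis=1).mean()))
    return aligned, tf, distance


def _normalise(points: np.ndarray) -> np.ndarray:
    """Centre at the origin and scale to unit centroid size."""
    c = points - points.mean(axis=0)
    return c / np.sqrt((c**2).sum())


def canonical_rotation(shape: np.ndarray) -> np.ndarray:
    """Proper rotation taking a centred shape to a canonical orientation.

    The principal (largest-variance) axis is mapped to +y; the remaining
    180-degree ambiguity is resolved by the sign of the third moment of the
    y coordinates (then of x, for y-symmetric shapes). This makes the
    generalized Procrustes mean — defined only up to rotation — a
    deterministic function of the input shapes, so the averaging pipeline is
    invariant to a global similarity transform of all its inputs.
    """
    X = shape - shape.mean(axis=0)
    C = X.T @ X
    _, vecs = np.linalg.eigh(C)  # ascending eigenvalues
    v1 = vecs[:, -1]
    R = np.array([[v1[1], -v1[0]], [v1[0], v1[1]]])  # v1 -> (0, 1), det +1
    Y = X @ R.T
    sy = (Y[:, 1] ** 3).sum()
    sx = (Y[:, 0] ** 3).sum()
    flip = sy < 0 or (sy == 0 and sx < 0)
    if flip:
        R = -R  # rotate a further 180 degrees (still proper)
    return R


@dataclass
class GPAResult:
    mean_shape: np.ndarray  # unit centroid size, centred
    aligned: list[np.ndarray]
    n_iterations: int
    converged: bool
    rms_change: float


def generalized_procrustes(
    constellations: Sequence[np.ndarray],
    tol: float = 1e-7,
    max_iterations: int = 100,
    canonicalize: bool = True,
) -> GPAResult:
    """Iterative generalized Procrustes analysis.

    Initialises the mean as the first constellation (centred, unit centroid
    size), then alternates aligning every constellation to the mean and
    recomputing the normalised mean until the mean moves less than ``tol``
    RMS or the iteration cap is reached (cap -> warning, best iterate
    returned). The result is invariant, within tolerance, to similarity
    transforms of any input.
    """
    shapes = [_check_constellation(c, f"constellation {i}") for i, c in enumerate(constellations)]
    if len(shapes) < 2:
        raise ValueError("generalized Procrustes needs at least 2 constellations")
    mean = _normalise(shapes[0])
    aligned = shapes
    rms = np.inf
    converged = False
    n_iter = max_iterations
    for it in range(1, max_iterations + 1):
        aligned = [procrustes_align(s, mean)[0] for s in shapes]
        new_mean = _normalise(np.mean(aligned, axis=0))
        rms = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if rms < tol:
            converged, n_iter = True, it
            break
    if not converged:
        warnings.warn(
            f"generalized Procrustes did not converge in {max_iterations} iterations "
            f"(last RMS change {rms:.3g}); returning best iterate",
            RuntimeWarning,
        )
    if canonicalize:
        R = canonical_rotation(mean)
        mean = mean @ R.T
        aligned = [a @ R.T for a in aligned]
    return GPAResult(mean, aligned, n_iter, converged, rms)


def place_in_frame(shape: np.ndarray, size: int, box_fraction: float = 0.8) -> np.ndarray:
    """Map a centred shape into a raster frame, fitting its bounding box into a
    central ``box_fraction`` box, preserving aspect ratio."""
    shape = np.asarray(shape, dtype=float)
    lo, hi = shape.min(axis=0), shape.max(axis=0)
    span = (hi - lo).max()
    if span <= 0:
        raise ValueError("degenerate shape: zero extent")
    scale = box_fraction * size / span
    centre = (lo + hi) / 2.0
    return (shape - centre) * scale + size / 2.0


@dataclass
class TriangleMesh:
    """Delaunay mesh on a point set: vertices plus triangle index triples."""

    vertices: np.ndarray
    triangles: np.ndarray  # (m, 3) int
    _delaunay: Delaunay = field(repr=False)

    def __post_init__(self) -> None:
        v = self.vertices
        t = self.triangles
        a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
        area2 = np.abs(_cross2(b - a, c - a))
        if (area2 < 1e-12).any():
            raise ValueError("mesh contains a degenerate (zero-area) triangle")
        if set(np.unique(t)) != set(range(len(v))):
            raise ValueError("triangulation does not use every vertex")


def delaunay_mesh(points) -> TriangleMesh:
    """Delaunay triangulation of a constellation (covers its convex hull)."""
    pts = _check_constellation(points, "points")
    if len(pts) < 3:
        raise ValueError("need at least 3 points to triangulate")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(f"cannot triangulate (collinear points?): {exc}") from None
    if tri.simplices.shape[0] == 0:
        raise ValueError("degenerate (collinear) input: no triangles produced")
    return TriangleMesh(vertices=pts, triangles=tri.simplices.copy(), _delaunay=tri)


def _triangle_areas(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a, b, c = points[triangles[:, 0]], points[triangles[:, 1]], points[triangles[:, 2]]
    return 0.5 * np.abs(_cross2(b - a, c - a))


def piecewise_affine_warp(
    image: np.ndarray,
    source: np.ndarray,
    target_mesh: TriangleMesh,
    output_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp ``image`` onto the reference frame of ``target_mesh``.

    ``source`` gives the image-frame positions corresponding one-to-one to
    the mesh vertices. For every output pixel centre inside the mesh hull,
    the containing triangle's affine map (from its three vertex
    correspondences, expressed in barycentric coordinates) gives a source
    location, sampled bilinearly; source samples outside the image take the
    nearest edge value. Returns (warped, covered-mask); pixels outside the
    hull are zero and unmasked.
    """
    img = np.asarray(image, dtype=float)
    src = _check_constellation(source, "source")
    if src.shape[0] != target_mesh.vertices.shape[0]:
        raise ValueError("source points must correspond 1:1 with mesh vertices")
    bad = np.nonzero(_triangle_areas(src, target_mesh.triangles) < 1e-9)[0]
    if bad.size:
        raise ValueError(
            f"degenerate source triangle(s) {bad.tolist()} "
            f"(vertices {target_mesh.triangles[bad].tolist()})"
        )
    if output_shape is None:
        hi = target_mesh.vertices.max(axis=0)
        output_shape = (int(np.ceil(hi[1])) + 1, int(np.ceil(hi[0])) + 1)
    h, w = output_shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pix = np.column_stack([xs.ravel(), ys.ravel()])

    dela = target_mesh._delaunay
    simplex = dela.find_simplex(pix)
    covered = simplex >= 0
    # barycentric coordinates within each containing triangle
    T = dela.transform[simplex[covered]]  # (k, 3, 2)
    r = pix[covered] - T[:, 2, :]
    b12 = np.einsum("kij,kj->ki", T[:, :2, :], r)
    bary = np.column_stack([b12, 1.0 - b12.sum(axis=1)])
    verts = dela.simplices[simplex[covered]]  # (k, 3)
    src_xy = np.einsum("ki,kij->kj", bary, src[verts])

    mask = covered.reshape(h, w)
    coords = [src_xy[:, 1], src_xy[:, 0]]  # row (y), col (x)

    def sample(channel: np.ndarray) -> np.ndarray:
        out = np.zeros(h * w, dtype=float)
        out[covered] = ndimage.map_coordinates(
            channel, coords, order=1, mode="nearest"
        )
        return out.reshape(h, w)

    if img.ndim == 2:
        return sample(img), mask
    warped = np.dstack([sample(img[:, :, c]) for c in range(img.shape[2])])
    return warped, mask


def average_appearance(
    warped: Sequence[np.ndarray], masks: Sequence[np.ndarray] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean over covered contributions; returns (mean, coverage count)."""
    if not warped:
        raise ValueError("no rasters to average")
    stack = np.stack([np.asarray(wimg, dtype=float) for wimg in warped])
    if masks is None:
        coverage = np.full(stack.shape[1:3], stack.shape[0], dtype=int)
        return stack.mean(axis=0), coverage
    mstack = np.stack([np.asarray(m, dtype=bool) for m in masks])
    coverage = mstack.sum(axis=0)
    weights = mstack.astype(float)
    if stack.ndim == 4:  # colour: broadcast the mask over channels
        weights = weights[..., None]
    total = (stack * weights).sum(axis=0)
    denom = np.where(coverage == 0, 1, coverage)
    denom = denom[..., None] if stack.ndim == 4 else denom
    return total / denom, coverage


@dataclass
class AverageFace:
    """Group average: mean constellation (raster frame), mean appearance, coverage."""

    group: str
    mean_constellation: np.ndarray
    appearance: np.ndarray
    coverage: np.ndarray
    n: int
    gpa_iterations: int
    gpa_converged: bool


def build_average_face(
    images: Sequence[np.ndarray],
    constellations: Sequence[np.ndarray],
    group: str = "",
    size: int | None = None,
) -> AverageFace:
    """Full average-face pipeline for one patient group.

    Generalized Procrustes mean shape -> placement on the output raster ->
    Delaunay reference mesh -> piecewise affine warp of every face onto the
    mesh -> pixel-wise averaging over covered pixels.
    """
    if len(images) != len(constellations):
        raise ValueError("images and constellations must pair up 1:1")
    if len(images) < 2:
        raise ValueError("need at least 2 faces to build an average")
    if size is None:
        size = max(images[0].shape[:2])
    gpa = generalized_procrustes(constellations)
    mean_pts = place_in_frame(gpa.mean_shape, size)
    mesh = delaunay_mesh(mean_pts)
    warped, masks = [], []
    for img, lm in zip(images, constellations):
        wimg, mask = piecewise_affine_warp(img, lm, mesh, output_shape=(size, size))
        warped.append(wimg)
        masks.append(mask)
    appearance, coverage = average_appearance(warped, masks)
    return AverageFace(
        group=group,
        mean_constellation=mean_pts,
        appearance=appearance,
        coverage=coverage,
        n=len(images),
        gpa_iterations=gpa.n_iterations,
        gpa_converged=gpa.converged,
    )
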