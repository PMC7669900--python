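"""Acute insertion-trauma quantification from two-channel fluorescence stacks.

The pipeline mirrors the classical wholemount workflow: maximum-intensity
projection of the confocal z-stack, binarisation of the dead-cell (red)
channel, a binary open to remove isolated pixels, watershed splitting of
merged particles on the distance transform, and particle counting inside
a region of interest (ROI) drawn around the insertion site.  From these
it reports, per shank insertion:

* ITA  - insertion trauma area: the ROI polygon area in um^2, covering
  the insertion hole and the dead cells within/around it;
* ITR  - insertion trauma area ratio: ITA divided by the shank
  cross-section, i.e. how many times larger the footprint is than the
  shank itself;
* dead-cell count - segmented particles whose centroid lies strictly
  inside the ROI polygon.

ROIs may be imported (manual provenance) or proposed automatically from
the low-intensity void the insertion leaves in the cell-layer (green)
channel; auto-proposed ROIs never silently replace imported ones.
Pixel coordinates are 0-based, origin top-left, pixel-centre convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

__all__ = [
    "FluorescenceStack",
    "ROIPolygon",
    "Particle",
    "ParticleSet",
    "TraumaResult",
    "NoVoidError",
    "max_projection",
    "segment_dead_cells",
    "compute_trauma",
    "propose_roi",
    "quantify_stack",
]

#: 3x3 cross structuring element, as in the common ImageJ binary defaults.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class NoVoidError(ValueError):
    """Raised when no insertion void is found; draw/import the ROI manually."""


@dataclass
class FluorescenceStack:
    """Two-channel confocal z-stack with physical calibration.

    ``green`` marks the fluorescent cell layer, ``red`` the dead-cell
    stain; both are ``(z, y, x)`` arrays of identical shape.
    """

    green: np.ndarray
    red: np.ndarray
    pixel_size_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.shape != self.red.shape:
            raise ValueError("green and red channels must share a shape")
        if self.green.ndim != 3 or self.green.shape[0] < 1:
            raise ValueError("stacks must be (z, y, x) with >= 1 plane")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be > 0")


@dataclass
class ROIPolygon:
    """Closed polygon in pixel coordinates delimiting one insertion site.

    ``vertices`` is ``(n, 2)`` as ``(x, y)``; provenance records whether
    the outline was imported (``manual-import``) or generated
    (``auto-proposed``).
    """

    vertices: np.ndarray
    provenance: str = "manual-import"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("ROI polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ValueError("ROI polygon must enclose a positive area")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_px(self) -> float:
        return self.shapely.area


@dataclass(frozen=True)
class Particle:
    """One segmented dead-cell particle: centroid ``(x, y)`` px and area."""

    centroid_xy: tuple[float, float]
    area_px: int
    label: int


@dataclass
class ParticleSet:
    """Labelled particle image plus per-particle measurements."""

    labels: np.ndarray
    particles: list[Particle] = field(default_factory=list)
    threshold: float = float("nan")

    def __len__(self) -> int:
        return len(self.particles)


@dataclass
class TraumaResult:
    """Trauma metrics for one shank insertion."""

    ita_um2: float
    itr: float
    dead_count: int
    particle_centroids_xy: np.ndarray
    particle_areas_px: np.ndarray
    threshold: float
    roi_provenance: str


def max_projection(stack: FluorescenceStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel maximum-intensity projection over z of both channels."""
    return stack.green.max(axis=0), stack.red.max(axis=0)


def segment_dead_cells(
    red_projection: np.ndarray,
    threshold: float | None = None,
    min_area_px: int = 4,
    min_peak_distance_px: int = 3,
) -> ParticleSet:
    """Segment dead-cell puncta in a red-channel projection.

    Binarise at ``threshold`` (Otsu when None), apply a binary open with
    a 3x3 cross to remove isolated pixels, split merged particles by
    watershed on the (lightly smoothed) Euclidean distance transform,
    label with 8-connectivity, and discard components smaller than
    ``min_area_px``.  An all-background image yields an empty set.
    """
    img = np.asarray(red_projection, dtype=float)
    if img.ndim != 2:
        raise ValueError("red_projection must be 2-D")
    if threshold is None:
        if np.ptp(img) == 0:
            return ParticleSet(np.zeros(img.shape, dtype=int), [], float("nan"))
        threshold = float(threshold_otsu(img))
    mask = img > threshold
    mask = ndi.binary_opening(mask, structure=_CROSS)
    if not mask.any():
        return ParticleSet(np.zeros(img.shape, dtype=int), [], threshold)
    distance = ndi.distance_transform_edt(mask)
    # slight smoothing breaks plateau ties so round particles keep one peak
    smoothed = ndi.gaussian_filter(distance, sigma=0.7)
    coords = peak_local_max(
        smoothed,
        min_distance=min_peak_distance_px,
        labels=measure.label(mask, connectivity=2),
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = segmentation.watershed(-distance, markers, mask=mask)
    particles: list[Particle] = []
    out = np.zeros_like(labels)
    next_label = 1
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid
        particles.append(Particle((float(cx), float(cy)), int(region.area), next_label))
        out[labels == region.label] = next_label
        next_label += 1
    return ParticleSet(out, particles, threshold)


def compute_trauma(
    roi: ROIPolygon,
    particles: ParticleSet | list[Particle],
    pixel_size_um: float,
    shank_cross_section_um2: float,
) -> TraumaResult:
    """Compute ITA, ITR and the in-ROI dead-cell count.

    ITA is the polygon area scaled by ``pixel_size_um**2``; the count
    includes exactly those particles whose centroid falls strictly inside
    the polygon (centroid-in-polygon rule).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if shank_cross_section_um2 <= 0:
        raise ValueError("shank_cross_section_um2 must be > 0")
    plist = particles.particles if isinstance(particles, ParticleSet) else particles
    threshold = particles.threshold if isinstance(particles, ParticleSet) else float("nan")
    poly = roi.shapely
    ita = poly.area * pixel_size_um**2
    inside = [p for p in plist if poly.contains(Point(*p.centroid_xy))]
    return TraumaResult(
        ita_um2=ita,
        itr=ita / shank_cross_section_um2,
        dead_count=len(inside),
        particle_centroids_xy=np.array(
            [p.centroid_xy for p in plist], dtype=float
        ).reshape(-1, 2),
        particle_areas_px=np.array([p.area_px for p in plist], dtype=int),
        threshold=threshold,
        roi_provenance=roi.provenance,
    )


def _mask_to_polygon(mask: np.ndarray) -> np.ndarray:
    """Convex-hull outline of a boolean mask as (x, y) vertices."""
    hull = morphology.convex_hull_image(mask)
    contours = measure.find_contours(hull.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col) pairs
    return contour[:, ::-1]  # -> (x, y)


def propose_roi(
    green_projection: np.ndarray,
    particles: ParticleSet | None = None,
    void_rel_threshold: float = 0.3,
    min_void_px: int = 50,
    adjacency_px: int = 5,
) -> ROIPolygon:
    """Propose an insertion-site ROI from the green-channel void.

    The insertion hole appears as a low-intensity region in the cell
    layer: pixels darker than ``void_rel_threshold`` times the image
    median form the void candidate, whose largest connected component
    (after closing, if at least ``min_void_px`` pixels) seeds the ROI.
    Segmented red particles whose footprint touches the void dilated by
    ``adjacency_px`` are merged in, so dead cells immediately around the
    hole are enclosed.  The returned polygon is the convex hull outline,
    with ``auto-proposed`` provenance.
    """
    img = np.asarray(green_projection, dtype=float)
    if img.ndim != 2:
        raise ValueError("green_projection must be 2-D")
    void = img < void_rel_threshold * np.median(img)
    void = ndi.binary_closing(void, structure=morphology.disk(2))
    labels = measure.label(void, connectivity=2)
    if labels.max() == 0:
        raise NoVoidError("no low-intensity void found; provide a manual ROI")
    sizes = np.bincount(labels.ravel())[1:]
    if sizes.max() < min_void_px:
        raise NoVoidError("void candidates too small; provide a manual ROI")
    mask = labels == (int(np.argmax(sizes)) + 1)
    if particles is not None and len(particles):
        reach = ndi.binary_dilation(mask, structure=morphology.disk(adjacency_px))
        for p in particles.particles:
            footprint = particles.labels == p.label
            if (footprint & reach).any():
                mask = mask | footprint
    return ROIPolygon(_mask_to_polygon(mask), provenance="auto-proposed")


def quantify_stack(
    stack: FluorescenceStack,
    roi: ROIPolygon | str = "auto",
    shank_cross_section_um2: float = 350.0,
    threshold: float | None = None,
    min_area_px: int = 4,
) -> TraumaResult:
    """Full trauma pipeline on one stack: project, segment, (propose ROI), measure.

    ``roi`` may be an imported :class:`ROIPolygon` or ``"auto"`` to derive
    one from the green-channel void.
    """
    green_proj, red_proj = max_projection(stack)
    particles = segment_dead_cells(red_proj, threshold=threshold, min_area_px=min_area_px)
    if isinstance(roi, str):
        if roi != "auto":
            raise ValueError("roi must be an ROIPolygon or 'auto'")
        roi = propose_roi(green_proj, particles)
    return compute_trauma(roi, particles, stack.pixel_size_um, shank_cross_section_um2)
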