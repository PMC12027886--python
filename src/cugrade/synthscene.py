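"""Synthetic board-and-cucumber scene generation with exact ground truth.

Real grading rigs photograph a cucumber lying on a white board with a
fiducial marker in each corner; the marker spacing (40 cm x 30 cm) lets the
pixel-to-centimeter scale be recovered from the image alone.  This module
renders that scene synthetically: a white board, four solid blue square
markers, and one green curved-tube "cucumber" whose centerline is a circular
arc.  Because the renderer knows the exact geometry, it emits pixel-perfect
ground truth (the rasterized mask, the analytic area, the grade label) that
downstream detection, calibration, segmentation, and measurement stages can
be tested against.

Grades combine a curvature class (A straightest, then B, then C) with a
size class (L largest, then M, then S); B and C have no L size, giving the
seven market grades AL, AM, AS, BM, BS, CM, CS.  The numeric cut-offs vary
by agricultural cooperative and are configurable via :class:`GradeThresholds`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError, RenderError

#: The seven market grades, in canonical order.
GRADES = ("AL", "AM", "AS", "BM", "BS", "CM", "CS")

BOARD_COLOR = (255, 255, 255)
MARKER_COLOR = (0, 0, 255)
CUCUMBER_COLOR = (40, 160, 60)


@dataclass(frozen=True)
class SceneSpec:
    """Physical layout of the board and rendering resolution.

    Marker *centers* sit exactly ``board_width_cm`` apart horizontally and
    ``board_height_cm`` apart vertically, mirroring the 40 cm x 30 cm
    spacing of the physical rig.
    """

    board_width_cm: float = 40.0
    board_height_cm: float = 30.0
    marker_size_cm: float = 2.0
    render_px_per_cm: float = 10.0
    margin_px: int = 10
    background_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.board_width_cm <= 0 or self.board_height_cm <= 0:
            raise ConfigurationError("board dimensions must be positive")
        if self.render_px_per_cm <= 0:
            raise ConfigurationError("render_px_per_cm must be positive")
        if self.marker_size_cm >= min(self.board_width_cm, self.board_height_cm) / 4:
            raise ConfigurationError("marker_size_cm too large for the board")

    @property
    def marker_px(self) -> int:
        return max(1, round(self.marker_size_cm * self.render_px_per_cm))

    @property
    def image_shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered image."""
        h = round(self.board_height_cm * self.render_px_per_cm)
        w = round(self.board_width_cm * self.render_px_per_cm)
        pad = 2 * self.margin_px + self.marker_px
        return (h + pad, w + pad)

    def marker_centers_px(self) -> dict[str, tuple[float, float]]:
        """True marker-center positions as (x, y) pixel-index coordinates."""
        off = self.margin_px + (self.marker_px - 1) / 2.0
        w = round(self.board_width_cm * self.render_px_per_cm)
        h = round(self.board_height_cm * self.render_px_per_cm)
        return {
            "top_left": (off, off),
            "top_right": (off + w, off),
            "bottom_left": (off, off + h),
            "bottom_right": (off + w, off + h),
        }


@dataclass(frozen=True)
class CucumberParams:
    """Geometry of one curved-tube cucumber.

    The centerline is a circular arc of length ``arc_length_cm`` turning
    through ``bend_angle_deg`` in total; ``bend_angle_deg == 0`` degenerates
    to a straight segment.  ``orientation_deg`` rotates the chord away from
    vertical; ``center`` is the chord midpoint in board (cm) coordinates
    with the origin at the top-left marker center, x right, y down.
    """

    arc_length_cm: float
    bend_angle_deg: float
    thickness_cm: float
    color: tuple[int, int, int] = CUCUMBER_COLOR
    center: tuple[float, float] | None = None
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.arc_length_cm <= 0 or self.thickness_cm <= 0:
            raise ConfigurationError("arc length and thickness must be positive")
        if not (0 <= self.bend_angle_deg < 180):
            raise ConfigurationError("bend angle must lie in [0, 180) degrees")
        if self.bend_angle_deg > 0:
            radius = self.arc_length_cm * 180.0 / (np.pi * self.bend_angle_deg)
            if self.thickness_cm / 2 >= radius:
                raise ConfigurationError(
                    "tube thickness exceeds the radius of curvature "
                    "(self-intersecting tube)"
                )

    @property
    def analytic_area_cm2(self) -> float:
        """Exact tube area: arc_length x thickness (square-capped ends)."""
        return self.arc_length_cm * self.thickness_cm


@dataclass(frozen=True)
class GradeThresholds:
    """Cut-offs mapping (bend, length) to the 7 grades.

    Curvature: A for bend <= ``bend_a_max_deg``, B up to ``bend_b_max_deg``,
    C beyond.  Size: L for length >= ``size_l_min_cm``, M down to
    ``size_m_min_cm``, S below.  Bent cucumbers of L length clamp to M
    because the grade set has no BL/CL.
    """

    bend_a_max_deg: float = 20.0
    bend_b_max_deg: float = 60.0
    size_l_min_cm: float = 24.0
    size_m_min_cm: float = 18.0
    # Sampling bounds for the open-ended cells (C-class bend, S-class length).
    bend_max_deg: float = 110.0
    length_min_cm: float = 12.0
    length_max_cm: float = 25.5
    thickness_range_cm: tuple[float, float] = (2.0, 3.5)

    def __post_init__(self) -> None:
        if not self.bend_a_max_deg < self.bend_b_max_deg:
            raise ConfigurationError("bend thresholds must increase A -> B")
        if not self.size_m_min_cm < self.size_l_min_cm:
            raise ConfigurationError("size thresholds must increase M -> L")
        if not self.bend_b_max_deg < self.bend_max_deg:
            raise ConfigurationError("bend_max_deg must exceed bend_b_max_deg")
        if not self.length_min_cm < self.size_m_min_cm:
            raise ConfigurationError("length_min_cm must lie below size_m_min_cm")
        if not self.size_l_min_cm < self.length_max_cm:
            raise ConfigurationError("length_max_cm must exceed size_l_min_cm")


@dataclass
class SceneTruth:
    """Ground truth paired with a rendered scene."""

    mask: np.ndarray
    params: CucumberParams
    analytic_area_cm2: float
    grade: str
    marker_centers_px: dict[str, tuple[float, float]] = field(default_factory=dict)


def assign_grade(params: CucumberParams, thresholds: GradeThresholds) -> str:
    """Map cucumber geometry to one of the 7 grades.

    Curvature class comes from the bend angle, size class from the arc
    length; an L-length cucumber in curvature class B or C is assigned M
    (the grade set has no BL/CL).
    """
    if params.bend_angle_deg <= thresholds.bend_a_max_deg:
        curv = "A"
    elif params.bend_angle_deg <= thresholds.bend_b_max_deg:
        curv = "B"
    else:
        curv = "C"
    if params.arc_length_cm >= thresholds.size_l_min_cm:
        size = "L"
    elif params.arc_length_cm >= thresholds.size_m_min_cm:
        size = "M"
    else:
        size = "S"
    if size == "L" and curv != "A":
        size = "M"
    return curv + size


def _grade_cell(
    grade: str, t: GradeThresholds
) -> tuple[tuple[float, float], tuple[float, float]]:
    """(bend_lo, bend_hi), (len_lo, len_hi) sampling cell for a grade."""
    curv, size = grade[0], grade[1]
    bend_cells = {
        "A": (0.0, t.bend_a_max_deg),
        "B": (t.bend_a_max_deg, t.bend_b_max_deg),
        "C": (t.bend_b_max_deg, t.bend_max_deg),
    }
    len_cells = {
        "L": (t.size_l_min_cm, t.length_max_cm),
        "M": (t.size_m_min_cm, t.size_l_min_cm),
        "S": (t.length_min_cm, t.size_m_min_cm),
    }
    return bend_cells[curv], len_cells[size]


def sample_params(
    grade: str,
    thresholds: GradeThresholds | None = None,
    rng: np.random.Generator | int | None = None,
    jitter: bool = True,
) -> CucumberParams:
    """Draw cucumber geometry uniformly from a grade's (bend, length) cell.

    Thickness is uniform over ``thresholds.thickness_range_cm``; a small
    placement jitter (position and orientation) is applied unless
    ``jitter=False``.  Deterministic given the rng seed, and
    ``assign_grade(sample_params(g)) == g`` for every grade.
    """
    thresholds = thresholds or GradeThresholds()
    if grade not in GRADES:
        raise ConfigurationError(f"unknown grade {grade!r}; expected one of {GRADES}")
    rng = np.random.default_rng(rng)
    (b_lo, b_hi), (l_lo, l_hi) = _grade_cell(grade, thresholds)
    if not (b_lo < b_hi and l_lo < l_hi):
        raise ConfigurationError(f"empty parameter cell for grade {grade}")
    # sample strictly inside half-open cells: bend in [lo, hi) except A which
    # is closed at its upper threshold; lengths in [lo, hi)
    bend = float(rng.uniform(b_lo, b_hi))
    if grade[0] != "A" and bend == b_lo:
        bend = np.nextafter(b_lo, b_hi)
    length = float(rng.uniform(l_lo, l_hi))
    t_lo, t_hi = thresholds.thickness_range_cm
    thickness = float(rng.uniform(t_lo, t_hi))
    if jitter:
        cx = 20.0 + float(rng.uniform(-1.0, 1.0))
        cy = 15.0 + float(rng.uniform(-0.6, 0.6))
        orient = float(rng.uniform(-8.0, 8.0))
    else:
        cx, cy, orient = 20.0, 15.0, 0.0
    params = CucumberParams(
        arc_length_cm=length,
        bend_angle_deg=bend,
        thickness_cm=thickness,
        center=(cx, cy),
        orientation_deg=orient,
    )
    assert assign_grade(params, thresholds) == grade
    return params


def _tube_mask(
    spec: SceneSpec, params: CucumberParams, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize the circular-arc tube: pixels whose centers lie within
    thickness/2 of the arc centerline (square caps: no end dilation)."""
    ppc = spec.render_px_per_cm
    centers = spec.marker_centers_px()
    ox, oy = centers["top_left"]
    rows = np.arange(shape[0])
    cols = np.arange(shape[1])
    # pixel index -> board cm coordinates
    xs = (cols - ox) / ppc
    ys = (rows - oy) / ppc
    X, Y = np.meshgrid(xs, ys)

    cx, cy = params.center if params.center is not None else (
        spec.board_width_cm / 2,
        spec.board_height_cm / 2,
    )
    # rotate board coords into the cucumber frame (chord along +y)
    th = np.deg2rad(params.orientation_deg)
    dx, dy = X - cx, Y - cy
    lx = np.cos(th) * dx + np.sin(th) * dy
    ly = -np.sin(th) * dx + np.cos(th) * dy

    L = params.arc_length_cm
    half_t = params.thickness_cm / 2
    phi = np.deg2rad(params.bend_angle_deg)
    # half-open membership ([-t/2, t/2) across the tube, [-L/2, L/2) along
    # it) so a boundary lying exactly on a pixel-center line is counted
    # once, not twice — keeps rasterized extents unbiased across resolutions
    if phi < 1e-9:
        return (
            (lx >= -half_t) & (lx < half_t) & (ly >= -L / 2) & (ly < L / 2)
        )
    r = L / phi
    # chord vertical through the local origin; arc center on +x side so the
    # tube bulges toward -x
    d = r * np.cos(phi / 2)
    vx, vy = lx - d, ly
    rho = np.hypot(vx, vy)
    ang = np.arctan2(vy, vx)  # arc midpoint sits at angle pi from the center
    dang = np.abs((ang - np.pi + np.pi) % (2 * np.pi) - np.pi)
    return (rho - r >= -half_t) & (rho - r < half_t) & (dang <= phi / 2)


def render_scene(
    spec: SceneSpec,
    params: CucumberParams,
    rng: np.random.Generator | int | None = None,
    thresholds: GradeThresholds | None = None,
) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene and its ground truth.

    Returns an (H, W, 3) uint8 RGB image — white board, four blue square
    markers whose centers span board_width_cm x board_height_cm, one green
    tube — and a :class:`SceneTruth` whose mask marks exactly the rasterized
    tube pixels.  Gaussian pixel noise of sd ``spec.background_noise_sd`` is
    added when nonzero.

    Raises :class:`RenderError` if the tube leaves the marker quadrilateral
    interior or touches a marker.
    """
    thresholds = thresholds or GradeThresholds()
    shape = spec.image_shape
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[...] = BOARD_COLOR

    m = spec.marker_px
    centers = spec.marker_centers_px()
    marker_boxes = []
    for x, y in centers.values():
        c0 = int(round(x - (m - 1) / 2.0))
        r0 = int(round(y - (m - 1) / 2.0))
        img[r0 : r0 + m, c0 : c0 + m] = MARKER_COLOR
        marker_boxes.append((r0, c0))

    mask = _tube_mask(spec, params, shape)
    if not mask.any():
        raise RenderError("cucumber rasterized to zero pixels")

    # the tube must stay strictly inside the marker quadrilateral interior
    # and clear of the marker squares themselves
    ox, oy = centers["top_left"]
    bx, by = centers["bottom_right"]
    rows_any = np.flatnonzero(mask.any(axis=1))
    cols_any = np.flatnonzero(mask.any(axis=0))
    half = (m - 1) / 2.0
    if (
        cols_any[0] <= ox + half
        or cols_any[-1] >= bx - half
        or rows_any[0] <= oy + half
        or rows_any[-1] >= by - half
    ):
        raise RenderError("cucumber overlaps a marker or leaves the board interior")

    img[mask] = params.color

    if spec.background_noise_sd > 0:
        rng = np.random.default_rng(rng)
        noise = rng.normal(0.0, spec.background_noise_sd, img.shape)
        img = np.clip(img.astype(np.float64) + noise, 0, 255).astype(np.uint8)

    truth = SceneTruth(
        mask=mask,
        params=params,
        analytic_area_cm2=params.analytic_area_cm2,
        grade=assign_grade(params, thresholds),
        marker_centers_px=centers,
    )
    return img, truth


def generate_dataset(
    n_per_grade: int | dict[str, int],
    out_dir: str | Path,
    spec: SceneSpec | None = None,
    thresholds: GradeThresholds | None = None,
    seed: int = 0,
) -> Path:
    """Write a graded scene dataset to disk.

    Files are named ``<GRADE>_<sequence>.png`` (the grade prefixed so labels
    survive in the file name) alongside a ``manifest.csv`` with the true
    geometry.  ``n_per_grade`` may be a single count or a per-grade mapping.
    Returns the manifest path.
    """
    spec = spec or SceneSpec()
    thresholds = thresholds or GradeThresholds()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = (
        {g: int(n_per_grade) for g in GRADES}
        if isinstance(n_per_grade, int)
        else dict(n_per_grade)
    )
    if any(c < 1 for c in counts.values()):
        raise ConfigurationError("n_per_grade must be >= 1")
    rng = np.random.default_rng(seed)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "grade", "length_cm", "bend_deg", "thickness_cm"])
        for grade in GRADES:
            for i in range(counts.get(grade, 0)):
                params = sample_params(grade, thresholds, rng)
                img, _ = render_scene(spec, params, rng, thresholds)
                fname = f"{grade}_{i + 1:04d}.png"
                Image.fromarray(img).save(out_dir / fname)
                writer.writerow(
                    [
                        fname,
                        grade,
                        f"{params.arc_length_cm:.4f}",
                        f"{params.bend_angle_deg:.4f}",
                        f"{params.thickness_cm:.4f}",
                    ]
                )
    return manifest_path


def scene_for_grade(
    grade: str,
    spec: SceneSpec | None = None,
    thresholds: GradeThresholds | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, SceneTruth]:
    """Convenience: sample params for a grade and render the scene."""
    spec = spec or SceneSpec()
    thresholds = thresholds or GradeThresholds()
    rng = np.random.default_rng(rng)
    params = sample_params(grade, thresholds, rng)
    return render_scene(spec, params, rng, thresholds)
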