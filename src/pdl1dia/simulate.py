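"""Synthetic TMA-core generator.

Builds ground-truth tissue-microarray cores — CK+ tumour nests surrounded by
stroma, populated with nucleated cells of four lineages (tumour, macrophage,
T-cell, other stromal) — and renders them as 5-channel fluorescence stacks
(DAPI / CK / CD68 / CD8 / PD-L1) and as paired pseudo-H-DAB brightfield
images.  Immune cells are placed both inside and outside the tumour nests so
that PD-L1+ macrophages and T-cells sit among CK+ tumour cells, the
confounder that makes phenotyping order matter downstream.

PD-L1 positivity among tumour cells is assigned by exact quota by default,
so the true tumour proportion score is sharply recoverable; a Bernoulli mode
is available behind a flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

CHANNELS = ("DAPI", "CK", "CD68", "CD8", "PDL1")

#: lineage labels used throughout
LINEAGES = ("tumour", "macrophage", "tcell", "other")

#: which fluorescence channel marks which lineage
LINEAGE_CHANNEL = {"tumour": "CK", "macrophage": "CD68", "tcell": "CD8"}

# Standard haematoxylin / DAB optical-density vectors (unit norm).
_H = np.array([0.65, 0.70, 0.29])
_D = np.array([0.27, 0.57, 0.78])
DEFAULT_STAIN_MATRIX = np.vstack([_H / np.linalg.norm(_H), _D / np.linalg.norm(_D)])


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap after bounded retries."""


def _zero_crosstalk() -> np.ndarray:
    return np.zeros((len(CHANNELS), len(CHANNELS)))


@dataclass(frozen=True)
class SimParams:
    """Parameters of one synthetic TMA core.

    Geometry is in pixels; ``pixel_size_um`` converts to physical units.
    Defaults emulate a 0.45 mm core scanned at 0.5 µm/px with a moderate
    immune infiltrate and mid-range true tumour proportion score.
    """

    seed: int = 0
    core_diameter_px: int = 900
    pixel_size_um: float = 0.5
    n_cells: int = 400
    tumour_fraction: float = 0.5
    n_nests: int = 3
    tps_true: float = 30.0
    macrophage_fraction: float = 0.1
    tcell_fraction: float = 0.1
    intratumoural_immune_fraction: float = 0.4
    pdl1_pos_prob_macrophage: float = 0.5
    pdl1_pos_prob_tcell: float = 0.2
    background_level: float = 0.05
    noise_sd: float = 0.05
    crosstalk: np.ndarray = field(default_factory=_zero_crosstalk)
    section_jitter_px: float = 2.0
    section_dropout_prob: float = 0.05
    nucleus_radius_px: float = 6.0
    dab_od_level: float = 0.3
    pdl1_bernoulli: bool = False

    def __post_init__(self):
        probs = {
            "tumour_fraction": self.tumour_fraction,
            "macrophage_fraction": self.macrophage_fraction,
            "tcell_fraction": self.tcell_fraction,
            "intratumoural_immune_fraction": self.intratumoural_immune_fraction,
            "pdl1_pos_prob_macrophage": self.pdl1_pos_prob_macrophage,
            "pdl1_pos_prob_tcell": self.pdl1_pos_prob_tcell,
            "section_dropout_prob": self.section_dropout_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.tumour_fraction + self.macrophage_fraction + self.tcell_fraction > 1 + 1e-9:
            raise ValueError("tumour_fraction + macrophage_fraction + tcell_fraction must be <= 1")
        if not 0.0 <= self.tps_true <= 100.0:
            raise ValueError(f"tps_true must be in [0, 100], got {self.tps_true}")
        for name in ("background_level", "noise_sd", "section_jitter_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        xt = np.asarray(self.crosstalk, dtype=float)
        if xt.shape != (len(CHANNELS), len(CHANNELS)) or (xt < 0).any():
            raise ValueError(f"crosstalk must be a non-negative {len(CHANNELS)}x{len(CHANNELS)} matrix")
        object.__setattr__(self, "crosstalk", xt)

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)

    def __eq__(self, other):
        if not isinstance(other, SimParams):
            return NotImplemented
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if f.name == "crosstalk":
                if not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True


@dataclass
class TrueCell:
    """Ground truth for one cell: position, lineage and PD-L1 status."""

    id: int
    x: float
    y: float
    nucleus_radius_px: float
    lineage: str
    pdl1_positive: bool
    intratumoural: bool


@dataclass
class CoreTruth:
    """Ground-truth description of one synthetic core."""

    cells: list[TrueCell]
    nests: list[np.ndarray]  # each (n_vertices, 2) array of (x, y), closed implicitly
    params: SimParams

    def nest_polygons(self) -> list[Polygon]:
        return [Polygon(v) for v in self.nests]

    @property
    def n_tumour(self) -> int:
        return sum(c.lineage == "tumour" for c in self.cells)

    def true_tps(self) -> float:
        """True tumour proportion score implied by the labels (percent)."""
        n_t = self.n_tumour
        if n_t == 0:
            raise ValueError("no tumour cells; true TPS undefined")
        pos = sum(c.lineage == "tumour" and c.pdl1_positive for c in self.cells)
        return 100.0 * pos / n_t

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "id": c.id,
                    "x": c.x,
                    "y": c.y,
                    "radius": c.nucleus_radius_px,
                    "lineage": c.lineage,
                    "pdl1": int(c.pdl1_positive),
                    "intratumoural": int(c.intratumoural),
                }
                for c in self.cells
            ],
            columns=["id", "x", "y", "radius", "lineage", "pdl1", "intratumoural"],
        )


@dataclass
class ChannelStack:
    """Named 2-D fluorescence channels over a common pixel grid."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self):
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def as_array(self, order=CHANNELS) -> np.ndarray:
        return np.stack([self.channels[name] for name in order])


@dataclass
class HDABImage:
    """RGB brightfield image of a haematoxylin + DAB stained section."""

    rgb: np.ndarray  # (H, W, 3) uint8
    stain_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_MATRIX.copy())

    def __post_init__(self):
        sm = np.asarray(self.stain_matrix, dtype=float)
        norms = np.linalg.norm(sm, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain_matrix rows must have unit Euclidean norm")
        self.stain_matrix = sm


# ---------------------------------------------------------------------------
# geometry helpers


def _nest_outline(rng, cx, cy, base_radius, n_vertices=64):
    """Smooth random blob: an ellipse-like radius profile with low-order perturbations."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, 1.0)
    for k in (2, 3, 4):
        r += rng.uniform(0.04, 0.13) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r *= base_radius
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _sample_in_geom(rng, geom, n_tries=200):
    """Uniform rejection sample of a point inside a shapely geometry."""
    minx, miny, maxx, maxy = geom.bounds
    for _ in range(n_tries):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if shapely.contains_xy(geom, x, y):
            return x, y
    return None


class _DartBoard:
    """Rejection placement with a minimum centre-to-centre separation."""

    def __init__(self, min_sep):
        self.min_sep = min_sep
        self.xs: list[float] = []
        self.ys: list[float] = []

    def ok(self, x, y) -> bool:
        if not self.xs:
            return True
        dx = np.asarray(self.xs) - x
        dy = np.asarray(self.ys) - y
        return float(np.min(dx * dx + dy * dy)) >= self.min_sep**2

    def add(self, x, y):
        self.xs.append(x)
        self.ys.append(y)


# per-cell area budget for dart-throwing feasibility checks (px² per unit sep²)
_PACKING_FACTOR = 2.2


def generate_core(params: SimParams) -> CoreTruth:
    """Generate the ground truth for one synthetic TMA core.

    Nest polygons are sized so the requested number of tumour cells fits at
    the minimum centre separation; tumour cells are placed inside nests with
    a small interior margin, immune cells inside or outside nests according
    to ``intratumoural_immune_fraction``, and remaining stromal cells outside
    nests.  PD-L1 positivity among tumour cells follows an exact quota of
    ``round(tps_true/100 × n_tumour)`` unless ``pdl1_bernoulli`` is set.

    Raises
    ------
    PlacementError
        If cells cannot be placed at the minimum separation after bounded
        retries; the message names the parameter to relax.
    """
    rng = np.random.default_rng([params.seed, 0])
    r_nuc = params.nucleus_radius_px
    min_sep = 3.0 * r_nuc  # 1.5 nucleus diameters between centres
    core_r = params.core_diameter_px / 2.0
    cx0 = cy0 = core_r
    core_area = np.pi * core_r**2

    # lineage counts (fractions applied with rounding; remainder is "other")
    n_tum = int(round(params.n_cells * params.tumour_fraction))
    n_mac = int(round(params.n_cells * params.macrophage_fraction))
    n_tc = int(round(params.n_cells * params.tcell_fraction))
    if n_tum + n_mac + n_tc > params.n_cells:  # rounding overflow
        n_tum = params.n_cells - n_mac - n_tc
    n_other = params.n_cells - n_tum - n_mac - n_tc

    n_mac_in = int(round(params.intratumoural_immune_fraction * n_mac))
    n_tc_in = int(round(params.intratumoural_immune_fraction * n_tc))
    n_intratumoural = n_tum + n_mac_in + n_tc_in
    n_stromal = params.n_cells - n_intratumoural

    # nests sized to hold the intratumoural population at the min separation
    need_nest = max(n_intratumoural, 1) * _PACKING_FACTOR * min_sep**2
    nest_area = max(0.18 * core_area, need_nest)
    if nest_area > 0.55 * core_area:
        raise PlacementError(
            "tumour nests would need more than 55% of the core area; "
            "reduce n_cells or increase core_diameter_px"
        )
    stroma_area = core_area - nest_area
    if n_stromal * _PACKING_FACTOR * min_sep**2 > 0.9 * stroma_area:
        raise PlacementError(
            "stromal cells do not fit outside the nests; "
            "reduce n_cells or increase core_diameter_px"
        )

    n_nests = max(params.n_nests, 1)
    base_r = np.sqrt(nest_area / (np.pi * n_nests))

    # place nest centres inside the core, spread apart where possible
    nests: list[np.ndarray] = []
    max_c = core_r - 1.25 * base_r
    if max_c <= 0:
        raise PlacementError("nests do not fit in the core; increase core_diameter_px")
    centres: list[tuple[float, float]] = []
    for _ in range(n_nests):
        best = None
        for _ in range(300):
            ang = rng.uniform(0, 2 * np.pi)
            rad = max_c * np.sqrt(rng.uniform())
            x, y = cx0 + rad * np.cos(ang), cy0 + rad * np.sin(ang)
            d = min((np.hypot(x - a, y - b) for a, b in centres), default=np.inf)
            if best is None or d > best[0]:
                best = (d, x, y)
            if d >= 2.2 * base_r:
                break
        centres.append((best[1], best[2]))
        nests.append(_nest_outline(rng, best[1], best[2], base_r))

    polys = [Polygon(v) for v in nests]
    nest_union = shapely.unary_union(polys)
    core_disc = shapely.Point(cx0, cy0).buffer(core_r - 2 * r_nuc, quad_segs=64)
    # tumour centroids keep a margin inside nests so that segmentation jitter
    # cannot push a detected tumour centroid outside the polygon
    tumour_region = shapely.intersection(nest_union.buffer(-0.5 * r_nuc), core_disc)
    immune_in_region = shapely.intersection(nest_union.buffer(-0.2 * r_nuc), core_disc)
    stroma_region = shapely.difference(core_disc, nest_union.buffer(0.2 * r_nuc))
    shapely.prepare(tumour_region)
    shapely.prepare(immune_in_region)
    shapely.prepare(stroma_region)

    board = _DartBoard(min_sep)

    def place(n, region, what):
        pts = []
        for _ in range(n):
            for attempt in range(400):
                p = _sample_in_geom(rng, region)
                if p is not None and board.ok(*p):
                    board.add(*p)
                    pts.append(p)
                    break
            else:
                raise PlacementError(
                    f"could not place {what} cell {len(pts) + 1}/{n} after bounded "
                    "retries; reduce n_cells or increase core_diameter_px"
                )
        return pts

    specs = [
        ("tumour", True, place(n_tum, tumour_region, "tumour")),
        ("macrophage", True, place(n_mac_in, immune_in_region, "intratumoural macrophage")),
        ("tcell", True, place(n_tc_in, immune_in_region, "intratumoural T")),
        ("macrophage", False, place(n_mac - n_mac_in, stroma_region, "stromal macrophage")),
        ("tcell", False, place(n_tc - n_tc_in, stroma_region, "stromal T")),
        ("other", False, place(n_other, stroma_region, "stromal")),
    ]

    cells: list[TrueCell] = []
    cid = 0
    for lineage, intratum, pts in specs:
        for x, y in pts:
            cells.append(TrueCell(cid, x, y, r_nuc, lineage, False, intratum))
            cid += 1

    # PD-L1 assignment
    tum_idx = [i for i, c in enumerate(cells) if c.lineage == "tumour"]
    if tum_idx:
        if params.pdl1_bernoulli:
            draws = rng.uniform(size=len(tum_idx)) < params.tps_true / 100.0
            for i, hit in zip(tum_idx, draws):
                cells[i].pdl1_positive = bool(hit)
        else:
            k = int(round(params.tps_true / 100.0 * len(tum_idx)))
            for i in rng.choice(tum_idx, size=k, replace=False):
                cells[i].pdl1_positive = True
    for c in cells:
        if c.lineage == "macrophage":
            c.pdl1_positive = bool(rng.uniform() < params.pdl1_pos_prob_macrophage)
        elif c.lineage == "tcell":
            c.pdl1_positive = bool(rng.uniform() < params.pdl1_pos_prob_tcell)

    return CoreTruth(cells=cells, nests=nests, params=params)


# ---------------------------------------------------------------------------
# rendering


def _window(shape, cx, cy, extent):
    x0 = max(int(np.floor(cx - extent)), 0)
    x1 = min(int(np.ceil(cx + extent)) + 1, shape[1])
    y0 = max(int(np.floor(cy - extent)), 0)
    y1 = min(int(np.ceil(cy + extent)) + 1, shape[0])
    return x0, x1, y0, y1


def _add_gaussian(img, cx, cy, sigma, amp):
    x0, x1, y0, y1 = _window(img.shape, cx, cy, 4 * sigma)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


def _add_disc(img, cx, cy, radius, amp):
    x0, x1, y0, y1 = _window(img.shape, cx, cy, radius + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    # soft 1 px edge so discs do not alias harshly
    prof = np.clip(radius + 0.5 - np.sqrt(d2), 0.0, 1.0)
    img[y0:y1, x0:x1] += amp * prof


def _add_annulus(img, cx, cy, r_in, r_out, amp, arc_start, arc_frac):
    """Membrane ring with partial angular coverage (``arc_frac`` of the circle)."""
    x0, x1, y0, y1 = _window(img.shape, cx, cy, r_out + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    d = np.sqrt(dx**2 + dy**2)
    radial = np.clip(r_out + 0.5 - d, 0, 1) * np.clip(d - (r_in - 0.5), 0, 1)
    ang = np.mod(np.arctan2(dy, dx) - arc_start, 2 * np.pi)
    mask = ang <= arc_frac * 2 * np.pi
    img[y0:y1, x0:x1] += amp * radial * mask


def render_channels(truth: CoreTruth) -> ChannelStack:
    """Render a ground-truth core as a 5-channel fluorescence stack.

    Every nucleated cell appears in DAPI; CK / CD68 / CD8 are rendered as
    cytoplasmic discs on their lineages; PD-L1 as a membrane annulus with
    randomised partial arc coverage (≥ 25%) on PD-L1+ cells of any lineage.
    Background, Gaussian noise and channel crosstalk are then applied, and
    intensities clipped at zero.
    """
    p = truth.params
    h = w = p.core_diameter_px
    clean = np.zeros((len(CHANNELS), h, w), dtype=np.float32)
    imgs = {name: clean[i] for i, name in enumerate(CHANNELS)}
    rng = np.random.default_rng([p.seed, 1])

    for c in truth.cells:
        r = c.nucleus_radius_px
        _add_gaussian(imgs["DAPI"], c.x, c.y, 0.55 * r, rng.uniform(0.85, 1.0))
        ch = LINEAGE_CHANNEL.get(c.lineage)
        if ch is not None:
            _add_disc(imgs[ch], c.x, c.y, 2.0 * r, rng.uniform(0.7, 0.9))
        if c.pdl1_positive:
            _add_annulus(
                imgs["PDL1"], c.x, c.y, 1.15 * r, 1.9 * r,
                rng.uniform(0.9, 1.1),
                arc_start=rng.uniform(0, 2 * np.pi),
                arc_frac=rng.uniform(0.25, 1.0),
            )

    clean += np.float32(p.background_level)
    if p.noise_sd > 0:
        noise = rng.standard_normal(size=clean.shape, dtype=np.float32)
        noise *= np.float32(p.noise_sd)
        clean += noise
    if p.crosstalk.any():
        mixed = clean + np.einsum("ij,jhw->ihw", p.crosstalk.astype(np.float32), clean)
    else:
        mixed = clean
    np.maximum(mixed, 0.0, out=mixed)
    return ChannelStack({name: mixed[i] for i, name in enumerate(CHANNELS)}, p.pixel_size_um)


def emulate_serial_section(truth: CoreTruth) -> CoreTruth:
    """Emulate an adjacent tissue section of the same core.

    Serial sections sample nearly, but not exactly, the same cells: each
    cell's centroid is displaced by isotropic Gaussian jitter of sd
    ``section_jitter_px`` and cells are independently lost with probability
    ``section_dropout_prob``.  Lineage and PD-L1 labels are preserved on
    survivors; nest polygons carry over unchanged.
    """
    p = truth.params
    rng = np.random.default_rng([p.seed, 2])
    hi = p.core_diameter_px - 1.0
    cells = []
    for c in truth.cells:
        drop = rng.uniform() < p.section_dropout_prob
        dx, dy = rng.normal(0.0, p.section_jitter_px or 0.0, size=2) if p.section_jitter_px else (0.0, 0.0)
        if drop:
            continue
        cells.append(
            TrueCell(
                c.id,
                float(np.clip(c.x + dx, 0.0, hi)),
                float(np.clip(c.y + dy, 0.0, hi)),
                c.nucleus_radius_px,
                c.lineage,
                c.pdl1_positive,
                c.intratumoural,
            )
        )
    return CoreTruth(cells=cells, nests=[v.copy() for v in truth.nests], params=p)


def _marker_positive(cell: TrueCell, marker: str) -> bool:
    if marker == "PDL1":
        return cell.pdl1_positive
    for lineage, ch in LINEAGE_CHANNEL.items():
        if ch == marker:
            return cell.lineage == lineage
    raise ValueError(f"unknown marker {marker!r}; expected one of CK, CD68, CD8, PDL1")


def render_hdab(
    truth: CoreTruth,
    marker: str,
    stain_matrix: np.ndarray | None = None,
) -> HDABImage:
    """Render a single-marker chromogenic (H-DAB) image of a core.

    Haematoxylin optical density is deposited at every nucleus; DAB optical
    density, at level ``params.dab_od_level``, as a cytoplasmic disc on
    marker-positive cells (the DAB reaction product is diffuse, so membrane
    markers also fill the cytoplasmic footprint here).  RGB is obtained by
    the Beer–Lambert transform through the stain matrix and quantised to
    8 bits.
    """
    _check_marker(marker)
    p = truth.params
    h = w = p.core_diameter_px
    od_h = np.zeros((h, w))
    od_d = np.zeros((h, w))
    rng = np.random.default_rng([p.seed, 3])
    for c in truth.cells:
        r = c.nucleus_radius_px
        _add_gaussian(od_h, c.x, c.y, 0.55 * r, rng.uniform(0.55, 0.7))
        if _marker_positive(c, marker):
            _add_disc(od_d, c.x, c.y, 2.0 * r, p.dab_od_level)
    if p.noise_sd > 0:
        od_h = np.clip(od_h + rng.normal(0, 0.2 * p.noise_sd, od_h.shape), 0, None)
        od_d = np.clip(od_d + rng.normal(0, 0.2 * p.noise_sd, od_d.shape), 0, None)
    sm = DEFAULT_STAIN_MATRIX if stain_matrix is None else np.asarray(stain_matrix, float)
    return HDABImage(rgb=ods_to_rgb(od_h, od_d, sm), stain_matrix=sm.copy())


def _check_marker(marker: str):
    if marker not in ("CK", "CD68", "CD8", "PDL1"):
        raise ValueError(f"unknown marker {marker!r}; expected one of CK, CD68, CD8, PDL1")


def ods_to_rgb(od_h: np.ndarray, od_d: np.ndarray, stain_matrix: np.ndarray = DEFAULT_STAIN_MATRIX) -> np.ndarray:
    """Beer–Lambert forward transform: per-stain OD maps → 8-bit RGB."""
    od_rgb = od_h[..., None] * stain_matrix[0] + od_d[..., None] * stain_matrix[1]
    transmittance = np.power(10.0, -od_rgb)
    return np.clip(np.round(255.0 * transmittance), 0, 255).astype(np.uint8)
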