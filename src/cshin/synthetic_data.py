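"""Synthetic inputs for the whole pipeline, generated at desk scale.

Real inputs to this kind of study are micrographs of cultured epithelial
cells: manually delineated cell outlines for morphometry, and two-channel
confocal images of junctional markers for colocalization.  This module
replaces both with controlled generators:

* **Outlines** — geometric base shapes (circle, ellipse, square, rectangle,
  triangle, blob) whose border can be undulated: for radial shapes the
  radius is modulated as ``r(theta) = R(theta) * (1 + eps * w(k*theta))``
  with ``w`` a sine ("sinusoidal") or triangle wave ("serrated"); for
  cornered polygons the same wave is applied along the outward normal of
  the base boundary parameterized by arc length.  Smooth elongated outlines
  emulate epithelial morphology (CShin below 1); wavy borders emulate
  mesenchymal-like morphology (CShin above 1).
* **Belt pairs** — two-channel images of an annular "junctional belt":
  channel A positive on the whole belt, channel B positive on a seeded
  contiguous arc covering a chosen fraction ``rho`` of A's foreground, plus
  Gaussian noise.  ``rho`` is defined on channel-A foreground pixels, so it
  is directly interpretable as the expected count-based M1.
* **Surrogate sequences** — a synthetic vinculin-like protein carrying the
  three tankyrase-binding motifs of human vinculin at their published
  coordinates, and a small synthetic homolog alignment for conservation
  reporting (no sequence database is bundled or downloaded).

Every generator is a pure function of (spec, seed): reruns are
bit-identical, and no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.signal import sawtooth
from shapely.geometry import Polygon

from cshin.colocalization import BinaryMask, ChannelImage
from cshin.morphometry import CellContour
from cshin.sequence_motifs import (
    AMINO_ACIDS,
    Alignment,
    AlignedRecord,
    MotifHit,
    ProteinRecord,
    _build_maps,
    scan_tbm,
)

__all__ = [
    "ShapeSpec",
    "ParameterSpreads",
    "BeltPairSpec",
    "make_shape",
    "make_population",
    "epithelial_population",
    "mesenchymal_population",
    "rasterize",
    "make_belt_pair",
    "make_surrogate_vcl",
    "make_surrogate_homolog_alignment",
]

_RADIAL_KINDS = {"circle", "ellipse", "blob"}
_CORNERED_KINDS = {"square", "rectangle", "triangle"}


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic outline.

    ``size`` is the characteristic radius (radial kinds) or side length
    (cornered kinds) in px; ``aspect`` the major/minor ratio (>= 1);
    ``wave_amplitude`` (eps, dimensionless, < 1) and ``wave_count`` (k) set
    the border undulation; ``wave_form`` is "sinusoidal" or "serrated"
    (triangle wave).
    """

    kind: str = "circle"
    size: float = 100.0
    aspect: float = 1.0
    wave_amplitude: float = 0.0
    wave_count: int = 0
    wave_form: str = "sinusoidal"
    n_vertices: int = 720
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _RADIAL_KINDS | _CORNERED_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.size <= 0:
            raise ValueError("size must be > 0")
        if self.aspect < 1:
            raise ValueError("aspect must be >= 1")
        if not 0 <= self.wave_amplitude < 1:
            raise ValueError("wave_amplitude must be in [0, 1)")
        if self.wave_amplitude > 0 and self.wave_count < 3:
            raise ValueError("wave_count must be >= 3 when wave_amplitude > 0")
        if self.wave_form not in {"sinusoidal", "serrated"}:
            raise ValueError(f"unknown wave_form {self.wave_form!r}")
        if self.n_vertices < 32:
            raise ValueError("n_vertices must be >= 32")


def _wave(phase: np.ndarray, form: str) -> np.ndarray:
    if form == "sinusoidal":
        return np.sin(phase)
    return sawtooth(phase, width=0.5)  # triangle wave in [-1, 1]


def _base_boundary(spec: ShapeSpec, rng: np.random.Generator | None) -> np.ndarray:
    """Dense (x, y) sampling of the unperturbed boundary, centered at 0."""
    n = spec.n_vertices
    if spec.kind in _RADIAL_KINDS:
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        if spec.kind == "circle" and spec.aspect == 1.0:
            r = np.full(n, spec.size)
        elif spec.kind in {"circle", "ellipse"}:
            a, b = spec.size, spec.size / spec.aspect
            r = a * b / np.hypot(b * np.cos(theta), a * np.sin(theta))
        else:  # blob: smooth random low-order radial modulation
            if rng is None:
                rng = np.random.default_rng(0)
            r = np.full(n, float(spec.size))
            for order in range(2, 6):
                amp = 0.08 * spec.size * rng.uniform(0.2, 1.0) / order
                r += amp * np.cos(order * theta + rng.uniform(0, 2 * np.pi))
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    # cornered kinds: walk the polygon boundary at equal arc-length steps
    if spec.kind == "square":
        s = spec.size
        corners = np.array([[-s, -s], [s, -s], [s, s], [-s, s]]) / 2.0
    elif spec.kind == "rectangle":
        w, h = spec.size, spec.size / spec.aspect
        corners = np.array([[-w, -h], [w, -h], [w, h], [-w, h]]) / 2.0
    else:  # equilateral triangle, side = size
        s = spec.size
        rad = s / np.sqrt(3.0)
        ang = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3])
        corners = rad * np.column_stack([np.cos(ang), np.sin(ang)])
    edges = np.roll(corners, -1, axis=0) - corners
    edge_len = np.linalg.norm(edges, axis=1)
    # sample each edge from its corner (inclusive) so corners are exact
    counts = np.maximum(1, np.round(n * edge_len / edge_len.sum()).astype(int))
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n:
        counts[np.argmin(counts)] += 1
    pieces = [
        corners[i] + np.linspace(0.0, 1.0, counts[i], endpoint=False)[:, None] * edges[i]
        for i in range(len(corners))
    ]
    return np.concatenate(pieces)


def make_shape(
    spec: ShapeSpec, rng: np.random.Generator | int | None = None
) -> CellContour:
    """Sample one outline from its spec.

    ``rng`` (Generator or int seed) is consumed only by the "blob" kind.
    Raises if the requested undulation self-intersects, naming the
    offending (wave_amplitude, wave_count).
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    base = _base_boundary(spec, rng)
    if spec.wave_amplitude > 0:
        if spec.kind in _RADIAL_KINDS:
            theta = np.arctan2(base[:, 1], base[:, 0])
            factor = 1.0 + spec.wave_amplitude * _wave(
                spec.wave_count * theta, spec.wave_form
            )
            pts = base * factor[:, None]
        else:
            # normal displacement, wave phased by arc length; amplitude is
            # scaled by the mean centroid distance so eps is comparable
            # across kinds
            seg = np.roll(base, -1, axis=0) - base
            seg_len = np.linalg.norm(seg, axis=1)
            s_mid = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]
            total = seg_len.sum()
            tangent = seg / seg_len[:, None]
            normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])  # outward (CCW, y-down handled later)
            # ensure outward: flip if pointing toward centroid
            centroid = base.mean(axis=0)
            outward = np.sign(np.sum((base - centroid) * normal, axis=1))
            outward[outward == 0] = 1.0
            normal *= outward[:, None]
            r_char = float(np.mean(np.linalg.norm(base - centroid, axis=1)))
            disp = spec.wave_amplitude * r_char * _wave(
                2 * np.pi * spec.wave_count * s_mid / total, spec.wave_form
            )
            pts = base + disp[:, None] * normal
    else:
        pts = base
    if spec.rotation:
        c, s = np.cos(spec.rotation), np.sin(spec.rotation)
        pts = pts @ np.array([[c, -s], [s, c]]).T
    if not Polygon(pts).is_simple:
        raise ValueError(
            "self-intersecting outline: wave_amplitude="
            f"{spec.wave_amplitude} too large for wave_count={spec.wave_count} "
            f"on kind={spec.kind!r}"
        )
    return CellContour(pts)


@dataclass(frozen=True)
class ParameterSpreads:
    """Uniform jitter ranges for population sampling (lo, hi); a range of
    None leaves the base value untouched."""

    size: tuple[float, float] | None = None
    aspect: tuple[float, float] | None = None
    wave_amplitude: tuple[float, float] | None = None
    wave_count: tuple[int, int] | None = None
    rotation: tuple[float, float] = (0.0, 2 * np.pi)

    def __post_init__(self) -> None:
        for name in ("size", "aspect", "wave_amplitude", "wave_count", "rotation"):
            rng = getattr(self, name)
            if rng is not None and rng[1] < rng[0]:
                raise ValueError(f"invalid spread for {name}: {rng}")


def make_population(
    n: int, base: ShapeSpec, jitter: ParameterSpreads, seed: int
) -> list[CellContour]:
    """Draw ``n`` outlines with independently jittered parameters.

    Reproducible for a fixed seed; each contour's size/aspect/undulation/
    rotation is drawn uniformly from the spreads in ``jitter``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    contours = []
    for i in range(n):
        kwargs: dict[str, object] = {"rotation": rng.uniform(*jitter.rotation)}
        if jitter.size is not None:
            kwargs["size"] = rng.uniform(*jitter.size)
        if jitter.aspect is not None:
            kwargs["aspect"] = rng.uniform(*jitter.aspect)
        if jitter.wave_amplitude is not None:
            kwargs["wave_amplitude"] = rng.uniform(*jitter.wave_amplitude)
        if jitter.wave_count is not None:
            kwargs["wave_count"] = int(rng.integers(jitter.wave_count[0], jitter.wave_count[1] + 1))
        spec = replace(base, **kwargs)
        contour = make_shape(spec, rng)
        object.__setattr__(contour, "label", f"cell_{i:03d}")
        contours.append(contour)
    return contours


#: smooth elongated outlines under junctional tension: CShin stays below 1
EPITHELIAL_PRESET = (
    ShapeSpec(kind="ellipse", size=100.0, aspect=1.5, wave_amplitude=0.0),
    ParameterSpreads(size=(80.0, 120.0), aspect=(1.2, 2.0)),
)

#: wavy, serrated borders (filopodia/lamellipodia-like): CShin above 1
MESENCHYMAL_PRESET = (
    ShapeSpec(kind="ellipse", size=100.0, aspect=1.5, wave_amplitude=0.12, wave_count=14),
    ParameterSpreads(
        size=(80.0, 120.0),
        aspect=(1.2, 2.0),
        wave_amplitude=(0.08, 0.18),
        wave_count=(10, 20),
    ),
)


def epithelial_population(n: int, seed: int) -> list[CellContour]:
    """Smooth-bordered elongated outlines (epithelial-like morphology)."""
    return make_population(n, *EPITHELIAL_PRESET, seed=seed)


def mesenchymal_population(n: int, seed: int) -> list[CellContour]:
    """Wavy-bordered outlines (mesenchymal-like morphology)."""
    return make_population(n, *MESENCHYMAL_PRESET, seed=seed)


def rasterize(contour: CellContour, image_size: tuple[int, int]) -> BinaryMask:
    """Fill an outline onto a pixel grid: a pixel is foreground iff its
    center lies inside the polygon.  The contour must fit on the canvas."""
    h, w = image_size
    v = contour.vertices
    if v[:, 0].min() < -0.5 or v[:, 1].min() < -0.5 or v[:, 0].max() > w - 0.5 or v[:, 1].max() > h - 0.5:
        raise ValueError(
            f"contour bounding box {v.min(axis=0)}..{v.max(axis=0)} exceeds "
            f"canvas {image_size}"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    inside = MplPath(v).contains_points(centers).reshape(h, w)
    if not inside.any():
        warnings.warn("contour encloses no pixel centers: empty mask", stacklevel=2)
    return BinaryMask(inside)


# ---------------------------------------------------------------------------
# Belt pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeltPairSpec:
    """Two-channel annular-belt image pair with known co-occurrence.

    ``co_occurrence`` (rho) is the fraction of channel-A belt pixels that
    are also channel-B positive — the expected count-based M1.  Channel B
    occupies one seeded contiguous arc of the belt; ``b_off_belt_fraction``
    optionally adds B-only foreground off the belt (fraction of belt pixel
    count).  Gaussian noise of sd ``noise_sd`` is added to both channels
    (clipped at 0).
    """

    image_size: tuple[int, int] = (256, 256)
    belt_radius: float = 90.0
    belt_width: float = 14.0
    co_occurrence: float = 0.6
    fg_intensity: float = 200.0
    bg_intensity: float = 20.0
    noise_sd: float = 8.0
    b_off_belt_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.co_occurrence <= 1.0:
            raise ValueError("co_occurrence must be in [0, 1]")
        if not self.fg_intensity > self.bg_intensity >= 0:
            raise ValueError("need fg_intensity > bg_intensity >= 0")
        if self.noise_sd < 0 or self.b_off_belt_fraction < 0:
            raise ValueError("noise_sd and b_off_belt_fraction must be >= 0")


def make_belt_pair(
    spec: BeltPairSpec,
) -> tuple[ChannelImage, ChannelImage, tuple[BinaryMask, BinaryMask]]:
    """Generate the (channel A, channel B, ground-truth masks) triple."""
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = np.hypot(xx - cx, yy - cy)
    belt = np.abs(radius - spec.belt_radius) <= spec.belt_width / 2.0
    n_belt = int(belt.sum())
    if n_belt == 0:
        raise ValueError("belt is empty: radius/width do not fit the canvas")
    gt_a = belt
    # channel B: one contiguous arc (by polar angle) covering rho of A
    angle = np.arctan2(yy - cy, xx - cx)[belt]
    order = np.argsort(angle)
    n_b_on = int(round(spec.co_occurrence * n_belt))
    start = int(rng.integers(0, n_belt))
    take = (np.arange(n_b_on) + start) % n_belt
    belt_idx = np.flatnonzero(belt.ravel())[order]
    gt_b = np.zeros(h * w, dtype=bool)
    gt_b[belt_idx[take]] = True
    gt_b = gt_b.reshape(h, w)
    if spec.b_off_belt_fraction > 0:
        off = np.flatnonzero(~belt.ravel())
        n_extra = min(len(off), int(round(spec.b_off_belt_fraction * n_belt)))
        gt_b.ravel()[rng.choice(off, size=n_extra, replace=False)] = True
    img_a = np.where(gt_a, spec.fg_intensity, spec.bg_intensity).astype(float)
    img_b = np.where(gt_b, spec.fg_intensity, spec.bg_intensity).astype(float)
    if spec.noise_sd > 0:
        img_a += rng.normal(0.0, spec.noise_sd, size=(h, w))
        img_b += rng.normal(0.0, spec.noise_sd, size=(h, w))
    img_a = np.clip(img_a, 0.0, None)
    img_b = np.clip(img_b, 0.0, None)
    return (
        ChannelImage(img_a, channel_name="A"),
        ChannelImage(img_b, channel_name="B"),
        (BinaryMask(gt_a), BinaryMask(gt_b)),
    )


# ---------------------------------------------------------------------------
# Surrogate sequences (synthetic stand-ins; no database access)
# ---------------------------------------------------------------------------

# the three tankyrase-binding motifs of human vinculin with their published
# 1-based start coordinates
VCL_TBMS: tuple[tuple[int, str, str], ...] = (
    (339, "RARGQG", "canonical"),
    (449, "RRQGKG", "canonical"),
    (520, "RGLVAEG", "non_canonical"),
)
VCL_LENGTH = 1066


def make_surrogate_vcl(seed: int = 0) -> ProteinRecord:
    """Synthetic vinculin-like sequence (stand-in, not the RefSeq entry).

    A random 1066-residue background with human vinculin's three
    tankyrase-binding motifs spliced in at their published coordinates
    (RARGQG at 339-344, RRQGKG at 449-454, RGLVAEG at 520-526), then
    repaired so that no spurious motif occurs anywhere else.  Deterministic
    in ``seed``; useful wherever the real accession is unavailable but the
    scanner's positional behaviour must be exercised end to end.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    seq = list(rng.choice(aa, size=VCL_LENGTH))
    protected: set[int] = set()
    for start, motif, _cls in VCL_TBMS:
        for off, ch in enumerate(motif):
            seq[start - 1 + off] = ch
            protected.add(start - 1 + off)
    wanted = {(start, motif) for start, motif, _ in VCL_TBMS}
    for _ in range(200):  # repair loop: mutate residues creating stray hits
        record = ProteinRecord(id="surrogate_hVCL", sequence="".join(seq), species="synthetic")
        stray = [
            h for h in scan_tbm(record) if (h.start, h.matched) not in wanted
        ]
        if not stray:
            return record
        hit = stray[0]
        window = range(hit.start - 1, hit.end)
        free = [i for i in window if i not in protected]
        if not free:  # cannot happen for distinct hits, guard anyway
            raise RuntimeError("stray motif entirely inside protected region")
        # prefer breaking an anchor (first R, last G, or the O position)
        anchors = {hit.start - 1, hit.end - 1}
        target = next((i for i in free if i in anchors), free[-1])
        seq[target] = "L" if seq[target] != "L" else "M"
    raise RuntimeError("surrogate repair did not converge")


# Hand-built synthetic homolog alignment (equal-length rows).  Vertebrate
# rows conserve all three motif loci; the fly row keeps only the second
# (first degenerate: O-position broken; third absent: R lost); the worm row
# has none.  Coordinates are compressed — this is a toy alignment for
# exercising conservation reporting, not a real vinculin alignment.
_SURROGATE_ALIGNMENT_ROWS: tuple[tuple[str, str], ...] = (
    ("Human",      "MSTLKE" "RARGQG" "TPLNDE" "RRQGKG" "AVSMDH" "RGLVAEG" "KLTDSW"),
    ("Mouse",      "MSTLKE" "RARGQG" "TPLNDE" "RRQGKG" "AVSMDH" "RGLVAEG" "KLTDSW"),
    ("Chicken",    "MSALKE" "RSRGTG" "TPLNDE" "RKQGNG" "AVSLDH" "RGIVADG" "KLTDSW"),
    ("Xenopus",    "MTTLKE" "RARGSG" "SPLNDE" "RRTGKG" "AVSMDH" "RSLVACG" "KLSDSW"),
    ("Zebrafish",  "MSTLRE" "RTRGQG" "TPLNDD" "RRQAKG" "AVTMDH" "RGLIAEG" "KLTDTW"),
    ("Drosophila", "MNVLKD" "RARFQG" "SQLNDE" "RKAGSG" "GVSLDH" "KGLVAEG" "QLTENW"),
    ("Celegans",   "MDHIKE" "KDSFTN" "SSLDPE" "KSSIHD" "GVNLEH" "TSMIESN" "ELSNTW"),
)


def make_surrogate_homolog_alignment() -> Alignment:
    """Synthetic toy alignment of vinculin-like homologs (stand-in).

    Emulates the qualitative conservation pattern reported for vinculin's
    tankyrase-binding motifs — conserved in vertebrates, a single motif
    retained in *Drosophila*, none in *C. elegans* — on short invented
    sequences.  Not derived from any real alignment.
    """
    rows = []
    for name, aligned in _SURROGATE_ALIGNMENT_ROWS:
        col_map, res_map = _build_maps(aligned)
        rows.append(
            AlignedRecord(id=name, aligned=aligned, col_of_residue=col_map, residue_of_col=res_map)
        )
    return Alignment(rows)
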