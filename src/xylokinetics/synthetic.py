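"""Synthetic measurement tables, section profiles and stained-section images.

The study's raw material is histology: Toluidine-Blue-stained transverse
sections of the Arabidopsis root base at 7, 11, 15 and 21 days after
germination (DAG), from which basal secondary-xylem area, cell number and
longitudinal extension are measured on ~10 replicate roots per day. That
material is emulated here with known ground truth so every downstream
stage — counting, summarising, fitting — is testable end to end.

Three generators:

* :func:`generate_trajectory` draws replicate-level measurement tables
  around exponential forward trajectories. Area and extension noise is
  multiplicative lognormal with a stated coefficient of variation (the
  measurements are strictly positive and span orders of magnitude, so
  additive noise would be unphysical); cell counts are Poisson about the
  forward value, switchable to a rounded lognormal.
* :func:`generate_profile` lays a serial-section grid (5 µm sections in
  successive 0.5 cm blocks from the root base) over a known longitudinal
  extension, marking in which sections secondary vascular cells appear.
* :func:`generate_section_image` draws a section micrograph: light
  lumens ringed by dark walls on a light background, cells as randomly
  perturbed ellipses, a chosen fraction placed as touching (fused) pairs
  to exercise object splitting, plus Gaussian sensor noise. The paired
  label map and true count are returned alongside.

The default :class:`GenerativeParams` reproduce the study conditions:
four sampling days (7/11/15/21 DAG), ten replicates per day, and forward
trajectories through the reported group means (initial values and
log-slopes from closed-form log-OLS through those means).

All randomness is driven by explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from . import units

__all__ = [
    "GenerativeParams",
    "SectionProfile",
    "ImageSpec",
    "GroundTruth",
    "generate_trajectory",
    "generate_profile",
    "generate_section_image",
]


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenerativeParams:
    """Ground-truth parameters of the synthetic study.

    Initial values are at t = 0 (germination); the defaults place the
    forward trajectories through the reported 7/11/15/21-DAG group means
    (log-OLS through the means: a(7 DAG) = 1519.56 µm^2 etc.).

    Units: a0 mm^2, h0 mm, rates 1/day; cv_* are dimensionless
    coefficients of variation of the multiplicative lognormal noise.
    ``count_noise`` switches count dispersion off (0) or on (>0); with
    ``count_model="lognormal"`` it is the coefficient of variation of the
    rounded lognormal, while ``"poisson"`` dispersion is the Poisson one.
    """

    a0: float = 1.2645345e-4       # mm^2
    k_A: float = 0.3951594         # 1/day
    N0: float = 0.3245502          # cells
    k_Ncount: float = 0.3221277    # 1/day
    h0: float = 0.9616419          # mm
    k_h: float = 0.2276335         # 1/day
    cv_area: float = 0.1
    cv_height: float = 0.1
    count_noise: float = 1.0
    count_model: str = "poisson"
    times: tuple = (7.0, 11.0, 15.0, 21.0)
    n_reps: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("a0", "N0", "h0"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name in ("k_A", "k_Ncount", "k_h"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("cv_area", "cv_height", "count_noise"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.count_model not in ("poisson", "lognormal"):
            raise ValueError(f"count_model must be 'poisson' or 'lognormal', "
                             f"got {self.count_model!r}")
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or not np.all(np.diff(t) > 0):
            raise ValueError("times must be non-empty and strictly increasing")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")


def _lognormal_factor(rng, cv, size):
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def generate_trajectory(params: GenerativeParams, seed=None) -> pd.DataFrame:
    """Draw a replicate-level measurement table from the forward model.

    One row per (sampling day, replicate), in the canonical columns of
    :mod:`xylokinetics.series`. The expectation of every record at time t
    is the forward value X0*exp(k*t); with all noise set to zero the
    records equal the forward values exactly. A fixed seed gives
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rows = []
    for t in params.times:
        a_true = params.a0 * math.exp(params.k_A * t)
        n_true = params.N0 * math.exp(params.k_Ncount * t)
        h_true = params.h0 * math.exp(params.k_h * t)
        areas = a_true * _lognormal_factor(rng, params.cv_area, params.n_reps)
        heights = h_true * _lognormal_factor(rng, params.cv_height, params.n_reps)
        if params.count_noise == 0:
            counts = np.full(params.n_reps, n_true)
        elif params.count_model == "poisson":
            counts = rng.poisson(n_true, size=params.n_reps).astype(float)
        else:
            counts = np.round(
                n_true * _lognormal_factor(rng, params.count_noise, params.n_reps)
            )
        for rep in range(params.n_reps):
            rows.append((t, rep, areas[rep], counts[rep], heights[rep]))
    return pd.DataFrame(
        rows, columns=["dag", "replicate", "area_mm2", "cell_count", "extension_mm"]
    )


# ---------------------------------------------------------------------------
# serial-section profiles
# ---------------------------------------------------------------------------


@dataclass
class SectionProfile:
    """Presence/absence of secondary vascular cells along a serial-section run.

    ``positions`` are section midpoints in mm from the root base
    (uppermost part), increasing towards the root tip; ``present`` marks
    sections in which secondary vascular cells were observed. Sections
    are ``section_thickness_um`` thick, cut from successive
    ``sampling_block_cm`` blocks.
    """

    positions: np.ndarray
    present: np.ndarray
    section_thickness_um: float = 5.0
    sampling_block_cm: float = 0.5

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.positions.shape != self.present.shape or self.positions.ndim != 1:
            raise ValueError("positions and present must be equal-length 1-D")
        if self.positions.size and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.section_thickness_um <= 0:
            raise ValueError("section_thickness_um must be > 0")
        if self.sampling_block_cm <= 0:
            raise ValueError("sampling_block_cm must be > 0")


def generate_profile(true_extension_mm: float,
                     section_thickness_um: float = 5.0,
                     sampling_block_cm: float = 0.5,
                     n_extra_blocks: int = 1,
                     seed=None) -> SectionProfile:
    """Lay a section grid over a root with known secondary-growth extension.

    Sections of ``section_thickness_um`` tile successive
    ``sampling_block_cm`` blocks from the root base; each section is
    marked present when its midpoint lies within ``true_extension_mm``.
    The grid extends ``n_extra_blocks`` blocks past the extension so the
    transition to primary-only tissue is always covered. ``seed`` is
    accepted for interface uniformity; the profile is deterministic.
    """
    if true_extension_mm < 0:
        raise ValueError(f"true_extension_mm must be >= 0, got {true_extension_mm}")
    thick_mm = units.um_to_mm(section_thickness_um)
    block_mm = units.cm_to_mm(sampling_block_cm)
    n_blocks = int(math.ceil(true_extension_mm / block_mm)) + n_extra_blocks
    n_sections = int(round(n_blocks * block_mm / thick_mm))
    positions = (np.arange(n_sections) + 0.5) * thick_mm
    present = positions <= true_extension_mm
    return SectionProfile(positions, present, section_thickness_um,
                          sampling_block_cm)


# ---------------------------------------------------------------------------
# section images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSpec:
    """Recipe for one synthetic stained-section micrograph.

    Intensities are on the 8-bit scale with the Toluidine-Blue contrast
    polarity: dark cell walls (``wall_intensity``) around light lumens
    (``lumen_intensity``) on a light background. ``touching_fraction`` of
    the cells are placed as fused pairs whose lumens merge into one
    bright region (their separation needs object splitting);
    ``noise_sd`` is the Gaussian sensor noise.
    """

    width: int = 768
    height: int = 768
    n_cells: int = 50
    cell_radius_range: tuple = (6.0, 12.0)
    wall_thickness: float = 3.0
    wall_intensity: float = 50.0
    lumen_intensity: float = 240.0
    background_intensity: float = 200.0
    touching_fraction: float = 0.1
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0, got {self.n_cells}")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"cell_radius_range must be positive and ordered, "
                             f"got {self.cell_radius_range}")
        if not self.wall_intensity < self.lumen_intensity:
            raise ValueError("wall_intensity must be darker than lumen_intensity")
        if not 0 <= self.touching_fraction <= 1:
            raise ValueError(f"touching_fraction must be in [0, 1], "
                             f"got {self.touching_fraction}")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("width", "height"):
            if getattr(self, name) < 8:
                raise ValueError(f"{name} must be >= 8 pixels")


@dataclass
class GroundTruth:
    """Label map (0 = background, i = lumen of cell i) and true cell count."""

    label_map: np.ndarray
    true_count: int

    def __post_init__(self):
        labels = np.unique(self.label_map)
        n = int((labels != 0).sum())
        if n != self.true_count:
            raise ValueError(
                f"true_count {self.true_count} != {n} distinct nonzero labels")


@dataclass
class _Cell:
    cy: float
    cx: float
    r_major: float
    r_minor: float
    rot: float

    @property
    def r(self):  # circumscribing radius used for separation tests
        return self.r_major


def _try_place(rng, spec, cells, partner=None, circular=False, max_tries=400):
    """Place one perturbed-ellipse cell; returns a _Cell or None.

    Non-partnered cells keep lumen-to-lumen clearance of two wall
    thicknesses so distinct cells never share a bright region; a partner
    cell is fused at 95% of the radius sum so the pair's lumens merge
    into a dumbbell. Fused-pair members are kept near-circular so the
    fusion depth is controlled by the centre distance, not by the
    orientation of an elongated axis.
    """
    lo, hi = spec.cell_radius_range
    wall = spec.wall_thickness
    for _ in range(max_tries):
        r = rng.uniform(lo, hi)
        ecc = rng.uniform(0.0, 0.08 if circular else 0.25)
        r_major, r_minor = r, r * (1.0 - ecc)
        rot = rng.uniform(0.0, math.pi)
        margin = r_major + wall + 2.0
        if partner is None:
            cy = rng.uniform(margin, spec.height - margin)
            cx = rng.uniform(margin, spec.width - margin)
        else:
            theta = rng.uniform(0.0, 2.0 * math.pi)
            d = 0.95 * (partner.r_minor + r_minor)
            cy = partner.cy + d * math.sin(theta)
            cx = partner.cx + d * math.cos(theta)
            if not (margin <= cy <= spec.height - margin
                    and margin <= cx <= spec.width - margin):
                continue
        ok = True
        for other in cells:
            if other is partner:
                continue
            dist = math.hypot(cy - other.cy, cx - other.cx)
            if dist < r_major + other.r + 2.0 * wall + 2.0:
                ok = False
                break
        if ok:
            return _Cell(cy, cx, r_major, r_minor, rot)
    return None


def generate_section_image(spec: ImageSpec):
    """Draw one synthetic section micrograph with pixel-level ground truth.

    Returns ``(image, GroundTruth)`` where ``image`` is a uint8 array of
    shape (height, width). The reported ``true_count`` is the number of
    cells actually drawn: if the canvas cannot hold ``n_cells`` at the
    requested geometry the placement shortfall is reported truthfully
    with a warning, never silently. A fixed seed gives byte-identical
    images.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    n_pair_cells = int(round(spec.touching_fraction * spec.n_cells)) // 2 * 2
    n_singles = spec.n_cells - n_pair_cells

    cells, pair_of = [], {}
    for _ in range(n_pair_cells // 2):
        first = _try_place(rng, spec, cells, circular=True)
        if first is None:
            continue
        cells.append(first)
        second = _try_place(rng, spec, cells, partner=first, circular=True)
        if second is not None:
            pair_of[id(second)] = first
            cells.append(second)
    for _ in range(n_singles):
        cell = _try_place(rng, spec, cells)
        if cell is not None:
            cells.append(cell)
    if len(cells) < spec.n_cells:
        warnings.warn(
            f"placed {len(cells)} of {spec.n_cells} requested cells; "
            "canvas too crowded for the requested geometry", stacklevel=2)

    image = np.full(shape, spec.background_intensity, dtype=float)
    labels = np.zeros(shape, dtype=np.uint16)

    # all walls first, then all lumens: fused pairs share one bright region
    for c in cells:
        rr, cc = draw_ellipse(c.cy, c.cx, c.r_major + spec.wall_thickness,
                              c.r_minor + spec.wall_thickness,
                              shape=shape, rotation=c.rot)
        image[rr, cc] = spec.wall_intensity
    for i, c in enumerate(cells, start=1):
        rr, cc = draw_ellipse(c.cy, c.cx, c.r_major, c.r_minor,
                              shape=shape, rotation=c.rot)
        image[rr, cc] = spec.lumen_intensity
        labels[rr, cc] = i

    # a fused partner may overwrite part of its mate's lumen; count only
    # the labels that survived so the invariant holds pixelwise
    surviving = np.unique(labels)
    surviving = surviving[surviving != 0]
    if surviving.size < len(cells):
        remap = np.zeros(len(cells) + 1, dtype=np.uint16)
        remap[surviving] = np.arange(1, surviving.size + 1, dtype=np.uint16)
        labels = remap[labels]
        warnings.warn("a fused cell was fully overdrawn by its partner",
                      stacklevel=2)

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return image, GroundTruth(label_map=labels, true_count=int(surviving.size))
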