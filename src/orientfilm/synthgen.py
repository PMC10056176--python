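"""Synthetic biofilm-like images and point patterns with known ground truth.

Real crystal-violet-stained biofilms appear as a dark, high-coverage layer on
a lighter substrate, with colony-scale blobs and mosaic subdomains in which
the texture has a locally preferred orientation.  This module emulates those
features with fully parameterized generators so that every downstream stage
(thresholding, shape statistics, Voronoi regularity, structure-tensor
orientation) can be validated against an exact ground truth.

Angle convention (shared with :mod:`orientfilm.tensorfield`): orientations are
measured in degrees on [0, 180), counter-clockwise from the +x (column) axis
in image coordinates with y increasing downward; 0 deg means horizontal
structures (intensity constant along rows).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "PointPattern",
    "Subdomain",
    "gen_oriented_texture",
    "gen_biofilm_image",
    "gen_point_pattern",
    "tile_subdomains",
    "biofilm_study_spec",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Subdomain:
    """Axis-aligned rectangular subdomain with a preferred texture direction.

    ``region`` is (row0, col0, row1, col1), half-open; ``angle`` in degrees on
    [0, 180); ``anisotropy`` in [0, 1], 0 = isotropic, 1 = pure grating.
    """

    region: tuple[int, int, int, int]
    angle: float
    anisotropy: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic biofilm image.

    foreground_level < background_level: the stained biofilm is dark on a
    lighter substrate.  Regeneration with an identical spec is bit-identical.
    """

    image_size: tuple[int, int] = (512, 512)
    coverage_target: float = 0.65
    subdomains: tuple[Subdomain, ...] = ()
    texture_wavelength: float = 16.0
    colony_count: int = 10
    colony_radius_range: tuple[float, float] = (8.0, 20.0)
    background_level: float = 200.0
    foreground_level: float = 40.0
    noise_sd: float = 2.5
    rng_seed: int = 0
    blob_scale: float = 24.0  # correlation length (px) of the coverage field

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError("image_size must be positive")
        if not 0.0 <= self.coverage_target <= 1.0:
            raise ValueError("coverage_target must lie in [0, 1]")
        if not self.foreground_level < self.background_level:
            raise ValueError("foreground_level must be below background_level")
        if self.colony_count and self.colony_radius_range[1] >= min(h, w):
            raise ValueError("colony radius exceeds image size")
        for sd in self.subdomains:
            r0, c0, r1, c1 = sd.region
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"subdomain region {sd.region} outside image")
        # overlap check: subdomains must not overlap
        occ = np.zeros(self.image_size, dtype=bool)
        for sd in self.subdomains:
            r0, c0, r1, c1 = sd.region
            if occ[r0:r1, c0:c1].any():
                raise ValueError("subdomain regions overlap")
            occ[r0:r1, c0:c1] = True

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        d["subdomains"] = tuple(
            Subdomain(tuple(s["region"]), s["angle"], s["anisotropy"])
            for s in d["subdomains"]
        )
        d["image_size"] = tuple(d["image_size"])
        d["colony_radius_range"] = tuple(d["colony_radius_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact per-pixel truth for a generated image.

    ``angle_map`` holds the subdomain target angle where anisotropy > 0 and
    NaN (isotropic sentinel) elsewhere.
    """

    coverage_mask: np.ndarray
    angle_map: np.ndarray
    subdomain_table: list[dict] = field(default_factory=list)

    @property
    def realized_coverage(self) -> float:
        return float(self.coverage_mask.mean())


@dataclass(frozen=True)
class PointPattern:
    kind: str
    points: np.ndarray  # (n, 2) array of (x, y)
    window: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    jitter_sd: float = 0.0
    rng_seed: int = 0


# --------------------------------------------------------------------------
# oriented texture
# --------------------------------------------------------------------------

def _vm_kappa(anisotropy: float) -> float:
    # von-Mises concentration, monotone in anisotropy, 0 at 0, -> inf at 1
    a = float(anisotropy)
    return 10.0 * a * a / max(1.0 - a, 1e-9)


def gen_oriented_texture(
    size: tuple[int, int],
    angle: float,
    anisotropy: float,
    wavelength: float,
    seed: int,
) -> np.ndarray:
    """Zero-mean, unit-variance texture with a controlled dominant orientation.

    anisotropy = 1 returns a pure sinusoidal grating (1-D pattern); smaller
    values return band-pass-filtered white noise whose Fourier spectrum is
    weighted by a von-Mises angular window centred on the target direction,
    giving continuous control from a grating down to isotropic noise at 0.

    Parameters
    ----------
    size : (height, width) in pixels.
    angle : target structure orientation, degrees in [0, 180).
    anisotropy : directional concentration in [0, 1].
    wavelength : dominant spatial wavelength in pixels (>= 2).
    seed : RNG seed; the generator is a pure function of its arguments.
    """
    if not (np.isfinite(angle) and np.isfinite(anisotropy) and np.isfinite(wavelength)):
        raise ValueError("angle, anisotropy and wavelength must be finite")
    if not 0.0 <= angle < 180.0:
        raise ValueError("angle must lie in [0, 180)")
    if not 0.0 <= anisotropy <= 1.0:
        raise ValueError("anisotropy must lie in [0, 1]")
    if wavelength < 2.0:
        raise ValueError("wavelength must be at least 2 px")

    h, w = int(size[0]), int(size[1])
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(angle)

    if anisotropy == 1.0:
        # pure grating: wave vector normal to the structure direction
        phase = rng.uniform(0.0, 2.0 * np.pi)
        y, x = np.mgrid[0:h, 0:w].astype(float)
        arg = 2.0 * np.pi / wavelength * (x * np.sin(theta) + y * np.cos(theta))
        tex = np.cos(arg + phase)
    else:
        noise = rng.standard_normal((h, w))
        spec = np.fft.fft2(noise)
        u = np.fft.fftfreq(w)[None, :]  # cycles/px along x (columns)
        v = np.fft.fftfreq(h)[:, None]  # cycles/px along y (rows)
        r = np.hypot(u, v)
        r0 = 1.0 / wavelength
        radial = np.exp(-0.5 * ((r - r0) / (0.5 * r0)) ** 2)
        radial[0, 0] = 0.0  # kill DC
        kappa = _vm_kappa(anisotropy)
        phi = np.arctan2(v, u)
        phi0 = np.arctan2(np.cos(theta), np.sin(theta))  # target wave-vector dir
        angular = np.exp(kappa * (np.cos(2.0 * (phi - phi0)) - 1.0))
        tex = np.fft.ifft2(spec * radial * angular).real

    sd = tex.std()
    if sd > 0:
        tex = (tex - tex.mean()) / sd
    return tex


# --------------------------------------------------------------------------
# biofilm image
# --------------------------------------------------------------------------

def gen_biofilm_image(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Composite biofilm-like image plus its exact ground truth.

    Construction: a smooth random coverage field (minus colony wells) is
    thresholded at the coverage_target quantile, which decouples realized
    coverage from texture parameters; intensity follows a soft tanh ramp
    between foreground and background levels across that threshold; oriented
    textures modulate each subdomain with an amplitude that vanishes at the
    foreground/background midpoint so the noiseless image crosses the midpoint
    exactly on the ground-truth mask; additive Gaussian noise comes last.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.rng_seed)
    mid = 0.5 * (spec.foreground_level + spec.background_level)
    half_span = 0.5 * (spec.background_level - spec.foreground_level)

    # oriented texture per subdomain: this is the structural field whose
    # level sets become the dark biomass, so the segmented structures
    # themselves carry the subdomain orientation (as in a stained biofilm,
    # where the oriented features are the biomass ridges, not an overlay)
    texture = np.zeros((h, w))
    angle_map = np.full((h, w), np.nan)
    table: list[dict] = []
    for i, sd_ in enumerate(spec.subdomains):
        r0, c0, r1, c1 = sd_.region
        sub_seed = int(rng.integers(0, 2**31 - 1))
        tex = gen_oriented_texture(
            (r1 - r0, c1 - c0), sd_.angle, sd_.anisotropy,
            spec.texture_wavelength, sub_seed,
        )
        texture[r0:r1, c0:c1] = np.clip(tex, -2.5, 2.5)
        if sd_.anisotropy > 0:
            angle_map[r0:r1, c0:c1] = sd_.angle
        table.append({
            "subdomain": i, "region": list(sd_.region),
            "angle_deg": sd_.angle, "anisotropy": sd_.anisotropy,
        })

    # coverage level field: oriented structure plus a smooth colony-scale
    # component that clusters the biomass; low values = biofilm (dark)
    raw = rng.standard_normal((h, w))
    lowfreq = ndimage.gaussian_filter(raw, sigma=spec.blob_scale / 3.0,
                                      mode="wrap")
    sd = lowfreq.std()
    if sd > 0:
        lowfreq = lowfreq / sd
    level = 0.85 * texture + 0.55 * lowfreq
    if not spec.subdomains:
        level = lowfreq
    lsd = level.std()
    if lsd > 0:
        level = level / lsd

    # colony wells: dark discs with Gaussian-smoothed edges, pushed below
    # threshold so they always count as (dark) foreground
    if spec.colony_count > 0:
        rmin, rmax = spec.colony_radius_range
        wells = np.zeros((h, w))
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        for _ in range(spec.colony_count):
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            rad = rng.uniform(rmin, rmax)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            wells += np.exp(-0.5 * d2 / (0.5 * rad) ** 2)
        level = level - 4.0 * wells

    if spec.coverage_target <= 0.0:
        mask = np.zeros((h, w), dtype=bool)
        base = np.full((h, w), spec.background_level)
    elif spec.coverage_target >= 1.0:
        mask = np.ones((h, w), dtype=bool)
        base = np.full((h, w), spec.foreground_level)
    else:
        thr = np.quantile(level, spec.coverage_target)
        mask = level < thr
        # sharp edge (a ramp a couple of px wide): the two intensity classes
        # stay well separated, as in a stained-biofilm micrograph
        soft = 0.03
        base = mid + half_span * np.tanh((level - thr) / soft)

    # in-class graininess: a small aligned modulation whose amplitude is kept
    # well below the class separation (local window statistics stay bimodal)
    # and vanishes toward the midpoint, so the noiseless image never crosses
    # sides of the ground-truth mask
    margin = np.abs(base - mid)
    amp = np.minimum(0.2 * margin, 6.0)
    noiseless = np.clip(base + amp * texture,
                        spec.foreground_level - 30.0, 255.0)

    image = noiseless + rng.normal(0.0, spec.noise_sd, (h, w))
    image = np.clip(image, 0.0, 255.0)

    truth = GroundTruth(coverage_mask=mask, angle_map=angle_map,
                        subdomain_table=table)
    return image, truth


def tile_subdomains(
    image_size: tuple[int, int],
    grid: tuple[int, int],
    angles: Sequence[float],
    anisotropy: float = 0.9,
) -> tuple[Subdomain, ...]:
    """Tile the image with a rows x cols grid of subdomains.

    ``angles`` are assigned to tiles in row-major order (cycled if shorter).
    """
    h, w = image_size
    rows, cols = grid
    subs = []
    redges = np.linspace(0, h, rows + 1).astype(int)
    cedges = np.linspace(0, w, cols + 1).astype(int)
    k = 0
    for i in range(rows):
        for j in range(cols):
            a = float(angles[k % len(angles)]) % 180.0
            subs.append(Subdomain(
                (int(redges[i]), int(cedges[j]),
                 int(redges[i + 1]), int(cedges[j + 1])),
                float(a), float(anisotropy)))
            k += 1
    return tuple(subs)


def biofilm_study_spec(
    angle_center: float,
    seed: int,
    image_size: tuple[int, int] = (512, 512),
    coverage: float = 0.7,
    angle_spread: float = 10.0,
    grid: tuple[int, int] = (3, 3),
    anisotropy: float = 0.9,
) -> SyntheticSpec:
    """Spec for one synthetic 'strain' replicate.

    Subdomain angles are drawn around ``angle_center`` (deg) with a uniform
    +/- ``angle_spread`` jitter, emulating a strain whose oriented microdomains
    share a characteristic directional regime.
    """
    rng = np.random.default_rng(seed)
    n_tiles = grid[0] * grid[1]
    angles = (angle_center + rng.uniform(-angle_spread, angle_spread, n_tiles)) % 180.0
    return SyntheticSpec(
        image_size=image_size,
        coverage_target=coverage,
        subdomains=tile_subdomains(image_size, grid, angles, anisotropy),
        rng_seed=seed,
    )


# --------------------------------------------------------------------------
# point patterns
# --------------------------------------------------------------------------

def gen_point_pattern(
    kind: str,
    n: int,
    window: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0),
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> PointPattern:
    """2-D point pattern for Voronoi-regularity validation.

    kind = 'lattice': square grid filling the window (all nearest-neighbour
    distances equal); 'jittered_lattice': lattice plus i.i.d. Gaussian
    displacement of SD ``jitter_sd`` (clipped back into the window);
    'poisson': uniform i.i.d. points (binomial process).
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    if kind not in {"lattice", "jittered_lattice", "poisson"}:
        raise ValueError(f"unknown kind {kind!r}")
    xmin, xmax, ymin, ymax = window
    rng = np.random.default_rng(seed)

    if kind == "poisson":
        pts = np.column_stack([
            rng.uniform(xmin, xmax, n),
            rng.uniform(ymin, ymax, n),
        ])
    else:
        m = int(np.ceil(np.sqrt(n)))
        if m * m < n:
            raise ValueError("n exceeds lattice capacity")
        # cell-centred square grid, spacing equal in both axes for square window
        xs = xmin + (xmax - xmin) * (np.arange(m) + 0.5) / m
        ys = ymin + (ymax - ymin) * (np.arange(m) + 0.5) / m
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])[:n].astype(float)
        if kind == "jittered_lattice" and jitter_sd > 0:
            pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
            pts[:, 0] = np.clip(pts[:, 0], xmin, xmax)
            pts[:, 1] = np.clip(pts[:, 1], ymin, ymax)
    return PointPattern(kind=kind, points=pts, window=window,
                        jitter_sd=jitter_sd if kind == "jittered_lattice" else 0.0,
                        rng_seed=seed)
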