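"""Synthetic paired VNIR/SWIR scene generation.

Emulates the statistical structure of Worldview-3 style imagery over a
volcanic island landscape: six land-cover classes (bare soil,
bedrock/colluvium, forest/trees, grass, mulch i.e. rock gardens, and
urban/developed) arranged as elliptical patches on a grass background, with
class-conditional spectra drawn from per-class multivariate Gaussians.  The
library is constructed so classes — in particular rock-garden mulch versus
natural bedrock/colluvium — are well separated in the 8 SWIR bands but
strongly overlapping in the 8 VNIR bands, which is the premise the whole
mapping approach rests on: SWIR wavelengths resolve mineralogical and
moisture contrasts that the visible/near-infrared range cannot.

Reflectances are 8-bit-range digital numbers (floats clipped to [0, 255]).
All randomness flows through explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from .geo_io import (DEFAULT_CRS, GridTransform, LabelRaster, LabeledPolygon,
                     MultibandRaster)

CLASS_NAMES = ("bare_soil", "bedrock_colluvium", "forest_trees", "grass",
               "mulch", "urban_developed")

#: Worldview-3 band names: 8 VNIR then 8 SWIR.
VNIR_BANDS = ("Coastal blue", "Blue", "Green", "Yellow", "Red", "Red edge",
              "NIR1", "NIR2")
SWIR_BANDS = tuple(f"SWIR-{i}" for i in range(1, 9))
BAND_NAMES = VNIR_BANDS + SWIR_BANDS

SWIR_PIXEL_SIZE = 3.7  # m
VNIR_PIXEL_SIZE = 1.2  # m

#: Training plan mirroring the field survey: (feature count, total area m^2)
#: per class — 27/66/25/36/40/30 polygons, 224 in total.
FIELD_TRAINING_PLAN = {
    "bare_soil": (27, 0.101e6),
    "bedrock_colluvium": (66, 0.090e6),
    "forest_trees": (25, 0.235e6),
    "grass": (36, 0.090e6),
    "mulch": (40, 0.031e6),
    "urban_developed": (30, 0.053e6),
}


@dataclass
class SpectralLibrary:
    """Per-class Gaussian spectral model over the 16 Worldview-3 bands."""

    class_names: tuple[str, ...]
    band_names: tuple[str, ...]
    means: np.ndarray        # (classes, bands)
    covariances: np.ndarray  # (classes, bands, bands)

    def band_indices(self, names) -> np.ndarray:
        return np.array([self.band_names.index(n) for n in names])

    def marginal(self, class_name: str, band_names):
        """Mean and covariance restricted to a band subset."""
        c = self.class_names.index(class_name)
        idx = self.band_indices(band_names)
        return self.means[c, idx], self.covariances[c][np.ix_(idx, idx)]

    def mahalanobis(self, class_a: str, class_b: str, band_names) -> float:
        """Pooled-covariance Mahalanobis distance on a band subset."""
        mu_a, cov_a = self.marginal(class_a, band_names)
        mu_b, cov_b = self.marginal(class_b, band_names)
        pooled = 0.5 * (cov_a + cov_b)
        d = mu_a - mu_b
        return float(np.sqrt(d @ np.linalg.solve(pooled, d)))


def _cs_cov(sigma: float, n: int, rho: float) -> np.ndarray:
    """Compound-symmetric covariance sigma^2 * ((1-rho) I + rho J)."""
    return sigma ** 2 * ((1 - rho) * np.eye(n) + rho * np.ones((n, n)))


def default_spectral_library() -> SpectralLibrary:
    """Six-class, 16-band library with SWIR-separable / VNIR-confusable mulch.

    Mulch and bedrock/colluvium VNIR means differ by ~1 digital number per
    band (visually near-identical grey rock), while their SWIR means diverge
    strongly (fresh broken rock vs. weathered colluvium moisture/mineral
    response).  Covariances are compound-symmetric per class.
    """
    # VNIR shapes follow the material (vegetation red edge, bright built
    # surfaces); broadband VNIR intensity tracks overall albedo so the two
    # sensors see a consistent brightness structure.
    vnir = {
        "bare_soil":         [88, 98, 108, 113, 118, 123, 127, 129],
        "bedrock_colluvium": [82, 89, 96, 100, 104, 108, 112, 114],
        "forest_trees":      [39, 43, 60, 52, 43, 95, 120, 125],
        "grass":             [53, 62, 84, 75, 62, 106, 132, 132],
        "mulch":             [82, 89, 97, 101, 104, 108, 112, 114],
        "urban_developed":   [115, 123, 131, 134, 138, 141, 144, 146],
    }
    swir = {
        "bare_soil":         [150, 140, 130, 125, 110, 105, 100, 95],
        "bedrock_colluvium": [120, 115, 110, 108, 100, 96, 92, 88],
        "forest_trees":      [60, 55, 50, 48, 42, 40, 38, 36],
        "grass":             [95, 88, 82, 78, 70, 66, 62, 58],
        "mulch":             [85, 78, 72, 68, 95, 100, 105, 110],
        "urban_developed":   [170, 165, 160, 158, 150, 146, 142, 138],
    }
    sigma = {"bare_soil": 10.0, "bedrock_colluvium": 10.0,
             "forest_trees": 9.0, "grass": 9.0, "mulch": 8.0,
             "urban_developed": 12.0}
    rho = 0.3
    means = np.array([vnir[c] + swir[c] for c in CLASS_NAMES], dtype=float)
    covs = np.array([_cs_cov(sigma[c], 16, rho) for c in CLASS_NAMES])
    return SpectralLibrary(CLASS_NAMES, BAND_NAMES, means, covs)


@dataclass
class SceneConfig:
    """Geometry, composition and seeding of a synthetic scene.

    ``height``/``width`` are in SWIR pixels; the VNIR grid is the same extent
    at the finer pixel size (dimensions rounded).  ``class_fractions`` give
    target pixel shares for the patch classes; the remainder is the grass
    background.  Patch semi-axes (in SWIR cells) are drawn uniformly from
    ``patch_axis_range`` per class.
    """

    height: int = 128
    width: int = 128
    swir_pixel_size: float = SWIR_PIXEL_SIZE
    vnir_pixel_size: float = VNIR_PIXEL_SIZE
    class_fractions: dict = field(default_factory=lambda: {
        "bare_soil": 0.10,
        "bedrock_colluvium": 0.12,
        "forest_trees": 0.15,
        "urban_developed": 0.08,
        "mulch": 0.08,
    })
    patch_axis_range: dict = field(default_factory=lambda: {
        "bare_soil": (6, 14),
        "bedrock_colluvium": (4, 10),
        "forest_trees": (9, 18),
        "urban_developed": (5, 10),
        "mulch": (3, 8),
    })
    boundary_jitter: float = 0.25
    coastal_bias_class: str = "mulch"
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.swir_pixel_size <= 0 or self.vnir_pixel_size <= 0:
            raise ValueError("pixel sizes must be positive")
        total = sum(self.class_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"class fractions sum to {total:.3f} > 1")
        for c in self.class_fractions:
            if c not in CLASS_NAMES:
                raise ValueError(f"unknown class {c!r}")

    @property
    def vnir_shape(self) -> tuple[int, int]:
        scale = self.swir_pixel_size / self.vnir_pixel_size
        return int(round(self.height * scale)), int(round(self.width * scale))


def _place_patches(config: SceneConfig, rng: np.random.Generator
                   ) -> np.ndarray:
    """Assemble the truth grid by stamping jittered ellipses on grass."""
    h, w = config.height, config.width
    grass_idx = CLASS_NAMES.index("grass")
    truth = np.full((h, w), grass_idx, dtype=np.int16)
    total = h * w
    rr, cc = np.mgrid[0:h, 0:w]
    order = [c for c in CLASS_NAMES
             if c in config.class_fractions and c != "grass"]
    for cname in order:
        target = int(config.class_fractions[cname] * total)
        cidx = CLASS_NAMES.index(cname)
        lo, hi = config.patch_axis_range.get(cname, (4, 10))
        placed = 0
        attempts = 0
        while placed < target and attempts < 20 * total:
            attempts += 1
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            cx = rng.uniform(0, w)
            if cname == config.coastal_bias_class:
                # bias patch centres toward the bottom ("coastal") edge
                cy = h * (1 - np.sqrt(rng.uniform(0, 1)) * 0.6)
            else:
                cy = rng.uniform(0, h)
            r2 = ((cc - cx) / a) ** 2 + ((rr - cy) / b) ** 2
            jitter = 1 + config.boundary_jitter * rng.uniform(
                -1, 1, size=truth.shape)
            inside = (r2 <= jitter) & (truth == grass_idx)
            n_new = int(inside.sum())
            if n_new == 0:
                continue
            if placed + n_new > target * 1.15:
                continue  # would badly overshoot; try a smaller patch
            truth[inside] = cidx
            placed += n_new
    return truth


def _draw_class_spectra(truth: np.ndarray, library: SpectralLibrary,
                        band_names, rng: np.random.Generator) -> np.ndarray:
    """Per-pixel band values drawn from each class's band-subset Gaussian."""
    n_bands = len(band_names)
    out = np.empty((n_bands,) + truth.shape, dtype=np.float32)
    for cname in CLASS_NAMES:
        cidx = CLASS_NAMES.index(cname)
        mask = truth == cidx
        n = int(mask.sum())
        if n == 0:
            continue
        mu, cov = library.marginal(cname, band_names)
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((n, n_bands))
        samples = mu + z @ chol.T
        out[:, mask] = samples.T.astype(np.float32)
    np.clip(out, 0.0, 255.0, out=out)
    return out


def generate_scene(config: SceneConfig, library: SpectralLibrary | None = None
                   ) -> tuple[MultibandRaster, MultibandRaster, LabelRaster]:
    """Generate a (vnir, swir, truth) triple from the config's seed.

    The truth map lives on the SWIR grid; the VNIR raster is drawn on the
    finer grid from the truth upsampled by cell-centre lookup.  Identical
    configs (including seed) produce bit-identical outputs.
    """
    config.validate()
    if library is None:
        library = default_spectral_library()
    rng = np.random.default_rng(config.seed)
    truth = _place_patches(config, rng)

    h, w = truth.shape
    swir_tf = GridTransform(config.swir_pixel_size, 0.0,
                            h * config.swir_pixel_size)
    vnir_tf = GridTransform(config.vnir_pixel_size, 0.0,
                            h * config.swir_pixel_size)
    swir_vals = _draw_class_spectra(truth, library, SWIR_BANDS, rng)

    vh, vw = config.vnir_shape
    # upsample truth to the VNIR grid by cell-centre containment
    vr = np.minimum(((np.arange(vh) + 0.5) * config.vnir_pixel_size
                     / config.swir_pixel_size).astype(int), h - 1)
    vc = np.minimum(((np.arange(vw) + 0.5) * config.vnir_pixel_size
                     / config.swir_pixel_size).astype(int), w - 1)
    vnir_truth = truth[np.ix_(vr, vc)]
    vnir_vals = _draw_class_spectra(vnir_truth, library, VNIR_BANDS, rng)

    swir = MultibandRaster(swir_vals, list(SWIR_BANDS), swir_tf, DEFAULT_CRS)
    vnir = MultibandRaster(vnir_vals, list(VNIR_BANDS), vnir_tf, DEFAULT_CRS)
    truth_raster = LabelRaster(truth, list(CLASS_NAMES), swir_tf, DEFAULT_CRS)
    return vnir, swir, truth_raster


# ---------------------------------------------------------------------------
# Training polygons
# ---------------------------------------------------------------------------

def scaled_training_plan(area_scale: float = 0.12,
                         count_scale: float = 1.0) -> dict:
    """The field-survey plan with areas (and optionally counts) rescaled.

    Used to fit the survey's polygon counts onto scenes much smaller than
    the real island.
    """
    return {c: (max(2, int(round(n * count_scale))), a * area_scale)
            for c, (n, a) in FIELD_TRAINING_PLAN.items()}


def _find_uniform_block(truth: np.ndarray, cidx: int, kr: int, kc: int,
                        rng: np.random.Generator, tries: int = 300):
    """Random search for a kr x kc all-``cidx`` block; None if not found."""
    h, w = truth.shape
    if kr > h or kc > w:
        return None
    rows, cols = np.nonzero(truth == cidx)
    if rows.size == 0:
        return None
    for _ in range(tries):
        i = rng.integers(rows.size)
        r0 = int(np.clip(rows[i] - rng.integers(kr), 0, h - kr))
        c0 = int(np.clip(cols[i] - rng.integers(kc), 0, w - kc))
        if np.all(truth[r0:r0 + kr, c0:c0 + kc] == cidx):
            return r0, c0
    return None


def generate_training_polygons(truth: LabelRaster, plan: dict, seed: int = 0,
                               area_tolerance: float = 0.25
                               ) -> list[LabeledPolygon]:
    """Rectangular training polygons wholly inside single-class regions.

    ``plan`` maps class name -> (feature count, target total area in m^2).
    Per-class counts match the plan exactly; per-class total areas land
    within ``area_tolerance`` of the target or a RuntimeError is raised.
    Rectangles are inset from cell edges so they are strictly inside the
    class region; their cells are exactly the enclosed cell centres.
    """
    rng = np.random.default_rng(seed)
    px = truth.pixel_size
    cell_area = px * px
    tf = truth.transform
    polygons: list[LabeledPolygon] = []
    pid = 0
    for cname, (count, target_area) in plan.items():
        if cname not in truth.class_names:
            raise ValueError(f"class {cname!r} absent from truth")
        cidx = truth.class_names.index(cname)
        if not np.any(truth.labels == cidx):
            raise ValueError(f"class {cname!r} absent from truth")
        target_cells = target_area / cell_area
        achieved_cells = 0
        achieved = 0.0
        for k in range(count):
            # adaptive per-feature target keeps the running total on track
            remaining = max(target_cells - achieved_cells, 1.0)
            n_cells = max(1, int(round(remaining / (count - k)
                                       * rng.uniform(0.8, 1.2))))
            kr = max(1, int(round(np.sqrt(n_cells))))
            kc_lo = max(1, n_cells // kr)
            kc = kc_lo if abs(kr * kc_lo - n_cells) <= \
                abs(kr * (kc_lo + 1) - n_cells) else kc_lo + 1
            block = None
            # shrink on failure, trying both aspect orders
            while block is None and kr * kc >= 1:
                block = _find_uniform_block(truth.labels, cidx, kr, kc, rng)
                if block is None and kr != kc:
                    block = _find_uniform_block(truth.labels, cidx, kc, kr,
                                                rng)
                    if block is not None:
                        kr, kc = kc, kr
                if block is None:
                    if kr >= kc and kr > 1:
                        kr -= 1
                    elif kc > 1:
                        kc -= 1
                    else:
                        break
            if block is None:
                raise RuntimeError(
                    f"could not place a training polygon for {cname!r}")
            r0, c0 = block
            inset = 0.05 * px
            x0 = tf.x0 + c0 * px + inset
            x1 = tf.x0 + (c0 + kc) * px - inset
            y1 = tf.y0 - r0 * px - inset
            y0 = tf.y0 - (r0 + kr) * px + inset
            polygons.append(LabeledPolygon(box(x0, y0, x1, y1), cname, pid))
            pid += 1
            achieved_cells += kr * kc
            achieved += kr * kc * cell_area
        if abs(achieved - target_area) > area_tolerance * target_area:
            raise RuntimeError(
                f"training area target unattainable for {cname!r}: "
                f"achieved {achieved:.0f} m^2 of {target_area:.0f} m^2")
    return polygons
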