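"""PCA component-substitution pan-sharpening and band stacking.

Sharpening raises the 3.7 m SWIR bands to the 1.2 m VNIR grid by replacing
the first principal component of the (resampled) SWIR bands with a
high-resolution intensity layer — here the per-pixel mean of the 8 VNIR
bands, affinely matched to PC1's mean and variance — and inverting the PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geo_io import MultibandRaster, resample


@dataclass
class SharpenConfig:
    method: str = "pca"
    histogram_match: bool = True

    def __post_init__(self) -> None:
        if self.method != "pca":
            raise ValueError("only the PCA method is supported")


def pansharpen_pca(swir: MultibandRaster, vnir: MultibandRaster,
                   cfg: SharpenConfig | None = None) -> MultibandRaster:
    """Sharpen SWIR to the VNIR grid by PC1 substitution.

    Steps: cubic-resample SWIR onto the VNIR grid; PCA across the resampled
    SWIR bands; build intensity as the VNIR band mean, mean/variance-matched
    to PC1; substitute PC1; invert the PCA.  If PC1 carries zero variance
    (spatially constant input) the resampled raster is returned unchanged.
    """
    if cfg is None:
        cfg = SharpenConfig()
    if vnir.pixel_size >= swir.pixel_size:
        raise ValueError("vnir grid must be finer than swir grid")
    if (abs(swir.transform.x0 - vnir.transform.x0) > 1e-6
            or abs(swir.transform.y0 - vnir.transform.y0) > 1e-6):
        raise ValueError("swir and vnir extents are not co-registered")
    up = resample(swir, vnir.pixel_size, method="cubic",
                  target_shape=vnir.shape)
    B = up.n_bands
    X = up.values.reshape(B, -1)
    mu = X.mean(axis=1, keepdims=True)
    Xc = X - mu
    cov = (Xc @ Xc.T) / (Xc.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # canonical sign: PC1 loads positively on overall brightness so the
    # substituted intensity has the right orientation
    if evecs[:, 0].sum() < 0:
        evecs[:, 0] = -evecs[:, 0]
    if evals[0] <= 1e-12:
        return replace(up, values=up.values.copy())
    if np.any(evals < -1e-6 * evals[0]):
        raise np.linalg.LinAlgError("rank-deficient PCA decomposition")
    scores = evecs.T @ Xc                    # (B, N)
    intensity = vnir.values.mean(axis=0).reshape(-1)
    if cfg.histogram_match:
        pc1 = scores[0]
        s_i = intensity.std()
        if s_i > 0:
            intensity = ((intensity - intensity.mean()) * (pc1.std() / s_i)
                         + pc1.mean())
        else:
            intensity = np.full_like(pc1, pc1.mean())
    scores = scores.copy()
    scores[0] = intensity
    out = (evecs @ scores + mu).reshape(up.values.shape)
    np.clip(out, 0.0, 255.0, out=out)
    return replace(up, values=out)


def stack_bands(a: MultibandRaster, b: MultibandRaster) -> MultibandRaster:
    """Concatenate two co-gridded rasters band-wise (a first)."""
    if a.shape != b.shape or abs(a.pixel_size - b.pixel_size) > 1e-9:
        raise ValueError("rasters must share an identical grid")
    if (abs(a.transform.x0 - b.transform.x0) > 1e-6
            or abs(a.transform.y0 - b.transform.y0) > 1e-6):
        raise ValueError("rasters must share an identical origin")
    values = np.concatenate([np.asarray(a.values, dtype=float),
                             np.asarray(b.values, dtype=float)], axis=0)
    return MultibandRaster(values=values,
                           band_names=list(a.band_names) + list(b.band_names),
                           transform=a.transform, crs=a.crs,
                           nodata=a.nodata if a.nodata == b.nodata else None)
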