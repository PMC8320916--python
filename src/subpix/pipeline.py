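"""Detection pipelines: preprocessing, blob extraction, centroiding and
optional PSF refinement behind one configuration object.

The named presets follow the algorithm variants compared on synthetic scenes:

======  =============================================================
alg01   plain moment method (manual threshold, i_base = 0, r = 1)
alg02   alg01 with i_base = threshold
alg03   alg02 preceded by a Hann filter (N = 5)
alg04   alg03 with the threshold chosen by Otsu's method
alg05   alg04 with gamma adjustment (gamma = 3)
alg06   alg01 + Hann filter (N = 5) + generalized-Gaussian fit
alg07   alg06 with the threshold chosen by Otsu's method
alg08   alg01 with search radius r = 1 (simply connected sets)
alg09   alg01 with search radius r > 1 (default 2.5)
alg10   alg01 + Hann filter (N = 5)
alg11   alg02 with a large manual threshold (default 190/255) and r = 1
alg12   alg11 + generalized-Gaussian fit
======  =============================================================

Stage order: gamma adjustment, Hann filtering, threshold selection, blob
extraction and constraint filtering, base-corrected centroiding — all on the
preprocessed image — then PSF refinement on the *original* image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .blob import (BlobConstraints, Detection, centroid, extract_blobs,
                   filter_blobs, moments)
from .preproc import gamma_adjust, hann_filter, intermodes_threshold, otsu_threshold
from .psf import (GenGaussParams, fit_particle, gengauss_peak,
                  partition_tiles)

__all__ = ["PipelineConfig", "ConfigError", "resolve_preset", "run_pipeline",
           "detections_to_frame", "PRESETS"]


class ConfigError(ValueError):
    """Invalid or conflicting pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """Full parameterization of one detection pipeline run.

    ``threshold`` (on the ``[0, 1]`` scale) is required in ``manual`` mode and
    forbidden otherwise.  ``i_base_mode`` selects the centroid base intensity:
    zero, or the resolved threshold.
    """

    preset: str = "custom"
    gamma: float | None = None
    hann_n: int | None = None
    threshold_mode: str = "manual"  # manual | otsu | intermodes
    threshold: float | None = None
    i_base_mode: str = "zero"  # zero | threshold
    search_radius: float = 1.0
    constraints: BlobConstraints = field(default_factory=BlobConstraints)
    fit_enabled: bool = False
    fit_amp: bool = True
    delta_max: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if self.threshold_mode not in ("manual", "otsu", "intermodes"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.i_base_mode not in ("zero", "threshold"):
            raise ConfigError(f"unknown i_base_mode {self.i_base_mode!r}")
        if self.threshold_mode == "manual":
            if self.threshold is None:
                raise ConfigError("manual threshold_mode requires a threshold value")
        elif self.threshold is not None:
            raise ConfigError(
                f"threshold value conflicts with threshold_mode={self.threshold_mode!r}")
        if self.gamma is not None and not self.gamma > 0:
            raise ConfigError("gamma must be > 0")
        if self.hann_n is not None and (self.hann_n < 3 or self.hann_n % 2 == 0):
            raise ConfigError("hann_n must be an odd integer >= 3")
        if not self.search_radius > 0:
            raise ConfigError("search_radius must be > 0")


# preset -> overrides on top of the alg01 baseline
_BASE = dict(threshold_mode="manual", i_base_mode="zero", search_radius=1.0,
             gamma=None, hann_n=None, fit_enabled=False)
PRESETS: dict[str, dict] = {
    "alg01": {},
    "alg02": dict(i_base_mode="threshold"),
    "alg03": dict(i_base_mode="threshold", hann_n=5),
    "alg04": dict(i_base_mode="threshold", hann_n=5, threshold_mode="otsu"),
    "alg05": dict(i_base_mode="threshold", hann_n=5, threshold_mode="otsu", gamma=3.0),
    "alg06": dict(hann_n=5, fit_enabled=True),
    "alg07": dict(hann_n=5, fit_enabled=True, threshold_mode="otsu"),
    "alg08": dict(search_radius=1.0),
    "alg09": dict(search_radius=2.5),
    "alg10": dict(hann_n=5),
    "alg11": dict(i_base_mode="threshold", threshold=190 / 255),
    "alg12": dict(i_base_mode="threshold", threshold=190 / 255, fit_enabled=True),
}


def resolve_preset(name: str, threshold: float | None = None, **overrides
                   ) -> PipelineConfig:
    """Expand a preset name into a fully determined configuration.

    ``threshold`` supplies the manual threshold where the preset needs one
    (alg01-alg03, alg06, alg08-alg10) or overrides a preset default (alg11,
    alg12).  Keyword overrides replace any other field, e.g.
    ``resolve_preset('alg09', 0.1, search_radius=2.5)``.
    """
    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}")
    params = dict(_BASE)
    params.update(PRESETS[name])
    if threshold is not None:
        params["threshold"] = threshold
    params.update(overrides)
    cfg = PipelineConfig(preset=name, **params)
    cfg.validate()
    return cfg


def run_pipeline(img: np.ndarray, cfg: PipelineConfig
                 ) -> tuple[list[Detection], dict]:
    """Run one full detection pass and return detections plus run metadata.

    Metadata records every resolved parameter and the threshold actually
    used, which is sufficient to re-run the pipeline bit-identically.
    """
    cfg.validate()
    original = np.asarray(img, dtype=float)
    work = original
    if cfg.gamma is not None:
        work = gamma_adjust(work, cfg.gamma)
    if cfg.hann_n is not None:
        work = hann_filter(work, cfg.hann_n)

    if cfg.threshold_mode == "manual":
        thr = float(cfg.threshold)
    elif cfg.threshold_mode == "otsu":
        thr = otsu_threshold(work).threshold
    else:
        thr = intermodes_threshold(work).threshold
    i_base = thr if cfg.i_base_mode == "threshold" else 0.0

    blobs = filter_blobs(extract_blobs(work, thr, cfg.search_radius),
                         cfg.constraints)
    detections: list[Detection] = []
    for b in blobs:
        try:
            xc, yc = centroid(b, i_base)
        except ValueError:
            xc, yc = centroid(b, 0.0)  # i_base too aggressive for this blob
        detections.append(Detection(x=xc, y=yc, blob=b, x_moment=xc, y_moment=yc))

    if cfg.fit_enabled and detections:
        _refine(original, detections, cfg)

    meta = {
        "preset": cfg.preset,
        "gamma": cfg.gamma,
        "hann_n": cfg.hann_n,
        "threshold_mode": cfg.threshold_mode,
        "threshold_used": thr,
        "i_base": i_base,
        "search_radius": cfg.search_radius,
        "constraints": cfg.constraints,
        "fit_enabled": cfg.fit_enabled,
        "fit_amp": cfg.fit_amp,
        "delta_max": cfg.delta_max,
        "seed": cfg.seed,
        "n_detections": len(detections),
    }
    return detections, meta


def _refine(original: np.ndarray, detections: list[Detection],
            cfg: PipelineConfig) -> None:
    """Fit the generalized-Gaussian PSF around every detection in place."""
    centers = np.array([[d.x, d.y] for d in detections])
    tiles = partition_tiles(centers, original.shape, delta_max=cfg.delta_max)
    for det, tile in zip(detections, tiles):
        init = _initial_params(original, det, tile)
        result = fit_particle(original, tile, init, fit_amp=cfg.fit_amp)
        det.fit = result
        det.fit_converged = result.converged
        if result.converged:
            det.x = result.params.x
            det.y = result.params.y


def _initial_params(original: np.ndarray, det: Detection, tile) -> GenGaussParams:
    """Moment-based initialization: sigma from second central moments, p = 2,
    background from the tile median, amplitude chosen so the model peak
    matches the brightest blob pixel above that background."""
    ms = moments(det.blob, max_order=2)
    m00 = ms.central[(0, 0)]
    var = 0.5 * (ms.central[(2, 0)] + ms.central[(0, 2)]) / m00 if m00 > 0 else 1.0
    sigma0 = float(np.clip(math.sqrt(max(var, 1e-4)), 0.2, 8.0))
    b0 = float(np.clip(np.median(tile.crop(original)), 0.0, 1.0))
    peak = max(float(det.blob.intensity.max()) - b0, 1e-4)
    amp0 = peak / gengauss_peak(sigma0, 2.0)
    x0 = float(np.clip(det.x, tile.x_lo, tile.x_hi))
    y0 = float(np.clip(det.y, tile.y_lo, tile.y_hi))
    return GenGaussParams(x=x0, y=y0, sigma=sigma0, p=2.0, b=b0, amp=amp0)


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    """Detections as a table: ``id,x,y,n_pixels,sum_intensity,xd,yd`` plus
    streak and fit columns when present."""
    rows = []
    for i, d in enumerate(detections):
        row = {
            "id": i, "x": d.x, "y": d.y,
            "x_moment": d.x_moment, "y_moment": d.y_moment,
            "n_pixels": len(d.blob),
            "sum_intensity": float(d.blob.intensity.sum()),
            "xd": d.blob.extent_x, "yd": d.blob.extent_y,
        }
        if d.streak is not None:
            row["angle_deg"] = d.streak.angle_deg
            row["length_px"] = d.streak.length
        if d.fit is not None:
            pr = d.fit.params
            row.update(x_fit=pr.x, y_fit=pr.y, sigma_fit=pr.sigma, p_fit=pr.p,
                       b_fit=pr.b, amp_fit=pr.amp, converged=d.fit.converged,
                       objective=d.fit.objective)
        rows.append(row)
    return pd.DataFrame(rows)
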