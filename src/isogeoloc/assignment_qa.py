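"""Probabilistic geographic assignment and split-sample quality assessment.

Given a tissue isoscape (mean mu(x), sd sigma(x)), the posterior
probability that a sample with measured value y originated in cell x is
the normal density N(y; mu(x), sigma(x)) normalized over the study area
with cos(latitude) cell-area weights (lon/lat grids are not equal-area,
and assignment regions are *area* statements).

Assignment regions take cells in decreasing posterior-density order until
a fraction q of the total area is covered. Quality assessment (QA) is an
iterated split-sample test: the dataset is randomly split into calibration
and validation sets, a tissue isoscape is fitted on the calibration set,
and for each validation sample and each area quantile q we record whether
the cell containing its reported origin falls inside the top-q region.
The accuracy-vs-q curve summarizes how geographically specific assignments
from the dataset can be; random (uninformative) data give accuracy = q.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationError, TissueIsoscape, calibrate, predict_tissue_isoscape
from .data_model import Dataset
from .isoscape import Raster

logger = logging.getLogger("isogeoloc")

__all__ = [
    "PosteriorSurface",
    "QAResult",
    "QAConfig",
    "posterior_surface",
    "assignment_region",
    "qa",
    "compare_qa",
]

NORMALIZATION_TOL = 1e-8


@dataclass
class PosteriorSurface:
    """Per-cell posterior probability density of origin for one sample.

    Normalized so that sum over valid cells of prob * area_weight = 1,
    where area weights are the normalized cos(latitude) weights of the
    raster. All probabilities are >= 0; nodata cells are NaN.
    """

    probs: Raster
    sample_id: str = ""

    def __post_init__(self) -> None:
        w = self.probs.area_weights()
        valid = self.probs.valid_mask()
        total = float(np.nansum(self.probs.values[valid] * w[valid]))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"posterior not normalized (area-weighted sum {total})")
        if np.any(self.probs.values[valid] < 0):
            raise ValueError("negative posterior probability")


def posterior_surface(obs: float, iso: TissueIsoscape, sample_id: str = "") -> PosteriorSurface:
    """Normal-likelihood posterior of origin for one measured value.

    Per valid cell i: f_i = phi((obs - mu_i)/sigma_i)/sigma_i, then
    normalized by the area-weighted sum. A flat prior over area is
    implicit in the area weighting.
    """
    if not np.isfinite(obs):
        raise ValueError(f"observed value must be finite, got {obs!r}")
    mu = iso.mean.values
    sd = iso.sd.values
    valid = iso.mean.valid_mask()
    w = iso.mean.area_weights()

    dens = np.full(mu.shape, np.nan)
    z = (obs - mu[valid]) / sd[valid]
    # log-space for numerical range; constant factors cancel in normalization
    logf = -0.5 * z**2 - np.log(sd[valid])
    logf -= logf.max()
    f = np.exp(logf)
    total = float((f * w[valid]).sum())
    dens[valid] = f / total
    return PosteriorSurface(probs=iso.mean.copy_with(dens), sample_id=sample_id)


def assignment_region(post: PosteriorSurface, q: float) -> np.ndarray:
    """Boolean grid of the smallest top-density region covering area q.

    Valid cells are sorted by posterior density descending (ties broken by
    row-major cell index); the region is the shortest prefix whose
    cumulative area weight reaches q.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError("area fraction q must be in (0, 1]")
    grid = post.probs
    valid = grid.valid_mask()
    w = grid.area_weights()
    flat_idx = np.flatnonzero(valid.ravel())
    dens = grid.values.ravel()[flat_idx]
    # stable sort on -density keeps row-major order within ties
    order = np.argsort(-dens, kind="stable")
    chosen = flat_idx[order]
    cumw = np.cumsum(w.ravel()[chosen])
    # number of cells needed to reach cumulative area >= q
    k = int(np.searchsorted(cumw, q - 1e-12) + 1)
    k = min(k, len(chosen))
    region = np.zeros(grid.values.size, dtype=bool)
    region[chosen[:k]] = True
    return region.reshape(grid.shape)


@dataclass
class QAConfig:
    n_iterations: int = 10
    validation_fraction: float = 0.25
    q_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.01, 1.001, 0.01), 2))
    weighting: str = "site_frequency"
    seed: int = 0
    split_by_site: bool = False


@dataclass
class QAResult:
    """Accuracy-vs-area-quantile curve from iterated split-sample validation."""

    area_quantiles: np.ndarray
    accuracy: np.ndarray
    n_iterations: int
    n_validation: int
    seed: int
    config: dict = field(default_factory=dict)

    def accuracy_at(self, q: float) -> float:
        idx = int(np.argmin(np.abs(self.area_quantiles - q)))
        return float(self.accuracy[idx])

    def to_json(self) -> str:
        return json.dumps(
            {
                "area_quantiles": self.area_quantiles.tolist(),
                "accuracy": self.accuracy.tolist(),
                "n_iterations": self.n_iterations,
                "n_validation": self.n_validation,
                "seed": self.seed,
                "config": self.config,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "QAResult":
        d = json.loads(text)
        return cls(
            area_quantiles=np.asarray(d["area_quantiles"], dtype=float),
            accuracy=np.asarray(d["accuracy"], dtype=float),
            n_iterations=int(d["n_iterations"]),
            n_validation=int(d["n_validation"]),
            seed=int(d["seed"]),
            config=d.get("config", {}),
        )


def _split(dataset: Dataset, cfg: QAConfig, rng: np.random.Generator) -> tuple[Dataset, Dataset]:
    records = list(dataset)
    if cfg.split_by_site:
        sites = sorted({r.site_id for r in records})
        n_val = max(1, int(round(cfg.validation_fraction * len(sites))))
        val_sites = set(rng.choice(sites, size=n_val, replace=False))
        val = [r for r in records if r.site_id in val_sites]
        cal = [r for r in records if r.site_id not in val_sites]
    else:
        n_val = max(1, int(round(cfg.validation_fraction * len(records))))
        idx = rng.permutation(len(records))
        val_idx = set(idx[:n_val].tolist())
        val = [r for i, r in enumerate(records) if i in val_idx]
        cal = [r for i, r in enumerate(records) if i not in val_idx]
    return Dataset(cal, dataset.provenance), Dataset(val, dataset.provenance)


def qa(dataset: Dataset, env: Raster, config: QAConfig | None = None) -> QAResult:
    """Iterated split-sample quality assessment of geographic assignment.

    Per iteration: seeded random split into calibration/validation sets;
    calibrate on the calibration set and predict a tissue isoscape; for
    each validation sample compute its posterior surface and record, for
    every q in the grid, whether the cell containing its reported origin
    lies inside the top-q assignment region. Accuracy is averaged over all
    validation samples across iterations. Fully reproducible per seed.

    "Correct" means the origin's cell is in the region — a cell-membership
    criterion, not a distance buffer.
    """
    cfg = config or QAConfig()
    rng = np.random.default_rng(cfg.seed)
    q_grid = np.asarray(cfg.q_grid, dtype=float)
    hits = np.zeros(len(q_grid))
    n_total = 0
    n_skipped = 0

    # precompute sort-free structures reused across samples
    for it in range(cfg.n_iterations):
        cal, val = _split(dataset, cfg, rng)
        try:
            fit = calibrate(cal, env, weighting=cfg.weighting)
        except CalibrationError as exc:
            logger.warning("QA iteration %d skipped: %s", it, exc)
            n_skipped += 1
            continue
        iso = predict_tissue_isoscape(fit, env)
        w = iso.mean.area_weights()
        valid = iso.mean.valid_mask()
        for rec in val:
            try:
                row, col = iso.mean.index_of(rec.longitude, rec.latitude)
            except Exception:
                continue
            if not valid[row, col]:
                continue
            post = posterior_surface(rec.value, iso, sample_id=rec.sample_id)
            # rank the origin cell once instead of building every region:
            # origin is inside the top-q region iff cumulative area of cells
            # with density >= (density at origin, with row-major tie-break)
            # is <= ... equivalently q >= cumw at the origin's rank.
            flat_idx = np.flatnonzero(valid.ravel())
            dens = post.probs.values.ravel()[flat_idx]
            order = np.argsort(-dens, kind="stable")
            chosen = flat_idx[order]
            cumw = np.cumsum(w.ravel()[chosen])
            origin_flat = row * iso.mean.shape[1] + col
            rank = int(np.flatnonzero(chosen == origin_flat)[0])
            q_needed = cumw[rank]
            hits += (q_grid >= q_needed - 1e-12).astype(float)
            n_total += 1

    if n_total == 0:
        raise RuntimeError("QA produced no validation evaluations (all iterations skipped)")
    accuracy = hits / n_total
    return QAResult(
        area_quantiles=q_grid,
        accuracy=accuracy,
        n_iterations=cfg.n_iterations - n_skipped,
        n_validation=n_total,
        seed=cfg.seed,
        config={
            "validation_fraction": cfg.validation_fraction,
            "weighting": cfg.weighting,
            "split_by_site": cfg.split_by_site,
        },
    )


def compare_qa(uncorrected: QAResult, corrected: QAResult) -> dict:
    """Per-quantile accuracy difference (corrected - uncorrected).

    Requires identical q grids; returns the per-q delta and its mean.
    """
    if len(uncorrected.area_quantiles) != len(corrected.area_quantiles) or not np.allclose(
        uncorrected.area_quantiles, corrected.area_quantiles
    ):
        raise ValueError("QA results have mismatched area-quantile grids")
    delta = corrected.accuracy - uncorrected.accuracy
    return {
        "area_quantiles": uncorrected.area_quantiles.tolist(),
        "delta_accuracy": delta.tolist(),
        "mean_delta": float(delta.mean()),
    }
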