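"""First-order and gray-level co-occurrence texture features on masked volumes.

Texture is computed inside a binary structure mask on a 3-D intensity
volume.  First-order features (mean, SD, skewness, kurtosis) describe the
in-mask gray-level distribution; second-order Haralick features are
derived from a gray-level co-occurrence matrix (GLCM) accumulated over
the 26 neighbour offsets of the 3-D Chebyshev-1 neighbourhood at distance
1 voxel.  A pair is counted only when both voxels lie inside the mask, so
no padding value is ever invented at the boundary.  Because every offset
and its opposite are both included, the accumulated matrix is symmetric
by construction; it is normalized to sum 1 once all offsets are in.

Conventions (configurable, reported with results): intensities are
quantized into 32 equal-width bins between the in-mask min and max;
entropy is in bits (log base 2); kurtosis is the Pearson standardized
fourth moment (normal distribution = 3, not 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDesignError, ValidationError

__all__ = [
    "FIRST_ORDER_FEATURES",
    "HARALICK_FEATURES",
    "ALL_FEATURES",
    "OFFSETS_26",
    "MaskedVolume",
    "GLCMConfig",
    "first_order_features",
    "quantize",
    "glcm_26",
    "haralick_features",
    "texture_features",
    "select_features",
]

FIRST_ORDER_FEATURES = ("mean", "sd", "kurtosis", "skewness")
HARALICK_FEATURES = (
    "contrast", "entropy", "correlation", "variance",
    "sum_average", "sum_variance", "inverse_difference_moment",
)
ALL_FEATURES = FIRST_ORDER_FEATURES + HARALICK_FEATURES

#: The 26 nonzero displacement triples in {-1, 0, 1}^3.
OFFSETS_26 = tuple(
    (i, j, k)
    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
)


@dataclass
class MaskedVolume:
    """3-D intensity array restricted to a binary structure mask."""

    intensities: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    structure_id: str = "structure"

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be a 3-D array")
        if self.intensities.shape != self.mask.shape:
            raise ValidationError("mask shape must match intensities")
        if not self.mask.any():
            raise ValidationError("mask is empty")
        if not np.all(np.isfinite(self.intensities[self.mask])):
            raise ValidationError("non-finite intensities inside mask")

    @property
    def values(self) -> np.ndarray:
        """In-mask intensities as a flat vector."""
        return self.intensities[self.mask]


@dataclass
class GLCMConfig:
    n_levels: int = 32
    distance: int = 1
    offsets: tuple = OFFSETS_26

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValidationError("n_levels must be >= 2")
        if self.distance < 1:
            raise ValidationError("distance must be >= 1")
        if len(self.offsets) != 26:
            raise ValidationError("expected exactly 26 offsets")


def first_order_features(vol: MaskedVolume) -> dict[str, float]:
    """Mean, SD, Pearson kurtosis and skewness of in-mask intensities."""
    x = vol.values
    if x.size < 4:
        raise ValidationError("need at least 4 in-mask voxels")
    mean = float(x.mean())
    sd = float(x.std())
    if sd == 0:
        raise DegenerateDesignError(
            "constant in-mask intensities: kurtosis/skewness undefined"
        )
    z = (x - mean) / sd
    return {
        "mean": mean,
        "sd": sd,
        "kurtosis": float(np.mean(z**4)),   # Pearson: normal -> 3
        "skewness": float(np.mean(z**3)),
    }


def quantize(vol: MaskedVolume, n_levels: int = 32) -> np.ndarray:
    """Equal-width quantization of in-mask intensities into 1..n_levels.

    Out-of-mask voxels are labeled 0 (background).  The in-mask minimum
    maps to level 1 and the maximum to level n_levels; a constant volume
    collapses to a single level.
    """
    if n_levels < 2:
        raise ValidationError("n_levels must be >= 2")
    x = vol.values
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(vol.intensities.shape, dtype=np.int32)
    if hi == lo:
        levels[vol.mask] = 1
        return levels
    scaled = (x - lo) / (hi - lo) * n_levels
    binned = np.minimum(np.floor(scaled).astype(np.int32) + 1, n_levels)
    levels[vol.mask] = binned
    return levels


def glcm_26(levels: np.ndarray, mask: np.ndarray,
            config: GLCMConfig | None = None) -> np.ndarray:
    """Normalized co-occurrence matrix over the 26 distance-D offsets.

    ``levels`` holds labels 1..n_levels (0 = background).  For every
    offset, each ordered voxel pair with both endpoints inside the mask
    contributes one count; pairs crossing the mask or the array boundary
    are skipped.
    """
    config = config or GLCMConfig()
    mask = np.asarray(mask).astype(bool)
    n = config.n_levels
    d = config.distance
    counts = np.zeros((n, n), dtype=np.int64)
    shape = levels.shape

    for off in config.offsets:
        off = tuple(o * d for o in off)
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)
        )
        valid = mask[src] & mask[dst]
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        np.add.at(counts, (a, b), 1)

    total = counts.sum()
    if total == 0:
        raise DegenerateDesignError("no valid in-mask voxel pair (empty GLCM)")
    return counts / total


def haralick_features(P: np.ndarray, tol: float = 1e-8,
                      log_base: float = 2.0) -> dict[str, float]:
    """Seven Haralick features from a normalized GLCM.

    Levels are indexed 1..n for the moment computations.  sum_variance is
    centered on sum_average (modern convention).  correlation requires
    nonzero marginal SDs.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("GLCM must be square")
    if np.any(P < 0) or abs(P.sum() - 1.0) > tol:
        raise ValidationError("GLCM must be nonnegative and sum to 1")
    n = P.shape[0]
    i = np.arange(1, n + 1)
    I, J = np.meshgrid(i, i, indexing="ij")

    contrast = float(np.sum((I - J) ** 2 * P))
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log(nz) / np.log(log_base)))

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))
    if sd_x * sd_y == 0:
        raise DegenerateDesignError("zero marginal SD: correlation undefined")
    correlation = float(np.sum((I - mu_x) * (J - mu_y) * P) / (sd_x * sd_y))

    mu = (mu_x + mu_y) / 2.0
    variance = float(np.sum((I - mu) ** 2 * P))

    # distribution of the level sum i + j, support 2..2n
    k = np.arange(2, 2 * n + 1)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (I + J).ravel() - 2, P.ravel())
    sum_average = float(k @ p_sum)
    sum_variance = float(np.sum((k - sum_average) ** 2 * p_sum))

    idm = float(np.sum(P / (1.0 + (I - J) ** 2)))
    return {
        "contrast": contrast,
        "entropy": entropy,
        "correlation": correlation,
        "variance": variance,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "inverse_difference_moment": idm,
    }


def texture_features(vol: MaskedVolume, n_levels: int = 32) -> dict[str, float]:
    """All 11 texture features (4 first-order + 7 GLCM) for one structure."""
    feats = first_order_features(vol)
    levels = quantize(vol, n_levels)
    P = glcm_26(levels, vol.mask, GLCMConfig(n_levels=n_levels))
    feats.update(haralick_features(P))
    return feats


def select_features(features: pd.DataFrame, subtype_codes,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Correlation-based feature selection against the ordinal subtype code.

    ``features`` is a tidy table (subject_id, structure_id, feature,
    value) aligned with ``subtype_codes`` through subject_id; each
    (structure, feature) is Spearman-correlated with the subtype code and
    retained when its raw p < alpha.  Constant features are skipped with a
    warning.  Returns the per-feature table with rho, p and a
    ``selected`` flag; downstream group tests should be run on the
    selected rows with FDR across them.
    """
    required = {"subject_id", "structure_id", "feature", "value"}
    if not required.issubset(features.columns):
        raise ValidationError(f"feature table needs columns {sorted(required)}")
    codes = pd.Series(subtype_codes)
    rows = []
    for (structure, feature), grp in features.groupby(
            ["structure_id", "feature"], sort=True):
        vals = grp.set_index("subject_id")["value"]
        common = vals.index.intersection(codes.index)
        x = vals.loc[common].to_numpy(dtype=float)
        y = codes.loc[common].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(
                f"constant feature skipped: {structure}/{feature}")
            continue
        rho, p = sps.spearmanr(x, y)
        rows.append({
            "structure_id": structure, "feature": feature,
            "rho": float(rho), "p_raw": float(p),
            "selected": bool(p < alpha), "n": len(common),
        })
    return pd.DataFrame.from_records(rows)
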