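"""Histogram and gray-level co-occurrence (GLCM) texture features.

Each trabecular ROI yields a fixed 45-entry feature vector:

* 5 first-order histogram statistics of the in-ROI HU values — mean,
  sample standard deviation, skewness, kurtosis, and Shannon entropy
  (k = 1..5);
* 40 second-order GLCM statistics: for each of 2 offset directions
  (l = 1 horizontal, l = 2 vertical) and 4 gray-level counts
  (m = 1..4 ↦ n_levels 16, 32, 64, 128), one GLCM is accumulated — eight
  matrices per ROI — and summarized by 5 statistics (n = 1..5: contrast,
  correlation, energy, homogeneity, variance).

Features are placed at a unique index j in 1..45:
``j = k`` for histogram features and ``j = 5 + (l−1)·20 + (m−1)·5 + n``
for GLCM features — the lexicographic (l, m, n) order.

For longitudinal analysis, the two timepoints' 45-vectors are
concatenated into a 90-entry change design whose target is the BMC (or
BMD) difference.

Conventions, fixed for bit-reproducibility: gray levels are ROI-relative
equal-width bins over [min, max] with half-open bins and a closed top
edge, levels labelled 1..n; GLCM accumulation is asymmetric over ordered
distance-1 pixel pairs with both pixels in the ROI; constant-ROI
degenerate statistics are 0 (and energy/homogeneity 1 for the
single-entry GLCM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import MIN_ROI_PIXELS, CTSlice, CTVolume, ROIMask
from .exceptions import ConfigurationError, ROIFragmentedError, ROITooSmallError
from . import roi as _roi

__all__ = [
    "LEVEL_COUNTS",
    "DIRECTIONS",
    "N_FEATURES",
    "N_CHANGE_FEATURES",
    "QuantizedROI",
    "GLCM",
    "FeatureVector",
    "ChangeDesign",
    "histogram_statistics",
    "histogram_features",
    "quantize_roi",
    "compute_glcm",
    "glcm_statistics",
    "feature_index",
    "feature_names",
    "extract_feature_vector",
    "build_change_design",
    "TextureFeatureExtractor",
]

LEVEL_COUNTS: Tuple[int, ...] = (16, 32, 64, 128)
DIRECTIONS: Tuple[str, str] = ("horizontal", "vertical")
HISTOGRAM_STATS: Tuple[str, ...] = ("mean", "std", "skewness", "kurtosis", "entropy")
GLCM_STATS: Tuple[str, ...] = ("contrast", "correlation", "energy", "homogeneity", "variance")
N_FEATURES = 45
N_CHANGE_FEATURES = 90
ENTROPY_BINS = 64

_OFFSETS: Dict[str, Tuple[int, int]] = {"horizontal": (0, 1), "vertical": (1, 0)}


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class QuantizedROI:
    """ROI re-expressed on gray levels 1..n; 0 marks out-of-ROI pixels."""

    levels: np.ndarray  # int array, 0 outside ROI
    n: int

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=np.int64)
        object.__setattr__(self, "levels", levels)
        inside = levels[levels > 0]
        if inside.size and (inside.min() < 1 or inside.max() > self.n):
            raise ValueError("in-ROI levels must lie in [1, n]")


@dataclass(frozen=True)
class GLCM:
    """Co-occurrence counts and probabilities for one direction and level count."""

    counts: np.ndarray  # (n, n) nonnegative ints
    probs: np.ndarray  # (n, n), sums to 1
    direction: str
    n: int

    def __post_init__(self) -> None:
        if self.counts.shape != (self.n, self.n):
            raise ValueError("counts must be n×n")
        total = self.probs.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"probs must sum to 1, got {total}")


@dataclass(frozen=True)
class FeatureVector:
    """The 45 indexed features of one ROI; ``values[j-1]`` is feature j."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "values", values)

    def __getitem__(self, j: int) -> float:
        """1-based access by feature index j."""
        if not 1 <= j <= N_FEATURES:
            raise IndexError(f"feature index {j} outside 1..{N_FEATURES}")
        return float(self.values[j - 1])


@dataclass(frozen=True)
class ChangeDesign:
    """Concatenated two-timepoint features with the change target."""

    values: np.ndarray  # length 90: timepoint 1 then timepoint 2
    target: float  # y2 - y1 (g or g/cm^2)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_CHANGE_FEATURES,):
            raise ValueError(f"expected {N_CHANGE_FEATURES} values")
        object.__setattr__(self, "values", values)


# ---------------------------------------------------------------------------
# first-order statistics

def histogram_statistics(x: np.ndarray) -> np.ndarray:
    """Mean, sample SD, skewness, kurtosis, entropy of a value sample.

    Skewness and kurtosis are the third/fourth central moments scaled by
    the sample SD (so a constant sample yields 0 for both by convention);
    entropy is the Shannon entropy in bits of a 64-bin equal-width
    histogram over [min, max], 0 for a constant sample.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ROITooSmallError("histogram statistics need at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return np.array([mean, 0.0, 0.0, 0.0, 0.0])
    centred = x - mean
    skew = float((centred**3).mean() / sd**3)
    kurt = float((centred**4).mean() / sd**4)
    counts, _ = np.histogram(x, bins=ENTROPY_BINS, range=(x.min(), x.max()))
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    return np.array([mean, sd, skew, kurt, entropy])


def histogram_features(slc: CTSlice, mask: ROIMask) -> np.ndarray:
    """First-order statistics of the in-ROI HU; see :func:`histogram_statistics`."""
    x = mask.pixel_values(slc)
    if x.size < MIN_ROI_PIXELS:
        raise ROITooSmallError(f"{x.size} in-ROI pixels < {MIN_ROI_PIXELS}")
    return histogram_statistics(x)


# ---------------------------------------------------------------------------
# quantization and co-occurrence

def quantize_roi(slc: CTSlice, mask: ROIMask, n: int) -> QuantizedROI:
    """Bin in-ROI HU into equal-width gray levels 1..n over [min, max].

    Bins are half-open with the top edge closed (the maximum maps to n);
    a constant ROI maps everything to level 1.
    """
    if n < 2:
        raise ConfigurationError("gray-level count n must be >= 2")
    x = mask.pixel_values(slc)
    if x.size < MIN_ROI_PIXELS:
        raise ROITooSmallError(f"{x.size} in-ROI pixels < {MIN_ROI_PIXELS}")
    levels = np.zeros(slc.shape, dtype=np.int64)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        levels[mask.mask] = 1
        return QuantizedROI(levels=levels, n=n)
    binned = np.floor((slc.hu - lo) / (hi - lo) * n).astype(np.int64) + 1
    np.clip(binned, 1, n, out=binned)
    levels[mask.mask] = binned[mask.mask]
    return QuantizedROI(levels=levels, n=n)


def compute_glcm(q: QuantizedROI, direction: str) -> GLCM:
    """Accumulate the asymmetric distance-1 co-occurrence matrix.

    ``counts[i-1, j-1]`` is the number of ordered pixel pairs
    (p, p+offset) with both pixels in the ROI, level(p)=i and
    level(p+offset)=j; the offset is (0, +1) for ``horizontal`` and
    (+1, 0) for ``vertical``.  No reverse-pair accumulation is performed.
    """
    if direction not in _OFFSETS:
        raise ConfigurationError(f"direction must be one of {DIRECTIONS}")
    dr, dc = _OFFSETS[direction]
    lv = q.levels
    a = lv[: lv.shape[0] - dr, : lv.shape[1] - dc]
    b = lv[dr:, dc:]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        raise ROIFragmentedError("no in-ROI pixel pair at the co-occurrence offset")
    i = a[valid] - 1
    j = b[valid] - 1
    counts = np.bincount(i * q.n + j, minlength=q.n * q.n).reshape(q.n, q.n)
    probs = counts / counts.sum()
    return GLCM(counts=counts, probs=probs, direction=direction, n=q.n)


def glcm_statistics(g: GLCM) -> np.ndarray:
    """Contrast, correlation, energy, homogeneity, variance of a GLCM.

    Level indices run 1..n.  With marginal means/SDs μ_i, μ_j, σ_i, σ_j:
    contrast = Σ (i−j)² p;  correlation = (Σ i·j·p − μ_i μ_j)/(σ_i σ_j)
    (0 when σ_i σ_j = 0);  energy = Σ p²;  homogeneity = Σ p/(1+|i−j|);
    variance = Σ (i−μ_i)² p.
    """
    p = g.probs
    idx = np.arange(1, g.n + 1, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(idx @ pi)
    mu_j = float(idx @ pj)
    var_i = float(((idx - mu_i) ** 2) @ pi)
    var_j = float(((idx - mu_j) ** 2) @ pj)
    contrast = float(((i - j) ** 2 * p).sum())
    denom = np.sqrt(var_i * var_j)
    if denom == 0.0:
        correlation = 0.0
    else:
        correlation = float(((i * j * p).sum() - mu_i * mu_j) / denom)
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    variance = float(((i - mu_i) ** 2 * p).sum())
    return np.array([contrast, correlation, energy, homogeneity, variance])


# ---------------------------------------------------------------------------
# feature indexing and assembly

def feature_index(kind: str, *, k: int | None = None, l: int | None = None,
                  m: int | None = None, n: int | None = None) -> int:
    """Map a feature label to its unique index j in 1..45.

    Histogram statistic k ↦ j = k; GLCM statistic (direction l, level-set
    m, statistic n) ↦ j = 5 + (l−1)·20 + (m−1)·5 + n.
    """
    if kind == "histogram":
        if k is None or not 1 <= k <= 5:
            raise ConfigurationError("histogram statistic k must be in 1..5")
        return k
    if kind == "glcm":
        if l is None or not 1 <= l <= 2:
            raise ConfigurationError("direction l must be in 1..2")
        if m is None or not 1 <= m <= 4:
            raise ConfigurationError("level-set m must be in 1..4")
        if n is None or not 1 <= n <= 5:
            raise ConfigurationError("statistic n must be in 1..5")
        return 5 + (l - 1) * 20 + (m - 1) * 5 + n
    raise ConfigurationError("kind must be 'histogram' or 'glcm'")


def feature_names() -> List[str]:
    """Human-readable names in index order, ``names[j-1]`` for feature j."""
    names = [f"hist_{s}" for s in HISTOGRAM_STATS]
    for l, direction in enumerate(DIRECTIONS, start=1):
        for m, n_levels in enumerate(LEVEL_COUNTS, start=1):
            for stat in GLCM_STATS:
                names.append(f"glcm_{direction}_n{n_levels}_{stat}")
    return names


def extract_feature_vector(slc: CTSlice, mask: ROIMask) -> FeatureVector:
    """Compute all 45 features of one ROI.

    Builds exactly eight GLCMs (2 directions × 4 level counts) and five
    statistics per matrix, plus the five histogram statistics, placed by
    :func:`feature_index`.
    """
    values = np.empty(N_FEATURES)
    values[0:5] = histogram_features(slc, mask)
    for m, n_levels in enumerate(LEVEL_COUNTS, start=1):
        q = quantize_roi(slc, mask, n_levels)
        for l, direction in enumerate(DIRECTIONS, start=1):
            stats = glcm_statistics(compute_glcm(q, direction))
            for n_stat in range(1, 6):
                j = feature_index("glcm", l=l, m=m, n=n_stat)
                values[j - 1] = stats[n_stat - 1]
    return FeatureVector(values=values)


def build_change_design(
    fv1: FeatureVector, fv2: FeatureVector, y1: float, y2: float
) -> ChangeDesign:
    """Concatenate a subject's two timepoint vectors; target is y2 − y1."""
    values = np.concatenate([fv1.values, fv2.values])
    return ChangeDesign(values=values, target=float(y2) - float(y1))


# ---------------------------------------------------------------------------
# scikit-learn adapter

class TextureFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: CT volumes/slices → (n_cases, 45) features.

    Composes with sklearn pipelines: each input item may be a
    :class:`CTVolume` (slice selection + thresholding + circular ROI are
    applied with this extractor's parameters), a :class:`CTSlice`
    (thresholding + circular ROI only) or a ``(CTSlice, ROIMask)`` pair.

    Parameters
    ----------
    hu_low, hu_high : float
        Trabecular HU window for thresholding.
    shrink : float
        Radius shrink factor of the circular ROI, in (0, 1].
    """

    def __init__(
        self,
        hu_low: float = _roi.DEFAULT_HU_WINDOW[0],
        hu_high: float = _roi.DEFAULT_HU_WINDOW[1],
        shrink: float = _roi.DEFAULT_SHRINK,
    ) -> None:
        self.hu_low = hu_low
        self.hu_high = hu_high
        self.shrink = shrink

    def fit(self, X: Sequence, y=None) -> "TextureFeatureExtractor":
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        rows = [self._extract_one(item).values for item in X]
        return np.asarray(rows)

    def _extract_one(
        self, item: Union[CTVolume, CTSlice, Tuple[CTSlice, ROIMask]]
    ) -> FeatureVector:
        if isinstance(item, CTVolume):
            _, slc = _roi.select_largest_trabecular_slice(
                item, self.hu_low, self.hu_high
            )
            mask = _roi.circular_trabecular_roi(
                slc, self.hu_low, self.hu_high, self.shrink
            )
        elif isinstance(item, CTSlice):
            slc = item
            mask = _roi.circular_trabecular_roi(
                slc, self.hu_low, self.hu_high, self.shrink
            )
        else:
            slc, mask = item
        return extract_feature_vector(slc, mask)
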