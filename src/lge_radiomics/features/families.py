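"""Feature formulas for the five texture families plus first-order statistics.

Definitions follow the standard reference formulations used throughout the
radiomics literature (gray levels indexed from 1, logarithms base 2,
0*log(0) := 0).  Degenerate inputs — a single occupied gray level, zero
variance — take their closed-form constant-image values instead of NaN, so
every feature is finite on every non-empty ROI.
"""

from __future__ import annotations

import numpy as np

from ..core import QuantizedROI
from .matrices import (
    CooccurrenceMatrix,
    DependenceMatrix,
    NeighborhoodDifferenceTable,
    RunLengthMatrix,
    SizeZoneMatrix,
)

__all__ = [
    "glcm_features",
    "ngtdm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "firstorder_features",
]

_EPS = np.finfo(float).eps


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy(p: np.ndarray) -> float:
    return float(-_xlog2x(p).sum())


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """Full co-occurrence feature family.

    Includes the two signature members used downstream: Autocorrelation
    (sum_ij i*j*p(i,j), large for coarse/rough texture) and DifferenceEntropy
    (entropy of the |i-j| margin, in bits).
    """
    ng = m.n_levels
    p = m.p
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sigma_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # difference margin p_{x-y}(k), k = 0..Ng-1
    k_diff = np.abs(ii - jj)
    p_diff = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=ng)[:ng]
    kd = np.arange(ng)
    # sum margin p_{x+y}(k), k = 2..2Ng
    k_sum = ii + jj
    p_sum = np.bincount(k_sum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    ks = np.arange(2, 2 * ng + 1)

    diff_avg = float((kd * p_diff).sum())
    hxy = _entropy(p)
    hx = _entropy(px)
    hy = _entropy(py)
    pxy_outer = np.outer(px, py)
    hxy1 = float(-(p * np.where(pxy_outer > 0, np.log2(pxy_outer + _EPS), 0.0)).sum())
    hxy2 = _entropy(pxy_outer)

    corr_num = float((ii * jj * p).sum()) - mu_x * mu_y
    correlation = 1.0 if sigma_x * sigma_y == 0 else corr_num / (sigma_x * sigma_y)
    imc1 = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    features = {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float(((kd - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + k_diff)).sum()),
        "Idm": float((p / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p / (1.0 + k_diff**2 / ng**2)).sum()),
        "Idn": float((p / (1.0 + k_diff / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p[off] / k_diff[off] ** 2).sum()),
        "JointAverage": mu_x,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((ks * p_sum).sum()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
    }
    return features


def ngtdm_features(t: NeighborhoodDifferenceTable) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity and Strength."""
    i = np.arange(1, t.n_levels + 1, dtype=float)
    p, s = t.p, t.s
    nz = p > 0
    n_gp = int(nz.sum())
    n_v = t.n_valid

    ps = float((p * s).sum())
    coarseness = min(1.0 / ps, 1e6) if ps > 0 else 1e6

    if n_gp > 1:
        ii, jj = np.meshgrid(i[nz], i[nz], indexing="ij")
        pi_, pj_ = np.meshgrid(p[nz], p[nz], indexing="ij")
        si_, sj_ = np.meshgrid(s[nz], s[nz], indexing="ij")
        contrast = (
            float((pi_ * pj_ * (ii - jj) ** 2).sum()) / (n_gp * (n_gp - 1))
        ) * (float(s.sum()) / n_v)
        busy_den = float(np.abs(ii * pi_ - jj * pj_).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (np.abs(ii - jj) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum()
        ) / n_v
        strength = (
            float(((pi_ + pj_) * (ii - jj) ** 2).sum()) / float(s.sum())
            if s.sum() > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def _weighted_matrix_features(counts: np.ndarray, prefix_pairs: dict) -> dict[str, float]:
    """Shared emphasis/nonuniformity features of gray-level x size matrices.

    GLRLM, GLSZM and GLDM all share this structure: rows are gray levels,
    columns a size axis (run length, zone size, dependence).  ``prefix_pairs``
    maps the generic names ("Small", "Large") to the family's vocabulary.
    """
    n_s = counts.sum()
    p = counts / n_s
    ng, ns = counts.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, ns + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg = p.sum(axis=1)
    psz = p.sum(axis=0)
    mu_g = float((i * pg).sum())
    mu_s = float((j * psz).sum())

    small = prefix_pairs["small"]
    large = prefix_pairs["large"]
    f = {
        small: float((p / jj**2).sum()),
        large: float((p * jj**2).sum()),
        "GrayLevelNonUniformity": float((counts.sum(axis=1) ** 2).sum()) / n_s,
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        prefix_pairs["nonuniformity"]: float((counts.sum(axis=0) ** 2).sum()) / n_s,
        prefix_pairs["nonuniformity"] + "Normalized": float((psz**2).sum()),
        "GrayLevelVariance": float(((ii - mu_g) ** 2 * p).sum()),
        prefix_pairs["variance"]: float(((jj - mu_s) ** 2 * p).sum()),
        prefix_pairs["entropy"]: _entropy(p.ravel()),
        "LowGrayLevel" + prefix_pairs["gl_suffix"]: float((p / ii**2).sum()),
        "HighGrayLevel" + prefix_pairs["gl_suffix"]: float((p * ii**2).sum()),
        small.replace("Emphasis", "") + "LowGrayLevelEmphasis": float(
            (p / (ii**2 * jj**2)).sum()
        ),
        small.replace("Emphasis", "") + "HighGrayLevelEmphasis": float(
            (p * ii**2 / jj**2).sum()
        ),
        large.replace("Emphasis", "") + "LowGrayLevelEmphasis": float(
            (p * jj**2 / ii**2).sum()
        ),
        large.replace("Emphasis", "") + "HighGrayLevelEmphasis": float(
            (p * ii**2 * jj**2).sum()
        ),
        prefix_pairs["percentage"]: float(n_s) / prefix_pairs["percentage_den"],
    }
    return f


def glrlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """Run-length family (ShortRunEmphasis, LongRunEmphasis, ...).

    RunPercentage uses masked voxels x number of pooled directions as the
    denominator so it stays in (0, 1] for the pooled matrix.
    """
    return _weighted_matrix_features(
        m.counts,
        {
            "small": "ShortRunEmphasis",
            "large": "LongRunEmphasis",
            "nonuniformity": "RunLengthNonUniformity",
            "variance": "RunVariance",
            "entropy": "RunEntropy",
            "gl_suffix": "RunEmphasis",
            "percentage": "RunPercentage",
            "percentage_den": float(m.n_voxels * m.n_directions),
        },
    )


def glszm_features(m: SizeZoneMatrix) -> dict[str, float]:
    """Size-zone family (SmallAreaEmphasis, LargeAreaEmphasis, ...)."""
    return _weighted_matrix_features(
        m.counts,
        {
            "small": "SmallAreaEmphasis",
            "large": "LargeAreaEmphasis",
            "nonuniformity": "SizeZoneNonUniformity",
            "variance": "ZoneVariance",
            "entropy": "ZoneEntropy",
            "gl_suffix": "ZoneEmphasis",
            "percentage": "ZonePercentage",
            "percentage_den": float(m.n_voxels),
        },
    )


def gldm_features(m: DependenceMatrix) -> dict[str, float]:
    """Dependence family (SmallDependenceEmphasis, LargeDependenceEmphasis, ...)."""
    f = _weighted_matrix_features(
        m.counts,
        {
            "small": "SmallDependenceEmphasis",
            "large": "LargeDependenceEmphasis",
            "nonuniformity": "DependenceNonUniformity",
            "variance": "DependenceVariance",
            "entropy": "DependenceEntropy",
            "gl_suffix": "Emphasis",
            "percentage": "DependencePercentage",
            "percentage_den": float(m.n_voxels),
        },
    )
    # every masked voxel has a dependence entry, so the percentage is always 1
    f.pop("DependencePercentage")
    return f


def firstorder_features(values: np.ndarray, quantized: QuantizedROI) -> dict[str, float]:
    """First-order intensity statistics over masked, normalized values.

    Entropy and Uniformity are computed on the quantized gray-level
    histogram; all other statistics use the continuous values.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty value set")
    mean = float(x.mean())
    sd = float(x.std())
    var = float(x.var())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    hist = np.bincount(
        quantized.levels[quantized.mask] - 1, minlength=quantized.n_levels
    )
    p_hist = hist / hist.sum()
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / sd**4)
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float((x**2).sum()),
        "Entropy": _entropy(p_hist),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p_hist**2).sum()),
    }
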