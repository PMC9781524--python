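"""First-order (histogram) features of the VOI values (18 features).

Statistics are computed on the raw in-VOI values except Entropy and
Uniformity, which use the discretized histogram (base-2 entropy).  Energy is
the plain sum of squares (no intensity shift); Total Energy scales it by the
voxel volume.  Kurtosis is non-excess (a Gaussian scores 3).  Degenerate
rule for a constant VOI: variance 0, entropy 0, uniformity 1, skewness 0,
kurtosis 3.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedVOI

_EPS = np.spacing(1.0)


def firstorder_features(voi: DiscretizedVOI) -> dict[str, float]:
    x = np.asarray(voi.raw_values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty VOI")
    n = x.size
    voxel_volume = float(np.prod(voi.voxel_spacing))

    mean = float(x.mean())
    var = float(x.var())          # population variance
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # robust MAD: mean absolute deviation of values within [P10, P90]
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if sd > 0:
        skew = float(np.mean(((x - mean) / sd) ** 3))
        kurt = float(np.mean(((x - mean) / sd) ** 4))
    else:
        skew, kurt = 0.0, 3.0

    # histogram features on the discretized labels
    labels = voi.voi_labels
    counts = np.bincount(labels, minlength=voi.n_bins + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p ** 2))

    energy = float(np.sum(x ** 2))
    return {
        "10th Percentile": float(p10),
        "90th Percentile": float(p90),
        "Energy": energy,
        "Entropy": entropy,
        "Interquartile Range": float(p75 - p25),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean Absolute Deviation": float(np.abs(x - mean).mean()),
        "Mean": mean,
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "Robust Mean Absolute Deviation": rmad,
        "Root Mean Squared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "Total Energy": voxel_volume * energy,
        "Uniformity": uniformity,
        "Variance": var,
    }
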