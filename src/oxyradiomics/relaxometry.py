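"""Transverse relaxation-rate mapping from multi-echo magnitude volumes.

The rate map (R2* from gradient-echo trains, R2 from spin-echo trains) is
obtained voxelwise by unweighted least squares on log-magnitude vs. echo
time; the negated slope is the rate.  This log-linear fit is deterministic,
exact on noiseless mono-exponential data, and invariant to a common scaling
of all magnitudes.  Voxels with any non-positive magnitude cannot be
log-transformed and are marked invalid; fitted rates are clamped at zero
(negative slopes arise only from noise).

Background-field and stimulated-echo corrections are *not* applied here;
input echo trains are assumed corrected upstream.
"""

from __future__ import annotations

import numpy as np

from .maps import QuantMap, Quantity
from .synthetic import EchoTrain


def fit_relaxation_rate(echo_train: EchoTrain,
                        mask: np.ndarray | None = None,
                        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                        quantity: Quantity | None = None) -> QuantMap:
    """Fit a relaxation-rate map by log-linear least squares.

    Parameters
    ----------
    echo_train
        Multi-echo magnitudes with ascending echo times (seconds).
    mask
        Optional fit region; outside voxels are marked invalid.  Must contain
        at least one voxel with all-positive magnitudes.
    spacing
        Voxel spacing of the output map (mm).
    quantity
        Output quantity; defaults to R2STAR for gradient-echo trains and R2
        for spin-echo trains.

    Returns
    -------
    QuantMap
        Rate map in 1/s, clamped at >= 0; voxels with any non-positive
        magnitude (or outside ``mask``) are invalid.
    """
    tes = echo_train.echo_times
    mags = echo_train.magnitudes
    if tes.size < 2:
        raise ValueError("need at least 2 echoes to fit a rate")
    shape = mags.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)

    positive = np.all(mags > 0, axis=0)
    valid = mask & positive
    if not np.any(valid):
        raise ValueError("no voxel with all-positive magnitudes inside the mask")

    # slope of log S on TE: slope = cov(TE, logS) / var(TE); rate = -slope
    log_s = np.zeros_like(mags)
    np.log(mags, out=log_s, where=mags > 0)
    t_centered = tes - tes.mean()
    denom = float(np.sum(t_centered ** 2))
    slope = np.tensordot(t_centered, log_s, axes=(0, 0)) / denom
    rate = np.clip(-slope, 0.0, None)
    rate[~valid] = 0.0

    if quantity is None:
        quantity = (Quantity.R2 if echo_train.sequence_kind == "spin-echo"
                    else Quantity.R2STAR)
    return QuantMap(values=rate, spacing=spacing, quantity=quantity, valid=valid)
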