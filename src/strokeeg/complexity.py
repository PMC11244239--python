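"""Per-channel sample entropy.

Sample entropy of a series is ``-ln(A/B)`` where ``B`` is the number of
template pairs of length ``m`` within Chebyshev distance ``r`` of each
other (self-matches excluded) and ``A`` the same count for length
``m+1``; templates at both lengths range over the same ``K-m`` start
positions (Richman-Moorman convention). Higher values mean a more
irregular, less predictable signal. By default ``r`` is expressed in
units of the series' standard deviation, which makes the estimate
amplitude-scale invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import EpochSet
from .errors import ParameterError, UndefinedSampleEntropyWarning


@dataclass
class SaEnParams:
    """Sample-entropy parameters.

    ``m`` is the template length, ``r`` the similarity radius. With
    ``r_absolute=False`` (default) the radius is ``r * SD(x)``; the EEG
    field standard is m=2, r=0.2.
    """

    m: int = 2
    r: float = 0.2
    r_absolute: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError("m must be >= 1")
        if self.r <= 0:
            raise ParameterError("r must be positive")


def _counts(x: np.ndarray, m: int, radius: float) -> tuple[int, int]:
    """Template match counts (B at length m, A at length m+1).

    Both counts run over ordered pairs i != j with template start
    positions 0..K-m-1, strict inequality d < radius.
    """
    K = x.size
    n = K - m
    # pairwise |x_i - x_j| shifted along the template, running max
    d_m = None
    for k in range(m):
        dk = np.abs(x[k:k + n, None] - x[None, k:k + n])
        d_m = dk if d_m is None else np.maximum(d_m, dk)
    d_m1 = np.maximum(d_m, np.abs(x[m:m + n, None] - x[None, m:m + n]))
    b = int((d_m < radius).sum()) - n      # remove self-pairs (distance 0)
    a = int((d_m1 < radius).sum()) - n
    return b, a


def sample_entropy(x: np.ndarray, params: SaEnParams | None = None) -> float:
    """Sample entropy of one series (nats).

    Degenerate cases: a constant series is perfectly regular and returns
    0.0; when no template pair matches at length ``m+1`` (or ``m``) the
    value is undefined and is capped at ``ln(K - m)`` with a warning so
    downstream feature maps stay finite.
    """
    if params is None:
        params = SaEnParams()
    x = np.asarray(x, dtype=np.float64).ravel()
    K = x.size
    if K <= params.m + 1:
        raise ParameterError(f"series length {K} must exceed m+1 = {params.m + 1}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("series contains non-finite samples")
    sd = x.std()
    if sd == 0.0 and not params.r_absolute:
        return 0.0
    radius = params.r if params.r_absolute else params.r * sd
    b, a = _counts(x, params.m, radius)
    cap = float(np.log(K - params.m))
    if a == 0 or b == 0:
        warnings.warn(
            f"no template matches at length m{'+1' if b else ''}; "
            f"sample entropy undefined, capped at ln(K-m)={cap:.4f}",
            UndefinedSampleEntropyWarning,
        )
        return cap
    return float(-np.log(a / b))


def saen_vector(epoch: np.ndarray, params: SaEnParams | None = None) -> np.ndarray:
    """Sample entropy per channel for one epoch ``[C x K]``."""
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2:
        raise ParameterError("epoch must be [C x K]")
    return np.array([sample_entropy(ch, params) for ch in epoch])


def saen_epoch_stack(ep: EpochSet, params: SaEnParams | None = None) -> np.ndarray:
    """Per-channel sample entropy for every epoch: ``[n_epochs x C]``."""
    out = np.empty((ep.n_epochs, ep.n_channels))
    for e in range(ep.n_epochs):
        out[e] = saen_vector(ep.epochs[e], params)
    return out
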