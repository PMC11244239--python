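"""Phase-lag-index (PLI) connectivity and its correlation-weighted form.

The PLI between two signals is ``|mean_k sign(dphi(t_k))|`` where ``dphi``
is the Hilbert-phase difference wrapped to (-pi, pi]. It is 0 when phase
differences are symmetric around zero (or exactly zero, as with volume
conduction) and 1 when one signal consistently leads the other.

The correlation weight of a channel pair scores how consistently that
pair's PLI separates stroke subjects from controls: over all P x M
cross-group subject pairs, ``w_ij = |n_greater - n_smaller| / (P*M)``,
where ``n_greater`` counts stroke subjects whose PLI_ij exceeds the
control's and ``n_smaller`` the reverse (ties count for neither). The
correlation-weighted PLI (cwPLI) is the elementwise product ``PLI * w``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .data import EpochSet
from .errors import DegeneratePhaseWarning, ParameterError
from .montage import CHANNELS

#: |dphi| below this counts as a zero phase difference (sign contributes 0),
#: so numerically identical channels give PLI exactly 0.
ZERO_PHASE_TOL = 1e-9


@dataclass
class PliMatrix:
    """Symmetric [C x C] PLI matrix with zero diagonal, entries in [0, 1]."""

    values: np.ndarray
    channel_names: Sequence[str] = field(default_factory=lambda: list(CHANNELS))
    subject_id: str | None = None
    epoch_id: int | None = None


@dataclass
class CorrelationWeights:
    """Group-derived per-pair weights in [0, 1] (symmetric, zero diagonal)."""

    values: np.ndarray
    n_stroke: int = 0
    n_control: int = 0
    channel_names: Sequence[str] = field(default_factory=lambda: list(CHANNELS))


@dataclass
class CwPliMatrix:
    """Correlation-weighted PLI: elementwise ``PLI * w``."""

    values: np.ndarray
    channel_names: Sequence[str] = field(default_factory=lambda: list(CHANNELS))
    subject_id: str | None = None
    epoch_id: int | None = None


def wrap_phase(d: np.ndarray) -> np.ndarray:
    """Wrap phase differences to the interval (-pi, pi]."""
    w = np.mod(np.asarray(d, dtype=np.float64), 2 * np.pi)
    return np.where(w > np.pi, w - 2 * np.pi, w)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Hilbert instantaneous phase in (-pi, pi], one value per sample."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 8:
        raise ParameterError("need a 1-D signal of at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ParameterError("signal contains non-finite samples")
    if np.ptp(x) == 0:
        warnings.warn("constant signal: instantaneous phase is undefined",
                      DegeneratePhaseWarning)
    return np.angle(hilbert(x))


def _signed_mean(dphi: np.ndarray, axis: int = -1) -> np.ndarray:
    s = np.sign(dphi)
    s = np.where(np.abs(dphi) < ZERO_PHASE_TOL, 0.0, s)
    return np.abs(s.mean(axis=axis))


def _edge_slice(n_samples: int, exclude_edge_fraction: float) -> slice:
    if not 0.0 <= exclude_edge_fraction < 0.5:
        raise ParameterError("exclude_edge_fraction must lie in [0, 0.5)")
    k = int(exclude_edge_fraction * n_samples)
    return slice(k, n_samples - k if k else None)


def pli(x: np.ndarray, y: np.ndarray, exclude_edge_fraction: float = 0.0) -> float:
    """Phase lag index between two equal-length signals (in [0, 1]).

    ``exclude_edge_fraction`` optionally drops that fraction of samples
    at each end of the epoch from the sign average, where the Hilbert
    phase estimate is least reliable (off by default).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ParameterError(f"length mismatch: {x.shape} vs {y.shape}")
    dphi = wrap_phase(instantaneous_phase(x) - instantaneous_phase(y))
    return float(_signed_mean(dphi[_edge_slice(dphi.shape[-1], exclude_edge_fraction)]))


def phase_matrix(epoch: np.ndarray) -> np.ndarray:
    """Hilbert phase per channel for one epoch ``[C x K]``."""
    epoch = np.asarray(epoch, dtype=np.float64)
    return np.angle(hilbert(epoch, axis=-1))


def pli_matrix(epoch: np.ndarray,
               channel_names: Sequence[str] | None = None,
               epoch_id: int | None = None,
               subject_id: str | None = None,
               exclude_edge_fraction: float = 0.0) -> PliMatrix:
    """PLI matrix for one epoch ``[C x K]`` (symmetric, zero diagonal)."""
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise ParameterError("epoch must be [C x K] with C >= 2")
    phases = phase_matrix(epoch)
    dphi = wrap_phase(phases[:, None, :] - phases[None, :, :])
    dphi = dphi[..., _edge_slice(dphi.shape[-1], exclude_edge_fraction)]
    m = _signed_mean(dphi, axis=-1)
    np.fill_diagonal(m, 0.0)
    if channel_names is None:
        channel_names = [f"Ch{i:02d}" for i in range(epoch.shape[0])] \
            if epoch.shape[0] != len(CHANNELS) else list(CHANNELS)
    return PliMatrix(values=m, channel_names=channel_names,
                     epoch_id=epoch_id, subject_id=subject_id)


def pli_epoch_stack(ep: EpochSet) -> np.ndarray:
    """PLI matrices for every epoch: array ``[n_epochs x C x C]``."""
    out = np.empty((ep.n_epochs, ep.n_channels, ep.n_channels))
    for e in range(ep.n_epochs):
        out[e] = pli_matrix(ep.epochs[e]).values
    return out


def subject_mean_pli(ep: EpochSet) -> PliMatrix:
    """Subject-level PLI: mean of the per-epoch matrices."""
    stack = pli_epoch_stack(ep)
    if stack.shape[0] == 0:
        raise ParameterError("no epochs to average")
    return PliMatrix(values=stack.mean(axis=0),
                     channel_names=list(ep.channel_names),
                     subject_id=ep.subject_id)


def correlation_weights(stroke_plis: Sequence[PliMatrix | np.ndarray],
                        control_plis: Sequence[PliMatrix | np.ndarray]) -> CorrelationWeights:
    """Per-pair class-separation weights from subject-level PLI matrices.

    For each channel pair, all P x M ordered (stroke, control) subject
    pairs are compared; ``w_ij = |n_greater - n_smaller| / (P*M)``.
    """
    def stack(ms):
        return np.stack([m.values if isinstance(m, PliMatrix) else np.asarray(m)
                         for m in ms])

    if len(stroke_plis) == 0 or len(control_plis) == 0:
        raise ParameterError("both groups must be non-empty")
    s = stack(stroke_plis)
    c = stack(control_plis)
    if s.shape[1:] != c.shape[1:]:
        raise ParameterError("channel count mismatch between groups")
    diff = s[:, None] - c[None, :]            # [P x M x C x C]
    n_greater = (diff > 0).sum(axis=(0, 1))
    n_smaller = (diff < 0).sum(axis=(0, 1))
    w = np.abs(n_greater - n_smaller) / (s.shape[0] * c.shape[0])
    np.fill_diagonal(w, 0.0)
    names = stroke_plis[0].channel_names if isinstance(stroke_plis[0], PliMatrix) \
        else list(CHANNELS)[: s.shape[1]] if s.shape[1] == len(CHANNELS) else \
        [f"Ch{i:02d}" for i in range(s.shape[1])]
    return CorrelationWeights(values=w, n_stroke=s.shape[0], n_control=c.shape[0],
                              channel_names=list(names))


def apply_weights(pli_m: PliMatrix | np.ndarray, w: CorrelationWeights | np.ndarray) -> CwPliMatrix:
    """Elementwise product ``PLI * w`` -> cwPLI (never exceeds the PLI)."""
    pv = pli_m.values if isinstance(pli_m, PliMatrix) else np.asarray(pli_m)
    wv = w.values if isinstance(w, CorrelationWeights) else np.asarray(w)
    if pv.shape != wv.shape:
        raise ParameterError(f"shape mismatch: PLI {pv.shape} vs weights {wv.shape}")
    if isinstance(pli_m, PliMatrix) and isinstance(w, CorrelationWeights):
        if list(pli_m.channel_names) != list(w.channel_names):
            raise ParameterError("channel name mismatch between PLI and weights")
    names = pli_m.channel_names if isinstance(pli_m, PliMatrix) else w.channel_names \
        if isinstance(w, CorrelationWeights) else list(CHANNELS)[: pv.shape[0]]
    return CwPliMatrix(values=pv * wv, channel_names=list(names),
                       subject_id=getattr(pli_m, "subject_id", None),
                       epoch_id=getattr(pli_m, "epoch_id", None))


# ---------------------------------------------------------------- plotting

def plot_matrix_heatmap(values: np.ndarray, channel_names: Sequence[str] = CHANNELS,
                        ax=None, vmin: float = 0.0, vmax: float = 1.0, title: str = ""):
    """Channel-by-channel connectivity heatmap."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(values, vmin=vmin, vmax=vmax, cmap="viridis")
    ax.set_xticks(range(len(channel_names)))
    ax.set_yticks(range(len(channel_names)))
    ax.set_xticklabels(channel_names, rotation=90, fontsize=6)
    ax.set_yticklabels(channel_names, fontsize=6)
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax)
    return ax


def plot_connectivity_graph(values: np.ndarray, channel_names: Sequence[str] = CHANNELS,
                            threshold: float = 0.10, ax=None):
    """Scalp graph: draw an edge where connectivity exceeds ``threshold``.

    The default threshold 0.10 matches the convention used for sparse
    functional-connectivity displays of this kind of matrix.
    """
    import matplotlib.pyplot as plt

    from .montage import positions_2d

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    xy = positions_2d()[: len(channel_names)]
    C = len(channel_names)
    for i in range(C):
        for j in range(i + 1, C):
            if values[i, j] > threshold:
                ax.plot([xy[i, 0], xy[j, 0]], [xy[i, 1], xy[j, 1]],
                        color="tab:blue", lw=0.8, alpha=0.7)
    ax.scatter(xy[:, 0], xy[:, 1], s=30, color="k", zorder=3)
    for i, name in enumerate(channel_names):
        ax.annotate(name, xy[i], fontsize=6, ha="center", va="bottom")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
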