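"""Functional connectivity: phase-lag index, graph efficiency and
entropy-based information transfer.

The phase-lag index (PLI) between two channels is the absolute mean of
the sign of their instantaneous phase difference: 0 when the lag is
symmetric around zero (as volume conduction produces), 1 when one
channel consistently leads the other.  Exactly zero lag contributes a
sign of 0, so identical signals have PLI 0 - the measure deliberately
ignores zero-lag coupling.

Weighted global and local efficiency (Latora-Marchiori) summarize the
PLI graph, with edge length = 1 / weight so strong coupling means a
short path.

Information transfer between channel pairs is the mutual information
``MI(q, s) = H(q) + H(s) - H(q, s)`` in bits, with entropies estimated
from histogram probabilities of delay-embedded signal states.  The
measure is symmetric; it quantifies shared information, not direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.sparse.csgraph import shortest_path

from .core import Montage, Segment
from .spectral import ANALYSIS_RANGE

__all__ = [
    "instantaneous_phase",
    "pli_matrix",
    "PLIMatrix",
    "top_links",
    "efficiency",
    "GraphMetrics",
    "embed",
    "Embedding",
    "mi_matrix",
    "MIMatrix",
]

log = logging.getLogger(__name__)


def _as_data_fs(seg_or_data, fs: float | None) -> tuple[np.ndarray, float]:
    if isinstance(seg_or_data, Segment):
        return seg_or_data.data, seg_or_data.fs
    if fs is None:
        raise ValueError("fs required when passing a bare array")
    return np.atleast_2d(np.asarray(seg_or_data, float)), fs


def band_filter(data: np.ndarray, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} must lie within (0, fs/2)")
    sos = signal.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def instantaneous_phase(
    seg_or_data, band: tuple[float, float] = ANALYSIS_RANGE,
    fs: float | None = None,
) -> np.ndarray:
    """Analytic-signal phase per channel after band-pass filtering.

    Values in (-pi, pi].  Edge samples are distorted by the filter and
    Hilbert transients; callers should trim them (see
    :func:`pli_matrix`).
    """
    data, fs = _as_data_fs(seg_or_data, fs)
    return np.angle(signal.hilbert(band_filter(data, fs, band), axis=-1))


@dataclass(frozen=True)
class PLIMatrix:
    """Symmetric channels x channels PLI with zero diagonal."""

    values: np.ndarray
    band: tuple[float, float]
    channel_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLI matrix must be square")
        object.__setattr__(self, "values", v)


def pli_matrix(
    seg_or_data,
    band: tuple[float, float] = ANALYSIS_RANGE,
    fs: float | None = None,
    trim: float = 0.05,
    channel_names: Sequence[str] | None = None,
) -> PLIMatrix:
    """Stam phase-lag index for every channel pair.

    ``trim`` drops that fraction of samples at each end before
    averaging, avoiding filter/Hilbert edge transients.  The sign of an
    exactly-zero phase difference contributes 0.
    """
    data, fs_ = _as_data_fs(seg_or_data, fs)
    if channel_names is None:
        if isinstance(seg_or_data, Segment):
            channel_names = seg_or_data.montage.channel_names
        else:
            channel_names = tuple(f"ch{i}" for i in range(data.shape[0]))
    phases = instantaneous_phase(data, band, fs_)
    n = phases.shape[1]
    a, b = int(n * trim), n - int(n * trim)
    phases = phases[:, a:b]
    n_ch = phases.shape[0]
    values = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        dphi = phases[i][None, :] - phases[i + 1:]
        values[i, i + 1:] = np.abs(np.mean(np.sign(np.sin(dphi)), axis=-1))
    values = values + values.T
    meta = {}
    if isinstance(seg_or_data, Segment):
        meta = {"subject": seg_or_data.meta.subject,
                "session": seg_or_data.meta.session,
                "task": seg_or_data.meta.task,
                "stage": seg_or_data.meta.stage,
                "segment": seg_or_data.index}
    return PLIMatrix(values, tuple(band), tuple(channel_names), meta)


def long_range_mask(
    montage: Montage, rule: str = "median_distance"
) -> np.ndarray:
    """Boolean channel-pair mask selecting long-range electrode pairs.

    ``median_distance``: pairs farther apart (template 10-20 Euclidean
    distance) than the median inter-electrode distance.
    ``interhemispheric``: pairs spanning the two hemispheres.
    """
    pos = montage.position_array()
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    iu = np.triu_indices(len(pos), 1)
    if rule == "median_distance":
        return d > np.median(d[iu])
    if rule == "interhemispheric":
        return np.sign(pos[:, 0])[:, None] != np.sign(pos[None, :, 0])
    raise ValueError(f"unknown long-range rule {rule!r}")


def top_links(
    pli: PLIMatrix,
    montage: Montage,
    k: int = 10,
    value_range: tuple[float, float] = (0.5, 0.7),
    rule: str = "median_distance",
) -> list[tuple[str, str, float]]:
    """The k strongest long-range links with PLI inside ``value_range``.

    Ties break deterministically by (channel index, channel index).  If
    fewer than k links qualify, all of them are returned and the
    shortfall is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = long_range_mask(montage, rule)
    lo, hi = value_range
    cand = []
    n = pli.values.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            v = pli.values[i, j]
            if mask[i, j] and lo <= v <= hi:
                cand.append((i, j, v))
    cand.sort(key=lambda t: (-t[2], t[0], t[1]))
    if len(cand) < k:
        log.info("only %d of %d requested links qualify", len(cand), k)
    names = pli.channel_names
    return [(names[i], names[j], float(v)) for i, j, v in cand[:k]]


@dataclass(frozen=True)
class GraphMetrics:
    global_efficiency: float
    local_efficiency: float


def _global_efficiency(weights: np.ndarray) -> float:
    """Weighted Latora-Marchiori global efficiency, edge length 1/w."""
    n = weights.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        dist = np.where(weights > 0, 1.0 / weights, np.inf)
    np.fill_diagonal(dist, 0.0)
    sp = shortest_path(dist, method="D", directed=False)
    iu = np.triu_indices(n, 1)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(sp[iu]), 1.0 / sp[iu], 0.0)
    return float(inv.mean())


def efficiency(pli_or_weights) -> GraphMetrics:
    """Weighted global and local efficiency of a nonnegative graph.

    Global: mean over node pairs of 1 / shortest-path length.  Local:
    mean over nodes of the global efficiency of each node's
    neighbour-induced subgraph (nodes with fewer than two neighbours
    contribute 0).  Disconnected pairs contribute 0.  For weights in
    [0, 1] - e.g. a PLI graph - both metrics lie in [0, 1].
    """
    w = pli_or_weights.values if isinstance(pli_or_weights, PLIMatrix) \
        else np.asarray(pli_or_weights, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    n = w.shape[0]
    glob = _global_efficiency(w)
    locals_ = []
    for i in range(n):
        nbrs = np.flatnonzero((w[i] > 0) & (np.arange(n) != i))
        if nbrs.size < 2:
            locals_.append(0.0)
        else:
            locals_.append(_global_efficiency(w[np.ix_(nbrs, nbrs)]))
    return GraphMetrics(global_efficiency=glob,
                        local_efficiency=float(np.mean(locals_)))


@dataclass(frozen=True)
class Embedding:
    """Delay embedding: row i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""

    m: int
    tau: int
    vectors: np.ndarray


def embed(channel_data: np.ndarray, m: int, tau: int) -> Embedding:
    """Phase-space reconstruction of a scalar series by time delays."""
    x = np.asarray(channel_data, float).ravel()
    if m < 1 or tau < 1:
        raise ValueError("need m >= 1 and tau >= 1")
    n_vec = x.size - (m - 1) * tau
    if n_vec < 1:
        raise ValueError(
            f"series of {x.size} samples too short for m={m}, tau={tau}")
    idx = np.arange(n_vec)[:, None] + tau * np.arange(m)[None, :]
    return Embedding(m=m, tau=tau, vectors=x[idx])


@dataclass(frozen=True)
class MIMatrix:
    """Symmetric nonnegative MI matrix (bits); diagonal = channel entropy."""

    values: np.ndarray
    m: int
    tau: int
    bins: int
    bias_correction: bool
    channel_names: tuple[str, ...]


def _entropy_bits(counts: np.ndarray, correct: bool) -> float:
    counts = counts[counts > 0].astype(float)
    n = counts.sum()
    p = counts / n
    h = -np.sum(p * np.log2(p))
    if correct:  # Miller-Madow plug-in bias correction
        h += (counts.size - 1) / (2.0 * n * np.log(2.0))
    return float(h)


def _discretize(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning over the series' own range -> codes 0..bins-1."""
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros(values.size, dtype=np.intp)
    edges = np.linspace(lo, hi, bins + 1)
    codes = np.searchsorted(edges, values, side="right") - 1
    return np.clip(codes, 0, bins - 1).astype(np.intp)


def mi_matrix(
    seg_or_data,
    m: int = 3,
    tau: int = 4,
    bins: int = 16,
    bias_correction: bool = True,
    fs: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> MIMatrix:
    """Pairwise mutual information of delay-embedded channel states.

    Each channel is delay-embedded (``m``, ``tau``); its state series is
    the leading embedding coordinate discretized into ``bins``
    equal-width bins over the channel's own range, which keeps marginal
    and joint histograms well populated at 10-s window lengths.
    ``MI(q, s) = H(q) + H(s) - H(q, s)`` in bits; the diagonal holds the
    channel entropies.  ``bias_correction`` applies the Miller-Madow
    correction to each entropy term; estimates are clipped at zero.  A
    constant channel has zero entropy and zero MI with every other.
    """
    data, _ = _as_data_fs(seg_or_data, fs if fs is not None else 1.0)
    if channel_names is None:
        if isinstance(seg_or_data, Segment):
            channel_names = seg_or_data.montage.channel_names
        else:
            channel_names = tuple(f"ch{i}" for i in range(data.shape[0]))
    n_ch = data.shape[0]
    codes = []
    for c in range(n_ch):
        e = embed(data[c], m, tau)
        codes.append(_discretize(e.vectors[:, 0], bins))
    n_states = codes[0].size
    marg_h = np.empty(n_ch)
    for c in range(n_ch):
        marg_h[c] = _entropy_bits(np.bincount(codes[c], minlength=bins),
                                  bias_correction)
    values = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        values[i, i] = marg_h[i]
        for j in range(i + 1, n_ch):
            joint = np.bincount(codes[i] * bins + codes[j],
                                minlength=bins * bins)
            h_ij = _entropy_bits(joint, bias_correction)
            mi = marg_h[i] + marg_h[j] - h_ij
            values[i, j] = values[j, i] = max(mi, 0.0)
    return MIMatrix(values=values, m=m, tau=tau, bins=bins,
                    bias_correction=bias_correction,
                    channel_names=tuple(channel_names))
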