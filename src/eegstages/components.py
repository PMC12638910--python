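"""Group task-related component analysis (gTRCA).

Task-related component analysis finds spatial filters ``w`` that
maximize the reproducibility of the filtered signal across repeated
trials: with per-trial covariances pooled into ``Q`` and the summed
cross-trial covariances into ``S``, the filters solve the generalized
eigenproblem ``S w = lambda Q w``.  The group variant pools trials
across subjects, so components capture structure shared both between
trials and between subjects.  The leading eigenvalue is the
reproducibility objective; for K identical trials it attains its
maximum K - 1.

The scalp topography of a component is its forward-model pattern,
``pattern = Cov * w`` (normalized): the pattern, not the filter, is what
maps onto the head.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
from scipy import linalg

__all__ = ["TrialSet", "SpatialComponent", "fit_gtrca", "project_pattern"]

log = logging.getLogger(__name__)


@dataclass
class TrialSet:
    """Equal-channel trials (channels x samples), optionally per subject.

    Trials of unequal length are truncated to the common minimum.  At
    least two trials are required for a cross-trial objective to exist.
    """

    trials: list[np.ndarray]
    subjects: list[str] | None = None
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, float) for t in self.trials]
        if len(self.trials) < 2:
            raise ValueError("need at least 2 trials")
        n_ch = {t.shape[0] for t in self.trials}
        if len(n_ch) != 1:
            raise ValueError("all trials must have the same channel count")
        t_min = min(t.shape[1] for t in self.trials)
        self.trials = [t[:, :t_min] for t in self.trials]
        if self.subjects is not None and len(self.subjects) != len(self.trials):
            raise ValueError("subjects must align with trials")

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class SpatialComponent:
    """One fitted component: unit-norm filter, normalized pattern, score."""

    filter_weights: np.ndarray
    pattern: np.ndarray
    objective: float
    rank: int


def _covariances(ts: TrialSet) -> tuple[np.ndarray, np.ndarray]:
    """Within-trial pooled covariance Q and summed cross-trial covariance S."""
    centered = [t - t.mean(axis=1, keepdims=True) for t in ts.trials]
    T = centered[0].shape[1]
    Q = sum(x @ x.T for x in centered) / T
    total = sum(centered)
    # sum_{i != j} Cov(X_i, X_j) = Cov(sum X, sum X) - sum Cov(X_i, X_i)
    S = (total @ total.T) / T - Q
    return Q, (S + S.T) / 2.0


def fit_gtrca(
    ts: TrialSet,
    n_components: int = 1,
    ridge: float = 1e-6,
) -> list[SpatialComponent]:
    """Fit gTRCA components by the generalized eigendecomposition.

    ``ridge`` scales a diagonal loading of ``ridge * trace(Q)/C`` added
    to Q, which keeps the solve well-posed for rank-deficient trial
    covariances (the regularization strength is logged when the loading
    is material).  Components are returned sorted by descending
    objective with the sign fixed so the largest-magnitude pattern entry
    is positive.
    """
    if n_components < 1 or n_components > ts.n_channels:
        raise ValueError("n_components must be in 1..n_channels")
    Q, S = _covariances(ts)
    C = ts.n_channels
    loading = ridge * np.trace(Q) / C
    if loading == 0:
        loading = ridge
    cond = np.linalg.cond(Q)
    if cond > 1e10:
        log.info("trial covariance ill-conditioned (cond=%.2e); "
                 "ridge loading %.3e applied", cond, loading)
    Qr = Q + loading * np.eye(C)
    eigvals, eigvecs = linalg.eigh(S, Qr)
    order = np.argsort(eigvals)[::-1]
    comps = []
    for rank, idx in enumerate(order[:n_components]):
        w = eigvecs[:, idx]
        w = w / np.linalg.norm(w)
        pattern = Q @ w
        norm = np.linalg.norm(pattern)
        if norm > 0:
            pattern = pattern / norm
        sign = np.sign(pattern[np.argmax(np.abs(pattern))])
        if sign < 0:
            w, pattern = -w, -pattern
        comps.append(SpatialComponent(
            filter_weights=w, pattern=pattern,
            objective=float(eigvals[idx]), rank=rank))
    return comps


def project_pattern(comp: SpatialComponent, ts: TrialSet) -> np.ndarray:
    """Forward-model topography of a component on a trial set.

    Recomputes ``Cov * w`` from the pooled trial covariance, normalized
    to unit length with the fitted sign convention; suitable for
    scalp-map rendering against montage positions.
    """
    Q, _ = _covariances(ts)
    pattern = Q @ comp.filter_weights
    norm = np.linalg.norm(pattern)
    if norm > 0:
        pattern = pattern / norm
    sign = np.sign(pattern[np.argmax(np.abs(pattern))])
    return pattern * (sign if sign != 0 else 1.0)


def component_timecourse(comp: SpatialComponent, trial: np.ndarray) -> np.ndarray:
    """Filtered single-trial time course ``w' X``."""
    x = np.asarray(trial, float)
    return comp.filter_weights @ (x - x.mean(axis=1, keepdims=True))


def to_dict(comp: SpatialComponent) -> dict:
    """JSON-serializable form (weights, pattern, objective, rank)."""
    return {
        "filter_weights": comp.filter_weights.tolist(),
        "pattern": comp.pattern.tolist(),
        "objective": comp.objective,
        "rank": comp.rank,
    }
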