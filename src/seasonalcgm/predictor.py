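"""Real-time Global Seasonal Model: weighting, integration, CI/NI indices.

At each sampling instant tp the predictor weights the c local SARIMA
forecasts of the active partition by fuzzy memberships computed in two steps:
(1) membership of the segment since event onset discards coarsely
non-contributing clusters (below ``mu_factor`` of the maximum membership);
(2) membership of a short sliding window (20 min) refines the weighting over
the survivors.  The integrated forecast is the convex combination of local
trajectories.  Two scalar diagnostics accompany every forecast:

* crispness index (CI): normalized Manhattan distance of the weight vector
  from uniform — 1 when a single local model dominates, 0 when all
  contribute equally;
* normality index (NI): mean possibilistic membership over the surviving
  clusters — low values flag CGM behavior unrepresented in training history.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .clustering import (
    ClusterSet,
    EmptyOverlapError,
    possibilistic_membership,
    segment_membership,
)
from .data import GlucoseSeries
from .partition import group_of
from .seasonal import forecast_local

__all__ = [
    "WeightState",
    "Forecast",
    "prototype_slice",
    "two_step_weights",
    "integrate",
    "crispness",
    "normality",
    "RealTimePredictor",
]

DEFAULT_WINDOW = 4        # sampling intervals (20 min at 5-min sampling)
DEFAULT_MU_FACTOR = 0.2
DEFAULT_NI_THRESHOLD = 0.2


@dataclasses.dataclass
class WeightState:
    tp: int
    tek: int
    I1: np.ndarray
    I2: np.ndarray
    u_onset: np.ndarray
    u_window: np.ndarray
    gamma: np.ndarray
    gammaP: np.ndarray
    mu_min: float
    W: int

    @property
    def nI(self) -> int:
        return self.I2.size


@dataclasses.dataclass
class Forecast:
    tp: int
    horizon: int
    trajectory: np.ndarray
    local_trajectories: np.ndarray
    weights: WeightState
    CI: float
    NI: float
    NIthr: float

    @property
    def abnormal(self) -> bool:
        return bool(self.NI < self.NIthr)


def prototype_slice(prototype: np.ndarray, start: int, stop: int) -> np.ndarray:
    """Prototype samples on positions [start, stop); the last prototype value
    is held constant beyond the regularized length."""
    L = prototype.size
    idx = np.clip(np.arange(start, stop), 0, L - 1)
    return prototype[idx]


def two_step_weights(
    cgm: GlucoseSeries,
    cs: ClusterSet,
    tek: int,
    tp: int,
    W: int = DEFAULT_WINDOW,
    mu_factor: float = DEFAULT_MU_FACTOR,
) -> WeightState:
    """Two-step cluster weighting at time tp for the event started at tek."""
    if tp < tek:
        raise ValueError("tp must not precede the event onset tek")
    if W < 1:
        raise ValueError("window W must be >= 1")
    values = cgm.values if isinstance(cgm, GlucoseSeries) else np.asarray(cgm, dtype=float)
    c = cs.c
    I1 = np.arange(c)

    # step 1: membership of the whole segment since event onset
    seg = values[tek:tp + 1]
    slices = [prototype_slice(cs.V[i], 0, tp - tek + 1) for i in range(c)]
    u_onset = segment_membership(seg, slices, cs.m)
    mu_min = float(mu_factor * u_onset.max())
    I2 = np.nonzero(u_onset >= mu_min)[0]

    # step 2: membership of the sliding window over the survivors
    w_start = max(tek, tp - W)
    win = values[w_start:tp + 1]
    if np.all(np.isnan(win)):
        raise EmptyOverlapError("window is entirely blank")
    win_slices = [prototype_slice(cs.V[i], w_start - tek, tp - tek + 1) for i in I2]
    u_window = segment_membership(win, win_slices, cs.m)

    gamma = np.zeros(c)
    gamma[I2] = u_window
    gammaP = np.zeros(c)
    if cs.eta is None:
        raise ValueError("ClusterSet.eta is unset; run calibrate_eta first")
    for k, i in enumerate(I2):
        gammaP[i] = possibilistic_membership(win, win_slices[k], cs.eta, cs.m)
    return WeightState(tp=tp, tek=tek, I1=I1, I2=I2, u_onset=u_onset,
                       u_window=u_window, gamma=gamma, gammaP=gammaP,
                       mu_min=mu_min, W=W)


def integrate(local_trajectories: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Elementwise convex combination of the c local trajectories."""
    local_trajectories = np.atleast_2d(np.asarray(local_trajectories, dtype=float))
    gamma = np.asarray(gamma, dtype=float)
    if local_trajectories.shape[0] != gamma.size:
        raise ValueError("one weight per local trajectory is required")
    if abs(gamma.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    return gamma @ local_trajectories


def crispness(gamma: np.ndarray) -> float:
    """CI = [2(1−1/c)]⁻¹ Σ|γi − 1/c| ∈ [0,1]; defined as 1 for c = 1."""
    gamma = np.asarray(gamma, dtype=float)
    c = gamma.size
    if c < 1:
        raise ValueError("empty weight vector")
    if abs(gamma.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    if c == 1:
        return 1.0
    return float(np.abs(gamma - 1.0 / c).sum() / (2.0 * (1.0 - 1.0 / c)))


def normality(gammaP: np.ndarray, I2: np.ndarray) -> float:
    """NI = |I2|⁻¹ Σ γiP ∈ [0,1]; the closer to 0, the more abnormal."""
    I2 = np.asarray(I2)
    if I2.size == 0:
        raise ValueError("index set I2 must be non-empty")
    return float(np.asarray(gammaP, dtype=float).sum() / I2.size)


# ---------------------------------------------------------------------------
# Streaming predictor
# ---------------------------------------------------------------------------

class RealTimePredictor:
    """Sample-by-sample glucose predictor over trained per-partition models.

    Feed CGM samples with :meth:`step` and event onsets with
    :meth:`on_event`.  When an event closes, its subseries is regularized
    (tail blanks, truncated at L) and appended — preceded by its presample —
    to the seasonal history of the cluster with the highest membership.
    """

    def __init__(self, clustersets: dict, modelsets: dict,
                 sampling_period: int = 5,
                 W: int = DEFAULT_WINDOW,
                 mu_factor: float = DEFAULT_MU_FACTOR,
                 ni_threshold: float = DEFAULT_NI_THRESHOLD):
        self.clustersets = dict(clustersets)
        self.modelsets = dict(modelsets)
        self.sampling_period = sampling_period
        self.W = W
        self.mu_factor = mu_factor
        self.ni_threshold = ni_threshold
        self.samples: list = []
        self.active_key: str | None = None
        self.tek: int | None = None
        self._presample: np.ndarray | None = None

    @property
    def t(self) -> int:
        """Offset of the latest received sample."""
        return len(self.samples) - 1

    def _values(self) -> np.ndarray:
        return np.asarray(self.samples, dtype=float)

    def feed(self, sample: float) -> None:
        """Receive one CGM sample without forecasting (pre-event warm-up)."""
        self.samples.append(float(sample))

    def on_event(self, label: str) -> None:
        """Register an event onset at the time of the latest sample."""
        key = group_of(label)
        if key not in self.modelsets:
            raise KeyError(f"no trained partition for event group {key!r}")
        now = self.t
        if now < 0:
            raise ValueError("feed at least one sample before the first event")
        if self.active_key is not None:
            self._close_subseries(end=now)
        lms = self.modelsets[key]
        pr = lms.Pr
        vals = self._values()
        pres = vals[max(0, now - pr):now]
        if pres.size < pr:
            pres = np.concatenate([np.full(pr - pres.size, np.nan), pres])
        self._presample = pres
        self.active_key = key
        self.tek = now

    def _close_subseries(self, end: int) -> None:
        lms = self.modelsets[self.active_key]
        cs = self.clustersets[self.active_key]
        seg = self._values()[self.tek:end]
        if seg.size < 1:
            return
        slices = [prototype_slice(cs.V[i], 0, seg.size) for i in range(cs.c)]
        u = segment_membership(seg, slices, cs.m)
        winner = int(np.argmax(u))           # ties go to the lowest index
        row = np.full(lms.L, np.nan)
        row[: min(seg.size, lms.L)] = seg[: lms.L]
        lms.histories[winner].append_block(self._presample, row)

    def step(self, sample: float, horizon: int) -> Forecast:
        """Receive a sample and produce the integrated forecast at its time."""
        if self.active_key is None:
            raise RuntimeError("no active event; call on_event first")
        self.feed(sample)
        tp = self.t
        cs = self.clustersets[self.active_key]
        lms = self.modelsets[self.active_key]
        ws = two_step_weights(self._values(), cs, self.tek, tp,
                              W=self.W, mu_factor=self.mu_factor)
        current = np.concatenate([self._presample,
                                  self._values()[self.tek:tp + 1]])
        locals_ = np.empty((cs.c, horizon))
        for i in range(cs.c):
            locals_[i] = forecast_local(lms.models[i], lms.histories[i],
                                        current, horizon)
        traj = integrate(locals_, ws.gamma)
        ci = crispness(ws.gamma)
        ni = normality(ws.gammaP, ws.I2)
        return Forecast(tp=tp, horizon=horizon, trajectory=traj,
                        local_trajectories=locals_, weights=ws,
                        CI=ci, NI=ni, NIthr=self.ni_threshold)
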