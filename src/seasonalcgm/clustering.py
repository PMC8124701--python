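"""Partial Distance Strategy Fuzzy C-Means (PDSFCM) over regularized subseries.

Length regularization leaves trailing blanks in most subseries, so distances
and prototype updates must cope with missing coordinates.  The partial
distance between two length-L vectors rescales the sum of squared differences
over jointly observed coordinates by L/(L−B), with B the number of positions
blank in either vector; for complete data it reduces to the Euclidean
distance and PDSFCM reduces to textbook fuzzy c-means.

The module also provides the Fukuyama–Sugeno index for model-order selection,
fuzzy segment memberships used for real-time weighting, and their
possibilistic counterpart used by the normality index.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = [
    "ClusterSet",
    "EmptyOverlapError",
    "partial_distance",
    "pairwise_sqdist",
    "pdsfcm",
    "fs_index",
    "select_c",
    "segment_membership",
    "possibilistic_membership",
    "calibrate_eta",
    "assign_crisp",
]

ETA_CEILING = 1e6  # fallback possibilistic scale when training distances degenerate


class EmptyOverlapError(ValueError):
    """Partial distance undefined: no jointly observed coordinate."""


@dataclasses.dataclass
class ClusterSet:
    """Fitted fuzzy partition of one regularized subseries matrix."""

    c: int
    m: float
    V: np.ndarray          # (c, L) prototypes, blank-free
    U: np.ndarray          # (c, n) fuzzy partition matrix
    Jm: float
    key: str = "M"
    L: int = 0
    eta: float | None = None   # possibilistic scale, set by calibrate_eta
    fs: float | None = None
    jm_history: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if not self.L:
            self.L = self.V.shape[1]
        if np.isnan(self.V).any():
            raise ValueError("prototypes must be blank-free")

    @property
    def n(self) -> int:
        return self.U.shape[1]

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = {
            "key": self.key,
            "c": self.c,
            "m": self.m,
            "L": self.L,
            "eta": self.eta,
            "Jm": self.Jm,
            "fs": self.fs,
            "prototypes": self.V.tolist(),
            "U": self.U.tolist(),
        }
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "ClusterSet":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            c=d["c"], m=d["m"], V=np.array(d["prototypes"]),
            U=np.array(d["U"]), Jm=d["Jm"], key=d["key"], L=d["L"],
            eta=d["eta"], fs=d.get("fs"),
        )


# ---------------------------------------------------------------------------
# Partial distance
# ---------------------------------------------------------------------------

def partial_sqdist(a: np.ndarray, b: np.ndarray) -> float:
    """Squared partial distance between two equal-length vectors with blanks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    L = a.size
    joint = ~np.isnan(a) & ~np.isnan(b)
    n_obs = int(joint.sum())
    if n_obs == 0:
        raise EmptyOverlapError("empty overlap: no jointly observed position")
    diff = a[joint] - b[joint]
    return float(L / n_obs * np.dot(diff, diff))


def partial_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial distance sqrt(L/(L−B) · Σ D_i²); Euclidean when B = 0."""
    return float(np.sqrt(partial_sqdist(a, b)))


def pairwise_sqdist(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Squared partial distances between rows of X (with blanks) and blank-free
    prototypes V.  Returns a (c, n) matrix."""
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    n, L = X.shape
    obs = ~np.isnan(X)
    n_obs = obs.sum(axis=1)
    if np.any(n_obs == 0):
        raise EmptyOverlapError("a row has no observed position")
    Xf = np.where(obs, X, 0.0)
    d2 = np.empty((V.shape[0], n))
    for i in range(V.shape[0]):
        diff = (Xf - V[i]) * obs
        d2[i] = np.einsum("jk,jk->j", diff, diff)
    return d2 * (L / n_obs)


# ---------------------------------------------------------------------------
# PDSFCM
# ---------------------------------------------------------------------------

def _memberships_from_sqdist(d2: np.ndarray, m: float) -> np.ndarray:
    """Fuzzy membership update; zero-distance columns become one-hot."""
    c, n = d2.shape
    U = np.empty((c, n))
    zero_cols = np.any(d2 <= 0.0, axis=0)
    with np.errstate(divide="ignore"):
        w = d2 ** (-1.0 / (m - 1.0))
    ok = ~zero_cols
    U[:, ok] = w[:, ok] / w[:, ok].sum(axis=0)
    for j in np.nonzero(zero_cols)[0]:
        U[:, j] = 0.0
        U[int(np.argmax(d2[:, j] <= 0.0)), j] = 1.0
    return U


def _as_matrix(X) -> np.ndarray:
    rows = getattr(X, "rows", X)
    return np.asarray(rows, dtype=float)


def pdsfcm(
    X,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    restarts: int = 5,
    seed: int | None = 0,
    key: str | None = None,
) -> ClusterSet:
    """Fit PDSFCM by alternating optimization, best of ``restarts`` seeded runs.

    The prototype update weights each row by u^m · L/(L−B_j) on its observed
    coordinates, the exact minimizer of the objective, so the objective is
    non-increasing at every iteration; with complete data the weights reduce
    to u^m and the algorithm coincides with standard FCM.
    """
    Xm = _as_matrix(X)
    n, L = Xm.shape
    if c < 1:
        raise ValueError("c must be >= 1")
    if c > n:
        raise ValueError(f"c={c} exceeds the number of subseries n={n}")
    obs = ~np.isnan(Xm)
    if np.any(obs.sum(axis=0) == 0):
        raise ValueError("a column of X is never observed")
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    row_factor = L / obs.sum(axis=1)          # L/(L−B_j), constant per row
    Xf = np.where(obs, Xm, 0.0)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, restarts)):
        U = rng.dirichlet(np.ones(c), size=n).T
        history = []
        for _it in range(max_iter):
            W = (U ** m) * row_factor                 # (c, n)
            num = W @ (Xf * obs)                      # observed-coordinate sums
            den = W @ obs
            V = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
            # empty prototype coordinate: fall back to the observed column mean
            if np.isnan(V).any():
                col_mean = np.nansum(Xf, axis=0) / obs.sum(axis=0)
                V = np.where(np.isnan(V), col_mean, V)
            d2 = pairwise_sqdist(Xm, V)
            U_new = _memberships_from_sqdist(d2, m)
            jm = float(np.sum((U_new ** m) * d2))
            history.append(jm)
            delta = float(np.max(np.abs(U_new - U)))
            U = U_new
            if delta < tol:
                break
        fit = ClusterSet(c=c, m=m, V=V, U=U, Jm=history[-1],
                         key=key or getattr(X, "key", "M"), L=L,
                         jm_history=history)
        if best is None or fit.Jm < best.Jm:
            best = fit
    return best


def fs_index(cs: ClusterSet, X) -> float:
    """Fukuyama–Sugeno index Σ u^m [d²(x, νi) − ‖νi − ν̄‖²]; lower is better."""
    Xm = _as_matrix(X)
    if Xm.shape[1] != cs.L:
        raise ValueError("regularized length mismatch between ClusterSet and X")
    d2 = pairwise_sqdist(Xm, cs.V)
    vbar = cs.V.mean(axis=0)
    sep = np.sum((cs.V - vbar) ** 2, axis=1)  # (c,)
    return float(np.sum((cs.U ** cs.m) * (d2 - sep[:, None])))


def _single_cluster(Xm: np.ndarray, key: str, m: float) -> ClusterSet:
    obs = ~np.isnan(Xm)
    if np.any(obs.sum(axis=0) == 0):
        raise ValueError("a column of X is never observed")
    proto = np.nansum(np.where(obs, Xm, 0.0), axis=0) / obs.sum(axis=0)
    V = proto[None, :]
    U = np.ones((1, Xm.shape[0]))
    d2 = pairwise_sqdist(Xm, V)
    return ClusterSet(c=1, m=m, V=V, U=U, Jm=float(d2.sum()), key=key,
                      L=Xm.shape[1])


def select_c(
    X,
    c_range=range(2, 11),
    m: float = 2.0,
    n_min: int = 10,
    seed: int | None = 0,
    **fcm_kwargs,
) -> ClusterSet:
    """Fit PDSFCM across ``c_range`` and keep the Fukuyama–Sugeno minimizer.

    With fewer than ``n_min`` subseries clustering is skipped and a degenerate
    single-cluster set is returned (prototype = partial-distance-aware
    elementwise mean, all memberships 1).
    """
    Xm = _as_matrix(X)
    key = getattr(X, "key", "M")
    n = Xm.shape[0]
    if n < n_min:
        return _single_cluster(Xm, key, m)
    best = None
    for c in c_range:
        if c > n:
            continue
        fit = pdsfcm(X, c=c, m=m, seed=seed, key=key, **fcm_kwargs)
        fit.fs = fs_index(fit, X)
        if best is None or fit.fs < best.fs:
            best = fit
    if best is None:
        return _single_cluster(Xm, key, m)
    return best


# ---------------------------------------------------------------------------
# Segment memberships (real-time weighting) and possibilistic counterpart
# ---------------------------------------------------------------------------

def segment_membership(g: np.ndarray, prototype_slices, m: float = 2.0) -> np.ndarray:
    """Fuzzy membership of an observed segment to each prototype slice.

    Memberships are normalized over the supplied index set; an exact match
    (zero distance) gets the whole mass on the first zero-distance cluster.
    """
    if len(prototype_slices) == 0:
        raise ValueError("index set must be non-empty")
    d2 = np.array([partial_sqdist(g, s) for s in prototype_slices])
    return _memberships_from_sqdist(d2[:, None], m)[:, 0]


def possibilistic_membership(g: np.ndarray, prototype_slice: np.ndarray,
                             eta: float, m: float = 2.0) -> float:
    """Typicality u^P = [1 + (η d²)^(1/(m−1))]^(−1) ∈ [0, 1]."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    d2 = partial_sqdist(g, prototype_slice)
    return float(1.0 / (1.0 + (eta * d2) ** (1.0 / (m - 1.0))))


def calibrate_eta(cs: ClusterSet, X, window: int = 5,
                  ceiling: float = ETA_CEILING) -> float:
    """Set η so a typical training window scores u^P = 0.5 at m = 2.

    η = 1 / median over training rows of the squared partial distance between
    a sliding ``window``-sample segment of the row and the same segment of its
    crisp-assigned prototype.
    """
    Xm = _as_matrix(X)
    labels = assign_crisp(cs)
    d2s = []
    for j in range(Xm.shape[0]):
        row = Xm[j]
        proto = cs.V[labels[j]]
        n_valid = int(np.max(np.nonzero(~np.isnan(row))[0])) + 1 if (~np.isnan(row)).any() else 0
        for start in range(0, max(1, n_valid - window + 1)):
            seg = row[start:start + window]
            if np.all(np.isnan(seg)):
                continue
            d2s.append(partial_sqdist(seg, proto[start:start + window]))
    med = float(np.median(d2s)) if d2s else 0.0
    eta = ceiling if med <= 0 else min(1.0 / med, ceiling)
    cs.eta = eta
    return eta


def assign_crisp(cs: ClusterSet, X=None) -> np.ndarray:
    """Crisp labels: argmax membership per row, ties to the lowest index."""
    return np.argmax(cs.U, axis=0)
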