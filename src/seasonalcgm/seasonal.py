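"""Concatenated seasonal series and per-cluster SARIMA local models.

Subseries assigned to a cluster are regularized to length L, preceded by Pr
pre-samples and concatenated in event-time order.  The resulting series has
an enforced seasonality s = L + Pr: the seasonal lags of a SARIMA model then
align corresponding samples across event instances.  Samples that are blank
(regularization padding or sensor gaps) or belong to pre-sampling periods are
entered in the state-space filter as missing observations — they feed no
innovation into the likelihood, which is the operational meaning of weighting
their residuals zero in the identification cost.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from pathlib import Path

import numpy as np

from statsmodels.tools.sm_exceptions import ConvergenceWarning
from statsmodels.tsa.statespace.sarimax import SARIMAX

__all__ = [
    "SCORED",
    "PRESAMPLE",
    "BLANK",
    "SeasonalSeries",
    "SarimaOrder",
    "SarimaModel",
    "LocalModelSet",
    "concatenate_cluster",
    "fit_sarima",
    "default_order_grid",
    "compact_order_grid",
    "search_order",
    "train_local_models",
    "batch_forecasts",
]

# mask codes
SCORED = 0
PRESAMPLE = 1
BLANK = 2


class FitError(RuntimeError):
    """SARIMA estimation failed (too-short series or no converged candidate)."""


@dataclasses.dataclass
class SarimaOrder:
    p: int = 0
    d: int = 0
    q: int = 0
    P: int = 0
    D: int = 0
    Q: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        if self.d not in (0, 1, 2) or self.D not in (0, 1, 2):
            raise ValueError("d and D must be in {0, 1, 2}")
        if min(self.p, self.q, self.P, self.Q) < 0:
            raise ValueError("orders must be nonnegative")

    @property
    def n_params(self) -> int:
        # coefficients + intercept (if undifferenced) + sigma2
        return self.p + self.q + self.P + self.Q + (1 if self.d + self.D == 0 else 0) + 1

    def key(self) -> tuple:
        return (self.p, self.d, self.q, self.P, self.D, self.Q)

    def __str__(self) -> str:
        return f"({self.p},{self.d},{self.q})({self.P},{self.D},{self.Q}){self.s}"


@dataclasses.dataclass
class SeasonalSeries:
    """Concatenation of [presample ++ regularized subseries] blocks."""

    values: np.ndarray   # raw samples (presamples included), blanks as NaN
    mask: np.ndarray     # SCORED / PRESAMPLE / BLANK per sample
    L: int
    Pr: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have the same shape")
        if self.s > 0 and self.values.size % self.s != 0:
            raise ValueError("length must be an exact multiple of s = L + Pr")
        # a blank value must carry valid data nowhere
        self.mask[np.isnan(self.values)] = np.where(
            self.mask[np.isnan(self.values)] == PRESAMPLE, PRESAMPLE, BLANK
        )

    @property
    def s(self) -> int:
        return self.L + self.Pr

    @property
    def n_blocks(self) -> int:
        return self.values.size // self.s

    def endog_for_fit(self) -> np.ndarray:
        """Samples entering the likelihood: presamples and blanks as NaN."""
        out = self.values.copy()
        out[self.mask != SCORED] = np.nan
        return out

    def endog_for_filter(self) -> np.ndarray:
        """Samples conditioning forecasts: only blanks as NaN."""
        out = self.values.copy()
        out[self.mask == BLANK] = np.nan
        return out

    def scored_count(self) -> int:
        return int(np.sum((self.mask == SCORED) & ~np.isnan(self.values)))

    def append_block(self, presample: np.ndarray, row: np.ndarray) -> None:
        """Append one [presample ++ length-L row] block in event-time order."""
        presample = np.asarray(presample, dtype=float)
        row = np.asarray(row, dtype=float)
        if presample.size != self.Pr or row.size != self.L:
            raise ValueError("block dimensions must match (Pr, L)")
        vals = np.concatenate([presample, row])
        msk = np.concatenate([
            np.full(self.Pr, PRESAMPLE, dtype=np.int8),
            np.where(np.isnan(row), BLANK, SCORED).astype(np.int8),
        ])
        self.values = np.concatenate([self.values, vals])
        self.mask = np.concatenate([self.mask, msk])

    def copy(self) -> "SeasonalSeries":
        return SeasonalSeries(self.values.copy(), self.mask.copy(), self.L, self.Pr)


def concatenate_cluster(presamples: np.ndarray, rows: np.ndarray,
                        L: int, Pr: int) -> SeasonalSeries:
    """Build the seasonal series from (n, Pr) presamples and (n, L) rows,
    already sorted in ascending event time."""
    presamples = np.atleast_2d(np.asarray(presamples, dtype=float))
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] == 0:
        raise ValueError("cannot concatenate an empty cluster")
    if rows.shape[1] != L or presamples.shape != (rows.shape[0], Pr):
        raise ValueError("block dimensions must match (Pr, L)")
    series = SeasonalSeries(np.empty(0), np.empty(0, dtype=np.int8), L=L, Pr=Pr)
    for j in range(rows.shape[0]):
        series.append_block(presamples[j], rows[j])
    return series


# ---------------------------------------------------------------------------
# SARIMA estimation through the state-space representation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SarimaModel:
    """Fitted SARIMA (p,d,q)(P,D,Q)s local model."""

    order: SarimaOrder
    params: np.ndarray
    param_names: list
    bse: np.ndarray
    sigma2: float
    llf: float
    aicc: float
    converged: bool

    @property
    def alpha(self) -> float:
        return self._coef("intercept")

    @property
    def phi(self) -> np.ndarray:
        return self._coefs("ar.L")

    @property
    def theta(self) -> np.ndarray:
        return self._coefs("ma.L")

    @property
    def Phi(self) -> np.ndarray:
        return self._coefs("ar.S.L")

    @property
    def Theta(self) -> np.ndarray:
        return self._coefs("ma.S.L")

    def _coef(self, name: str) -> float:
        for n, v in zip(self.param_names, self.params):
            if n == name:
                return float(v)
        return 0.0

    def _coefs(self, prefix: str) -> np.ndarray:
        out = [float(v) for n, v in zip(self.param_names, self.params)
               if n.startswith(prefix) and not n[len(prefix):].startswith("S")]
        return np.array(out)

    def statespace(self, endog: np.ndarray) -> SARIMAX:
        o = self.order
        return _build_sarimax(endog, o)

    def to_dict(self) -> dict:
        return {
            "order": list(self.order.key()) + [self.order.s],
            "params": list(map(float, self.params)),
            "param_names": list(self.param_names),
            "bse": list(map(float, self.bse)),
            "sigma2": self.sigma2,
            "llf": self.llf,
            "aicc": self.aicc,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SarimaModel":
        p, dd, q, P, D, Q, s = d["order"]
        return cls(
            order=SarimaOrder(p, dd, q, P, D, Q, s),
            params=np.array(d["params"]),
            param_names=list(d["param_names"]),
            bse=np.array(d["bse"]),
            sigma2=d["sigma2"],
            llf=d["llf"],
            aicc=d["aicc"],
            converged=d["converged"],
        )


def _build_sarimax(endog: np.ndarray, o: SarimaOrder) -> SARIMAX:
    seasonal = (o.P, o.D, o.Q, o.s) if (o.P or o.D or o.Q) else (0, 0, 0, 0)
    trend = "c" if o.d + o.D == 0 else None
    return SARIMAX(
        endog,
        order=(o.p, o.d, o.q),
        seasonal_order=seasonal,
        trend=trend,
        enforce_stationarity=True,
        enforce_invertibility=True,
        concentrate_scale=True,
    )


def _shrink(coefs: np.ndarray, budget: float = 0.9) -> np.ndarray:
    total = np.abs(coefs).sum()
    return coefs * (budget / total) if total > budget else coefs


def _warm_start(endog: np.ndarray, o: SarimaOrder):
    """Masked-OLS starting values for the AR/seasonal-AR terms.

    Regresses y_t on its (seasonal) AR lags over complete cases; MA terms
    start at zero.  Returns None (statsmodels defaults) when the regression
    is infeasible or the model is differenced.
    """
    if o.d + o.D > 0:
        return None
    lags = list(range(1, o.p + 1)) + [o.s * j for j in range(1, o.P + 1)]
    if not lags:
        ok = ~np.isnan(endog)
        if not ok.any():
            return None
        return np.array([float(np.mean(endog[ok]))] + [0.0] * (o.q + o.Q))
    mx = max(lags)
    if endog.size <= mx + len(lags) + 2:
        return None
    X = np.column_stack([np.ones(endog.size - mx)]
                        + [endog[mx - l: endog.size - l] for l in lags])
    yy = endog[mx:]
    ok = ~np.isnan(yy) & ~np.isnan(X).any(axis=1)
    if ok.sum() < len(lags) + 2:
        return None
    try:
        beta, *_ = np.linalg.lstsq(X[ok], yy[ok], rcond=None)
    except np.linalg.LinAlgError:
        return None
    phi = _shrink(beta[1: 1 + o.p])
    Phi = _shrink(beta[1 + o.p:])
    return np.concatenate([
        [beta[0]], phi, np.zeros(o.q), Phi, np.zeros(o.Q),
    ])


def fit_sarima(series: SeasonalSeries, order: SarimaOrder,
               maxiter: int = 50, min_seasons: int = 3,
               compute_cov: bool = False) -> SarimaModel:
    """Maximum-likelihood SARIMA fit with blanks/presamples unobserved.

    The likelihood is evaluated by the Kalman filter; masked samples trigger
    the prediction step only, contributing no innovation, so the information
    criterion is computed over scored samples alone.  The innovation variance
    is concentrated out of the likelihood and recovered afterwards; standard
    errors are computed only on request (``compute_cov``), since the
    numerical Hessian is expensive for long seasonal periods.
    """
    if order.s != series.s and (order.P or order.D or order.Q):
        raise ValueError("model seasonality must equal the series seasonality")
    n_scored = series.scored_count()
    needed = min_seasons * series.s if (order.P or order.D or order.Q) else 5 * max(order.p + order.q, 1)
    if n_scored < needed:
        raise FitError(
            f"series too short for order {order}: {n_scored} scored samples < {needed}"
        )
    endog = series.endog_for_fit()
    mod = _build_sarimax(endog, order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            if compute_cov:
                # standard-error-grade fit: exact score, tight tolerances
                res = mod.fit(disp=0, method="lbfgs", maxiter=max(maxiter, 200),
                              start_params=_warm_start(endog, order))
            else:
                # order-search-grade fit: finite-difference gradient, loose stop
                res = mod.fit(
                    disp=0, method="lbfgs", maxiter=maxiter,
                    start_params=_warm_start(endog, order), cov_type="none",
                    approx_grad=True, epsilon=1e-5, factr=1e9, pgtol=1e-4,
                )
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"estimation failed for order {order}: {exc}") from None
    converged = bool(res.mle_retvals.get("converged", True))
    k = len(res.params) + 1  # concentrated scale counts as a free parameter
    if n_scored > k + 1:
        aicc = float(-2 * res.llf + 2 * k + 2 * k * (k + 1) / (n_scored - k - 1))
    else:
        aicc = np.inf
    sigma2 = float(res.scale)
    if not np.isfinite(res.llf) or sigma2 <= 0:
        raise FitError(f"degenerate fit for order {order}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bse = np.asarray(res.bse, dtype=float) if compute_cov \
            else np.full(len(res.params), np.nan)
    return SarimaModel(
        order=order,
        params=np.asarray(res.params, dtype=float),
        param_names=list(res.param_names),
        bse=bse,
        sigma2=sigma2,
        llf=float(res.llf),
        aicc=aicc,
        converged=converged,
    )


def default_order_grid(s: int) -> list:
    """Exhaustive search grid p∈0..4, q∈0..4, P∈0..2, Q∈0..2, d,D∈{0,1}."""
    grid = []
    for p, d, q, P, D, Q in itertools.product(
        range(5), (0, 1), range(5), range(3), (0, 1), range(3)
    ):
        if p + q + P + Q + d + D == 0:
            continue
        grid.append(SarimaOrder(p, d, q, P, D, Q, s))
    return grid


def compact_order_grid(s: int) -> list:
    """Small candidate list used by the pipeline's default configuration."""
    keys = [
        (1, 0, 0, 1, 0, 0),
        (2, 0, 0, 1, 0, 0),
        (1, 0, 1, 1, 0, 0),
        (1, 0, 0, 0, 0, 0),
    ]
    return [SarimaOrder(p, d, q, P, D, Q, s) for p, d, q, P, D, Q in keys]


def search_order(series: SeasonalSeries, grid=None, maxiter: int = 100) -> SarimaModel:
    """Grid search over SARIMA orders; minimal small-sample-corrected criterion.

    Non-converged or failed candidates are dropped; ties break toward fewer
    parameters, then the lexicographically smallest order.
    """
    if grid is None:
        grid = default_order_grid(series.s)
    if not grid:
        raise ValueError("order grid must be non-empty")
    candidates = []
    for order in grid:
        try:
            fit = fit_sarima(series, order, maxiter=maxiter)
        except FitError:
            continue
        if not fit.converged or not np.isfinite(fit.aicc):
            continue
        candidates.append(fit)
    if not candidates:
        raise FitError("no candidate order converged")
    candidates.sort(key=lambda f: (f.aicc, f.order.n_params, f.order.key()))
    return candidates[0]


# ---------------------------------------------------------------------------
# Forecasting
# ---------------------------------------------------------------------------

def _filter(model: SarimaModel, endog: np.ndarray):
    mod = _build_sarimax(endog, model.order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mod.filter(model.params)


def forecast_local(model: SarimaModel, history: SeasonalSeries,
                   current: np.ndarray, horizon: int) -> np.ndarray:
    """MMSE forecast of the ``horizon`` samples following the current block.

    ``current`` is the presample plus the partial subseries observed so far
    (blanks as NaN), placed at the next seasonal slot after the history.  If
    the horizon runs past the current slot the forecast simply continues into
    subsequent slots.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    endog = np.concatenate([history.endog_for_filter(), np.asarray(current, dtype=float)])
    res = _filter(model, endog)
    return np.asarray(res.forecast(horizon))


def batch_forecasts(model: SarimaModel, endog: np.ndarray, horizon: int) -> np.ndarray:
    """All fixed-origin forecasts ŷ(t+h | t) for t = 0..n−1, h = 1..horizon.

    A single Kalman-filter pass gives the filtered states a(t|t); h-step
    forecasts follow from iterating the (time-invariant) transition equation,
    which is orders of magnitude cheaper than refiltering per origin.
    Returns an (n, horizon) array.
    """
    res = _filter(model, endog)
    fr = res.filter_results
    T = fr.transition[:, :, 0]
    Z = fr.design[0, :, 0]
    c = fr.state_intercept
    c = c[:, 0] if c.ndim == 2 else c
    d = fr.obs_intercept
    d = float(d.ravel()[0]) if d.size else 0.0
    A = np.array(fr.filtered_state)          # (k_states, n)
    out = np.empty((A.shape[1], horizon))
    for h in range(horizon):
        A = T @ A + c[:, None]
        out[:, h] = Z @ A + d
    return out


# ---------------------------------------------------------------------------
# Training: 80/20 split per cluster, order search, fallbacks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LocalModelSet:
    """Per-partition clusters, their SARIMA models and growing histories."""

    key: str
    models: list                 # SarimaModel per cluster
    histories: list              # SeasonalSeries per cluster (all rows)
    heldout_blocks: list         # per cluster: block indices held out (0-based)
    L: int
    Pr: int

    @property
    def c(self) -> int:
        return len(self.models)

    @property
    def s(self) -> int:
        return self.L + self.Pr

    def to_json(self, path) -> None:
        payload = {
            "key": self.key,
            "L": self.L,
            "Pr": self.Pr,
            "heldout_blocks": self.heldout_blocks,
            "models": [m.to_dict() for m in self.models],
            "histories": [
                {
                    "values": [None if np.isnan(v) else float(v) for v in h.values],
                    "mask": h.mask.tolist(),
                }
                for h in self.histories
            ],
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "LocalModelSet":
        dd = json.loads(Path(path).read_text(encoding="utf-8"))
        histories = [
            SeasonalSeries(
                np.array([np.nan if v is None else v for v in h["values"]]),
                np.array(h["mask"], dtype=np.int8),
                L=dd["L"], Pr=dd["Pr"],
            )
            for h in dd["histories"]
        ]
        return cls(
            key=dd["key"],
            models=[SarimaModel.from_dict(m) for m in dd["models"]],
            histories=histories,
            heldout_blocks=dd["heldout_blocks"],
            L=dd["L"],
            Pr=dd["Pr"],
        )


_FALLBACK_KEYS = [(1, 0, 0, 0, 0, 0), (0, 0, 0, 0, 0, 0)]


def _fit_with_fallback(series: SeasonalSeries, grid, maxiter: int) -> SarimaModel:
    try:
        return search_order(series, grid, maxiter=maxiter)
    except FitError:
        pass
    for key in _FALLBACK_KEYS:
        try:
            return fit_sarima(series, SarimaOrder(*key, s=series.s), maxiter=maxiter)
        except FitError:
            continue
    raise FitError("no SARIMA candidate could be fitted, even the fallbacks")


def train_local_models(partition, cs, grid=None, train_frac: float = 0.8,
                       min_rows: int = 5, maxiter: int = 100) -> LocalModelSet:
    """Identify one SARIMA model per cluster on the first 80% of its rows.

    Rows (subseries) are in event-time order; the remaining 20% stay in the
    seasonal history as held-out validation blocks.  Clusters with fewer than
    ``min_rows`` rows use all rows and the fallback candidate chain.
    """
    from .clustering import assign_crisp

    labels = assign_crisp(cs)
    models, histories, heldout = [], [], []
    for i in range(cs.c):
        idx = np.nonzero(labels == i)[0]
        if idx.size == 0:
            raise FitError(f"cluster {i} is empty after crisp assignment")
        full = concatenate_cluster(partition.presamples[idx], partition.rows[idx],
                                   partition.L, partition.Pr)
        if idx.size < min_rows:
            warnings.warn(
                f"cluster {i} has only {idx.size} subseries; "
                "using all rows and the fallback model chain", stacklevel=2)
            n_tr = idx.size
        else:
            n_tr = max(1, int(np.floor(train_frac * idx.size + 1e-9)))
        ident = concatenate_cluster(partition.presamples[idx[:n_tr]],
                                    partition.rows[idx[:n_tr]],
                                    partition.L, partition.Pr)
        models.append(_fit_with_fallback(ident, grid, maxiter))
        histories.append(full)
        heldout.append(list(range(n_tr, idx.size)))
    return LocalModelSet(key=cs.key, models=models, histories=histories,
                         heldout_blocks=heldout, L=partition.L, Pr=partition.Pr)
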