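"""Forecast accuracy metrics, offline validation replay and NI analysis.

Two residual conventions are reported:

* ``traj`` — residuals over each whole predicted trajectory, one RMSE/MAPE
  per prediction, averaged over predictions;
* ``last`` — residuals of the PH-ahead point predictions, one RMSE/MAPE per
  subseries (li − PH residuals each), averaged over subseries.

The replay harness runs a trained predictor over an independent dataset,
selecting the per-event-group predictor at each event, appending each closed
subseries to the winning cluster's seasonal history, and collecting both
metric families, the crispness/normality indices, and a zero-order-hold
baseline.  A single Kalman-filter pass per (cluster, subseries) yields all
fixed-origin forecasts, which keeps the replay tractable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import segment_membership
from .data import DataFormatError, EventLog, GlucoseSeries
from .partition import group_of
from .predictor import prototype_slice
from .seasonal import batch_forecasts

__all__ = [
    "metrics_traj",
    "metrics_last",
    "ReplayResult",
    "replay",
    "validate",
    "ni_error_analysis",
    "summarize_metrics",
]

MAPE_FLOOR = 1.0  # mg/dL; guards the MAPE division (unreachable with clamped CGM)


def _rmse(e: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(e))))


def metrics_traj(pairs) -> tuple:
    """Mean per-prediction RMSE and MAPE over full predicted trajectories.

    ``pairs`` is an iterable of (predicted, actual) arrays; residuals at
    blank actuals are excluded, fully blank predictions are skipped.
    """
    rmses, mapes = per_prediction_metrics(pairs)
    if rmses.size == 0:
        raise ValueError("no scorable predictions")
    return float(rmses.mean()), float(mapes.mean())


def per_prediction_metrics(pairs) -> tuple:
    rmses, mapes = [], []
    for pred, actual in pairs:
        pred = np.asarray(pred, dtype=float)
        actual = np.asarray(actual, dtype=float)
        ok = ~np.isnan(actual) & ~np.isnan(pred) & (actual >= MAPE_FLOOR)
        if not ok.any():
            continue
        e = actual[ok] - pred[ok]
        rmses.append(_rmse(e))
        mapes.append(float(100.0 * np.mean(np.abs(e) / actual[ok])))
    return np.array(rmses), np.array(mapes)


def metrics_last(per_subseries_pairs) -> tuple:
    """Mean per-subseries RMSE and MAPE of PH-ahead point predictions."""
    rmses, mapes = per_prediction_metrics(per_subseries_pairs)
    if rmses.size == 0:
        raise ValueError("no scorable subseries")
    return float(rmses.mean()), float(mapes.mean())


# ---------------------------------------------------------------------------
# Vectorized segment distances along a subseries
# ---------------------------------------------------------------------------

def _onset_sqdists(g: np.ndarray, V: np.ndarray) -> np.ndarray:
    """d²([G]_{tek..tp}, [νi]) for every tp; (c, li) matrix, hold-last slices."""
    li = g.size
    obs = ~np.isnan(g)
    gf = np.where(obs, g, 0.0)
    n_obs = np.cumsum(obs)
    seg_len = np.arange(1, li + 1)
    d2 = np.empty((V.shape[0], li))
    for i in range(V.shape[0]):
        prot = prototype_slice(V[i], 0, li)
        sq = np.square(gf - prot) * obs
        csum = np.cumsum(sq)
        with np.errstate(divide="ignore", invalid="ignore"):
            d2[i] = seg_len / n_obs * csum
    d2[:, n_obs == 0] = np.nan
    return d2


def _window_sqdists(g: np.ndarray, V: np.ndarray, W: int) -> np.ndarray:
    """d²([G]_{tp−W..tp}, [νi]) per tp with the window truncated at onset."""
    li = g.size
    obs = ~np.isnan(g)
    gf = np.where(obs, g, 0.0)
    starts = np.maximum(0, np.arange(li) - W)
    seg_len = np.arange(li) - starts + 1
    obs_c = np.concatenate([[0], np.cumsum(obs)])
    n_obs = obs_c[np.arange(li) + 1] - obs_c[starts]
    d2 = np.empty((V.shape[0], li))
    for i in range(V.shape[0]):
        prot = prototype_slice(V[i], 0, li)
        sq_c = np.concatenate([[0.0], np.cumsum(np.square(gf - prot) * obs)])
        ssum = sq_c[np.arange(li) + 1] - sq_c[starts]
        with np.errstate(divide="ignore", invalid="ignore"):
            d2[i] = seg_len / n_obs * ssum
    d2[:, n_obs == 0] = np.nan
    return d2


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Columnwise fuzzy memberships from squared distances (NaN-safe)."""
    c, n = d2.shape
    U = np.full((c, n), np.nan)
    valid = ~np.any(np.isnan(d2), axis=0)
    zero = valid & np.any(d2 <= 0.0, axis=0)
    plain = valid & ~zero
    with np.errstate(divide="ignore"):
        w = d2[:, plain] ** (-1.0 / (m - 1.0))
    U[:, plain] = w / w.sum(axis=0)
    for j in np.nonzero(zero)[0]:
        U[:, j] = 0.0
        U[int(np.argmax(d2[:, j] <= 0.0)), j] = 1.0
    return U


# ---------------------------------------------------------------------------
# Replay of a dataset through the trained predictor
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SubseriesRecord:
    event_index: int
    key: str
    label: str
    start: int
    length: int
    gamma: np.ndarray       # (c, li)
    ci: np.ndarray          # (li,)
    ni: np.ndarray          # (li,)
    forecasts: np.ndarray   # (li, max_ph) GSM fixed-origin forecasts
    zoh: np.ndarray         # (li,) last observed value at each tp


@dataclasses.dataclass
class ReplayResult:
    records: list
    series: GlucoseSeries
    max_ph: int

    def stream_frame(self, ph: int, ni_threshold: float = 0.2) -> pd.DataFrame:
        """Per-sample streaming output (one row per tp)."""
        rows = []
        for rec in self.records:
            for j in range(rec.length):
                row = {
                    "tp": rec.start + j,
                    "PH": ph,
                    "CI": rec.ci[j],
                    "NI": rec.ni[j],
                    "abnormal": bool(rec.ni[j] < ni_threshold),
                    "active_event": rec.label,
                    "active_partition": rec.key,
                }
                for h in range(ph):
                    row[f"pred_{h + 1}"] = rec.forecasts[j, h]
                for i in range(rec.gamma.shape[0]):
                    row[f"gamma_{i + 1}"] = rec.gamma[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def replay(clustersets: dict, modelsets: dict, series: GlucoseSeries,
           log: EventLog, max_ph: int, W: int = 4, mu_factor: float = 0.2,
           min_length: int = 2, strict: bool = True,
           max_history_blocks: int = 12) -> ReplayResult:
    """Replay a dataset through the trained per-partition predictors.

    Histories are copied and grow as each closed subseries is appended to its
    winning cluster, mirroring real-time operation.  ``strict=False`` skips
    subseries whose event group has no trained predictor instead of raising.
    Forecasts condition on at most the ``max_history_blocks`` most recent
    seasonal blocks — seasonal lags reach back a handful of blocks at most,
    so older history carries no extra forecast information.
    """
    if len(log) < 2:
        raise DataFormatError("need at least two events to replay")
    offsets = log.to_offsets(series)
    bounds = list(offsets) + [len(series)]
    histories = {
        key: [h.copy() for h in lms.histories] for key, lms in modelsets.items()
    }
    records = []
    for i, label in enumerate(log.labels):
        key = group_of(label)
        start, end = bounds[i], bounds[i + 1]
        li = end - start
        if li < min_length:
            continue
        if key not in modelsets:
            if strict:
                raise KeyError(f"no trained partition for event group {key!r}")
            continue
        cs = clustersets[key]
        lms = modelsets[key]
        g = series.values[start:end]
        pres = series.values[max(0, start - lms.Pr):start]
        if pres.size < lms.Pr:
            pres = np.concatenate([np.full(lms.Pr - pres.size, np.nan), pres])

        # local fixed-origin forecasts from every tp, one filter pass/cluster
        F_loc = np.empty((cs.c, li, max_ph))
        for ci_ in range(cs.c):
            hist = histories[key][ci_].endog_for_filter()
            if max_history_blocks is not None:
                hist = hist[-max_history_blocks * lms.s:]
            endog = np.concatenate([hist, pres, g])
            base = endog.size - li
            F_loc[ci_] = batch_forecasts(lms.models[ci_], endog, max_ph)[base:]

        # two-step weights at every tp
        d2_on = _onset_sqdists(g, cs.V)
        u_on = _memberships(d2_on, cs.m)
        mu_min = mu_factor * np.nanmax(u_on, axis=0)
        survive = u_on >= mu_min                      # (c, li)
        d2_w = _window_sqdists(g, cs.V, W)
        d2_w_surv = np.where(survive, d2_w, np.nan)
        gamma = np.zeros_like(d2_w)
        ciarr = np.full(li, np.nan)
        niarr = np.full(li, np.nan)
        for j in range(li):
            I2 = np.nonzero(survive[:, j])[0]
            if I2.size == 0 or np.any(np.isnan(d2_w_surv[I2, j])):
                continue
            u = _memberships(d2_w_surv[I2, j][:, None], cs.m)[:, 0]
            gamma[I2, j] = u
            gP = 1.0 / (1.0 + (cs.eta * d2_w[I2, j]) ** (1.0 / (cs.m - 1.0)))
            ciarr[j] = _crisp(gamma[:, j])
            niarr[j] = gP.sum() / I2.size

        F = np.einsum("cj,cjh->jh", gamma, F_loc)
        bad = np.isnan(ciarr)
        F[bad] = np.nan

        # zero-order-hold baseline: last observed value at each tp
        zoh = np.empty(li)
        last = np.nan
        for j in range(li):
            if not np.isnan(g[j]):
                last = g[j]
            zoh[j] = last

        records.append(SubseriesRecord(
            event_index=i, key=key, label=label, start=start, length=li,
            gamma=gamma, ci=ciarr, ni=niarr, forecasts=F, zoh=zoh,
        ))

        # close the subseries: append to the winning cluster's history
        slices = [prototype_slice(cs.V[k], 0, li) for k in range(cs.c)]
        u_full = segment_membership(g, slices, cs.m)
        winner = int(np.argmax(u_full))
        row = np.full(lms.L, np.nan)
        row[: min(li, lms.L)] = g[: lms.L]
        histories[key][winner].append_block(pres, row)

    return ReplayResult(records=records, series=series, max_ph=max_ph)


def _crisp(gamma: np.ndarray) -> float:
    c = gamma.size
    if c == 1:
        return 1.0
    return float(np.abs(gamma - 1.0 / c).sum() / (2.0 * (1.0 - 1.0 / c)))


# ---------------------------------------------------------------------------
# Metric extraction from a replay
# ---------------------------------------------------------------------------

def _collect(result: ReplayResult, ph: int, use_zoh: bool = False):
    """Per-prediction trajectory pairs and per-subseries last-point pairs."""
    actual = result.series.values
    n_total = actual.size
    traj_pairs = {}
    last_pairs = {}
    for rec in result.records:
        li = rec.length
        if li <= ph:
            continue  # subseries shorter than or equal to PH are discarded
        tp_max = li - ph          # inclusive bound for trajectory origins
        tpairs, lpred, lact = [], [], []
        for j in range(tp_max + 1):
            hi = rec.start + j + ph
            if hi >= n_total:
                break
            if use_zoh:
                pred = np.full(ph, rec.zoh[j])
            else:
                pred = rec.forecasts[j, :ph]
            tpairs.append((pred, actual[rec.start + j + 1: hi + 1]))
        for j in range(li - ph):
            lpred.append(rec.zoh[j] if use_zoh else rec.forecasts[j, ph - 1])
            lact.append(actual[rec.start + j + ph])
        traj_pairs.setdefault(rec.key, []).extend(tpairs)
        if lpred:
            last_pairs.setdefault(rec.key, []).append(
                (np.array(lpred), np.array(lact)))
    return traj_pairs, last_pairs


def summarize_metrics(result: ReplayResult, ph_list: list,
                      use_zoh: bool = False) -> pd.DataFrame:
    """Table-style report: per-partition and overall rows for each PH.

    Per-item values (per prediction for ``traj``, per subseries for
    ``last``) are pooled; mean, SD, median and quartiles are reported.
    """
    rows = []
    for ph in ph_list:
        traj_pairs, last_pairs = _collect(result, ph, use_zoh=use_zoh)
        keys = sorted(set(traj_pairs) | set(last_pairs))
        for key in keys + ["overall"]:
            if key == "overall":
                tp_ = [p for v in traj_pairs.values() for p in v]
                lp_ = [p for v in last_pairs.values() for p in v]
            else:
                tp_ = traj_pairs.get(key, [])
                lp_ = last_pairs.get(key, [])
            if not tp_ and not lp_:
                continue
            r_t, m_t = per_prediction_metrics(tp_)
            r_l, m_l = per_prediction_metrics(lp_)
            row = {"partition": key, "PH_samples": ph, "n_predictions": len(r_t)}
            for name, arr in [("RMSEtraj", r_t), ("MAPEtraj", m_t),
                              ("RMSElast", r_l), ("MAPElast", m_l)]:
                if arr.size:
                    row.update({
                        f"{name}_mean": float(arr.mean()),
                        f"{name}_sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                        f"{name}_median": float(np.median(arr)),
                        f"{name}_q25": float(np.percentile(arr, 25)),
                        f"{name}_q75": float(np.percentile(arr, 75)),
                    })
                else:
                    row.update({f"{name}_{s}": np.nan
                                for s in ("mean", "sd", "median", "q25", "q75")})
            rows.append(row)
    return pd.DataFrame(rows)


def validate(clustersets: dict, modelsets: dict, series: GlucoseSeries,
             log: EventLog, ph_minutes: list, sampling_period: int = 5,
             W: int = 4, mu_factor: float = 0.2, strict: bool = True):
    """Full offline validation: replay + metric report at each PH (minutes)."""
    ph_samples = []
    for ph in ph_minutes:
        if ph % sampling_period != 0:
            raise ValueError(f"PH={ph} min is not a multiple of the sampling period")
        ph_samples.append(ph // sampling_period)
    result = replay(clustersets, modelsets, series, log, max(ph_samples),
                    W=W, mu_factor=mu_factor, strict=strict)
    report = summarize_metrics(result, ph_samples)
    report.insert(1, "PH_min", report["PH_samples"] * sampling_period)
    return report, result


def local_heldout_report(modelsets: dict, ph_samples: int = 6) -> pd.DataFrame:
    """Per-cluster PH-ahead accuracy on the held-out 20% blocks.

    Held-out subseries stay appended to each cluster's seasonal history, so
    seasonal lags exist; only their own scored samples are scored.
    """
    from .seasonal import SCORED, batch_forecasts

    rows = []
    for key, lms in modelsets.items():
        for i, model in enumerate(lms.models):
            hist = lms.histories[i]
            held = lms.heldout_blocks[i]
            if not held:
                continue
            endog = hist.endog_for_filter()
            F = batch_forecasts(model, endog, ph_samples)
            resid = []
            for b in held:
                for j in range(b * lms.s, (b + 1) * lms.s):
                    origin = j - ph_samples
                    if origin < 0:
                        continue
                    if hist.mask[j] != SCORED or np.isnan(hist.values[j]):
                        continue
                    resid.append(hist.values[j] - F[origin, ph_samples - 1])
            if resid:
                resid = np.asarray(resid)
                rows.append({
                    "partition": key, "cluster": i + 1,
                    "order": str(model.order),
                    "n_heldout_blocks": len(held),
                    "n_residuals": resid.size,
                    "RMSElast": float(np.sqrt(np.mean(resid ** 2))),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NI vs prediction-error analysis
# ---------------------------------------------------------------------------

def ni_stream(result: ReplayResult, ph: int, use_zoh: bool = False):
    """(NI(tp), |residual at tp+PH|) pairs across all subseries."""
    actual = result.series.values
    nis, errs = [], []
    for rec in result.records:
        li = rec.length
        for j in range(li - ph):
            a = actual[rec.start + j + ph]
            f = rec.zoh[j] if use_zoh else rec.forecasts[j, ph - 1]
            if np.isnan(a) or np.isnan(f) or np.isnan(rec.ni[j]):
                continue
            nis.append(rec.ni[j])
            errs.append(abs(a - f))
    return np.array(nis), np.array(errs)


def ni_error_analysis(ni: np.ndarray, abs_resid: np.ndarray,
                      thresholds=None) -> pd.DataFrame:
    """Median |residual| below vs above each NI threshold + rank-sum test.

    The difference is median(below) − median(above): positive values mean
    low-NI samples carry larger errors.  Thresholds with an empty group are
    marked undefined (NaN row).
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.1, 0.95, 0.1), 10)
    ni = np.asarray(ni, dtype=float)
    abs_resid = np.asarray(abs_resid, dtype=float)
    rows = []
    for thr in thresholds:
        below = abs_resid[ni < thr]
        above = abs_resid[ni >= thr]
        if below.size == 0 or above.size == 0:
            rows.append({"NIthr": thr, "n_below": below.size,
                         "n_above": above.size, "median_below": np.nan,
                         "median_above": np.nan, "difference": np.nan,
                         "p_value": np.nan})
            continue
        stat = stats.mannwhitneyu(below, above, alternative="two-sided")
        rows.append({
            "NIthr": float(thr),
            "n_below": int(below.size),
            "n_above": int(above.size),
            "median_below": float(np.median(below)),
            "median_above": float(np.median(above)),
            "difference": float(np.median(below) - np.median(above)),
            "p_value": float(stat.pvalue),
        })
    return pd.DataFrame(rows)
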