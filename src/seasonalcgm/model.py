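"""Statsmodels-style facade: a model built from CGM + event data, whose
``fit`` returns a results object carrying the per-partition cluster sets,
local SARIMA models, diagnostics and a summary table; prediction, validation
and plotting hang off the results object.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation
from .clustering import ClusterSet, calibrate_eta, select_c
from .data import EventLog, GlucoseSeries, read_cgm_csv, read_events_csv
from .partition import PARTITION_KEYS, build_partitions, regularize
from .seasonal import LocalModelSet, compact_order_grid, train_local_models

__all__ = ["SeasonalGlucoseModel", "SeasonalGlucoseResults"]


class SeasonalGlucoseModel:
    """Event-driven seasonal local-model glucose predictor.

    Parameters
    ----------
    series : GlucoseSeries
        Training CGM trace (5-min grid, mg/dL).
    events : EventLog
        Time-stamped labeled events driving the partitioning.
    pr : int
        Pre-sampling length Pr in samples (default 5).
    m : float
        Clustering fuzziness (default 2).
    c_range : iterable of int
        Cluster counts scored by the Fukuyama–Sugeno index (default 2..10).
    n_min : int
        Below this many subseries a partition falls back to a single model.
    order_grid : callable s -> list of SarimaOrder, optional
        SARIMA candidate orders; default is a compact candidate list.
    exclude_events : iterable of int
        Event indices whose subseries are dropped from training (e.g.
        missed-bolus postprandial periods).
    """

    def __init__(self, series: GlucoseSeries, events: EventLog, *,
                 pr: int = 5, m: float = 2.0, c_range=range(2, 11),
                 n_min: int = 10, window: int = 4, mu_factor: float = 0.2,
                 ni_threshold: float = 0.2, order_grid=None,
                 exclude_events=()):
        self.series = series
        self.events = events
        self.pr = pr
        self.m = m
        self.c_range = list(c_range)
        self.n_min = n_min
        self.window = window
        self.mu_factor = mu_factor
        self.ni_threshold = ni_threshold
        self.order_grid = order_grid or compact_order_grid
        self.exclude_events = set(exclude_events)

    @classmethod
    def from_csv(cls, cgm_path, events_path, **kwargs) -> "SeasonalGlucoseModel":
        series = read_cgm_csv(cgm_path)
        events = read_events_csv(events_path, sampling_period=series.sampling_period,
                                 grid_epoch=series.start_time)
        return cls(series, events, **kwargs)

    def fit(self, seed: int = 0, restarts: int = 5,
            maxiter: int = 100, verbose: bool = False) -> "SeasonalGlucoseResults":
        """Partition, cluster, calibrate and identify local models per group."""
        subs = build_partitions(self.series, self.events, pr=self.pr)
        clustersets, modelsets, skipped = {}, {}, []
        for key in PARTITION_KEYS:
            rows = [s for s in subs[key] if s.event_index not in self.exclude_events]
            if not rows:
                skipped.append(key)
                continue
            part = regularize(rows, key, pr=self.pr)
            cs = select_c(part, c_range=self.c_range, m=self.m,
                          n_min=self.n_min, seed=seed, restarts=restarts)
            calibrate_eta(cs, part, window=self.window + 1)
            try:
                lms = train_local_models(part, cs,
                                         grid=self.order_grid(part.L + self.pr),
                                         maxiter=maxiter)
            except Exception as exc:  # a partition that cannot be modeled is skipped
                warnings.warn(f"partition {key}: local model training failed: {exc}",
                              stacklevel=2)
                skipped.append(key)
                continue
            clustersets[key] = cs
            modelsets[key] = lms
            if verbose:
                orders = ", ".join(str(mdl.order) for mdl in lms.models)
                print(f"partition {key}: n={part.n}, L={part.L}, c={cs.c}, orders: {orders}")
        if not clustersets:
            raise RuntimeError("no partition could be trained")
        return SeasonalGlucoseResults(self, clustersets, modelsets, skipped)


@dataclasses.dataclass
class SeasonalGlucoseResults:
    """Fitted per-partition cluster sets and SARIMA local model sets."""

    model: SeasonalGlucoseModel
    clustersets: dict
    modelsets: dict
    skipped: list

    def summary(self) -> str:
        lines = ["Seasonal stochastic local glucose model", "=" * 54]
        for key, cs in self.clustersets.items():
            lms = self.modelsets[key]
            lines.append(f"Partition {key}: n={cs.n} subseries, L={cs.L}, "
                         f"s={lms.s}, c={cs.c}, eta={cs.eta:.3g}")
            for i, mdl in enumerate(lms.models):
                n_blocks = lms.histories[i].n_blocks
                lines.append(f"  cluster {i + 1}: {n_blocks} subseries, "
                             f"SARIMA{mdl.order}  AICc={mdl.aicc:.1f}")
        if self.skipped:
            lines.append(f"Untrained partitions (no usable data): {', '.join(self.skipped)}")
        return "\n".join(lines)

    # -- prediction / validation -------------------------------------------

    def predict(self, series: GlucoseSeries, events: EventLog, ph_minutes: int = 30,
                strict: bool = True) -> pd.DataFrame:
        """Streaming per-sample forecasts with weights, CI, NI and flags."""
        ph = ph_minutes // series.sampling_period
        result = evaluation.replay(self.clustersets, self.modelsets, series, events,
                                   max_ph=ph, W=self.model.window,
                                   mu_factor=self.model.mu_factor, strict=strict)
        return result.stream_frame(ph, ni_threshold=self.model.ni_threshold)

    def validate(self, series: GlucoseSeries, events: EventLog,
                 ph_minutes=(15, 30, 60, 120, 180, 240), strict: bool = False):
        """Offline validation report (per-partition and overall metrics)."""
        return evaluation.validate(self.clustersets, self.modelsets, series, events,
                                   list(ph_minutes),
                                   sampling_period=series.sampling_period,
                                   W=self.model.window,
                                   mu_factor=self.model.mu_factor, strict=strict)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "partitions": sorted(self.clustersets),
            "skipped": self.skipped,
            "pr": self.model.pr,
            "window": self.model.window,
            "mu_factor": self.model.mu_factor,
            "ni_threshold": self.model.ni_threshold,
            "m": self.model.m,
        }
        (directory / "bundle.json").write_text(json.dumps(meta), encoding="utf-8")
        for key, cs in self.clustersets.items():
            cs.to_json(directory / f"clusters_{key}.json", extra={"Pr": self.model.pr})
            self.modelsets[key].to_json(directory / f"models_{key}.json")

    @classmethod
    def load(cls, directory) -> "SeasonalGlucoseResults":
        directory = Path(directory)
        meta = json.loads((directory / "bundle.json").read_text(encoding="utf-8"))
        clustersets, modelsets = {}, {}
        for key in meta["partitions"]:
            clustersets[key] = ClusterSet.from_json(directory / f"clusters_{key}.json")
            modelsets[key] = LocalModelSet.from_json(directory / f"models_{key}.json")
        shell = SeasonalGlucoseModel.__new__(SeasonalGlucoseModel)
        shell.pr = meta["pr"]
        shell.window = meta["window"]
        shell.mu_factor = meta["mu_factor"]
        shell.ni_threshold = meta["ni_threshold"]
        shell.m = meta["m"]
        shell.series = None
        shell.events = None
        return cls(shell, clustersets, modelsets, meta["skipped"])

    # -- plotting -----------------------------------------------------------

    def plot_prototypes(self, key: str = "M", ax=None):
        """Plot the cluster prototype glucose profiles of one partition."""
        import matplotlib.pyplot as plt

        cs = self.clustersets[key]
        if ax is None:
            _, ax = plt.subplots()
        minutes = np.arange(cs.L) * 5
        for i in range(cs.c):
            ax.plot(minutes, cs.V[i], label=f"cluster {i + 1}")
        ax.set_xlabel("minutes since event onset")
        ax.set_ylabel("glucose (mg/dL)")
        ax.set_title(f"Partition {key} prototypes")
        ax.legend()
        return ax
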