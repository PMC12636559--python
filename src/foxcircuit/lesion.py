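"""In-silico silencing experiment: weight x rate sweeps under lesion conditions.

Reproduces the digital protocol used to show the fox pair is the bottleneck
between sweet gustatory input and PAM dopaminergic readout: Poisson-stimulate
the unilateral sweet GRNs (and optionally GINs), sweep the free synaptic
weight and the stimulation rate, repeat with selected neuron sets silenced,
and count how many readout neurons respond in each cell of the grid.

A readout neuron counts as *activated* if its mean firing rate over the
stimulation window is non-zero in at least one trial; the per-cell heatmap
value is the trial-averaged activated count, and both are retained so either
reading of "responding" can be exported.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import (
    ConnectomeGraph,
    PopulationSelector,
    Side,
    by_cell_type,
    by_population,
    by_ids,
    classify_fda,
)
from .lif import LifParams, SilenceSpec, StimulusSpec, TrialSummary, run_trials

__all__ = [
    "SweepConfig",
    "ResponseGrid",
    "default_conditions",
    "default_stimulated",
    "classify_activated",
    "run_sweep",
    "suppression_summary",
    "SuppressionStat",
    "export_grid",
    "read_grid",
]

DEFAULT_WEIGHTS = (0.37, 0.38, 0.382, 0.386, 0.39)
DEFAULT_RATES = (20, 40, 80, 100, 120, 140, 150, 160, 170, 180, 190, 200)


def default_stimulated(graph: ConnectomeGraph,
                       include_gins: bool = True) -> frozenset:
    """Unilateral (left) sweet GRNs, plus the left GINs unless disabled."""
    stim = set(by_population("GRN", side=Side.LEFT).resolve(graph))
    if include_gins:
        stim |= set(by_population("GIN", side=Side.LEFT).resolve(graph))
    return frozenset(stim)


def default_conditions(graph: ConnectomeGraph) -> dict:
    """The standard named silencing conditions for the reference circuit."""
    fox = by_cell_type("fox").resolve(graph)
    pam = by_population("PAM").resolve(graph)
    fda1, fda2 = classify_fda(graph, fox, pam)
    cb = by_cell_type("CB0233").resolve(graph)
    return {
        "intact": SilenceSpec(),
        "fox_silenced": SilenceSpec(fox),
        "FDA_I_silenced": SilenceSpec(fda1),
        "FDA_II_silenced": SilenceSpec(fda2),
        "all_FDA_silenced": SilenceSpec(fda1 | fda2),
        "CB0233_silenced": SilenceSpec(cb),
    }


@dataclass(frozen=True)
class SweepConfig:
    """Grid of synaptic weights and stimulation rates, plus conditions.

    ``stimulated`` and ``readout`` may be explicit neuron sets or
    :class:`PopulationSelector`; None picks the defaults for the reference
    circuit (left-side GRNs + GINs stimulated, PAM population read out).
    """

    weights: Sequence[float] = DEFAULT_WEIGHTS
    rates: Sequence[float] = DEFAULT_RATES
    n_trials: int = 5
    stimulated: object = None
    readout: object = None
    conditions: Mapping[str, SilenceSpec] | None = None
    include_gins: bool = True
    base_seed: int = 0

    def __post_init__(self):
        if not self.weights or not self.rates:
            raise ValueError("weights and rates must be non-empty")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.conditions is not None and "intact" not in self.conditions:
            raise ValueError("conditions must include 'intact'")

    def resolve(self, graph: ConnectomeGraph):
        stim = self.stimulated
        if stim is None:
            stim = default_stimulated(graph, self.include_gins)
        elif isinstance(stim, PopulationSelector):
            stim = stim.resolve(graph)
        else:
            stim = frozenset(stim)
        readout = self.readout
        if readout is None:
            readout = by_population("PAM").resolve(graph)
        elif isinstance(readout, PopulationSelector):
            readout = readout.resolve(graph)
        else:
            readout = frozenset(readout)
        conditions = (dict(self.conditions) if self.conditions is not None
                      else default_conditions(graph))
        return frozenset(stim), frozenset(readout), conditions


@dataclass(frozen=True)
class ResponseGrid:
    """Per-(condition, weight, rate) responsive-readout counts.

    ``trials`` is the long table (condition, w_syn, rate_hz, trial,
    activated_count); ``any_trial`` holds the size of the any-trial activated
    set per cell.  ``activated_sets`` retains the sets themselves when the
    grid was produced by :func:`run_sweep` (they are not recoverable from an
    exported CSV).
    """

    trials: pd.DataFrame
    any_trial: pd.DataFrame
    readout_size: int
    conditions: tuple
    weights: tuple
    rates: tuple
    activated_sets: Mapping[tuple, frozenset] | None = None

    def mean_counts(self, condition: str) -> pd.DataFrame:
        """Trial-averaged activated count, weights x rates (ascending)."""
        sub = self.trials[self.trials.condition == condition]
        if sub.empty:
            raise KeyError(f"unknown condition {condition!r}")
        return (sub.pivot_table(index="w_syn", columns="rate_hz",
                                values="activated_count", aggfunc="mean")
                .sort_index().sort_index(axis=1))

    def any_trial_counts(self, condition: str) -> pd.DataFrame:
        sub = self.any_trial[self.any_trial.condition == condition]
        if sub.empty:
            raise KeyError(f"unknown condition {condition!r}")
        return (sub.pivot_table(index="w_syn", columns="rate_hz",
                                values="any_trial_count")
                .sort_index().sort_index(axis=1))


def classify_activated(trials: Sequence[TrialSummary],
                       readout) -> frozenset:
    """Readout neurons with non-zero mean rate in at least one trial."""
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    readout = frozenset(readout)
    return frozenset(
        n for n in readout
        if any(trial.rates.get(n, 0.0) > 0.0 for trial in trials))


def _cell_seed(base_seed: int, condition: str, w: float, rate: float) -> int:
    token = f"{condition}|{w!r}|{rate!r}".encode()
    return (int(base_seed) ^ zlib.crc32(token)) & 0x7FFFFFFF


def run_sweep(graph: ConnectomeGraph, params_base: LifParams,
              sweep: SweepConfig) -> ResponseGrid:
    """Run the full (condition x weight x rate) grid.

    Each cell derives its seed from ``base_seed`` and its own coordinates,
    so the grid is deterministic and invariant to the order in which
    conditions are run.
    """
    stim_ids, readout, conditions = sweep.resolve(graph)
    rows, any_rows = [], []
    sets: dict[tuple, frozenset] = {}
    for cond_name, silence in conditions.items():
        for w in sweep.weights:
            params = replace(params_base, w_syn=float(w))
            for rate in sweep.rates:
                stimulus = StimulusSpec(neurons=stim_ids, rate=float(rate))
                seed = _cell_seed(sweep.base_seed, cond_name, w, rate)
                try:
                    trials = run_trials(graph, params, stimulus, silence,
                                        n_trials=sweep.n_trials,
                                        base_seed=seed)
                except Exception as exc:
                    raise RuntimeError(
                        f"sweep cell failed (condition={cond_name!r}, "
                        f"w_syn={w}, rate={rate} Hz): {exc}") from exc
                for trial in trials:
                    count = sum(1 for nid in readout
                                if trial.rates.get(nid, 0.0) > 0.0)
                    rows.append((cond_name, float(w), float(rate),
                                 trial.trial_index, count))
                activated = classify_activated(trials, readout)
                sets[(cond_name, float(w), float(rate))] = activated
                any_rows.append((cond_name, float(w), float(rate),
                                 len(activated)))
    trials_df = pd.DataFrame(
        rows, columns=["condition", "w_syn", "rate_hz", "trial",
                       "activated_count"])
    any_df = pd.DataFrame(
        any_rows, columns=["condition", "w_syn", "rate_hz",
                           "any_trial_count"])
    return ResponseGrid(
        trials=trials_df, any_trial=any_df, readout_size=len(readout),
        conditions=tuple(conditions), weights=tuple(float(w) for w in
                                                    sweep.weights),
        rates=tuple(float(r) for r in sweep.rates), activated_sets=sets)


@dataclass(frozen=True)
class SuppressionStat:
    """Mean fractional reduction vs baseline over cells with baseline > 0."""

    mean_reduction: float
    n_cells: int
    n_excluded: int   # cells whose baseline count was zero


def suppression_summary(grid: ResponseGrid,
                        baseline: str = "intact") -> dict:
    """Per-condition mean of (1 - count / baseline_count) across grid cells.

    Counts are trial-averaged per cell.  Cells where the baseline count is
    zero are excluded from the mean and reported in ``n_excluded``.
    """
    if baseline not in grid.conditions:
        raise KeyError(f"baseline condition {baseline!r} not in grid")
    base = grid.mean_counts(baseline)
    out = {}
    for cond in grid.conditions:
        if cond == baseline:
            continue
        other = grid.mean_counts(cond)
        b = base.to_numpy(dtype=float)
        c = other.to_numpy(dtype=float)
        ok = b > 0
        reductions = 1.0 - c[ok] / b[ok]
        out[cond] = SuppressionStat(
            mean_reduction=float(reductions.mean()) if ok.any() else float("nan"),
            n_cells=int(ok.sum()),
            n_excluded=int((~ok).sum()))
    return out


def export_grid(grid: ResponseGrid, directory) -> dict:
    """Write the long CSV, an aggregated CSV and one heatmap PNG per condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    long_path = directory / "sweep_trials.csv"
    grid.trials.to_csv(long_path, index=False)

    agg = (grid.trials.groupby(["condition", "w_syn", "rate_hz"],
                               as_index=False, sort=False)["activated_count"]
           .mean()
           .rename(columns={"activated_count": "mean_count"}))
    agg = agg.merge(grid.any_trial, on=["condition", "w_syn", "rate_hz"])
    agg_path = directory / "sweep_cells.csv"
    agg.to_csv(agg_path, index=False)

    paths = {"trials": long_path, "cells": agg_path, "heatmaps": {}}
    for cond in grid.conditions:
        mat = grid.mean_counts(cond)   # ascending in both axes
        fig, ax = plt.subplots(figsize=(6, 3))
        im = ax.imshow(mat.to_numpy(), origin="lower", aspect="auto",
                       vmin=0, vmax=grid.readout_size, cmap="viridis")
        ax.set_xticks(range(len(mat.columns)),
                      [f"{r:g}" for r in mat.columns])
        ax.set_yticks(range(len(mat.index)), [f"{w:g}" for w in mat.index])
        ax.set_xlabel("stimulation rate (Hz)")
        ax.set_ylabel("synaptic weight")
        ax.set_title(f"responding readout neurons — {cond}")
        fig.colorbar(im, ax=ax, label="mean activated count")
        png = directory / f"heatmap_{cond}.png"
        fig.savefig(png, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths["heatmaps"][cond] = png
    return paths


def read_grid(directory, readout_size: int) -> ResponseGrid:
    """Rebuild a :class:`ResponseGrid` from :func:`export_grid` output."""
    directory = Path(directory)
    trials = pd.read_csv(directory / "sweep_trials.csv")
    cells = pd.read_csv(directory / "sweep_cells.csv")
    if trials.empty:
        raise ValueError("exported grid contains no trials")
    any_df = cells[["condition", "w_syn", "rate_hz", "any_trial_count"]]
    return ResponseGrid(
        trials=trials, any_trial=any_df, readout_size=readout_size,
        conditions=tuple(dict.fromkeys(trials.condition)),
        weights=tuple(sorted(trials.w_syn.unique())),
        rates=tuple(sorted(trials.rate_hz.unique())),
        activated_sets=None)
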