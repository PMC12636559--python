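"""Behavioral and imaging assay statistics.

Four bounded indices and one calibration conversion used around optogenetic
feeding and learning experiments:

* positional preference index — frame-averaged occupancy contrast between the
  illuminated and dark halves of an arena, in [-1, 1];
* closed-loop sip preference — (sips on the LED-paired probe - sips on the
  unpaired probe) / total sips;
* olfactory learning index — time-averaged occupancy contrast between the
  CS+ and CS- quadrant pairs during the test minute;
* dF/F — background- and baseline-corrected fluorescence change, with the
  baseline taken over the 5 volumes preceding each stimulation pulse;
* dye-extraction mass — absorbance -> concentration via a standard curve,
  times the extraction volume (300 uL carcass, 500 uL excreta).

A seeded generator of synthetic assay records supports parameter-recovery
testing: occupancy and quadrant counts follow a binomial side-choice model,
sip counts a Poisson model, and fluorescence a pulse-locked exponential
transient with Gaussian noise, each parameterized by the population-level
index it should produce in expectation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccupancyTrace",
    "SipRecord",
    "QuadrantCounts",
    "FluorTrace",
    "AssayScenario",
    "UndefinedIndexError",
    "positional_pi",
    "sip_preference",
    "learning_pi",
    "delta_f_over_f",
    "conex_mass",
    "generate_assay_data",
    "CARCASS_VOLUME_UL",
    "EXCRETA_VOLUME_UL",
]

CARCASS_VOLUME_UL = 300.0
EXCRETA_VOLUME_UL = 500.0


class UndefinedIndexError(Exception):
    """An index has no defined value (zero denominator everywhere)."""


@dataclass(frozen=True)
class OccupancyTrace:
    """Per-frame fly counts on the illuminated vs dark arena side."""

    n_illuminated: np.ndarray
    n_dark: np.ndarray
    frame_rate: float = 30.0
    window: tuple | None = None   # (start_frame, end_frame); None = all

    def __post_init__(self):
        a = np.asarray(self.n_illuminated, dtype=int)
        b = np.asarray(self.n_dark, dtype=int)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("side counts must be 1-D arrays of equal length")
        if (a < 0).any() or (b < 0).any():
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "n_illuminated", a)
        object.__setattr__(self, "n_dark", b)
        if self.window is not None:
            lo, hi = self.window
            if not 0 <= lo < hi <= len(a):
                raise ValueError(f"window {self.window} outside the recording")

    def swapped(self) -> "OccupancyTrace":
        return replace(self, n_illuminated=self.n_dark,
                       n_dark=self.n_illuminated)


@dataclass(frozen=True)
class SipRecord:
    """Per-fly sip counts on the LED-paired (on) and unpaired (off) probes."""

    on_probe: int
    off_probe: int

    def __post_init__(self):
        if self.on_probe < 0 or self.off_probe < 0:
            raise ValueError("sip counts must be >= 0")

    def swapped(self) -> "SipRecord":
        return SipRecord(self.off_probe, self.on_probe)


@dataclass(frozen=True)
class QuadrantCounts:
    """Per-frame fly counts in the CS+ vs CS- quadrant pairs during test."""

    n_cs_plus: np.ndarray
    n_cs_minus: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.n_cs_plus, dtype=int)
        b = np.asarray(self.n_cs_minus, dtype=int)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("quadrant counts must be 1-D arrays of equal length")
        if (a < 0).any() or (b < 0).any():
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "n_cs_plus", a)
        object.__setattr__(self, "n_cs_minus", b)

    def swapped(self) -> "QuadrantCounts":
        return QuadrantCounts(self.n_cs_minus, self.n_cs_plus)


@dataclass(frozen=True)
class FluorTrace:
    """ROI fluorescence series with background ROI and pulse onsets.

    ``fluor_avg`` and ``fluor_bckgr`` are per-volume mean intensities;
    ``pulse_onsets`` are volume indices; the baseline window is the
    ``baseline_volumes`` volumes immediately preceding each pulse.
    """

    fluor_avg: np.ndarray
    fluor_bckgr: np.ndarray
    pulse_onsets: Sequence[int]
    baseline_volumes: int = 5

    def __post_init__(self):
        a = np.asarray(self.fluor_avg, dtype=float)
        b = np.asarray(self.fluor_bckgr, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("signal and background must be 1-D, equal length")
        if (a < 0).any() or (b < 0).any():
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "fluor_avg", a)
        object.__setattr__(self, "fluor_bckgr", b)
        if self.baseline_volumes < 1:
            raise ValueError("baseline window must span >= 1 volume")
        for p in self.pulse_onsets:
            if p - self.baseline_volumes < 0 or p >= len(a):
                raise ValueError(
                    f"pulse at volume {p} lacks a full baseline window")


def _contrast_index(a: np.ndarray, b: np.ndarray) -> float:
    """Mean of per-frame (a - b)/(a + b); zero-total frames are skipped."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    total = a + b
    ok = total > 0
    if not ok.any():
        raise UndefinedIndexError("no frames with at least one fly")
    return float(((a[ok] - b[ok]) / total[ok]).mean())


def positional_pi(trace: OccupancyTrace) -> float:
    """Positional preference index in [-1, 1]; > 0 means attraction to light."""
    sl = slice(*trace.window) if trace.window is not None else slice(None)
    return _contrast_index(trace.n_illuminated[sl], trace.n_dark[sl])


def sip_preference(rec: SipRecord) -> float:
    """Closed-loop sip preference (on - off) / total, in [-1, 1]."""
    total = rec.on_probe + rec.off_probe
    if total == 0:
        raise UndefinedIndexError("fly made no sips")
    return (rec.on_probe - rec.off_probe) / total


def learning_pi(counts: QuadrantCounts) -> float:
    """Appetitive learning index: occupancy contrast CS+ vs CS-, in [-1, 1]."""
    return _contrast_index(counts.n_cs_plus, counts.n_cs_minus)


def delta_f_over_f(trace: FluorTrace) -> list:
    """Per-pulse dF/F series.

    For each pulse, baseline signal and background are averaged over the
    ``baseline_volumes`` volumes preceding the pulse onset; then for each
    volume t from the onset to the next pulse (or the end),

        dF/F(t) = ((avg(t) - bckgr(t)) - (bseln - bckgr_bseln))
                  / (bseln - bckgr_bseln).

    Returns one numpy array per pulse.  A non-positive background-subtracted
    baseline makes the pulse's response undefined.
    """
    onsets = sorted(trace.pulse_onsets)
    n = len(trace.fluor_avg)
    out = []
    for k, p in enumerate(onsets):
        lo = p - trace.baseline_volumes
        bseln = trace.fluor_avg[lo:p].mean()
        bckgr_bseln = trace.fluor_bckgr[lo:p].mean()
        denom = bseln - bckgr_bseln
        if denom <= 0:
            raise UndefinedIndexError(
                f"pulse at volume {p}: background-subtracted baseline "
                f"{denom:.3g} is not positive")
        end = onsets[k + 1] if k + 1 < len(onsets) else n
        corrected = (trace.fluor_avg[p:end] - trace.fluor_bckgr[p:end]) - denom
        out.append(corrected / denom)
    return out


def conex_mass(carcass_absorbance, excreta_absorbance,
               standard_curve) -> float:
    """Consumed dye mass per vial from carcass + excreta absorbance readings.

    ``standard_curve`` is a sequence of (concentration, absorbance) pairs,
    strictly monotone in both coordinates; sample absorbances are linearly
    interpolated to concentrations (mass/volume), multiplied by the
    extraction volume (300 uL carcass, 500 uL excreta) and summed.
    Absorbances outside the curve range are linearly extrapolated from the
    end segments with a RuntimeWarning.
    """
    import warnings

    curve = sorted(standard_curve)
    if len(curve) < 2:
        raise ValueError("standard curve needs >= 2 points")
    conc = np.array([c for c, _ in curve], dtype=float)
    absb = np.array([a for _, a in curve], dtype=float)
    if not (np.all(np.diff(conc) > 0) and np.all(np.diff(absb) > 0)):
        raise ValueError("standard curve must be strictly monotone")

    def to_conc(a):
        a = float(a)
        if a < absb[0] or a > absb[-1]:
            warnings.warn(
                f"absorbance {a:.3g} outside standard curve range "
                f"[{absb[0]:.3g}, {absb[-1]:.3g}]; extrapolating",
                RuntimeWarning, stacklevel=3)
            seg = 0 if a < absb[0] else -2
            slope = (conc[seg + 1] - conc[seg]) / (absb[seg + 1] - absb[seg])
            return conc[seg] + slope * (a - absb[seg])
        return float(np.interp(a, absb, conc))

    mass = 0.0
    for a in np.atleast_1d(carcass_absorbance):
        mass += to_conc(a) * CARCASS_VOLUME_UL
    for a in np.atleast_1d(excreta_absorbance):
        mass += to_conc(a) * EXCRETA_VOLUME_UL
    return mass


# ---------------------------------------------------------------------------
# synthetic assay data
# ---------------------------------------------------------------------------

class AssayScenario(str, enum.Enum):
    OCCUPANCY = "occupancy"
    SIPS = "sips"
    QUADRANT = "quadrant"
    FLUORESCENCE = "fluorescence"


def generate_assay_data(scenario, effect_size: float, n: int, seed: int,
                        n_flies: int = 8, n_frames: int = 5400,
                        mean_sips: float = 50.0, pulse_amplitude_noise: float
                        = 0.02):
    """Seeded synthetic assay records whose index equals ``effect_size``.

    * ``occupancy`` / ``quadrant``: ``n`` traces; each frame places
      ``n_flies`` flies on the favored side with probability
      (1 + effect_size)/2, so the occupancy contrast is unbiased for
      ``effect_size``.  Occupancy uses 5400 frames (3 min at 30 Hz),
      the quadrant test 1800 (1 min).
    * ``sips``: ``n`` flies; on/off probe sips are Poisson with rates
      mean_sips*(1 +- effect_size)/... split so that conditional on the
      total, on-probe sips are Binomial(total, (1+effect_size)/2) — the
      per-fly preference is exactly unbiased given at least one sip.
    * ``fluorescence``: ``n`` traces of 4 pulses each; the underlying
      response is an exponential transient of peak ``effect_size`` relative
      to baseline, with Gaussian intensity noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scenario = AssayScenario(scenario)
    if scenario is not AssayScenario.FLUORESCENCE and not -1 <= effect_size <= 1:
        raise ValueError("index effect size must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    p = (1.0 + effect_size) / 2.0

    if scenario in (AssayScenario.OCCUPANCY, AssayScenario.QUADRANT):
        frames = n_frames if scenario is AssayScenario.OCCUPANCY else 1800
        out = []
        for _ in range(n):
            fav = rng.binomial(n_flies, p, size=frames)
            if scenario is AssayScenario.OCCUPANCY:
                out.append(OccupancyTrace(fav, n_flies - fav))
            else:
                out.append(QuadrantCounts(fav, n_flies - fav))
        return out

    if scenario is AssayScenario.SIPS:
        totals = rng.poisson(2.0 * mean_sips, size=n)
        on = rng.binomial(totals, p)
        return [SipRecord(int(o), int(t - o)) for o, t in zip(on, totals)]

    # fluorescence: 4 pulses, 24-s inter-pulse interval at ~3.3 volumes/s
    n_volumes, onsets, tau_volumes = 340, (10, 90, 170, 250), 5.0
    base, bckgr = 100.0, 40.0
    out = []
    for _ in range(n):
        signal = np.full(n_volumes, base)
        t = np.arange(n_volumes, dtype=float)
        for p0 in onsets:
            rise = t >= p0
            signal[rise] += (base - bckgr) * effect_size * np.exp(
                -(t[rise] - p0) / tau_volumes)
        noise_sd = pulse_amplitude_noise * (base - bckgr)
        signal = np.clip(signal + rng.normal(0.0, noise_sd, n_volumes), 0, None)
        background = np.clip(
            bckgr + rng.normal(0.0, noise_sd / 4, n_volumes), 0, None)
        out.append(FluorTrace(signal, background, onsets))
    return out


def tidy_table(records) -> pd.DataFrame:
    """Flatten a list of assay records into a tidy DataFrame for export."""
    rows = []
    for i, rec in enumerate(records):
        if isinstance(rec, SipRecord):
            rows.append({"record": i, "on_probe": rec.on_probe,
                         "off_probe": rec.off_probe})
        elif isinstance(rec, OccupancyTrace):
            for f, (a, b) in enumerate(zip(rec.n_illuminated, rec.n_dark)):
                rows.append({"record": i, "frame": f, "n_illuminated": a,
                             "n_dark": b})
        elif isinstance(rec, QuadrantCounts):
            for f, (a, b) in enumerate(zip(rec.n_cs_plus, rec.n_cs_minus)):
                rows.append({"record": i, "frame": f, "n_cs_plus": a,
                             "n_cs_minus": b})
        elif isinstance(rec, FluorTrace):
            for v, (a, b) in enumerate(zip(rec.fluor_avg, rec.fluor_bckgr)):
                rows.append({"record": i, "volume": v, "fluor_avg": a,
                             "fluor_bckgr": b})
        else:
            raise TypeError(f"unsupported record type {type(rec).__name__}")
    return pd.DataFrame(rows)
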