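"""Deterministic generator of the reference hourglass connectome.

The real sweet-taste circuit funnels many gustatory inputs through the single
bilateral fox pair before fanning out to ascending, premotor and peptidergic
targets ("hourglass" motif).  No machine-readable extract of that circuit is
distributed, so this module builds a synthetic stand-in: a layered
feedforward network

    sweet GRNs -> GINs (incl. Fdg) -> fox -> {FDA, premotor, DSKMP1B}
                                              FDA-I -> PAM
                                              FDA-II -> PAM-upstream relays -> PAM

whose synapse-count allocations reproduce, at the printed precision, the
published connectivity fractions: Fdg contributes 10% of fox input; FDA-I and
FDA-II receive 4.4% and 10.5% of fox output; CB0233 receives 41% of the fox
output that goes to FDA neurons; and fox supplies >20% (default 22%) of
DSKMP1B's synaptic input from the SEZ.

Counts on constrained connections are fixed by exact integer apportionment
(largest-remainder), so the fractions are deterministic properties of the
graph; randomness is confined to background neurons and the edges among them,
which never enter a constrained denominator.

Note the published fractions are not mutually consistent: 41% of the 14.9%
FDA allocation is 6.1% of total fox output, not the 7% quoted for CB0233's
total share.  The generator treats the within-FDA share (41%) as the binding
constraint, so CB0233's achieved total share is 6.1%.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .connectome import (
    ConnectomeGraph,
    EdgeRecord,
    NeuronRecord,
    Side,
    write_tables,  # re-exported: tables are written in the loader's dialect
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_reference",
    "generate_micro_fixture",
    "write_tables",
    "MicroFixture",
]


class ConfigurationError(Exception):
    """The generator configuration cannot realize its fraction targets."""


#: named fraction -> printed precision (the decimal resolution the value is
#: quoted at; achieved values must round to the target at this precision)
FRACTION_PRECISION = {
    "fdg_input_share": 0.1,
    "fda1_output_share": 0.1,
    "fda2_output_share": 0.1,
    "cb0233_share_of_fda": 1.0,
    "dskmp1b_sez_input_share_from_fox": 1.0,
}

DEFAULT_FRACTIONS = {
    "fdg_input_share": 10.0,
    "fda1_output_share": 4.4,
    "fda2_output_share": 10.5,
    "cb0233_share_of_fda": 41.0,
    "dskmp1b_sez_input_share_from_fox": 22.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Layer sizes, fraction targets and synapse scales for the generator.

    The GRN and GIN input shares of fox (30% / 40% of the input scale) are
    free parameters: the source circuit quotes only the Fdg share.  Sizes are
    per side where the population is bilateral.
    """

    grns_per_side: int = 10
    gin_pair_types: tuple = ("Clavicle", "Rattle", "FMIn", "Bract", "Rounddown")
    fda1_pairs: int = 3
    fda2_pairs: int = 8          # includes CB0233
    pam_count: int = 20
    premotor_pairs: int = 2
    relay_pairs: int = 2         # PAM-upstream relays between FDA-II and PAM
    sez_local_pairs: int = 2     # unconstrained extra SEZ input providers
    background_count: int = 300
    background_edges: int = 600
    fox_output_scale: int = 1000  # total synapses out of the fox pair
    fox_input_scale: int = 1000   # total synapses onto the fox pair
    fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS))
    grn_input_share: float = 30.0   # free parameter, % of fox input
    gin_input_share: float = 40.0   # free parameter, % of fox input
    seed: int = 7

    def __post_init__(self):
        if min(self.grns_per_side, self.fda1_pairs, self.fda2_pairs,
               self.pam_count, self.premotor_pairs, self.relay_pairs,
               self.sez_local_pairs) < 1 or len(self.gin_pair_types) < 1:
            raise ConfigurationError("all layer sizes must be >= 1")
        for name, value in self.fractions.items():
            if not 0 < value < 100:
                raise ConfigurationError(
                    f"fraction {name}={value} outside (0, 100)")
        out_total = (self.fractions["fda1_output_share"]
                     + self.fractions["fda2_output_share"])
        in_total = (self.fractions["fdg_input_share"]
                    + self.grn_input_share + self.gin_input_share)
        if out_total >= 100 or in_total >= 100:
            raise ConfigurationError(
                "fractions sharing a denominator must sum to < 100")


@dataclass(frozen=True)
class GroundTruth:
    """Named populations and the exact fractions the generated graph achieves."""

    populations: Mapping[str, frozenset]
    achieved_fractions: Mapping[str, float]


def largest_remainder(total: int, weights) -> list[int]:
    """Apportion ``total`` into integers proportional to ``weights``.

    Classic largest-remainder (Hamilton) method: floor the exact quotas and
    hand the remaining units to the largest fractional parts, ties broken by
    position.  The result sums to ``total`` exactly.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0 or np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("need total >= 0 and nonnegative weights summing > 0")
    quotas = total * weights / weights.sum()
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    return base.tolist()


def _check_fraction(name, count, denom, target, errors):
    achieved = 100.0 * count / denom
    tol = FRACTION_PRECISION[name] / 2.0
    if abs(achieved - target) >= tol:
        errors.append(name)
    return achieved


def _fraction_counts(cfg: GeneratorConfig, suggest_scale: bool = True):
    """Integer synapse counts realizing the fraction targets, or raise."""
    f = cfg.fractions
    S_out, S_in = cfg.fox_output_scale, cfg.fox_input_scale
    dsk_sez_total = round(500 * S_out / 1000)

    fda1 = round(f["fda1_output_share"] / 100 * S_out)
    fda2 = round(f["fda2_output_share"] / 100 * S_out)
    cb = round(f["cb0233_share_of_fda"] / 100 * (fda1 + fda2))
    dsk_fox = round(f["dskmp1b_sez_input_share_from_fox"] / 100 * dsk_sez_total)
    fdg = round(f["fdg_input_share"] / 100 * S_in)
    grn = round(cfg.grn_input_share / 100 * S_in)
    gin = round(cfg.gin_input_share / 100 * S_in)

    errors: list[str] = []
    achieved = {
        "fda1_output_share": _check_fraction(
            "fda1_output_share", fda1, S_out, f["fda1_output_share"], errors),
        "fda2_output_share": _check_fraction(
            "fda2_output_share", fda2, S_out, f["fda2_output_share"], errors),
        "cb0233_share_of_fda": _check_fraction(
            "cb0233_share_of_fda", cb, fda1 + fda2,
            f["cb0233_share_of_fda"], errors),
        "dskmp1b_sez_input_share_from_fox": _check_fraction(
            "dskmp1b_sez_input_share_from_fox", dsk_fox, dsk_sez_total,
            f["dskmp1b_sez_input_share_from_fox"], errors),
        "fdg_input_share": _check_fraction(
            "fdg_input_share", fdg, S_in, f["fdg_input_share"], errors),
    }
    if cb > fda2:
        errors.append("cb0233_share_of_fda (exceeds the FDA-II allocation)")
    if fda1 + fda2 + dsk_fox >= S_out or fdg + grn + gin >= S_in:
        errors.append("denominator overflow")
    if min(fda1, fda2, cb, dsk_fox, fdg, grn, gin) < 1:
        errors.append("zero allocation")
    if errors:
        hint = (f"; smallest feasible output scale: "
                f"{_smallest_feasible_scale(cfg)}" if suggest_scale else "")
        raise ConfigurationError(
            f"fraction targets infeasible at scales (out={S_out}, in={S_in}); "
            f"failing: {sorted(set(errors))}{hint}")
    counts = {
        "fda1_total": fda1, "fda2_total": fda2, "cb_total": cb,
        "other_fda2_total": fda2 - cb,
        "dsk_from_fox": dsk_fox, "dsk_sez_total": dsk_sez_total,
        "premotor_total": S_out - fda1 - fda2 - dsk_fox,
        "fdg_total": fdg, "grn_total": grn, "gin_total": gin,
        "feeder_total": S_in - fdg - grn - gin,
    }
    return counts, achieved


def _smallest_feasible_scale(cfg: GeneratorConfig, limit: int = 200_000) -> int:
    for scale in range(100, limit + 1, 100):
        probe = replace(cfg, fox_output_scale=scale, fox_input_scale=scale)
        try:
            _fraction_counts(probe, suggest_scale=False)
        except ConfigurationError:
            continue
        return scale
    return -1


def _split_lr(total: int) -> dict:
    left, right = largest_remainder(total, [1, 1])
    return {Side.LEFT: left, Side.RIGHT: right}


def generate_reference(config: GeneratorConfig | None = None
                       ) -> tuple[ConnectomeGraph, GroundTruth]:
    """Build the reference hourglass connectome and its ground truth.

    Identical (config, seed) pairs yield identical graphs; the randomized
    background edges are drawn from a seeded generator and connect only
    background neurons.
    """
    cfg = config or GeneratorConfig()
    counts, achieved = _fraction_counts(cfg)

    neurons: list[NeuronRecord] = []
    edges: list[EdgeRecord] = []
    pops: dict[str, set] = {k: set() for k in (
        "grn", "gin", "fdg", "fox", "fda1", "fda2", "pam", "premotor",
        "dskmp1b", "relay", "sez_local")}

    def add(nid, ct, labels, side, region, pop):
        neurons.append(NeuronRecord(nid, ct, frozenset(labels), side, region))
        pops[pop].add(nid)
        return nid

    sides = (Side.LEFT, Side.RIGHT)
    grn, gin, fdg, fox = {}, {}, {}, {}
    fda1, fda2_other, cb, relay, premotor, dsk, feeder = \
        {}, {}, {}, {}, {}, {}, {}
    for s in sides:
        t = s.value
        grn[s] = [add(f"GRN_{t}_{i:02d}", f"sweet-GRN-{i + 1:02d}",
                      {"GRN", "sweet", "labellar"}, s, "labellum", "grn")
                  for i in range(cfg.grns_per_side)]
        gin[s] = [add(f"GIN_{t}_{ct}", ct, {"GIN"}, s, "SEZ", "gin")
                  for ct in cfg.gin_pair_types]
        fdg[s] = add(f"Fdg_{t}", "Fdg", {"GIN", "Fdg"}, s, "SEZ", "fdg")
        fox[s] = add(f"fox_{t}", "fox", {"SEZ-interneuron"}, s, "SEZ", "fox")
        fda1[s] = [add(f"FDA1_{t}_{i}", f"FDA-I-{i + 1}",
                       {"FDA", "ascending"}, s, "SEZ", "fda1")
                   for i in range(cfg.fda1_pairs)]
        cb[s] = add(f"CB0233_{t}", "CB0233", {"FDA", "ascending"}, s, "SEZ",
                    "fda2")
        fda2_other[s] = [add(f"FDA2_{t}_{i}", f"FDA-II-{i + 1}",
                             {"FDA", "ascending"}, s, "SEZ", "fda2")
                         for i in range(cfg.fda2_pairs - 1)]
        relay[s] = [add(f"RELAY_{t}_{i}", f"PAM-upstream-{i + 1}",
                        {"PAM-upstream"}, s, "central", "relay")
                    for i in range(cfg.relay_pairs)]
        premotor[s] = [add(f"PM_{t}_{i}", f"premotor-{i + 1}",
                           {"premotor"}, s, "SEZ", "premotor")
                       for i in range(cfg.premotor_pairs)]
        dsk[s] = add(f"DSKMP1B_{t}", "DSKMP1B", {"DSK"}, s, "SEZ", "dskmp1b")
        feeder[s] = [add(f"SEZLN_{t}_{i}", f"SEZ-LN-{i + 1}",
                         {"SEZ-LN"}, s, "SEZ", "sez_local")
                     for i in range(cfg.sez_local_pairs)]
    pam = [add(f"PAM_{'L' if i < (cfg.pam_count + 1) // 2 else 'R'}_{i:02d}",
               "PAM", {"PAM", "DAN"},
               Side.LEFT if i < (cfg.pam_count + 1) // 2 else Side.RIGHT,
               "central", "pam")
           for i in range(cfg.pam_count)]
    background = [
        NeuronRecord(f"BG_{i:03d}", "background", frozenset({"background"}),
                     Side.UNKNOWN, "central" if i % 2 else "SEZ")
        for i in range(cfg.background_count)
    ]
    neurons.extend(background)

    def spread(pre_ids, post_ids, total):
        """One edge pre->post for an all-to-all block, counts apportioned."""
        n = len(pre_ids) * len(post_ids)
        for (p, q), c in zip(((a, b) for a in pre_ids for b in post_ids),
                             largest_remainder(total, [1] * n)):
            if c > 0:
                edges.append(EdgeRecord(p, q, c))

    # --- fox output (constrained denominator: fox_output_scale) ---------
    for s, tot in _split_lr(counts["fda1_total"]).items():
        spread([fox[s]], fda1[s], tot)
    for s, tot in _split_lr(counts["cb_total"]).items():
        spread([fox[s]], [cb[s]], tot)
    for s, tot in _split_lr(counts["other_fda2_total"]).items():
        spread([fox[s]], fda2_other[s], tot)
    for s, tot in _split_lr(counts["dsk_from_fox"]).items():
        spread([fox[s]], [dsk[s]], tot)
    for s, tot in _split_lr(counts["premotor_total"]).items():
        spread([fox[s]], premotor[s], tot)

    # --- fox input (constrained denominator: fox_input_scale) -----------
    for s, tot in _split_lr(counts["fdg_total"]).items():
        spread([fdg[s]], [fox[s]], tot)
    for s, tot in _split_lr(counts["grn_total"]).items():
        spread(grn[s], [fox[s]], tot)
    for s, tot in _split_lr(counts["gin_total"]).items():
        spread(gin[s], [fox[s]], tot)
    for s, tot in _split_lr(counts["feeder_total"]).items():
        spread(feeder[s], [fox[s]], tot)

    # --- other SEZ inputs to DSKMP1B (constrained by region filter) ------
    rest = counts["dsk_sez_total"] - counts["dsk_from_fox"]
    gin_dsk, pm_dsk, feeder_dsk = largest_remainder(rest, [20, 10, 9])
    for s, tot in _split_lr(gin_dsk).items():
        spread(gin[s], [dsk[s]], tot)
    for s, tot in _split_lr(pm_dsk).items():
        spread(premotor[s], [dsk[s]], tot)
    for s, tot in _split_lr(feeder_dsk).items():
        spread(feeder[s], [dsk[s]], tot)
    # non-SEZ input to DSKMP1B, excluded by the SEZ region filter
    for s in sides:
        for r in relay[s]:
            edges.append(EdgeRecord(r, dsk[s], 30))

    # --- unconstrained feedforward wiring --------------------------------
    for s in sides:
        for g_ in grn[s]:
            for q in gin[s]:
                edges.append(EdgeRecord(g_, q, 8))
        for q in gin[s]:
            edges.append(EdgeRecord(q, fdg[s], 10))
            for p in premotor[s]:
                edges.append(EdgeRecord(q, p, 10))
        for a in fda1[s]:
            for p in pam:
                edges.append(EdgeRecord(a, p, 4))
        for r in relay[s]:
            edges.append(EdgeRecord(cb[s], r, 80))
            for a in fda2_other[s]:
                edges.append(EdgeRecord(a, r, 10))
        for r in relay[s]:
            for i, p in enumerate(pam):
                edges.append(EdgeRecord(r, p, 15 + 8 * i))

    # --- seeded background edges (background neurons only) ---------------
    rng = np.random.default_rng(cfg.seed)
    bg_ids = [n.neuron_id for n in background]
    drawn: dict[tuple, int] = {}
    if len(bg_ids) >= 2:
        for _ in range(cfg.background_edges):
            a, b = rng.choice(len(bg_ids), size=2, replace=False)
            key = (bg_ids[a], bg_ids[b])
            drawn[key] = drawn.get(key, 0) + int(rng.geometric(1 / 3))
    edges.extend(EdgeRecord(p, q, c) for (p, q), c in sorted(drawn.items()))

    graph = ConnectomeGraph(neurons, edges)
    truth = GroundTruth(
        populations={k: frozenset(v) for k, v in pops.items()},
        achieved_fractions=dict(achieved),
    )
    return graph, truth


class MicroFixture(str, enum.Enum):
    CHAIN3 = "chain3"
    FANIN = "fanin"
    DIAMOND = "diamond"
    INHIBITORY_PAIR = "inhibitory_pair"


#: fixture registry: name -> (neuron ids, (pre, post, count, sign) edges)
_MICRO = {
    MicroFixture.CHAIN3: (
        ["A", "B", "C"], [("A", "B", 10, 1), ("B", "C", 10, 1)]),
    MicroFixture.FANIN: (
        ["A1", "A2", "A3", "B"],
        [("A1", "B", 5, 1), ("A2", "B", 5, 1), ("A3", "B", 5, 1)]),
    MicroFixture.DIAMOND: (
        ["A", "B", "C", "D"],
        [("A", "B", 10, 1), ("A", "C", 10, 1),
         ("B", "D", 10, 1), ("C", "D", 10, 1)]),
    MicroFixture.INHIBITORY_PAIR: (
        ["A", "B"], [("A", "B", 10, -1)]),
}


def generate_micro_fixture(name) -> ConnectomeGraph:
    """Hand-specified <= 5-neuron graphs used to oracle-test the LIF engine."""
    try:
        key = MicroFixture(name)
    except ValueError:
        raise ValueError(
            f"unknown micro fixture {name!r}; known: "
            f"{[m.value for m in MicroFixture]}") from None
    ids, edge_spec = _MICRO[key]
    return ConnectomeGraph(
        [NeuronRecord(i, i, frozenset({"fixture"}), Side.UNKNOWN, "fixture")
         for i in ids],
        [EdgeRecord(p, q, c, s) for p, q, c, s in edge_spec],
    )
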