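"""Bond-order classification and conjugation-extent analysis.

Predicted bond-length changes are added to reference (dark-state) bond
lengths and classified into single / double / intermediate character by two
thresholds; the alternation pattern along the chain then yields the extent
of π-conjugation (longest strictly alternating single/double run) and, for
a pair of photoproduct states, an antagonism report flagging bonds whose
character flips between the states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inversion import BondDeltaPrediction
from .trajectory_io import ChromophoreTopology

__all__ = [
    "BondOrderPattern",
    "AntagonismReport",
    "classify_bond_orders",
    "conjugation_extent",
    "compare_states",
    "write_pattern_csv",
    "write_antagonism_json",
]

# Bracketing typical conjugated C=C vs C-C lengths within the observed
# 1.4-1.5 Å fluctuation band; qualitative and fully configurable.
DEFAULT_T_DOUBLE = 1.40  # Å: below -> double
DEFAULT_T_SINGLE = 1.44  # Å: above -> single
# Plausible conjugated C-C window: ~1.33 Å (strong double) to ~1.54 Å (pure
# single). Semi-quantitative predictions may overshoot it; those are flagged.
PLAUSIBLE_MIN = 1.30  # Å
PLAUSIBLE_MAX = 1.60  # Å


@dataclass(frozen=True)
class BondOrderPattern:
    """Per-bond single/double/intermediate character for one state."""

    state_name: str
    bond_labels: tuple[str, ...]
    predicted_length_A: np.ndarray
    order_label: tuple[str, ...]
    t_double_A: float
    t_single_A: float
    implausible: tuple[bool, ...]


@dataclass(frozen=True)
class AntagonismReport:
    """Bond-character opposition between two classified states."""

    state_a: str
    state_b: str
    bond_labels: tuple[str, ...]
    labels_a: tuple[str, ...]
    labels_b: tuple[str, ...]
    opposite: tuple[bool, ...]
    fraction_opposite: float


def _order_label(length: float, t_double: float, t_single: float) -> str:
    if length < t_double:
        return "double"
    if length > t_single:
        return "single"
    return "intermediate"


def classify_bond_orders(reference_A: dict[str, float],
                         delta: BondDeltaPrediction,
                         t_double_A: float = DEFAULT_T_DOUBLE,
                         t_single_A: float = DEFAULT_T_SINGLE,
                         state_name: str | None = None,
                         plausible_min_A: float = PLAUSIBLE_MIN,
                         plausible_max_A: float = PLAUSIBLE_MAX) -> BondOrderPattern:
    """Classify predicted bond lengths (reference + Δd) into bond orders.

    Predicted lengths outside the chemically plausible conjugated C-C
    window (1.30–1.60 Å by default) are flagged implausible — the inversion
    is semi-quantitative and large predicted changes can overshoot physical
    bond lengths — but still receive a label.
    """
    if not t_double_A < t_single_A:
        raise ValueError("t_double must be smaller than t_single")
    missing = [b for b in delta.bond_labels if b not in reference_A]
    if missing:
        raise ValueError(f"reference lengths missing for bond(s) {missing}")
    ref = np.array([reference_A[b] for b in delta.bond_labels], dtype=float)
    predicted = ref + delta.delta_pm / 100.0  # pm -> Å
    labels = tuple(_order_label(x, t_double_A, t_single_A) for x in predicted)
    implausible = tuple(bool(x <= plausible_min_A or x >= plausible_max_A)
                        for x in predicted)
    return BondOrderPattern(
        state_name or delta.transition_name, delta.bond_labels,
        predicted, labels, t_double_A, t_single_A, implausible,
    )


def conjugation_extent(p: BondOrderPattern,
                       topo: ChromophoreTopology) -> tuple[int, set[str]]:
    """Longest strictly alternating single/double run and the rings it spans.

    Intermediate labels terminate a run (conservative estimate of the
    conjugation length). A ring is included when the run contains a bond
    with both endpoints inside that ring.
    """
    if not p.bond_labels:
        raise ValueError("empty bond-order pattern")
    bond_map = {f"{a}-{b}": (a, b) for a, b in topo.bonds}
    pairs = []
    for lab in p.bond_labels:
        if lab not in bond_map:
            raise ValueError(f"pattern bond {lab!r} not present in topology")
        pairs.append(bond_map[lab])
    for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]):
        if len({a1, b1} & {a2, b2}) != 1:
            raise ValueError("pattern bonds must form a connected chain in the topology")

    best_len, best_range = 0, (0, 0)
    start = None
    for i, lab in enumerate(p.order_label):
        if lab == "intermediate":
            start = None
            continue
        if start is None or lab == p.order_label[i - 1]:
            start = i
        if i - start + 1 > best_len:
            best_len, best_range = i - start + 1, (start, i + 1)
    rings: set[str] = set()
    for a, b in pairs[best_range[0]: best_range[1]]:
        ra = topo.ring_membership.get(a)
        rb = topo.ring_membership.get(b)
        if ra is not None and ra == rb:
            rings.add(ra)
    return best_len, rings


def compare_states(a: BondOrderPattern, b: BondOrderPattern) -> AntagonismReport:
    """Flag bonds whose single/double character is opposite between two states."""
    in_b = {lab: i for i, lab in enumerate(b.bond_labels)}
    shared = [lab for lab in a.bond_labels if lab in in_b]
    if not shared:
        raise ValueError("states share no bonds")
    la, lb, flags = [], [], []
    for lab in shared:
        ia = a.bond_labels.index(lab)
        oa, ob = a.order_label[ia], b.order_label[in_b[lab]]
        la.append(oa)
        lb.append(ob)
        flags.append({oa, ob} == {"single", "double"})
    return AntagonismReport(
        a.state_name, b.state_name, tuple(shared), tuple(la), tuple(lb),
        tuple(flags), float(np.mean(flags)),
    )


def write_pattern_csv(path: str | Path, patterns: list[BondOrderPattern]) -> None:
    rows = []
    for p in patterns:
        for lab, length, order, impl in zip(p.bond_labels, p.predicted_length_A,
                                            p.order_label, p.implausible):
            rows.append({"state": p.state_name, "bond": lab,
                         "predicted_length_A": length, "order": order,
                         "implausible": impl})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_antagonism_json(path: str | Path, report: AntagonismReport,
                          extents: dict[str, tuple[int, set[str]]] | None = None) -> None:
    payload = {
        "state_a": report.state_a,
        "state_b": report.state_b,
        "bonds": [
            {"bond": lab, "order_a": oa, "order_b": ob, "opposite": flag}
            for lab, oa, ob, flag in zip(report.bond_labels, report.labels_a,
                                         report.labels_b, report.opposite)
        ],
        "fraction_opposite": report.fraction_opposite,
    }
    if extents:
        payload["conjugation_extent"] = {
            state: {"n_alternating_bonds": n, "included_rings": sorted(rings)}
            for state, (n, rings) in extents.items()
        }
    Path(path).write_text(json.dumps(payload, indent=2))
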