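"""Knot-interconversion fluxes under strand-passage policies.

For a set of labelled diagrams, firing a strand passage at every site a
policy permits and labelling the results gives the *adjacency table*
count[from][to]: the number of passage events converting a diagram of
one knot type into a diagram of another.  Each (diagram, site) pair is
one event; self-fluxes (no type change) are included.

Because a commutation is an involution, the unbiased table over a set
closed under passages (an exhaustive census) is exactly symmetric: the
system is at topological equilibrium and shows detailed balance.
Restricting passages to (strongly) hooked juxtapositions breaks that
symmetry toward simpler knots; the *knotting reduction factor*
flux(knot -> unknot) / flux(unknot -> knot) measures how far below
topological equilibrium the knotting level would settle under repeated
hooked-only passages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _bulk
from .census import Census

__all__ = [
    "FluxTable",
    "ReductionReport",
    "flux_table",
    "transition_probabilities",
    "knot_closeness",
    "reduction_factor",
    "area_sweep",
]


@dataclass
class FluxTable:
    """Directed counts of strand-passage events between knot types."""

    labels: list[str]
    counts: np.ndarray  # (L, L) int64; counts[i, j] = events i -> j
    policy: str
    max_area: Optional[int]  # None for the unbiased policy
    scope: str  # e.g. "gn=5..7 exhaustive" or a sample descriptor
    per_gn: dict[int, np.ndarray] = field(default_factory=dict)
    diagram_counts: dict[str, int] = field(default_factory=dict)

    def _code(self, label: str) -> int:
        return self.labels.index(label)

    def count(self, from_label: str, to_label: str) -> int:
        return int(self.counts[self._code(from_label), self._code(to_label)])

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    @property
    def type_changing_events(self) -> int:
        off = self.counts.sum() - np.trace(self.counts)
        return int(off)

    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.counts, self.counts.T))

    def asymmetry(self, a: str, b: str) -> float:
        """Relative asymmetry |c_ab - c_ba| / (c_ab + c_ba)."""
        ab = self.count(a, b)
        ba = self.count(b, a)
        if ab + ba == 0:
            return 0.0
        return abs(ab - ba) / (ab + ba)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        L = len(self.labels)
        for i in range(L):
            for j in range(L):
                if self.counts[i, j]:
                    rows.append(
                        (
                            self.scope,
                            self.policy,
                            self.max_area if self.max_area is not None else "",
                            self.labels[i],
                            self.labels[j],
                            int(self.counts[i, j]),
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["gn_scope", "policy", "max_area", "from_knot", "to_knot", "count"],
        )

    def normalized(self) -> pd.DataFrame:
        """Chord-diagram export: fluxes normalized so the total is 1."""
        df = self.to_frame()
        total = df["count"].sum()
        df["flux"] = df["count"] / total if total else 0.0
        return df


@dataclass(frozen=True)
class ReductionReport:
    """Directed flux ratio for one ordered knot pair under a policy."""

    pair: tuple[str, str]
    forward: int  # flux(A -> B)
    backward: int  # flux(B -> A)
    factor: float  # forward / backward; inf when backward == 0 < forward
    degenerate: bool  # both fluxes zero (factor 1 by convention)
    unbiased_forward: Optional[int] = None
    unbiased_backward: Optional[int] = None


def flux_table(
    cen: Census,
    policy: str = "unbiased",
    max_area: int = 1,
    gn_min: Optional[int] = None,
    gn_max: Optional[int] = None,
) -> FluxTable:
    """Adjacency table over an exhaustive census under a passage policy.

    For every census diagram and every admissible site the commuted
    diagram is labelled by canonical-key lookup into the census index
    (commutation preserves grid number, so the result is always in the
    census) and the (from, to) cell is incremented.
    """
    if policy not in ("unbiased", "hooked"):
        raise ValueError(f"unknown passage policy {policy!r}")
    gns = [gn for gn in cen.gns if (gn_min is None or gn >= gn_min) and (gn_max is None or gn <= gn_max)]
    if not gns:
        raise ValueError("no census grid numbers in requested range")
    L = len(cen.labels)
    total = np.zeros((L, L), dtype=np.int64)
    per_gn: dict[int, np.ndarray] = {}
    diagram_counts: dict[str, int] = {}
    for gn in gns:
        for label, k in cen.counts[gn].items():
            diagram_counts[label] = diagram_counts.get(label, 0) + k
        idx = cen.index[gn]
        XS, OS = _bulk.unpack_pair(idx.keys, gn)
        from_codes = idx.codes
        mat = np.zeros((L, L), dtype=np.int64)
        for axis in ("col", "row"):
            if axis == "col":
                A, B = XS, OS
            else:
                A, B = _bulk.invert_perms(XS), _bulk.invert_perms(OS)
            AINV = _bulk.invert_perms(A)
            BINV = _bulk.invert_perms(B)
            for i in range(gn - 1):
                inter, hooked, area = _bulk.col_pair_info(A, B, AINV, BINV, i)
                if policy == "unbiased":
                    mask = inter
                else:
                    mask = hooked & (area <= max_area)
                if not mask.any():
                    continue
                A2, B2 = _bulk.commute_cols(A[mask], B[mask], i)
                if axis == "row":
                    A2, B2 = _bulk.invert_perms(A2), _bulk.invert_perms(B2)
                to_codes = idx.lookup(_bulk.canonical_keys(A2, B2))
                pair = from_codes[mask].astype(np.int64) * L + to_codes
                mat += np.bincount(pair, minlength=L * L).reshape(L, L)
        per_gn[gn] = mat
        total += mat
    scope = f"gn={gns[0]}..{gns[-1]} exhaustive"
    return FluxTable(
        labels=list(cen.labels),
        counts=total,
        policy=policy,
        max_area=None if policy == "unbiased" else max_area,
        scope=scope,
        per_gn=per_gn,
        diagram_counts=diagram_counts,
    )


def transition_probabilities(f: FluxTable) -> pd.DataFrame:
    """Row-normalized table: P(row knot -> column knot | a passage fires).

    Rows with no events are returned as NaN (undefined) rather than 0.
    """
    sums = f.counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(sums > 0, f.counts / sums, np.nan)
    return pd.DataFrame(P, index=f.labels, columns=f.labels)


def knot_closeness(f: FluxTable, a: str, b: str) -> float:
    """Fraction of all type-changing events that interconvert a and b."""
    denom = f.type_changing_events
    if denom == 0:
        raise ValueError("no type-changing events in this flux table")
    if a == b:
        raise ValueError("closeness is defined for distinct knot types")
    return (f.count(a, b) + f.count(b, a)) / denom


def reduction_factor(
    unbiased: FluxTable,
    hooked: FluxTable,
    a: str = "3_1",
    b: str = "0_1",
) -> ReductionReport:
    """Knotting reduction factor for the ordered pair (a, b).

    The ratio of the hooked-restricted fluxes a -> b and b -> a; the
    unbiased fluxes (equal for an exhaustive census) are attached for
    context.  A zero denominator with nonzero numerator reports inf.
    """
    fwd = hooked.count(a, b)
    bwd = hooked.count(b, a)
    if fwd == 0 and bwd == 0:
        factor, degenerate = 1.0, True
    elif bwd == 0:
        factor, degenerate = math.inf, False
    else:
        factor, degenerate = fwd / bwd, False
    return ReductionReport(
        pair=(a, b),
        forward=fwd,
        backward=bwd,
        factor=factor,
        degenerate=degenerate,
        unbiased_forward=unbiased.count(a, b),
        unbiased_backward=unbiased.count(b, a),
    )


def area_sweep(
    cen: Census,
    max_areas: Sequence[int],
    pair: tuple[str, str] = ("3_1", "0_1"),
    gn_min: Optional[int] = None,
    gn_max: Optional[int] = None,
) -> list[tuple[int, ReductionReport]]:
    """Reduction factor as the hooked-area threshold varies.

    Tightening the threshold (smaller maximum rectangle area, i.e. more
    sharply bent juxtapositions) should increase the reduction factor,
    peaking at the elementary square.
    """
    unb = flux_table(cen, policy="unbiased", gn_min=gn_min, gn_max=gn_max)
    out = []
    for a in max_areas:
        hk = flux_table(cen, policy="hooked", max_area=a, gn_min=gn_min, gn_max=gn_max)
        out.append((a, reduction_factor(unb, hk, *pair)))
    return out
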