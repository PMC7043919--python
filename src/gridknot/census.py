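"""Exhaustive enumeration and knot censuses of small grid diagrams.

A diagram of grid number n is a pair of permutations; restricting to a
single closed component and counting modulo the X/O swap leaves exactly
n!(n-1)!/2 diagrams (equivalently n/2 ((n-1)!)^2).  For n = 3..7 that is
6; 72; 1,440; 43,200; 1,814,400 -- a grand total of 1,859,118 diagrams,
every one of which is enumerated and identified here.  n = 8 (about 10^8
diagrams) is accepted as expert mode but takes correspondingly long.

Enumeration is constructive and duplicate-free: xs runs over all
permutations and the component cycle xs o os^-1 over all n-cycles
(os = c^-1 o xs then has a single component automatically, and the two
markings of a column can never coincide because an n-cycle is
fixed-point-free); the swap quotient is applied arithmetically by
keeping only pairs with (xs, os) lexicographically below (os, xs).

The census keeps, besides the per-knot counts, a packed-key index of
every diagram's label; flux scans label passage results by lookup into
this index (a commutation preserves grid number, so every result is
itself a census diagram).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from . import _bulk
from .grid import GridDiagram
from .invariants import KnotTable, OTHER, default_table, identify

__all__ = [
    "GN_ENUM_MIN",
    "GN_ENUM_MAX",
    "grid_count_formula",
    "enumerate_grids",
    "CensusIndex",
    "Census",
    "census",
    "occurrence_probabilities",
]

GN_ENUM_MIN = 3
GN_ENUM_MAX = 8


def _check_range(n_min: int, n_max: int) -> None:
    if not (GN_ENUM_MIN <= n_min <= n_max <= GN_ENUM_MAX):
        raise ValueError(
            f"exhaustive enumeration supports {GN_ENUM_MIN} <= gn <= {GN_ENUM_MAX}, "
            f"got [{n_min}, {n_max}]"
        )


def grid_count_formula(n: int) -> int:
    """Number of canonical single-component diagrams of grid number n.

    n/2 ((n-1)!)^2, i.e. n!(n-1)!/2.
    """
    if n < 3:
        raise ValueError(f"the census formula applies for n >= 3, got {n}")
    return factorial(n) * factorial(n - 1) // 2


def enumerate_grids(n: int) -> Iterator[GridDiagram]:
    """Yield every canonical single-component diagram of size n once."""
    _check_range(n, n)
    cinvs = [tuple(int(v) for v in row) for row in _bulk.cycle_inverses(n)]
    for xs in permutations(range(n)):
        for cinv in cinvs:
            os_ = tuple(cinv[v] for v in xs)
            if xs < os_:
                yield GridDiagram(n=n, xs=xs, os=os_)


@dataclass
class CensusIndex:
    """Sorted packed canonical keys with aligned label codes for one gn."""

    keys: np.ndarray  # uint64, sorted ascending
    codes: np.ndarray  # uint8, codes[k] labels keys[k]

    def lookup(self, keys: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(self.keys, keys)
        if np.any(pos >= len(self.keys)) or np.any(self.keys[pos] != keys):
            raise KeyError("diagram not present in census index")
        return self.codes[pos]


@dataclass
class Census:
    """Per-(gn, knot) diagram counts plus the label index per gn."""

    labels: list[str]  # code -> label name
    counts: dict[int, dict[str, int]]
    index: dict[int, CensusIndex]

    @property
    def gns(self) -> list[int]:
        return sorted(self.counts)

    def total(self, gn: int) -> int:
        return sum(self.counts[gn].values())

    def count(self, gn: int, label: str) -> int:
        return self.counts[gn].get(label, 0)

    def grand_total(self) -> int:
        return sum(self.total(gn) for gn in self.counts)

    def label_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for gn in self.counts:
            for label, k in self.counts[gn].items():
                out[label] = out.get(label, 0) + k
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (gn, label, k)
            for gn in sorted(self.counts)
            for label, k in sorted(self.counts[gn].items())
            if k
        ]
        return pd.DataFrame(rows, columns=["gn", "knot", "count"])


def _det_shortlists(table: KnotTable) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for name, entry in table.entries.items():
        det = int(abs(entry.alexander(-1)))
        out.setdefault(det, []).append(name)
    return out


def census(
    n_min: int,
    n_max: int,
    table: Optional[KnotTable] = None,
    progress: bool = False,
) -> Census:
    """Exhaustive knot census of canonical diagrams, n_min <= gn <= n_max.

    Identification uses the batched knot-determinant fast path; only
    diagrams whose determinant is shared by several table knots (at
    GN <= 7: determinants 3, 5 and 7, about 5% of diagrams) fall back to
    the per-diagram fingerprint/identification pipeline.
    """
    _check_range(n_min, n_max)
    table = table or default_table()
    labels = table.labels + [OTHER]
    code_of = {name: k for k, name in enumerate(labels)}
    det_map = _det_shortlists(table)
    counts: dict[int, dict[str, int]] = {}
    index: dict[int, CensusIndex] = {}
    for n in range(n_min, n_max + 1):
        P = _bulk.perms_array(n)
        kx_all = _bulk.pack_half(P)
        cinvs = _bulk.cycle_inverses(n)
        cyc_iter = range(len(cinvs))
        if progress:
            try:
                from tqdm import tqdm

                cyc_iter = tqdm(cyc_iter, desc=f"census gn={n}", unit="cycle")
            except ImportError:
                pass
        key_chunks: list[np.ndarray] = []
        code_chunks: list[np.ndarray] = []
        for ci in cyc_iter:
            cinv = cinvs[ci]
            OS = cinv[P]
            keep = kx_all < _bulk.pack_half(OS)
            XS = P[keep]
            OS = OS[keep]
            dets = _bulk.knot_determinant_batch(_bulk.winding_batch(XS, OS))
            codes = np.empty(len(XS), dtype=np.uint8)
            for det in np.unique(dets):
                sel = dets == det
                names = det_map.get(int(det), [])
                if len(names) == 1:
                    codes[sel] = code_of[names[0]]
                elif not names:
                    codes[sel] = code_of[OTHER]
                else:
                    for idx in np.nonzero(sel)[0]:
                        g = GridDiagram(
                            n=n, xs=tuple(XS[idx]), os=tuple(OS[idx])
                        )
                        codes[idx] = code_of[identify(g, table)]
            key_chunks.append(_bulk.pack_pair(XS, OS))
            code_chunks.append(codes)
        keys = np.concatenate(key_chunks)
        codes = np.concatenate(code_chunks)
        order = np.argsort(keys)
        keys = keys[order]
        codes = codes[order]
        expected = grid_count_formula(n)
        if len(keys) != expected:
            raise AssertionError(
                f"enumeration at gn={n} produced {len(keys)} diagrams, expected {expected}"
            )
        tallies = np.bincount(codes, minlength=len(labels))
        counts[n] = {labels[k]: int(v) for k, v in enumerate(tallies) if v}
        index[n] = CensusIndex(keys=keys, codes=codes)
    return Census(labels=labels, counts=counts, index=index)


def occurrence_probabilities(c: Census) -> pd.DataFrame:
    """Per-gn fraction of diagrams of each knot type (sums to 1 per gn)."""
    if not c.counts:
        raise ValueError("empty census")
    rows = []
    for gn in sorted(c.counts):
        total = c.total(gn)
        for label, k in sorted(c.counts[gn].items()):
            rows.append((gn, label, k / total))
    return pd.DataFrame(rows, columns=["gn", "knot", "probability"])
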