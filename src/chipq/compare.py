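"""Cross-sample comparison of occupancy tables.

Bound sets at a Q threshold, 2/3-way Venn overlap, proliferation vs
differentiation category tallies for the top-bound genes, and pairwise
two-sided Mann-Whitney U tests (Holm-adjusted) between samples' Q-value
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import RegionSet
from .occupancy import QTable

__all__ = ["CategoryTable", "VennResult", "ComparisonResult", "bound_set",
           "venn", "classify_top", "compare_q_distributions"]

CATEGORIES = ("proliferation", "differentiation", "other")

ALPHA_LADDER = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def _canonical(name: str) -> str:
    """Case-insensitive, hyphen/underscore-insensitive gene-name key."""
    return name.casefold().replace("-", "").replace("_", "")


class CategoryTable:
    """Gene name -> {proliferation, differentiation, other} lookup."""

    def __init__(self, mapping: Mapping[str, str], provenance: str = ""):
        self._raw = dict(mapping)
        self.provenance = provenance
        self._lookup: dict[str, str] = {}
        for name, cat in mapping.items():
            cat = cat.strip().lower()
            if cat not in CATEGORIES:
                raise ValueError(f"invalid category {cat!r} for {name!r}")
            key = _canonical(name)
            if key in self._lookup and self._lookup[key] != cat:
                raise ValueError(f"conflicting categories for {name!r}")
            self._lookup[key] = cat

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "CategoryTable":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["name", "category"])
        return cls(dict(zip(df["name"].astype(str), df["category"])),
                   provenance or str(path))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, cat in self._raw.items():
                fh.write(f"{name}\t{cat}\n")

    def get(self, name: str) -> str | None:
        return self._lookup.get(_canonical(name))

    def __len__(self) -> int:
        return len(self._lookup)


@dataclass
class VennResult:
    """Inclusion-exclusion cell counts for 2 or 3 named sets.

    ``cells`` maps a frozenset of member labels to the number of elements
    belonging to exactly those sets.
    """

    labels: tuple[str, ...]
    cells: dict[frozenset, int]
    threshold: float | None = None

    @property
    def universe_size(self) -> int:
        return sum(self.cells.values())

    def count(self, *labels: str) -> int:
        return self.cells.get(frozenset(labels), 0)

    def to_dict(self) -> dict:
        return {"labels": list(self.labels),
                "cells": {"&".join(sorted(k)): v for k, v in self.cells.items()},
                "threshold": self.threshold,
                "universe_size": self.universe_size}


@dataclass
class ComparisonResult:
    pair: tuple[str, str]
    statistic: float     # Mann-Whitney U for the first member of the pair
    p_value: float
    p_adjusted: float
    label: str

    def to_row(self) -> dict:
        return {"sample_a": self.pair[0], "sample_b": self.pair[1],
                "U": self.statistic, "p": self.p_value,
                "p_adj": self.p_adjusted, "label": self.label}


def bound_set(q: QTable, threshold: float = 0.5,
              exclude: Iterable[str] = ()) -> set[str]:
    """Names of regions with Q strictly greater than the threshold.

    ``exclude`` removes regions (e.g. those that failed an upstream
    liftover) from the universe before thresholding.
    """
    excluded = set(exclude)
    s = q.q_series()
    return {name for name, val in s.items()
            if name not in excluded and val > threshold}


def venn(sets: Mapping[str, Iterable]) -> VennResult:
    """Standard inclusion-exclusion cell counts for 2 or 3 named sets."""
    labels = tuple(sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("venn supports 2 or 3 sets")
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be distinct")
    materialized = {k: set(v) for k, v in sets.items()}
    universe = set().union(*materialized.values())
    cells: dict[frozenset, int] = {}
    for element in universe:
        member = frozenset(k for k, v in materialized.items() if element in v)
        cells[member] = cells.get(member, 0) + 1
    # ensure all non-empty membership cells exist (possibly zero)
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            cells.setdefault(frozenset(combo), 0)
    return VennResult(labels, cells)


def classify_top(top_regions: RegionSet | Sequence[str],
                 categories: CategoryTable,
                 q: QTable | None = None) -> tuple[dict[str, int], pd.DataFrame]:
    """Tally the top-bound genes by category.

    Returns (tallies, detail) where tallies counts proliferation /
    differentiation / other / unclassified, and detail carries the
    per-gene category (and Q when a table is supplied) for plotting.
    """
    names = top_regions.names if isinstance(top_regions, RegionSet) \
        else list(top_regions)
    tallies = {c: 0 for c in CATEGORIES}
    tallies["unclassified"] = 0
    rows = []
    qseries = q.q_series() if q is not None else None
    for name in names:
        cat = categories.get(name) or "unclassified"
        tallies[cat] += 1
        rows.append({"name": name, "category": cat,
                     "Q": float(qseries[name]) if qseries is not None
                     and name in qseries.index else np.nan})
    return tallies, pd.DataFrame(rows, columns=["name", "category", "Q"])


def significance_label(p: float) -> str:
    for alpha, stars in ALPHA_LADDER:
        if p < alpha:
            return stars
    return "ns"


def compare_q_distributions(tables: Mapping[str, QTable]
                            ) -> list[ComparisonResult]:
    """Pairwise two-sided Mann-Whitney U on per-region Q values, with Holm
    adjustment across all pairs and a significance-star label.

    All tables must cover the same region universe (unpaired test, but a
    shared universe keeps the samples comparable).
    """
    names = list(tables)
    if len(names) < 2:
        raise ValueError("need at least two tables to compare")
    universes = {k: set(t.names) for k, t in tables.items()}
    ref_label = names[0]
    ref = universes[ref_label]
    for k, u in universes.items():
        if u != ref:
            diff = sorted((ref ^ u))[:10]
            raise ValueError(
                f"region universe mismatch between {ref_label!r} and {k!r}; "
                f"differing regions include {diff}")
    pairs = list(combinations(names, 2))
    raw = []
    stats_u = []
    for a, b in pairs:
        xa = tables[a].q_series().to_numpy()
        xb = tables[b].q_series().to_numpy()
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                 method="auto")
        raw.append(float(res.pvalue))
        stats_u.append(float(res.statistic))
    adj = multipletests(raw, method="holm")[1] if len(raw) > 1 else raw
    results = []
    for (a, b), u, p, padj in zip(pairs, stats_u, raw, adj):
        results.append(ComparisonResult((a, b), u, p, float(padj),
                                        significance_label(float(padj))))
    return results


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
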