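"""Deterministic toy SNP matrices with planted, exactly recoverable truth.

These generators exist so that every tabulation in :mod:`igcsim.sfs` and
:mod:`igcsim.popgen` can be tested against known counts without running the
simulator: the planted three-copy categories and fixed differences are
reproduced exactly by the downstream classifiers, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import PolarizedSNPMatrix
from .sfs import THREE_COPY_CATEGORIES

_PARALOGS = ("P1", "P2", "P3")


class InfeasibleFixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Recipe for a planted matrix.

    ``category_counts`` plants segregating sites per three-copy category
    (derived counts drawn in 1..n-1 for each involved paralog).
    ``fixed_diffs`` plants sites derived-fixed in one paralog and absent
    from the other two, keyed by (X, Y) meaning "fixed in X, absent in Y";
    such sites also tally as private-X in the three-copy classification,
    which the returned truth accounts for.
    """

    n_alleles: dict = field(default_factory=lambda: {"P1": 8, "P2": 7, "P3": 9})
    category_counts: dict = field(default_factory=dict)
    fixed_diffs: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_sites(self) -> int:
        return (sum(self.category_counts.values())
                + sum(self.fixed_diffs.values()))


def _involved(category: str) -> tuple[str, ...]:
    if category == "shared-all":
        return _PARALOGS
    kind, rest = category.split("-", 1)
    if kind == "private":
        return (rest,)
    return (rest[:2], rest[2:])


def make_planted_matrix(spec: FixtureSpec) -> tuple[PolarizedSNPMatrix, dict]:
    """Build the matrix and return (matrix, truth) where ``truth`` holds the
    exact expected three-copy category totals and pairwise fixed counts."""
    for c in spec.category_counts:
        if c not in THREE_COPY_CATEGORIES:
            raise InfeasibleFixtureError(f"unknown category {c!r}")
    for c, cnt in spec.category_counts.items():
        if cnt < 0:
            raise InfeasibleFixtureError(f"negative count for {c}")
        for p in _involved(c):
            if cnt > 0 and spec.n_alleles.get(p, 0) < 2:
                raise InfeasibleFixtureError(
                    f"category {c} needs >= 2 alleles of {p}")
    for (x, y), cnt in spec.fixed_diffs.items():
        if x not in _PARALOGS or y not in _PARALOGS or x == y:
            raise InfeasibleFixtureError(f"bad fixed-diff pair ({x}, {y})")
        if cnt > 0 and spec.n_alleles.get(x, 0) < 1:
            raise InfeasibleFixtureError(f"fixed diff needs alleles of {x}")

    rng = np.random.default_rng(spec.seed)
    cols = {p: spec.n_alleles.get(p, 0) for p in _PARALOGS}
    n_total = sum(cols.values())
    offsets = {}
    off = 0
    for p in _PARALOGS:
        offsets[p] = off
        off += cols[p]

    rows = []
    truth_cats = {c: 0 for c in THREE_COPY_CATEGORIES}
    truth_fixed = {}

    def _plant(paralogs_derived, fixed_in=None):
        row = np.zeros(n_total, dtype=np.int8)
        for p in paralogs_derived:
            n_p = cols[p]
            if fixed_in == p:
                k = n_p
            else:
                k = int(rng.integers(1, n_p))  # 1..n_p-1: segregating
            chosen = rng.choice(n_p, size=k, replace=False)
            row[offsets[p] + chosen] = 1
        rows.append(row)

    for c, cnt in spec.category_counts.items():
        for _ in range(cnt):
            _plant(_involved(c))
        truth_cats[c] += cnt
    for (x, y), cnt in spec.fixed_diffs.items():
        for _ in range(cnt):
            _plant((x,), fixed_in=x)
        truth_fixed[(x, y)] = cnt
        truth_cats[f"private-{x}"] += cnt

    if not rows:
        data = np.empty((0, n_total), dtype=np.int8)
    else:
        data = np.vstack(rows)
    order = rng.permutation(len(rows)) if rows else np.array([], dtype=int)
    data = data[order]
    paralogs = [p for p in _PARALOGS for _ in range(cols[p])]
    ids = [f"{p}_{i}" for p in _PARALOGS for i in range(cols[p])]
    matrix = PolarizedSNPMatrix(
        positions=np.arange(1, len(rows) + 1), anc=np.full(len(rows), "A"),
        data=data, allele_ids=ids, paralogs=paralogs,
        total_sites=max(len(rows), 1))
    return matrix, {"categories": truth_cats, "fixed": truth_fixed,
                    "n_sites": len(rows)}


def rpp8_preset(seed: int = 0) -> tuple[PolarizedSNPMatrix, dict]:
    """An RPP8-shaped toy: three paralogs with realistic sample sizes
    (P1 pools the S and D1 chromosomal types), 470 segregating sites, and
    two-way-shared category proportions echoing the observed 234/51/15
    split.  A shape fixture for exercising the tabulators — not a
    reconstruction of the real sequences."""
    spec = FixtureSpec(
        n_alleles={"P1": 15, "P2": 7, "P3": 9},
        category_counts={"shared-P1P3": 234, "shared-P1P2": 51,
                         "shared-P2P3": 15, "shared-all": 58,
                         "private-P1": 60, "private-P2": 28,
                         "private-P3": 24},
        seed=seed)
    return make_planted_matrix(spec)
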