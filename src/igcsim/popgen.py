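"""Summary statistics over polarized SNP matrices.

All statistics accept either a :class:`~igcsim.matrix.PolarizedSNPMatrix`
or a plain ``(n_sites, n_alleles)`` array of 0/1/-1 calls.  Diversity is
reported per site: when the matrix records the alignment length it came
from (``total_sites``), the invariant sites are counted in the denominator.
Gaps are excluded pairwise (each pair of alleles is compared over the sites
where both are called), matching the usual pairwise-deletion policy;
complete deletion is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GAP, PolarizedSNPMatrix


@dataclass
class DiversityResult:
    pi: float              # per-site pairwise nucleotide diversity
    S: int                 # segregating sites
    theta_w: float         # Watterson's theta per site
    n: int                 # alleles
    sites_used: int


def _unpack(matrix, scope=None):
    """Return (data, positions, total_sites)."""
    if isinstance(matrix, PolarizedSNPMatrix):
        data = matrix.data
        pos = matrix.positions
        total = matrix.total_sites
    else:
        data = np.asarray(matrix, dtype=np.int8)
        pos = np.arange(1, data.shape[0] + 1)
        total = None
    if scope is not None:
        lo, hi = scope
        keep = (pos >= lo) & (pos <= hi)
        data = data[keep]
        pos = pos[keep]
        total = hi - lo + 1
    return data, pos, total


def _segregating(data: np.ndarray) -> np.ndarray:
    called = data != GAP
    der = ((data == 1) & called).sum(axis=1)
    tot = called.sum(axis=1)
    return (der > 0) & (der < tot)


def nucleotide_diversity(matrix, scope=None,
                         complete_deletion: bool = False) -> DiversityResult:
    """Average pairwise difference per site (pi), plus S and Watterson's
    theta.  With pairwise deletion each allele pair is normalized by its
    own number of co-called sites."""
    data, _, total = _unpack(matrix, scope)
    n = data.shape[1]
    if n < 2:
        raise ValueError(f"need >= 2 alleles, got {n}")
    if complete_deletion:
        data = data[(data != GAP).all(axis=1)]
    n_invariant = 0 if total is None else total - data.shape[0]
    sites_used = data.shape[0] + n_invariant
    S = int(_segregating(data).sum())

    pair_pi = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = (data[:, i] != GAP) & (data[:, j] != GAP)
            denom = int(ok.sum()) + n_invariant
            if denom == 0:
                continue
            diffs = int((data[ok, i] != data[ok, j]).sum())
            pair_pi.append(diffs / denom)
    pi = float(np.mean(pair_pi)) if pair_pi else 0.0
    a1 = sum(1.0 / k for k in range(1, n))
    theta_w = S / a1 / sites_used if sites_used else 0.0
    return DiversityResult(pi=pi, S=S, theta_w=theta_w, n=n,
                           sites_used=sites_used)


def _pairwise_mean_diffs(data: np.ndarray) -> float:
    """Mean pairwise difference count (not per site), frequency-based with
    per-site gap exclusion."""
    called = data != GAP
    der = ((data == 1) & called).sum(axis=1).astype(float)
    m = called.sum(axis=1).astype(float)
    ok = m >= 2
    der, m = der[ok], m[ok]
    return float(np.sum(2.0 * der * (m - der) / (m * (m - 1.0))))


def tajimas_d(matrix, scope=None) -> float:
    """Tajima's D with the canonical variance constants.  Returns NaN when
    there are no segregating sites (undefined, never reported as 0)."""
    data, _, _ = _unpack(matrix, scope)
    n = data.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 alleles for Tajima's D, got {n}")
    S = int(_segregating(data).sum())
    if S == 0:
        return math.nan
    k_hat = _pairwise_mean_diffs(data)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (k_hat - S / a1) / math.sqrt(var)


def sliding_windows(matrix, stat: str = "pi", width: int = 300,
                    step: int = 25) -> pd.DataFrame:
    """Per-window statistic track (1-based inclusive windows).

    ``stat`` is ``pi`` or ``tajimas_d``.  Windows with insufficient data
    (no called sites, or S=0 for Tajima's D) are flagged NaN, never 0.
    """
    if stat not in ("pi", "tajimas_d"):
        raise ValueError(f"unknown statistic {stat!r}")
    if step < 1 or width < step:
        raise ValueError(f"need width >= step >= 1, got width={width}, step={step}")
    data, pos, total = _unpack(matrix)
    if total is None:
        total = int(pos[-1]) if len(pos) else 0
    if width > total:
        raise ValueError(f"window width {width} exceeds sequence length {total}")
    out = []
    start = 1
    while start + width - 1 <= total:
        end = start + width - 1
        sub = data[(pos >= start) & (pos <= end)]
        if stat == "pi":
            called = sub != GAP
            der = ((sub == 1) & called).sum(axis=1).astype(float)
            m = called.sum(axis=1).astype(float)
            ok = m >= 2
            val = float(np.sum(2 * der[ok] * (m[ok] - der[ok])
                               / (m[ok] * (m[ok] - 1))) / width)
        else:
            if sub.shape[0] == 0 or not _segregating(sub).any():
                val = math.nan
            else:
                val = tajimas_d(sub)
        out.append((start, end, val))
        start += step
    return pd.DataFrame(out, columns=["start", "end", stat])


def ld_r2(matrix, paralog: str | None = None,
          max_dist: float | None = None) -> pd.DataFrame:
    """Pairwise r^2 between segregating sites (haploid/phased alleles).

    r^2 = D^2 / (p1 q1 p2 q2) over the alleles called at both sites; pairs
    with a monomorphic member are skipped.  Returns a frame with columns
    pos1, pos2, dist, r2.
    """
    if isinstance(matrix, PolarizedSNPMatrix) and paralog is not None:
        matrix = matrix.submatrix(paralog)
    data, pos, _ = _unpack(matrix)
    rows = []
    ns = data.shape[0]
    for i in range(ns):
        for j in range(i + 1, ns):
            d = pos[j] - pos[i]
            if max_dist is not None and d > max_dist:
                continue
            ok = (data[i] != GAP) & (data[j] != GAP)
            x = data[i, ok].astype(float)
            y = data[j, ok].astype(float)
            m = len(x)
            if m < 2:
                continue
            p1 = x.mean()
            p2 = y.mean()
            if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
                continue
            D = (x * y).mean() - p1 * p2
            rows.append((int(pos[i]), int(pos[j]), int(d),
                         D * D / (p1 * (1 - p1) * p2 * (1 - p2))))
    return pd.DataFrame(rows, columns=["pos1", "pos2", "dist", "r2"])


def ld_decay(ld: pd.DataFrame, bins) -> pd.DataFrame:
    """Mean +/- SD of r^2 per inter-site distance bin."""
    bins = np.asarray(bins)
    lab = pd.cut(ld["dist"], bins=bins)
    g = ld.groupby(lab, observed=True)["r2"]
    out = g.agg(["mean", "std", "count"]).reset_index(names="bin")
    out["bin_left"] = [iv.left for iv in out["bin"]]
    out["bin_right"] = [iv.right for iv in out["bin"]]
    return out[["bin_left", "bin_right", "mean", "std", "count"]]


def fixed_and_shared(matrix: PolarizedSNPMatrix, x: str, y: str) -> dict:
    """Classify every site carrying a derived allele in paralog X or Y.

    Categories partition those sites: derived present in both samples ->
    ``shared``; fixed derived in one sample and absent in the other ->
    ``fixed_in_X_not_Y`` / ``fixed_in_Y_not_X``; segregating in one and
    absent in the other -> ``private_X`` / ``private_Y``.
    """
    dx = matrix.data[:, matrix.columns_of(x)]
    dy = matrix.data[:, matrix.columns_of(y)]
    if dx.shape[1] < 1 or dy.shape[1] < 1:
        raise ValueError("both paralogs need at least one sampled allele")

    def _freqs(d):
        called = (d != GAP).sum(axis=1)
        der = (d == 1).sum(axis=1)
        return der, called

    der_x, n_x = _freqs(dx)
    der_y, n_y = _freqs(dy)
    in_x = der_x > 0
    in_y = der_y > 0
    fixed_x = in_x & (der_x == n_x)
    fixed_y = in_y & (der_y == n_y)
    res = {
        "shared": int((in_x & in_y).sum()),
        "fixed_in_X_not_Y": int((fixed_x & ~in_y).sum()),
        "fixed_in_Y_not_X": int((fixed_y & ~in_x).sum()),
        "private_X": int((in_x & ~fixed_x & ~in_y).sum()),
        "private_Y": int((in_y & ~fixed_y & ~in_x).sum()),
    }
    res["total"] = int((in_x | in_y).sum())
    return res


def poisson_sampling_adequacy(m: float, S: int = 0) -> dict:
    """Probability that a segregating-site category was missed by sampling.

    Under Poisson sampling with mean allele count ``m``, a site leaves zero
    sampled copies with probability e^-m, so a category of S sites is
    expected to miss S*e^-m of them.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    if S < 0:
        raise ValueError(f"S must be >= 0, got {S}")
    p_zero = math.exp(-m)
    return {"p_zero": p_zero, "frac_sampled": 1.0 - p_zero,
            "expected_missed": S * p_zero}


def haplotype_count(matrix, scope=None, gap_as_state: bool = True) -> dict:
    """Number of distinct allele strings over the scoped sites."""
    data, _, _ = _unpack(matrix, scope)
    cols = [tuple(data[:, j]) for j in range(data.shape[1])]
    if not gap_as_state:
        cols = [tuple(v for v in c if v != GAP) for c in cols]
    return {"n_haplotypes": len(set(cols)), "n_alleles": data.shape[1]}
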