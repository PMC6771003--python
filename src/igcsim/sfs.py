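"""Site-frequency spectra of duplicated loci and IGC-rate classification.

A pairwise SFS splits the derived SNPs of an "acceptor" paralog into those
shared with a "donor" paralog and those specific to the acceptor, binned by
derived-allele count 1..n-1 in the acceptor sample (sites derived-fixed in
the acceptor, count n, are tabulated separately).  Sequence exchange (IGC)
moves derived alleles between paralogs, so the balance of shared versus
specific SNPs — and their frequencies — is informative about the exchange
rate C.

The rate is assigned by parametric-bootstrap classification: 1000 resampled
spectra are generated from the observed SNPs via per-SNP gamma draws
(shape = n_target * allele frequency, scale 1), each resample is assigned
to the candidate theoretical spectrum at minimum Kolmogorov-Smirnov
distance, and a chi-squared test against a uniform split measures how
decisively the replicates prefer one candidate.  Theoretical spectra for
candidate rates are regenerated by the two-copy simulator rather than
transcribed from published tables; their provenance (reps, seed) is kept in
the result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .matrix import GAP, PolarizedSNPMatrix

THREE_COPY_CATEGORIES = ("private-P1", "private-P2", "private-P3",
                         "shared-P1P2", "shared-P1P3", "shared-P2P3",
                         "shared-all")


@dataclass
class PairwiseSFS:
    """Shared/specific derived-SNP spectra of an acceptor paralog."""

    acceptor: str
    donor: str
    n: int
    shared: np.ndarray         # counts, classes 1..n-1
    specific: np.ndarray
    fixed_shared: int = 0      # derived count == n in the acceptor sample
    fixed_specific: int = 0
    snp_freq: np.ndarray = field(default_factory=lambda: np.empty(0))
    snp_is_shared: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    @property
    def total(self) -> int:
        return int(self.shared.sum() + self.specific.sum())


@dataclass
class ThreeCopySFS:
    """Seven-way classification of derived-bearing sites across P1/P2/P3."""

    counts: dict
    category: np.ndarray       # per retained site
    freqs: np.ndarray          # (n_sites, 3) derived freq per paralog
    positions: np.ndarray

    def pairwise_shared(self, x: str, y: str) -> int:
        """Derived SNPs present in both X and Y (marginalizes the 7-way
        table: the XY-only class plus the shared-all class)."""
        key = "shared-" + "".join(sorted((x, y)))
        return int(self.counts[key] + self.counts["shared-all"])


@dataclass
class TheoreticalSFS:
    """Simulation-regenerated expected spectra for one candidate IGC rate."""

    C: float
    n: int
    R: float
    shared: np.ndarray          # normalized: shared+specific sum to 1
    specific: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class BootstrapSFS:
    """Gamma-resampled spectra: one row per replicate."""

    shared: np.ndarray          # (reps, n_target-1)
    specific: np.ndarray
    n_target: int
    discarded: int


@dataclass
class IGCClassification:
    counts: dict                # candidate C -> replicates assigned
    chisq: float
    df: int
    p_value: float
    assigned_C: float
    reps: int
    seed: int


def pairwise_sfs(matrix: PolarizedSNPMatrix, acceptor: str,
                 donor: str) -> PairwiseSFS:
    """Classify each site with the derived allele present in the acceptor
    sample as shared (also present in the donor sample) or specific."""
    da = matrix.data[:, matrix.columns_of(acceptor)]
    dd = matrix.data[:, matrix.columns_of(donor)]
    n = da.shape[1]
    if n < 2:
        raise ValueError(f"acceptor {acceptor} has n={n} < 2 alleles")
    k = (da == 1).sum(axis=1)
    called = (da != GAP).sum(axis=1)
    donor_has = ((dd == 1).sum(axis=1)) > 0
    shared = np.zeros(n - 1, dtype=np.int64)
    specific = np.zeros(n - 1, dtype=np.int64)
    fixed_shared = fixed_specific = 0
    freqs, is_shared = [], []
    for i in range(len(k)):
        if k[i] == 0:
            continue
        if k[i] == called[i] and called[i] == n:
            if donor_has[i]:
                fixed_shared += 1
            else:
                fixed_specific += 1
            continue
        cls = int(k[i])
        if cls > n - 1:
            continue
        if donor_has[i]:
            shared[cls - 1] += 1
        else:
            specific[cls - 1] += 1
        freqs.append(k[i] / n)
        is_shared.append(bool(donor_has[i]))
    return PairwiseSFS(acceptor=acceptor, donor=donor, n=n, shared=shared,
                       specific=specific, fixed_shared=fixed_shared,
                       fixed_specific=fixed_specific,
                       snp_freq=np.asarray(freqs),
                       snp_is_shared=np.asarray(is_shared, dtype=bool))


def merge_pairwise_sfs(parts) -> PairwiseSFS:
    """Pool pairwise SFS from independent samples with the same layout
    (e.g. several unlinked duplicate pairs treated as one dataset)."""
    parts = list(parts)
    first = parts[0]
    if any(p.n != first.n for p in parts):
        raise ValueError("cannot merge SFS with different sample sizes")
    return PairwiseSFS(
        acceptor=first.acceptor, donor=first.donor, n=first.n,
        shared=np.sum([p.shared for p in parts], axis=0),
        specific=np.sum([p.specific for p in parts], axis=0),
        fixed_shared=sum(p.fixed_shared for p in parts),
        fixed_specific=sum(p.fixed_specific for p in parts),
        snp_freq=np.concatenate([p.snp_freq for p in parts]),
        snp_is_shared=np.concatenate([p.snp_is_shared for p in parts]))


def three_copy_sfs(matrix: PolarizedSNPMatrix) -> ThreeCopySFS:
    """Assign every derived-bearing site to one of seven categories by the
    presence of the derived allele in each paralog's sample."""
    present = {}
    freq = {}
    for p in ("P1", "P2", "P3"):
        cols = matrix.columns_of(p)
        if len(cols) == 0:
            raise ValueError(f"paralog {p} has no sampled alleles")
        d = matrix.data[:, cols]
        der = (d == 1).sum(axis=1)
        called = (d != GAP).sum(axis=1)
        present[p] = der > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[p] = np.where(called > 0, der / np.maximum(called, 1), 0.0)
    any_derived = present["P1"] | present["P2"] | present["P3"]
    cats = np.empty(int(any_derived.sum()), dtype=object)
    idx = np.flatnonzero(any_derived)
    for out_i, i in enumerate(idx):
        who = [p for p in ("P1", "P2", "P3") if present[p][i]]
        if len(who) == 3:
            cats[out_i] = "shared-all"
        elif len(who) == 2:
            cats[out_i] = "shared-" + "".join(who)
        else:
            cats[out_i] = "private-" + who[0]
    counts = {c: int((cats == c).sum()) for c in THREE_COPY_CATEGORIES}
    freqs = np.column_stack([freq[p][idx] for p in ("P1", "P2", "P3")])
    return ThreeCopySFS(counts=counts, category=cats, freqs=freqs,
                        positions=matrix.positions[idx])


def gamma_bootstrap(observed: PairwiseSFS, reps: int = 1000,
                    n_target: int = 10, seed: int = 0) -> BootstrapSFS:
    """Resample the observed SNPs into spectra for a sample of ``n_target``
    alleles: per SNP with derived frequency p, draw
    g ~ Gamma(shape = n_target * p, scale = 1) and assign it to frequency
    class round(g); draws outside [1, n_target-1] are discarded (the SNP is
    unsampled or fixed in that replicate)."""
    if reps <= 0:
        raise ValueError(f"reps must be positive, got {reps}")
    if observed.snp_freq.size == 0:
        raise ValueError("observed SFS has no segregating SNPs")
    rng = np.random.default_rng(seed)
    shape = n_target * observed.snp_freq
    draws = rng.gamma(np.broadcast_to(shape, (reps, len(shape))), 1.0)
    cls = np.rint(draws).astype(np.int64)
    valid = (cls >= 1) & (cls <= n_target - 1)
    shared_mask = observed.snp_is_shared[None, :] & valid
    specific_mask = (~observed.snp_is_shared)[None, :] & valid
    nclasses = n_target - 1
    shared = np.zeros((reps, nclasses), dtype=np.int64)
    specific = np.zeros((reps, nclasses), dtype=np.int64)
    rep_idx = np.repeat(np.arange(reps), len(shape)).reshape(reps, -1)
    for mask, out in ((shared_mask, shared), (specific_mask, specific)):
        np.add.at(out, (rep_idx[mask], cls[mask] - 1), 1)
    return BootstrapSFS(shared=shared, specific=specific, n_target=n_target,
                        discarded=int((~valid).sum()))


def _spectra(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, (PairwiseSFS, TheoreticalSFS)):
        return (np.asarray(obj.specific, float), np.asarray(obj.shared, float))
    spec, shr = obj
    return np.asarray(spec, float), np.asarray(shr, float)


def ks_distance(a, b, mode: str = "concat") -> float:
    """Kolmogorov-Smirnov distance between two shared+specific spectra.

    ``concat`` (default): the specific classes 1..n-1 then the shared
    classes are concatenated into one distribution of total mass 1 and the
    maximum absolute CDF difference is taken.  ``percat`` sums the KS
    distance of the two categories normalized separately.
    """
    a_spec, a_shr = _spectra(a)
    b_spec, b_shr = _spectra(b)
    if len(a_spec) != len(b_spec) or len(a_shr) != len(b_shr):
        raise ValueError("spectra have mismatched class layouts")

    def _ks(x, y):
        sx, sy = x.sum(), y.sum()
        if sx <= 0 or sy <= 0:
            raise ValueError("cannot normalize an empty spectrum")
        return float(np.max(np.abs(np.cumsum(x / sx) - np.cumsum(y / sy))))

    if mode == "concat":
        return _ks(np.concatenate([a_spec, a_shr]),
                   np.concatenate([b_spec, b_shr]))
    if mode == "percat":
        return _ks(a_spec, b_spec) + _ks(a_shr, b_shr)
    raise ValueError(f"unknown mode {mode!r}")


def classify_igc_rate(observed: PairwiseSFS, theoretical,
                      reps: int = 1000, seed: int = 0,
                      mode: str = "concat") -> IGCClassification:
    """Assign an IGC rate by minimum-KS classification of gamma-bootstrap
    replicates against the candidate spectra (ties break to the lowest C);
    chi-squared compares the assignment counts with a uniform split."""
    theory = sorted(theoretical, key=lambda t: t.C)
    if len(theory) < 2:
        raise ValueError("need at least two theoretical spectra")
    for i in range(len(theory)):
        for j in range(i + 1, len(theory)):
            ti, tj = theory[i], theory[j]
            if (np.allclose(ti.shared, tj.shared)
                    and np.allclose(ti.specific, tj.specific)):
                raise ValueError(
                    f"degenerate theoretical set: spectra for C={ti.C} and "
                    f"C={tj.C} are identical")
    n_target = theory[0].n
    boot = gamma_bootstrap(observed, reps=reps, n_target=n_target, seed=seed)
    t_cdfs = []
    for t in theory:
        conc = np.concatenate([t.specific, t.shared]).astype(float)
        if mode == "concat":
            t_cdfs.append(np.cumsum(conc / conc.sum()))
    assignments = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        spec = boot.specific[r].astype(float)
        shr = boot.shared[r].astype(float)
        tot = spec.sum() + shr.sum()
        if tot == 0:
            assignments[r] = 0  # empty resample: lowest-C convention
            continue
        if mode == "concat":
            cdf = np.cumsum(np.concatenate([spec, shr]) / tot)
            d = [np.max(np.abs(cdf - tc)) for tc in t_cdfs]
        else:
            d = [ks_distance((spec, shr), t, mode=mode) for t in theory]
        assignments[r] = int(np.argmin(d))
    counts = np.bincount(assignments, minlength=len(theory))
    expected = reps / len(theory)
    chisq = float(((counts - expected) ** 2 / expected).sum())
    df = len(theory) - 1
    p = float(sps.chi2.sf(chisq, df))
    assigned = theory[int(np.argmax(counts))].C
    return IGCClassification(
        counts={t.C: int(c) for t, c in zip(theory, counts)},
        chisq=chisq, df=df, p_value=p, assigned_C=assigned,
        reps=reps, seed=seed)


def generate_theoretical_sfs(C: float, n: int = 10, R: float = 1.0,
                             reps: int = 100, seed: int = 0,
                             N: int = 100, L: int = 1000,
                             mu: float = 0.02) -> TheoreticalSFS:
    """Regenerate the expected shared/specific spectra for IGC rate ``C`` by
    simulating the two-copy design (phases I-III) at crossover rate ``R``
    and averaging the pairwise SFS of ``n`` sampled alleles per copy over
    ``reps`` equilibrium replicates (both exchange directions pooled).

    Under neutrality the SFS *shape* is invariant to the mutation rate
    (mutations Poisson-mark the joint genealogy), so ``mu`` defaults to a
    value high enough to populate all frequency classes with modest
    ``reps``."""
    from .params import SimParams
    from .sim_core import run_simulation, sample_alleles

    if C < 0:
        raise ValueError(f"C must be >= 0, got {C}")
    shared = np.zeros(n - 1, dtype=np.int64)
    specific = np.zeros(n - 1, dtype=np.int64)
    for r in range(reps):
        params = SimParams.two_copy(C=C, R=R, N=N, L=L, mu=mu, seed=seed + r)
        res = run_simulation(params, thin=5000)
        m = sample_alleles(res.population, n_per_copy=n, copies=("P1", "P2"),
                           seed=seed + 60013 + r)
        for acc, don in (("P1", "P2"), ("P2", "P1")):
            s = pairwise_sfs(m, acc, don)
            shared += s.shared
            specific += s.specific
    tot = shared.sum() + specific.sum()
    if tot == 0:
        raise ValueError(f"no segregating SNPs produced for C={C}")
    empty = int((shared == 0).sum() + (specific == 0).sum())
    if empty:
        warnings.warn(
            f"theoretical SFS for C={C}: {empty} of {2 * (n - 1)} classes "
            f"unpopulated after {reps} replicates", stacklevel=2)
    return TheoreticalSFS(C=C, n=n, R=R, shared=shared / tot,
                          specific=specific / tot,
                          meta={"reps": reps, "seed": seed,
                                "source": "two-copy forward simulation",
                                "N": N, "L": L, "mu": mu})
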