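"""Forward-in-time Wright-Fisher simulation of a three-copy gene family.

The simulated chromosome carries five blocks — copy1, spacer1, copy2,
spacer2, copy3 — of ``L`` binary sites each.  A run proceeds through six
phases: burn-in of the single-copy layout (I), seeding of copy2 from a
random copy1 haplotype and conditioning of its frequency trajectory to
neutral fixation by rejection (II), neutral two-copy evolution (III), the
same seeding/fixation for copy3 beyond the second spacer (IV), neutral
three-copy evolution (V), and, optionally, loss of copy2 on one chromosome
followed by frequency-dependent balancing selection that holds the
presence/absence classes of the resulting CNV near 50% each (VI).

Every generation applies, in order: Wright-Fisher resampling of the 2N
chromosomes with per-block crossover (selfing folded into effective rates),
mutation (ancestral -> derived, idempotent), and interlocus gene conversion
(IGC): Poisson(C_eff) tract-copy events split across the six directed
donor->acceptor channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import mix_seed
from .matrix import PolarizedSNPMatrix
from .params import (BLOCK_NAMES, COPY1, COPY2, COPY3, ParameterError,
                     SimParams)

_COPY_BLOCK = {"P1": COPY1, "P2": COPY2, "P3": COPY3,
               "copy1": COPY1, "copy2": COPY2, "copy3": COPY3}


class FixationRestartError(RuntimeError):
    """Raised when a conditioned-fixation phase exceeds the restart cap."""


@dataclass
class Population:
    """2N chromosomes of five L-site blocks plus copy-presence flags."""

    state: np.ndarray       # uint64, shape (2N, 5L/8); packed site bytes
    has2: np.ndarray        # uint8, shape (2N,)
    has3: np.ndarray        # uint8, shape (2N,)
    L: int
    generation: int = 0

    @property
    def n_chrom(self) -> int:
        return self.state.shape[0]

    @property
    def sites(self) -> np.ndarray:
        """Per-site uint8 view, shape (2N, 5, L).  Blocks flagged absent on
        a chromosome hold stale bytes and must be masked by the flags."""
        n = self.state.shape[0]
        return self.state.view(np.uint8).reshape(n, 5, self.L)

    def carriers(self, block: int) -> np.ndarray:
        if block == COPY2:
            return np.flatnonzero(self.has2)
        if block == COPY3:
            return np.flatnonzero(self.has3)
        return np.arange(self.n_chrom)

    def copy2_freq(self) -> float:
        return float(self.has2.mean())

    def copy(self) -> "Population":
        return Population(self.state.copy(), self.has2.copy(),
                          self.has3.copy(), self.L, self.generation)

    def block_pi(self) -> np.ndarray:
        out = np.empty(6)
        _kernels.record_stats(self.state, self.has2, self.has3, self.L, out)
        return out[:5]


@dataclass
class SimResult:
    """Thinned diversity trajectory and end state of one run."""

    params: SimParams
    gens: np.ndarray            # recorded generations
    pi: np.ndarray              # (n_rec, 5) per-block diversity, NaN if absent
    freq2: np.ndarray           # copy2 carrier frequency
    restarts: dict = field(default_factory=dict)
    fixation_gens: dict = field(default_factory=dict)
    skipped_igc: int = 0
    population: Population | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pi, columns=BLOCK_NAMES)
        df.insert(0, "generation", self.gens)
        df["copy2_freq"] = self.freq2
        return df

    def window_mean_pi(self, block: int, window: tuple[int, int]) -> float:
        lo, hi = window
        sel = (self.gens >= lo) & (self.gens <= hi)
        with np.errstate(invalid="ignore"):
            return float(np.nanmean(self.pi[sel, block]))


def init_population(params: SimParams) -> Population:
    """All-ancestral starting population: copy1 and both spacers present on
    2N chromosomes, copy2 and copy3 absent."""
    if not isinstance(params, SimParams):
        raise ParameterError("params must be a SimParams instance")
    n = 2 * params.N
    state = np.zeros((n, 5 * params.L // 8), dtype=np.uint64)
    has2 = np.zeros(n, dtype=np.uint8)
    has3 = np.zeros(n, dtype=np.uint8)
    return Population(state, has2, has3, params.L, generation=0)


def _gen_args(params: SimParams):
    pblock = np.asarray(params.crossover_probs(), dtype=np.float64)
    frac_cum = np.cumsum(np.asarray(params.igc_fractions, dtype=np.float64))
    frac_cum[-1] = 1.0
    return pblock, frac_cum


def step_generation(pop: Population, params: SimParams,
                    phase: str = "V", attempt: int = 0) -> Population:
    """Advance the population by one generation.

    ``phase`` selects phase-dependent behaviour: balancing selection is
    applied in phase VI only.  The RNG stream is derived from
    (params.seed, pop.generation, attempt), so stepping is replayable.
    """
    pblock, frac_cum = _gen_args(params)
    sel_on = phase == "VI"
    new = Population(np.empty_like(pop.state), np.empty_like(pop.has2),
                     np.empty_like(pop.has3), pop.L, pop.generation + 1)
    c_eff = params.C_eff
    if not pop.has2.any() and not pop.has3.any():
        c_eff = 0.0  # single-copy layout: no IGC partner exists
    rc = _kernels.one_generation(
        pop.state, pop.has2, pop.has3, new.state, new.has2, new.has3,
        pop.L, pblock, params.mu, c_eff, frac_cum, params.tract_len,
        sel_on, params.sel_strength,
        mix_seed(params.seed, pop.generation + 1, attempt))
    if rc < 0:
        raise FixationRestartError(
            "balancing-selection weights degenerate (zero total weight)")
    new._skipped = rc  # type: ignore[attr-defined]
    return new


def apply_igc(pop: Population, params: SimParams, seed: int | None = None) -> int:
    """Apply one generation's worth of IGC events in place; returns the
    number of events skipped because a named copy had no carrier."""
    _, frac_cum = _gen_args(params)
    if seed is None:
        seed = mix_seed(params.seed, pop.generation, attempt=0xA11C)
    return int(_kernels.igc_only(pop.state, pop.has2, pop.has3, pop.L,
                                 params.C_eff, frac_cum, params.tract_len,
                                 int(seed) & 0x7FFFFFFF))


def _seed_duplication(pop: Population, which: int, rng: np.random.Generator) -> int:
    """Copy the copy1 block of a random chromosome into its own copy2 or
    copy3 slot and set the presence flag; returns the donor row."""
    row = int(rng.integers(pop.n_chrom))
    sites = pop.sites
    sites[row, which, :] = sites[row, COPY1, :]
    if which == COPY2:
        pop.has2[row] = 1
    else:
        pop.has3[row] = 1
    return row


class _Recorder:
    def __init__(self, params: SimParams, thin: int):
        self.thin = thin
        n_rec = params.schedule.end // thin + 1
        self.gens = np.arange(n_rec) * thin
        self.buf = np.full((n_rec, 6), np.nan)

    @property
    def pi(self) -> np.ndarray:
        return self.buf[:, :5]

    @property
    def freq2(self) -> np.ndarray:
        return self.buf[:, 5]

    def maybe_record(self, pop: Population) -> None:
        g = pop.generation
        if g % self.thin:
            return
        idx = g // self.thin
        if idx >= len(self.gens):
            return
        _kernels.record_stats(pop.state, pop.has2, pop.has3, pop.L,
                              self.buf[idx])


_NO_REC = np.empty((0, 6))


def _run_span(pop: Population, params: SimParams, ngens: int, phase: str,
              attempt: int = 0, watch: int = 0,
              recorder: _Recorder | None = None,
              scratch: tuple | None = None) -> tuple[int, int]:
    """Advance ``pop`` in place by up to ``ngens`` generations with the
    compiled loop; returns (status, generations run)."""
    if ngens <= 0:
        return 0, 0
    pblock, frac_cum = _gen_args(params)
    c_eff = params.C_eff
    if not pop.has2.any() and not pop.has3.any():
        c_eff = 0.0
    if scratch is None:
        scratch = (np.empty_like(pop.state), np.empty_like(pop.has2),
                   np.empty_like(pop.has3))
    buf_s, buf_h2, buf_h3 = scratch
    thin = recorder.thin if recorder is not None else 0
    rec = recorder.buf if recorder is not None else _NO_REC
    status, done, skipped = _kernels.run_gens(
        pop.state, pop.has2, pop.has3, buf_s, buf_h2, buf_h3,
        pop.L, pblock, params.mu, c_eff, frac_cum, params.tract_len,
        phase == "VI", params.sel_strength, params.seed, pop.generation,
        attempt, ngens, watch, thin, rec)
    pop.generation += done
    pop.skipped_igc = getattr(pop, "skipped_igc", 0) + int(skipped)
    return status, done


def duplicate_and_fix(pop: Population, params: SimParams, which: str,
                      rng: np.random.Generator | None = None,
                      recorder: _Recorder | None = None,
                      phase: str = "II",
                      scratch: tuple | None = None) -> tuple[Population, int, int]:
    """Seed a duplication (copy2 or copy3) and evolve until it fixes,
    restarting from the seeding event whenever it is lost (rejection
    conditioning on a neutral fixation trajectory).

    Returns (population at fixation, restart count, generations consumed by
    the successful attempt).
    """
    block = _COPY_BLOCK[which]
    if block not in (COPY2, COPY3):
        raise ParameterError(f"which must name copy2 or copy3, got {which!r}")
    flags = pop.has2 if block == COPY2 else pop.has3
    if flags.any():
        raise ParameterError(f"{which} is already present; cannot seed it")
    if rng is None:
        rng = np.random.default_rng(mix_seed(params.seed, pop.generation, 0xD0))
    snapshot = pop.copy()
    start_gen = pop.generation
    restarts = 0
    watch = 2 if block == COPY2 else 3
    attempt_pop = pop.copy()
    while True:
        np.copyto(attempt_pop.state, snapshot.state)
        np.copyto(attempt_pop.has2, snapshot.has2)
        np.copyto(attempt_pop.has3, snapshot.has3)
        attempt_pop.generation = snapshot.generation
        _seed_duplication(attempt_pop, block, rng)
        status, _ = _run_span(attempt_pop, params, ngens=1 << 30, phase=phase,
                              attempt=restarts, watch=watch,
                              recorder=recorder, scratch=scratch)
        if status == 2:
            return attempt_pop, restarts, attempt_pop.generation - start_gen
        restarts += 1
        if restarts > params.restart_cap:
            raise FixationRestartError(
                f"conditioned fixation of {which} exceeded "
                f"{params.restart_cap} restarts")


def introduce_cnv_and_balance(pop: Population, params: SimParams,
                              until: int | None = None,
                              rng: np.random.Generator | None = None,
                              recorder: _Recorder | None = None,
                              scratch: tuple | None = None) -> tuple[Population, int]:
    """Phase VI: delete copy2 from one random chromosome and evolve under
    frequency-dependent selection holding both CNV classes near 50% until
    generation ``until``.  If either class is lost the phase restarts from
    the deletion event.  Returns (population, restart count)."""
    if params.sel_strength < 0:
        raise ParameterError("sel_strength must be >= 0")
    if not (pop.has2.all() and pop.has3.all()):
        raise ParameterError("phase VI requires all three copies fixed")
    if until is None:
        until = params.schedule.end
    if rng is None:
        rng = np.random.default_rng(mix_seed(params.seed, pop.generation, 0xC2))
    snapshot = pop.copy()
    n = pop.n_chrom
    restarts = 0
    attempt_pop = pop.copy()
    while True:
        np.copyto(attempt_pop.state, snapshot.state)
        np.copyto(attempt_pop.has2, snapshot.has2)
        np.copyto(attempt_pop.has3, snapshot.has3)
        attempt_pop.generation = snapshot.generation
        row = int(rng.integers(n))
        attempt_pop.has2[row] = 0
        status, _ = _run_span(attempt_pop, params,
                              ngens=until - attempt_pop.generation,
                              phase="VI", attempt=restarts, watch=2,
                              recorder=recorder, scratch=scratch)
        if status == 0:
            return attempt_pop, restarts
        restarts += 1
        if restarts > params.restart_cap:
            raise FixationRestartError(
                f"CNV balancing phase exceeded {params.restart_cap} restarts")


def run_simulation(params: SimParams, thin: int = 10,
                   keep_population: bool = True) -> SimResult:
    """Execute phases I..III/V/VI per ``params.phases`` and record the
    thinned per-block diversity trajectory.  Fully reproducible from
    ``params.seed``."""
    sched = params.schedule
    rec = _Recorder(params, thin)
    rng = np.random.default_rng(mix_seed(params.seed, 0, 0xEE))
    pop = init_population(params)
    scratch = (np.empty_like(pop.state), np.empty_like(pop.has2),
               np.empty_like(pop.has3))
    rec.maybe_record(pop)
    restarts: dict[str, int] = {}
    fixation: dict[str, int] = {}

    def _evolve_to(pop: Population, until: int, phase: str) -> Population:
        _run_span(pop, params, ngens=until - pop.generation, phase=phase,
                  recorder=rec, scratch=scratch)
        return pop

    pop = _evolve_to(pop, sched.dup2_at, "I")
    pop, r2, f2 = duplicate_and_fix(pop, params, "copy2", rng=rng,
                                    recorder=rec, phase="II", scratch=scratch)
    restarts["II"] = r2
    fixation["copy2"] = f2
    end3 = sched.dup3_at if params.phases != "I-III" else sched.end
    pop = _evolve_to(pop, max(end3, pop.generation), "III")
    if params.phases != "I-III":
        pop, r4, f4 = duplicate_and_fix(pop, params, "copy3", rng=rng,
                                        recorder=rec, phase="IV",
                                        scratch=scratch)
        restarts["IV"] = r4
        fixation["copy3"] = f4
        end5 = sched.cnv_at if params.phases == "I-VI" else sched.end
        pop = _evolve_to(pop, max(end5, pop.generation), "V")
        if params.phases == "I-VI":
            pop, r6 = introduce_cnv_and_balance(pop, params, until=sched.end,
                                                rng=rng, recorder=rec,
                                                scratch=scratch)
            restarts["VI"] = r6

    return SimResult(params=params, gens=rec.gens, pi=rec.pi,
                     freq2=rec.freq2, restarts=restarts,
                     fixation_gens=fixation,
                     skipped_igc=getattr(pop, "skipped_igc", 0),
                     population=pop if keep_population else None)


def sample_alleles(pop: Population, n_per_copy: int,
                   copies: tuple[str, ...] = ("P1", "P2", "P3"),
                   seed: int = 0) -> PolarizedSNPMatrix:
    """Sample alleles uniformly without replacement per copy and return the
    segregating sites as a polarized SNP matrix (the simulator's derived
    states are the truth; there is no polarization error)."""
    rng = np.random.default_rng(seed)
    cols = []
    labels = []
    ids = []
    sites = pop.sites
    for name in copies:
        block = _COPY_BLOCK[name]
        carriers = pop.carriers(block)
        if len(carriers) < n_per_copy:
            raise ValueError(
                f"cannot sample {n_per_copy} alleles of {name}: only "
                f"{len(carriers)} chromosomes carry it")
        chosen = rng.choice(carriers, size=n_per_copy, replace=False)
        for row in chosen:
            cols.append(sites[row, block, :])
            lab = "P" + str(block // 2 + 1)
            labels.append(lab)
            ids.append(f"{lab}_chr{row}")
    data = np.asarray(cols, dtype=np.int8).T        # sites x alleles
    seg = (data.sum(axis=1) > 0) & (data.sum(axis=1) < data.shape[1])
    data = data[seg]
    positions = np.flatnonzero(seg) + 1
    anc = np.full(len(positions), "A")
    return PolarizedSNPMatrix(positions=positions, anc=anc, data=data,
                              allele_ids=ids, paralogs=labels,
                              total_sites=pop.L)
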