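"""Parameterization of a simulation run.

Rates follow the population-rate convention used throughout: ``R_*`` and
``C_total`` count events in the whole population per generation, and ``mu``
counts expected mutations per chromosome per block per generation (so the
population-wide expectation is ``2N * mu`` per block).  Selfing at fraction
``s`` is modelled by scaling every crossover and gene-conversion rate by
``(1 - s)`` — the "effective rate" treatment — rather than by explicit mate
choice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: block order on the chromosome
BLOCK_NAMES = ("copy1", "spacer1", "copy2", "spacer2", "copy3")
COPY1, SPACER1, COPY2, SPACER2, COPY3 = range(5)

#: ordered donor->acceptor pairs for the six directed IGC channels
IGC_PAIRS = ((1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2))

#: equal-exchange scenario: each directed channel gets 1/6 of the total rate
EQUAL_FRACTIONS = (1 / 6,) * 6

#: unequal-exchange scenario estimated for the RPP8 family.  Channel rates
#: (events per generation): 1->2: 1.0, 2->1: 0.2, 1->3: 1.0, 3->1: 5.0,
#: 2->3: 0.2, 3->2: 1.0; they sum to 8.4 and are expressed as fractions.
RPP8_FRACTIONS = tuple(x / 8.4 for x in (1.0, 0.2, 1.0, 5.0, 0.2, 1.0))

VALID_PHASES = ("I-III", "I-V", "I-VI")


class ParameterError(ValueError):
    """Raised when a SimParams field is out of its admissible range."""


@dataclass(frozen=True)
class PhaseSchedule:
    """Generation boundaries of the six simulation phases.

    Phase I (burn-in of copy1 + the two spacers) runs up to ``dup2_at``,
    where copy2 is seeded and conditioned to fixation (phase II).  Phase III
    (neutral two-copy evolution) runs to ``dup3_at``, where copy3 is seeded
    (phase IV).  Phase V (neutral three-copy evolution) runs to ``cnv_at``,
    where one chromosome loses copy2 and balancing selection on the CNV
    starts (phase VI), ending at ``end``.
    """

    dup2_at: int = 3000
    dup3_at: int = 8000
    cnv_at: int = 16000
    end: int = 26000

    def __post_init__(self) -> None:
        ok = (0 < self.dup2_at < self.dup3_at <= self.cnv_at <= self.end)
        if not ok:
            raise ParameterError(
                "phase boundaries must satisfy 0 < dup2_at < dup3_at <= "
                f"cnv_at <= end, got dup2_at={self.dup2_at}, "
                f"dup3_at={self.dup3_at}, cnv_at={self.cnv_at}, end={self.end}"
            )

    # -- equilibrium measurement windows ------------------------------------
    # Expressed as fixed fractions of the phase spans so that they scale
    # proportionally if the schedule is reconfigured.  At the default
    # schedule they evaluate to the canonical windows: two-copy 4300-6500,
    # three-copy 11000-16000, CNV 21000-26000, spacer1 3000-15000.

    def two_copy_window(self) -> tuple[int, int]:
        span = self.dup3_at - self.dup2_at
        return (round(self.dup2_at + 0.26 * span), round(self.dup2_at + 0.70 * span))

    def three_copy_window(self) -> tuple[int, int]:
        span = self.cnv_at - self.dup3_at
        return (round(self.dup3_at + 0.375 * span), self.cnv_at)

    def cnv_window(self) -> tuple[int, int]:
        span = self.end - self.cnv_at
        return (round(self.cnv_at + 0.5 * span), self.end)

    def spacer_window(self) -> tuple[int, int]:
        span = self.cnv_at - self.dup2_at
        return (self.dup2_at, round(self.dup2_at + (12.0 / 13.0) * span))


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of one simulation run."""

    N: int = 100
    L: int = 1000
    mu: float = 0.001
    R_c1: float = 3.2
    R_c2: float = 3.2
    R_c3: float = 3.2
    R_s1: float = 2.4
    R_s2: float = 1600.0
    C_total: float = 8.4
    igc_fractions: tuple = RPP8_FRACTIONS
    tract_len: int = 100
    s: float = 0.97
    sel_strength: float = 2.0
    phases: str = "I-VI"
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    seed: int = 0
    restart_cap: int = 100_000

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ParameterError(f"N must be >= 1, got {self.N}")
        if self.L < 8 or self.L % 8:
            raise ParameterError(f"L must be a positive multiple of 8, got {self.L}")
        for name in ("mu", "R_c1", "R_c2", "R_c3", "R_s1", "R_s2", "C_total"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        fr = tuple(float(f) for f in self.igc_fractions)
        if len(fr) != 6 or any(f < 0 for f in fr):
            raise ParameterError("igc_fractions must be 6 nonnegative values")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ParameterError(f"igc_fractions must sum to 1, got {sum(fr)}")
        object.__setattr__(self, "igc_fractions", fr)
        if not (0 <= self.tract_len <= self.L):
            raise ParameterError(f"tract_len must be in [0, L], got {self.tract_len}")
        if not (0.0 <= self.s < 1.0):
            raise ParameterError(f"s must be in [0, 1), got {self.s}")
        if self.sel_strength < 0:
            raise ParameterError(f"sel_strength must be >= 0, got {self.sel_strength}")
        if self.phases not in VALID_PHASES:
            raise ParameterError(f"phases must be one of {VALID_PHASES}")

    # -- derived effective rates --------------------------------------------

    @property
    def outcross(self) -> float:
        return 1.0 - self.s

    @property
    def C_eff(self) -> float:
        return self.C_total * self.outcross

    def crossover_probs(self) -> tuple:
        """Per-offspring per-block probability of one crossover, capped at 1."""
        rates = (self.R_c1, self.R_s1, self.R_c2, self.R_s2, self.R_c3)
        n = 2 * self.N
        return tuple(min(1.0, r * self.outcross / n) for r in rates)

    # -- construction helpers -----------------------------------------------

    @classmethod
    def two_copy(cls, C: float, R: float = 1.0, *, N: int = 100, L: int = 1000,
                 mu: float = 0.001, tract_len: int = 100, seed: int = 0,
                 schedule: PhaseSchedule | None = None) -> "SimParams":
        """Two-copy configuration (phases I-III): the original duplicated-pair
        design with a single crossover rate ``R`` applied to every block and
        the whole IGC rate ``C`` split equally between the 1<->2 channels."""
        if schedule is None:
            schedule = PhaseSchedule(dup2_at=2000, dup3_at=5000, cnv_at=5000,
                                     end=5000)
        return cls(N=N, L=L, mu=mu, R_c1=R, R_c2=R, R_c3=R, R_s1=R, R_s2=R,
                   C_total=C, igc_fractions=(0.5, 0.5, 0, 0, 0, 0),
                   tract_len=tract_len, s=0.0, phases="I-III",
                   schedule=schedule, seed=seed)

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["igc_fractions"] = list(self.igc_fractions)
        d["schedule"] = dataclasses.asdict(self.schedule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        if "schedule" in d and isinstance(d["schedule"], dict):
            d["schedule"] = PhaseSchedule(**d["schedule"])
        if "igc_fractions" in d:
            d["igc_fractions"] = tuple(d["igc_fractions"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
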