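"""Replicated simulation experiments: equilibrium diversity multiples.

The quantity of interest throughout is the *copy/spacer ratio*: the mean
equilibrium nucleotide diversity of a duplicated block, averaged over
replicate runs and over the equilibrium window of the relevant phase,
divided by the mean diversity of the single-copy spacer1 block over its own
reference window.  Replicate ``r`` of an experiment runs with seed
``base_seed + r``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import EQUAL_FRACTIONS, RPP8_FRACTIONS, SimParams
from .sim_core import run_simulation

COPY_BLOCKS = {"copy1": 0, "copy2": 2, "copy3": 4}
SPACER1 = 1


def _window_means(result, phases: str) -> dict:
    sched = result.params.schedule
    win_copy = (sched.cnv_window() if phases == "I-VI"
                else sched.three_copy_window())
    out = {name: result.window_mean_pi(block, win_copy)
           for name, block in COPY_BLOCKS.items()}
    out["spacer1"] = result.window_mean_pi(SPACER1, sched.spacer_window())
    out["two_copy"] = result.window_mean_pi(0, sched.two_copy_window())
    return out


def diversity_ratios(params: SimParams, reps: int = 20, thin: int = 20) -> dict:
    """Run ``reps`` replicates and return copy/spacer diversity multiples.

    Averaging follows the replicate-mean convention: per-block window means
    are averaged across replicates first, then divided by the averaged
    spacer1 diversity.
    """
    acc: dict[str, list] = {}
    restarts = 0
    for r in range(reps):
        res = run_simulation(params.replace(seed=params.seed + r), thin=thin,
                             keep_population=False)
        restarts += sum(res.restarts.values())
        for k, v in _window_means(res, params.phases).items():
            acc.setdefault(k, []).append(v)
    means = {k: float(np.nanmean(v)) for k, v in acc.items()}
    spacer = means["spacer1"]
    out = {f"ratio_{k}": means[k] / spacer for k in COPY_BLOCKS}
    out["ratio_two_copy"] = means["two_copy"] / spacer
    out.update({f"pi_{k}": v for k, v in means.items()})
    out["restarts"] = restarts
    out["reps"] = reps
    return out


def neutral_condition(C: float, s: float, fractions=RPP8_FRACTIONS,
                      reps: int = 20, base_seed: int = 0,
                      schedule=None, **overrides) -> dict:
    """Neutral three-copy experiment (phases I-V) at IGC rate ``C`` and
    selfing fraction ``s``; other parameters at the RPP8 defaults.  The
    equilibrium windows scale with the schedule."""
    from .params import PhaseSchedule
    if schedule is None:
        schedule = PhaseSchedule(3000, 8000, 16000, 16000)
    params = SimParams(C_total=C, s=s, igc_fractions=fractions,
                       phases="I-V", schedule=schedule,
                       seed=base_seed, **overrides)
    return diversity_ratios(params, reps=reps)


def neutral_sweep(C_values=(0.2, 8.4, 200.0, 2000.0),
                  s_values=(0.0, 0.97, 0.999),
                  fractions=RPP8_FRACTIONS, reps: int = 20,
                  base_seed: int = 0, schedule=None) -> pd.DataFrame:
    """Cross IGC rate with selfing fraction under neutrality; one row per
    condition with the three copy/spacer ratios."""
    rows = []
    for ci, C in enumerate(C_values):
        for si, s in enumerate(s_values):
            cond_seed = base_seed + 10_000 * (ci * len(s_values) + si)
            r = neutral_condition(C, s, fractions=fractions, reps=reps,
                                  base_seed=cond_seed, schedule=schedule)
            rows.append({"C": C, "s": s, **r})
    return pd.DataFrame(rows)


def balancing_condition(C: float, s: float = 0.97,
                        fractions=RPP8_FRACTIONS, sel_strength: float = 2.0,
                        reps: int = 20, base_seed: int = 0,
                        schedule=None, **overrides) -> dict:
    """Phase I-VI experiment: balancing selection holds the copy2 CNV near
    50% from the CNV introduction onward; ratios taken in the phase-VI
    equilibrium window."""
    kw = dict(overrides)
    if schedule is not None:
        kw["schedule"] = schedule
    params = SimParams(C_total=C, s=s, igc_fractions=fractions,
                       sel_strength=sel_strength, phases="I-VI",
                       seed=base_seed, **kw)
    return diversity_ratios(params, reps=reps)


def max_neutral_ratio(sweep: pd.DataFrame) -> float:
    """Largest copy/spacer multiple over all conditions and copies of a
    neutral sweep."""
    cols = [f"ratio_{k}" for k in COPY_BLOCKS]
    return float(sweep[cols].to_numpy().max())


def igc_recovery_experiment(C_values=(0.2, 1.0, 5.0), n_datasets: int = 20,
                            n: int = 10, R: float = 1.0, mu: float = 0.02,
                            families_per_dataset: int = 4,
                            theory_reps: int = 100, classify_reps: int = 1000,
                            base_seed: int = 0) -> dict:
    """Parameter-recovery check for the SFS classifier: simulate datasets at
    each candidate C with the two-copy simulator, classify each against
    regenerated theoretical spectra, and report the fraction assigned to
    the generating rate.

    One dataset pools the pairwise SFS of ``families_per_dataset``
    independent duplicate families, giving it several hundred SNPs over
    many independent genealogical segments — the information regime the
    classifier is meant for (a single family's SNPs share a handful of
    correlated genealogies and cannot pin down C).  ``mu`` scales the SNP
    count per family (the SFS shape is mutation-rate invariant under
    neutrality)."""
    from .sfs import (classify_igc_rate, generate_theoretical_sfs,
                      merge_pairwise_sfs, pairwise_sfs)
    from .sim_core import sample_alleles

    theory = [generate_theoretical_sfs(C, n=n, R=R, mu=mu, reps=theory_reps,
                                       seed=base_seed + 500_000 + 1000 * i)
              for i, C in enumerate(C_values)]
    out = {"theory": theory, "per_C": {}}
    for ci, C in enumerate(C_values):
        hits = 0
        assigned = []
        for d in range(n_datasets):
            parts = []
            for f in range(families_per_dataset):
                seed = (base_seed + 900_000 + 40_000 * ci
                        + 1000 * d + f)
                params = SimParams.two_copy(C=C, R=R, mu=mu, seed=seed)
                res = run_simulation(params, thin=5000)
                m = sample_alleles(res.population, n_per_copy=n,
                                   copies=("P1", "P2"), seed=seed + 1)
                parts.append(pairwise_sfs(m, acceptor="P2", donor="P1"))
            obs = merge_pairwise_sfs(parts)
            cls = classify_igc_rate(obs, theory, reps=classify_reps,
                                    seed=base_seed + 777 + 100 * ci + d)
            assigned.append(cls.assigned_C)
            hits += cls.assigned_C == C
        out["per_C"][C] = {"accuracy": hits / n_datasets,
                           "assigned": assigned}
    return out
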