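"""Stochastic forward Wright-Fisher engine with selection and dominance.

Brute-force counterpart of :mod:`purgekit.purging_model` (used as its
Monte-Carlo oracle) and the allele-frequency source for synthetic cohorts.
Sites are unlinked; each generation applies the deterministic selection update
followed by Binomial(2N, q') resampling, with binomial repopulation at epoch
boundaries — the same discrete process the transition matrix encodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .purging_model import (
    AlleleFrequencyState,
    BurdenPrediction,
    DemographicTrajectory,
    SelectionClass,
    msd_equilibrium,
    selection_update,
)

__all__ = [
    "SiteTrajectory",
    "simulate_site",
    "simulate_burden",
    "simulate_diploid_cohort",
]


@dataclass
class SiteTrajectory:
    """Copy-count path of one site; absorption in {'lost', 'fixed', 'segregating'}."""

    counts: np.ndarray
    absorption: str
    seed: int


def _step_counts(
    counts: np.ndarray, N: int, sc: SelectionClass, rng, inbreeding: float = 0.0
) -> np.ndarray:
    """One generation: selection then binomial drift, for an array of counts."""
    q = counts / (2 * N)
    qp = selection_update(q, sc.s, sc.h, inbreeding)
    return rng.binomial(2 * N, qp)


def _repopulate(counts: np.ndarray, N_old: int, N_new: int, rng) -> np.ndarray:
    return rng.binomial(2 * N_new, counts / (2 * N_old))


def simulate_site(
    j0: int, traj: DemographicTrajectory, sc: SelectionClass, seed: int
) -> SiteTrajectory:
    """Simulate one site's copy-count path through a demographic trajectory."""
    N0 = traj.ancestral_N
    if not (0 <= j0 <= 2 * N0):
        raise ValueError(f"initial count {j0} outside [0, {2 * N0}]")
    rng = np.random.default_rng(seed)
    counts = [int(j0)]
    j = np.asarray([j0])
    cur_N = N0
    for N, dur in traj.epochs:
        if N != cur_N:
            j = _repopulate(j, cur_N, N, rng)
            cur_N = N
        for _ in range(dur):
            if 0 < j[0] < 2 * cur_N:
                j = _step_counts(j, cur_N, sc, rng)
            counts.append(int(j[0]))
    if j[0] == 0:
        absorption = "lost"
    elif j[0] == 2 * cur_N:
        absorption = "fixed"
    else:
        absorption = "segregating"
    return SiteTrajectory(np.asarray(counts), absorption, seed)


def simulate_burden(
    traj: DemographicTrajectory,
    sc: SelectionClass,
    reps: int,
    seed: int,
    *,
    record_every: int = 1,
) -> BurdenPrediction:
    """Monte-Carlo burden trajectory with Poisson(2N*lam) influx per generation.

    Runs ``reps`` independent replicate populations starting with no standing
    variation, injecting Poisson(2N*lam) new mutations at copy count 1 each
    generation (lam per haploid genome, N the current epoch size), and
    reports the mean and standard error over replicates of the
    segregating (sum_j j/N) and fixed (2 per fixed site) derived burden per
    diploid genome.  Fully determined by (inputs, seed).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(0, dtype=np.int64)
    rep_of = np.empty(0, dtype=np.int64)
    fixed = np.zeros(reps)

    total = traj.total_generations
    times = [total]
    seg_mean, seg_se = [0.0], [0.0]
    fix_mean, fix_se = [0.0], [0.0]

    def record(elapsed: int, N: int) -> None:
        seg = np.bincount(rep_of, weights=counts / N, minlength=reps)
        fx = 2.0 * fixed
        times.append(total - elapsed)
        seg_mean.append(float(seg.mean()))
        seg_se.append(float(seg.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0)
        fix_mean.append(float(fx.mean()))
        fix_se.append(float(fx.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0)

    elapsed = 0
    cur_N = traj.ancestral_N
    for N, dur in traj.epochs:
        if N != cur_N:
            counts = _repopulate(counts, cur_N, N, rng)
            keep = (counts > 0) & (counts < 2 * N)
            np.add.at(fixed, rep_of[counts == 2 * N], 1.0)
            counts, rep_of = counts[keep], rep_of[keep]
            cur_N = N
        for _ in range(dur):
            if counts.size:
                counts = _step_counts(counts, cur_N, sc, rng)
                hit_fix = counts == 2 * cur_N
                if hit_fix.any():
                    np.add.at(fixed, rep_of[hit_fix], 1.0)
                keep = (counts > 0) & ~hit_fix
                counts, rep_of = counts[keep], rep_of[keep]
            n_new = rng.poisson(2 * cur_N * sc.lam, reps)
            if n_new.sum():
                rep_of = np.concatenate([rep_of, np.repeat(np.arange(reps), n_new)])
                counts = np.concatenate(
                    [counts, np.ones(int(n_new.sum()), dtype=np.int64)]
                )
            elapsed += 1
            if elapsed % record_every == 0 or elapsed == total:
                record(elapsed, cur_N)

    return BurdenPrediction(
        times=np.asarray(times, dtype=float),
        n_seg=np.asarray(seg_mean),
        n_fixed=np.asarray(fix_mean),
        se_n_seg=np.asarray(seg_se),
        se_n_fixed=np.asarray(fix_se),
    )


def simulate_diploid_cohort(
    traj: DemographicTrajectory,
    classes: dict[str, tuple[SelectionClass, int]],
    n_individuals: int,
    seed: int,
    inbreeding: float = 0.0,
) -> dict[str, dict]:
    """Terminal allele frequencies and diploid genotypes for effect classes.

    ``classes`` maps class name -> (SelectionClass, budget), where the budget
    is the number of standing segregating sites at the ancestral MSD
    equilibrium, drawn from the equilibrium density at ``traj.ancestral_N``.
    The implied mutational influx (budget / standing mass per unit influx,
    scaled by the current 2N) continues through the post-ancestral epochs, so
    recent low-frequency mutations are represented.  Only sites segregating in
    the terminal population AND variant among the sampled individuals are
    kept, matching a VCF restricted to polymorphic cohort sites.  A nonzero
    ``inbreeding`` coefficient F applies to the selection step of the
    post-ancestral epochs (the cohort's mating system exposes recessives as
    autozygous homozygotes: purging under prolonged inbreeding); the ancestral
    equilibrium itself is panmictic.  Genotypes are drawn as Binomial(2, q)
    per individual; departures from Hardy-Weinberg within individuals are
    introduced downstream by ROH implantation.

    Returns class name -> {'q', 'genotypes', 'selection', 'n_lost', 'n_fixed'}.
    """
    rng = np.random.default_rng(seed)
    N0 = traj.ancestral_N
    out: dict[str, dict] = {}
    for name, (sc, budget) in sorted(classes.items()):
        if budget < 0:
            raise ValueError(f"negative site budget for class {name!r}")
        eq = msd_equilibrium(N0, sc)
        standing_mass = eq.mass[1:-1].sum()
        probs = eq.mass[1:-1] / standing_mass
        counts = rng.choice(np.arange(1, 2 * N0), size=budget, p=probs)
        # ancestral per-generation influx implied by the standing budget,
        # rescaled with the current population size within later epochs
        influx0 = budget / standing_mass * (2 * N0 * sc.lam) if sc.lam > 0 else 0.0
        cur_N = N0
        n_lost = 0
        n_fixed = 0
        for N, dur in traj.epochs[1:]:
            if N != cur_N:
                counts = _repopulate(counts, cur_N, N, rng)
                cur_N = N
            influx = influx0 * cur_N / N0
            for _ in range(dur):
                counts = _step_counts(counts, cur_N, sc, rng, inbreeding)
                n_lost += int((counts == 0).sum())
                hit_fix = counts == 2 * cur_N
                n_fixed += int(hit_fix.sum())
                counts = counts[(counts > 0) & ~hit_fix]
                n_new = rng.poisson(influx) if influx > 0 else 0
                if n_new:
                    counts = np.concatenate(
                        [counts, np.ones(n_new, dtype=counts.dtype)]
                    )
        seg = (counts > 0) & (counts < 2 * cur_N)
        q = counts[seg] / (2 * cur_N)
        genotypes = rng.binomial(2, q[:, None], size=(q.size, n_individuals)).astype(
            np.int8
        )
        # VCF semantics: keep only sites variant among the sampled individuals
        dosage = genotypes.sum(axis=1)
        observed = dosage > 0
        out[name] = {
            "q": q[observed],
            "genotypes": genotypes[observed],
            "selection": sc,
            "n_lost": n_lost + int((counts == 0).sum()),
            "n_fixed": n_fixed + int((counts == 2 * cur_N).sum()),
        }
    return out
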