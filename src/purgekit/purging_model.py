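"""Deterministic prediction of the derived deleterious burden under declining N.

The model tracks the expected density of derived-allele copy counts for a class
of unlinked mutations with genotype fitnesses 1, 1-hs, 1-s, under a constant
haploid genomic influx of ``lam`` new mutations per generation.  The ancestral
population sits at the mutation-selection-drift (MSD) equilibrium; subsequent
piecewise-constant reductions of the diploid effective size N are propagated
with exact Wright-Fisher transition-matrix numerics, yielding the expected
number of segregating and (newly) fixed derived alleles per diploid genome
through time.

Copy-count space is ``j = 0..2N``; states 0 and 2N are absorbing (loss and
fixation).  Everything is linear in ``lam``, so results for other influxes are
rescalings of the unit solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionClass",
    "DemographicTrajectory",
    "AlleleFrequencyState",
    "BurdenPrediction",
    "selection_update",
    "wf_transition_matrix",
    "absorption_probabilities",
    "msd_equilibrium",
    "equilibrium_mean_frequency",
    "empty_state",
    "evolve_burden",
    "purging_coefficient",
    "rescale_scenario",
    "predict_grid",
    "MAX_STATES",
    "DEFAULT_S_GRID",
    "DEFAULT_H_GRID",
    "GENERATION_TIME_YEARS",
    "MUTATION_RATE",
]

#: Dense-matrix guard: at most 2N = MAX_STATES copy-count states (N <= 2000).
MAX_STATES = 4000

#: Default selection / dominance grid for burden predictions.
DEFAULT_S_GRID = (0.001, 0.01, 0.1)
DEFAULT_H_GRID = (0.05, 0.25, 0.45)

#: Calendar-axis conversion constants (presentation only; model math is in
#: generations).
GENERATION_TIME_YEARS = 50.0
MUTATION_RATE = 7.0e-9

_MASS_RTOL = 1e-9


@dataclass(frozen=True)
class SelectionClass:
    """A mutation category: homozygous effect s, dominance h, haploid influx lam.

    Genotype fitnesses are 1 (ancestral homozygote), 1-hs (heterozygote) and
    1-s (derived homozygote); ``lam`` is the expected number of new mutations
    of this class entering per haploid genome per generation.
    """

    s: float
    h: float
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError(f"h must be in [0, 1], got {self.h}")
        if self.lam < 0.0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        for w in (1.0 - self.h * self.s, 1.0 - self.s):
            if w < 0.0:
                raise ValueError(f"negative genotype fitness for {self}")

    @property
    def d(self) -> float:
        """Purging coefficient d = s(1-2h)/2."""
        return purging_coefficient(self)


def purging_coefficient(sc: SelectionClass) -> float:
    """Per-copy purging strength d = s(1-2h)/2 (inbreeding-purging theory).

    Positive for (partially) recessive mutations (h < 1/2), zero for additive
    ones; used for reporting and diagnostics only.
    """
    return sc.s * (1.0 - 2.0 * sc.h) / 2.0


@dataclass(frozen=True)
class DemographicTrajectory:
    """Piecewise-constant diploid effective sizes with durations in generations.

    The first epoch is the ancestral equilibrium epoch; its N is the size at
    which the MSD equilibrium is computed.  Subsequent epochs are the stepwise
    size changes (typically reductions).
    """

    epochs: tuple[tuple[int, int], ...]

    def __init__(self, epochs) -> None:
        epochs = tuple((int(N), int(dur)) for N, dur in epochs)
        if not epochs:
            raise ValueError("trajectory needs at least one epoch")
        for N, dur in epochs:
            if N < 2:
                raise ValueError(f"diploid size must be >= 2, got {N}")
            if dur < 1:
                raise ValueError(f"epoch duration must be >= 1, got {dur}")
        object.__setattr__(self, "epochs", epochs)

    @property
    def ancestral_N(self) -> int:
        return self.epochs[0][0]

    @property
    def total_generations(self) -> int:
        return sum(d for _, d in self.epochs)

    @property
    def max_N(self) -> int:
        return max(N for N, _ in self.epochs)

    @classmethod
    def from_table(cls, path) -> "DemographicTrajectory":
        """Read a plain-text epoch table: columns epoch_index, N, duration."""
        tab = pd.read_csv(path, sep=r"\s+|,", engine="python", comment="#")
        cols = {c.lower(): c for c in tab.columns}
        n_col = cols.get("n", tab.columns[1])
        d_col = cols.get("duration_generations", cols.get("duration", tab.columns[2]))
        return cls(list(zip(tab[n_col], tab[d_col])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(len(self.epochs)),
                "N": [N for N, _ in self.epochs],
                "duration_generations": [d for _, d in self.epochs],
            }
        )


@dataclass
class AlleleFrequencyState:
    """Expected density over derived copy counts 0..2N plus absorbed mass.

    ``mass[j]`` is the expected number of sites currently segregating with j
    derived copies (per the influx encoded in the generating SelectionClass);
    entries at j=0 and j=2N are kept at zero, with absorbed density accumulated
    in ``lost_mass`` / ``fixed_mass``.  ``fix_flux`` is the per-generation
    fixation flux of the state (nonzero for equilibria).
    """

    N: int
    mass: np.ndarray
    fixed_mass: float = 0.0
    lost_mass: float = 0.0
    injected_mass: float = 0.0
    fix_flux: float = 0.0
    loss_flux: float = 0.0

    @property
    def n_seg(self) -> float:
        """Expected segregating derived alleles per diploid genome, sum_j m_j * j/N."""
        j = np.arange(2 * self.N + 1)
        return float(self.mass @ j / self.N)

    def check_mass_balance(self, rtol: float = _MASS_RTOL) -> None:
        total = float(self.mass.sum()) + self.fixed_mass + self.lost_mass
        if self.injected_mass > 0 and not np.isclose(
            total, self.injected_mass, rtol=rtol, atol=1e-12
        ):
            raise AssertionError(
                f"mass not conserved: accounted {total!r} vs injected "
                f"{self.injected_mass!r}"
            )


@dataclass
class BurdenPrediction:
    """Expected derived-allele burden per diploid genome through time.

    ``times`` are generations before present (descending); ``n_fixed`` counts 2
    copies per newly fixed site, reported relative to the ancestral-equilibrium
    fixation baseline so that the pre-decline burden is flat.
    """

    times: np.ndarray
    n_seg: np.ndarray
    n_fixed: np.ndarray
    se_n_seg: np.ndarray | None = None
    se_n_fixed: np.ndarray | None = None

    @property
    def n_total(self) -> np.ndarray:
        return self.n_seg + self.n_fixed

    def to_frame(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            log10_gen = np.where(self.times > 0, np.log10(np.maximum(self.times, 1e-300)), np.nan)
        out = pd.DataFrame(
            {
                "generation_before_present": self.times,
                "log10_generation": log10_gen,
                "n_seg": self.n_seg,
                "n_fixed": self.n_fixed,
                "n_total": self.n_total,
            }
        )
        if self.se_n_seg is not None:
            out["se_n_seg"] = self.se_n_seg
        if self.se_n_fixed is not None:
            out["se_n_fixed"] = self.se_n_fixed
        return out


def selection_update(q, s: float, h: float, inbreeding: float = 0.0):
    """One deterministic generation of viability selection on derived frequency q.

    With random mating (``inbreeding`` = 0) this is the marginal-fitness form
    w_der = p(1-hs) + q(1-s), w_anc = p + q(1-hs), wbar = p*w_anc + q*w_der,
    q' = q*w_der/wbar.  A nonzero inbreeding coefficient F shifts genotype
    frequencies to q^2 + Fpq, 2pq(1-F), p^2 + Fpq before selection, exposing
    recessives to selection as homozygotes (the purging mechanism of
    prolonged inbreeding).
    """
    q = np.asarray(q, dtype=float)
    p = 1.0 - q
    F = inbreeding
    if not (0.0 <= F <= 1.0):
        raise ValueError(f"inbreeding coefficient must be in [0, 1], got {F}")
    f22 = q * q + F * p * q
    f12 = 2.0 * p * q * (1.0 - F)
    wbar = (p * p + F * p * q) + f12 * (1.0 - h * s) + f22 * (1.0 - s)
    if np.any(wbar <= 0.0):
        raise ValueError(f"mean fitness <= 0 for s={s}, h={h}")
    return (f22 * (1.0 - s) + 0.5 * f12 * (1.0 - h * s)) / wbar


def _check_states(N: int) -> None:
    if N < 2:
        raise ValueError(f"diploid size must be >= 2, got {N}")
    if 2 * N > MAX_STATES:
        raise ValueError(
            f"2N = {2 * N} exceeds the dense-matrix cap of {MAX_STATES} states; "
            "use rescale_scenario or the stochastic engine"
        )


def wf_transition_matrix(
    N: int, sc: SelectionClass, inbreeding: float = 0.0
) -> np.ndarray:
    """Row-stochastic Wright-Fisher transition matrix over copy counts 0..2N.

    Row j gives Binomial(2N, q') sampling probabilities with q' from
    :func:`selection_update` at q = j/2N; states 0 and 2N are absorbing.
    """
    _check_states(N)
    two_n = 2 * N
    j = np.arange(two_n + 1)
    # the absorbing endpoints are not pushed through selection (for lethals
    # the mean fitness vanishes at fixation; the state is absorbing anyway)
    qp = np.empty(two_n + 1)
    qp[1:-1] = selection_update(j[1:-1] / two_n, sc.s, sc.h, inbreeding)
    qp[0], qp[-1] = 0.0, 1.0
    T = stats.binom.pmf(j[None, :], two_n, qp[:, None])
    T[0] = 0.0
    T[0, 0] = 1.0
    T[-1] = 0.0
    T[-1, -1] = 1.0
    return T


def absorption_probabilities(N: int, sc: SelectionClass) -> np.ndarray:
    """Probability of ultimate fixation from each transient copy count 1..2N-1.

    Solves (I - Q) b = r where Q is the transient block of the transition
    matrix and r the one-step fixation probabilities.
    """
    T = wf_transition_matrix(N, sc)
    Q = T[1:-1, 1:-1]
    r = T[1:-1, -1]
    A = np.eye(Q.shape[0]) - Q
    return np.linalg.solve(A, r)


def msd_equilibrium(
    N: int,
    sc: SelectionClass,
    *,
    inbreeding: float = 0.0,
    max_iter: int = 1_000_000,
    tol: float = 1e-10,
) -> AlleleFrequencyState:
    """Stationary segregating density under mutational influx at copy count 1.

    ``lam`` is the haploid genomic mutation rate, so the population receives
    2N*lam new mutations per generation, each entering as a single copy.
    Solves x = x Q + 2N*lam*e1 on the transient states by direct linear solve,
    falling back to fixed-point iteration (relative tolerance ``tol``) if the
    solve is unusable.  Also records the per-generation equilibrium fixation
    and loss fluxes.
    """
    T = wf_transition_matrix(N, sc, inbreeding)
    Q = T[1:-1, 1:-1]
    influx = np.zeros(Q.shape[0])
    influx[0] = 2 * N * sc.lam
    A = np.eye(Q.shape[0]) - Q
    try:
        x = np.linalg.solve(A.T, influx)
    except np.linalg.LinAlgError:
        x = None
    if x is None or np.any(~np.isfinite(x)) or np.any(x < -1e-8):
        x = np.zeros_like(influx)
        for it in range(max_iter):
            x_new = x @ Q + influx
            if np.allclose(x_new, x, rtol=tol, atol=0.0):
                x = x_new
                break
            x = x_new
        else:
            raise RuntimeError(
                f"MSD equilibrium iteration did not converge within {max_iter} "
                f"generations at N={N}, s={sc.s}, h={sc.h}"
            )
    x = np.clip(x, 0.0, None)
    mass = np.zeros(2 * N + 1)
    mass[1:-1] = x
    fix_flux = float(x @ T[1:-1, -1])
    loss_flux = float(x @ T[1:-1, 0])
    return AlleleFrequencyState(
        N=N, mass=mass, fix_flux=fix_flux, loss_flux=loss_flux
    )


def persite_transition_matrix(N: int, sc: SelectionClass, u: float) -> np.ndarray:
    """Wright-Fisher matrix for a single site with recurrent two-way mutation.

    Selection update, then symmetric mutation q'' = q'(1-u) + (1-q')u, then
    Binomial(2N, q'') sampling.  Unlike :func:`wf_transition_matrix` this chain
    is ergodic (no absorbing states), so it has a proper stationary
    distribution — the per-site MSD equilibrium.
    """
    _check_states(N)
    if not (0.0 < u < 0.5):
        raise ValueError(f"per-site mutation rate must be in (0, 0.5), got {u}")
    two_n = 2 * N
    j = np.arange(two_n + 1)
    qp = selection_update(j / two_n, sc.s, sc.h)
    qm = qp * (1.0 - u) + (1.0 - qp) * u
    return stats.binom.pmf(j[None, :], two_n, qm[:, None])


def persite_stationary(N: int, sc: SelectionClass, u: float) -> np.ndarray:
    """Stationary distribution of the per-site recurrent-mutation chain."""
    T = persite_transition_matrix(N, sc, u)
    n = T.shape[0]
    A = T.T - np.eye(n)
    A[-1, :] = 1.0  # normalization replaces one redundant balance equation
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def equilibrium_mean_frequency(N: int, sc: SelectionClass, u: float) -> float:
    """Mean derived frequency at per-site MSD equilibrium with mutation rate u.

    Computed from the stationary distribution of the recurrent-mutation chain;
    approaches the deterministic balance limits u/(hs) (partially dominant,
    4Nhs >> 1) and sqrt(u/s) (fully recessive, strong confinement) in the
    appropriate regimes.
    """
    pi = persite_stationary(N, sc, u)
    j = np.arange(2 * N + 1)
    return float(pi @ j / (2 * N))


def empty_state(N: int) -> AlleleFrequencyState:
    """A state with no standing variation (burden accumulates from influx only)."""
    return AlleleFrequencyState(N=N, mass=np.zeros(2 * N + 1))


def _remap_mass(mass: np.ndarray, N_old: int, N_new: int):
    """Binomial repopulation of copy-count density into a new population size.

    Each old count j resamples as Binomial(2*N_new, j/2*N_old); mass landing on
    the absorbing boundaries is returned separately.
    """
    two_new = 2 * N_new
    j_old = np.arange(2 * N_old + 1)
    q_old = j_old / (2 * N_old)
    B = stats.binom.pmf(np.arange(two_new + 1)[None, :], two_new, q_old[:, None])
    new_mass = mass @ B
    lost = float(new_mass[0])
    fixed = float(new_mass[-1])
    new_mass[0] = 0.0
    new_mass[-1] = 0.0
    return new_mass, lost, fixed


def evolve_burden(
    eq: AlleleFrequencyState,
    traj: DemographicTrajectory,
    sc: SelectionClass,
    *,
    record_every: int = 1,
    check_mass: bool = True,
) -> BurdenPrediction:
    """Propagate a copy-count state through a demographic trajectory.

    Starting from ``eq`` (normally the MSD equilibrium at ``traj.ancestral_N``),
    iterates the Wright-Fisher matrix one generation at a time, injecting
    2*N*lam new mutations per generation at copy count 1 (lam per haploid
    genome, N the current epoch size), remapping the density by binomial
    repopulation at epoch boundaries, and recording the segregating and
    baseline-subtracted fixed burden per diploid genome.
    """
    if eq.N != traj.ancestral_N:
        raise ValueError(
            f"equilibrium state is at N={eq.N} but trajectory starts at "
            f"N={traj.ancestral_N}"
        )
    for N, _ in traj.epochs:
        _check_states(N)

    mass = eq.mass.copy()
    cur_N = eq.N
    fixed = 0.0
    lost = 0.0
    injected = eq.injected_mass
    initial_mass = float(mass.sum()) + eq.fixed_mass + eq.lost_mass
    baseline_flux = eq.fix_flux

    total = traj.total_generations
    times = [total]
    n_seg = [float(mass @ np.arange(2 * cur_N + 1)) / cur_N]
    n_fixed = [0.0]

    elapsed = 0
    matrices: dict[int, np.ndarray] = {}
    for N, dur in traj.epochs:
        if N != cur_N:
            mass, d_lost, d_fixed = _remap_mass(mass, cur_N, N)
            lost += d_lost
            fixed += d_fixed
            cur_N = N
        if N not in matrices:
            matrices[N] = wf_transition_matrix(N, sc)
        T = matrices[N]
        j = np.arange(2 * N + 1)
        for _ in range(dur):
            mass = mass @ T
            lost += float(mass[0])
            fixed += float(mass[-1])
            mass[0] = 0.0
            mass[-1] = 0.0
            mass[1] += 2 * N * sc.lam
            injected += 2 * N * sc.lam
            elapsed += 1
            if elapsed % record_every == 0 or elapsed == total:
                times.append(total - elapsed)
                n_seg.append(float(mass @ j) / N)
                n_fixed.append(2.0 * (fixed - baseline_flux * elapsed))
        if check_mass:
            accounted = float(mass.sum()) + fixed + lost
            expected = initial_mass + injected - eq.injected_mass
            if expected > 0 and not np.isclose(accounted, expected, rtol=_MASS_RTOL):
                raise AssertionError(
                    f"mass not conserved at epoch N={N}: {accounted} vs {expected}"
                )

    return BurdenPrediction(
        times=np.asarray(times, dtype=float),
        n_seg=np.asarray(n_seg),
        n_fixed=np.asarray(n_fixed),
    )


def rescale_scenario(
    traj: DemographicTrajectory, sc: SelectionClass, target_max_N: int
):
    """Diffusion-scale rescaling: divide every N by c, multiply s by c.

    c = max(N)/target_max_N; durations shrink by the same factor so that time in
    units of N generations (and hence 4Ns and the diffusion dynamics) is
    approximately preserved.  Refuses if the scaled s (or hs) would exceed 1.
    Returns (scaled trajectory, scaled class, report dict).
    """
    c = traj.max_N / float(target_max_N)
    if c <= 1.0:
        report = {"factor": 1.0, "note": "no rescaling needed"}
        return traj, sc, report
    s_new = sc.s * c
    if s_new > 1.0 or s_new * sc.h > 1.0:
        raise ValueError(
            f"rescaling by c={c:.3g} would push s to {s_new:.3g} (> 1); "
            "choose a larger target_max_N"
        )
    epochs = []
    for N, dur in traj.epochs:
        epochs.append((max(2, round(N / c)), max(1, round(dur / c))))
    traj_new = DemographicTrajectory(epochs)
    sc_new = replace(sc, s=s_new)
    report = {
        "factor": c,
        "note": (
            "Ns preserved; expect O(s) = "
            f"{s_new:.3g} discrete-time corrections relative to the diffusion limit"
        ),
    }
    return traj_new, sc_new, report


def predict_grid(
    trajectories: dict[str, DemographicTrajectory],
    s_values=DEFAULT_S_GRID,
    h_values=DEFAULT_H_GRID,
    lam: float = 1.0,
    *,
    record_every: int = 1,
) -> pd.DataFrame:
    """Burden predictions over a named-trajectory x s x h grid (long format)."""
    frames = []
    for name, traj in trajectories.items():
        for s in s_values:
            for h in h_values:
                sc = SelectionClass(s=s, h=h, lam=lam)
                eq = msd_equilibrium(traj.ancestral_N, sc)
                pred = evolve_burden(eq, traj, sc, record_every=record_every)
                frame = pred.to_frame()
                frame.insert(0, "h", h)
                frame.insert(0, "s", s)
                frame.insert(0, "trajectory", name)
                frames.append(frame)
    return pd.concat(frames, ignore_index=True)
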