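"""Gillespie kinetic Monte Carlo folding simulator.

Trajectories start from the straight rod and evolve by corner flips and
90-degree end flips with Metropolis rates W_i = min(1, exp(-dE/T))
(kB = 1, and the physical attempt-frequency prefactor is fixed to 1, so
times are in reduced units).  Each event advances the clock by an
exponential waiting time -ln(xi)/W_T and displaces exactly one bead by a
lattice diagonal.  A run ends when the chain first attains the
ground-state energy E0 — for a unique-ground-state sequence this is
equivalent to reaching the native structure, since energy is invariant
under the lattice symmetries — or when the event cap is hit (censored).

The module-level functions :func:`legal_moves` and
:func:`gillespie_step` are a straightforward pure-Python realization of
the same dynamics, used as the reference against which the compiled
trajectory kernel is tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kmc_kernels
from .core import DEFAULT_PARAMS, Conformation, HPSequence, InteractionParams, energy
from .enumeration import ground_state

__all__ = [
    "MoveProposal",
    "MoveCatalog",
    "KMCResult",
    "FPTCurve",
    "TrappedStateError",
    "legal_moves",
    "gillespie_step",
    "apply_move",
    "first_passage",
    "mean_fpt_curve",
    "run_seed",
]

DEFAULT_MAX_EVENTS = 10**8


class TrappedStateError(RuntimeError):
    """The chain reached a conformation with no legal move."""


@dataclass(frozen=True)
class MoveProposal:
    kind: str  # "corner" or "end"
    bead: int
    target: tuple[int, int, int]
    delta_e: int
    rate: float


@dataclass(frozen=True)
class MoveCatalog:
    conformation: Conformation
    proposals: tuple[MoveProposal, ...]
    total_rate: float


@dataclass(frozen=True)
class KMCResult:
    fpt: float
    events: int
    reached: bool
    censored: bool
    seed: int


@dataclass(frozen=True)
class FPTCurve:
    temperatures: np.ndarray
    mean_fpt: np.ndarray  # NaN where every run was censored
    sem: np.ndarray
    n_runs: int
    n_censored: np.ndarray

    def argmin_temperature(self) -> float:
        """Grid temperature with the smallest mean first-passage time."""
        return float(self.temperatures[int(np.nanargmin(self.mean_fpt))])


def _metropolis(delta_e: int, temperature: float) -> float:
    return min(1.0, math.exp(-delta_e / temperature))


def _delta_e_python(pos, occ, types, emat, i, new_pos) -> int:
    old = tuple(pos[i])
    de = 0
    for ax in range(3):
        for sgn in (1, -1):
            for site, sign in ((old, -1), (new_pos, +1)):
                q = list(site)
                q[ax] += sgn
                j = occ.get(tuple(q))
                if j is not None and not (i - 1 <= j <= i + 1):
                    de += sign * int(emat[types[i], types[j]])
    return de


def legal_moves(
    conf: Conformation,
    seq: HPSequence,
    params: InteractionParams = DEFAULT_PARAMS,
    temperature: float = 1.0,
) -> MoveCatalog:
    """Every legal corner flip and 90-degree end flip, with dE and rate.

    Corner flip: interior bead i whose bonds are perpendicular moves to
    the diagonal site pos(i-1) + pos(i+1) - pos(i) if unoccupied.  End
    flip: a terminal bead moves to any free site adjacent to its bonded
    neighbor and perpendicular to the terminal bond; the straight-back
    180-degree reversal is never generated.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    pos = conf.positions
    n = len(pos)
    occ = {tuple(p): i for i, p in enumerate(pos)}
    types = seq.type_codes.astype(np.intp)
    emat = params.matrix
    props: list[MoveProposal] = []

    for endi, piv in ((0, 1), (n - 1, n - 2)):
        pivot = pos[piv]
        cur = tuple(pos[endi])
        anti = tuple(2 * pivot - pos[endi])
        for ax in range(3):
            for sgn in (1, -1):
                t = list(pivot)
                t[ax] += sgn
                t = tuple(t)
                if t == cur or t == anti or t in occ:
                    continue
                de = _delta_e_python(pos, occ, types, emat, endi, t)
                props.append(
                    MoveProposal("end", endi, t, de, _metropolis(de, temperature))
                )
    for i in range(1, n - 1):
        d1 = pos[i - 1] - pos[i]
        d2 = pos[i + 1] - pos[i]
        if np.any(d1 + d2):  # perpendicular bonds
            t = tuple(pos[i] + d1 + d2)
            if t not in occ:
                de = _delta_e_python(pos, occ, types, emat, i, t)
                props.append(
                    MoveProposal("corner", i, t, de, _metropolis(de, temperature))
                )
    return MoveCatalog(conf, tuple(props), sum(p.rate for p in props))


def gillespie_step(
    catalog: MoveCatalog, rng: np.random.Generator
) -> tuple[MoveProposal, float]:
    """Draw (move, waiting time) from a catalog.

    The move is chosen with probability W_i / W_T and the waiting time is
    -ln(xi)/W_T with xi uniform on (0, 1); draws of exactly zero are
    rejected and redrawn.
    """
    if not catalog.proposals:
        raise TrappedStateError("no legal moves from this conformation")
    r = rng.random() * catalog.total_rate
    acc = 0.0
    chosen = catalog.proposals[-1]
    for p in catalog.proposals:
        acc += p.rate
        if r <= acc:
            chosen = p
            break
    xi = rng.random()
    while xi == 0.0:
        xi = rng.random()
    return chosen, -math.log(xi) / catalog.total_rate


def apply_move(conf: Conformation, move: MoveProposal) -> Conformation:
    pos = conf.positions.copy()
    pos[move.bead] = move.target
    return Conformation(pos)


def _rate_table(params: InteractionParams, temperature: float):
    emax = max(abs(e) for e in params.as_tuple())
    woff = 8 * emax
    de = np.arange(-woff, woff + 1, dtype=np.float64)
    wtab = np.minimum(1.0, np.exp(-de / temperature))
    return wtab, woff


_M64 = (1 << 64) - 1


def _mix64(z: int) -> int:
    z = (z + 0x9E3779B97F4A7C15) & _M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return z ^ (z >> 31)


def run_seed(base_seed: int, temp_index: int, run_index: int) -> int:
    """Independent per-(temperature, run) stream seed from a base seed."""
    z = base_seed & _M64
    for salt in (temp_index, run_index):
        z = _mix64(z ^ ((salt * 0xD1342543DE82EF95) & _M64))
    return z & 0x7FFFFFFFFFFFFFFF  # keep within int64 for the kernel


def first_passage(
    seq: HPSequence | str,
    params: InteractionParams = DEFAULT_PARAMS,
    temperature: float = 1.0,
    e0: int | None = None,
    seed: int = 0,
    max_events: int = DEFAULT_MAX_EVENTS,
    _check_every: int = 0,
) -> KMCResult:
    """First-passage time from the straight rod to the native energy.

    ``e0`` defaults to the exact ground-state energy, in which case the
    sequence must have a unique ground state (otherwise "native state"
    is ill-defined and the run is refused).
    """
    seq = HPSequence(str(seq))
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if e0 is None:
        gs = ground_state(seq, params)
        if not gs.unique:
            raise ValueError(
                f"sequence {seq} has n(E0) = {gs.n0} != 8: no unique native "
                "state, first-passage target undefined"
            )
        e0 = gs.e0
    wtab, woff = _rate_table(params, temperature)
    types = seq.type_codes.astype(np.uint8)
    t, events, status, ecur = _kmc_kernels.run_fpt(
        len(seq), types, params.matrix, wtab, woff, e0, seed, max_events,
        _check_every,
    )
    if status == -1:
        raise TrappedStateError(
            f"no legal move after {events} events (energy {ecur})"
        )
    if status == -2:
        raise RuntimeError("incremental energy bookkeeping diverged")
    return KMCResult(
        fpt=float(t),
        events=int(events),
        reached=status == 1,
        censored=status == 0,
        seed=seed,
    )


def mean_fpt_curve(
    seq: HPSequence | str,
    params: InteractionParams = DEFAULT_PARAMS,
    temperatures: Sequence[float] = tuple(np.arange(3.0, 7.01, 0.5)),
    runs: int = 10_000,
    seed: int = 0,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> FPTCurve:
    """Mean first-passage time over a temperature grid.

    Every (temperature, run) pair gets its own deterministic RNG stream
    derived from ``seed``, so the sweep is reproducible and
    order-independent.  Censored runs are excluded from the mean and
    reported per temperature.
    """
    seq = HPSequence(str(seq))
    gs = ground_state(seq, params)
    if not gs.unique:
        raise ValueError(f"sequence {seq} lacks a unique ground state")
    temps = np.asarray(list(temperatures), dtype=float)
    means = np.full(len(temps), np.nan)
    sems = np.full(len(temps), np.nan)
    censored = np.zeros(len(temps), dtype=int)
    for ti, T in enumerate(temps):
        fpts = []
        for run in range(runs):
            res = first_passage(
                seq,
                params,
                temperature=float(T),
                e0=gs.e0,
                seed=run_seed(seed, ti, run),
                max_events=max_events,
            )
            if res.reached:
                fpts.append(res.fpt)
            else:
                censored[ti] += 1
        if fpts:
            arr = np.array(fpts)
            means[ti] = arr.mean()
            sems[ti] = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
    return FPTCurve(temps, means, sems, runs, censored)
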