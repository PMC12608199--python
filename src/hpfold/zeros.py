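"""Partition-function zeros, heat capacity, and its per-zero decomposition.

With x = exp(1/kB T) (kB = 1 throughout), the partition function of an HP
chain is a degree-M polynomial with positive integer coefficients,

    Z(x) = n(E0) prod_k (x - x_k),

so its zeros x_k come in complex-conjugate pairs apart from a few on the
negative real axis, and none lie on the physical half-line x > 1.  The
heat capacity follows from U = -d ln Z / d beta:

    CV(x) = x (ln x)^2 d/dx [ x d/dx ln Z(x) ]
          = -x (ln x)^2 sum_k x_k / (x - x_k)^2,

which attributes to every zero the real component

    CV_k(x) = -x (ln x)^2 Re[ x_k / (x - x_k)^2 ],

summing exactly to CV.  A zero close to the positive real axis produces a
sharp peak in its component; the peak position defines a finite-size
transition temperature.  Zeros cluster in modulus rings: the inner ring
(|x| near 1, i.e. high T) is the coil-globule collapse transition, the
outer ring the folding transition, and any intermediate ring signals
crossovers from metastable compact globules — the signature of a slow
folder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import mpmath as mp
import numpy as np
from scipy.optimize import minimize_scalar

from .enumeration import PartitionPolynomial

__all__ = [
    "ZeroSet",
    "ComponentProfile",
    "TransitionReport",
    "ConvergenceError",
    "find_zeros",
    "heat_capacity_direct",
    "component",
    "decompose",
    "band_zeros",
    "transition_temperatures",
    "classify_foldability",
    "temperature_to_x",
    "x_to_temperature",
]

#: Default search range for component peaks, in reduced temperature.
PEAK_T_RANGE = (0.05, 50.0)
PEAK_GRID_POINTS = 400
DEFAULT_GAP_FACTOR = 1.08
DEFAULT_THRESHOLD = 0.5


class ConvergenceError(RuntimeError):
    """Root refinement failed at the requested precision."""


def temperature_to_x(t: float) -> float:
    return math.exp(1.0 / t)


def x_to_temperature(x: float) -> float:
    return 1.0 / math.log(x)


@dataclass(frozen=True)
class ZeroSet:
    """All M zeros of a partition polynomial at working precision.

    ``roots`` are mpmath complex numbers closed under conjugation;
    ``residuals`` are |Z(x_k)| scaled by the leading coefficient and the
    root magnitude; ``bands`` (after :func:`band_zeros`) label each root
    0 = inner/collapse ring outward.
    """

    roots: tuple
    residuals: tuple
    poly: PartitionPolynomial
    precision: int
    bands: tuple | None = None

    def __len__(self) -> int:
        return len(self.roots)

    @property
    def moduli(self) -> np.ndarray:
        return np.array([float(abs(r)) for r in self.roots])

    @property
    def n_bands(self) -> int:
        return 1 if self.bands is None else max(self.bands) + 1

    def as_complex(self) -> np.ndarray:
        return np.array([complex(r) for r in self.roots])


@dataclass(frozen=True)
class ComponentProfile:
    """Peak of one heat-capacity component.

    A conjugate pair contributes twice the single-zero term; ``paired``
    records whether the profile (and its peak height) is the doubled pair
    component or a lone negative-real-root component.
    """

    root: complex
    paired: bool
    peak_t: float | None
    peak_height: float | None
    peakless: bool = False
    band: int | None = None


@dataclass(frozen=True)
class TransitionReport:
    """Collapse/folding temperatures and crossover classification."""

    t_theta: float | None
    t_f: float | None
    sigma: float | None
    collapse_zero: complex | None
    folding_zero: complex | None
    intermediates: tuple[ComponentProfile, ...]
    crossover_score: float | None = None
    group: int | None = None
    gap_factor: float = DEFAULT_GAP_FACTOR
    threshold: float = DEFAULT_THRESHOLD
    precision: int | None = None

    def as_dict(self) -> dict:
        return {
            "t_theta": self.t_theta,
            "t_f": self.t_f,
            "sigma": self.sigma,
            "crossover_score": self.crossover_score,
            "group": self.group,
            "gap_factor": self.gap_factor,
            "threshold": self.threshold,
            "precision": self.precision,
        }


# ---------------------------------------------------------------------------
# Root finding
# ---------------------------------------------------------------------------


def _horner(coeffs_desc, x):
    acc = x * 0
    for c in coeffs_desc:
        acc = acc * x + c
    return acc


def _polish_root(coeffs, dcoeffs, x0, maxiter=80):
    """Newton iteration on the exact integer polynomial."""
    x = mp.mpc(x0)
    tol = mp.mpf(10) ** (-mp.mp.dps + 8)
    for _ in range(maxiter):
        p = _horner(coeffs, x)
        dp = _horner(dcoeffs, x)
        if dp == 0:
            break
        step = p / dp
        x -= step
        if abs(step) <= tol * max(1, abs(x)):
            return x, True
    return x, False


def _rel_residual(coeffs, leading, degree, x):
    scale = abs(leading) * max(1.0, abs(x)) ** degree
    return float(abs(_horner(coeffs, x)) / scale)


def find_zeros(poly: PartitionPolynomial, precision: int = 60) -> ZeroSet:
    """All roots of Z, polished to ``precision`` decimal digits.

    Double-precision companion-matrix eigenvalues seed Newton iterations
    on the exact integer polynomial; conjugate symmetry is then enforced
    by pairing each upper-half-plane root with its mirror partner and
    averaging.  Falls back to mpmath's simultaneous solver if any polished
    root fails its residual bound.
    """
    if poly.degree < 1:
        raise ValueError("polynomial must have degree >= 1 to have zeros")
    coeffs = [mp.mpf(c) for c in reversed(poly.coefficients)]  # descending
    dcoeffs = [c * (len(coeffs) - 1 - i) for i, c in enumerate(coeffs[:-1])]
    degree = poly.degree
    res_bound = 10.0 ** (-precision / 2)

    with mp.workdps(precision + 15):
        initial = np.roots(np.array(poly.coefficients[::-1], dtype=float))
        roots = []
        ok_all = True
        for x0 in initial:
            x, ok = _polish_root(coeffs, dcoeffs, x0)
            ok_all = ok_all and ok
            roots.append(x)
        if not ok_all or any(
            _rel_residual(coeffs, poly.leading, degree, r) > res_bound for r in roots
        ):
            try:
                roots = mp.polyroots(coeffs, maxsteps=200, extraprec=precision * 4)
            except mp.libmp.NoConvergence as exc:
                raise ConvergenceError(
                    f"root finding did not converge at {precision} digits; "
                    "retry with higher precision"
                ) from exc

        # enforce conjugate closure: snap near-real roots, mirror the rest
        im_tol = mp.mpf(10) ** (-precision // 2)
        real = [r.real for r in roots if abs(r.imag) <= im_tol * max(1, abs(r))]
        upper = [r for r in roots if r.imag > im_tol * max(1, abs(r))]
        lower = [r for r in roots if r.imag < -im_tol * max(1, abs(r))]
        if len(upper) != len(lower) or len(real) + 2 * len(upper) != degree:
            raise ConvergenceError(
                "conjugate pairing failed; retry with higher precision"
            )
        paired = []
        pool = list(lower)
        for r in upper:
            j = min(range(len(pool)), key=lambda i: abs(mp.conj(pool[i]) - r))
            paired.append((r + mp.conj(pool.pop(j))) / 2)
        final = [mp.mpc(r, 0) for r in sorted(real)]
        for r in sorted(paired, key=lambda z: (z.real, z.imag)):
            final.append(r)
            final.append(mp.conj(r))

        residuals = tuple(
            _rel_residual(coeffs, poly.leading, degree, r) for r in final
        )
    if max(residuals) > res_bound:
        raise ConvergenceError(
            f"residuals up to {max(residuals):.2e} exceed {res_bound:.2e}; "
            "retry with higher precision"
        )
    for r in final:
        if r.imag == 0 and r.real > 1:
            raise ConvergenceError(
                "found a root on the physical axis x > 1; Z has positive "
                "coefficients there, so this indicates a numerical failure"
            )
    return ZeroSet(tuple(final), residuals, poly, precision)


# ---------------------------------------------------------------------------
# Heat capacity
# ---------------------------------------------------------------------------


def heat_capacity_direct(poly: PartitionPolynomial, x: float) -> float:
    """CV from the polynomial and its exact derivatives (no roots needed).

    CV(x) = (ln x)^2 [ x Z'/Z + x^2 Z''/Z - (x Z'/Z)^2 ], the variance of
    the contact-number distribution times (ln x)^2; nonnegative for all
    x > 1.
    """
    if x <= 1:
        raise ValueError(f"require x > 1 (physical T > 0), got {x}")
    with mp.workdps(50):
        xm = mp.mpf(x)
        c = [mp.mpf(v) for v in reversed(poly.coefficients)]
        d1 = [v * (len(c) - 1 - i) for i, v in enumerate(c[:-1])]
        d2 = [v * (len(d1) - 1 - i) for i, v in enumerate(d1[:-1])]
        z = _horner(c, xm)
        g = xm * _horner(d1, xm) / z if d1 else mp.mpf(0)
        h = xm**2 * _horner(d2, xm) / z if d2 else mp.mpf(0)
        cv = mp.log(xm) ** 2 * (g + h - g * g)
        return float(cv)


def component(zero: complex, x: float, paired: bool = True) -> float:
    """Heat-capacity component of one zero (doubled for a conjugate pair).

    CV_k(x) = -x (ln x)^2 Re[ x_k / (x - x_k)^2 ]; a conjugate pair
    contributes twice this (``paired=True``).  May be negative away from
    its peak.
    """
    if x <= 1:
        raise ValueError(f"require x > 1, got {x}")
    zk = complex(zero)
    denom = (x - zk) ** 2
    if denom == 0:
        raise ZeroDivisionError("x coincides with a real root")
    val = -x * math.log(x) ** 2 * (zk / denom).real
    return 2 * val if paired else val


def _component_of_t(zero: complex, t: float, paired: bool) -> float:
    return component(zero, math.exp(1.0 / t), paired)


def _profile_one(zero: complex, paired: bool, t_range, n_grid) -> ComponentProfile:
    lo, hi = t_range
    grid = np.geomspace(lo, hi, n_grid)
    vals = np.array([_component_of_t(zero, t, paired) for t in grid])
    i = int(np.argmax(vals))
    if i == 0 or i == n_grid - 1:
        return ComponentProfile(zero, paired, None, None, peakless=True)
    res = minimize_scalar(
        lambda t: -_component_of_t(zero, t, paired),
        bounds=(grid[i - 1], grid[i + 1]),
        method="bounded",
        options={"xatol": 1e-9 * grid[i]},
    )
    return ComponentProfile(zero, paired, float(res.x), float(-res.fun))


def decompose(
    zs: ZeroSet,
    t_range: tuple[float, float] = PEAK_T_RANGE,
    n_grid: int = PEAK_GRID_POINTS,
) -> list[ComponentProfile]:
    """Peak temperature and height of every component.

    One profile per conjugate pair (the doubled component) and one per
    lone negative-real root.  Peaks are bracketed on a geometric grid in T
    and refined by bounded scalar maximization to ~1e-9 relative.
    """
    bands = zs.bands if zs.bands is not None else [0] * len(zs)
    profiles = []
    for r, b in zip(zs.roots, bands):
        if r.imag < 0:
            continue  # the conjugate partner carries the pair
        paired = r.imag > 0
        prof = _profile_one(complex(r), paired, t_range, n_grid)
        profiles.append(replace(prof, band=b))
    return profiles


# ---------------------------------------------------------------------------
# Bands, transitions, classification
# ---------------------------------------------------------------------------


def band_zeros(zs: ZeroSet, gap_factor: float = DEFAULT_GAP_FACTOR) -> ZeroSet:
    """Partition roots into 1-3 modulus rings.

    The outermost (folding) ring is split off at the largest
    multiplicative gap of the sorted modulus sequence — every
    unique-ground-state sequence has a folding transition, but its ring
    can be diffuse, so no fixed gap threshold is applied to this split.
    A middle (intermediate/crossover) ring is split off additionally if
    the second-largest gap exceeds ``gap_factor``.  The inner ring is the
    collapse transition.  All-equal moduli yield a single band.
    """
    if len(zs) < 2:
        return ZeroSet(zs.roots, zs.residuals, zs.poly, zs.precision, (0,) * len(zs))
    mods = zs.moduli
    order = np.argsort(mods)
    sorted_mods = mods[order]
    ratios = sorted_mods[1:] / sorted_mods[:-1]
    cuts = []
    i_max = int(np.argmax(ratios))
    if ratios[i_max] > 1 + 1e-9:
        cuts.append(i_max)
        rest = ratios.copy()
        rest[i_max] = 0
        i_second = int(np.argmax(rest))
        if rest[i_second] > gap_factor:
            cuts.append(i_second)
    cuts = sorted(cuts)
    labels = np.zeros(len(zs), dtype=int)
    for b, cut in enumerate(cuts):
        labels[order[cut + 1 :]] = b + 1
    return ZeroSet(zs.roots, zs.residuals, zs.poly, zs.precision, tuple(int(b) for b in labels))


def _first_zero_index(zs: ZeroSet, band: int) -> int:
    """Root with minimal |arg| within a band (ties -> upper half-plane)."""
    best = None
    for i, (r, b) in enumerate(zip(zs.roots, zs.bands)):
        if b != band:
            continue
        a = abs(float(mp.arg(r)))
        key = (a, 0 if r.imag >= 0 else 1)
        if best is None or key < best[0]:
            best = (key, i)
    assert best is not None
    return best[1]


def _match_profile(profiles: Sequence[ComponentProfile], root) -> ComponentProfile:
    rc = complex(root)
    target = rc if rc.imag >= 0 else rc.conjugate()
    return min(profiles, key=lambda p: abs(p.root - target))


def transition_temperatures(
    zs: ZeroSet,
    profiles: Sequence[ComponentProfile],
    gap_factor: float = DEFAULT_GAP_FACTOR,
) -> TransitionReport:
    """Collapse and folding temperatures from the first-zero components.

    The collapse (folding) first zero is the root closest in argument to
    the positive real axis within the innermost (outermost) ring; T_theta
    and T_f are the peak temperatures of their components.  A single-ring
    spectrum has no folding transition and T_f is reported absent.
    """
    if zs.bands is None:
        zs = band_zeros(zs, gap_factor)
    n_bands = zs.n_bands
    ci = _first_zero_index(zs, 0)
    collapse_root = complex(zs.roots[ci])
    cprof = _match_profile(profiles, collapse_root)
    t_theta = cprof.peak_t
    if n_bands == 1:
        return TransitionReport(
            t_theta, None, None, collapse_root, None, (), gap_factor=gap_factor,
            precision=zs.precision,
        )
    fi = _first_zero_index(zs, n_bands - 1)
    folding_root = complex(zs.roots[fi])
    fprof = _match_profile(profiles, folding_root)
    t_f = fprof.peak_t
    sigma = None
    if t_theta is not None and t_f is not None:
        sigma = (t_theta - t_f) / t_theta
    inter = tuple(
        p
        for p in profiles
        if p is not cprof
        and p is not fprof
        and not p.peakless
        and t_f is not None
        and t_theta is not None
        and t_f < p.peak_t < t_theta
    )
    return TransitionReport(
        t_theta,
        t_f,
        sigma,
        collapse_root,
        folding_root,
        inter,
        gap_factor=gap_factor,
        precision=zs.precision,
    )


def classify_foldability(
    report: TransitionReport,
    threshold: float = DEFAULT_THRESHOLD,
) -> TransitionReport:
    """Score crossovers between T_f and T_theta and label the sequence.

    The crossover score S is the largest intermediate component peak
    height relative to the folding component's peak height (S = 0 with no
    intermediate peaks).  Group 1 (fast folder): S < threshold; group 2
    (slow folder, metastable globules compete with the native state):
    S >= threshold.  S is continuous and is the primary output; the label
    is qualitative.
    """
    if report.t_theta is None or report.t_f is None:
        raise ValueError("classification requires both T_theta and T_f")
    f_height = _folding_peak_height(report)
    if report.intermediates:
        s = max(p.peak_height / f_height for p in report.intermediates)
    else:
        s = 0.0
    group = 2 if s >= threshold else 1
    return replace(report, crossover_score=s, group=group, threshold=threshold)


def _folding_peak_height(report: TransitionReport) -> float:
    zk = report.folding_zero
    prof = _profile_one(
        zk if zk.imag >= 0 else zk.conjugate(),
        paired=zk.imag != 0,
        t_range=PEAK_T_RANGE,
        n_grid=PEAK_GRID_POINTS,
    )
    return prof.peak_height
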