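"""Readers and writers for the package's plain-text artifact formats.

All formats are line-oriented text: densities of states as two-column
TSV with a provenance header, the sequence screen as three-column TSV,
zeros as CSV, transition reports as JSON, and first-passage-time curves
as CSV.  Real numbers are serialized with 12 significant digits so that
a write/read round trip is value-exact at that precision and repeated
runs with the same seed produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import HPSequence, InteractionParams
from .enumeration import DensityOfStates
from .kmc import FPTCurve
from .zeros import ComponentProfile, TransitionReport, ZeroSet

__all__ = [
    "write_dos",
    "read_dos",
    "write_screen",
    "read_screen",
    "write_zeros",
    "write_report",
    "read_report",
    "write_fpt_curve",
    "read_fpt_curve",
    "read_sequences",
]


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_dos(dos: DensityOfStates, path: str | Path) -> None:
    p = ",".join(str(e) for e in dos.params.as_tuple())
    lines = [f"# seq={dos.seq} params={p} N={len(dos.seq)}"]
    for e, c in dos.items():
        lines.append(f"{e}\t{c}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dos(path: str | Path) -> DensityOfStates:
    lines = Path(path).read_text().splitlines()
    header = lines[0]
    if not header.startswith("# seq="):
        raise ValueError(f"{path}: missing density-of-states header")
    fields = dict(tok.split("=", 1) for tok in header[2:].split())
    e = [int(v) for v in fields["params"].split(",")]
    counts = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        energy, count = line.split("\t")
        counts[int(energy)] = int(count)
    return DensityOfStates(
        counts, HPSequence(fields["seq"]), InteractionParams(*e)
    )


def write_screen(
    rows: Sequence[tuple[str, int, int]], path: str | Path, n: int,
    params: InteractionParams,
) -> None:
    p = ",".join(str(e) for e in params.as_tuple())
    lines = [f"# screen N={n} params={p} candidates={len(rows)}",
             "sequence\tE0\tnE0"]
    for seq, e0, n0 in rows:
        lines.append(f"{seq}\t{e0}\t{n0}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_screen(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or line.startswith("sequence") or not line.strip():
            continue
        seq, e0, n0 = line.split("\t")
        out.append((seq, int(e0), int(n0)))
    return out


def write_zeros(
    zs: ZeroSet, profiles: Sequence[ComponentProfile], path: str | Path
) -> None:
    """Zeros CSV: one row per root, with its band and component peak.

    The peak columns repeat the conjugate pair's (doubled) component for
    both members of a pair; lone real roots carry their single-term
    component.
    """
    by_root = {}
    for prof in profiles:
        by_root[complex(prof.root)] = prof
    lines = ["re,im,modulus,arg,residual,band,peak_T,peak_height,paired"]
    bands = zs.bands if zs.bands is not None else [0] * len(zs)
    for r, res, b in zip(zs.roots, zs.residuals, bands):
        rc = complex(r)
        key = rc if rc.imag >= 0 else rc.conjugate()
        prof = by_root.get(key)
        peak_t = _fmt(prof.peak_t) if prof and prof.peak_t is not None else ""
        peak_h = _fmt(prof.peak_height) if prof and prof.peak_height is not None else ""
        paired = str(int(prof.paired)) if prof else ""
        lines.append(
            ",".join(
                [
                    _fmt(rc.real),
                    _fmt(rc.imag),
                    _fmt(abs(rc)),
                    _fmt(math.atan2(rc.imag, rc.real)),
                    f"{res:.3e}",
                    str(b),
                    peak_t,
                    peak_h,
                    paired,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(report: TransitionReport, path: str | Path, **extra) -> None:
    doc = report.as_dict()
    # temperatures echoed at 6 decimals alongside full precision
    for key in ("t_theta", "t_f"):
        v = doc.get(key)
        doc[f"{key}_6dp"] = None if v is None else f"{v:.6f}"
    doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_fpt_curve(curve: FPTCurve, path: str | Path) -> None:
    lines = ["T,mean_fpt,sem,n_runs,n_censored"]
    for i, t in enumerate(curve.temperatures):
        m = curve.mean_fpt[i]
        s = curve.sem[i]
        lines.append(
            ",".join(
                [
                    _fmt(float(t)),
                    "" if np.isnan(m) else _fmt(float(m)),
                    "" if np.isnan(s) else _fmt(float(s)),
                    str(curve.n_runs),
                    str(int(curve.n_censored[i])),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_fpt_curve(path: str | Path) -> FPTCurve:
    lines = Path(path).read_text().splitlines()[1:]
    temps, means, sems, cens = [], [], [], []
    n_runs = 0
    for line in lines:
        t, m, s, nr, nc = line.split(",")
        temps.append(float(t))
        means.append(float(m) if m else np.nan)
        sems.append(float(s) if s else np.nan)
        n_runs = int(nr)
        cens.append(int(nc))
    return FPTCurve(
        np.array(temps), np.array(means), np.array(sems), n_runs, np.array(cens)
    )


def read_sequences(path: str | Path) -> list[HPSequence]:
    """Sequences from plain text (one per line) or FASTA."""
    out = []
    body: list[str] = []
    in_fasta = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if body:
                out.append(HPSequence("".join(body)))
                body = []
            in_fasta = True
        elif in_fasta:
            body.append(line)
        else:
            out.append(HPSequence(line))
    if body:
        out.append(HPSequence("".join(body)))
    return out
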