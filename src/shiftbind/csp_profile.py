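"""Combined chemical-shift-perturbation (CSP) profiles across a titration.

Under fast exchange each amide shows a single peak at the population
weighted average of its free and bound positions, so the peak moves
continuously as ligand is added.  The per-residue perturbation relative
to the apo (zero-ligand) reference is summarised by the combined amide
statistic

    Δδ = sqrt(ΔδH² + (ΔδN / s)²),   s = 6.5 by default,

where the ¹⁵N divisor compensates the larger nitrogen shift dispersion.
Residues whose combined CSP exceeds the ensemble mean + 2σ are flagged
as significantly perturbed, and a cation titration can be compared
against a salt (NaCl) control at matched concentration to separate
specific binding from generic electrostatic screening.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .peaklist_io import Condition, ShiftTable

__all__ = [
    "ResidueRecord",
    "CSPProfile",
    "SignificanceResult",
    "SaltComparison",
    "combined_csp",
    "build_profile",
    "significance",
    "salt_comparison",
    "profile_from_arrays",
]

DEFAULT_SCALE_N = 6.5


def combined_csp(delta_H: float, delta_N: float, scale_N: float = DEFAULT_SCALE_N):
    """Combined amide CSP, sqrt(ΔδH² + (ΔδN/scale_N)²), in ppm.

    Symmetric in the sign of both inputs and monotone in their
    magnitudes.  Accepts scalars or arrays.
    """
    if scale_N <= 0:
        raise ValueError(f"scale_N must be > 0, got {scale_N}")
    return np.hypot(np.asarray(delta_H), np.asarray(delta_N) / scale_N)[()]


@dataclass
class ResidueRecord:
    """Per-residue CSP trajectory across all titration points."""

    delta_H: np.ndarray
    delta_N: np.ndarray
    delta_combined: np.ndarray
    tracked: np.ndarray  # bool per point


@dataclass
class CSPProfile:
    """Per-residue combined CSPs relative to the apo reference.

    ``points`` holds every titration condition (the reference included)
    in ascending ligand-concentration order; ``records`` maps residue
    number to its CSP trajectory, with per-point tracked flags for
    residues that could not be followed at some conditions.
    """

    reference: Condition
    points: list[Condition]
    records: dict[int, ResidueRecord]
    reference_index: int
    scale_N: float = DEFAULT_SCALE_N

    @property
    def residues(self) -> list[int]:
        return sorted(self.records)

    @property
    def ligand_concs(self) -> np.ndarray:
        return np.array([c.ligand_conc for c in self.points])

    def tracked_residues(self, point_index: int) -> list[int]:
        return [r for r in self.residues if self.records[r].tracked[point_index]]

    def point_index_near(self, ligand_conc: float, rel_tol: float = 0.10) -> int:
        """Index of the point whose concentration is nearest ``ligand_conc``
        within ``rel_tol`` relative tolerance."""
        concs = self.ligand_concs
        idx = int(np.argmin(np.abs(concs - ligand_conc)))
        if ligand_conc > 0 and abs(concs[idx] - ligand_conc) > rel_tol * ligand_conc:
            raise ValueError(
                f"no titration point within {rel_tol:.0%} of {ligand_conc} mM "
                f"(available: {concs.tolist()})"
            )
        return idx


@dataclass(frozen=True)
class SignificanceResult:
    """Mean + 2σ significance call at one titration point."""

    mean: float
    sd: float
    threshold: float
    flagged: frozenset[int]
    point_index: int
    n_tracked: int


@dataclass(frozen=True)
class SaltComparison:
    """Cation titration vs salt control at a matched concentration.

    ``mean_delta_H``/``sd_delta_H`` are the control's amide-proton shift
    statistics (the conventional salt-effect summary); the test profile's
    are reported alongside.  ``specific`` are residues significant in the
    test titration but not in the control.
    """

    point_conc: float
    delta_H_test: dict[int, float]
    delta_H_control: dict[int, float]
    delta_combined_test: dict[int, float]
    delta_combined_control: dict[int, float]
    mean_delta_H: float
    sd_delta_H: float
    mean_delta_H_test: float
    sd_delta_H_test: float
    flagged_test: frozenset[int]
    flagged_control: frozenset[int]
    specific: frozenset[int]


def build_profile(
    tables: Sequence[ShiftTable],
    reference_index: int | None = None,
    scale_N: float = DEFAULT_SCALE_N,
) -> CSPProfile:
    """Build a CSP profile from one ShiftTable per titration point.

    The reference is the zero-ligand table (or ``reference_index`` if
    given, counted in the input order).  Tables are re-ordered by
    ascending ligand concentration.  Residues absent from the reference
    are excluded with a warning; residues missing at a non-reference
    point are marked untracked at that point only.
    """
    if scale_N <= 0:
        raise ValueError(f"scale_N must be > 0, got {scale_N}")
    if len(tables) < 2:
        raise ValueError("need at least two titration points (reference + one)")
    if reference_index is None:
        zero = [i for i, t in enumerate(tables) if t.condition.ligand_conc == 0]
        if not zero:
            raise ValueError("no zero-ligand reference table found")
        reference_index = zero[0]
    if not 0 <= reference_index < len(tables):
        raise ValueError(f"reference_index {reference_index} out of range")
    reference = tables[reference_index]

    order = sorted(range(len(tables)), key=lambda i: tables[i].condition.ligand_conc)
    ordered = [tables[i] for i in order]
    ref_pos = order.index(reference_index)

    extra = set()
    for t in ordered:
        extra |= set(t.residues) - set(reference.residues)
    if extra:
        warnings.warn(
            f"residues {sorted(extra)} appear at titration points but not in "
            f"the reference; excluded",
            stacklevel=2,
        )

    n = len(ordered)
    records: dict[int, ResidueRecord] = {}
    for resnum in reference.residues:
        ref_peak = reference[resnum]
        dH = np.full(n, np.nan)
        dN = np.full(n, np.nan)
        tracked = np.zeros(n, dtype=bool)
        for i, table in enumerate(ordered):
            if resnum in table:
                p = table[resnum]
                dH[i] = p.shift_H - ref_peak.shift_H
                dN[i] = p.shift_N - ref_peak.shift_N
                tracked[i] = True
        dc = np.where(tracked, combined_csp(np.nan_to_num(dH), np.nan_to_num(dN), scale_N), np.nan)
        records[resnum] = ResidueRecord(dH, dN, dc, tracked)

    return CSPProfile(
        reference=reference.condition,
        points=[t.condition for t in ordered],
        records=records,
        reference_index=ref_pos,
        scale_N=scale_N,
    )


def profile_from_arrays(
    conditions: Sequence[Condition],
    delta_H: Mapping[int, Sequence[float]],
    delta_N: Mapping[int, Sequence[float]],
    reference_index: int = 0,
    scale_N: float = DEFAULT_SCALE_N,
) -> CSPProfile:
    """Assemble a CSPProfile directly from per-residue delta arrays
    (NaN marks untracked points).  Used when re-loading a CSP table."""
    records = {}
    for resnum, dh in delta_H.items():
        dh = np.asarray(dh, dtype=float)
        dn = np.asarray(delta_N[resnum], dtype=float)
        tracked = ~(np.isnan(dh) | np.isnan(dn))
        dc = np.where(tracked, combined_csp(np.nan_to_num(dh), np.nan_to_num(dn), scale_N), np.nan)
        records[resnum] = ResidueRecord(dh, dn, dc, tracked)
    return CSPProfile(
        reference=conditions[reference_index],
        points=list(conditions),
        records=records,
        reference_index=reference_index,
        scale_N=scale_N,
    )


def significance(profile: CSPProfile, point_index: int) -> SignificanceResult:
    """Flag residues whose combined CSP exceeds mean + 2·sd at one point.

    Statistics run over tracked residues only; sd is the sample (n−1)
    standard deviation; the comparison is strict, so a zero-variance
    profile flags nothing.
    """
    tracked = profile.tracked_residues(point_index)
    if len(tracked) < 2:
        raise ValueError(
            f"need >= 2 tracked residues at point {point_index}, got {len(tracked)}"
        )
    values = np.array([profile.records[r].delta_combined[point_index] for r in tracked])
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    threshold = mean + 2.0 * sd
    flagged = frozenset(r for r, v in zip(tracked, values) if v > threshold)
    return SignificanceResult(
        mean=mean,
        sd=sd,
        threshold=threshold,
        flagged=flagged,
        point_index=point_index,
        n_tracked=len(tracked),
    )


def salt_comparison(
    test: CSPProfile, control: CSPProfile, point_conc: float
) -> SaltComparison:
    """Compare a cation titration against a salt control at ``point_conc``.

    Residues significant (mean + 2σ) in the test but not in the control
    are reported as cation-specific.
    """
    it = test.point_index_near(point_conc)
    ic = control.point_index_near(point_conc)
    rt = set(test.tracked_residues(it))
    rc = set(control.tracked_residues(ic))
    if not rt & rc:
        raise ValueError("test and control profiles share no tracked residues")

    def stats(profile: CSPProfile, idx: int, residues) -> tuple[float, float]:
        vals = np.array([profile.records[r].delta_H[idx] for r in sorted(residues)])
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    mean_c, sd_c = stats(control, ic, rc)
    mean_t, sd_t = stats(test, it, rt)
    sig_t = significance(test, it)
    sig_c = significance(control, ic)
    return SaltComparison(
        point_conc=point_conc,
        delta_H_test={r: float(test.records[r].delta_H[it]) for r in sorted(rt)},
        delta_H_control={r: float(control.records[r].delta_H[ic]) for r in sorted(rc)},
        delta_combined_test={
            r: float(test.records[r].delta_combined[it]) for r in sorted(rt)
        },
        delta_combined_control={
            r: float(control.records[r].delta_combined[ic]) for r in sorted(rc)
        },
        mean_delta_H=mean_c,
        sd_delta_H=sd_c,
        mean_delta_H_test=mean_t,
        sd_delta_H_test=sd_t,
        flagged_test=sig_t.flagged,
        flagged_control=sig_c.flagged,
        specific=frozenset(sig_t.flagged - sig_c.flagged),
    )
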