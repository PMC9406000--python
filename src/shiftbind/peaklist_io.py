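"""Reading and writing assigned amide peak lists and shift tables.

The pipeline starts from *assigned* peak positions: each backbone amide
(one per residue, prolines excepted) contributes a single cross-peak in a
2D ¹⁵N–¹H correlation spectrum whose position is given as a (¹⁵N, ¹H)
chemical-shift pair in ppm.  Two on-disk dialects are supported:

* Sparky peak lists (``.list``) — whitespace tables with an assignment
  column (``D99N-H``) followed by the two axis positions.  Condition
  metadata (ligand concentration, protein concentration, pH, ...) is not
  part of the format and is supplied by the caller.
* a plain shift CSV holding a whole titration, one row per
  (residue, ligand concentration).

All shifts are in ppm, all concentrations in mM.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AmidePeak",
    "Condition",
    "ShiftTable",
    "read_sparky_list",
    "write_sparky_list",
    "read_shift_csv",
    "write_shift_csv",
    "write_csp_table",
    "read_csp_table",
]

#: Plausible backbone-amide shift windows (ppm); values outside are kept
#: but flagged, since they usually indicate an axis swap or a typo.
H_RANGE = (4.0, 13.0)
N_RANGE = (95.0, 140.0)

AMINO_CODES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AmidePeak:
    """One assigned backbone NH cross-peak."""

    residue_number: int
    residue_code: str
    shift_N: float
    shift_H: float

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(
                f"residue_number must be >= 1, got {self.residue_number}"
            )
        code = self.residue_code.upper()
        if code not in AMINO_CODES:
            raise ValueError(f"unknown one-letter residue code {self.residue_code!r}")
        object.__setattr__(self, "residue_code", code)
        if not (H_RANGE[0] <= self.shift_H <= H_RANGE[1]) or not (
            N_RANGE[0] <= self.shift_N <= N_RANGE[1]
        ):
            warnings.warn(
                f"peak {code}{self.residue_number} at "
                f"(N={self.shift_N}, H={self.shift_H}) ppm lies outside the "
                f"usual amide window; kept as-is",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Condition:
    """Sample condition of one titration point.

    Concentrations in mM; ``protein_conc_monomer`` is the *monomeric*
    protein concentration (a tetramer counts four binding-competent
    monomers).
    """

    ligand_conc: float
    protein_conc_monomer: float = 0.1
    ph: float = 7.4
    nacl_background: float = 0.0
    temperature: float = 25.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("ligand_conc", "protein_conc_monomer", "nacl_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


class ShiftTable:
    """Assigned peaks of one titration point plus its condition.

    At most one peak per residue; prolines (which carry no backbone NH)
    are rejected outright.
    """

    def __init__(self, peaks: Iterable[AmidePeak], condition: Condition):
        self.condition = condition
        self.peaks: dict[int, AmidePeak] = {}
        for peak in peaks:
            if peak.residue_code == "P":
                raise ValueError(
                    f"proline P{peak.residue_number} has no backbone amide"
                )
            if peak.residue_number in self.peaks:
                raise ValueError(f"duplicate residue {peak.residue_number}")
            self.peaks[peak.residue_number] = peak

    def __len__(self) -> int:
        return len(self.peaks)

    def __contains__(self, residue_number: int) -> bool:
        return residue_number in self.peaks

    def __getitem__(self, residue_number: int) -> AmidePeak:
        return self.peaks[residue_number]

    @property
    def residues(self) -> list[int]:
        return sorted(self.peaks)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ShiftTable({len(self)} peaks, "
            f"ligand={self.condition.ligand_conc} mM)"
        )


# Assignment dialects: "D99N-H", "D99N-HN", "D99NH", bare "D99".
_ASSIGNMENT_RE = re.compile(
    r"^(?P<code>[A-Za-z])(?P<num>\d+)(?:N-?H(?:N)?)?$"
)


def _parse_assignment(token: str) -> tuple[str, int]:
    m = _ASSIGNMENT_RE.match(token)
    if m is None:
        raise ValueError(f"unparsable assignment {token!r}")
    return m.group("code").upper(), int(m.group("num"))


def read_sparky_list(
    path: str | Path,
    condition: Condition | None = None,
    *,
    axis_order: str = "nh",
) -> ShiftTable:
    """Read a Sparky-style peak list.

    Lines are ``Assignment  w1  w2``; with the default ``axis_order="nh"``
    w1 is ¹⁵N and w2 is ¹H (the usual convention for ¹⁵N–¹H correlation
    maps); ``axis_order="hn"`` swaps them.  A header line starting with
    "Assignment" and blank lines are skipped.  ``condition`` supplies the
    metadata the file format cannot carry; defaults to a zero-ligand
    placeholder.
    """
    if axis_order not in ("nh", "hn"):
        raise ValueError(f"axis_order must be 'nh' or 'hn', got {axis_order!r}")
    path = Path(path)
    condition = condition if condition is not None else Condition(ligand_conc=0.0)
    peaks: list[AmidePeak] = []
    seen: set[int] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 fields, got {len(fields)}"
                )
            try:
                code, resnum = _parse_assignment(fields[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            try:
                w1, w2 = float(fields[1]), float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric shift in {fields[1:3]!r}"
                ) from None
            if resnum in seen:
                raise ValueError(f"{path}:{lineno}: duplicate residue {resnum}")
            seen.add(resnum)
            shift_N, shift_H = (w1, w2) if axis_order == "nh" else (w2, w1)
            peaks.append(
                AmidePeak(
                    residue_number=resnum,
                    residue_code=code,
                    shift_N=shift_N,
                    shift_H=shift_H,
                )
            )
    return ShiftTable(peaks, condition)


def write_sparky_list(table: ShiftTable, path: str | Path) -> None:
    """Write a ShiftTable as a Sparky-style list (w1 = ¹⁵N, w2 = ¹H)."""
    path = Path(path)
    lines = ["      Assignment         w1         w2"]
    for resnum in table.residues:
        p = table[resnum]
        lines.append(
            f"{p.residue_code}{p.residue_number}N-H"
            f" {p.shift_N:10.4f} {p.shift_H:10.4f}"
        )
    path.write_text("\n".join(lines) + "\n")


_REQUIRED_CSV_COLS = ["residue_number", "residue_code", "shift_N", "shift_H", "ligand_conc"]
_OPTIONAL_CONDITION_COLS = [
    "protein_conc_monomer",
    "ph",
    "nacl_background",
    "temperature",
    "label",
]


def read_shift_csv(path: str | Path) -> list[ShiftTable]:
    """Read a whole-titration shift CSV into one ShiftTable per ligand
    concentration, ordered by ascending concentration."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_CSV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dup = df.duplicated(subset=["residue_number", "ligand_conc"])
    if dup.any():
        bad = df.loc[dup, ["residue_number", "ligand_conc"]].values.tolist()
        raise ValueError(f"{path}: duplicated (residue, ligand_conc) rows: {bad}")
    tables: list[ShiftTable] = []
    for conc, group in df.groupby("ligand_conc", sort=True):
        extra = {}
        for col in _OPTIONAL_CONDITION_COLS:
            if col in group.columns:
                extra[col] = group[col].iloc[0]
        condition = Condition(ligand_conc=float(conc), **extra)
        peaks = [
            AmidePeak(
                residue_number=int(row.residue_number),
                residue_code=str(row.residue_code),
                shift_N=float(row.shift_N),
                shift_H=float(row.shift_H),
            )
            for row in group.itertuples()
        ]
        tables.append(ShiftTable(peaks, condition))
    return tables


def write_shift_csv(tables: Sequence[ShiftTable], path: str | Path) -> None:
    """Write titration ShiftTables to the shift-CSV dialect."""
    rows = []
    for table in tables:
        c = table.condition
        for resnum in table.residues:
            p = table[resnum]
            rows.append(
                {
                    "residue_number": p.residue_number,
                    "residue_code": p.residue_code,
                    "shift_N": p.shift_N,
                    "shift_H": p.shift_H,
                    "ligand_conc": c.ligand_conc,
                    "protein_conc_monomer": c.protein_conc_monomer,
                    "ph": c.ph,
                    "nacl_background": c.nacl_background,
                    "temperature": c.temperature,
                    "label": c.label,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def write_csp_table(profile, path: str | Path) -> None:
    """Write a CSPProfile as a TSV (residue, ligand_conc, delta_H, delta_N,
    delta_combined, tracked); untracked points keep empty shift fields."""
    if not profile.residues:
        raise ValueError("refusing to write an empty CSP profile")
    rows = []
    for resnum in profile.residues:
        rec = profile.records[resnum]
        for i, cond in enumerate(profile.points):
            tracked = bool(rec.tracked[i])
            rows.append(
                {
                    "residue": resnum,
                    "ligand_conc": cond.ligand_conc,
                    "delta_H": f"{rec.delta_H[i]:.6f}" if tracked else "",
                    "delta_N": f"{rec.delta_N[i]:.6f}" if tracked else "",
                    "delta_combined": f"{rec.delta_combined[i]:.6f}" if tracked else "",
                    "tracked": tracked,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_csp_table(path: str | Path) -> pd.DataFrame:
    """Read the TSV written by :func:`write_csp_table`."""
    return pd.read_csv(path, sep="\t")
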