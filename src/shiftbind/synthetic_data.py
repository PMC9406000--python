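"""Ground-truth-known synthetic inputs for every pipeline stage.

Two generators:

* :func:`simulate_titration` — fast-exchange amide peak lists across a
  ligand titration.  Each residue's peak sits at its apo position plus
  Δδ_max times the exact 1:1 bound fraction for its site's Kd (zero for
  inert residues), with independent Gaussian peak-position noise on each
  axis.  The default design mirrors a weak-binding protein titration:
  0.1 mM monomeric protein, ligand points 0–100 mM, mM-range Kds, and
  peak-position noise at the digital resolution of a 2D correlation
  spectrum (σ_H = 0.002 ppm, σ_N = 0.01 ppm).
* :func:`simulate_trajectory` — toy ion trajectories with prescribed
  per-residue contact fractions, for exact verification of the
  persistence analysis.  Residues are single atoms on a 10 Å grid; a
  single ion visits residue r inside 0.9·cutoff in exactly k_r frames
  and is parked far from everything otherwise.  No physics — a
  geometric construction with known ground truth.

All randomness flows from the single integer seed of the spec, so runs
are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .binding_model import bound_fraction
from .csp_profile import combined_csp
from .peaklist_io import AmidePeak, Condition, ShiftTable, write_sparky_list
from .trajectory_contacts import ResidueAtoms, TrajectoryFrames

__all__ = [
    "SimSite",
    "TitrationSimSpec",
    "TrajectorySimSpec",
    "simulate_titration",
    "simulate_trajectory",
    "two_site_spec",
    "screened_site_spec",
    "salt_control_spec",
    "write_titration",
    "load_titration_spec",
    "load_trajectory_spec",
]

#: Titration design mirroring a typical weak-binding experiment:
#: ligand points in mM and monomeric protein concentration in mM.
DEFAULT_LIGAND_POINTS = (0.0, 5.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0)
DEFAULT_T0 = 0.1

#: Peak-position reproducibility of a well-digitised 2D spectrum (ppm).
DEFAULT_NOISE_H = 0.002
DEFAULT_NOISE_N = 0.01

_CODES = "ACDEFGHIKLMNQRSTVWY"  # no proline: no backbone amide


@dataclass(frozen=True)
class SimSite:
    """Ground truth for one binding site: shared Kd, per-residue
    saturation amplitudes (ppm) on each axis."""

    site_id: str
    kd: float
    residues: dict[int, tuple[float, float]]  # residue -> (dmax_H, dmax_N)


@dataclass
class TitrationSimSpec:
    """Parameters of a synthetic fast-exchange titration."""

    sites: list[SimSite]
    inert_residues: int = 20
    protein_conc_monomer: float = DEFAULT_T0
    ligand_points: tuple[float, ...] = DEFAULT_LIGAND_POINTS
    noise_sd_H: float = DEFAULT_NOISE_H
    noise_sd_N: float = DEFAULT_NOISE_N
    base_shifts: dict[int, tuple[float, float]] | None = None  # res -> (H, N)
    dropout_rate: float = 0.0
    ph: float = 7.4
    nacl_background: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not self.ligand_points or self.ligand_points[0] != 0:
            problems.append("ligand_points must start at 0 (apo reference)")
        if any(l < 0 for l in self.ligand_points):
            problems.append("ligand_points must be >= 0")
        if self.protein_conc_monomer <= 0:
            problems.append("protein_conc_monomer must be > 0")
        for site in self.sites:
            if site.kd <= 0:
                problems.append(f"site {site.site_id}: kd must be > 0")
            if not site.residues:
                problems.append(f"site {site.site_id}: no residues")
        if self.noise_sd_H < 0 or self.noise_sd_N < 0:
            problems.append("noise sds must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            problems.append("dropout_rate must be in [0, 1)")
        if self.inert_residues < 0:
            problems.append("inert_residues must be >= 0")
        seen: set[int] = set()
        for site in self.sites:
            overlap = seen & set(site.residues)
            if overlap:
                problems.append(f"residues {sorted(overlap)} assigned to two sites")
            seen |= set(site.residues)
        if problems:
            raise ValueError("invalid TitrationSimSpec: " + "; ".join(problems))


@dataclass
class TrajectorySimSpec:
    """Parameters of a synthetic contact-patterned trajectory."""

    n_frames: int
    target_fractions: dict[int, Fraction]  # residue -> k/n_frames
    residues: int | None = None  # total residue count; default = targets only
    cutoff: float = 3.5
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_frames < 1:
            problems.append("n_frames must be >= 1")
        if self.cutoff <= 0:
            problems.append("cutoff must be > 0")
        for r, frac in self.target_fractions.items():
            frac = Fraction(frac)
            if not 0 <= frac <= 1:
                problems.append(f"residue {r}: fraction {frac} outside [0, 1]")
            elif (frac * self.n_frames).denominator != 1:
                problems.append(
                    f"residue {r}: fraction {frac} has no denominator "
                    f"{self.n_frames}"
                )
        if problems:
            raise ValueError("invalid TrajectorySimSpec: " + "; ".join(problems))


def _assign_base_shifts(spec: TitrationSimSpec, rng: np.random.Generator):
    """Residue numbering, one-letter codes and apo peak positions."""
    site_res = sorted({r for s in spec.sites for r in s.residues})
    next_num = 1
    inert = []
    taken = set(site_res)
    while len(inert) < spec.inert_residues:
        if next_num not in taken:
            inert.append(next_num)
        next_num += 1
    residues = sorted(site_res + inert)
    if spec.base_shifts is not None:
        missing = set(residues) - set(spec.base_shifts)
        if missing:
            raise ValueError(f"base_shifts missing residues {sorted(missing)}")
        base = {r: spec.base_shifts[r] for r in residues}
    else:
        base = {
            r: (float(rng.uniform(7.0, 9.5)), float(rng.uniform(105.0, 130.0)))
            for r in residues
        }
    codes = {r: _CODES[int(rng.integers(len(_CODES)))] for r in residues}
    return residues, base, codes


def simulate_titration(
    spec: TitrationSimSpec,
) -> tuple[list[ShiftTable], dict]:
    """Generate one ShiftTable per ligand point plus a ground-truth record.

    shift_H = base_H + dmax_H·b(L) + ε_H (and likewise for ¹⁵N), where
    b(L) is the exact 1:1 bound fraction at the residue's site Kd and ε
    is zero-mean Gaussian noise.  The apo reference point is never
    dropped; each other (residue, point) is dropped with probability
    ``dropout_rate``.  Identical seeds give identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    residues, base, codes = _assign_base_shifts(spec, rng)
    kd_of = {r: s.kd for s in spec.sites for r in s.residues}
    dmax_of = {r: amps for s in spec.sites for r, amps in s.residues.items()}

    tables: list[ShiftTable] = []
    for L in spec.ligand_points:
        peaks = []
        for r in residues:
            if r in kd_of:
                b = bound_fraction(spec.protein_conc_monomer, L, kd_of[r])
                dH, dN = dmax_of[r][0] * b, dmax_of[r][1] * b
            else:
                dH = dN = 0.0
            eps_H = rng.normal(0.0, spec.noise_sd_H) if spec.noise_sd_H else 0.0
            eps_N = rng.normal(0.0, spec.noise_sd_N) if spec.noise_sd_N else 0.0
            dropped = (
                L > 0
                and spec.dropout_rate > 0
                and rng.random() < spec.dropout_rate
            )
            if dropped:
                continue
            peaks.append(
                AmidePeak(
                    residue_number=r,
                    residue_code=codes[r],
                    shift_H=base[r][0] + dH + eps_H,
                    shift_N=base[r][1] + dN + eps_N,
                )
            )
        tables.append(
            ShiftTable(
                peaks,
                Condition(
                    ligand_conc=L,
                    protein_conc_monomer=spec.protein_conc_monomer,
                    ph=spec.ph,
                    nacl_background=spec.nacl_background,
                    label=f"sim L={L:g} mM",
                ),
            )
        )

    truth = {
        "seed": spec.seed,
        "protein_conc_monomer": spec.protein_conc_monomer,
        "ligand_points": list(spec.ligand_points),
        "noise_sd_H": spec.noise_sd_H,
        "noise_sd_N": spec.noise_sd_N,
        "dropout_rate": spec.dropout_rate,
        "sites": {
            s.site_id: {
                "kd": s.kd,
                "residues": {
                    str(r): {
                        "dmax_H": amps[0],
                        "dmax_N": amps[1],
                        "dmax_combined": float(combined_csp(amps[0], amps[1])),
                    }
                    for r, amps in s.residues.items()
                },
            }
            for s in spec.sites
        },
        "inert_residues": [r for r in residues if r not in kd_of],
        "base_shifts": {str(r): list(base[r]) for r in residues},
    }
    return tables, truth


def two_site_spec(seed: int = 0, **overrides) -> TitrationSimSpec:
    """Default low-salt scenario: two sites with mM Kds of 8.7 and
    13.5 mM and combined amplitudes in the 0.05–0.3 ppm range."""
    sites = [
        SimSite("site-1", 8.7, {66: (0.05, 0.50), 99: (0.12, 1.20)}),
        SimSite("site-2", 13.5, {10: (0.08, 0.80), 104: (0.04, 0.45), 126: (0.05, 0.35)}),
    ]
    return TitrationSimSpec(sites=sites, seed=seed, ph=6.5, **overrides)


def screened_site_spec(seed: int = 0, **overrides) -> TitrationSimSpec:
    """Physiological-salt scenario: one electrostatically screened site
    with Kd = 32.7 mM and attenuated amplitudes."""
    sites = [SimSite("site-1", 32.7, {66: (0.03, 0.30), 99: (0.08, 0.80)})]
    return TitrationSimSpec(
        sites=sites, seed=seed, nacl_background=154.0, **overrides
    )


def salt_control_spec(seed: int = 0, **overrides) -> TitrationSimSpec:
    """NaCl control: no specific site, small uniform solvent-effect
    scatter realised as inert residues under measurement noise."""
    overrides.setdefault("inert_residues", 25)
    overrides.setdefault("noise_sd_H", 0.02)
    overrides.setdefault("noise_sd_N", 0.08)
    return TitrationSimSpec(sites=[], seed=seed, **overrides)


def simulate_trajectory(spec: TrajectorySimSpec) -> TrajectoryFrames:
    """Construct a toy trajectory realising exact contact fractions.

    Residues sit as single atoms on a 10 Å-spaced line; in each of the
    k_r frames prescribed for residue r the ion is placed 0.9·cutoff
    away from r (perpendicular to the line, so every other residue is
    ≥ 10 Å away); in all remaining frames it is parked > 3·cutoff from
    every residue.  Frames for different residues never overlap; if the
    prescriptions need more frames than exist, the geometry cannot
    satisfy them (two residues 10 Å apart cannot both be within a
    3.5 Å-class cutoff of one ion) and a hard error is raised.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    targets = {r: Fraction(f) for r, f in spec.target_fractions.items()}
    resnums = sorted(targets)
    if spec.residues is not None:
        extra = []
        next_num = 1
        while len(resnums) + len(extra) < spec.residues:
            if next_num not in targets:
                extra.append(next_num)
            next_num += 1
        resnums = sorted(resnums + extra)
        targets.update({r: Fraction(0) for r in extra})

    n = spec.n_frames
    spacing = 10.0
    counts = {r: int(targets[r] * n) for r in resnums}
    overflow = sum(counts.values()) - n
    events: list[tuple[int, ...]] = []
    if overflow > 0:
        # Frames must be shared: only possible if one ion can reach two
        # grid-adjacent residues at once (midpoint distance spacing/2).
        if spec.cutoff < spacing / 2:
            raise ValueError(
                f"target fractions need {sum(counts.values())} contact frames "
                f"but only {n} frames exist; one ion cannot contact two "
                f"residues {spacing:g} Å apart within cutoff {spec.cutoff} Å"
            )
        while overflow > 0:
            pair = next(
                (
                    (resnums[i], resnums[i + 1])
                    for i in range(len(resnums) - 1)
                    if counts[resnums[i]] > 0 and counts[resnums[i + 1]] > 0
                ),
                None,
            )
            if pair is None:
                raise ValueError(
                    "conflicting contact targets cannot be realised even "
                    "with shared frames"
                )
            events.append(pair)
            counts[pair[0]] -= 1
            counts[pair[1]] -= 1
            overflow -= 1
    for r in resnums:
        events.extend([(r,)] * counts[r])
    events.extend([()] * (n - len(events)))

    frame_order = rng.permutation(n)
    x_of = {r: spacing * i for i, r in enumerate(resnums)}
    far = np.array([-5.0 * spacing, 10.0 * spacing, 0.0])  # > 3·cutoff from all

    ion_coords = np.zeros((n, 1, 3))
    for f, event in zip(frame_order, events):
        if len(event) == 1:
            # perpendicular offset keeps every other residue >= spacing away
            ion_coords[f, 0] = (x_of[event[0]], 0.9 * spec.cutoff, 0.0)
        elif len(event) == 2:
            ion_coords[f, 0] = ((x_of[event[0]] + x_of[event[1]]) / 2.0, 0.0, 0.0)
        else:
            ion_coords[f, 0] = far

    residue_atoms = {
        r: ResidueAtoms(
            atom_names=["CA"],
            coords=np.tile(np.array([[x_of[r], 0.0, 0.0]]), (n, 1, 1)),
            res_name="GLY",
        )
        for r in resnums
    }
    return TrajectoryFrames(
        residue_atoms=residue_atoms,
        ion_labels=["CA1"],
        ion_coords=ion_coords,
    )


def write_titration(
    tables: Sequence[ShiftTable], truth: Mapping, out_dir: str | Path
) -> dict[str, Path]:
    """Write a simulated titration as Sparky .list files (one per point),
    a conditions CSV and a ground-truth JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rows = []
    for i, table in enumerate(tables):
        c = table.condition
        name = f"point_{i:02d}_{c.ligand_conc:g}mM.list"
        write_sparky_list(table, out_dir / name)
        paths[name] = out_dir / name
        rows.append(
            {
                "file": name,
                "ligand_conc": c.ligand_conc,
                "protein_conc_monomer": c.protein_conc_monomer,
                "ph": c.ph,
                "nacl_background": c.nacl_background,
                "temperature": c.temperature,
            }
        )
    import pandas as pd

    cond_path = out_dir / "conditions.csv"
    pd.DataFrame(rows).to_csv(cond_path, index=False)
    paths["conditions.csv"] = cond_path
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["ground_truth.json"] = truth_path
    return paths


def load_titration_spec(path: str | Path) -> TitrationSimSpec:
    """Load a TitrationSimSpec from YAML (fields as in the dataclass;
    sites as a list of {site_id, kd, residues: {num: [dmax_H, dmax_N]}})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sites = [
        SimSite(
            site_id=str(s["site_id"]),
            kd=float(s["kd"]),
            residues={
                int(r): (float(a[0]), float(a[1]))
                for r, a in s["residues"].items()
            },
        )
        for s in raw.pop("sites", [])
    ]
    if "ligand_points" in raw:
        raw["ligand_points"] = tuple(float(x) for x in raw["ligand_points"])
    if raw.get("base_shifts"):
        raw["base_shifts"] = {
            int(r): (float(v[0]), float(v[1]))
            for r, v in raw["base_shifts"].items()
        }
    return TitrationSimSpec(sites=sites, **raw)


def load_trajectory_spec(path: str | Path) -> TrajectorySimSpec:
    """Load a TrajectorySimSpec from YAML; target_fractions given as
    "k/n" strings or floats with denominator n_frames."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    n = int(raw["n_frames"])
    targets = {}
    for r, f in raw.get("target_fractions", {}).items():
        frac = Fraction(f).limit_denominator(n) if isinstance(f, float) else Fraction(f)
        targets[int(r)] = frac
    return TrajectorySimSpec(
        n_frames=n,
        target_fractions=targets,
        residues=raw.get("residues"),
        cutoff=float(raw.get("cutoff", 3.5)),
        seed=int(raw.get("seed", 0)),
    )
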