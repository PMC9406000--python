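"""Ion–protein contact persistence over an MD trajectory.

A residue is "in contact" in a frame when the minimum distance between
any of its atoms (optionally restricted to side-chain or backbone atoms)
and any ion is at or below a cutoff — 3.5 Å is the conventional
first-shell criterion for Ca²⁺.  The persistence of a residue is the
fraction of frames in contact; residues in contact for strictly more
than a threshold fraction (default 50%) of the trajectory are called
persistent interactors.

Only analysis lives here: trajectories arrive as multi-model PDB files
(or are constructed synthetically) with coordinates assumed already
wrapped — no periodic-image handling is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "ResidueAtoms",
    "TrajectoryFrames",
    "PersistenceProfile",
    "min_ion_distance",
    "persistence",
    "read_multimodel_pdb",
    "write_trajectory_pdb",
    "BACKBONE_ATOMS",
]

#: Default residue names identifying calcium ions.  Selection is by
#: residue name, never by atom name, to avoid the PDB "CA" collision
#: between Cα carbons and Ca²⁺ ions.
DEFAULT_ION_RESNAMES = frozenset({"CA", "CAL"})

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)

HYDROGEN_PREFIXES = ("H", "1H", "2H", "3H")


@dataclass
class ResidueAtoms:
    """One residue's atoms across all frames."""

    atom_names: list[str]
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    res_name: str = "GLY"


@dataclass
class TrajectoryFrames:
    """Protein and ion coordinates for every frame of a trajectory."""

    residue_atoms: dict[int, ResidueAtoms]
    ion_labels: list[str]
    ion_coords: np.ndarray  # (n_frames, n_ions, 3), Å
    box_diagonal: float | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("trajectory must have at least one frame")
        for resnum, ra in self.residue_atoms.items():
            if ra.coords.shape[0] != self.n_frames:
                raise ValueError(
                    f"residue {resnum}: {ra.coords.shape[0]} frames, "
                    f"expected {self.n_frames}"
                )
            if not np.all(np.isfinite(ra.coords)):
                raise ValueError(f"residue {resnum}: non-finite coordinates")
        if not np.all(np.isfinite(self.ion_coords)):
            raise ValueError("non-finite ion coordinates")

    @property
    def n_frames(self) -> int:
        return int(self.ion_coords.shape[0])

    @property
    def residues(self) -> list[int]:
        return sorted(self.residue_atoms)


@dataclass(frozen=True)
class PersistenceProfile:
    """Per-residue contact fractions and the persistent-residue set."""

    cutoff: float
    threshold: float
    atom_scope: str
    n_frames: int
    contact_frames: dict[int, int]
    fractions: dict[int, Fraction]
    persistent: frozenset[int]

    def fraction(self, residue: int) -> float:
        return float(self.fractions[residue])


def min_ion_distance(residue_atoms: np.ndarray, ions: np.ndarray) -> float:
    """Minimum Euclidean distance (Å) over all atom–ion pairs."""
    residue_atoms = np.atleast_2d(np.asarray(residue_atoms, dtype=float))
    ions = np.atleast_2d(np.asarray(ions, dtype=float))
    if residue_atoms.size == 0 or ions.size == 0:
        raise ValueError("both coordinate sets must be non-empty")
    diff = residue_atoms[:, None, :] - ions[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).min())


def _scope_mask(atom_names: list[str], atom_scope: str, include_h: bool) -> np.ndarray:
    names = [n.strip().upper() for n in atom_names]
    if atom_scope == "all":
        mask = np.ones(len(names), dtype=bool)
    elif atom_scope == "backbone":
        mask = np.array([n in BACKBONE_ATOMS for n in names])
    elif atom_scope == "side-chain":
        mask = np.array([n not in BACKBONE_ATOMS for n in names])
    else:
        raise ValueError(
            f"atom_scope must be 'all', 'side-chain' or 'backbone', got {atom_scope!r}"
        )
    if not include_h:
        is_h = np.array([n.startswith(HYDROGEN_PREFIXES) for n in names])
        mask &= ~is_h
    return mask


def persistence(
    traj: TrajectoryFrames,
    cutoff: float = 3.5,
    threshold: float = 0.5,
    atom_scope: str = "all",
    include_hydrogens: bool = True,
) -> PersistenceProfile:
    """Per-residue fraction of frames with an ion within ``cutoff`` Å.

    Fractions are exact rationals over the frame count; the persistent
    set uses a strict ``>`` comparison against ``threshold`` so that a
    residue at exactly the threshold is not called persistent.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    n = traj.n_frames
    if n < 1:
        raise ValueError("trajectory has no frames")
    contact_frames: dict[int, int] = {}
    warned_box = False
    for resnum in traj.residues:
        ra = traj.residue_atoms[resnum]
        mask = _scope_mask(ra.atom_names, atom_scope, include_hydrogens)
        if not mask.any():
            contact_frames[resnum] = 0
            continue
        count = 0
        for f in range(n):
            d = min_ion_distance(ra.coords[f][mask], traj.ion_coords[f])
            if d <= cutoff:
                count += 1
            if (
                traj.box_diagonal is not None
                and d > traj.box_diagonal
                and not warned_box
            ):
                warnings.warn(
                    f"ion–protein distance {d:.1f} Å exceeds the box diagonal "
                    f"{traj.box_diagonal:.1f} Å; periodic images are NOT "
                    f"unwrapped by this analysis",
                    stacklevel=2,
                )
                warned_box = True
        contact_frames[resnum] = count
    fractions = {r: Fraction(k, n) for r, k in contact_frames.items()}
    persistent = frozenset(r for r, f in fractions.items() if f > Fraction(threshold))
    return PersistenceProfile(
        cutoff=cutoff,
        threshold=threshold,
        atom_scope=atom_scope,
        n_frames=n,
        contact_frames=contact_frames,
        fractions=fractions,
        persistent=persistent,
    )


def read_multimodel_pdb(
    path: str | Path,
    ion_names: frozenset[str] | set[str] = DEFAULT_ION_RESNAMES,
) -> TrajectoryFrames:
    """Read a multi-model PDB into TrajectoryFrames.

    Each MODEL becomes one frame; ions are selected by *residue* name
    (``ion_names``, default {CA, CAL}); waters are dropped; remaining
    atoms are grouped by residue number.  A file without MODEL records
    is treated as a single-frame trajectory with a warning.
    """
    path = Path(path)
    ion_names = {n.strip().upper() for n in ion_names}
    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no coordinates found")
    has_model_records = any(
        line.startswith("MODEL") for line in pdb_file.lines
    )
    if not has_model_records:
        warnings.warn(
            f"{path}: no MODEL records; treating as a single-frame trajectory",
            stacklevel=2,
        )
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        raise ValueError(
            f"{path}: inconsistent models (atom counts must match across "
            f"MODEL records): {exc}"
        ) from exc

    res_names = np.char.upper(np.char.strip(stack.res_name.astype(str)))
    is_ion = np.isin(res_names, sorted(ion_names))
    is_water = np.isin(res_names, sorted(WATER_RESNAMES))
    if not is_ion.any():
        raise ValueError(
            f"{path}: no ion with residue name in {sorted(ion_names)}"
        )
    ion_sel = stack[:, is_ion]
    prot_sel = stack[:, ~is_ion & ~is_water]

    residue_atoms: dict[int, ResidueAtoms] = {}
    for res_id in np.unique(prot_sel.res_id):
        m = prot_sel.res_id == res_id
        sub = prot_sel[:, m]
        residue_atoms[int(res_id)] = ResidueAtoms(
            atom_names=[str(n) for n in sub.atom_name],
            coords=np.asarray(sub.coord, dtype=float),
            res_name=str(sub.res_name[0]),
        )
    ion_labels = [f"{rn}{ri}" for rn, ri in zip(ion_sel.res_name, ion_sel.res_id)]
    diag = None
    box = stack.box
    if box is not None:
        vecs = np.asarray(box)[0] if np.asarray(box).ndim == 3 else np.asarray(box)
        diag = float(np.linalg.norm(vecs.sum(axis=0)))
    return TrajectoryFrames(
        residue_atoms=residue_atoms,
        ion_labels=ion_labels,
        ion_coords=np.asarray(ion_sel.coord, dtype=float),
        box_diagonal=diag,
    )


def write_trajectory_pdb(traj: TrajectoryFrames, path: str | Path) -> None:
    """Write TrajectoryFrames as a multi-model PDB (ions as residue CA)."""
    n_frames = traj.n_frames
    n_prot = sum(len(ra.atom_names) for ra in traj.residue_atoms.values())
    n_ions = traj.ion_coords.shape[1]
    n_atoms = n_prot + n_ions

    atoms = struc.AtomArray(n_atoms)
    coords = np.zeros((n_frames, n_atoms, 3))
    i = 0
    for resnum in traj.residues:
        ra = traj.residue_atoms[resnum]
        for j, name in enumerate(ra.atom_names):
            atoms.atom_name[i] = name
            atoms.res_name[i] = ra.res_name
            atoms.res_id[i] = resnum
            atoms.chain_id[i] = "A"
            atoms.element[i] = name.strip()[:1] or "C"
            coords[:, i, :] = ra.coords[:, j, :]
            i += 1
    max_res = max(traj.residues) if traj.residues else 0
    for k in range(n_ions):
        atoms.atom_name[i] = "CA"
        atoms.res_name[i] = "CA"
        atoms.res_id[i] = max_res + 1 + k
        atoms.chain_id[i] = "B"
        atoms.element[i] = "CA"
        atoms.hetero[i] = True
        coords[:, i, :] = traj.ion_coords[:, k, :]
        i += 1

    stack = struc.from_template(atoms, coords)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
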