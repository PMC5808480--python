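"""Structure data model, PDB reading/writing and rigid superposition.

The atomic model is deliberately minimal: an ordered list of atoms carrying
chain / residue / name / element / coordinates, which is all the elastic-network
and hydrogen-bond machinery downstream needs.  Reading goes through biotite
(robust fixed-column parsing, altloc resolution by occupancy, model selection);
writing is done in-package so that TER records separate chains and coordinates
are emitted at the canonical three decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Element symbols flagged as metal ions when read from HETATM/ATOM records.
METAL_ELEMENTS = frozenset({"CU", "ZN", "FE", "MN", "CO", "NI", "MG", "CA", "NA", "K"})

WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


class EmptyStructureError(ValueError):
    """Raised when a model contains no atoms."""


@dataclass(frozen=True)
class Atom:
    """One atom: identity plus Cartesian coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: tuple[float, float, float]
    insertion_code: str = ""
    hetero: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_metal(self) -> bool:
        return self.element in METAL_ELEMENTS

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def atom_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.name)


@dataclass
class Structure:
    """An ordered collection of atoms with a stable identifier."""

    identifier: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(
                f"structure {self.identifier!r} contains no atoms"
            )
        seen: set[tuple[str, int, str, str]] = set()
        for a in self.atoms:
            if a.atom_key in seen:
                raise ValueError(
                    f"duplicate atom {a.atom_key} in structure {self.identifier!r}"
                )
            seen.add(a.atom_key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    @property
    def coords(self) -> np.ndarray:
        """N x 3 coordinate array in atom order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, identifier: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates (same atom order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match atom count {len(self.atoms)}"
            )
        atoms = [
            replace(a, coords=(float(c[0]), float(c[1]), float(c[2])))
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(identifier or self.identifier, atoms)

    def select(self, predicate) -> list[Atom]:
        return [a for a in self.atoms if predicate(a)]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom_index(self) -> dict[tuple[str, int, str, str], int]:
        return {a.atom_key: i for i, a in enumerate(self.atoms)}


# Residue roles of the reference Cu/Zn dismutase dimer (positions per subunit,
# numbering 1..153; applicable to both chains).
RESIDUE_ANNOTATIONS: dict[str, frozenset[int]] = {
    "zinc_site": frozenset({63, 71, 80, 83}),
    "copper_site": frozenset({46, 48, 63, 120}),
    "disulfide": frozenset({57, 146}),
    "loop_disulfide": frozenset(range(49, 63)),
    "loop_zinc": frozenset(range(63, 86)),
    "loop_greek_key": frozenset(range(102, 116)),
    "loop_electrostatic": frozenset(range(121, 143)),
    "dimer_interface": frozenset({5, 7, 17, 50, 51, 52, 53, 54, 113, 114, 115, 148, 150, 151, 152, 153}),
    "aggregate_contact": frozenset(
        {11, 12, 13, 14, 15, 24, 26, 91, 92, 97, 98, 99, 101, 102, 103, 104, 109, 128, 129, 130, 131}
    ),
}

#: The 25 positions treated as structurally critical: metal-binding residues,
#: dimer-interface residues and the intrasubunit disulfide pair.
IMPORTANT_POSITIONS: frozenset[int] = (
    RESIDUE_ANNOTATIONS["zinc_site"]
    | RESIDUE_ANNOTATIONS["copper_site"]
    | RESIDUE_ANNOTATIONS["dimer_interface"]
    | RESIDUE_ANNOTATIONS["disulfide"]
)


def annotate_position(position: int) -> list[str]:
    """Roles a per-subunit position belongs to (empty list if none)."""
    return [role for role, pos in RESIDUE_ANNOTATIONS.items() if position in pos]


def read_pdb(path: str | Path, model_index: int = 1, identifier: str | None = None) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer;
    insertion codes are preserved as part of the residue key.  CU/ZN and other
    metal ions are flagged via their element symbol.

    Parameters
    ----------
    path:
        PDB file to read.
    model_index:
        1-based model number (MODEL records); single-model files use 1.
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        arr = pdb_file.get_structure(
            model=model_index, altloc="occupancy", extra_fields=["atom_id"]
        )
    except Exception as exc:  # biotite raises several error types
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise EmptyStructureError(f"model {model_index} of {path} contains no atoms")

    atoms: list[Atom] = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).upper()
        atoms.append(
            Atom(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]),
                element=element,
                residue_name=str(arr.res_name[i]),
                residue_number=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                coords=tuple(float(x) for x in arr.coord[i]),
                insertion_code=str(arr.ins_code[i]).strip(),
                hetero=bool(arr.hetero[i]),
            )
        )
    if not np.all(np.isfinite(arr.coord)):
        raise PDBParseError(f"{path}: non-finite coordinates")
    return Structure(identifier or path.stem, atoms)


def _pdb_atom_line(a: Atom) -> str:
    record = "HETATM" if a.hetero else "ATOM"
    name = a.name
    # Standard alignment: 1/2-letter elements start in column 14 unless the
    # atom name is four characters long.
    if len(name) < 4 and len(a.element) == 1:
        name = f" {name}"
    x, y, z = a.coords
    return (
        f"{record:<6s}{a.serial % 100000:>5d} {name:<4s} "
        f"{a.residue_name:>3s} {a.chain_id:1s}{a.residue_number:>4d}{a.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a fixed-column PDB file with TER records between chains.

    Coordinates are rounded to three decimals, so ``read_pdb(write_pdb(s))``
    reproduces atoms and coordinates at PDB precision.
    """
    path = Path(path)
    lines: list[str] = []
    prev_chain: str | None = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        lines.append(_pdb_atom_line(a))
        prev_chain = a.chain_id
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_multimodel_pdb(structures: Sequence[Structure], path: str | Path) -> None:
    """Write several conformers of the same topology as MODEL/ENDMDL blocks."""
    path = Path(path)
    lines: list[str] = []
    for k, s in enumerate(structures, start=1):
        lines.append(f"MODEL     {k:>4d}")
        prev_chain: str | None = None
        for a in s.atoms:
            if prev_chain is not None and a.chain_id != prev_chain:
                lines.append("TER")
            lines.append(_pdb_atom_line(a))
            prev_chain = a.chain_id
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising |R p + t - q|."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = qc - r @ pc
    return r, t


def superpose_rmsd(
    a: Structure,
    b: Structure,
    pairing: Iterable[tuple[int, int]] | None = None,
) -> float:
    """Least-squares superpose ``a`` onto ``b`` and return the RMSD (Angstrom).

    By default atoms are paired by their full key (chain, residue number,
    insertion code, atom name); atoms present in only one structure are
    dropped with a logged count.  An explicit index pairing may be given.
    """
    if pairing is None:
        idx_b = b.atom_index()
        pairs = [(i, idx_b[at.atom_key]) for i, at in enumerate(a.atoms) if at.atom_key in idx_b]
        dropped = len(a) + len(b) - 2 * len(pairs)
        if dropped:
            logger.info("superpose_rmsd: %d unpaired atoms dropped", dropped)
    else:
        pairs = list(pairing)
    if len(pairs) < 3:
        raise ValueError(f"degenerate pairing: only {len(pairs)} atom pairs (need >= 3)")
    ca = a.coords[[i for i, _ in pairs]]
    cb = b.coords[[j for _, j in pairs]]
    r, t = _kabsch(ca, cb)
    moved = ca @ r.T + t
    return float(np.sqrt(np.mean(np.sum((moved - cb) ** 2, axis=1))))


def inter_chain_rmsd(structure: Structure, chain_a: str, chain_b: str) -> float:
    """RMSD between two chains of one structure after superposition.

    Atoms are paired across the chains by (residue number, insertion code,
    atom name); unpaired atoms are dropped with a logged count.
    """
    sel_a = {
        (a.residue_number, a.insertion_code, a.name): i
        for i, a in enumerate(structure.atoms)
        if a.chain_id == chain_a
    }
    sel_b = {
        (a.residue_number, a.insertion_code, a.name): i
        for i, a in enumerate(structure.atoms)
        if a.chain_id == chain_b
    }
    common = [k for k in sel_a if k in sel_b]
    dropped = len(sel_a) + len(sel_b) - 2 * len(common)
    if dropped:
        logger.info("inter_chain_rmsd: %d unpaired atoms dropped", dropped)
    pairs = [(sel_a[k], sel_b[k]) for k in common]
    return superpose_rmsd(structure, structure, pairing=pairs)
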