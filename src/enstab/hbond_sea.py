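"""Geometric hydrogen-bond detection and ensemble-average stability (SEA).

A hydrogen bond is scored purely geometrically on explicit hydrogens: donor
heavy atom D (N or O carrying a hydrogen within covalent range), acceptor A
(any N or O), bond present iff ``|D - A| <= dist_cutoff`` and the D-H-A angle
is at least ``angle_cutoff`` degrees.  SEA of a bond in a structure is the
fraction of that structure's conformers in which the bond is present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .enm import ConformerEnsemble
from .structure_io import Structure, WATER_RESNAMES

logger = logging.getLogger(__name__)

DEFAULT_DIST_CUTOFF = 3.0  # donor..acceptor heavy-atom distance, Angstrom
DEFAULT_ANGLE_CUTOFF = 135.0  # donor-H-acceptor angle, degrees
COVALENT_H_CUTOFF = 1.2  # H bonded to heavy atom if within this range


@dataclass(frozen=True, order=True)
class HBondKey:
    """Orientation-specific hydrogen-bond identity (donor -> acceptor)."""

    donor_chain: str
    donor_residue: int
    donor_atom: str
    hydrogen: str
    acceptor_chain: str
    acceptor_residue: int
    acceptor_atom: str

    def to_string(self) -> str:
        return (
            f"{self.donor_chain}:{self.donor_residue}:{self.donor_atom}"
            f"-{self.hydrogen}->"
            f"{self.acceptor_chain}:{self.acceptor_residue}:{self.acceptor_atom}"
        )

    @classmethod
    def from_string(cls, s: str) -> "HBondKey":
        try:
            left, right = s.split("->")
            donor_part, hydrogen = left.rsplit("-", 1)
            dc, dr, da = donor_part.split(":")
            ac, ar, aa = right.split(":")
            return cls(dc, int(dr), da, hydrogen, ac, int(ar), aa)
        except ValueError as exc:
            raise ValueError(f"unparseable bond label {s!r}") from exc

    @property
    def residues(self) -> set[tuple[str, int]]:
        return {(self.donor_chain, self.donor_residue), (self.acceptor_chain, self.acceptor_residue)}


def detect_hbonds(
    structure: Structure,
    dist_cutoff: float = DEFAULT_DIST_CUTOFF,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
) -> set[HBondKey]:
    """Hydrogen bonds of one conformation under distance + angle criteria.

    Intra-residue pairs are excluded; water is ignored.  The structure must
    carry explicit hydrogens (covalently assigned to the nearest N/O within
    1.2 Angstrom).
    """
    atoms = structure.atoms
    coords = structure.coords
    h_idx = [i for i, a in enumerate(atoms) if a.is_hydrogen]
    if not h_idx:
        raise ValueError(
            "structure has no hydrogens; hydrogen-bond detection needs protonated input"
        )
    no_idx = [
        i
        for i, a in enumerate(atoms)
        if a.element in ("N", "O") and a.residue_name not in WATER_RESNAMES
    ]
    if not no_idx:
        return set()
    no_coords = coords[no_idx]
    no_tree = cKDTree(no_coords)

    # assign hydrogens to their covalent donor heavy atom
    donors: list[tuple[int, int]] = []  # (donor heavy index, hydrogen index)
    for h in h_idx:
        dists, nn = no_tree.query(coords[h], k=1, distance_upper_bound=COVALENT_H_CUTOFF)
        if np.isfinite(dists):
            donors.append((no_idx[int(nn)], h))

    bonds: set[HBondKey] = set()
    for d, h in donors:
        da = atoms[d]
        cands = no_tree.query_ball_point(coords[d], dist_cutoff)
        for c in cands:
            a_i = no_idx[c]
            aa = atoms[a_i]
            if aa.residue_key == da.residue_key:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a_i] - coords[h]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
            angle = np.degrees(np.arccos(cosang))
            if angle >= angle_cutoff:
                bonds.add(
                    HBondKey(
                        da.chain_id, da.residue_number, da.name,
                        atoms[h].name,
                        aa.chain_id, aa.residue_number, aa.name,
                    )
                )
    return bonds


@dataclass
class SEATable:
    """Bonds x structures matrix of ensemble-average bond stability in [0,1].

    ``values`` is a DataFrame indexed by bond label strings with one column
    per structure id; bonds absent from a structure's ensemble hold explicit
    zeros so that deviation sums run over the full bond union.
    """

    values: pd.DataFrame
    wt_id: str
    n_conformers: int

    def __post_init__(self) -> None:
        if self.wt_id not in self.values.columns:
            raise ValueError(f"wild-type id {self.wt_id!r} not among structure columns")
        v = self.values.to_numpy()
        if np.any((v < 0) | (v > 1)):
            raise ValueError("SEA values must lie in [0, 1]")

    @property
    def bonds(self) -> list[str]:
        return list(self.values.index)

    @property
    def structures(self) -> list[str]:
        return list(self.values.columns)

    @property
    def variants(self) -> list[str]:
        return [c for c in self.values.columns if c != self.wt_id]

    def bond_keys(self) -> list[HBondKey | None]:
        out: list[HBondKey | None] = []
        for label in self.values.index:
            try:
                out.append(HBondKey.from_string(label))
            except ValueError:
                out.append(None)
        return out

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.index.name = "bond"
        # %.17g round-trips IEEE doubles exactly: pipeline results computed
        # from a re-read TSV are bit-identical to the in-memory route
        df.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path, wt_id: str, n_conformers: int = 55) -> "SEATable":
        df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
        return cls(values=df, wt_id=wt_id, n_conformers=n_conformers)


def compute_sea_table(
    ensembles: Mapping[str, ConformerEnsemble],
    wt_id: str,
    dist_cutoff: float = DEFAULT_DIST_CUTOFF,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
) -> SEATable:
    """Assemble the SEA table over the union of bonds seen in any conformer.

    ``SEA_i^m = N_i^m / |ensemble of m|`` where ``N_i^m`` counts the
    conformers of structure m in which bond i is present.
    """
    if wt_id not in ensembles:
        raise ValueError(f"wild-type id {wt_id!r} missing from ensembles")
    sizes = {len(e) for e in ensembles.values()}
    if not sizes or 0 in sizes:
        raise ValueError("all ensembles must be non-empty")
    if len(sizes) > 1:
        logger.warning("unequal ensemble sizes %s; per-structure denominators used", sorted(sizes))

    counts: dict[str, dict[HBondKey, int]] = {}
    for sid, ens in ensembles.items():
        c: dict[HBondKey, int] = {}
        for conf in ens.conformers:
            for b in detect_hbonds(conf.structure, dist_cutoff, angle_cutoff):
                c[b] = c.get(b, 0) + 1
        counts[sid] = c

    universe = sorted({b for c in counts.values() for b in c})
    labels = [b.to_string() for b in universe]
    data = {
        sid: [counts[sid].get(b, 0) / len(ensembles[sid]) for b in universe]
        for sid in ensembles
    }
    df = pd.DataFrame(data, index=labels)
    n_conf = len(ensembles[wt_id])
    return SEATable(values=df, wt_id=wt_id, n_conformers=n_conf)


_ID_COLUMNS = ("donor", "hydrogen", "acceptor")


def read_stability_table(
    path: str | Path, wt_column: str, n_conformers: int = 55
) -> SEATable:
    """Read a bond-stability table (TSV or spreadsheet) into a SEATable.

    Accepts either the in-package TSV layout (single ``bond`` identifier
    column) or a layout with separate donor / hydrogen / acceptor columns, as
    stability tables exported from other tools commonly have.  Any remaining
    non-numeric leading columns are treated as part of the bond identifier.
    Values outside [0, 1] and duplicate bond rows are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")

    cols = list(df.columns)
    lower = [str(c).strip().lower() for c in cols]
    if all(c in lower for c in _ID_COLUMNS):
        idx = [
            "-".join([str(r[cols[lower.index("donor")]]), str(r[cols[lower.index("hydrogen")]])])
            + "->" + str(r[cols[lower.index("acceptor")]])
            for _, r in df.iterrows()
        ]
        value_df = df.drop(columns=[cols[lower.index(c)] for c in _ID_COLUMNS])
    else:
        # auto-detect: leading non-numeric columns form the identifier
        non_numeric = []
        for c in cols:
            if pd.api.types.is_numeric_dtype(df[c]):
                break
            non_numeric.append(c)
        if not non_numeric:
            raise ValueError(f"{path}: no bond-identifier column found")
        if len(non_numeric) > 1:
            logger.warning("%s: %d identifier columns joined into bond label", path, len(non_numeric))
        idx = df[non_numeric].astype(str).agg("|".join, axis=1).tolist()
        value_df = df.drop(columns=non_numeric)

    value_df = value_df.astype(float)
    value_df.index = pd.Index(idx, name="bond")
    dup = value_df.index[value_df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate bond rows: {sorted(set(dup))[:5]}")
    arr = value_df.to_numpy()
    bad = np.argwhere((arr < 0) | (arr > 1))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: value {arr[r, c]} outside [0,1] at row {value_df.index[r]!r}, "
            f"column {value_df.columns[c]!r}"
        )
    if wt_column not in value_df.columns:
        raise ValueError(f"{path}: wild-type column {wt_column!r} not present")
    return SEATable(values=value_df, wt_id=wt_column, n_conformers=n_conformers)
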