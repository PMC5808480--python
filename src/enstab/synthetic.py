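"""Synthetic inputs: toy structures, variants, planted SEA tables, survival.

The toy structures are backbone-only chains (N, H, CA, C, O per residue)
built from ideal internal coordinates, so that hydrogen-bond detection, the
elastic network and the stiffness map can all be exercised without any real
protein input.  An alpha-helical geometry guarantees the i -> i+4 backbone
hydrogen-bond ladder at the default geometric criteria; a small seeded
coordinate jitter breaks the exact helical symmetry (which would otherwise
produce degenerate normal modes) without disturbing the ladder.

Ground truth for planted signals is always returned alongside the data,
never embedded in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import Atom, Structure

# backbone internal coordinates (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N = 1.458, 1.525, 1.329
B_C_O, B_N_H = 1.231, 1.010
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
A_CA_C_O, A_C_N_H = 120.5, 119.0
# dihedrals chosen to give a canonical i -> i+4 amide ladder (N..O ~ 2.8 A,
# D-H-A ~ 166 deg) under the ideal bond geometry above
HELIX_PHI, HELIX_PSI, OMEGA = -59.0, -50.0, 180.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0

Geometry = Literal["helix", "sheet_hairpin"]


@dataclass(frozen=True)
class ToySpec:
    n_res_per_chain: int = 12
    n_chains: int = 2
    geometry: Geometry = "helix"
    metal_sites: Sequence[tuple[str, Sequence[int]]] = ()
    seed: int = 0
    jitter: float = 0.03  # Angstrom, symmetry-breaking noise

    def __post_init__(self) -> None:
        if self.n_res_per_chain < 4:
            raise ValueError("need >= 4 residues per chain")
        if self.n_chains < 1:
            raise ValueError("need >= 1 chain")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position of atom d given a-b-c and internal coords."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.cos(tor) * np.sin(ang), bond * np.sin(tor) * np.sin(ang)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(n_res: int, phi_psi) -> dict[str, np.ndarray]:
    """Backbone N/CA/C positions for given per-residue (phi, psi)."""
    coords: dict[tuple[int, str], np.ndarray] = {}
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([B_N_CA, 0.0, 0.0])
    ang = np.radians(A_N_CA_C)
    coords[(0, "C")] = coords[(0, "CA")] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        phi_prev, psi_prev = phi_psi(i - 1)
        phi_i, _ = phi_psi(i)
        coords[(i, "N")] = _place(
            coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")], B_C_N, A_CA_C_N, psi_prev
        )
        coords[(i, "CA")] = _place(
            coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")], B_N_CA, A_C_N_CA, OMEGA
        )
        coords[(i, "C")] = _place(
            coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")], B_CA_C, A_N_CA_C, phi_i
        )
    return coords


def _build_hairpin(n_res: int) -> tuple[dict, dict]:
    """Antiparallel two-strand ladder with an explicit cross-strand
    amide ladder (idealised, not a physical beta-sheet).

    Strand 1 runs along +x, strand 2 (reversed residue order, so the chain
    termini sit at the same end) lies 4.13 Angstrom away in y with its N-H
    groups pointing back across the gap; every aligned N/O pair forms a
    hydrogen bond at the default criteria.  CA atoms zigzag in z so the
    structure is not coplanar (a coplanar network would add spurious
    zero-energy out-of-plane modes).
    """
    n1 = (n_res + 1) // 2
    spacing, gap = 4.8, 4.13
    backbone: dict[tuple[int, str], np.ndarray] = {}
    extra: dict[tuple[int, str], np.ndarray] = {}
    for i in range(n_res):
        on_first = i < n1
        k = i if on_first else (n_res - 1 - i)  # rung index along x
        y = 0.0 if on_first else gap
        s = 1.0 if on_first else -1.0  # H/O point into the inter-strand gap
        x0 = spacing * k + (0.0 if on_first else 2.4)
        z = 0.9 if (k % 2 == 0) else -0.9
        backbone[(i, "N")] = np.array([x0, y, 0.0])
        backbone[(i, "CA")] = np.array([x0 + 1.2, y, z])
        backbone[(i, "C")] = np.array([x0 + 2.4, y, 0.0])
        extra[(i, "O")] = np.array([x0 + 2.4, y + 1.23 * s, 0.0])
        if i > 0:
            extra[(i, "H")] = backbone[(i, "N")] + np.array([0.0, 1.0 * s, 0.0])
    return backbone, extra


def make_toy_structure(spec: ToySpec) -> Structure:
    """Deterministic backbone-only toy structure.

    Each residue carries N, H, CA, C, O (the N-terminal residue has no H).
    Chains are laid side by side ~5 Angstrom apart so that a 2-chain toy has
    inter-chain elastic contacts at the default 8 Angstrom cutoff.  Optional
    metal atoms (CU) are placed at the centroid of their coordinating
    residues' CA positions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_res_per_chain
    if spec.geometry == "helix":
        phi_psi = lambda i: (HELIX_PHI, HELIX_PSI)  # noqa: E731
        backbone = _build_chain(n, phi_psi)
        extra: dict[tuple[int, str], np.ndarray] = {}
        for i in range(n):
            psi = phi_psi(i)[1]
            # O trans to the following N; amide H trans to the carbonyl O
            extra[(i, "O")] = _place(
                backbone[(i, "N")], backbone[(i, "CA")], backbone[(i, "C")], B_C_O, A_CA_C_O, psi + 180.0
            )
            if i > 0:
                extra[(i, "H")] = _place(
                    backbone[(i - 1, "CA")], backbone[(i - 1, "C")], backbone[(i, "N")], B_N_H, A_C_N_H, 0.0
                )
    elif spec.geometry == "sheet_hairpin":
        backbone, extra = _build_hairpin(n)
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    chain_ids = [chr(ord("A") + k) for k in range(spec.n_chains)]
    if spec.geometry == "helix":
        # offset direction roughly perpendicular to the helix axis
        ca = np.array([backbone[(i, "CA")] for i in range(n)])
        axis = ca[-1] - ca[0]
        axis /= np.linalg.norm(axis)
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(axis, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        spacing = 7.0
    else:
        perp = np.array([0.0, 0.0, 1.0])  # hairpin ladder lies near the xy plane
        spacing = 7.0

    atoms: list[Atom] = []
    serial = 1
    order = ("N", "H", "CA", "C", "O")
    for k, cid in enumerate(chain_ids):
        offset = k * spacing * perp
        for i in range(n):
            for name in order:
                pos = backbone.get((i, name), extra.get((i, name)))
                if pos is None:
                    continue
                pos = pos + offset + rng.normal(0.0, spec.jitter, 3)
                element = "H" if name == "H" else name[0]
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=element,
                        residue_name="ALA",
                        residue_number=i + 1,
                        chain_id=cid,
                        coords=tuple(float(x) for x in pos),
                    )
                )
                serial += 1

    for cid, positions in spec.metal_sites:
        if cid not in chain_ids:
            raise ValueError(f"metal site chain {cid!r} not in structure")
        cas = [a for a in atoms if a.chain_id == cid and a.name == "CA" and a.residue_number in set(positions)]
        if len(cas) != len(set(positions)):
            raise ValueError(f"metal site positions {positions} missing in chain {cid}")
        centroid = np.mean([c.coords for c in cas], axis=0)
        atoms.append(
            Atom(
                serial=serial,
                name="CU",
                element="CU",
                residue_name="CU",
                residue_number=1000 + len([a for a in atoms if a.is_metal]),
                chain_id=cid,
                coords=tuple(float(x) for x in centroid),
                hetero=True,
            )
        )
        serial += 1

    label = f"toy_{spec.geometry}_{n}x{spec.n_chains}_s{spec.seed}"
    return Structure(label, atoms)


def make_variant(
    structure: Structure,
    positions: Mapping[str, Sequence[int]] | Sequence[int],
    sigma: float,
    seed: int,
    identifier: str | None = None,
) -> Structure:
    """Locally perturbed copy: Gaussian noise (sd sigma, Angstrom) on every
    atom of the listed residues, all other atoms identical.

    ``positions`` is either a chain -> residue-number mapping or a plain
    residue-number list applying to all chains.
    """
    if not isinstance(positions, Mapping):
        positions = {c: list(positions) for c in structure.chains}
    targets = {(c, int(r)) for c, rs in positions.items() for r in rs}
    known = {(a.chain_id, a.residue_number) for a in structure.atoms}
    missing = targets - known
    if missing:
        raise ValueError(f"positions not in structure: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    coords = structure.coords.copy()
    if not targets:
        import logging

        logging.getLogger(__name__).warning("make_variant: empty position set, identity copy")
    for i, a in enumerate(structure.atoms):
        if (a.chain_id, a.residue_number) in targets:
            coords[i] += rng.normal(0.0, sigma, 3)
    return structure.with_coords(coords, identifier or f"{structure.identifier}_var")


@dataclass(frozen=True)
class PlantSpec:
    """Direct-generation spec for a SEA table with planted destructive bonds."""

    n_bonds: int = 200
    n_variants: int = 9
    n_planted_bonds: int = 5
    n_planted_variants: int | None = None  # default: all variants carry the shift
    delta: float = 0.4
    background_sigma: float = 0.02
    n_conformers: int = 55
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.delta <= 1:
            raise ValueError("delta must lie in (0, 1]")
        if self.n_planted_bonds > self.n_bonds:
            raise ValueError("more planted bonds than bonds")
        if self.delta <= 2 * self.background_sigma:
            import logging

            logging.getLogger(__name__).warning(
                "delta <= 2*background_sigma: planted shift may be undetectable"
            )


@dataclass
class PlantTruth:
    planted_bonds: list[str]
    planted_variants: list[str]


def simulate_sea_table(plant: PlantSpec):
    """SEA table on the 1/n_conformers grid with planted occupancy shifts.

    The wild-type column is uniform on the occupancy grid; background entries
    are the wild type plus grid-rounded Gaussian noise; planted (bond,
    variant) entries are additionally shifted by delta (direction chosen away
    from the nearer boundary) and clipped to [0, 1].  Returns
    ``(SEATable, PlantTruth)``.
    """
    from .hbond_sea import SEATable

    rng = np.random.default_rng(plant.seed)
    n_c = plant.n_conformers
    grid = 1.0 / n_c
    bonds = [f"bond{j:04d}" for j in range(plant.n_bonds)]
    variants = [f"M{v:02d}" for v in range(plant.n_variants)]
    wt = rng.integers(0, n_c + 1, size=plant.n_bonds) / n_c

    noise = rng.normal(0.0, plant.background_sigma, size=(plant.n_bonds, plant.n_variants))
    values = wt[:, None] + np.round(noise / grid) * grid
    values = np.clip(values, 0.0, 1.0)

    planted_bonds = sorted(rng.choice(plant.n_bonds, size=plant.n_planted_bonds, replace=False).tolist())
    n_pv = plant.n_planted_variants or plant.n_variants
    planted_variants = sorted(rng.choice(plant.n_variants, size=n_pv, replace=False).tolist())
    for j in planted_bonds:
        direction = 1.0 if wt[j] <= 0.5 else -1.0
        shift = np.round(direction * plant.delta / grid) * grid
        for v in planted_variants:
            values[j, v] = np.clip(wt[j] + shift, 0.0, 1.0)

    df = pd.DataFrame(values, index=bonds, columns=variants)
    df.insert(0, "WT", wt)
    table = SEATable(values=df, wt_id="WT", n_conformers=n_c)
    truth = PlantTruth(
        planted_bonds=[bonds[j] for j in planted_bonds],
        planted_variants=[variants[v] for v in planted_variants],
    )
    return table, truth


def simulate_survival(
    stiffness: Mapping[str, float],
    a: float = 5.0,
    b: float = -0.5,
    sigma: float = 1.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Survival times from a linear model on a stiffness covariate.

    ``s_m = a + b * kappa_m + Normal(0, sigma^2)``, truncated below at 0.1
    years.  Returns the table (columns mutation, years) and the true
    parameters.
    """
    if len(stiffness) < 3:
        raise ValueError("need >= 3 variants")
    rng = np.random.default_rng(seed)
    rows = []
    for name, k in stiffness.items():
        s = a + b * float(k) + rng.normal(0.0, sigma)
        rows.append({"mutation": name, "years": max(float(s), 0.1)})
    return pd.DataFrame(rows), {"a": a, "b": b, "sigma": sigma}
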