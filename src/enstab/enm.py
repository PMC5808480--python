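"""Elastic-network models, normal modes and DQ-sweep conformer ensembles.

The network is the standard anisotropic network model (ANM): nodes joined by
identical Hookean springs whenever their equilibrium separation is within a
distance cutoff.  The Hessian carries directional 3x3 blocks

    H_ij = -(gamma / R_ij^2) (R_ij x R_ij^T),   i != j within cutoff,

with diagonal blocks closing each row to zero (translational invariance).
Low-frequency eigenvectors of H approximate the collective motions of the
structure; sweeping a perturbation coordinate DQ along a mode produces a
conformer ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree
from scipy.sparse.csgraph import connected_components
from scipy.sparse import coo_matrix

from .structure_io import Atom, Structure

logger = logging.getLogger(__name__)

NodePolicy = Literal["all_atoms", "heavy_atoms", "calpha"]

#: Relative eigenvalue tolerance below which a mode counts as rigid-body.
RIGID_TOL = 1e-8


@dataclass(frozen=True)
class EnsembleConfig:
    """Parameters of the ensemble stage.

    ``dq`` is the dimensionless perturbation coordinate swept from ``dq_min``
    to ``dq_max`` in steps of ``dq_step``; ``|dq| = 100`` maps onto a maximum
    nodal displacement of ``amplitude_scale`` Angstrom (eigenvectors are
    rescaled to unit maximum nodal displacement before use, which is what
    makes the amplitude interpretable).
    """

    n_modes: int = 5
    dq_min: float = -100.0
    dq_max: float = 100.0
    dq_step: float = 20.0
    cutoff: float = 8.0
    gamma: float = 1.0
    node_policy: NodePolicy = "heavy_atoms"
    amplitude_scale: float = 2.0
    nrbl: object = None  # accepted for config-file compatibility; ignored

    def __post_init__(self) -> None:
        if self.dq_min > self.dq_max:
            raise ValueError("dq_min must be <= dq_max")
        if self.dq_step <= 0:
            raise ValueError("dq_step must be > 0")
        n = (self.dq_max - self.dq_min) / self.dq_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(dq_max - dq_min) must be an integer multiple of dq_step")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")

    @property
    def dq_values(self) -> np.ndarray:
        n = int(round((self.dq_max - self.dq_min) / self.dq_step))
        return self.dq_min + self.dq_step * np.arange(n + 1)


class DisconnectedNetworkError(ValueError):
    """The spring network is not a single connected component."""


def select_nodes(structure: Structure, policy: NodePolicy) -> list[int]:
    """Indices of the atoms serving as network nodes under a node policy.

    Metal ions are always nodes.  Under ``calpha`` the nodes are one CA per
    residue plus the metals; under ``heavy_atoms`` everything but hydrogen.
    """
    if policy == "all_atoms":
        return list(range(len(structure.atoms)))
    if policy == "heavy_atoms":
        return [i for i, a in enumerate(structure.atoms) if not a.is_hydrogen]
    if policy == "calpha":
        return [
            i
            for i, a in enumerate(structure.atoms)
            if (a.name == "CA" and not a.is_metal) or a.is_metal
        ]
    raise ValueError(f"unknown node policy {policy!r}")


@dataclass
class ElasticModel:
    """Spring network plus assembled ANM Hessian."""

    coords: np.ndarray  # N x 3
    springs: np.ndarray  # M x 2 int, i < j
    gamma: float
    hessian: np.ndarray  # 3N x 3N
    node_atoms: list[Atom] = field(default_factory=list)
    node_atom_indices: list[int] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]


def _assemble_hessian(coords: np.ndarray, springs: np.ndarray, gamma: float) -> np.ndarray:
    n = coords.shape[0]
    h = np.zeros((3 * n, 3 * n))
    for i, j in springs:
        rij = coords[j] - coords[i]
        r2 = float(rij @ rij)
        block = -(gamma / r2) * np.outer(rij, rij)
        h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += block
        h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += block
        h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return h


def build_elastic_model(structure: Structure, config: EnsembleConfig | None = None) -> ElasticModel:
    """Build the ANM spring network and Hessian for a structure.

    Springs connect every node pair within ``config.cutoff`` Angstrom.  The
    network must form a single connected component; otherwise the rigid-body
    null space exceeds dimension six and mode bookkeeping breaks down.
    """
    config = config or EnsembleConfig()
    node_idx = select_nodes(structure, config.node_policy)
    if len(node_idx) < 2:
        raise ValueError(f"need >= 2 network nodes, got {len(node_idx)}")
    coords = structure.coords[node_idx]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(config.cutoff, output_type="ndarray")
    if pairs.size and np.any(
        np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1) < 1e-9
    ):
        raise ValueError("coincident nodes: zero-length spring")
    if pairs.size == 0:
        raise DisconnectedNetworkError("no springs at this cutoff")
    n = coords.shape[0]
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise DisconnectedNetworkError(
            f"network has {n_comp} components (sizes {sizes.tolist()}) at cutoff {config.cutoff} A"
        )
    hessian = _assemble_hessian(coords, pairs, config.gamma)
    return ElasticModel(
        coords=coords,
        springs=pairs,
        gamma=config.gamma,
        hessian=hessian,
        node_atoms=[structure.atoms[i] for i in node_idx],
        node_atom_indices=list(node_idx),
    )


@dataclass
class ModeSet:
    """Eigen-decomposition of an ANM Hessian.

    ``eigenvalues``/``eigenvectors`` hold the non-trivial spectrum in
    ascending order (rigid-body modes removed); ``collectivities`` is the
    entropy-based collectivity of each non-trivial mode.
    """

    eigenvalues: np.ndarray  # (K,)
    eigenvectors: np.ndarray  # (3N, K), columns orthonormal
    collectivities: np.ndarray  # (K,)
    n_rigid: int
    node_atoms: list[Atom] = field(default_factory=list)
    node_atom_indices: list[int] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.eigenvectors.shape[0] // 3

    def highest_collectivity(self, k: int) -> list[int]:
        """Indices of the k non-trivial modes of highest collectivity.

        Ties in collectivity are broken toward lower frequency (lower index).
        The returned indices are sorted ascending (low frequency first).
        """
        order = np.lexsort((np.arange(len(self.collectivities)), -self.collectivities))
        return sorted(order[:k].tolist())


def collectivity(mode: np.ndarray) -> float:
    """Entropy-based collectivity of a mode, in (0, 1].

    With p_i the normalised squared displacement of node i,
    ``kappa = exp(-sum p_i ln p_i) / N``: 1 for a uniformly distributed mode,
    1/N for a single displaced node.
    """
    v = np.asarray(mode, dtype=float).reshape(-1, 3)
    mags = np.sum(v * v, axis=1)
    total = mags.sum()
    if total <= 0:
        raise ValueError("zero mode vector")
    p = mags / total
    nz = p[p > 0]
    entropy = -np.sum(nz * np.log(nz))
    return float(np.exp(entropy) / len(p))


def compute_modes(
    model: ElasticModel, n_nontrivial: int | None = None, strict: bool = True
) -> ModeSet:
    """Diagonalise the Hessian and strip rigid-body modes.

    A connected 3-D network has exactly six near-zero eigenvalues; with
    ``strict`` a different count raises (degenerate geometry, e.g. perfectly
    collinear chains, produces more).  ``n_nontrivial`` only validates that
    enough non-trivial modes exist.
    """
    evals, evecs = scipy.linalg.eigh(model.hessian)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise ValueError("Hessian has no positive eigenvalues")
    n_rigid = int(np.sum(evals < RIGID_TOL * lam_max))
    if strict and n_rigid != 6:
        raise DisconnectedNetworkError(
            f"expected 6 rigid-body modes, found {n_rigid}: disconnected or degenerate geometry"
        )
    nt_vals = evals[n_rigid:]
    nt_vecs = evecs[:, n_rigid:]
    if n_nontrivial is not None and nt_vals.size < n_nontrivial:
        raise ValueError(
            f"only {nt_vals.size} non-trivial modes available, {n_nontrivial} requested"
        )
    # warn on (near-)degenerate eigenvalues: mode ranking across structures is
    # then solver-order dependent
    if nt_vals.size > 1:
        rel_gap = np.diff(nt_vals) / np.maximum(nt_vals[1:], 1e-300)
        if np.any(rel_gap < 1e-10):
            logger.warning("near-degenerate non-trivial eigenvalues; mode order is solver-dependent")
    coll = np.array([collectivity(nt_vecs[:, k]) for k in range(nt_vals.size)])
    return ModeSet(
        eigenvalues=nt_vals,
        eigenvectors=nt_vecs,
        collectivities=coll,
        n_rigid=n_rigid,
        node_atoms=model.node_atoms,
        node_atom_indices=model.node_atom_indices,
    )


@dataclass
class Conformer:
    mode_index: int  # index into the non-trivial mode list
    dq: float
    structure: Structure


@dataclass
class ConformerEnsemble:
    parent_id: str
    conformers: list[Conformer]

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def structures(self) -> list[Structure]:
        return [c.structure for c in self.conformers]


def _residue_node_map(structure: Structure, node_atom_indices: Sequence[int]) -> np.ndarray:
    """For each atom, the index (into the node list) of the node it rides with.

    Atoms that are themselves nodes map to themselves; other atoms (hydrogens
    under ``heavy_atoms``, side-chain atoms under ``calpha``) ride rigidly with
    the nearest node of their own residue.
    """
    node_set = {ai: k for k, ai in enumerate(node_atom_indices)}
    coords = structure.coords
    by_residue: dict[tuple, list[int]] = {}
    for k, ai in enumerate(node_atom_indices):
        by_residue.setdefault(structure.atoms[ai].residue_key, []).append(k)
    all_nodes = np.array(list(node_atom_indices))
    mapping = np.empty(len(structure.atoms), dtype=int)
    for i, a in enumerate(structure.atoms):
        if i in node_set:
            mapping[i] = node_set[i]
            continue
        candidates = by_residue.get(a.residue_key)
        if candidates is None:
            # residue contributed no node (should not happen for policies in use)
            d = np.linalg.norm(coords[all_nodes] - coords[i], axis=1)
            mapping[i] = int(np.argmin(d))
        else:
            d = np.linalg.norm(coords[all_nodes[candidates]] - coords[i], axis=1)
            mapping[i] = candidates[int(np.argmin(d))]
    return mapping


def generate_conformers(
    structure: Structure,
    modes: ModeSet,
    config: EnsembleConfig | None = None,
) -> ConformerEnsemble:
    """DQ-sweep conformer ensemble along the most collective low modes.

    The ``config.n_modes`` non-trivial modes of highest collectivity are each
    swept over the DQ grid; displacement of node n at perturbation dq is
    ``(dq/100) * amplitude_scale * u(n)`` with the eigenvector u scaled to
    unit maximum nodal displacement.  Non-node atoms translate rigidly with
    their residue's nearest node so that hydrogens survive into conformers.
    Under the defaults this yields 5 modes x 11 dq values = 55 conformers,
    five of which (dq = 0) equal the input.
    """
    config = config or EnsembleConfig()
    if modes.eigenvalues.size < config.n_modes:
        raise ValueError(
            f"{modes.eigenvalues.size} non-trivial modes available, {config.n_modes} requested"
        )
    selected = modes.highest_collectivity(config.n_modes)
    ride = _residue_node_map(structure, modes.node_atom_indices)
    base = structure.coords
    conformers: list[Conformer] = []
    for m in selected:
        u = modes.eigenvectors[:, m].reshape(-1, 3)
        max_disp = np.max(np.linalg.norm(u, axis=1))
        u = u / max_disp  # unit maximum nodal displacement
        atom_disp = u[ride]  # broadcast node displacement to every atom
        for dq in config.dq_values:
            coords = base + (dq / 100.0) * config.amplitude_scale * atom_disp
            label = f"{structure.identifier}|m{m}|dq{dq:g}"
            conformers.append(
                Conformer(mode_index=m, dq=float(dq), structure=structure.with_coords(coords, label))
            )
    return ConformerEnsemble(parent_id=structure.identifier, conformers=conformers)


def mode_correlation(modes_a: ModeSet, modes_b: ModeSet, k: int) -> np.ndarray:
    """|Pearson r| between same-rank non-trivial eigenvectors of two models.

    The absolute value removes the arbitrary sign of eigenvectors.  Values
    near 1 indicate that variant structures preserve the wild-type mode
    shapes, i.e. eigenvector differences reflect structural perturbation and
    not a reshuffling of the spectrum.
    """
    if modes_a.eigenvectors.shape[0] != modes_b.eigenvectors.shape[0]:
        raise ValueError("mode sets come from networks of different size")
    if k > min(modes_a.eigenvalues.size, modes_b.eigenvalues.size):
        raise ValueError("k exceeds available non-trivial modes")
    out = np.empty(k)
    for i in range(k):
        va = modes_a.eigenvectors[:, i]
        vb = modes_b.eigenvectors[:, i]
        out[i] = abs(float(np.corrcoef(va, vb)[0, 1]))
    return out
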