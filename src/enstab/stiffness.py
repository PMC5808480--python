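"""ANM mechanical stiffness: pairwise effective spring constants and maps.

For a pair of nodes (i, j) pulled apart along the line between their
equilibrium positions, the elastic network responds with compliance

    c_ij = sum_k (1 / lambda_k) [ (u_k(j) - u_k(i)) . n_ij ]^2

summed over the non-trivial modes (uniaxial-extension formulation); the
effective spring constant is kappa_ij = 1 / c_ij, in units of the network
spring constant gamma.  Row averages give the per-residue stiffness map
K_bar_i; the row of a metal-ion node gives the site profile kappa_site,i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .enm import ModeSet

logger = logging.getLogger(__name__)

#: Compliance below this is treated as a fully rigid pair (kappa -> inf).
RIGID_COMPLIANCE = 1e-12

NodeId = tuple[str, int]  # (chain, residue_number); metals use their own residue number


@dataclass
class StiffnessMatrix:
    """Symmetric pairwise effective spring constants with node identities."""

    node_ids: list[NodeId]
    kappa: np.ndarray  # n x n, diagonal NaN (undefined)
    coords: np.ndarray  # n x 3 equilibrium node positions
    modes_used: int
    rigid_pairs: list[tuple[int, int]] = field(default_factory=list)
    metal_nodes: list[NodeId] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index_of(self, node: NodeId) -> int:
        try:
            return self.node_ids.index(node)
        except ValueError:
            raise KeyError(f"node {node} not in stiffness matrix") from None

    def offdiag_values(self) -> np.ndarray:
        """All finite upper-triangle kappa values (the kappa_ij population)."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.kappa[iu]
        return vals[np.isfinite(vals)]

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{c}:{r}" for c, r in self.node_ids]
        return pd.DataFrame(self.kappa, index=labels, columns=labels)


def pairwise_stiffness(modes: ModeSet, coords: np.ndarray | None = None) -> StiffnessMatrix:
    """Mode-sum effective spring constant for every node pair.

    ``coords`` defaults to the node coordinates recorded in the mode set.
    Pairs with compliance below 1e-12 (fully rigid under the included modes)
    carry a +inf sentinel and are flagged; downstream summaries exclude them.
    """
    if coords is None:
        coords = np.array([a.coords for a in modes.node_atoms], dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need >= 2 nodes")
    if modes.eigenvalues.size < 1:
        raise ValueError("need >= 1 non-trivial mode")

    diff = coords[None, :, :] - coords[:, None, :]  # n x n x 3
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist[np.triu_indices(n, k=1)] == 0):
        raise ValueError("coincident nodes")
    with np.errstate(invalid="ignore", divide="ignore"):
        nhat = diff / dist[:, :, None]

    compliance = np.zeros((n, n))
    u = modes.eigenvectors.reshape(3 * modes.n_nodes, -1)
    for k in range(modes.eigenvalues.size):
        uk = u[:, k].reshape(-1, 3)
        du = uk[None, :, :] - uk[:, None, :]  # n x n x 3
        proj = np.einsum("ijk,ijk->ij", du, np.nan_to_num(nhat))
        compliance += (proj**2) / modes.eigenvalues[k]

    kappa = np.full((n, n), np.nan)
    iu = np.triu_indices(n, k=1)
    rigid_pairs: list[tuple[int, int]] = []
    with np.errstate(divide="ignore"):
        vals = 1.0 / compliance[iu]
    rigid = compliance[iu] < RIGID_COMPLIANCE
    vals[rigid] = np.inf
    kappa[iu] = vals
    kappa[(iu[1], iu[0])] = vals
    for i, j in zip(iu[0][rigid], iu[1][rigid]):
        rigid_pairs.append((int(i), int(j)))
    if rigid_pairs:
        logger.warning("%d fully rigid pairs flagged as +inf", len(rigid_pairs))

    node_ids = [(a.chain_id, a.residue_number) for a in modes.node_atoms]
    if len(set(node_ids)) != len(node_ids):
        # fall back to unique labels when residues contribute several nodes
        node_ids = [
            (a.chain_id + ("*" + a.name if node_ids.count((a.chain_id, a.residue_number)) > 1 else ""), a.residue_number)
            for a in modes.node_atoms
        ]
    metal_nodes = [nid for nid, a in zip(node_ids, modes.node_atoms) if a.is_metal]
    return StiffnessMatrix(
        node_ids=node_ids,
        kappa=kappa,
        coords=coords,
        modes_used=int(modes.eigenvalues.size),
        rigid_pairs=rigid_pairs,
        metal_nodes=metal_nodes,
    )


PartnerScope = Literal["all", "same_chain"]


def mean_stiffness(m: StiffnessMatrix, scope: PartnerScope = "all") -> pd.Series:
    """Row-mean stiffness K_bar_i over partners in scope.

    The divisor is the actual partner count (self and infinite sentinels
    excluded, with a log line when sentinels are dropped).
    """
    if scope not in ("all", "same_chain"):
        raise ValueError(f"unknown scope {scope!r}")
    out = {}
    n_inf = 0
    for i, nid in enumerate(m.node_ids):
        row = m.kappa[i].copy()
        mask = np.ones(m.n, dtype=bool)
        mask[i] = False
        if scope == "same_chain":
            mask &= np.array([other[0] == nid[0] for other in m.node_ids])
        vals = row[mask]
        finite = np.isfinite(vals)
        n_inf += int((~finite).sum())
        if not finite.any():
            raise ValueError(f"empty partner scope for node {nid}")
        out[nid] = float(vals[finite].mean())
    if n_inf:
        logger.info("mean_stiffness: %d infinite entries excluded", n_inf)
    return pd.Series(out, name="K_bar")


def site_stiffness_profile(m: StiffnessMatrix, site: NodeId) -> pd.Series:
    """kappa row of a named site node (e.g. a copper ion) over all residues."""
    try:
        i = m.index_of(site)
    except KeyError:
        raise KeyError(
            f"site {site} not a network node; metal nodes present: {m.metal_nodes}"
        ) from None
    profile = {nid: m.kappa[i, j] for j, nid in enumerate(m.node_ids) if j != i}
    return pd.Series(profile, name=f"kappa_{site[0]}:{site[1]}")


def top_tail(values: Mapping | pd.Series, fraction: float) -> set:
    """Keys of the rightmost ``fraction`` of the value distribution.

    The threshold is the k-th largest value with ``k = ceil(fraction * n)``
    (at least 1); every key at or above it is returned, so ties at the
    threshold are all included and fraction -> 1 returns every key.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    s = pd.Series(values).dropna()
    s = s[np.isfinite(s)]
    k = max(1, int(np.ceil(fraction * len(s))))
    thr = float(np.sort(s.to_numpy())[-k])
    return set(s[s >= thr].index)


def transmission_path(
    m: StiffnessMatrix,
    source: NodeId,
    sink: NodeId,
    contact_cutoff: float = 8.0,
) -> list[NodeId]:
    """Widest path from source to sink on the spatial contact graph.

    Edges join node pairs within ``contact_cutoff`` Angstrom, weighted by
    kappa; the returned path maximises the minimum edge stiffness along it
    (the bottleneck criterion), operationalising a chain of spatially close,
    mutually stiff residues.  Computed via the maximum spanning tree, on
    which bottleneck-optimal paths are realised.
    """
    si, ti = m.index_of(source), m.index_of(sink)
    tree = cKDTree(m.coords)
    pairs = tree.query_pairs(contact_cutoff, output_type="ndarray")
    g = nx.Graph()
    g.add_nodes_from(range(m.n))
    for i, j in pairs:
        w = m.kappa[i, j]
        if np.isfinite(w):
            g.add_edge(int(i), int(j), kappa=float(w))
        elif np.isinf(w):
            g.add_edge(int(i), int(j), kappa=float(np.nanmax(m.kappa[np.isfinite(m.kappa)]) * 10))
    if not nx.has_path(g, si, ti):
        raise ValueError(f"contact graph disconnects {source} from {sink} at {contact_cutoff} A")
    mst = nx.maximum_spanning_tree(g, weight="kappa")
    path = nx.shortest_path(mst, si, ti)
    return [m.node_ids[i] for i in path]


def site_mean_stiffness(
    m: StiffnessMatrix, position: NodeId, important: Iterable[NodeId]
) -> tuple[float, np.ndarray]:
    """Mean stiffness between one position and a set of important positions.

    Returns the mean and the raw per-pair sample, ready for a two-sample KS
    comparison against the full kappa_ij population
    (:meth:`StiffnessMatrix.offdiag_values`).
    """
    important = list(important)
    if not important:
        raise ValueError("important set is empty")
    if position in important:
        raise ValueError(f"position {position} overlaps the important set")
    i = m.index_of(position)
    sample = np.array([m.kappa[i, m.index_of(c)] for c in important])
    finite = sample[np.isfinite(sample)]
    if finite.size < sample.size:
        logger.info("site_mean_stiffness: %d infinite entries excluded", sample.size - finite.size)
    return float(finite.mean()), sample
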