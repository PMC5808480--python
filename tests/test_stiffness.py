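import numpy as np
import pandas as pd
import pytest

from enstab.enm import EnsembleConfig, build_elastic_model, compute_modes
from enstab.stiffness import (
    StiffnessMatrix,
    mean_stiffness,
    pairwise_stiffness,
    site_mean_stiffness,
    site_stiffness_profile,
    top_tail,
    transmission_path,
)
from enstab.structure_io import Atom, Structure
from conftest import make_atoms, random_connected_toy


def stiffness_of(coords, cutoff=8.0, strict=False, n_modes=None):
    s = Structure("toy", make_atoms(coords))
    model = build_elastic_model(s, EnsembleConfig(cutoff=cutoff))
    modes = compute_modes(model, strict=strict)
    if n_modes is not None:
        import dataclasses

        modes = dataclasses.replace(
            modes,
            eigenvalues=modes.eigenvalues[:n_modes],
            eigenvectors=modes.eigenvectors[:, :n_modes],
            collectivities=modes.collectivities[:n_modes],
        )
    return pairwise_stiffness(modes), model


def pseudoinverse_kappa(model, i, j):
    """Independent oracle: solve H x = f for paired unit forces along the
    inter-node axis, project out rigid modes, kappa = 1/(n.(x_j - x_i))."""
    n = model.n_nodes
    r = model.coords[j] - model.coords[i]
    nhat = r / np.linalg.norm(r)
    f = np.zeros(3 * n)
    f[3 * i : 3 * i + 3] = -nhat
    f[3 * j : 3 * j + 3] = nhat
    x = np.linalg.pinv(model.hessian, rcond=1e-10) @ f
    ext = nhat @ (x[3 * j : 3 * j + 3] - x[3 * i : 3 * i + 3])
    return 1.0 / ext


class TestPairwiseStiffness:
    def test_single_spring_kappa_equals_gamma(self):
        m, _ = stiffness_of([[0, 0, 0], [5, 0, 0]], strict=False)
        assert m.kappa[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_chain_series_law(self):
        # n collinear nearest-neighbour springs in series: kappa = gamma/(n-1)
        for n in (3, 5, 8):
            coords = [[3.0 * i, 0.0, 0.0] for i in range(n)]
            m, _ = stiffness_of(coords, cutoff=4.0, strict=False)
            assert m.kappa[0, n - 1] == pytest.approx(1.0 / (n - 1), abs=1e-9)

    def test_mode_sum_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            s = random_connected_toy(rng, n_nodes=12, box=6.0)
            model = build_elastic_model(s)
            m = pairwise_stiffness(compute_modes(model))
            i, j = rng.integers(0, 12, size=2)
            while j == i:
                j = rng.integers(0, 12)
            expected = pseudoinverse_kappa(model, i, j)
            assert m.kappa[i, j] == pytest.approx(expected, rel=1e-6)

    def test_symmetry_and_positivity(self):
        rng = np.random.default_rng(23)
        m, _ = stiffness_of(rng.uniform(0, 5, (10, 3)))
        iu = np.triu_indices(10, k=1)
        np.testing.assert_allclose(m.kappa[iu], m.kappa.T[iu], rtol=1e-9)
        assert (m.kappa[iu] > 0).all()
        assert np.isnan(np.diag(m.kappa)).all()

    def test_adding_springs_never_softens(self):
        # growing the cutoff adds springs; every kappa must stay or rise
        rng = np.random.default_rng(31)
        for _ in range(20):
            coords = rng.uniform(0, 6, (9, 3))
            m_small, _ = stiffness_of(coords, cutoff=7.0, strict=False)
            m_big, _ = stiffness_of(coords, cutoff=9.0, strict=False)
            iu = np.triu_indices(9, k=1)
            assert (m_big.kappa[iu] >= m_small.kappa[iu] * (1 - 1e-9)).all()

    def test_mode_truncation_biases_stiff(self):
        rng = np.random.default_rng(37)
        coords = rng.uniform(0, 5, (10, 3))
        m_all, _ = stiffness_of(coords)
        m_few, _ = stiffness_of(coords, n_modes=6)
        iu = np.triu_indices(10, k=1)
        assert (m_few.kappa[iu] >= m_all.kappa[iu] * (1 - 1e-9)).all()

    def test_coincident_nodes_rejected(self):
        s = Structure("dup", make_atoms([[0, 0, 0], [0, 0, 0], [3, 0, 0]]))
        with pytest.raises(ValueError, match="coincident"):
            pairwise_stiffness(compute_modes(build_elastic_model(s), strict=False))


def synthetic_matrix(kappa, coords=None):
    n = kappa.shape[0]
    if coords is None:
        coords = np.column_stack([np.arange(n) * 3.0, np.zeros(n), np.zeros(n)])
    atoms = make_atoms(coords)
    k = kappa.astype(float).copy()
    np.fill_diagonal(k, np.nan)
    return StiffnessMatrix(
        node_ids=[(a.chain_id, a.residue_number) for a in atoms],
        kappa=k,
        coords=np.asarray(coords, dtype=float),
        modes_used=0,
    )


class TestSummaries:
    def test_mean_stiffness_row_means(self):
        k = np.array([[0, 2.0, 4.0], [2.0, 0, 6.0], [4.0, 6.0, 0]])
        m = synthetic_matrix(k)
        kbar = mean_stiffness(m)
        assert kbar[("A", 1)] == pytest.approx(3.0)
        assert kbar[("A", 2)] == pytest.approx(4.0)
        assert kbar[("A", 3)] == pytest.approx(5.0)

    def test_homodimer_profile_symmetry(self):
        # chain B is the point reflection of chain A, so swapping chains is an
        # exact isometry of the dimer: K_bar identical across chains
        rng = np.random.default_rng(41)
        base = rng.uniform(0, 5, (5, 3))
        mirrored = np.array([5.0, 5.0, 11.0]) - base
        atoms = make_atoms(base, chain="A") + make_atoms(mirrored, chain="B")
        s = Structure("dimer", atoms)
        model = build_elastic_model(s)
        m = pairwise_stiffness(compute_modes(model))
        kbar = mean_stiffness(m)
        for r in range(1, 6):
            assert kbar[("A", r)] == pytest.approx(kbar[("B", r)], abs=1e-8)

    def test_same_chain_scope(self):
        k = np.arange(16, dtype=float).reshape(4, 4)
        k = (k + k.T) / 2
        m = synthetic_matrix(k)
        m.node_ids = [("A", 1), ("A", 2), ("B", 1), ("B", 2)]
        kbar = mean_stiffness(m, scope="same_chain")
        assert kbar[("A", 1)] == pytest.approx(k[0, 1])
        assert kbar[("B", 1)] == pytest.approx(k[2, 3])

    def test_single_node_chain_scope_rejected(self):
        m = synthetic_matrix(np.ones((3, 3)))
        m.node_ids = [("A", 1), ("A", 2), ("B", 1)]
        with pytest.raises(ValueError, match="empty partner scope"):
            mean_stiffness(m, scope="same_chain")

    def test_site_profile_is_matrix_row(self):
        k = np.array([[0, 2.0, 4.0], [2.0, 0, 6.0], [4.0, 6.0, 0]])
        m = synthetic_matrix(k)
        prof = site_stiffness_profile(m, ("A", 3))
        assert prof[("A", 1)] == pytest.approx(4.0)
        assert prof[("A", 2)] == pytest.approx(6.0)

    def test_missing_site_lists_metals(self):
        m = synthetic_matrix(np.ones((3, 3)))
        with pytest.raises(KeyError, match="metal"):
            site_stiffness_profile(m, ("Z", 99))

    def test_metal_coupled_residue_has_max_profile(self):
        # metal node within cutoff of only one residue: that residue tops the profile
        coords = [[0, 0, 0], [6, 0, 0], [12, 0, 0], [18, 0, 0.5], [20.5, 0, 0]]
        atoms = make_atoms(coords[:4])
        atoms.append(Atom(5, "CU", "CU", "CU", 1000, "A", tuple(map(float, coords[4])), hetero=True))
        s = Structure("mtoy", atoms)
        model = build_elastic_model(s, EnsembleConfig(cutoff=7.0))
        m = pairwise_stiffness(compute_modes(model, strict=False))
        prof = site_stiffness_profile(m, ("A", 1000))
        assert prof.idxmax() == ("A", 4)


class TestTopTail:
    def test_order_statistics(self):
        vals = {i: float(i) for i in range(1, 1001)}
        assert top_tail(vals, 0.005) == {996, 997, 998, 999, 1000}

    def test_fraction_near_one_takes_all(self):
        vals = {i: float(i) for i in range(10)}
        assert top_tail(vals, 0.999) == set(range(10))

    def test_ties_at_threshold_all_included(self):
        vals = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 3.0, "e": 3.0}
        out = top_tail(vals, 0.2)
        assert {"c", "d", "e"} <= out


class TestTransmissionPath:
    def test_linear_chain_is_the_path(self):
        k = np.ones((5, 5))
        m = synthetic_matrix(k)  # nodes 3 A apart; contact graph = chain at 4 A
        path = transmission_path(m, ("A", 1), ("A", 5), contact_cutoff=4.0)
        assert path == [("A", r) for r in range(1, 6)]

    def test_reversal_symmetry(self):
        k = np.ones((5, 5))
        m = synthetic_matrix(k)
        fwd = transmission_path(m, ("A", 1), ("A", 5), contact_cutoff=4.0)
        bwd = transmission_path(m, ("A", 5), ("A", 1), contact_cutoff=4.0)
        assert bwd == list(reversed(fwd))

    def test_widest_route_beats_shortcut(self):
        # brute-force oracle: enumerate all simple paths, pick max of min kappa
        import itertools
        import networkx as nx

        rng = np.random.default_rng(53)
        coords = rng.uniform(0, 4.0, (8, 3))  # dense contact graph at 8 A
        kappa = rng.uniform(0.1, 5.0, (8, 8))
        kappa = (kappa + kappa.T) / 2
        m = synthetic_matrix(kappa, coords)
        path = transmission_path(m, ("A", 1), ("A", 8), contact_cutoff=8.0)
        got_width = min(
            kappa[m.node_ids.index(a), m.node_ids.index(b)] for a, b in zip(path, path[1:])
        )
        g = nx.Graph()
        for i, j in itertools.combinations(range(8), 2):
            if np.linalg.norm(coords[i] - coords[j]) <= 8.0:
                g.add_edge(i, j)
        best = max(
            min(kappa[a, b] for a, b in zip(p, p[1:]))
            for p in nx.all_simple_paths(g, 0, 7)
        )
        assert got_width == pytest.approx(best)

    def test_disconnected_rejected(self):
        m = synthetic_matrix(np.ones((5, 5)))
        with pytest.raises(ValueError, match="disconnect"):
            transmission_path(m, ("A", 1), ("A", 5), contact_cutoff=2.0)


class TestSiteMeanStiffness:
    def test_uniform_field(self):
        m = synthetic_matrix(np.full((6, 6), 2.5))
        mean, sample = site_mean_stiffness(m, ("A", 1), [("A", i) for i in range(2, 7)])
        assert mean == pytest.approx(2.5)
        assert len(sample) == 5

    def test_singleton_set(self):
        k = np.ones((3, 3))
        k[0, 2] = k[2, 0] = 7.0
        m = synthetic_matrix(k)
        mean, _ = site_mean_stiffness(m, ("A", 1), [("A", 3)])
        assert mean == pytest.approx(7.0)

    def test_overlap_rejected(self):
        m = synthetic_matrix(np.ones((3, 3)))
        with pytest.raises(ValueError, match="overlap"):
            site_mean_stiffness(m, ("A", 1), [("A", 1), ("A", 2)])

    def test_ks_against_all_pairs(self):
        from enstab.stats import ks_two_sample

        rng = np.random.default_rng(59)
        m, _ = stiffness_of(rng.uniform(0, 5, (10, 3)))
        mean, sample = site_mean_stiffness(m, ("A", 1), [("A", i) for i in range(2, 7)])
        stat, p = ks_two_sample(sample, m.offdiag_values())
        assert 0 <= stat <= 1 and 0 <= p <= 1
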