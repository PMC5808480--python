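import numpy as np
import pandas as pd
import pytest

from enstab.destructive import (
    ContributionSet,
    build_h_table,
    compute_deviations,
    detect_destructive,
    mean_sh,
    residues_of_bonds,
    select_high_contribution_variants,
)
from enstab.hbond_sea import SEATable


def sea_from_values(values: dict, wt="WT", n_conformers=55) -> SEATable:
    df = pd.DataFrame(values, dtype=float)
    df.index = [f"b{i}" for i in range(len(df))]
    return SEATable(values=df, wt_id=wt, n_conformers=n_conformers)


class TestComputeDeviations:
    def test_single_bond_difference(self):
        t = sea_from_values({"WT": [1.0, 0.5], "M": [0.5, 0.5]})
        c = compute_deviations(t)
        assert c.D["M"] == pytest.approx(0.5)
        assert c.xi["M"].tolist() == pytest.approx([1.0, 0.0])

    def test_three_four_five(self):
        t = sea_from_values({"WT": [0.8, 0.9], "M": [0.5, 0.5]})
        c = compute_deviations(t)
        assert c.D["M"] == pytest.approx(0.5)
        assert sorted(c.xi["M"].tolist()) == pytest.approx([0.36, 0.64])

    def test_identical_variant_flagged_not_nan(self):
        t = sea_from_values({"WT": [0.5, 0.3], "M": [0.5, 0.3]})
        c = compute_deviations(t)
        assert c.zero_variants == ["M"]
        assert (c.xi["M"] == 0).all()

    def test_no_variants_rejected(self):
        t = sea_from_values({"WT": [0.5]})
        with pytest.raises(ValueError, match="no variants"):
            compute_deviations(t)

    def test_fuzzed_normalisation_and_oracle(self):
        # xi columns sum to 1 and D matches an element-by-element recomputation
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_b, n_v = rng.integers(3, 50), rng.integers(1, 6)
            vals = rng.integers(0, 56, size=(n_b, n_v + 1)) / 55
            t = sea_from_values(
                {("WT" if j == 0 else f"M{j}"): vals[:, j] for j in range(n_v + 1)}
            )
            c = compute_deviations(t)
            for v in t.variants:
                d_brute = np.sqrt(sum((t.values.loc[b, v] - t.values.loc[b, "WT"]) ** 2 for b in t.bonds))
                assert c.D[v] == pytest.approx(d_brute, abs=1e-12)
                if c.D[v] > 0:
                    assert c.xi[v].sum() == pytest.approx(1.0, abs=1e-9)


class TestHTable:
    def contrib_from_xi(self, xi_by_variant, sea=None):
        xi = pd.DataFrame(xi_by_variant, dtype=float)
        xi.index = [f"b{i}" for i in range(len(xi))]
        if sea is None:
            # make every bond "present" so both counting policies agree
            cols = {"WT": np.ones(len(xi))}
            cols.update({v: np.ones(len(xi)) for v in xi.columns})
            sea = sea_from_values(cols)
        d = pd.Series(np.ones(len(xi.columns)), index=xi.columns)
        return ContributionSet(D=d, xi=xi, sea=sea)

    def test_bin_assignment(self):
        c = self.contrib_from_xi({"M": [0.36, 0.64]})
        h = build_h_table(c, "union_bonds")
        assert h.counts.loc["M"].tolist() == [0, 0, 0, 1, 0, 0, 1, 0, 0]

    def test_bin9_closes_at_one(self):
        c = self.contrib_from_xi({"M": [0.95, 0.05]})
        h = build_h_table(c, "union_bonds")
        assert h.counts.loc["M", "H9"] == 1
        c2 = self.contrib_from_xi({"M": [1.0, 0.0]})
        assert build_h_table(c2, "union_bonds").counts.loc["M", "H9"] == 1

    def test_row_sum_equals_counted_bonds(self):
        rng = np.random.default_rng(5)
        xi = rng.dirichlet(np.ones(40), size=3).T
        c = self.contrib_from_xi({f"M{j}": xi[:, j] for j in range(3)})
        h = build_h_table(c, "union_bonds")
        assert (h.counts.sum(axis=1) == 40).all()

    def test_variant_present_policy_drops_absent_bonds(self):
        sea = sea_from_values({"WT": [0.0, 0.5], "M": [0.0, 0.9]})
        c = compute_deviations(sea)
        h_present = build_h_table(c, "variant_present_bonds")
        h_union = build_h_table(c, "union_bonds")
        assert h_present.counts.loc["M"].sum() == 1
        assert h_union.counts.loc["M"].sum() == 2

    def test_mean_sh(self):
        c = self.contrib_from_xi({"M": [0.5]})
        h = build_h_table(c, "union_bonds")
        h.counts.loc["M"] = [920, 6, 0, 0, 0, 0, 0, 0, 0]
        assert mean_sh(h, "M") == pytest.approx(0.75)
        h.counts.loc["M"] = [926, 0, 0, 0, 0, 0, 0, 0, 0]
        assert mean_sh(h, "M") == 0.0
        with pytest.raises(KeyError):
            mean_sh(h, "nope")


class TestSelection:
    def h_from_rows(self, rows):
        from enstab.destructive import HTable

        counts = pd.DataFrame(rows, dtype=float).T
        counts.columns = [f"H{i}" for i in range(1, 10)]
        return HTable(counts=counts)

    def test_tailed_variants_selected(self):
        rows = {f"flat{i}": [200, 0, 0, 0, 0, 0, 0, 0, 0] for i in range(26)}
        rows.update({f"tail{i}": [195, 4, 1, 0, 0, 0, 0, 0, 0] for i in range(9)})
        selected, _ = select_high_contribution_variants(self.h_from_rows(rows))
        assert selected == {f"tail{i}" for i in range(9)}

    def test_identical_rows_empty_selection(self):
        rows = {f"M{i}": [100, 0, 0, 0, 0, 0, 0, 0, 0] for i in range(5)}
        selected, _ = select_high_contribution_variants(self.h_from_rows(rows))
        assert selected == set()

    def test_two_planted_populations_two_clusters(self):
        rng = np.random.default_rng(3)
        rows = {}
        for i in range(8):
            rows[f"a{i}"] = [100 + rng.integers(0, 2), 0, 0, 0, 0, 0, 0, 0, 0]
        for i in range(8):
            rows[f"b{i}"] = [90 + rng.integers(0, 2), 8, 2, 0, 0, 0, 0, 0, 0]
        selected, result = select_high_contribution_variants(self.h_from_rows(rows), bandwidth=5.0)
        assert result.n_clusters == 2
        assert selected == {f"b{i}" for i in range(8)}


class TestDetectDestructive:
    def contrib_uniform_with_planted(self, n_bonds=100, n_planted=5, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.5, 1.0, size=n_bonds)
        base[:n_planted] *= 10
        xi_col = base / base.sum()
        xi = pd.DataFrame({"M0": xi_col, "M1": xi_col})
        xi.index = [f"b{i}" for i in range(n_bonds)]
        cols = {"WT": np.full(n_bonds, 0.5), "M0": np.full(n_bonds, 0.6), "M1": np.full(n_bonds, 0.6)}
        sea = sea_from_values(cols)
        return ContributionSet(D=pd.Series([1.0, 1.0], index=["M0", "M1"]), xi=xi, sea=sea)

    def test_planted_tail_recovered(self):
        c = self.contrib_uniform_with_planted()
        res = detect_destructive(c, ["M0", "M1"], tail=0.05)
        assert set(res.destructive_bonds) == {f"b{i}" for i in range(5)}
        assert 0 <= res.explained_fraction <= 1

    def test_zero_tail_empty(self):
        c = self.contrib_uniform_with_planted()
        res = detect_destructive(c, ["M0", "M1"], tail=0.0)
        assert res.destructive_bonds == [] and res.explained_fraction == 0.0

    def test_threshold_monotone_in_tail(self):
        c = self.contrib_uniform_with_planted(seed=4)
        sizes = [
            len(detect_destructive(c, ["M0", "M1"], tail=t).destructive_bonds)
            for t in (0.01, 0.05, 0.10, 0.25)
        ]
        assert sizes == sorted(sizes)

    def test_empty_selection_rejected(self):
        c = self.contrib_uniform_with_planted()
        with pytest.raises(ValueError, match="empty"):
            detect_destructive(c, [], tail=0.05)

    def test_explained_fraction_is_destructive_xi_share(self):
        c = self.contrib_uniform_with_planted()
        res = detect_destructive(c, ["M0"], tail=0.05)
        expected = c.xi.loc[res.destructive_bonds, "M0"].sum()
        assert res.explained_fraction == pytest.approx(expected)


class TestResiduesOfBonds:
    def test_extraction_and_roles(self):
        df = residues_of_bonds(["A:10:N-H->A:14:O"])
        assert set(zip(df.chain, df.residue)) == {("A", 10), ("A", 14)}
        roles_14 = df.loc[df.residue == 14, "roles"].iloc[0]
        assert "aggregate_contact" in roles_14

    def test_chain_tags_propagate(self):
        df = residues_of_bonds(["A:5:N-H->F:150:O"])
        assert set(df.chain) == {"A", "F"}
        # both positions belong to the dimer interface annotation
        assert all("dimer_interface" in r for r in df.roles)

    def test_opaque_labels_partial_result(self):
        df = residues_of_bonds(["A:10:N-H->A:14:O", "???"])
        assert len(df) == 2


class TestPipelineEquivalence:
    def test_tsv_round_trip_preserves_detection_bitwise(self, tmp_path, helix_dimer):
        from enstab.enm import EnsembleConfig, build_elastic_model, compute_modes, generate_conformers
        from enstab.hbond_sea import SEATable, compute_sea_table
        from enstab.synthetic import make_variant

        cfg = EnsembleConfig()
        structures = {"WT": helix_dimer}
        for i, pos in enumerate([[5, 6], [8, 9], [10, 11]]):
            structures[f"V{i}"] = make_variant(
                helix_dimer, {"A": pos}, sigma=1.0, seed=i, identifier=f"V{i}"
            )
        ensembles = {
            sid: generate_conformers(s, compute_modes(build_elastic_model(s, cfg)), cfg)
            for sid, s in structures.items()
        }
        sea = compute_sea_table(ensembles, "WT")
        direct = compute_deviations(sea)

        p = tmp_path / "sea.tsv"
        sea.to_tsv(p)
        reread = SEATable.from_tsv(p, wt_id="WT")
        via_tsv = compute_deviations(reread)

        pd.testing.assert_series_equal(direct.D, via_tsv.D)
        pd.testing.assert_frame_equal(direct.xi, via_tsv.xi)
        r1 = detect_destructive(direct, sea.variants, tail=0.05)
        r2 = detect_destructive(via_tsv, sea.variants, tail=0.05)
        assert r1.threshold == r2.threshold
        assert r1.destructive_bonds == r2.destructive_bonds
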