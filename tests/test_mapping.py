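"""Node strengths, bootstrap/permutation intervals, retention, recovery."""

import numpy as np
import pandas as pd
import pytest

import gldm
from gldm import mapping as mp
from gldm.types import GroundTruth
from tests.conftest import toy_graph


class TestNodeStrengths:
    def test_single_edge_node_inherits_edge_weights(self):
        g = toy_graph([(1, 2, 3, 0.3, 1.5)])
        st = mp.node_strengths(g)
        assert st.loc[1, "deficit_strength"] == pytest.approx(1.5)
        assert st.loc[1, "lesion_strength"] == pytest.approx(0.3)

    def test_constant_deficit_weights_propagate(self):
        g = toy_graph([(1, 2, 2, 0.2, 0.7), (2, 3, 5, 0.5, 0.7), (1, 3, 3, 0.3, 0.7)])
        st = mp.node_strengths(g)
        assert np.allclose(st["deficit_strength"], 0.7)

    def test_support_weighted_mean(self):
        """Supports (2, 4) with w_def (1.0, 0.25): (2*1 + 4*0.25)/6 = 0.5."""
        g = toy_graph([(1, 2, 2, 0.2, 1.0), (1, 3, 4, 0.4, 0.25)])
        st = mp.node_strengths(g)
        assert st.loc[1, "deficit_strength"] == pytest.approx(0.5)
        assert st.loc[1, "lesion_strength"] == pytest.approx(0.3)


def simulate_damage(seed, n=200, p_parcels=12, effect=1.5, p_dam=0.25):
    """Independent Bernoulli parcel damage with a two-parcel substrate."""
    rng = np.random.default_rng(seed)
    dam = (rng.random((n, p_parcels)) < p_dam).astype(int)
    dbin = pd.DataFrame(dam, columns=range(1, p_parcels + 1))
    load = dam[:, :2].mean(axis=1)
    z = pd.Series(effect * load + rng.normal(0, 1, n))
    return dbin, z


class TestBootstrapCis:
    def test_constant_z_degenerate_deficit_cis(self):
        dbin, _ = simulate_damage(0)
        z = pd.Series(np.full(len(dbin), 0.8))
        cis = mp.bootstrap_cis(dbin, z, n_boot=150, seed=1)
        ok = cis["n_boot_ok"] > 0
        assert np.allclose(cis.loc[ok, "def_ci_low"], 0.8)
        assert np.allclose(cis.loc[ok, "def_ci_high"], 0.8)

    def test_ci_ordering_and_seeding(self):
        dbin, z = simulate_damage(3)
        a = mp.bootstrap_cis(dbin, z, n_boot=120, seed=5)
        b = mp.bootstrap_cis(dbin, z, n_boot=120, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert (a["def_ci_low"] <= a["def_ci_high"]).all()
        assert (a["les_ci_low"] <= a["les_ci_high"]).all()

    def test_width_stabilizes_with_more_replicates(self):
        dbin, z = simulate_damage(7, n=250)
        w1 = mp.bootstrap_cis(dbin, z, n_boot=1000, seed=2)
        w2 = mp.bootstrap_cis(dbin, z, n_boot=2000, seed=2)
        width1 = (w1["def_ci_high"] - w1["def_ci_low"]).median()
        width2 = (w2["def_ci_high"] - w2["def_ci_low"]).median()
        assert abs(width1 - width2) / width1 < 0.10

    def test_minimum_replicates_enforced(self):
        dbin, z = simulate_damage(1)
        with pytest.raises(ValueError):
            mp.bootstrap_cis(dbin, z, n_boot=50)

    def test_empirical_coverage_of_node_strength(self):
        """95% bootstrap CIs cover the population deficit strength at a rate
        in [0.90, 0.99] (population value from one very large cohort)."""
        # population strengths: near-infinite sample
        dbin_big, z_big = simulate_damage(999, n=120_000)
        truth, _ = mp._strengths_fast(
            dbin_big.to_numpy(float), z_big.to_numpy(), m_min=2
        )
        hits, total = 0, 0
        for seed in range(200):
            dbin, z = simulate_damage(seed, n=250)
            cis = mp.bootstrap_cis(dbin, z, n_boot=200, seed=seed + 1)
            lo = cis["def_ci_low"].to_numpy()
            hi = cis["def_ci_high"].to_numpy()
            ok = cis["n_boot_ok"].to_numpy() > 150
            hits += int(np.sum((truth[ok] >= lo[ok]) & (truth[ok] <= hi[ok])))
            total += int(ok.sum())
        coverage = hits / total
        assert 0.90 <= coverage <= 0.99


class TestRetention:
    def frame(self, rows):
        df = pd.DataFrame(
            rows,
            columns=[
                "deficit_strength", "lesion_strength",
                "def_ci_low", "def_ci_high",
                "les_ci_low", "les_ci_high",
                "perm_ci_low", "perm_ci_high",
            ],
        )
        df.index.name = "parcel_id"
        return df

    def test_disjoint_above_retained(self):
        df = self.frame([[1.0, 0.2, 0.8, 1.2, 0.1, 0.3, 0.1, 0.3]])
        out = mp.retention_rule(df, lesion_reference="per_node")
        assert bool(out["retained"].iloc[0])
        out = mp.retention_rule(df, lesion_reference="permutation")
        assert bool(out["retained"].iloc[0])

    def test_overlapping_not_retained(self):
        df = self.frame([[0.5, 0.2, 0.2, 0.8, 0.1, 0.3, 0.1, 0.3]])
        out = mp.retention_rule(df, lesion_reference="per_node")
        assert not out["retained"].iloc[0]

    def test_direction_matters(self):
        # deficit CI strictly below the lesion CI: disjoint but not retained
        df = self.frame([[0.05, 0.5, 0.0, 0.08, 0.4, 0.6, 0.4, 0.6]])
        out = mp.retention_rule(df, lesion_reference="per_node")
        assert not out["retained"].iloc[0]

    def test_missing_ci_flagged(self):
        df = self.frame([[0.5, 0.2, np.nan, np.nan, 0.1, 0.3, 0.1, 0.3]])
        out = mp.retention_rule(df, lesion_reference="per_node")
        assert not out["retained"].iloc[0]
        assert out["retention_reason"].iloc[0] == "missing CI"


class TestSubstrateRecovery:
    def map_with_retained(self, retained, parcels=range(1, 7)):
        df = pd.DataFrame(index=pd.Index(parcels, name="parcel_id"))
        df["retained"] = [p in retained for p in parcels]
        return df

    def truth(self, parcels):
        return GroundTruth(substrate_parcels=frozenset(parcels))

    def test_perfect_recovery(self):
        rec = mp.substrate_recovery(self.map_with_retained({1, 2}), self.truth({1, 2}))
        assert rec["jaccard"] == 1.0 and rec["sensitivity"] == 1.0

    def test_disjoint_recovery(self):
        rec = mp.substrate_recovery(self.map_with_retained({3, 4}), self.truth({1, 2}))
        assert rec["jaccard"] == 0.0

    def test_partial_overlap(self):
        rec = mp.substrate_recovery(
            self.map_with_retained({1, 2, 3}), self.truth({2, 3, 4})
        )
        assert rec["jaccard"] == pytest.approx(0.5)


def test_export_parcel_map_roundtrip(tmp_path, small_scheme):
    from gldm import imaging

    parcels = small_scheme.parcel_ids
    df = pd.DataFrame(index=pd.Index(parcels, name="parcel_id"))
    df["deficit_strength"] = np.linspace(0.5, 2.0, len(parcels))
    df["retained"] = [p == 3 for p in parcels]
    vol = mp.export_parcel_map(df, small_scheme, tmp_path / "map.nii.gz",
                               table_path=tmp_path / "map.tsv")
    back = imaging.read_map(tmp_path / "map.nii.gz", small_scheme)
    assert np.allclose(back, vol)
    inside = small_scheme.labels == 3
    assert np.allclose(back[inside], df.loc[3, "deficit_strength"], atol=1e-6)
    assert np.allclose(back[~inside], 0.0)


def test_retention_sensitivity_monotone_in_effect(default_scheme):
    """Mean recovery sensitivity is non-decreasing in the effect size across
    the simulation grid (a scaled-down version of the full design)."""
    from gldm import imaging
    from gldm.graph import build_graph, deficit_scores, residualize_age
    from gldm.synth import default_substrate

    sub = default_substrate(default_scheme, 2)
    sens = []
    for beta in (0.0, 10.0, 30.0):
        hits = []
        for seed in range(3):
            truth = GroundTruth(substrate_parcels=sub, effect_beta=beta, noise_sd=5.0)
            masks, cohort = gldm.simulate_cohort(
                default_scheme, truth, n_patients=250, n_controls=80, seed=900 + seed
            )
            dm = imaging.damage_matrix(masks, default_scheme)
            dbin = imaging.binarize_damage(dm, 0.25)
            z = deficit_scores(cohort)
            zadj = residualize_age(
                z.z, cohort.loc[cohort["role"] == "patient", "age"].to_numpy()
            )
            g = build_graph(dbin, zadj)
            cis = mp.bootstrap_cis(dbin, zadj, n_boot=300, seed=seed)
            perm = mp.permutation_reference(dbin, zadj, n_perm=300, seed=seed + 1)
            nmap = mp.network_map(g, cis.join(perm))
            hits.append(mp.substrate_recovery(nmap, truth)["sensitivity"])
        sens.append(np.mean(hits))
    assert sens[0] <= sens[1] + 1e-9 <= sens[2] + 2e-9
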