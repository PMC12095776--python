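import numpy as np
import pandas as pd
import pytest

from gradr import Config
from gradr.core_io import GradientMatrix, ValidationError
from gradr.gradr_core import (CombinedDataset, DegenerateProfileError,
                              interactome_all, interactor_correlation_matrix,
                              linkage_to_newick, predict_interactors,
                              profile_pearson, zscore_profile)
from gradr.localization import LocalizationRecord


def brute_pearson(a, b):
    """Independent covariance / sigma-sigma evaluation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = len(a)
    cov = (a * b).mean() - a.mean() * b.mean()
    va = (a * a).mean() - a.mean() ** 2
    vb = (b * b).mean() - b.mean() ** 2
    return cov / np.sqrt(va * vb)


def profile_with_r(ref, r, rng):
    """A non-negative profile whose Pearson r with ``ref`` is exactly r."""
    x = (ref - ref.mean()) / ref.std()
    z = rng.normal(size=len(ref))
    z = z - z.mean()
    z = z - x * (z @ x) / (x @ x)
    z = z / z.std()
    y = r * x + np.sqrt(1 - r ** 2) * z
    return y - y.min() + 0.1


def _loc(eid, cls, compartment, reps=3):
    home = np.full(reps, 90.0)
    away = np.full(reps, 10.0)
    if compartment == "cytoplasmic":
        return LocalizationRecord(eid, cls, home, away)
    return LocalizationRecord(eid, cls, away, home)


def build_dataset(rna_compartment="cytoplasmic", rng=None):
    """One query RNA plus hand-built proteins spanning the filter grid."""
    rng = rng or np.random.default_rng(5)
    fr = np.arange(1, 23, dtype=float)
    rna = 100 * np.exp(-((fr - 8) ** 2) / 8.0)
    proteins = {
        "P_good_hi": (profile_with_r(rna, 0.95, rng), 8.0, 0.001, True, False),
        "P_good_lo": (profile_with_r(rna, 0.49, rng), 8.0, 0.001, True, False),
        "P_good_mid": (profile_with_r(rna, 0.70, rng), 4.0, 0.02, True, False),
        "P_not_rbp": (profile_with_r(rna, 0.99, rng), 1.5, 0.001, True, False),
        "P_bad_p": (profile_with_r(rna, 0.99, rng), 8.0, 0.2, True, False),
        "P_wrong_comp": (profile_with_r(rna, 0.99, rng), 8.0, 0.001, False, False),
        "P_mito": (profile_with_r(rna, 0.99, rng), 8.0, 0.001, True, True),
        "P_anti": (profile_with_r(rna, -0.8, rng), 8.0, 0.001, True, False),
        "P_weak": (profile_with_r(rna, 0.10, rng), 3.0, 0.01, True, False),
        "P_flat": (np.full(22, 7.0), 8.0, 0.001, True, False),
    }
    frac_cols = [f"F{i:02d}" for i in range(1, 23)]
    rna_gm = GradientMatrix(pd.DataFrame([rna], index=["RNA_Q"],
                                         columns=frac_cols), "rna")
    prot_gm = GradientMatrix(
        pd.DataFrame({p: v[0] for p, v in proteins.items()},
                     index=frac_cols).T, "protein")
    oops = pd.DataFrame({"fold_change": [v[1] for v in proteins.values()],
                         "p_value": [v[2] for v in proteins.values()]},
                        index=list(proteins))
    rbps = {p for p, v in proteins.items()
            if v[1] >= 2.0 and v[2] <= 0.05}
    loc = {"RNA_Q": _loc("RNA_Q", "rna", rna_compartment)}
    for p, v in proteins.items():
        same = v[3]
        comp = rna_compartment if same else (
            "nuclear" if rna_compartment == "cytoplasmic" else "cytoplasmic")
        loc[p] = _loc(p, "protein", comp)
    mito = {p for p, v in proteins.items() if v[4]}
    return CombinedDataset(rna_profiles=rna_gm, protein_profiles=prot_gm,
                           rbp_ids=rbps, localization=loc, mito_ids=mito,
                           oops=oops), proteins


class TestZScore:
    def test_mean_zero_sd_one(self):
        z = zscore_profile([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0, abs=1e-15)
        assert z.std() == pytest.approx(1.0)

    def test_constant_profile_is_degenerate(self):
        with pytest.raises(DegenerateProfileError):
            zscore_profile([5.0] * 22)

    def test_pearson_invariant_under_zscoring(self, rng):
        a, b = rng.lognormal(1, 1, 22), rng.lognormal(1, 1, 22)
        assert profile_pearson(a, b) == pytest.approx(
            profile_pearson(zscore_profile(a), zscore_profile(b)), abs=1e-12)


class TestProfilePearson:
    def test_self_correlation_is_one(self, rng):
        a = rng.uniform(0, 10, 22)
        assert profile_pearson(a, a) == pytest.approx(1.0)

    def test_negative_affine_gives_minus_one(self, rng):
        a = rng.uniform(0, 10, 22)
        assert profile_pearson(a, -2 * a + 30) == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        a, b = [0.0, 1.0, 4.0, 2.0], [1.0, 3.0, 7.0, 5.0]
        assert profile_pearson(a, b) == pytest.approx(brute_pearson(a, b),
                                                      abs=1e-14)

    def test_constant_input_signalled(self):
        with pytest.raises(DegenerateProfileError):
            profile_pearson([1.0] * 5, [1, 2, 3, 4, 5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            profile_pearson([1, 2], [1, 2, 3])


class TestPredictInteractors:
    def test_filter_chain_cytoplasmic_branch(self, cfg):
        ds, proteins = build_dataset("cytoplasmic")
        tab = predict_interactors("RNA_Q", ds, cfg)
        # non-RBPs, wrong-compartment proteins never scored
        assert "P_not_rbp" not in set(tab["protein_id"])
        assert "P_bad_p" not in set(tab["protein_id"])
        assert "P_wrong_comp" not in set(tab["protein_id"])
        # flat profile skipped (degenerate), not failed
        assert "P_flat" not in set(tab["protein_id"])
        # cytoplasmic branch does NOT remove mitochondrial proteins
        assert "P_mito" in set(tab["protein_id"])
        passed = set(tab.loc[tab["passed"], "protein_id"])
        assert passed == {"P_good_hi", "P_good_mid", "P_mito"}

    def test_r_below_threshold_not_passed(self, cfg):
        ds, _ = build_dataset("cytoplasmic")
        tab = predict_interactors("RNA_Q", ds, cfg).set_index("protein_id")
        assert tab.loc["P_good_lo", "pearson_r"] == pytest.approx(0.49)
        assert not tab.loc["P_good_lo", "passed"]

    def test_nuclear_branch_excludes_mitochondrial(self, cfg):
        ds, _ = build_dataset("nuclear")
        tab = predict_interactors("RNA_Q", ds, cfg)
        assert "P_mito" not in set(tab["protein_id"])

    def test_sorted_descending_with_dense_ranks(self, cfg):
        ds, _ = build_dataset("cytoplasmic")
        tab = predict_interactors("RNA_Q", ds, cfg)
        r = tab["pearson_r"].to_numpy()
        assert (np.diff(r) <= 1e-12).all()
        ranks = tab.loc[tab["passed"], "rank"].tolist()
        assert ranks == list(range(1, len(ranks) + 1))

    def test_invariant_to_input_row_order_and_zscoring(self, cfg):
        ds, _ = build_dataset("cytoplasmic")
        tab = predict_interactors("RNA_Q", ds, cfg)
        # shuffle protein rows
        shuffled = ds.protein_profiles.profiles.sample(
            frac=1.0, random_state=1)
        ds2 = CombinedDataset(ds.rna_profiles,
                              GradientMatrix(shuffled, "protein"),
                              ds.rbp_ids, ds.localization, ds.mito_ids,
                              ds.oops)
        tab2 = predict_interactors("RNA_Q", ds2, cfg)
        pd.testing.assert_frame_equal(tab, tab2)
        # z-score all non-degenerate profiles
        arr = ds.protein_profiles.profiles.to_numpy(dtype=float).copy()
        for i in range(arr.shape[0]):
            if arr[i].std() > 0:
                arr[i] = (arr[i] - arr[i].mean()) / arr[i].std()
        arr -= arr.min()  # keep abundances non-negative
        zs = pd.DataFrame(arr, index=ds.protein_profiles.profiles.index,
                          columns=ds.protein_profiles.profiles.columns)
        ds3 = CombinedDataset(ds.rna_profiles, GradientMatrix(zs, "protein"),
                              ds.rbp_ids, ds.localization, ds.mito_ids,
                              ds.oops)
        tab3 = predict_interactors("RNA_Q", ds3, cfg).set_index("protein_id")
        by_id = tab.set_index("protein_id")
        assert set(by_id.index) == set(tab3.index)
        np.testing.assert_allclose(by_id["pearson_r"],
                                   tab3.loc[by_id.index, "pearson_r"],
                                   atol=1e-10)

    def test_tightening_thresholds_never_enlarges_passed_set(self):
        ds, _ = build_dataset("cytoplasmic")
        base = predict_interactors("RNA_Q", ds, Config())
        base_passed = set(base.loc[base["passed"], "protein_id"])
        for tight in (Config(r_min=0.8), Config(oops_fc_min=5.0),
                      Config(oops_p_max=0.005)):
            tab = predict_interactors("RNA_Q", ds, tight)
            assert set(tab.loc[tab["passed"], "protein_id"]) <= base_passed

    def test_unknown_rna_rejected(self, cfg):
        ds, _ = build_dataset()
        with pytest.raises(KeyError):
            predict_interactors("NOPE", ds, cfg)


class TestInteractomeAll:
    def test_long_table_is_union_of_per_rna_tables(self, cfg, default_sim):
        ds = default_sim.combined_dataset(cfg)
        long, summary = interactome_all(ds, cfg)
        per_rna_passed = set()
        for rna_id in ds.rna_profiles.entity_ids:
            tab = predict_interactors(str(rna_id), ds, cfg)
            per_rna_passed |= {(str(rna_id), p)
                               for p in tab.loc[tab["passed"], "protein_id"]}
        long_passed = {(r, p) for r, p in
                       zip(long.loc[long["passed"], "rna_id"],
                           long.loc[long["passed"], "protein_id"])}
        assert long_passed == per_rna_passed
        assert (summary["n_passed"].sum()) == len(long_passed)


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, cfg, default_sim):
        ds = default_sim.combined_dataset(cfg)
        ids = list(map(str, ds.protein_profiles.entity_ids[:8]))
        corr, linkage, leaves = interactor_correlation_matrix(ids, ds)
        assert np.allclose(np.diag(corr.values), 1.0)
        assert np.allclose(corr.values, corr.values.T, atol=1e-12)
        assert sorted(leaves) == sorted(corr.index)

    def test_two_complexes_form_contiguous_leaf_blocks(self, cfg, default_sim):
        ds = default_sim.combined_dataset(cfg)
        members = [p for p in map(str, ds.protein_profiles.entity_ids)
                   if p.startswith("PROT_C")]
        _, _, leaves = interactor_correlation_matrix(members, ds)
        labels = [p.split("_")[1] for p in leaves]  # C1.. / C2..
        # complexes must not interleave
        assert len([i for i in range(1, len(labels))
                    if labels[i] != labels[i - 1]]) == 1

    def test_too_few_proteins_rejected(self, cfg, default_sim):
        ds = default_sim.combined_dataset(cfg)
        with pytest.raises(ValidationError):
            interactor_correlation_matrix(
                [str(ds.protein_profiles.entity_ids[0])], ds)

    def test_newick_contains_all_labels(self, cfg, default_sim):
        ds = default_sim.combined_dataset(cfg)
        ids = list(map(str, ds.protein_profiles.entity_ids[:5]))
        corr, linkage, _ = interactor_correlation_matrix(ids, ds)
        nwk = linkage_to_newick(linkage, list(corr.index))
        assert nwk.endswith(";")
        for pid in corr.index:
            assert pid in nwk
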