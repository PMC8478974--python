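"""Regulon inference, rank-AUC activity, modules, conservation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from eyeatlas.containers import GeneMatrix
from eyeatlas.imputation import build_diffusion_operator, impute
from eyeatlas.io_preprocess import normalize_log
from eyeatlas.regulons import (
    Regulon,
    combined_tf_score,
    detect_tf_modules,
    infer_regulons,
    module_activity,
    regulon_activity,
    tf_conservation,
)
from eyeatlas.synthetic import SyntheticConfig, generate_atlas


def matrix_from(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return GeneMatrix(values, genes, [f"c{i}" for i in range(values.shape[1])])


class TestInferRegulons:
    def test_planted_regulon_recovery(self):
        """Each TF's true target block dominates its inferred target list."""
        cfg = SyntheticConfig(n_cells=1000, n_genes=400, n_cell_types=5, n_tfs=4,
                              targets_per_tf=20, n_markers_per_type=0,
                              module_blocks=[[0], [1], [2], [3]],
                              species=(("human", 1.0),), seed=13)
        mats, truth = generate_atlas(cfg)
        norm = normalize_log(mats["human"])
        regs = infer_regulons(norm, list(truth.regulons), n_targets=20)
        for reg in regs:
            truth_set = set(truth.regulons[reg.tf])
            got = set(reg.target_genes)
            jacc = len(got & truth_set) / len(got | truth_set)
            assert jacc >= 0.6, (reg.tf, jacc)

    def test_constant_tf_flagged_empty(self):
        X = np.vstack([np.ones(30), np.random.default_rng(0).uniform(size=(5, 30))])
        regs = infer_regulons(matrix_from(X), ["g0"], n_targets=3)
        assert regs[0].targets == [] and not regs[0].usable

    def test_n_targets_bound(self, atlas):
        with pytest.raises(ValueError):
            infer_regulons(atlas["normalized"], [atlas["normalized"].gene_ids[0]],
                           n_targets=atlas["normalized"].n_genes)

    def test_positive_association_only(self, atlas):
        regs = infer_regulons(atlas["normalized"],
                              list(atlas["truth"].regulons)[:3], n_targets=30)
        for reg in regs:
            assert all(w > 0 for _, w in reg.targets)


def brute_force_auc(target_ranks, n_targets, threshold):
    """Oracle: step-curve integration of the recovery curve."""
    hits = [sum(1 for r in target_ranks if r <= k) for k in range(1, threshold + 1)]
    s = min(n_targets, threshold)
    best = [min(k, s) for k in range(1, threshold + 1)]
    return sum(hits) / sum(best)


class TestRegulonActivity:
    def test_all_targets_on_top_is_one(self):
        X = np.array([[9.0], [8.0], [5.0], [1.0], [0.5], [0.2], [0.1], [0.0], [0.0], [0.0]])
        m = matrix_from(X)
        reg = Regulon("g9", [("g0", 1.0), ("g1", 1.0)], min_targets=1)
        act = regulon_activity(m, [reg], top_frac=0.5)
        assert act.iloc[0, 0] == 1.0

    def test_all_targets_below_threshold_is_zero(self):
        X = np.arange(10, 0, -1, dtype=float)[:, None]
        m = matrix_from(X)
        reg = Regulon("g0", [("g8", 1.0), ("g9", 1.0)], min_targets=1)
        act = regulon_activity(m, [reg], top_frac=0.5)
        assert act.iloc[0, 0] == 0.0

    def test_matches_step_curve_oracle(self):
        """Targets at ranks 1 and 3 with threshold 5 over 10 genes."""
        X = np.arange(10, 0, -1, dtype=float)[:, None]  # gene gi has rank i+1
        m = matrix_from(X)
        reg = Regulon("g9", [("g0", 1.0), ("g2", 1.0)], min_targets=1)
        act = regulon_activity(m, [reg], top_frac=0.5)
        assert np.isclose(act.iloc[0, 0], brute_force_auc([1, 3], 2, 5))
        assert np.isclose(act.iloc[0, 0], 8.0 / 9.0)

    def test_invariant_to_monotone_transform(self, atlas, truth_regulons):
        norm = atlas["normalized"]
        a1 = regulon_activity(norm, truth_regulons[:3], seed=0)
        squashed = GeneMatrix(np.sqrt(norm.dense()), norm.gene_ids, norm.cell_ids)
        a2 = regulon_activity(squashed, truth_regulons[:3], seed=0)
        assert np.allclose(a1.to_numpy(), a2.to_numpy())

    def test_missing_targets_raise(self, atlas):
        reg = Regulon("ghost_tf", [("nope1", 1.0), ("nope2", 1.0)], min_targets=1)
        with pytest.raises(ValueError, match="ghost_tf"):
            regulon_activity(atlas["normalized"], [reg])

    def test_planted_activity_separates_types(self, atlas, truth_regulons):
        from sklearn.metrics import roc_auc_score

        truth = atlas["truth"]
        labels = truth.labels["human"]
        act = regulon_activity(atlas["normalized"], truth_regulons, seed=0)
        for reg in truth_regulons[:5]:
            on_types = np.flatnonzero(truth.tf_activation.loc[reg.tf].to_numpy())
            y = np.isin(labels, on_types)
            assert roc_auc_score(y, act.loc[reg.tf].to_numpy()) >= 0.9


class TestCombinedScore:
    def _frames(self, a, e):
        cells = [f"c{i}" for i in range(a.shape[1])]
        tfs = [f"t{i}" for i in range(a.shape[0])]
        return (pd.DataFrame(a, index=tfs, columns=cells),
                pd.DataFrame(e, index=tfs, columns=cells))

    def test_identical_inputs_idempotent(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 50))
        fa, fe = self._frames(a, a.copy())
        combined = combined_tf_score(fa, fe)
        za = (a - a.mean(1, keepdims=True)) / a.std(1, keepdims=True)
        assert np.allclose(combined.to_numpy(), za, atol=1e-10)

    def test_opposite_scores_cancel(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(1, 40))
        fa, fe = self._frames(a, -a)
        combined = combined_tf_score(fa, fe, weight=0.5)
        # z(a) and z(-a) cancel exactly; the zero row stays zero after
        # re-standardisation (degenerate sd guard)
        assert np.allclose(combined.to_numpy(), 0.0, atol=1e-10)

    def test_rows_standardized(self, atlas, truth_regulons):
        norm = atlas["normalized"]
        act = regulon_activity(norm, truth_regulons, seed=0)
        expr = norm.to_frame(list(act.index))
        combined = combined_tf_score(act, expr)
        vals = combined.to_numpy()
        assert np.allclose(vals.mean(axis=1), 0.0, atol=1e-8)
        assert np.allclose(vals.std(axis=1), 1.0, atol=1e-8)

    def test_partial_tf_overlap_warns_and_drops(self):
        rng = np.random.default_rng(2)
        fa, fe = self._frames(rng.normal(size=(3, 20)), rng.normal(size=(3, 20)))
        fe = fe.iloc[:2]
        with pytest.warns(UserWarning):
            combined = combined_tf_score(fa, fe)
        assert list(combined.index) == ["t0", "t1"]


def block_frame(n_per_block=5, n_cells=400, noise=0.0, seed=0, n_blocks=2):
    """TF x cell frame with planted correlated blocks."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for b in range(n_blocks):
        latent = rng.normal(size=n_cells)
        for i in range(n_per_block):
            rows.append(latent + noise * rng.normal(size=n_cells))
            truth.append(b)
    tfs = [f"t{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=tfs, columns=[f"c{i}" for i in range(n_cells)]), truth


class TestDetectModules:
    def test_noise_free_blocks_exact(self):
        frame, truth = block_frame(noise=1e-6)
        mods, corr = detect_tf_modules(frame)
        assert len(mods) == 2
        got = {tf: m.module_id for m in mods for tf in m.member_tfs}
        ari = adjusted_rand_score(truth, [got[tf] for tf in frame.index])
        assert ari == 1.0

    def test_independent_tfs_no_modules(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.normal(size=(12, 1000)),
                             index=[f"t{i}" for i in range(12)])
        mods, _ = detect_tf_modules(frame)
        assert mods == []

    def test_partition_contract_and_order_invariance(self):
        frame, _ = block_frame(noise=0.3, seed=4)
        mods, corr = detect_tf_modules(frame)
        members = [tf for m in mods for tf in m.member_tfs]
        assert len(members) == len(set(members))
        shuffled = frame.sample(frac=1.0, random_state=5)
        mods2, _ = detect_tf_modules(shuffled)
        sets1 = {frozenset(m.member_tfs) for m in mods}
        sets2 = {frozenset(m.member_tfs) for m in mods2}
        assert sets1 == sets2
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_fixed_module_count_cut(self):
        frame, truth = block_frame(noise=0.2, seed=6, n_blocks=3, n_per_block=4)
        mods, _ = detect_tf_modules(frame, n_modules=3)
        assert len(mods) == 3

    def test_end_to_end_block_recovery(self, atlas, truth_regulons):
        """activity -> combine -> detect recovers the planted TF blocks."""
        truth = atlas["truth"]
        norm = atlas["normalized"]
        act = regulon_activity(norm, truth_regulons, seed=0)
        op = build_diffusion_operator(norm)
        expr = impute(norm, op, t=3).to_frame(list(act.index))
        combined = combined_tf_score(act, expr)
        mods, _ = detect_tf_modules(combined)
        got = {tf: m.module_id for m in mods for tf in m.member_tfs}
        common = [tf for tf in truth.tf_modules if tf in got]
        assert len(common) >= 0.8 * len(truth.tf_modules)
        ari = adjusted_rand_score([truth.tf_modules[tf] for tf in common],
                                  [got[tf] for tf in common])
        assert ari >= 0.8


class TestModuleActivity:
    def test_single_tf_module_equals_row(self):
        frame, _ = block_frame(noise=0.2, seed=7)
        from eyeatlas.regulons import TFModule

        mod = TFModule("M1", ["t0"])
        scores, _ = module_activity(frame, [mod], np.zeros(frame.shape[1], dtype=int))
        assert np.allclose(scores.loc["M1"].to_numpy(), frame.loc["t0"].to_numpy())

    def test_member_order_irrelevant(self):
        frame, _ = block_frame(noise=0.2, seed=8)
        from eyeatlas.regulons import TFModule

        labels = np.zeros(frame.shape[1], dtype=int)
        s1, _ = module_activity(frame, [TFModule("M1", ["t0", "t3", "t2"])], labels)
        s2, _ = module_activity(frame, [TFModule("M1", ["t2", "t0", "t3"])], labels)
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_unknown_tf_raises(self):
        frame, _ = block_frame()
        from eyeatlas.regulons import TFModule

        with pytest.raises(KeyError):
            module_activity(frame, [TFModule("M1", ["nope"])],
                            np.zeros(frame.shape[1], dtype=int))

    def test_planted_module_specific_to_its_type(self, atlas, truth_regulons):
        truth = atlas["truth"]
        norm = atlas["normalized"]
        act = regulon_activity(norm, truth_regulons, seed=0)
        expr = norm.to_frame(list(act.index))
        combined = combined_tf_score(act, expr)
        mods, _ = detect_tf_modules(combined)
        labels = truth.cell_types("human")
        scores, type_means = module_activity(combined, mods, labels)
        for mod in mods:
            # the type where this module's TFs are active has the top mean
            tf = mod.member_tfs[0]
            on_type = truth.tf_activation.columns[
                int(np.flatnonzero(truth.tf_activation.loc[tf].to_numpy())[0])]
            row = type_means.loc[mod.module_id]
            assert row.idxmax() == on_type


class TestConservation:
    def _combined(self, atlas, species):
        from eyeatlas.regulons import Regulon

        truth = atlas["truth"]
        mat = atlas["matrices"][species]
        norm = normalize_log(mat) if species != "human" else atlas["normalized"]
        if species == "human":
            regs = [Regulon(tf, [(g, 1.0) for g in tg], min_targets=5)
                    for tf, tg in truth.regulons.items()]
        else:
            omap = truth.ortholog_maps[("human", "pig")]
            lut = dict(zip(omap.iloc[:, 0], omap.iloc[:, 1]))
            regs = [Regulon(lut[tf], [(lut[g], 1.0) for g in tg if g in lut], min_targets=5)
                    for tf, tg in truth.regulons.items() if tf in lut]
        act = regulon_activity(norm, regs, seed=0)
        expr = norm.to_frame(list(act.index))
        return combined_tf_score(act, expr)

    def test_identity_copy_gives_r_one(self, atlas):
        ca = self._combined(atlas, "human")
        labels = atlas["truth"].labels["human"]
        omap = pd.DataFrame({"a": list(ca.index), "b": list(ca.index)})
        recs, unmapped = tf_conservation(ca, labels, ca, labels, omap,
                                         [(t, t) for t in range(5)])
        assert unmapped == []
        assert np.allclose(recs["r"], 1.0)

    def test_cross_species_planted_conservation(self, atlas):
        """Planted TFs keep their type profile across species; scrambling breaks it."""
        truth = atlas["truth"]
        ca = self._combined(atlas, "human")
        cb = self._combined(atlas, "pig")
        omap = truth.ortholog_maps[("human", "pig")]
        la, lb = truth.labels["human"], truth.labels["pig"]
        recs, _ = tf_conservation(ca, la, cb, lb, omap, [(t, t) for t in range(5)])
        assert (recs["r"] >= 0.9).mean() >= 0.9
        # scrambled partner activity should not look conserved
        rng = np.random.default_rng(0)
        cb_scr = pd.DataFrame(cb.to_numpy()[:, rng.permutation(cb.shape[1])],
                              index=cb.index, columns=cb.columns)
        recs_scr, _ = tf_conservation(ca, la, cb_scr, lb, omap, [(t, t) for t in range(5)])
        assert recs_scr["r"].abs().median() < 0.5

    def test_unmapped_tfs_reported(self, atlas):
        ca = self._combined(atlas, "human")
        labels = atlas["truth"].labels["human"]
        omap = pd.DataFrame({"a": list(ca.index)[1:], "b": list(ca.index)[1:]})
        recs, unmapped = tf_conservation(ca, labels, ca, labels, omap,
                                         [(t, t) for t in range(5)])
        assert unmapped == [list(ca.index)[0]]

    def test_too_few_matched_types_rejected(self, atlas):
        ca = self._combined(atlas, "human")
        labels = atlas["truth"].labels["human"]
        omap = pd.DataFrame({"a": list(ca.index), "b": list(ca.index)})
        with pytest.raises(ValueError):
            tf_conservation(ca, labels, ca, labels, omap, [(0, 0), (1, 1)])
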