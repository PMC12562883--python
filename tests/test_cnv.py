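"""CNV smoothing, state calling, weights, scores, levels, arm landscape."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cnvscape as cs
from cnvscape.cnv import CNVState, DEFAULT_WEIGHTS


def _flat_annotation(n_genes, chrom="1", arm="1q"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{j}" for j in range(n_genes)],
            "chrom": chrom,
            "arm": arm,
            "start": np.arange(n_genes) * 10,
            "rank": np.arange(n_genes),
        }
    )


class TestSmoothing:
    def test_window_one_is_identity_after_clamp_and_recentre(self, rng):
        X = rng.normal(2.0, 0.5, size=(30, 40)).clip(0)
        ann = _flat_annotation(40)
        ref = np.zeros(30, bool)
        ref[:15] = True
        S, kept = cs.smooth_relative_expression(X, ann, ref, min_mean_cutoff=0,
                                                window=1, clamp=3.0)
        R = X - X[ref].mean(axis=0)
        lim = 3.0 * R[ref].std()
        R = np.clip(R, -lim, lim)
        R = R - np.median(R, axis=1, keepdims=True)
        assert np.allclose(S, R, atol=1e-12)

    def test_null_tumor_residuals_respect_clamp_bound(self, null_sim):
        _, adata, _ = null_sim
        adata, _ = cs.qc_filter(adata)
        X = cs.normalize_log(adata.X, cell_ids=adata.obs_names)
        ref = (adata.obs["group"] == "reference").to_numpy()
        ann = adata.var.reset_index().rename(columns={"index": "gene_id"})
        S, _ = cs.smooth_relative_expression(X, ann, ref)
        raw_ref_sd = np.std(
            X[ref] - X[ref].mean(axis=0)
        )
        assert (np.abs(S[~ref]) <= 3.0 * raw_ref_sd).mean() >= 0.99

    def test_reference_cells_centre_at_zero_median(self, processed):
        S, ref = processed["smoothed"], processed["ref"]
        assert np.allclose(np.median(S[ref], axis=1), 0.0, atol=1e-12)

    def test_planted_gain_arm_has_elevated_residual(self, processed):
        adata, truth = processed["adata"], processed["truth"]
        S, kept = processed["smoothed"], processed["kept"]
        carriers = (adata.obs["clone"] == "clone_mid").to_numpy()
        on_arm = (kept["arm"] == "1q").to_numpy()
        diploid = ~kept["arm"].isin(["1q"]).to_numpy()
        gained = S[np.ix_(carriers, on_arm)].mean()
        rest = S[np.ix_(carriers, diploid)].mean()
        assert gained > rest
        assert gained > 0

    def test_cutoff_drops_low_expression_genes(self, rng):
        X = rng.normal(1.0, 0.1, size=(30, 10)).clip(0)
        X[:, 3] = 0.01
        ann = _flat_annotation(10)
        ref = np.ones(30, bool)
        ref[20:] = False
        _, kept = cs.smooth_relative_expression(X, ann, ref, min_mean_cutoff=0.1)
        assert "g3" not in set(kept["gene_id"])

    def test_requires_reference_cells(self, rng):
        X = rng.normal(size=(12, 5)).clip(0)
        with pytest.raises(ValueError, match="reference"):
            cs.smooth_relative_expression(X, _flat_annotation(5),
                                          np.zeros(12, bool))


class TestCallStates:
    def _matrix_with_unit_ref_sd(self, values):
        """Reference rows alternate +-1 (SD exactly 1); one query row."""
        ref_block = np.tile([1.0, -1.0], (20, len(values) // 2 + 1))[:, : len(values)]
        S = np.vstack([ref_block, np.asarray(values, float)])
        ref = np.ones(len(S), bool)
        ref[-1] = False
        return S, ref

    def test_all_zero_residuals_are_degenerate(self):
        with pytest.raises(ValueError, match="SD is zero"):
            cs.call_states(np.zeros((20, 6)), np.ones(20, bool))

    @pytest.mark.parametrize(
        "residual,state",
        [
            (0.0, CNVState.NEUTRAL),
            (1.49, CNVState.NEUTRAL),
            (1.5, CNVState.ONE_COPY_GAIN),  # boundary maps upward
            (2.9, CNVState.ONE_COPY_GAIN),
            (3.0, CNVState.TWO_COPY_GAIN),
            (4.5, CNVState.MULTI_COPY_GAIN),
            (9.0, CNVState.MULTI_COPY_GAIN),
            (-1.5, CNVState.ONE_COPY_LOSS),
            (-3.0, CNVState.COMPLETE_LOSS),
            (-8.0, CNVState.COMPLETE_LOSS),  # losses saturate
        ],
    )
    def test_quantisation_boundaries(self, residual, state):
        S, ref = self._matrix_with_unit_ref_sd([residual, 0.0])
        states = cs.call_states(S, ref, sd_multipliers=(1.5, 3.0, 4.5))
        assert states[-1, 0] == int(state)

    def test_planted_one_copy_loss_called_as_loss(self, processed):
        adata = processed["adata"]
        kept, states = processed["kept"], processed["states"]
        carriers = (adata.obs["clone"] == "clone_high").to_numpy()
        on_arm = (kept["arm"] == "3q").to_numpy()
        block = states[np.ix_(carriers, on_arm)]
        loss = np.isin(block, [int(CNVState.ONE_COPY_LOSS),
                               int(CNVState.COMPLETE_LOSS)])
        assert loss.mean() >= 0.8

    def test_null_false_positive_rate_below_five_percent(self):
        """No planted events: tumor non-neutral call fraction stays <= 5%
        at default thresholds (mean over seeds; tolerance is the bound
        itself, each seed contributing ~1,200 cells)."""
        fracs = []
        for seed in (101, 102, 103):
            cfg = cs.default_config(seed)
            for clone in cfg.clones:
                clone.arm_events = {}
            ann = cs.simulate_gene_annotation(cfg.n_chromosomes,
                                              cfg.genes_per_arm, seed=seed)
            adata, _ = cs.simulate_counts(cfg, ann)
            adata, _ = cs.qc_filter(adata)
            X = cs.normalize_log(adata.X, cell_ids=adata.obs_names)
            ref = (adata.obs["group"] == "reference").to_numpy()
            annd = adata.var.reset_index().rename(columns={"index": "gene_id"})
            S, _ = cs.smooth_relative_expression(X, annd, ref)
            states = cs.call_states(S, ref)
            fracs.append((states[~ref] != int(CNVState.NEUTRAL)).mean())
        assert np.mean(fracs) <= 0.05


class TestWeightsAndScores:
    @pytest.mark.parametrize(
        "state,weight",
        [
            (CNVState.MULTI_COPY_GAIN, 3),
            (CNVState.TWO_COPY_GAIN, 2),
            (CNVState.ONE_COPY_GAIN, 1),
            (CNVState.ONE_COPY_LOSS, 1),
            (CNVState.COMPLETE_LOSS, 2),
            (CNVState.NEUTRAL, 0),
        ],
    )
    def test_default_weight_map(self, state, weight):
        assert cs.state_weight(state) == weight

    def test_invalid_weight_maps_rejected(self):
        bad = dict(DEFAULT_WEIGHTS)
        bad[CNVState.NEUTRAL] = 1
        with pytest.raises(ValueError, match="neutral"):
            cs.state_weight(CNVState.NEUTRAL, bad)
        with pytest.raises(ValueError, match="six states"):
            cs.state_weight(CNVState.NEUTRAL, {CNVState.NEUTRAL: 0})

    def test_cell_scores(self):
        neutral = int(CNVState.NEUTRAL)
        states = np.full((3, 3), neutral, dtype=np.int8)
        states[1, 0] = int(CNVState.MULTI_COPY_GAIN)
        states[2] = [int(CNVState.TWO_COPY_GAIN), int(CNVState.ONE_COPY_LOSS),
                     int(CNVState.COMPLETE_LOSS)]
        assert list(cs.cell_cnv_score(states)) == [0, 3, 2 + 1 + 2]

    @given(st.integers(0, 5), st.integers(0, 5))
    @settings(max_examples=36, deadline=None, derandomize=True)
    def test_score_monotone_under_state_promotion(self, s_from, s_to):
        """Promoting one gene to a higher-weight state never lowers the score."""
        table = {s: cs.state_weight(s) for s in CNVState}
        if table[CNVState(s_to)] < table[CNVState(s_from)]:
            s_from, s_to = s_to, s_from
        states = np.full((1, 5), int(CNVState.NEUTRAL), dtype=np.int8)
        states[0, 2] = s_from
        lo = cs.cell_cnv_score(states)[0]
        states[0, 2] = s_to
        hi = cs.cell_cnv_score(states)[0]
        assert hi >= lo

    def test_score_invariant_to_gene_permutation(self, processed, rng):
        states = processed["states"]
        perm = rng.permutation(states.shape[1])
        assert np.array_equal(cs.cell_cnv_score(states),
                              cs.cell_cnv_score(states[:, perm]))


class TestLevels:
    def test_null_tumor_mostly_low(self, rng):
        ref = rng.poisson(20, size=200).astype(float)
        tumor = rng.poisson(20, size=500).astype(float)
        levels = cs.classify_cnv_level(tumor, ref)
        assert (np.asarray(levels) == "low").mean() >= 0.95

    def test_three_clones_ordered_and_modal(self, processed):
        adata = processed["adata"]
        scores, ref = processed["scores"], processed["ref"]
        clones = adata.obs["clone"][~ref].to_numpy()
        tumor_scores = scores[~ref]
        means = pd.Series(tumor_scores).groupby(clones).mean()
        assert means["clone_low"] < means["clone_mid"] < means["clone_high"]
        levels = cs.classify_cnv_level(tumor_scores, scores[ref])
        modal = (
            pd.DataFrame({"clone": clones, "level": np.asarray(levels)})
            .groupby("clone")["level"].agg(lambda s: s.mode().iloc[0])
        )
        assert modal["clone_low"] == "low"
        assert modal["clone_mid"] == "medium"
        assert modal["clone_high"] == "high"

    def test_monotone_in_score(self, rng):
        ref = rng.poisson(20, size=100).astype(float)
        tumor = np.sort(rng.poisson(60, size=300).astype(float))
        levels = np.asarray(cs.classify_cnv_level(tumor, ref))
        order = {"low": 0, "medium": 1, "high": 2}
        codes = np.array([order[l] for l in levels])
        assert np.all(np.diff(codes) >= 0)

    def test_permutation_equivariance(self, rng):
        ref = rng.poisson(20, size=50).astype(float)
        tumor = rng.poisson(40, size=80).astype(float)
        perm = rng.permutation(80)
        a = np.asarray(cs.classify_cnv_level(tumor, ref))
        b = np.asarray(cs.classify_cnv_level(tumor[perm], ref))
        assert np.array_equal(a[perm], b)

    def test_all_below_baseline_warns_all_low(self, rng):
        ref = rng.poisson(50, size=100).astype(float)
        with pytest.warns(UserWarning, match="baseline"):
            levels = cs.classify_cnv_level(np.zeros(20), ref)
        assert (np.asarray(levels) == "low").all()


class TestArmLandscape:
    def test_all_neutral_gives_zero_scores(self):
        ann = _flat_annotation(6)
        states = np.full((4, 6), int(CNVState.NEUTRAL), dtype=np.int8)
        table = cs.arm_event_landscape(states, ann, ["g1"] * 4)
        assert (table["score"] == 0).all()

    def test_single_gain_arm_dominates(self, rng):
        """One clone, one planted gain arm: that arm's gain score dwarfs
        every other arm/direction score (exact zeros are impossible under
        count noise)."""
        cfg = cs.SimulationConfig(
            n_chromosomes=2, genes_per_arm=60, n_reference_cells=150,
            clones=[cs.CloneSpec("c1", 150, {"1q": 4})],
            activity_gene_sets={}, seed=21,
        )
        ann = cs.simulate_gene_annotation(2, 60, seed=21)
        adata, _ = cs.simulate_counts(cfg, ann)
        adata, _ = cs.qc_filter(adata)
        X = cs.normalize_log(adata.X, cell_ids=adata.obs_names)
        ref = (adata.obs["group"] == "reference").to_numpy()
        annd = adata.var.reset_index().rename(columns={"index": "gene_id"})
        S, kept = cs.smooth_relative_expression(X, annd, ref)
        states = cs.call_states(S, ref)
        table = cs.arm_event_landscape(states, kept,
                                       adata.obs["group"].astype(str))
        tumor = table[table["group"] == "tumor"].set_index(["arm", "direction"])
        planted = tumor.loc[("1q", "gain"), "score"]
        others = tumor.drop(index=("1q", "gain"))["score"]
        assert planted > 10 * others.max()
        assert tumor.loc[("1q", "loss"), "score"] < 0.1 * planted

    def test_per_cell_decomposition_matches_cnv_score(self, processed):
        """Summing per-arm gain+loss weighted sums over a one-cell group
        reproduces that cell's CNV score exactly."""
        states, kept = processed["states"], processed["kept"]
        scores = processed["scores"]
        take = [0, 57, 411, 800]
        groups = np.array([f"cell{i}" for i in range(states.shape[0])])
        table = cs.arm_event_landscape(states[take], kept, groups[take])
        total = table.groupby("group")["score"].sum()
        for i in take:
            assert total[f"cell{i}"] == pytest.approx(scores[i])

    def test_unknown_grouping_rejected(self, processed):
        with pytest.raises(ValueError, match="length"):
            cs.arm_event_landscape(processed["states"], processed["kept"],
                                   ["x", "y"])
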