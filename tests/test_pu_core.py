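import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binpu.backbone import ConstantBackbone, RuleBackbone
from binpu.errors import (
    ConsistencyError,
    ParameterError,
    UndefinedMetricError,
)
from binpu.pu_core import (
    BinAssignment,
    BinPUConfig,
    EntityIndex,
    PositiveSet,
    PseudoLabelConfig,
    ScoreTable,
    UnlabeledSet,
    assign_pseudo_labels,
    build_bin_training_set,
    compute_scr,
    generate_unlabeled,
    inject_spies,
    partition_bins,
    run_binpu,
    score_ensemble,
    split_spies,
)
from binpu.records import SPY, UNLABELED, CompoundRecord, InteractionPair, ProteinRecord


def _world(n_c, n_p):
    compounds = [CompoundRecord(f"c{i:03d}", f"CC{'O' * (i % 5)}N{i}") for i in range(n_c)]
    proteins = [ProteinRecord(f"p{j:03d}", f"ACDE{'G' * (j % 4)}K{j % 10}".replace("0", "A")
                              .replace("1", "C").replace("2", "D").replace("3", "E")
                              .replace("4", "F").replace("5", "G").replace("6", "H")
                              .replace("7", "I").replace("8", "K").replace("9", "L"))
                for j in range(n_p)]
    return compounds, proteins


class TestGenerateUnlabeled:
    def test_small_cross_product_matches_brute_force(self):
        compounds, proteins = _world(3, 2)
        positives = PositiveSet((
            InteractionPair("c000", "p000"), InteractionPair("c001", "p001"),
        ))
        out = generate_unlabeled(compounds, proteins, positives)
        brute = {
            (c.compound_id, p.protein_id)
            for c in compounds for p in proteins
        } - positives.keys
        assert {p.key for p in out.pairs} == brute
        assert len(out) == 4

    def test_emission_order_is_lexicographic(self):
        compounds, proteins = _world(3, 3)
        out = generate_unlabeled(compounds, proteins, PositiveSet(()))
        keys = [p.key for p in out.pairs]
        assert keys == sorted(keys)

    def test_paper_scale_count(self):
        # 291 x 241 cross product minus 500 positives = 69,631
        compounds, proteins = _world(291, 241)
        rng = np.random.default_rng(0)
        chosen = rng.choice(291 * 241, size=500, replace=False)
        positives = PositiveSet(tuple(
            InteractionPair(compounds[i // 241].compound_id, proteins[i % 241].protein_id)
            for i in sorted(chosen.tolist())
        ))
        out = generate_unlabeled(compounds, proteins, positives)
        assert len(out) == 69631

    def test_exhausted_cross_product_is_empty(self):
        compounds, proteins = _world(1, 1)
        positives = PositiveSet((InteractionPair("c000", "p000"),))
        assert len(generate_unlabeled(compounds, proteins, positives)) == 0

    def test_unknown_entity_in_positives_rejected(self):
        compounds, proteins = _world(2, 2)
        with pytest.raises(ConsistencyError):
            generate_unlabeled(
                compounds, proteins, PositiveSet((InteractionPair("cX", "p000"),))
            )

    def test_empty_world_rejected(self):
        with pytest.raises(ParameterError):
            generate_unlabeled([], [], PositiveSet(()))


class TestSplitSpies:
    def _positives(self, n):
        return PositiveSet(tuple(
            InteractionPair(f"c{i:03d}", f"p{i:03d}") for i in range(n)
        ))

    def test_500_at_20_percent_gives_100_spies(self):
        split = split_spies(self._positives(500), 0.2, seed=1)
        assert len(split.spies) == 100
        assert len(split.train_positives) == 400

    def test_zero_fraction_is_identity(self):
        positives = self._positives(10)
        split = split_spies(positives, 0.0, seed=1)
        assert split.spies == ()
        assert split.train_positives.keys == positives.keys

    def test_reproducible_and_seed_sensitive(self):
        positives = self._positives(500)
        a = split_spies(positives, 0.2, seed=5)
        b = split_spies(positives, 0.2, seed=5)
        c = split_spies(positives, 0.2, seed=6)
        assert {s.key for s in a.spies} == {s.key for s in b.spies}
        assert {s.key for s in a.spies} != {s.key for s in c.spies}

    def test_split_partitions_input(self):
        positives = self._positives(37)
        split = split_spies(positives, 0.3, seed=2)
        spy_keys = {s.key for s in split.spies}
        assert spy_keys | split.train_positives.keys == positives.keys
        assert not (spy_keys & split.train_positives.keys)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ParameterError):
            split_spies(self._positives(5), 1.0, seed=0)


class TestInjectSpies:
    def test_cardinality_and_flags(self):
        unlabeled = UnlabeledSet(tuple(
            InteractionPair(f"c{i}", "pU", label=UNLABELED) for i in range(20)
        ))
        spies = [InteractionPair(f"s{i}", "pS") for i in range(3)]
        out = inject_spies(unlabeled, spies)
        assert len(out) == 23
        assert len(out.spy_keys) == 3

    def test_empty_spy_list_is_identity(self):
        unlabeled = UnlabeledSet((InteractionPair("c1", "p1", label=UNLABELED),))
        assert inject_spies(unlabeled, []).pairs == unlabeled.pairs

    def test_overlap_rejected(self):
        unlabeled = UnlabeledSet((InteractionPair("c1", "p1", label=UNLABELED),))
        with pytest.raises(ConsistencyError):
            inject_spies(unlabeled, [InteractionPair("c1", "p1")])

    def test_spy_flag_masked_in_bin_training(self):
        # build_bin_training_set labels every pool member 0, spies included
        unlabeled = UnlabeledSet((InteractionPair("c1", "p1", label=UNLABELED),))
        pool = inject_spies(unlabeled, [InteractionPair("c2", "p1")])
        train_pos = PositiveSet((InteractionPair("c3", "p1"),))
        rows, labels = build_bin_training_set(list(pool.pairs), train_pos)
        spy_label = [lab for row, lab in zip(rows, labels) if row.key == ("c2", "p1")]
        assert spy_label == [0.0]


def _unlabeled(n):
    return UnlabeledSet(tuple(
        InteractionPair(f"c{i:04d}", "p0", label=UNLABELED) for i in range(n)
    ))


class TestPartitionBins:
    def test_sizes_differ_by_at_most_one_69731_into_20(self):
        # 69,731 = 20 * 3,486 + 11: eleven bins of 3,487, nine of 3,486
        bins = partition_bins(_unlabeled(69731), K=20, seed=0)
        sizes = sorted(
            np.bincount(list(bins.membership.values()))[1:].tolist(), reverse=True
        )
        assert sizes == [3487] * 11 + [3486] * 9

    def test_k1_single_bin(self):
        u = _unlabeled(10)
        bins = partition_bins(u, K=1, seed=0)
        assert set(bins.membership.values()) == {1}

    def test_10_into_3_pigeonhole(self):
        bins = partition_bins(_unlabeled(10), K=3, seed=0)
        sizes = sorted(np.bincount(list(bins.membership.values()))[1:].tolist())
        assert sizes == [3, 3, 4]

    def test_k_larger_than_pool_rejected(self):
        with pytest.raises(ParameterError):
            partition_bins(_unlabeled(3), K=4, seed=0)

    @given(
        n=st.integers(min_value=1, max_value=300),
        k=st.integers(min_value=1, max_value=40),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(deadline=None, max_examples=40)
    def test_partition_property(self, n, k, seed):
        if k > n:
            return
        u = _unlabeled(n)
        bins = partition_bins(u, K=k, seed=seed)
        assert set(bins.membership) == {p.key for p in u.pairs}  # disjoint cover
        sizes = np.bincount(list(bins.membership.values()), minlength=k + 1)[1:]
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1


class TestBuildBinTrainingSet:
    def test_cardinalities(self):
        positives = PositiveSet(tuple(
            InteractionPair(f"P{i}", "pp") for i in range(400)
        ))
        members = [InteractionPair(f"u{i}", "pp", label=UNLABELED) for i in range(3487)]
        rows, labels = build_bin_training_set(members, positives)
        assert len(rows) == 3887
        assert int(labels.sum()) == 400

    def test_empty_bin_gives_just_positives(self):
        positives = PositiveSet((InteractionPair("c1", "p1"),))
        rows, labels = build_bin_training_set([], positives)
        assert len(rows) == 1 and labels.tolist() == [1.0]

    def test_every_bin_contains_all_training_positives(self):
        positives = PositiveSet(tuple(InteractionPair(f"P{i}", "pp") for i in range(5)))
        bins = partition_bins(_unlabeled(30), K=4, seed=3)
        for k in range(1, 5):
            rows, labels = build_bin_training_set(bins.bin_members(k), positives)
            pos_keys = {r.key for r, lab in zip(rows, labels) if lab == 1.0}
            assert pos_keys == positives.keys

    def test_overlap_rejected(self):
        positives = PositiveSet((InteractionPair("c1", "p1"),))
        with pytest.raises(ConsistencyError):
            build_bin_training_set([InteractionPair("c1", "p1", label=UNLABELED)], positives)


def _scored_world(n_c=5, n_p=4, n_pos=3, K=3, seed=0, rule=None, scope="all"):
    compounds, proteins = _world(n_c, n_p)
    positives = PositiveSet(tuple(
        InteractionPair(compounds[i].compound_id, proteins[i % n_p].protein_id)
        for i in range(n_pos)
    ))
    entities = EntityIndex(compounds, proteins)
    unlabeled = generate_unlabeled(compounds, proteins, positives)
    bins = partition_bins(unlabeled, K=K, seed=seed)
    factory = (lambda: ConstantBackbone(0.7)) if rule is None else (lambda: RuleBackbone(rule))
    scores = score_ensemble(bins, positives, factory, entities, seed, score_scope=scope)
    return compounds, proteins, positives, unlabeled, bins, scores


class TestScoreEnsemble:
    def test_constant_backbone_gives_constant_means(self):
        *_, scores = _scored_world()
        assert all(v == pytest.approx(0.7) for v in scores.mean.values())

    def test_mean_is_arithmetic_mean_of_per_bin_scores(self):
        rule = lambda s, q: (hash((s, q)) % 97) / 96  # deterministic pair rule
        *_, scores = _scored_world(rule=rule)
        for key, entries in scores.per_bin.items():
            assert scores.mean[key] == pytest.approx(
                np.mean([v for _, v in entries])
            )

    def test_k1_mean_equals_single_model_score(self):
        *_, scores = _scored_world(K=1, rule=lambda s, q: 0.31)
        assert all(len(v) == 1 for v in scores.per_bin.values())
        assert all(v == pytest.approx(0.31) for v in scores.mean.values())

    def test_all_scope_collects_k_scores_per_pair(self):
        *_, scores = _scored_world(K=3)
        assert all(len(v) == 3 for v in scores.per_bin.values())

    def test_held_out_scope_skips_own_bin(self):
        compounds, proteins, positives, unlabeled, bins, scores = _scored_world(
            K=3, scope="held-out"
        )
        for p in unlabeled.pairs:
            own = bins.membership[p.key]
            bins_seen = [k for k, _ in scores.per_bin[p.key]]
            assert own not in bins_seen
            assert len(bins_seen) == 2

    def test_bin_order_invariance(self):
        # permuting bin labels leaves every mean unchanged for fixed models
        rule = lambda s, q: (len(s) * 7 % 13) / 13
        *_, scores_a = _scored_world(rule=rule, seed=1)
        *_, scores_b = _scored_world(rule=rule, seed=2)  # different partition
        for key in scores_a.mean:
            assert scores_a.mean[key] == pytest.approx(scores_b.mean[key])

    def test_out_of_range_backbone_rejected(self):
        with pytest.raises(Exception):
            _scored_world(rule=lambda s, q: 1.3)


def _table(values, labels=None):
    pairs = tuple(
        InteractionPair(f"c{i:02d}", "p0", label=(labels[i] if labels else UNLABELED))
        for i in range(len(values))
    )
    return ScoreTable(
        mean={p.key: v for p, v in zip(pairs, values)},
        per_bin={p.key: ((1, v),) for p, v in zip(pairs, values)},
        pairs=pairs,
    )


class TestAssignPseudoLabels:
    def test_strict_threshold_enumeration(self):
        scores = _table([0.95, 0.81, 0.80, 0.50, 0.20, 0.19])
        out = assign_pseudo_labels(scores, PseudoLabelConfig(0.8, 0.2, "score"))
        assert sorted(p.score for p in out.psi_pos) == [0.81, 0.95]
        assert [p.score for p in out.psi_neg] == [0.19]
        assert sorted(p.score for p in out.residual) == [0.20, 0.50, 0.80]

    def test_boundary_score_goes_to_residual(self):
        out = assign_pseudo_labels(_table([0.8]), PseudoLabelConfig(0.8, 0.2, "score"))
        assert len(out.residual) == 1 and not out.psi_pos

    def test_all_middling_scores_give_empty_pseudo_sets(self):
        out = assign_pseudo_labels(_table([0.5] * 6), PseudoLabelConfig(0.8, 0.2, "score"))
        assert not out.psi_pos and not out.psi_neg and len(out.residual) == 6

    def test_percentile_mode_takes_fractions(self):
        values = [i / 10 for i in range(10)]
        out = assign_pseudo_labels(
            _table(values), PseudoLabelConfig(0.2, 0.2, "percentile")
        )
        assert sorted(p.score for p in out.psi_pos) == [0.8, 0.9]
        assert sorted(p.score for p in out.psi_neg) == [0.0, 0.1]
        assert len(out.residual) == 6

    def test_percentile_ties_broken_lexicographically(self):
        out = assign_pseudo_labels(
            _table([0.5] * 5), PseudoLabelConfig(0.2, 0.2, "percentile")
        )
        # with all-equal scores the extremes are decided by pair id order
        assert [p.compound_id for p in out.psi_neg] == ["c00"]
        assert [p.compound_id for p in out.psi_pos] == ["c04"]

    def test_spies_never_emitted(self):
        labels = [SPY, UNLABELED, UNLABELED]
        out = assign_pseudo_labels(
            _table([0.99, 0.98, 0.01], labels), PseudoLabelConfig(0.8, 0.2, "score")
        )
        emitted = {p.key for p in out.psi_pos + out.psi_neg + out.residual}
        assert ("c00", "p0") not in emitted
        assert len(out) == 2

    def test_pseudo_sets_partition_scored_pool(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 1, 40).round(3).tolist()
        out = assign_pseudo_labels(_table(values), PseudoLabelConfig(0.8, 0.2, "score"))
        keys = [p.key for p in out.psi_pos + out.psi_neg + out.residual]
        assert len(keys) == 40 and len(set(keys)) == 40

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            PseudoLabelConfig(0.2, 0.8, "score")


class TestComputeScr:
    def test_ratios(self):
        spies = [InteractionPair(f"c{i:02d}", "p0", label=SPY) for i in range(4)]
        scores = _table([0.9, 0.9, 0.9, 0.9], labels=[SPY] * 4)
        assert compute_scr(scores, spies, 0.5).scr == 1.0
        low = _table([0.1, 0.1, 0.1, 0.1], labels=[SPY] * 4)
        assert compute_scr(low, spies, 0.5).scr == 0.0

    def test_92_of_100(self):
        spies = [InteractionPair(f"c{i:02d}", "p0", label=SPY) for i in range(100)]
        values = [0.9] * 92 + [0.1] * 8
        report = compute_scr(_table(values, labels=[SPY] * 100), spies, 0.5)
        assert report.scr == pytest.approx(0.92)
        assert report.n_captured == 92

    def test_zero_spies_rejected(self):
        with pytest.raises(UndefinedMetricError):
            compute_scr(_table([0.5]), [], 0.5)


class TestRunBinPU:
    def _run(self, seed=1, **kwargs):
        compounds, proteins = _world(6, 5)
        positives = PositiveSet(tuple(
            InteractionPair(compounds[i].compound_id, proteins[i].protein_id)
            for i in range(5)
        ))
        rule = lambda s, q: ((len(s) * 31 + len(q) * 17) % 89) / 88
        config = BinPUConfig(K=3, spy_fraction=0.2, **kwargs)
        return run_binpu(
            positives, compounds, proteins, lambda: RuleBackbone(rule), seed, config
        )

    def test_deterministic_for_fixed_seed(self):
        a, b = self._run(seed=7), self._run(seed=7)
        assert [p.key for p in a.pseudo_labels.psi_pos] == [p.key for p in b.pseudo_labels.psi_pos]
        assert a.scores.mean == b.scores.mean
        assert a.spy_report == b.spy_report

    def test_unattainable_threshold_gives_empty_psi_pos(self):
        out = self._run(pseudo=PseudoLabelConfig(theta_u=1.0, theta_l=0.0, mode="score"))
        assert not out.pseudo_labels.psi_pos
        assert not out.pseudo_labels.psi_neg

    def test_manifest_cardinalities_consistent(self):
        out = self._run()
        m = out.manifest
        assert m["n_unlabeled"] == 6 * 5 - 5
        assert m["n_pool"] == m["n_unlabeled"] + m["n_spies"]
        assert (
            m["n_pseudo_positive"] + m["n_pseudo_negative"] + m["n_residual"]
            == m["n_unlabeled"]
        )


class TestBruteForceOracleEquivalence:
    """Pipeline vs. an independent brute-force recomputation on a small
    instance with a deterministic stub backbone."""

    def test_end_to_end_exact_match(self):
        compounds, proteins = _world(7, 6)  # 42-pair cross product
        positives = PositiveSet(tuple(
            InteractionPair(compounds[i].compound_id, proteins[(i * 2) % 6].protein_id)
            for i in range(5)
        ))
        rule = lambda s, q: ((3 * len(s) + 5 * len(q) + len(s) * len(q)) % 101) / 100
        seed, K = 11, 4
        config = BinPUConfig(K=K, spy_fraction=0.2)
        result = run_binpu(
            positives, compounds, proteins, lambda: RuleBackbone(rule), seed, config
        )

        # ---- independent recomputation ---------------------------------
        from binpu.pu_core import stage_seed

        smiles = {c.compound_id: c.smiles for c in compounds}
        seqs = {p.protein_id: p.sequence for p in proteins}
        cross = sorted(
            (c.compound_id, p.protein_id) for c in compounds for p in proteins
        )
        unl = [k for k in cross if k not in positives.keys]
        # spy split replicated with the same stage seed
        rng = np.random.default_rng(stage_seed(seed, 1))
        idx = rng.permutation(len(positives))
        n_spies = round(0.2 * len(positives))
        spy_keys = {positives.pairs[i].key for i in idx[:n_spies]}
        pool = unl + sorted(spy_keys)
        # partition replicated with the same stage seed
        rng = np.random.default_rng(stage_seed(seed, 2))
        order = rng.permutation(len(pool))
        base, extra = divmod(len(pool), K)
        member_of = {}
        pos = 0
        for k in range(1, K + 1):
            size = base + (1 if k <= extra else 0)
            for i in order[pos:pos + size]:
                member_of[pool[i]] = k
            pos += size
        # the stub ignores training, so Pr-bar is the mean of K identical
        # per-pair scores = the rule itself
        expected_mean = {
            key: rule(smiles[key[0]], seqs[key[1]]) for key in pool
        }
        for key, value in expected_mean.items():
            assert result.scores.mean[key] == pytest.approx(value, abs=1e-12)
        # pseudo labels by strict thresholds on non-spies
        exp_pos = {k for k in unl if expected_mean[k] > 0.8}
        exp_neg = {k for k in unl if expected_mean[k] < 0.2}
        assert {p.key for p in result.pseudo_labels.psi_pos} == exp_pos
        assert {p.key for p in result.pseudo_labels.psi_neg} == exp_neg
        # SCR by direct count
        exp_scr = sum(1 for k in spy_keys if expected_mean[k] > 0.5) / len(spy_keys)
        assert result.spy_report.scr == pytest.approx(exp_scr)
        # bin construction: every bin's training set = Dtrp + its members
        bins_seen = {}
        for key, k in member_of.items():
            bins_seen.setdefault(k, set()).add(key)
        sizes = [len(v) for v in bins_seen.values()]
        assert max(sizes) - min(sizes) <= 1
        assert set(member_of) == set(pool)
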