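"""Robustness drivers, block-size sweep, and tree building."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

import dendropy

from fpe.experiments import (
    ExperimentConfig,
    TrialSummary,
    block_size_sweep,
    build_tree,
    insert_noise,
    noise_robustness,
    shuffle_robustness,
)
from fpe.distance import DistanceMatrix
from fpe.io_prep import CleanSequence
from fpe.mining import MiningParams
from fpe.reference import beta_globin_reference_matrix
from fpe.testdata import random_sequence


@pytest.fixture(scope="module")
def seq_1424():
    """Random stand-in at the scale of the human benchmark gene (1424 nt)."""
    return random_sequence(1424, seed=42)


class TestShuffleRobustness:
    CFG = ExperimentConfig(block_size=100, n_trials=6, seed=5, segment_fraction=0.1)

    def test_seed_determinism(self, seq_1424):
        a = shuffle_robustness(seq_1424, self.CFG)
        b = shuffle_robustness(seq_1424, self.CFG)
        assert a == b

    def test_summary_consistent_with_trials(self, seq_1424):
        s = shuffle_robustness(seq_1424, self.CFG)
        assert len(s.per_trial) == self.CFG.n_trials
        assert s.mean == pytest.approx(np.mean(s.per_trial))
        assert s.std == pytest.approx(np.std(s.per_trial, ddof=0))

    def test_homopolymer_segment_is_shuffle_invariant(self):
        seq = CleanSequence(id="polyA", bases="A" * 1000)
        s = shuffle_robustness(seq, ExperimentConfig(block_size=50, n_trials=4, seed=1))
        assert s.per_trial == (0.0,) * 4

    def test_segment_shorter_than_block_rejected(self, seq_1424):
        cfg = ExperimentConfig(block_size=200, n_trials=2, seed=0, segment_fraction=0.05)
        with pytest.raises(ValueError, match="zero blocks"):
            shuffle_robustness(seq_1424, cfg)


class TestNoiseRobustness:
    def test_zero_noise_zero_distance(self, seq_1424):
        cfg = ExperimentConfig(block_size=3000, n_trials=3, seed=2, noise_ratio=0.0)
        assert noise_robustness(seq_1424, cfg).per_trial == (0.0, 0.0, 0.0)

    def test_distance_grows_with_noise(self, seq_1424):
        # qualitative monotone trend over the sweep, not per-step monotonicity
        ratios = [0.01, 0.05, 0.1, 0.2, 0.3, 0.5]
        means = [
            noise_robustness(
                seq_1424,
                ExperimentConfig(block_size=3000, n_trials=3, seed=9, noise_ratio=r),
            ).mean
            for r in ratios
        ]
        rho = scipy_stats.spearmanr(ratios, means).statistic
        assert rho > 0

    def test_seed_determinism(self, seq_1424):
        cfg = ExperimentConfig(block_size=3000, n_trials=2, seed=4, noise_ratio=0.1)
        assert noise_robustness(seq_1424, cfg) == noise_robustness(seq_1424, cfg)

    def test_insert_noise_length_and_subsequence(self, seq_1424):
        rng = np.random.default_rng(0)
        noisy = insert_noise(seq_1424, 50, rng)
        assert noisy.length == seq_1424.length + 50
        it = iter(noisy.bases)  # original must survive as a subsequence
        assert all(c in it for c in seq_1424.bases)


class TestBlockSizeSweep:
    def test_identical_sequences_all_zero(self, seq_1424):
        out = block_size_sweep(seq_1424, seq_1424, [100, 200], MiningParams(3, 2))
        assert [d for _, d in out] == [0.0, 0.0]

    def test_finer_blocks_give_larger_distance(self, seq_1424):
        other = random_sequence(1344, seed=43)
        out = dict(block_size_sweep(seq_1424, other, [50, 400], MiningParams(3, 2)))
        assert out[50] >= out[400]

    def test_oversized_block_rejected(self, seq_1424):
        with pytest.raises(ValueError, match="too large"):
            block_size_sweep(seq_1424, seq_1424, [2000], MiningParams(3, 2))


class TestBuildTree:
    def test_two_leaf_cherry(self):
        m = DistanceMatrix(labels=("a", "b"), values=np.array([[0.0, 0.4], [0.4, 0.0]]))
        newick = build_tree(m)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"a", "b"}
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(0.2)

    def test_ultrametric_heights_reproduced(self):
        # leaves a,b merge at 0.2; c joins at 0.6 -> cophenetic == input
        values = np.array(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]]
        )
        m = DistanceMatrix(labels=("a", "b", "c"), values=values)
        tree = dendropy.Tree.get(data=build_tree(m), schema="newick")
        tree.is_rooted = True
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(0.2)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(0.6)

    def test_benchmark_matrix_recovers_primate_clade(self):
        tree = dendropy.Tree.get(
            data=build_tree(beta_globin_reference_matrix()), schema="newick"
        )
        tree.is_rooted = True
        mrca = tree.mrca(taxon_labels={"human", "chimpanzee", "gorilla"})
        clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        assert clade == {"human", "chimpanzee", "gorilla"}

    def test_asymmetric_matrix_rejected(self):
        values = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            build_tree(DistanceMatrix(labels=("a", "b"), values=values))


def test_trial_summary_recompute():
    s = TrialSummary.from_trials([1.0, 2.0, 3.0])
    assert s.mean == 2.0
    assert s.std == pytest.approx(np.std([1, 2, 3]))


def test_experiment_config_validation():
    with pytest.raises(ValueError):
        ExperimentConfig(n_trials=0)
    with pytest.raises(ValueError):
        ExperimentConfig(segment_fraction=0.0)
    with pytest.raises(ValueError):
        ExperimentConfig(noise_ratio=-0.1)
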