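import pytest

from biorgroup import (
    GenericMolecule,
    MatchConfig,
    collection_stereo_stats,
    ingest_library,
    np_score,
    parse_molecule,
    stereocenter_counts,
    timeout_sensitivity,
    train_np_scorer,
)
from biorgroup.analytics import double_bond_stereo_counts, stratified_sample

NATURAL = [
    "C[C@H](O)CC(O)=O",
    "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H]1O",
    "C[C@@H]1CC[C@H](C(C)C)C(=O)C1",
]
SYNTHETIC = ["c1ccccc1C(=O)OC", "CC(C)(C)OC(=O)NC", "Clc1ccc(Cl)cc1"]


class TestStereocenters:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("C[C@H](N)C(=O)O", (1, 1)),   # assigned center
            ("CC(N)C(=O)O", (0, 1)),       # potential but unassigned
            ("CCO", (0, 0)),               # achiral
            ("*[C@@H](N)C(=O)O", (1, 1)),  # wildcards permitted
        ],
    )
    def test_defined_and_total_counts(self, smiles, expected):
        assert stereocenter_counts(parse_molecule(smiles)) == expected

    def test_assigning_a_center_never_decreases_counts(self):
        before = stereocenter_counts(parse_molecule("CC(N)C(=O)O"))
        after = stereocenter_counts(parse_molecule("C[C@H](N)C(=O)O"))
        assert after[0] >= before[0]
        assert after[1] == before[1]

    def test_double_bond_stereo_counted_separately(self):
        assert double_bond_stereo_counts(parse_molecule("C/C=C/C")) == (1, 1)
        assert double_bond_stereo_counts(parse_molecule("CC=CC")) == (0, 1)
        assert stereocenter_counts(parse_molecule("C/C=C/C")) == (0, 0)

    def test_collection_statistics_arithmetic(self):
        mols = [parse_molecule(s) for s in ["C[C@H](N)C(=O)O", "CC(N)C(=O)O"]]
        stats = collection_stereo_stats(mols)
        assert stats.mean_defined == pytest.approx(0.5)
        assert stats.mean_defined_plus_undefined == pytest.approx(1.0)
        assert stats.frac_with_at_least_one == pytest.approx(1.0)

    def test_achiral_collection_is_all_zero(self):
        stats = collection_stereo_stats([parse_molecule("CCO"), parse_molecule("CC")])
        assert (
            stats.mean_defined,
            stats.mean_defined_plus_undefined,
            stats.frac_with_at_least_one,
        ) == (0.0, 0.0, 0.0)

    def test_singleton_alanine(self):
        stats = collection_stereo_stats([parse_molecule("C[C@H](N)C(=O)O")])
        assert stats.mean_defined == 1.0
        assert stats.frac_with_at_least_one == 1.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            collection_stereo_stats([])


@pytest.fixture(scope="module")
def collections():
    return (
        [parse_molecule(s) for s in NATURAL],
        [parse_molecule(s) for s in SYNTHETIC],
    )


class TestNpScorer:

    def test_identical_training_collections_give_all_zero(self, collections):
        natural, _ = collections
        table = train_np_scorer(natural, natural)
        assert all(value == 0.0 for _, value in table.scores)
        assert np_score(natural[0], table) == 0.0

    def test_swapping_collections_negates_exactly(self, collections):
        natural, synthetic = collections
        forward = train_np_scorer(natural, synthetic)
        backward = train_np_scorer(synthetic, natural)
        for (key_f, val_f), (key_b, val_b) in zip(forward.scores, backward.scores):
            assert key_f == key_b
            assert val_f == -val_b
        probe = parse_molecule("CCO")
        assert np_score(probe, forward) == pytest.approx(-np_score(probe, backward))

    def test_natural_only_fragments_score_positive(self, collections):
        natural, synthetic = collections
        table = train_np_scorer(natural, synthetic)
        # a training natural molecule shares no fragments with the synthetics
        assert np_score(natural[1], table) > 0
        assert np_score(synthetic[2], table) < 0

    def test_empty_training_collection_rejected(self, collections):
        natural, _ = collections
        with pytest.raises(ValueError):
            train_np_scorer(natural, [])

    def test_no_heavy_atoms_rejected(self, collections):
        natural, synthetic = collections
        table = train_np_scorer(natural, synthetic)
        with pytest.raises(ValueError):
            np_score(parse_molecule("[H][H]"), table)


@pytest.fixture(scope="module")
def queries(mixed_fixture):
    return [GenericMolecule.from_smiles(s, [i]) for i, s in mixed_fixture.queries]


class TestTimeoutSensitivity:

    def test_no_slow_candidates_means_full_coverage(self, queries, mixed_store):
        rows = timeout_sensitivity(
            queries, mixed_store, timeouts=(2.0, 10.0, 20.0), sample_size=3
        )
        assert [row["coverage"] for row in rows] == [1.0, 1.0, 1.0]

    def test_planted_delays_shift_coverage_by_their_count(self, queries, mixed_store):
        slow = {1001, 1005}

        def cost(query, compound):
            return 5.0 if compound.cids[0] in slow else 0.1

        rows = timeout_sensitivity(
            queries, mixed_store, timeouts=(2.0, 10.0), sample_size=3, cost_model=cost
        )
        total = rows[0]["total_pairs"]
        slow_pairs = rows[0]["total_pairs"] - rows[0]["evaluated_pairs"]
        assert rows[1]["coverage"] - rows[0]["coverage"] == pytest.approx(
            slow_pairs / total
        )
        assert rows[1]["coverage"] == 1.0

    def test_coverage_monotone_in_timeout(self, queries, mixed_store):
        def cost(query, compound):
            return float(compound.cids[0] % 25)

        rows = timeout_sensitivity(
            queries, mixed_store, timeouts=(2.0, 10.0, 20.0), sample_size=3,
            cost_model=cost,
        )
        coverages = [row["coverage"] for row in rows]
        assert coverages == sorted(coverages)

    def test_oversized_sample_uses_all_queries_with_warning(self, queries, mixed_store):
        with pytest.warns(UserWarning):
            rows = timeout_sensitivity(
                queries, mixed_store, timeouts=(10.0,), sample_size=50
            )
        assert len(rows[0]["per_query_timeouts"]) == len(queries)

    def test_stratified_sampling_spans_the_weight_range(self, queries):
        sample = stratified_sample(queries, 2)
        ordered = sorted(q.exact_mol_wt for q in queries)
        assert sample[0].exact_mol_wt == ordered[0]
        assert sample[-1].exact_mol_wt == ordered[-1]

    def test_unsorted_timeouts_rejected(self, queries, mixed_store):
        with pytest.raises(ValueError):
            timeout_sensitivity(queries, mixed_store, timeouts=(10.0, 2.0))
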