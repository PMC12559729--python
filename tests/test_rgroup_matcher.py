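import pytest

from biorgroup import (
    GenericMolecule,
    MatchClass,
    MatchConfig,
    TIMEOUT,
    classify_match,
    classify_pair,
    expand_query,
    ingest_library,
    match_core,
    oracle_classify,
    parse_molecule,
)
from biorgroup.errors import OracleSizeError, StructureError
from biorgroup.fixtures import (
    EXTENDED,
    FixtureSpec,
    LIGHT_DECOY,
    MULTICOMPONENT_EXTENDED,
    NO_MATCH,
    SUPERSTRUCTURE,
    generate_fixture,
)

from conftest import pairs_with_truth

EXT = MatchClass.RGROUP_EXTENDED
SUP = MatchClass.CORE_SUPERSTRUCTURE

PHENYL = GenericMolecule.from_smiles("*c1ccccc1", ["q"])


def classify(query_smiles, candidate_smiles, **config_kwargs):
    query = GenericMolecule.from_smiles(query_smiles, ["q"])
    config = MatchConfig(**config_kwargs)
    return classify_pair(query, parse_molecule(candidate_smiles), config)


class TestWorkedExamples:
    @pytest.mark.parametrize(
        "candidate,expected",
        [
            ("Cc1ccccc1", EXT),       # one methyl, exactly at R
            ("Cc1ccccc1C", SUP),      # two additions, one R position
            ("c1ccccc1", EXT),        # hydrogen-only substituent at R
            ("CCO", None),            # no benzene core
        ],
    )
    def test_phenyl_query_classifications(self, candidate, expected):
        assert classify("*c1ccccc1", candidate) == expected

    def test_methyl_query_accepts_ethane(self):
        assert classify("*C", "CC") == EXT

    def test_methane_without_hydrogen_substituent_is_not_extended(self):
        assert classify("*C", "C", allow_hydrogen_substituent=False) != EXT

    def test_substituent_assignment_reported(self):
        query = GenericMolecule.from_smiles("*c1ccccc1", ["q"])
        match = match_core(query, parse_molecule("Cc1ccccc1"))
        groups = match.substituents()
        assert set(groups) == {1}
        # methyl carbon plus its three hydrogens
        assert len(groups[1]) == 4
        assert match.leftover_atoms == frozenset()


class TestStereochemistry:
    def test_defined_center_with_preserved_parity_is_extended(self):
        assert classify("*[C@@H](N)C(=O)O", "C[C@@H](N)C(=O)O") == EXT

    def test_inverted_center_at_anchor_still_core_matches_via_h(self):
        # wildcard can take the stereocenter's H, leaving the methyl off-site
        assert classify("*[C@@H](N)C(=O)O", "C[C@H](N)C(=O)O") == SUP

    def test_flipping_a_remote_defined_center_demotes_to_no_match(self):
        assert classify("*C[C@H](O)CC(N)=O", "CC[C@H](O)CC(N)=O") == EXT
        assert classify("*C[C@H](O)CC(N)=O", "CC[C@@H](O)CC(N)=O") is None

    def test_candidate_without_defined_center_does_not_match_defined_query(self):
        assert classify("*C[C@H](O)CC(N)=O", "CCC(O)CC(N)=O") is None

    def test_query_undefined_stereo_matches_anything(self):
        assert classify("*CC(O)CC(N)=O", "CC[C@H](O)CC(N)=O") == EXT
        assert classify("*CC(O)CC(N)=O", "CCC(O)CC(N)=O") == EXT

    def test_double_bond_configuration_enforced(self):
        assert classify("*/C=C/CC(=O)O", "C/C=C/CC(=O)O") == EXT
        assert classify("*/C=C/CC(=O)O", "CC=CCC(=O)O") is None

    def test_stereo_matching_can_be_disabled(self):
        flipped = classify(
            "*C[C@H](O)CC(N)=O", "CC[C@@H](O)CC(N)=O", match_defined_stereo=False
        )
        assert flipped == EXT


class TestStrictness:
    def test_formal_charge_must_match_on_core_atoms(self):
        assert classify("*CC(=O)[O-]", "CCC(=O)[O-]") == EXT
        assert classify("*CC(=O)[O-]", "CCC(=O)O") is None

    def test_isotope_must_match_on_core_atoms(self):
        assert classify("*C[13CH2]O", "CC[13CH2]O") == EXT
        assert classify("*C[13CH2]O", "CCCO") is None

    def test_no_tautomer_leakage(self):
        # keto query must not match enol candidates
        assert classify("*CC(=O)C", "CCC(=O)C") == EXT
        assert classify("*CC(=O)C", "CC=C(O)C") is None
        assert classify("*CC(=O)C", "CCC(O)=C") is None

    def test_extra_ring_bond_between_core_atoms_is_not_extended(self):
        # a chain core embedded in a ring carries an addition that is a bond
        assert classify("*CCCC", "C1CCC1") == SUP

    def test_candidate_with_wildcard_is_a_contract_violation(self):
        with pytest.raises(StructureError):
            match_core(PHENYL, parse_molecule("*Cc1ccccc1"))

    def test_query_without_r_positions_is_rejected(self):
        no_r = GenericMolecule.from_smiles("c1ccccc1", ["q"])
        with pytest.raises(StructureError):
            match_core(no_r, parse_molecule("Cc1ccccc1"))


class TestClassifyMatch:
    def test_classification_is_existential_over_embeddings(self):
        # symmetric candidate: some embeddings leave leftovers, one does not
        assert classify("*c1ccc(O)cc1", "Cc1ccc(O)cc1") == EXT

    def test_match_object_feeds_classifier(self):
        query = GenericMolecule.from_smiles("*c1ccccc1", ["q"])
        match = match_core(query, parse_molecule("Cc1ccccc1C"))
        assert classify_match(match) == SUP


class TestExpandQuery:
    def test_fig2a_cardinalities(self, fig2a_query, fig2a_store):
        result = expand_query(fig2a_query, fig2a_store)
        assert len(result.superstructure) == 4
        assert len(result.rgroup_extended) == 2

    def test_empty_store_gives_empty_lists(self, fig2a_query):
        store, _ = ingest_library([])
        result = expand_query(fig2a_query, store)
        assert result.superstructure == [] and result.rgroup_extended == []

    def test_weight_prefilter_skips_light_candidates_entirely(self, fig2a_query):
        store, _ = ingest_library([(1, "C"), (2, "CC"), (3, "CCO")])
        result = expand_query(fig2a_query, store)
        assert result.n_match_calls == 0
        assert result.superstructure == []

    def test_extended_list_is_subset_of_superstructure_list(
        self, mixed_fixture, mixed_store
    ):
        for ident, smiles in mixed_fixture.queries:
            query = GenericMolecule.from_smiles(smiles, [ident])
            result = expand_query(query, mixed_store)
            sup = {e.smiles for e in result.superstructure}
            ext = {e.smiles for e in result.rgroup_extended}
            assert ext <= sup

    def test_every_match_is_strictly_heavier_than_the_query(
        self, mixed_fixture, mixed_store
    ):
        for ident, smiles in mixed_fixture.queries:
            query = GenericMolecule.from_smiles(smiles, [ident])
            result = expand_query(query, mixed_store)
            assert all(e.mol_wt > query.exact_mol_wt for e in result.superstructure)

    def test_results_ordered_by_weight_then_smiles(self, fig2a_query, fig2a_store):
        result = expand_query(fig2a_query, fig2a_store)
        keys = [(e.mol_wt, e.smiles) for e in result.superstructure]
        assert keys == sorted(keys)

    def test_two_runs_are_identical(self, fig2a_query, fig2a_store):
        first = expand_query(fig2a_query, fig2a_store)
        second = expand_query(fig2a_query, fig2a_store)
        assert first.superstructure == second.superstructure
        assert first.rgroup_extended == second.rgroup_extended

    def test_duplicate_structures_merge_their_cids(self, fig2a):
        # register the same extended candidate under a second identifier
        extended_cid, extended_smiles = next(
            (cid, smi)
            for cid, smi in fig2a.library
            if fig2a.ground_truth.labels[(fig2a.queries[0][1], cid)] == EXTENDED
        )
        library = list(fig2a.library) + [(9999, extended_smiles)]
        store, _ = ingest_library(library)
        query = GenericMolecule.from_smiles(fig2a.queries[0][1], ["q"])
        result = expand_query(query, store)
        entry = next(e for e in result.rgroup_extended if extended_cid in e.cids)
        assert 9999 in entry.cids

    def test_multicomponent_candidate_contributes_component_as_extended(self):
        fixture = generate_fixture(
            FixtureSpec(seed=2, n_scaffolds=1, n_extended=1, n_superstructure_only=0,
                        n_decoys=0, n_light_decoys=0, n_multicomponent=1)
        )
        store, _ = ingest_library(fixture.library)
        ident, smiles = fixture.queries[0]
        query = GenericMolecule.from_smiles(smiles, [ident])
        result = expand_query(query, store)
        composite_cid = next(
            cid
            for (q, cid), lbl in fixture.ground_truth.labels.items()
            if lbl == MULTICOMPONENT_EXTENDED
        )
        assert any(
            composite_cid in e.cids and "." not in e.smiles
            for e in result.rgroup_extended
        )
        # the whole composite entry still appears among the superstructures
        assert any(
            composite_cid in e.cids and "." in e.smiles
            for e in result.superstructure
        )


class TestTimeouts:
    @staticmethod
    def slow_for_odd(query, compound):
        return 30.0 if compound.cids[0] % 2 else 0.5

    def test_simulated_costs_cause_recorded_timeouts(self, fig2a_query, fig2a_store):
        config = MatchConfig(timeout_seconds=2.0)
        result = expand_query(
            fig2a_query, fig2a_store, config, cost_model=self.slow_for_odd
        )
        odd = [c for c in fig2a_store.query_heavier_than(fig2a_query.exact_mol_wt)
               if c.cids[0] % 2]
        assert len(result.timed_out) == len(odd)

    def test_non_timed_out_set_grows_with_budget(self, fig2a_query, fig2a_store):
        previous: set = set()
        for budget in (0.1, 2.0, 60.0):
            config = MatchConfig(timeout_seconds=budget)
            result = expand_query(
                fig2a_query, fig2a_store, config, cost_model=self.slow_for_odd
            )
            evaluated = {e.smiles for e in result.superstructure}
            assert previous <= evaluated
            previous = evaluated

    def test_exhausted_clock_returns_timeout_sentinel(self, fig2a_query):
        ticks = iter(range(100))
        candidate = parse_molecule("Cc1ccc(O)cc1")
        config = MatchConfig(timeout_seconds=0.5)
        outcome = match_core(
            fig2a_query, candidate, config, clock=lambda: next(ticks)
        )
        assert outcome is TIMEOUT


class TestOracle:
    def test_oracle_refuses_large_candidates(self):
        big = parse_molecule("C" * 30)
        with pytest.raises(OracleSizeError):
            oracle_classify(PHENYL, big)

    def test_oracle_matches_ground_truth_and_matcher(self, mixed_fixture):
        expected = {
            EXTENDED: EXT,
            SUPERSTRUCTURE: SUP,
            MULTICOMPONENT_EXTENDED: SUP,  # whole composite has leftover component
            NO_MATCH: None,
            LIGHT_DECOY: None,
        }
        for query, candidate_smiles, label in pairs_with_truth(mixed_fixture):
            candidate = parse_molecule(candidate_smiles)
            from_oracle = oracle_classify(query, candidate, max_heavy_atoms=30)
            from_matcher = classify_pair(query, candidate)
            assert from_oracle == expected[label]
            assert from_matcher == from_oracle
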