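"""Entity partitioning, rank assignment and query identification."""

import numpy as np
import pytest

import barcodetax as bt
from conftest import make_alignment, matrix_from_pct


def block_matrix(groups, within_pct, between_pct):
    """Labels grouped into clusters at within/between divergence."""
    labels = [l for grp in groups for l in grp]
    n = len(labels)
    owner = {l: gi for gi, grp in enumerate(groups) for l in grp}
    pct = np.full((n, n), between_pct, dtype=float)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if owner[a] == owner[b]:
                pct[i, j] = within_pct
    np.fill_diagonal(pct, 0.0)
    return matrix_from_pct(labels, pct)


class TestPartitionEntities:
    def test_separated_species_form_one_entity_each(self):
        m = block_matrix([["a1", "a2"], ["b1", "b2"], ["c1", "c2"]], 0.5, 20.0)
        assert len(bt.partition_entities(m, 4.4)) == 3

    def test_species_pair_below_ot_merges(self):
        # two nominal species at 0.9% cross-distance vs OT 4.4%
        m = block_matrix([["e1", "e2", "n1", "n2"]], 0.9, 20.0)
        parts = bt.partition_entities(m, 4.4)
        assert len(parts) == 1 and len(parts[0]) == 4

    def test_matches_brute_force_components(self, rng):
        from barcodetax.trees import single_linkage_components

        for _ in range(20):
            n = 12
            values = rng.uniform(0, 0.25, size=(n, n))
            values = (values + values.T) / 2
            np.fill_diagonal(values, 0.0)
            labels = tuple(f"s{i}" for i in range(n))
            m = bt.DistanceMatrix(labels, values)
            ot = float(rng.uniform(1, 20))
            parts = bt.partition_entities(m, ot)
            comps = single_linkage_components(values * 100, ot)
            assert [[labels[i] for i in c] for c in comps] == parts

    def test_raising_ot_never_increases_entity_count(self, rng):
        n = 15
        values = rng.uniform(0, 0.25, size=(n, n))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0.0)
        m = bt.DistanceMatrix(tuple(f"s{i}" for i in range(n)), values)
        counts = [len(bt.partition_entities(m, ot)) for ot in (1, 3, 5, 10, 20)]
        assert counts == sorted(counts, reverse=True)


class TestAssignRanks:
    def _rank_of(self, entities, species):
        ranks = {e.rank for e in entities if species in e.species}
        assert len(ranks) == 1, ranks
        return ranks.pop()

    def test_deep_allopatric_lineages_become_iotus(self):
        # one nominal species split into three entities at the OT, each
        # confined to its own region -> three IOTUs
        m = block_matrix(
            [["n1", "n2"], ["c1", "c2"], ["u1"]], 0.4, 9.0
        )
        species = ["Nat"] * 5
        localities = ["NIT", "NIT", "CIT", "SIT", "UK"]
        parts = bt.partition_entities(m, 4.4)
        assert len(parts) == 3
        entities = bt.assign_ranks(parts, m, species, localities, 4.4)
        assert [e.rank for e in entities] == ["IOTU", "IOTU", "IOTU"]
        for e in entities:
            assert bt.classify.GEOGRAPHY_CONGRUENT in e.evidence

    def test_fused_species_pair_is_mt_motu(self):
        m = block_matrix([["e1", "e2", "n1", "n2"]], 0.9, 20.0)
        species = ["Serotinus", "Serotinus", "Nilssonii", "Nilssonii"]
        parts = bt.partition_entities(m, 4.4)
        entities = bt.assign_ranks(parts, m, species, ["NIT"] * 4, 4.4)
        assert len(entities) == 1
        assert entities[0].rank == "MT_MOTU"

    def test_sympatric_shallow_lineages_are_ucs(self):
        # three lineages at ~2.6%, below OT, overlapping localities
        m = block_matrix([["p1", "p2"], ["p3", "p4"], ["p5", "p6"]], 0.4, 2.6)
        species = ["Auritus"] * 6
        localities = ["NIT", "CIT", "NIT", "NIT", "CIT", "SIT"]
        parts = bt.partition_entities(m, 4.4)
        assert len(parts) == 1
        entities = bt.assign_ranks(parts, m, species, localities, 4.4)
        assert entities[0].rank == "UCS"
        assert bt.classify.DIVERGENCE_2_TO_5 in entities[0].evidence

    def test_allopatric_sub_ot_lineages_are_iotus(self):
        # lineages below the OT but geographically disjoint: geography
        # corroborates the molecular split
        m = block_matrix([["p1", "p2"], ["p3", "p4"]], 0.4, 3.2)
        species = ["Bech"] * 4
        localities = ["NIT", "NIT", "SIT", "SIT"]
        parts = bt.partition_entities(m, 4.4)
        assert len(parts) == 1
        entities = bt.assign_ranks(parts, m, species, localities, 4.4)
        assert entities[0].rank == "IOTU"

    def test_coherent_species_is_species_match(self):
        m = block_matrix([["a1", "a2", "a3"]], 0.5, 20.0)
        entities = bt.assign_ranks(
            bt.partition_entities(m, 4.4), m, ["A"] * 3, ["NIT"] * 3, 4.4
        )
        assert entities[0].rank == "SPECIES_MATCH"
        assert entities[0].mean_internal_pct == pytest.approx(0.5)

    def test_split_with_shared_localities_is_ucs(self):
        # deep split at the OT but both entities occur in NIT -> no
        # geographic corroboration
        m = block_matrix([["x1", "x2"], ["y1", "y2"]], 0.4, 9.0)
        species = ["X"] * 4
        localities = ["NIT", "CIT", "NIT", "SIT"]
        entities = bt.assign_ranks(
            bt.partition_entities(m, 4.4), m, species, localities, 4.4
        )
        assert [e.rank for e in entities] == ["UCS", "UCS"]

    def test_every_entity_gets_exactly_one_rank(self, rng):
        m = block_matrix(
            [["a1", "a2"], ["b1", "b2"], ["c1"]], 0.5, 20.0
        )
        entities = bt.assign_ranks(
            bt.partition_entities(m, 4.4), m,
            ["A", "A", "B", "B", "C"], ["NIT"] * 5, 4.4,
        )
        assert len(entities) == 3
        assert all(e.rank in bt.classify.RANKS for e in entities)
        covered = sorted(s for e in entities for s in e.sample_ids)
        assert covered == sorted(m.labels)

    def test_unknown_samples_rejected(self):
        m = block_matrix([["a1", "q1"]], 0.5, 20.0)
        with pytest.raises(ValueError, match="identify_queries"):
            bt.assign_ranks(
                bt.partition_entities(m, 4.4), m,
                ["A", bt.UNKNOWN], ["NIT", "NIT"], 4.4,
            )

    def test_unlabelled_entity_rank_when_admitted(self):
        m = block_matrix([["a1", "a2"], ["q1", "q2"]], 0.5, 20.0)
        entities = bt.assign_ranks(
            bt.partition_entities(m, 4.4), m,
            ["A", "A", bt.UNKNOWN, bt.UNKNOWN], ["NIT"] * 4, 4.4,
            allow_unlabelled=True,
        )
        assert self._rank_of(entities, bt.UNKNOWN) == "MOTU_UNLABELLED"

    def test_iotu_requires_secondary_evidence(self):
        with pytest.raises(ValueError, match="evidence"):
            bt.TaxonomicEntity(
                "E1", ("a",), frozenset({"A"}), "IOTU",
                evidence=(bt.classify.DIVERGENCE_GT_OT,),
            )


class TestIdentifyQueries:
    R1 = "ACGTACGTACGTACGTACGT" * 2
    R2 = R1[:-1] + "A"                       # one substitution from R1
    R3 = "TGCATGCATGCATGCATGCA" * 2

    def _reference(self):
        return make_alignment(
            [
                ("r1", self.R1, "Alcathoe", "NIT"),
                ("r2", self.R2, "Alcathoe", "CIT"),
                ("r3", self.R3, "Mystacinus", "NIT"),
            ]
        )

    def test_exact_match_assigned_at_distance_zero(self):
        queries = make_alignment([("q1", self.R1)])
        (res,) = bt.identify_queries(queries, self._reference(), 4.4)
        assert res.assigned == "Alcathoe"
        assert res.min_distance_pct["Alcathoe"] == 0.0

    def test_near_reference_below_ot_assigned(self):
        # one substitution from r2 (~2.6% over 40 sites), far from Mystacinus
        query = self.R2[:10] + "A" + self.R2[11:]
        queries = make_alignment([("q1", query)])
        (res,) = bt.identify_queries(queries, self._reference(), 4.4)
        assert res.assigned == "Alcathoe"

    def test_distant_query_unassigned(self):
        queries = make_alignment([("q1", "GGGGGGGGGGAAAAAAAAAA" * 2)])
        (res,) = bt.identify_queries(queries, self._reference(), 4.4)
        assert res.assigned == bt.UNASSIGNED

    def test_two_species_within_margin_is_ambiguous(self):
        reference = make_alignment(
            [
                ("r1", "ACGTACGTACGTACGTACGT", "SpA"),
                ("r2", "ACGTACGTACGTACGTACGA", "SpB"),
            ]
        )
        queries = make_alignment([("q1", "ACGTACGTACGTACGTACGC")])
        (res,) = bt.identify_queries(queries, reference, 10.0, tie_margin_pct=0.3)
        assert res.assigned == bt.AMBIGUOUS

    def test_never_assigns_species_at_or_above_ot(self, rng):
        cfg = bt.SimulationConfig(
            n_species=4, samples_per_species=(3, 3), seed=17
        )
        ds = bt.simulate_dataset(cfg)
        reference = ds.alignment
        queries = make_alignment(
            [("q1", reference.records[0].sequence)]
        )
        for ot in (0.01, 1.0, 5.0):
            (res,) = bt.identify_queries(queries, reference, ot)
            if res.assigned not in (bt.UNASSIGNED, bt.AMBIGUOUS):
                assert res.min_distance_pct[res.assigned] < ot

    def test_length_mismatch_rejected(self):
        queries = make_alignment([("q1", "ACGT")])
        with pytest.raises(ValueError, match="length"):
            bt.identify_queries(queries, self._reference(), 4.4)


class TestEntityReport:
    def _entities(self):
        m = block_matrix([["a1", "a2"], ["b1", "b2"], ["c1"]], 0.5, 20.0)
        return bt.assign_ranks(
            bt.partition_entities(m, 4.4), m,
            ["A", "A", "B", "B", "C"], ["NIT"] * 5, 4.4,
        )

    def test_one_row_per_entity_and_round_trip(self, tmp_path):
        entities = self._entities()
        out = tmp_path / "entities.tsv"
        frame = bt.entity_report(entities, out)
        assert len(frame) == len(entities)
        back = bt.read_entity_report(out)
        assert [e.entity_id for e in back] == [e.entity_id for e in entities]
        assert [e.rank for e in back] == [e.rank for e in entities]
        assert [e.sample_ids for e in back] == [e.sample_ids for e in entities]

    def test_rank_counts_sum_to_entity_count(self, tmp_path):
        entities = self._entities()
        frame = bt.entity_report(entities, tmp_path / "e.tsv")
        assert frame["rank"].value_counts().sum() == len(entities)
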