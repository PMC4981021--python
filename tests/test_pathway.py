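import numpy as np
import pytest

from coexnet.diffexpr import de_results_for_collection
from coexnet.errors import InputError
from coexnet.io import PathwayDB
from coexnet.pathway import (
    gene_profile,
    pathway_score,
    permutation_null,
    restricted_datasets,
    score_pathways,
)
from coexnet.simulate import (
    PlantedDE,
    PlantedPartners,
    SimulationConfig,
    generate_collection,
)

from _oracles import pathway_score_loop


@pytest.fixture(scope="module")
def planted_run():
    """Collection with a DE focal gene and a leaf-only correlated module."""
    cfg = SimulationConfig(
        n_datasets=20, samples_per_dataset=16, n_genes=60,
        focal_genes=("g0000",),
        planted_partners={
            "g0000": PlantedPartners(
                ("g0010", "g0011", "g0012", "g0013"), rho=0.8, tissue="leaf"
            )
        },
        planted_de={"g0000": PlantedDE(delta=6.0)},
        seed=47,
    )
    coll = generate_collection(cfg)
    return coll, de_results_for_collection(coll)


class TestRestriction:
    def test_only_tissue_matched_de_datasets_kept(self, planted_run):
        coll, de = planted_run
        kept = restricted_datasets("g0000", "leaf", coll, de)
        assert all(d.tissue == "leaf" for d in kept)
        assert all(de[d.dataset_id].is_de("g0000") for d in kept)

    def test_gene_never_de_restricts_to_nothing(self, planted_run):
        coll, de = planted_run
        profile, n_used = gene_profile("g0050", "leaf", coll, de)
        assert n_used == 0
        assert profile.isna().all()


class TestPathwayScore:
    def test_single_gene_pathway_equals_gene_weight(self, planted_run):
        coll, de = planted_run
        profile = gene_profile("g0000", "leaf", coll, de)
        s = pathway_score("g0000", "P", ["g0010"], "leaf", coll, de,
                          profile=profile)
        assert s.score == pytest.approx(profile[0]["g0010"])
        assert s.m == s.m_used == 1

    def test_two_member_mean(self, planted_run):
        coll, de = planted_run
        profile = gene_profile("g0000", "leaf", coll, de)
        s = pathway_score("g0000", "P", ["g0020", "g0021"], "leaf", coll, de)
        expected = (profile[0]["g0020"] + profile[0]["g0021"]) / 2
        assert s.score == pytest.approx(expected, abs=1e-12)
        assert s.m == 2

    def test_tissue_restricted_module_scores_high_only_in_matching_tissue(
        self, planted_run
    ):
        coll, de = planted_run
        members = ["g0010", "g0011", "g0012", "g0013"]
        leaf = pathway_score("g0000", "P", members, "leaf", coll, de)
        root = pathway_score("g0000", "P", members, "root", coll, de)
        assert leaf.score == pytest.approx(0.8, abs=0.1)
        assert abs(root.score) < 0.2

    def test_matches_straight_from_the_formula_oracle(self, planted_run):
        coll, de = planted_run
        for members in (["g0010", "g0030"], ["g0040", "g0041", "g0042"]):
            for tissue in ("leaf", "root"):
                s = pathway_score("g0000", "P", members, tissue, coll, de)
                expected = pathway_score_loop(coll, de, "g0000", members, tissue)
                assert s.score == pytest.approx(expected, abs=1e-12)

    def test_full_universe_pathway_equals_mean_of_gene_profile(self, planted_run):
        coll, de = planted_run
        profile = gene_profile("g0000", "leaf", coll, de)
        s = pathway_score("g0000", "U", list(coll.gene_universe), "leaf",
                          coll, de, profile=profile)
        assert s.score == pytest.approx(float(profile[0].mean()), abs=1e-12)

    def test_empty_restriction_reports_missing(self, planted_run):
        coll, de = planted_run
        assert pathway_score("g0050", "P", ["g0010"], "leaf", coll, de) is None


class TestPermutationNull:
    def test_observed_above_all_nulls_is_significant(self, planted_run):
        coll, de = planted_run
        members = ["g0010", "g0011", "g0012", "g0013"]
        obs = pathway_score("g0000", "P", members, "leaf", coll, de)
        tested = permutation_null(
            "g0000", obs, coll.gene_universe, B=100, seed=1,
            collection=coll, de_results=de,
        )
        # a rho=0.8 planted module dwarfs any random 4-gene draw
        assert tested.null_exceed_count == 0
        assert tested.empirical_p == pytest.approx(1 / 101)
        assert tested.significant

    def test_observed_below_all_nulls_is_worst_case(self, planted_run):
        coll, de = planted_run
        obs = pathway_score("g0000", "P", ["g0020"], "leaf", coll, de)
        low = type(obs)(**{**obs.__dict__, "score": -1.0})
        tested = permutation_null(
            "g0000", low, coll.gene_universe, B=100, seed=1,
            collection=coll, de_results=de,
        )
        assert tested.null_exceed_count == 100
        assert tested.empirical_p == 1.0
        assert not tested.significant

    def test_same_seed_reproduces_null(self, planted_run):
        coll, de = planted_run
        obs = pathway_score("g0000", "P", ["g0020", "g0030"], "leaf", coll, de)
        runs = [
            permutation_null("g0000", obs, coll.gene_universe, B=50, seed=7,
                             collection=coll, de_results=de)
            for _ in range(2)
        ]
        assert runs[0].null_exceed_count == runs[1].null_exceed_count

    def test_draw_larger_than_universe_errors(self, planted_run):
        coll, de = planted_run
        obs = pathway_score("g0000", "P", ["g0020"], "leaf", coll, de)
        big = type(obs)(**{**obs.__dict__, "m": 60})
        with pytest.raises(InputError):
            permutation_null("g0000", big, coll.gene_universe, B=10, seed=1,
                             collection=coll, de_results=de)

    def test_monotone_power_in_planted_rho(self):
        """Detection frequency of a planted 5-gene module rises with rho."""
        detect = {}
        for rho in (0.2, 0.5, 0.8):
            hits = 0
            for rep in range(10):
                cfg = SimulationConfig(
                    n_datasets=10, samples_per_dataset=16, n_genes=60,
                    focal_genes=("g0000",),
                    tissue_labels=("leaf",),
                    planted_partners={
                        "g0000": PlantedPartners(
                            tuple(f"g{i:04d}" for i in range(10, 15)), rho=rho
                        )
                    },
                    planted_de={"g0000": PlantedDE(delta=6.0)},
                    seed=1000 + rep,
                )
                coll = generate_collection(cfg)
                de = de_results_for_collection(coll)
                members = [f"g{i:04d}" for i in range(10, 15)]
                obs = pathway_score("g0000", "P", members, "leaf", coll, de)
                tested = permutation_null(
                    "g0000", obs, coll.gene_universe, B=100, seed=rep,
                    collection=coll, de_results=de,
                )
                hits += tested.significant
            detect[rho] = hits
        assert detect[0.2] <= detect[0.5] <= detect[0.8]
        assert detect[0.8] == 10


class TestScorePathways:
    def test_scores_every_pathway_with_nulls_filled(self, planted_run):
        coll, de = planted_run
        db = PathwayDB(
            members={"P1": frozenset(["g0010", "g0011"]),
                     "P2": frozenset(["g0030", "g0031", "g0032"])},
        )
        scores = score_pathways("g0000", db, "leaf", coll, de, B=20, seed=3)
        assert {s.pathway_id for s in scores} == {"P1", "P2"}
        assert all(s.B == 20 and s.null_exceed_count is not None for s in scores)

    def test_independent_of_pathway_iteration_order(self, planted_run):
        coll, de = planted_run
        members = {"P1": frozenset(["g0010", "g0011"]),
                   "P2": frozenset(["g0030", "g0031"])}
        fwd = score_pathways("g0000", PathwayDB(members=dict(members)),
                             "leaf", coll, de, B=30, seed=5)
        rev = score_pathways(
            "g0000",
            PathwayDB(members=dict(reversed(list(members.items())))),
            "leaf", coll, de, B=30, seed=5,
        )
        assert {s.pathway_id: s.null_exceed_count for s in fwd} == \
            {s.pathway_id: s.null_exceed_count for s in rev}
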