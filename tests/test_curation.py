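"""Dead-end detection/pruning, generic reactions, balance, producibility."""

import pytest

from conftest import TOY_MEDIUM, TOY_GROWTH_OPTIMUM
from oracles import prune_oracle
from tubigem import (MetabolicModel, Metabolite, Reaction, check_mass_balance,
                     find_blocked_reactions, find_dead_ends,
                     find_generic_reactions, make_random_network, optimize,
                     precursor_producibility, prune_dead_ends)


class TestDeadEnds:
    def test_chain_terminal_metabolite_is_dead(self, chain_model):
        assert find_dead_ends(chain_model) == {"C_c"}

    def test_reversible_tail_still_dead_without_sink(self, chain_model):
        # B <-> C instead of B -> C: C gains a "producer" role but still has
        # no independent sink; B however is no longer a problem
        model = chain_model.copy()
        model.reaction("R2").lower_bound = -1000
        assert find_dead_ends(model) == {"C_c"}

    def test_fully_exchanged_toy_has_none(self, toy_model):
        assert find_dead_ends(toy_model) == set()

    def test_decoy_appendages_detected(self, toy_model_decoys):
        dead = find_dead_ends(toy_model_decoys)
        assert dead == {"dead0_c", "dead1_c", "dead2_c"}


class TestPruning:
    def test_chain_pruned_within_two_iterations(self, chain_model):
        pruned, report = prune_dead_ends(chain_model)
        assert report.removable_reactions == {"R1", "R2"}
        assert report.iterations <= 2
        assert find_dead_ends(pruned) == set()

    def test_clean_model_unchanged(self, toy_model):
        pruned, report = prune_dead_ends(toy_model)
        assert report.iterations == 0
        assert pruned.reaction_ids == toy_model.reaction_ids

    def test_removes_exactly_the_decoys(self, toy_model_decoys):
        pruned, report = prune_dead_ends(toy_model_decoys)
        assert report.removable_reactions == {"DEAD0", "DEAD1", "DEAD2"}
        assert "dead0_c" not in pruned.metabolite_ids

    def test_input_model_untouched(self, toy_model_decoys):
        n = len(toy_model_decoys.reactions)
        prune_dead_ends(toy_model_decoys)
        assert len(toy_model_decoys.reactions) == n

    def test_idempotent(self, toy_model_decoys):
        once, _ = prune_dead_ends(toy_model_decoys)
        twice, report = prune_dead_ends(once)
        assert report.iterations == 0
        assert twice.reaction_ids == once.reaction_ids

    def test_preserves_fba_optimum(self, toy_model_decoys):
        pruned, _ = prune_dead_ends(toy_model_decoys)
        assert optimize(pruned).objective_value == pytest.approx(
            TOY_GROWTH_OPTIMUM, abs=1e-9)

    def test_refuses_when_objective_touches_dead_end(self):
        mets = [Metabolite(id="a_e", compartment="e"),
                Metabolite(id="p_c", compartment="c")]
        rxns = [Reaction(id="EX_a", stoichiometry={"a_e": -1}, lower_bound=-10),
                Reaction(id="BIO", stoichiometry={"p_c": -1})]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        # make BIO non-boundary by giving it a second participant
        rxns = [Reaction(id="EX_a", stoichiometry={"a_e": -1}, lower_bound=-10),
                Reaction(id="BIO", stoichiometry={"p_c": -1, "a_e": -1})]
        model = MetabolicModel(metabolites=mets, reactions=rxns, objective="BIO")
        with pytest.raises(ValueError, match="p_c"):
            prune_dead_ends(model)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_remove_one_recheck_oracle(self, seed):
        """Fixed point equals the brute-force oracle on random networks."""
        model = make_random_network(seed)
        pruned, report = prune_dead_ends(model)
        assert report.removable_reactions == prune_oracle(model, set())
        again, second = prune_dead_ends(pruned)
        assert second.iterations == 0


class TestGenericReactions:
    def test_r_group_participant_flagged(self):
        mets = [Metabolite(id="fa_c", compartment="c", formula="RCOOH"),
                Metabolite(id="a_c", compartment="c", formula="C2H4O2")]
        rxns = [Reaction(id="GEN", stoichiometry={"fa_c": -1, "a_c": 1}),
                Reaction(id="OK", stoichiometry={"a_c": -1}, lower_bound=-1)]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        assert find_generic_reactions(model) == {"GEN"}

    def test_missing_formula_flagged(self):
        mets = [Metabolite(id="u_c", compartment="c", formula=None),
                Metabolite(id="a_c", compartment="c", formula="C2H4O2")]
        rxns = [Reaction(id="GEN", stoichiometry={"u_c": -1, "a_c": 1})]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        assert find_generic_reactions(model) == {"GEN"}

    def test_fully_specified_toy_clean(self, toy_model):
        # the biomass pseudo-metabolite is deliberately formula-free
        assert find_generic_reactions(toy_model) <= {"BIOMASS", "DM_biomass_c"}

    def test_designed_count_matches(self, toy_model):
        """A fixture with k generic appendages flags exactly those k."""
        model = toy_model.copy()
        expected = set()
        for k in range(6):
            met = Metabolite(id=f"gen{k}_c", compartment="c", formula="C2H4O2R")
            model.metabolites.append(met)
            model._met_index[met.id] = met
            model.add_reaction(Reaction(
                id=f"GEN{k}", stoichiometry={"cit_c": -1, f"gen{k}_c": 1}))
            expected.add(f"GEN{k}")
        flagged = find_generic_reactions(model) - {"BIOMASS", "DM_biomass_c"}
        assert flagged == expected


class TestMassBalance:
    def test_toy_internal_reactions_balanced(self, toy_model):
        report = check_mass_balance(toy_model)
        assert report.imbalances == {}
        assert report.n_balanced > 30

    def test_oxygen_loss_detected(self):
        mets = [Metabolite(id="a_c", compartment="c", formula="C6H12O6"),
                Metabolite(id="b_c", compartment="c", formula="C6H12O5")]
        model = MetabolicModel(
            metabolites=mets,
            reactions=[Reaction(id="R", stoichiometry={"a_c": -1, "b_c": 1})])
        assert check_mass_balance(model).imbalances == {"R": {"O": -1.0}}

    def test_exchange_skipped(self, toy_model):
        report = check_mass_balance(toy_model)
        assert report.skipped["EX_glc__D_e"] == "boundary reaction"
        assert "BIOMASS" in report.skipped

    def test_unparseable_formula_moved_to_skipped(self):
        mets = [Metabolite(id="r_c", compartment="c", formula="R-COOH"),
                Metabolite(id="a_c", compartment="c", formula="C2H4O2")]
        model = MetabolicModel(
            metabolites=mets,
            reactions=[Reaction(id="R", stoichiometry={"r_c": -1, "a_c": 1})])
        report = check_mass_balance(model)
        assert "R" in report.skipped and "R" not in report.imbalances


class TestProducibility:
    def test_all_precursors_on_glucose(self, toy_model):
        result = precursor_producibility(toy_model, TOY_MEDIUM)
        assert result and all(result.values())

    def test_knockout_breaks_one_precursor(self, toy_model):
        model = toy_model.copy()
        model.remove_reactions(["AASYN"])  # amino-acid synthesis
        result = precursor_producibility(model, TOY_MEDIUM)
        assert result["aa_c"] is False
        others = {k: v for k, v in result.items() if k != "aa_c"}
        assert all(others.values())

    def test_empty_medium_nothing_producible(self, toy_model):
        result = precursor_producibility(toy_model, set())
        assert not any(result.values())

    def test_requires_biomass_reaction(self, chain_model):
        with pytest.raises(ValueError, match="objective"):
            precursor_producibility(chain_model, set())


class TestBlockedReactions:
    def test_core_pathway_not_blocked_on_glucose(self, toy_model):
        blocked = find_blocked_reactions(toy_model, TOY_MEDIUM)
        assert {"GLYC", "TCA", "OXPHOS", "BIOMASS"}.isdisjoint(blocked)

    def test_no_catabolic_route_is_blocked(self, toy_model):
        blocked = find_blocked_reactions(toy_model, TOY_MEDIUM)
        assert "GALt" in blocked  # transported but never catabolised

    def test_blocked_superset_of_prunable(self, toy_model_decoys):
        _, report = prune_dead_ends(toy_model_decoys)
        blocked = find_blocked_reactions(toy_model_decoys, TOY_MEDIUM)
        assert report.removable_reactions <= blocked

    def test_all_blocked_when_exchanges_closed(self, toy_model):
        blocked = find_blocked_reactions(toy_model, set())
        internal = {r.id for r in toy_model.reactions
                    if not toy_model.is_boundary(r)}
        assert internal <= blocked
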