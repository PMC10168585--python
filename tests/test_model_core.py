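import copy
import dataclasses

import numpy as np
import pytest

from rbakit import (
    Compartment,
    Enzyme,
    Macromolecule,
    Medium,
    Metabolite,
    Process,
    RBAModel,
    Reaction,
    Target,
    impose_target,
    knock_out,
    maximize_growth,
    scale_efficiency,
    validate_model,
)
from rbakit.parameters import constant
from rbakit import toys


def test_valid_toy_has_no_diagnostics(self_replicator):
    assert validate_model(self_replicator) == []


def test_dangling_macromolecule_reference_is_reported(self_replicator):
    enzymes = dict(self_replicator.enzymes)
    enzymes["uptake_enzyme"] = dataclasses.replace(
        enzymes["uptake_enzyme"], composition={"ghost_protein": 1.0}
    )
    broken = dataclasses.replace(self_replicator, enzymes=enzymes)
    diagnostics = validate_model(broken)
    assert len(diagnostics) == 1
    assert "uptake_enzyme" in diagnostics[0].component
    assert "ghost_protein" in diagnostics[0].rule


def test_negative_density_capacity_is_reported(self_replicator):
    compartments = {"cytosol": Compartment("cytosol", constant(-1.0))}
    broken = dataclasses.replace(self_replicator, compartments=compartments)
    diagnostics = validate_model(broken)
    assert len(diagnostics) == 1
    assert "cytosol" in diagnostics[0].component
    assert "negative" in diagnostics[0].rule


class TestKnockOut:
    def test_sole_transporter_knockout_stops_growth(self, importer):
        edited = knock_out(importer, {"uptake_enzyme"})
        state = maximize_growth(edited, Medium({"nutrient_ext": 10.0}))
        assert state.mu < 1e-5

    def test_single_pathway_closed_form_after_branch_knockout(self, overflow, overflow_medium):
        # only respiration left: mu solves the single-pathway chain
        edited = knock_out(overflow, {"overflow_enzyme"})
        state = maximize_growth(edited, overflow_medium.updated(substrate_ext=1e6))
        # saturated importer (k=10), respiration k=1, yield 1, ribosome k=2,
        # pinned pool 0.1: mu = (1 - 0.1) / (1/10 + 1/1 + 1/2)
        assert state.mu == pytest.approx(0.9 / 1.6, rel=1e-5)

    def test_empty_id_set_returns_unchanged_model(self, pinned):
        assert knock_out(pinned, set()) == pinned

    def test_unknown_id_is_named(self, pinned):
        with pytest.raises(KeyError, match="nonexistent"):
            knock_out(pinned, {"nonexistent"})

    def test_input_model_is_not_mutated(self, pinned):
        before = copy.deepcopy(pinned)
        knock_out(pinned, {"uptake_enzyme"})
        assert pinned == before


class TestScaleEfficiency:
    def test_identity_factor_preserves_growth(self, self_replicator):
        scaled = scale_efficiency(self_replicator, "translation", 1.0)
        assert maximize_growth(scaled).mu == pytest.approx(1.0, rel=1e-5)

    def test_doubling_ribosome_efficiency_closed_form(self, self_replicator):
        scaled = scale_efficiency(self_replicator, "translation", 2.0)
        # mu = 1 / (1/2 + 1/4) = 4/3
        assert maximize_growth(scaled).mu == pytest.approx(4.0 / 3.0, rel=1e-5)

    @pytest.mark.parametrize("factor", [0.01, 100.0])
    def test_screen_range_endpoints_accepted(self, self_replicator, factor):
        scaled = scale_efficiency(self_replicator, "uptake_enzyme", factor)
        assert validate_model(scaled) == []

    @pytest.mark.parametrize("factor", [0.01, 0.37, 3.0, 100.0])
    def test_scaling_round_trip_recovers_parameters(self, importer, factor):
        round_tripped = scale_efficiency(
            scale_efficiency(importer, "uptake_enzyme", factor), "uptake_enzyme", 1.0 / factor
        )
        medium = Medium({"nutrient_ext": 0.25})
        for mu in np.linspace(0.0, 2.0, 7):
            original = importer.enzymes["uptake_enzyme"].forward_efficiency(mu, medium)
            recovered = round_tripped.enzymes["uptake_enzyme"].forward_efficiency(mu, medium)
            assert recovered == pytest.approx(original, rel=1e-12)

    def test_nonpositive_factor_rejected(self, pinned):
        with pytest.raises(ValueError):
            scale_efficiency(pinned, "uptake_enzyme", 0.0)


def _self_replicator_with_housekeeping():
    """Self-replicator extended by an (untargeted) housekeeping protein."""
    base = toys.make_self_replicator(kE=2, kR=2, n_E=1, n_R=1, D=1)
    housekeeping = Macromolecule(
        "housekeeping_protein", 1.0, "cytosol", {"precursor": 1.0}, "translation"
    )
    translation = base.processes["translation"]
    processes = {
        "translation": dataclasses.replace(
            translation, products=translation.products | {"housekeeping_protein"}
        )
    }
    macromolecules = dict(base.macromolecules)
    macromolecules["housekeeping_protein"] = housekeeping
    return dataclasses.replace(base, macromolecules=macromolecules, processes=processes)


class TestImposeTarget:
    def test_inactive_flux_target_keeps_growth(self, secretion, settings):
        # pin the uptake flux at its unconstrained optimum; with the
        # maintenance sink absorbing surplus below mu_max the constraint is
        # inactive at the optimum and mu_max is unchanged
        reference = maximize_growth(secretion)
        pinned_flux = reference.fluxes["uptake"]
        edited = impose_target(
            secretion, Target("pin_uptake", "flux_eq", "uptake", constant(pinned_flux))
        )
        assert maximize_growth(edited).mu == pytest.approx(
            reference.mu, rel=100 * settings.bisection_tol
        )

    def test_target_exceeding_density_capacity_is_infeasible(self, pinned):
        edited = impose_target(
            pinned,
            Target("too_much", "concentration_ge", "housekeeping_protein", constant(2.0)),
        )
        state = maximize_growth(edited)
        assert state.status == "infeasible"
        assert state.mu == 0.0

    def test_housekeeping_target_closed_form(self):
        model = _self_replicator_with_housekeeping()
        edited = impose_target(
            model,
            Target("housekeeping_level", "concentration_eq", "housekeeping_protein", constant(0.2)),
        )
        # mu = (1 - 0.2/1) / (1/2 + 1/2) = 0.8
        assert maximize_growth(edited).mu == pytest.approx(0.8, rel=1e-5)

    def test_duplicate_target_id_rejected(self, pinned):
        with pytest.raises(ValueError, match="housekeeping_level"):
            impose_target(
                pinned,
                Target("housekeeping_level", "flux_ge", "uptake", constant(0.0)),
            )

    def test_invalid_subject_rejected(self, pinned):
        with pytest.raises(ValueError, match="external metabolite"):
            impose_target(
                pinned,
                Target("bad", "concentration_eq", "nutrient_ext", constant(1.0)),
            )
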