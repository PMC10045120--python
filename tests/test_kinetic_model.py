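import numpy as np
import pytest
import yaml
from importlib import resources

from redoxcell import kinetic_model as km
from conftest import toy_network


def _default_config():
    text = resources.files("redoxcell.data").joinpath("default_model.yaml").read_text()
    return yaml.safe_load(text)


DRUG_SPECIES = ("blap_ext", "blapQ", "blapHQ", "blapSQ", "blapHQSG", "blapHQSG_ext")

#: the nine drug reactions and their printed rate terms
DRUG_RATE_TERMS = {
    "blap_permeation": ("gradient_permeation", "k34", ("blap_ext", "blapQ")),
    "blap_reduction": ("mass_action", "k29", ("blapQ", "NADPH")),
    "blap_semioxidation": ("mass_action", "k30", ("blapHQ", "O2")),
    "blap_oxidation": ("mass_action", "k31", ("blapSQ", "O2")),
    "superoxide_dismutation": ("second_order_self", "k32", ("O2s",)),
    "blap_semireduction": ("mass_action", "k33", ("blapQ", "NADPH")),
    "blap_sq_semireduction": ("mass_action", "k33", ("blapSQ", "NADPH")),
    "blap_glutathionylation": ("mass_action", "k35", ("blapHQ", "GSH")),
    "blap_conjugate_export": ("unidirectional_permeation", "k36", ("blapHQSG",)),
}


class TestBuildNetwork:
    def test_drug_reactions_match_printed_rate_terms(self, default_net):
        """All nine quinone-cycling reactions carry exactly the declared
        rate-law templates, rate constants and participating species."""
        by_name = {r.name: r for r in default_net.reactions}
        for name, (template, k, species) in DRUG_RATE_TERMS.items():
            law = by_name[name].rate_law
            assert law.template == template
            assert law.k_name == k
            assert law.species == species

    def test_missing_parameter_rejected_by_name(self):
        cfg = _default_config()
        del cfg["parameters"]["k32"]
        with pytest.raises(km.ConfigurationError, match="k32"):
            km.build_network(cfg)

    def test_unknown_species_rejected(self):
        cfg = _default_config()
        cfg["reactions"][0]["stoichiometry"]["bogus"] = 1
        with pytest.raises(km.ConfigurationError, match="bogus"):
            km.build_network(cfg)

    def test_nonpositive_volume_rejected(self):
        cfg = _default_config()
        cfg["compartments"]["cytosol"] = 0.0
        with pytest.raises(km.ConfigurationError):
            km.build_network(cfg)

    def test_drug_moiety_conserved_per_reaction(self, default_net):
        """Each reaction's signed sum over the drug moiety is zero: the drug
        is moved or transformed, never created or destroyed."""
        for rx in default_net.reactions:
            signed = sum(rx.stoichiometry.get(s, 0) for s in DRUG_SPECIES)
            assert signed == 0, rx.name


class TestEvaluateRates:
    def test_second_order_dismutation(self):
        net = toy_network(
            reactions=[{"name": "dis", "template": "second_order_self", "k": "k",
                        "species": ["S"], "stoichiometry": {"S": -2}}],
            species=[{"name": "S", "compartment": "cytosol", "initial": 3.0}],
            parameters={"k": 2.0},
        )
        assert km.evaluate_rates(net, {"S": 3.0})["dis"] == pytest.approx(18.0)

    def test_zero_gradient_permeation(self, default_net):
        state = {n: 0.0 for n in default_net.species_names}
        state["blap_ext"] = state["blapQ"] = 5e-6
        rates = km.evaluate_rates(default_net, state)
        assert rates["blap_permeation"] == pytest.approx(0.0)

    def test_bimolecular_reduction(self):
        net = toy_network(
            reactions=[{"name": "red", "template": "mass_action", "k": "k29",
                        "species": ["Q", "NADPH"],
                        "stoichiometry": {"Q": -1, "NADPH": -1}}],
            species=[{"name": "Q", "compartment": "cytosol", "initial": 2.0},
                     {"name": "NADPH", "compartment": "cytosol", "initial": 10.0}],
            parameters={"k29": 0.1},
        )
        assert km.evaluate_rates(net, {"Q": 2.0, "NADPH": 10.0})["red"] == pytest.approx(2.0)

    def test_negative_state_rejected(self, default_net):
        state = np.zeros(len(default_net.species))
        state[3] = -1e-3
        with pytest.raises(km.EvaluationError, match="negative"):
            km.evaluate_rates(default_net, state)

    def test_missing_species_rejected(self, default_net):
        with pytest.raises(km.EvaluationError, match="missing"):
            km.evaluate_rates(default_net, {"H2O2": 1e-9})


class TestDerivatives:
    def test_no_drug_no_drug_dynamics(self, default_net, resting_state):
        """With every drug form at zero, all drug-species derivatives vanish."""
        rhs = km.assemble_derivatives(default_net)
        dy = rhs(0.0, resting_state)
        for name in DRUG_SPECIES:
            assert dy[default_net.species_index(name)] == 0.0

    def test_first_order_decay_matches_closed_form(self):
        net = toy_network(
            reactions=[{"name": "decay", "template": "mass_action", "k": "k",
                        "species": ["A"], "stoichiometry": {"A": -1, "B": 1}}],
            species=[{"name": "A", "compartment": "cytosol", "initial": 1.0},
                     {"name": "B", "compartment": "cytosol", "initial": 0.0}],
            parameters={"k": 0.1},
            solver={"t_end": 30.0, "max_step": None, "atol": 1e-10, "rtol": 1e-8},
        )
        traj = km.simulate(net)
        expected = np.exp(-0.1 * traj.time)
        assert np.allclose(traj.series("A"), expected, atol=1e-6)
        assert np.allclose(traj.series("A") + traj.series("B"), 1.0, atol=1e-8)

    def test_volume_weighted_drug_amount_stationary(self, default_net):
        """d/dt of total drug moles is zero at any state: permeation moves
        material between compartments, chemistry interconverts forms."""
        rng = np.random.default_rng(7)
        rhs = km.assemble_derivatives(default_net)
        geo = default_net.geometry
        for _ in range(5):
            y = rng.uniform(0, 1e-5, size=len(default_net.species))
            dy = rhs(0.0, y)
            total = sum(
                geo.volume(default_net.species[default_net.species_index(n)].compartment)
                * dy[default_net.species_index(n)]
                for n in DRUG_SPECIES
            )
            assert abs(total) < 1e-25


class TestSimulate:
    def test_default_settings_are_reference_settings(self):
        s = km.SolverSettings()
        assert s.t_end == 7200.0
        assert s.max_step == 1.0
        assert s.atol == 1e-8

    def test_clamped_species_constant(self, default_net, dosed_state, fast_settings):
        traj = km.simulate(default_net, dosed_state, fast_settings)
        o2 = traj.series("O2")
        assert np.all(o2 == o2[0])

    def test_pathological_parameters_flagged_not_raised(self, default_net, dosed_state):
        bad = default_net.scaled({"k29": 1e12, "k_nadph": 1e12})
        traj = km.simulate(bad, dosed_state,
                           km.SolverSettings(t_end=7200, max_step=None, rtol=1e-6))
        assert traj.status in ("stable", "unstable")  # never an exception
        # and a grossly negative initial state is a hard error
        with pytest.raises(km.EvaluationError):
            km.simulate(default_net, -np.ones(len(default_net.species)))

    def test_moiety_conservation_under_drug(self, default_net, dosed_state):
        """NADP(H), Trx, Prx, GPX, protein-thiol, glutathione and drug moieties
        drift < 0.1% over the 2 h dosed run at reference settings."""
        traj = km.simulate(default_net, dosed_state)  # max_step=1, atol 1e-8
        assert traj.stable
        m0 = km.moiety_totals(default_net, traj.concentrations[0])
        m1 = km.moiety_totals(default_net, traj.endpoint())
        for name in m0:
            assert m1[name] == pytest.approx(m0[name], rel=1e-3), name

    def test_trajectory_tidy_export(self, default_net, resting_state, fast_settings):
        traj = km.simulate(default_net, resting_state, fast_settings)
        frame = km.trajectory_to_frame(traj, cell_id="c1")
        assert set(frame.columns) == {"time", "species", "concentration", "cell_id"}
        assert len(frame) == len(traj.time) * len(default_net.species)


class TestEquilibrium:
    def test_resting_state_is_fixed_point(self, default_net, resting_state, fast_settings):
        """After equilibration, a further 2 h drug-free run moves no species
        by more than 1%."""
        traj = km.simulate(default_net, resting_state, fast_settings)
        assert traj.stable
        end = traj.endpoint()
        for i, name in enumerate(default_net.species_names):
            if resting_state[i] > 1e-15:
                assert end[i] == pytest.approx(resting_state[i], rel=0.01), name
            else:
                assert abs(end[i]) < 1e-12, name
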