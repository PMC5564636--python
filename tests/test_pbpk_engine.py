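from dataclasses import replace

import numpy as np
import pytest

import irinopbpk as ip
from irinopbpk.compound_model import ConfigurationError, PartitionCoefficientSet
from irinopbpk.pbpk_engine import (
    DoseRegimen,
    EliminationRoutes,
    MetabolismNetwork,
    Reaction,
    run_ph_scan,
    simulate,
)
from irinopbpk.physiology import REFERENCE_ANATOMY, SYSTEMIC_ORGANS, Organ, VirtualIndividual


def unit_kps(compounds, organs):
    return {c.name: PartitionCoefficientSet(c.name, {o: 1.0 for o in organs})
            for c in compounds}


def fast_mixing_individual(flow=2000.0):
    """All organs tiny except muscle; huge flows so the body is one
    well-mixed pool to high accuracy."""
    organs = {}
    for name in REFERENCE_ANATOMY:
        if name == "muscle":
            v = 50.0
        elif name in ("arterial_blood", "venous_blood"):
            v = 2.0
        else:
            v = 0.01
        q = flow if name in SYSTEMIC_ORGANS else 0.0
        organs[name] = Organ(volume=v, blood_flow=q,
                             water_fraction=1.0, lipid_fraction=0.0)
    co = sum(organs[o].blood_flow for o in SYSTEMIC_ORGANS)
    for pool in ("lung", "arterial_blood", "venous_blood"):
        organs[pool] = replace(organs[pool], blood_flow=co)
    return VirtualIndividual(sex="male", age=50.0, body_weight=70.0,
                             height=170.0, body_surface_area=1.8,
                             hematocrit=0.45, gfr=1000.0, organs=organs)


class TestAssembly:
    def test_zero_state_zero_dose_has_zero_derivatives(self, model):
        regimen = DoseRegimen(total_dose=0.0, dose_per_bsa=None)
        f = model.rhs(regimen)
        assert np.all(f(10.0, np.zeros(model.n_states)) == 0.0)
        assert np.all(f(100.0, np.zeros(model.n_states)) == 0.0)

    def test_missing_partition_set_rejected(self, reference_individual,
                                            compounds, kps):
        with pytest.raises(ConfigurationError):
            ip.assemble_model(reference_individual, compounds,
                              {"CPT-11": kps["CPT-11"]},
                              ip.irinotecan_network())

    def test_unregistered_reaction_species_rejected(self, reference_individual,
                                                    compounds, kps):
        net = MetabolismNetwork(reactions=(Reaction("CPT-11", "ghost", 1.0),))
        with pytest.raises(ConfigurationError):
            ip.assemble_model(reference_individual, compounds, kps, net)

    def test_conservation_without_elimination(self, reference_individual,
                                              compounds):
        net = MetabolismNetwork()  # no reactions, no clearances
        m = ip.assemble_model(reference_individual, compounds,
                              unit_kps(compounds, reference_individual.organs),
                              net)
        prof = simulate(m, DoseRegimen(), t_end=30.0)
        after = prof.times_h > 0.6
        assert np.allclose(prof.body_burden()[after], prof.dose_umol,
                           rtol=1e-9)
        assert all(np.all(v == 0) for v in prof.eliminated.values())

    def test_noneliminating_organs_equilibrate_to_arterial(self,
                                                           reference_individual,
                                                           compounds, kps):
        """At late times without elimination, every organ's venous
        plasma-equivalent concentration equals the arterial one."""
        m = ip.assemble_model(reference_individual, compounds, kps,
                              MetabolismNetwork())
        prof = simulate(m, DoseRegimen(), t_end=3000.0,
                        output_grid=np.array([2999.0, 3000.0]),
                        tissue_output=True)
        kp = m.kps["CPT-11"]
        c_art = prof.tissues["CPT-11"]["arterial_blood"][-1]
        for organ in m.organs:
            c_eq = prof.tissues["CPT-11"][organ][-1] / (
                kp[organ] if organ not in ("arterial_blood", "venous_blood")
                else 1.0)
            assert c_eq == pytest.approx(c_art, rel=1e-6)


class TestSimulate:
    def test_dose_linearity(self, model):
        lo = simulate(model, DoseRegimen(total_dose=100.0, dose_per_bsa=None))
        hi = simulate(model, DoseRegimen(total_dose=200.0, dose_per_bsa=None))
        for s in model.species:
            assert np.allclose(hi.plasma[s], 2.0 * lo.plasma[s],
                               rtol=1e-12, atol=1e-15)

    def test_superposition_of_infusions(self, model, regimen):
        one = simulate(model, regimen)
        two = simulate(model, DoseRegimen(dose_per_bsa=700.0))
        for s in model.species:
            assert np.allclose(one.plasma[s] * 2.0, two.plasma[s], rtol=1e-12)

    def test_mass_balance_everywhere(self, model, regimen):
        prof = simulate(model, regimen, t_end=25.5)
        assert prof.mass_balance_error().max() < 0.005

    def test_everything_eliminated_eventually(self, model, regimen):
        prof = simulate(model, regimen, t_end=2000.0,
                        output_grid=np.array([1000.0, 2000.0]))
        total_elim = sum(v[-1] for v in prof.eliminated.values())
        assert total_elim == pytest.approx(prof.dose_umol, rel=0.005)

    def test_metabolites_start_at_zero_then_appear(self, model, regimen):
        prof = simulate(model, regimen)
        for s in ("SN-38", "SN-38G"):
            assert prof.plasma[s][0] == 0.0
            assert prof.plasma[s][-1] > 0.0

    def test_expm_and_lsoda_agree(self, model, regimen):
        grid = np.arange(0.0, 25.5, 0.1)
        a = simulate(model, regimen, output_grid=grid, method="expm")
        b = simulate(model, regimen, output_grid=grid, method="lsoda")
        for s in model.species:
            assert abs(a.plasma[s].max() - b.plasma[s].max()) \
                < 1e-3 * a.plasma[s].max()

    def test_one_compartment_bolus_limit_matches_closed_form(self, compounds):
        ind = fast_mixing_individual()
        net = MetabolismNetwork(
            elimination={"CPT-11": EliminationRoutes(0.0, 1.0)})
        m = ip.assemble_model(ind, compounds, unit_kps(compounds, ind.organs),
                              net)
        regimen = DoseRegimen(total_dose=350.0, dose_per_bsa=None,
                              infusion_duration=0.01)
        volume = sum(o.volume for o in ind.organs.values())
        clearance = ind.gfr / 1000.0 * compounds[0].fraction_unbound
        dose = regimen.dose_umol(ind, compounds[0])
        grid = np.array([0.5, 1.0, 2.0, 4.0])
        prof = simulate(m, regimen, t_end=4.0, output_grid=grid)
        expected = dose / volume * np.exp(-clearance * grid * 60.0 / volume)
        assert np.allclose(prof.plasma["CPT-11"], expected, rtol=1e-3)

    def test_grid_validation(self, model, regimen):
        with pytest.raises(ConfigurationError):
            simulate(model, regimen, t_end=0.1)
        with pytest.raises(ConfigurationError):
            simulate(model, regimen, output_grid=np.array([1.0, 1.0, 2.0]))


class TestPhScan:
    def test_pk_identical_speciation_differs(self, model, regimen):
        table = run_ph_scan(model, regimen,
                            plasma_ph_values=[6.0, 7.5],
                            tumor_ph_values=[6.0, 7.5])
        pk_cols = [c for c in table.columns
                   if c.startswith(("cpt11_", "sn38_"))]
        for col in pk_cols:
            assert table[col].nunique(dropna=False) == 1
        assert table["lactone_fraction_plasma"].nunique() > 1
        assert table["lactone_fraction_tumor"].nunique() > 1

    def test_single_scenario_matches_base_simulation(self, model, regimen):
        from irinopbpk.nca import run_nca
        table = run_ph_scan(model, regimen, plasma_ph_values=[7.4],
                            tumor_ph_values=[])
        assert len(table) == 1
        base = simulate(model, regimen, t_end=25.5)
        nca = run_nca(base, "CPT-11", regimen,
                      body_weight=model.individual.body_weight)
        assert table["cpt11_auc_tend"].iloc[0] == pytest.approx(nca.auc_tend)

    def test_invalid_ph_rejected(self, model, regimen):
        with pytest.raises(ValueError):
            run_ph_scan(model, regimen, plasma_ph_values=[15.0],
                        tumor_ph_values=[])
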