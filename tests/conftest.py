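import numpy as np
import pytest

import nemasim as ns
from nemasim.builder import ParameterSet
from nemasim.dynamics import LIFParams, ConductanceCellParams, SpikeSynapseParams, GapJunctionParams


@pytest.fixture(scope="session")
def params_a():
    return ParameterSet.from_level("A")


@pytest.fixture(scope="session")
def params_b():
    return ParameterSet.from_level("B")


@pytest.fixture(scope="session")
def params_c():
    return ParameterSet.from_level("C")


@pytest.fixture(scope="session")
def params_c1():
    return ParameterSet.from_level("C1")


def make_passive_lif_params(g_leak=0.1, C_m=3.0, E_leak=-60.0):
    """Level-A parameter set whose cells never spike (threshold far away):
    a plain RC membrane for closed-form comparisons."""
    cell = LIFParams(C_m=C_m, g_leak=g_leak, E_leak=E_leak,
                     V_thresh=1e6, V_reset=E_leak, t_refract=1.0)
    return ParameterSet(
        level="A", neuron_params=cell, muscle_params=cell,
        exc_syn=SpikeSynapseParams(E_syn=0.0, tau_decay=10.0),
        inh_syn=SpikeSynapseParams(E_syn=-70.0, tau_decay=10.0),
        gap=GapJunctionParams(), baseline_chem=0.01, baseline_gap=0.01)


def make_passive_conductance_params(g_leak=0.1, C_m=3.0, E_leak=-60.0):
    """Level-C parameter set with no channels: passive single compartments."""
    cell = ConductanceCellParams(C_m=C_m, g_leak=g_leak, E_leak=E_leak,
                                 channels=(), ca_rho=0.0, ca_tau=200.0)
    return ParameterSet(
        level="C", neuron_params=cell, muscle_params=cell,
        exc_syn=SpikeSynapseParams(E_syn=0.0, tau_decay=10.0),
        inh_syn=SpikeSynapseParams(E_syn=-70.0, tau_decay=10.0),
        gap=GapJunctionParams(), baseline_chem=0.01, baseline_gap=0.01)


def single_cell_network(pset, stimuli=()):
    """One isolated neuron named N1 under the given parameter set."""
    from nemasim.connectome import CellIdentity, Connectome

    c = Connectome(cells={"N1": CellIdentity("N1")})
    net = ns.build_network(c, parameter_set=pset)
    return net.with_stimuli(stimuli)


@pytest.fixture(scope="session")
def locomotion_run():
    """The canonical 5 s forward-locomotion run (level C1, shipped defaults),
    shared across analysis tests because it is the most expensive input."""
    p = ParameterSet.from_level("C1")
    cfg = ns.LocomotionConfig()
    net = ns.build_forward_locomotion(p, cfg)
    result = ns.simulate(net, ns.SimulationSpec(duration=5000.0, dt=0.05,
                                                record_every=10))
    return net, cfg, result
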