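import numpy as np
import pytest

from pulsesv import (ArterialSegment, ArterialTree, SolverConfig, SubjectRecord,
                     WindkesselTerminal, build_generic_tree, build_inflow,
                     simulate, subject_tree)
from pulsesv.solver import PressureFlowField
from pulsesv.units import MMHG_TO_PA


@pytest.fixture(scope="session")
def generic_tree():
    return build_generic_tree()


@pytest.fixture(scope="session")
def mean_subject():
    """A subject at the cohort-mean operating point."""
    return SubjectRecord(id="mean", gender="F", age=49, height_cm=170,
                         weight_kg=70, brsbp_mmhg=122, brdbp_mmhg=71,
                         hr_bpm=66, cfpwv_mps=7.0)


@pytest.fixture(scope="session")
def dd_subject():
    """The virtual diastolic-dysfunction (restrictive phenotype) subject."""
    return SubjectRecord(id="virtual-dd", gender="M", age=60, height_cm=170,
                         weight_kg=70, brsbp_mmhg=127, brdbp_mmhg=61,
                         hr_bpm=75, cfpwv_mps=5.97, sv_ref_ml=83.0)


@pytest.fixture(scope="session")
def mean_tree(mean_subject):
    return subject_tree(mean_subject)


@pytest.fixture(scope="session")
def default_inflow():
    return build_inflow(66, 450.0)


@pytest.fixture(scope="session")
def mean_field(mean_tree, default_inflow):
    """Forward run at the cohort-mean tree with the reference inflow."""
    return simulate(mean_tree, default_inflow)


@pytest.fixture(scope="session")
def fine_field(mean_tree, default_inflow):
    """Same run at half the spatial (and hence time) step."""
    return simulate(mean_tree, default_inflow, SolverConfig(dx_cm=0.25))


def make_uniform_tube(d_per_mmhg=1.925e-5 * MMHG_TO_PA, area_cm2=3.0,
                      seg_len_cm=30.0):
    """A straight lossless 3-segment tube with two wave-timing sites.

    The "carotid" site sits 10 cm in and the "femoral" site 70 cm in, so the
    subtracted path is exactly 0.6 m.  The terminal characteristic resistance
    is impedance-matched (transients absorbed) and the peripheral resistance
    is huge, so a quiescent tube stays quiescent and the first passage of a
    test pulse is clean.
    """
    rho = 1060.0
    c = 1.0 / np.sqrt(rho * d_per_mmhg / MMHG_TO_PA)
    z_clin = rho * c / (area_cm2 * 1e-4) * 1e-6 / MMHG_TO_PA
    segs = [ArterialSegment(f"tube_{i}", seg_len_cm, area_cm2, area_cm2,
                            d_per_mmhg, is_terminal=(i == 2)) for i in range(3)]
    tree = ArterialTree(
        segments=segs,
        parent_of={"tube_0": None, "tube_1": "tube_0", "tube_2": "tube_1"},
        terminals={"tube_2": WindkesselTerminal("tube_2", z_clin, 1e4, 0.2)},
        sites={"carotid": ("tube_0", 1.0 / 3.0),
               "brachial": ("tube_1", 0.5),
               "femoral": ("tube_2", 1.0 / 3.0)},
        blood_viscosity_mpa_s=0.0,
    )
    tree.validate()
    return tree


def pulse_wave(q_peak=100.0, width_s=0.05, t_period=1.0):
    """A single short sin^2 test pulse for first-passage wave timing."""
    from pulsesv import InflowWave
    t = np.arange(int(t_period * 1000)) * 1e-3
    flow = np.where(t < width_s,
                    q_peak * np.sin(np.pi * t / width_s) ** 2, 0.0)
    return InflowWave(t_period=t_period, t_systole=width_s, q_max=q_peak,
                      t_qmax=width_s / 2, time=t, flow=flow)


def first_passage_speed(tree):
    """Foot-to-foot speed of a single transient pulse between the two sites."""
    from pulsesv import SolverConfig, simulate
    from pulsesv.observables import model_cfpwv
    cfg = SolverConfig(init_pressure_mmhg=100.0, max_beats=1)
    field = simulate(tree, pulse_wave(), cfg)
    return model_cfpwv(field, tree)


@pytest.fixture()
def uniform_tube():
    return make_uniform_tube()


def synthetic_field(t, pressures, positions=None):
    """Wrap bare pressure series in a PressureFlowField for observable tests."""
    z = np.zeros_like(t)
    return PressureFlowField(
        t=t, dt=float(t[1] - t[0]), pressures=pressures,
        flows={k: z for k in pressures}, inflow=z, terminal_flows={},
        volume=z, volume_start=0.0, n_beats_run=1, periodicity_residual=0.0,
        converged=True, site_positions_m=positions or {})
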