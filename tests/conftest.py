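import numpy as np
import pytest

from lidex.dispersion_fit import DispersionCurve, DispersionDataset, filter_curves
from lidex.exchange_model import (
    CpmgSchedule,
    DispersionPoint,
    ExchangeParameters,
    NucleusMode,
    ProbeParameters,
    exchange_contribution,
)
from lidex.synthetic_data import (
    gen_dispersion_dataset,
    gen_reference_ensemble,
    gen_toy_system,
    make_state_restraints,
    wt_like_truth,
)


@pytest.fixture(scope="session")
def wt_exchange():
    """Wild-type-like global exchange parameters (293 K fit)."""
    return ExchangeParameters(p_excited=0.032, k_ex=2490.0, temperature=293.0)


@pytest.fixture(scope="session")
def mq_schedule():
    return CpmgSchedule.default_mq()


def make_noiseless_dataset(exch, probes, fields=(700.0, 850.0), schedule=None):
    """Exact forward-model dataset (no noise, floor sigmas)."""
    schedule = schedule or CpmgSchedule.default_mq()
    nu = np.asarray(schedule.nu_list)
    curves = {}
    for probe in probes:
        pts = []
        for f in fields:
            rex = exchange_contribution(exch, probe, f, nu, schedule.t_relax)
            r2 = probe.r2_base[f] + rex
            for v, r in zip(nu, r2):
                pts.append(DispersionPoint(f, float(v), float(r),
                                           max(0.02 * float(r), 1e-3)))
        curves[probe.probe_id] = DispersionCurve(probe, pts)
    return DispersionDataset(curves, {schedule.nucleus_mode: schedule},
                             exch.temperature)


def small_probes(n=3, fields=(700.0, 850.0), seed=11):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(
            ProbeParameters(
                f"P{i:02d}-CD1",
                NucleusMode.CH3_MQ,
                dw_X=float(rng.uniform(0.8, 2.0)),
                dw_H=float(rng.uniform(0.05, 0.2)),
                r2_base={f: float(rng.uniform(10.0, 16.0)) for f in fields},
            )
        )
    return out


@pytest.fixture(scope="session")
def small_noisy_dataset(wt_exchange):
    """5-probe, one-field noisy dataset for the stochastic fit tests."""
    truth = wt_like_truth(seed=5, n_probes=5, exch=wt_exchange,
                          fields_MHz=(700.0, 850.0))
    return filter_curves(gen_dispersion_dataset(truth)), truth


@pytest.fixture(scope="session")
def toy_system():
    return gen_toy_system(n_core=30, displacement=20.0, seed=0)


@pytest.fixture(scope="session")
def toy_restraints(toy_system):
    return make_state_restraints(toy_system)


@pytest.fixture(scope="session")
def reference_bundles(toy_system):
    ens_a = gen_reference_ensemble(toy_system, "A", n_models=20,
                                   coord_noise=0.3, seed=1)
    ens_b = gen_reference_ensemble(toy_system, "B", n_models=20,
                                   coord_noise=0.3, seed=2)
    return ens_a, ens_b
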