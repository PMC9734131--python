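"""Synthetic inputs with known ground truth for every pipeline stage.

Three families of generators, each a pure function of its parameters and a
seed:

* multi-field CPMG dispersion datasets computed from the two-state
  forward models and perturbed with multiplicative Gaussian noise
  (default 2% of R2,eff, matching the error convention of the fitting
  stage);
* a two-conformation toy protein — a rigid helical core carrying methyl
  groups plus a mobile segment whose conformation B is rigidly displaced
  from conformation A — standing in for open/closed structural ensembles;
* reference bundles (noisy copies of one conformation) and two-state jump
  trajectories (telegraph process between the conformations with
  coordinate noise), for the clustering and violation-monitoring stages.

The toy coordinates use real residue/atom naming conventions (ILE CD1 with
HD11–HD13 protons) so that restraint evaluation and PDB round-trips
exercise realistic parsing paths.  None of this emulates force-field
physics or spectral artefacts; it provides geometry and statistics with
known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dispersion_fit import DispersionCurve, DispersionDataset, apply_error_floor
from .ensemble_geometry import ConformerEnsemble
from .exchange_model import (
    CpmgSchedule,
    DispersionPoint,
    ExchangeParameters,
    NucleusMode,
    ProbeParameters,
    exchange_contribution,
)
from .restraints import AtomGroup, DistanceRestraint, StateTag

__all__ = [
    "SyntheticTruth",
    "ToySystem",
    "wt_like_truth",
    "gen_dispersion_dataset",
    "gen_toy_system",
    "gen_reference_ensemble",
    "gen_jump_trajectory",
    "make_state_restraints",
]

#: methyl-bearing residue types used for invented probe labels
_METHYL_TYPES = [
    ("ILE", "CD1", ("HD11", "HD12", "HD13")),
    ("LEU", "CD2", ("HD21", "HD22", "HD23")),
    ("MET", "CE", ("HE1", "HE2", "HE3")),
    ("THR", "CG2", ("HG21", "HG22", "HG23")),
    ("ALA", "CB", ("HB1", "HB2", "HB3")),
    ("VAL", "CG2", ("HG21", "HG22", "HG23")),
]


@dataclass
class SyntheticTruth:
    """Generating parameters of a synthetic dispersion dataset."""

    exch: ExchangeParameters
    probes: list[ProbeParameters]
    fields_MHz: tuple[float, ...] = (700.0, 850.0)
    noise_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


def wt_like_truth(
    seed: int = 0,
    n_probes: int = 21,
    exch: ExchangeParameters | None = None,
    fields_MHz: tuple[float, ...] = (700.0, 850.0),
    noise_fraction: float = 0.02,
) -> SyntheticTruth:
    """Truth emulating the wild-type methyl-MQ study conditions.

    Defaults: 21 methyl MQ probes at 700 and 850 MHz with 2% noise and
    global parameters p_B = 3.2%, k_ex = 2490 s^-1 at 293 K.  Per-probe
    shift differences and baselines are drawn once from ranges typical of
    methyl probes in chemical exchange (|dw_C| 0.3–2.2 ppm, |dw_H|
    0.02–0.25 ppm, R2,0 8–20 s^-1).
    """
    exch = exch or ExchangeParameters(p_excited=0.032, k_ex=2490.0,
                                      temperature=293.0)
    rng = np.random.default_rng(seed)
    probes = []
    for i in range(n_probes):
        resname, carbon, _ = _METHYL_TYPES[i % len(_METHYL_TYPES)]
        pid = f"{resname[0]}{100 + i}-{carbon}"
        r2 = {
            f: float(rng.uniform(8.0, 20.0) * (f / fields_MHz[0]) ** 0.5)
            for f in fields_MHz
        }
        probes.append(
            ProbeParameters(
                probe_id=pid,
                nucleus_mode=NucleusMode.CH3_MQ,
                dw_X=float(rng.uniform(0.3, 2.2)),
                dw_H=float(rng.uniform(0.02, 0.25)),
                r2_base=r2,
            )
        )
    return SyntheticTruth(exch, probes, tuple(fields_MHz), noise_fraction, seed)


def gen_dispersion_dataset(
    truth: SyntheticTruth, schedule: CpmgSchedule | None = None
) -> DispersionDataset:
    """Forward-model R2,eff curves with multiplicative Gaussian noise.

    The noise standard deviation is ``noise_fraction * R2,eff``; the sigma
    column is that generating value passed through the 2% error floor.
    Deterministic given ``truth.seed``.
    """
    if schedule is None:
        schedule = CpmgSchedule.default_mq()
    if not schedule.nu_list:
        raise ValueError("schedule has no CPMG frequencies")
    rng = np.random.default_rng(truth.seed)
    nu = np.asarray(schedule.nu_list)
    curves: dict[str, DispersionCurve] = {}
    for probe in truth.probes:
        pts = []
        for f in truth.fields_MHz:
            rex = exchange_contribution(truth.exch, probe, f, nu, schedule.t_relax)
            r2eff = probe.r2_base[f] + rex
            sigma_gen = truth.noise_fraction * r2eff
            noisy = r2eff + rng.standard_normal(len(nu)) * sigma_gen
            for v, r, s in zip(nu, noisy, sigma_gen):
                sig = apply_error_floor(max(float(r), 0.0), float(s))
                pts.append(DispersionPoint(f, float(v), float(r), max(sig, 1e-6)))
        curves[probe.probe_id] = DispersionCurve(probe, pts)
    return DispersionDataset(
        curves=curves,
        schedules={schedule.nucleus_mode: schedule},
        temperature=truth.exch.temperature,
    )


# ---------------------------------------------------------------------------
# toy structural system


@dataclass
class ToySystem:
    """Two-conformation toy protein with a rigid core and a mobile segment."""

    atoms: pd.DataFrame  # shared atom table (resid, resname, name)
    coords_a: np.ndarray
    coords_b: np.ndarray
    core_resids: tuple[int, ...]
    mobile_resids: tuple[int, ...]
    methyl_groups: list[AtomGroup] = field(default_factory=list)
    displacement: float = 0.0

    def ensemble(self, state: str) -> ConformerEnsemble:
        coords = {"A": self.coords_a, "B": self.coords_b}[state]
        return ConformerEnsemble(self.atoms, coords[None, :, :], label=state)


_BACKBONE_OFFSETS = {
    "N": np.array([1.2, 0.4, -0.8]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([-1.0, 0.9, 0.7]),
    "O": np.array([-0.7, 2.0, 1.1]),
}
# proton offsets around the methyl carbon (barycenter sits 0.33 A below it)
_METHYL_H_OFFSETS = np.array(
    [[0.94, 0.0, -0.33], [-0.47, 0.82, -0.33], [-0.47, -0.82, -0.33]]
)


def _residue_atoms(resid, resname, ca, methyl=None):
    rows, xyz = [], []
    for name, off in _BACKBONE_OFFSETS.items():
        rows.append((resid, resname, name))
        xyz.append(ca + off)
    if methyl is not None:
        carbon_name, proton_names, c_pos = methyl
        rows.append((resid, resname, carbon_name))
        xyz.append(c_pos)
        for pn, off in zip(proton_names, _METHYL_H_OFFSETS):
            rows.append((resid, resname, pn))
            xyz.append(c_pos + off)
    return rows, xyz


def gen_toy_system(
    n_core: int = 30,
    displacement: float = 20.0,
    n_mobile: int = 8,
    seed: int = 0,
) -> ToySystem:
    """Reproducible two-conformation toy protein.

    The core is an ideal helix (rise 1.5 A, 100 deg/residue) carrying ILE
    methyls on every third residue; the mobile segment extends beyond the
    core in conformation A and is rigidly displaced by ``displacement``
    (partly sideways, partly back along the core) in conformation B, so
    that both conformations form methyl-methyl contacts with the core and
    ``region_rmsd(A, B)`` measured on the mobile segment equals the
    displacement exactly.
    """
    if n_core < 10:
        raise ValueError("n_core must be >= 10")
    if displacement <= 0:
        raise ValueError("displacement must be positive")
    rng = np.random.default_rng(seed)
    rows: list[tuple[int, str, str]] = []
    xyz: list[np.ndarray] = []
    methyls: list[AtomGroup] = []
    radius, rise, twist = 2.3, 1.5, math.radians(100.0)

    for i in range(n_core):
        resid = i + 1
        theta = i * twist
        ca = np.array([radius * math.cos(theta), radius * math.sin(theta),
                       rise * i])
        methyl = None
        resname = "GLY"
        if i % 3 == 1:
            resname = "ILE"
            outward = np.array([math.cos(theta), math.sin(theta), 0.0])
            c_pos = ca + 1.8 * outward + np.array([0.0, 0.0, 0.3])
            methyl = ("CD1", ("HD11", "HD12", "HD13"), c_pos)
            methyls.append(AtomGroup(resid, "ILE", ("HD11", "HD12", "HD13")))
        r, x = _residue_atoms(resid, resname, ca, methyl)
        rows += r
        xyz += x

    # mobile segment (conformation A): straight continuation above the core
    z_top = rise * n_core
    for m in range(n_mobile):
        resid = n_core + 1 + m
        ca = np.array([radius, 0.0, z_top + 1.0 + 1.8 * m])
        methyl = None
        resname = "ALA"
        if m % 2 == 0:
            resname = "ILE"
            c_pos = ca + np.array([-1.8, 0.0, 0.0])
            methyl = ("CD1", ("HD11", "HD12", "HD13"), c_pos)
            methyls.append(AtomGroup(resid, "ILE", ("HD11", "HD12", "HD13")))
        r, x = _residue_atoms(resid, resname, ca, methyl)
        rows += r
        xyz += x

    atoms = pd.DataFrame(rows, columns=["resid", "resname", "name"])
    coords_a = np.array(xyz)
    # add a reproducible sub-angstrom ruffle so the toy is not perfectly
    # regular (exercises superposition on non-ideal geometry)
    coords_a = coords_a + rng.normal(0.0, 0.05, coords_a.shape)

    # conformation B: mobile segment rigidly translated sideways/downwards
    lateral = min(3.7, 0.5 * displacement)
    shift = np.array(
        [lateral, 0.0, -math.sqrt(max(displacement**2 - lateral**2, 0.0))]
    )
    if np.linalg.norm(shift) == 0.0:
        raise ValueError("degenerate displacement")
    mobile_mask = atoms["resid"].to_numpy() > n_core
    coords_b = coords_a.copy()
    coords_b[mobile_mask] += shift

    return ToySystem(
        atoms=atoms,
        coords_a=coords_a,
        coords_b=coords_b,
        core_resids=tuple(range(1, n_core + 1)),
        mobile_resids=tuple(range(n_core + 1, n_core + n_mobile + 1)),
        methyl_groups=methyls,
        displacement=displacement,
    )


def make_state_restraints(
    system: ToySystem,
    contact_cutoff: float = 6.0,
    far_cutoff: float = 8.5,
) -> tuple[list[DistanceRestraint], list[DistanceRestraint], list[DistanceRestraint]]:
    """Methyl-methyl restraints classified by the generating geometry.

    Returns (A-specific, B-specific, shared) restraint lists: a pair is
    state-specific when its barycenter distance is within
    ``contact_cutoff`` in that conformation and beyond ``far_cutoff`` in
    the other, and shared when within ``far_cutoff`` in both.
    """
    from .restraints import restraint_distance  # local import avoids cycle

    model_a = system.ensemble("A").model(0)
    model_b = system.ensemble("B").model(0)
    a_specific, b_specific, shared = [], [], []
    groups = system.methyl_groups
    counter = 0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            probe = DistanceRestraint(
                f"tmp", groups[i], groups[j], 2.0, contact_cutoff
            )
            d_a = restraint_distance(model_a, probe)
            d_b = restraint_distance(model_b, probe)
            counter += 1
            rid = f"r{counter:03d}"
            if d_a <= contact_cutoff and d_b > far_cutoff:
                a_specific.append(
                    DistanceRestraint(rid, groups[i], groups[j], 2.0,
                                      contact_cutoff,
                                      state_tag=StateTag.OPEN_SPECIFIC)
                )
            elif d_b <= contact_cutoff and d_a > far_cutoff:
                b_specific.append(
                    DistanceRestraint(rid, groups[i], groups[j], 2.0,
                                      contact_cutoff,
                                      state_tag=StateTag.CLOSED_SPECIFIC)
                )
            elif d_a <= far_cutoff and d_b <= far_cutoff:
                shared.append(
                    DistanceRestraint(rid, groups[i], groups[j], 2.0,
                                      far_cutoff, state_tag=StateTag.SHARED)
                )
    return a_specific, b_specific, shared


def gen_reference_ensemble(
    system: ToySystem,
    state: str,
    n_models: int = 20,
    coord_noise: float = 0.3,
    seed: int = 0,
) -> ConformerEnsemble:
    """Bundle of noisy copies of one conformation (reference ensemble)."""
    if coord_noise < 0:
        raise ValueError("coord_noise must be >= 0")
    base = {"A": system.coords_a, "B": system.coords_b}[state]
    rng = np.random.default_rng(seed)
    coords = base[None, :, :] + rng.normal(
        0.0, coord_noise, (n_models,) + base.shape
    )
    return ConformerEnsemble(system.atoms, coords, label=state)


def gen_jump_trajectory(
    system: ToySystem,
    n_frames: int = 100,
    p_switch: float = 0.02,
    seed: int = 0,
    coord_noise: float = 0.3,
    start_state: str = "B",
    forced_switch_frame: int | None = None,
    blend_frames: int = 4,
) -> tuple[ConformerEnsemble, np.ndarray]:
    """Two-state jump trajectory between the toy conformations.

    The latent state follows a telegraph process with per-frame switch
    probability ``p_switch`` (or a single forced switch at
    ``forced_switch_frame``); coordinates linearly interpolate between the
    conformations over ``blend_frames`` frames at each switch and carry
    isotropic Gaussian noise.  Returns the trajectory (with frame times)
    and the latent state series ("A"/"B") as ground truth.
    """
    if not 0.0 <= p_switch <= 1.0:
        raise ValueError("p_switch must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    states = np.empty(n_frames, dtype="<U1")
    s = start_state
    for t in range(n_frames):
        if forced_switch_frame is not None:
            if t == forced_switch_frame:
                s = "A" if s == "B" else "B"
        elif t > 0 and rng.random() < p_switch:
            s = "A" if s == "B" else "B"
        states[t] = s
    # fractional position between A (0) and B (1), smoothed at switches
    target = (states == "B").astype(float)
    frac = target.copy()
    if blend_frames > 1:
        kernel = np.ones(blend_frames) / blend_frames
        frac = np.convolve(target, kernel, mode="same") / np.convolve(
            np.ones_like(target), kernel, mode="same"
        )
    coords = (
        (1.0 - frac)[:, None, None] * system.coords_a[None]
        + frac[:, None, None] * system.coords_b[None]
    )
    coords += rng.normal(0.0, coord_noise, coords.shape)
    ens = ConformerEnsemble(
        system.atoms, coords, label=f"traj-{start_state}",
        times=np.arange(n_frames, dtype=float),
    )
    return ens, states
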