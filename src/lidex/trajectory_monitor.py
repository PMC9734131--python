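"""NOE-violation monitoring of trajectories against reference states.

For a set of state-specific methyl-methyl contacts {ij}, the per-frame
violation statistic is

    V(t) = (1/N) sum_ij max(0, d_ij(t) - d_ij^viol),

where the threshold d_ij^viol = <d_ij> + 2 sigma(d_ij) is taken over the
reference bundle of refined structures and d_ij is the barycenter-to-
barycenter distance of the methyl proton triplets.  Tracking V against the
starting state's own contacts and against the other state's contacts
classifies each trajectory as stable, transitioned, or neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_geometry import ConformerEnsemble
from .restraints import AtomGroup, DistanceRestraint, group_position

__all__ = [
    "ViolationSpec",
    "ViolationSeries",
    "ClassifyParams",
    "build_violation_spec",
    "violation_series",
    "classify_trajectory",
]


@dataclass
class ViolationSpec:
    """State-specific contact pairs and their violation thresholds."""

    state_label: str
    pairs: list[tuple[AtomGroup, AtomGroup]]
    d_viol: np.ndarray  # per-pair threshold, A

    def __post_init__(self) -> None:
        self.d_viol = np.asarray(self.d_viol, dtype=float)
        if len(self.pairs) == 0:
            raise ValueError("violation spec needs at least one pair")
        if len(self.d_viol) != len(self.pairs):
            raise ValueError("d_viol length must match the pair count")
        if np.any(self.d_viol <= 0):
            raise ValueError("all violation thresholds must be positive")


@dataclass
class ViolationSeries:
    """Per-frame violation statistic V for one trajectory and state."""

    times: np.ndarray
    V: np.ndarray
    state_label: str
    n_pairs: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if len(self.times) != len(self.V):
            raise ValueError("times and V must have equal length")
        if np.any(self.V < -1e-12):
            raise ValueError("V must be non-negative")


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds for the stable / transitioned / neither call.

    All distances in angstroms; ``window`` is the moving-average width in
    frames and ``final_fraction`` the trailing portion of the trajectory
    examined for arrival in the other state.
    """

    eps_stable: float = 0.5
    eps_arrive: float = 0.5
    eps_depart: float = 1.0
    window: int = 10
    final_fraction: float = 0.2


def _pair_distances(ens: ConformerEnsemble,
                    pairs: list[tuple[AtomGroup, AtomGroup]]) -> np.ndarray:
    """(n_models, n_pairs) barycenter distances; raises naming missing pairs."""
    out = np.empty((ens.n_models, len(pairs)))
    for j, (gi, gj) in enumerate(pairs):
        try:
            for m in range(ens.n_models):
                model = ens.model(m)
                d = group_position(model, gi) - group_position(model, gj)
                out[m, j] = np.linalg.norm(d)
        except KeyError as err:
            raise KeyError(
                f"pair {gi.residue_number}-{gj.residue_number} unresolvable: {err}"
            ) from None
    return out


def build_violation_spec(
    reference_ensemble: ConformerEnsemble,
    state_restraints: list[DistanceRestraint],
    ddof: int = 0,
) -> ViolationSpec:
    """Thresholds d_viol = mean + 2 std over the reference bundle.

    The population standard deviation (``ddof=0``) is used by default —
    the bundle is the complete reference set, not a sample.
    """
    if reference_ensemble.n_models < 2:
        raise ValueError("reference ensemble needs >= 2 models")
    pairs = [(r.group_i, r.group_j) for r in state_restraints]
    dists = _pair_distances(reference_ensemble, pairs)
    d_viol = dists.mean(axis=0) + 2.0 * dists.std(axis=0, ddof=ddof)
    return ViolationSpec(
        state_label=reference_ensemble.label, pairs=pairs, d_viol=d_viol
    )


def violation_series(
    trajectory: ConformerEnsemble, spec: ViolationSpec
) -> ViolationSeries:
    """Per-frame V = mean over pairs of max(0, d - d_viol)."""
    dists = _pair_distances(trajectory, spec.pairs)
    v = np.maximum(0.0, dists - spec.d_viol[None, :]).mean(axis=1)
    times = (
        trajectory.times
        if trajectory.times is not None
        else np.arange(trajectory.n_models, dtype=float)
    )
    return ViolationSeries(times=times, V=v, state_label=spec.state_label,
                           n_pairs=len(spec.pairs))


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v
    window = min(window, len(v))
    kernel = np.ones(window) / window
    # same-length smoothing with edge renormalization
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def classify_trajectory(
    v_home: ViolationSeries,
    v_other: ViolationSeries,
    params: ClassifyParams | None = None,
) -> str:
    """Classify a trajectory as ``"stable"``, ``"transitioned"`` or
    ``"neither"``.

    ``v_home`` is computed against the starting state's contacts, and
    ``v_other`` against the other state's.  After moving-average smoothing:
    stable if the home violation never exceeds ``eps_stable``; transitioned
    if over the final fraction of frames the other-state violation stays
    below ``eps_arrive`` while the home violation exceeds ``eps_depart``.
    """
    params = params or ClassifyParams()
    if len(v_home.V) != len(v_other.V) or not np.allclose(
        v_home.times, v_other.times
    ):
        raise ValueError("home and other series must share one time grid")
    home = _smooth(v_home.V, params.window)
    other = _smooth(v_other.V, params.window)
    if np.all(home < params.eps_stable):
        return "stable"
    n_tail = max(1, int(round(params.final_fraction * len(home))))
    if np.all(other[-n_tail:] < params.eps_arrive) and np.all(
        home[-n_tail:] > params.eps_depart
    ):
        return "transitioned"
    return "neither"
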