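"""NOE-derived distance restraints with methyl pseudo-atoms.

Distance bounds are derived qualitatively from NOESY cross-peak intensity
classes; inter-methyl distances are evaluated between the barycenters
(unweighted centroids) of the three methyl protons.  Restraints can be
checked against single structures or conformational ensembles and
partitioned between two structural states (satisfied only by A, only by
B, by both, or by neither) — the operation used to tell state-specific
contacts apart from shared ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .ensemble_geometry import ConformerEnsemble, Model, representative_model

__all__ = [
    "PeakClass",
    "StateTag",
    "AtomGroup",
    "DistanceRestraint",
    "SatisfactionRecord",
    "TwoStatePartition",
    "derive_bounds",
    "group_position",
    "restraint_distance",
    "evaluate_on_ensemble",
    "partition_two_states",
]

DEFAULT_TOLERANCE = 0.5  # A of slack above the upper bound


class PeakClass(str, Enum):
    """NOESY cross-peak intensity/provenance classes."""

    STRONG_SHORT_MIX = "strong_short_mix"
    WEAK_SHORT_MIX = "weak_short_mix"
    LONG_MIX_ONLY = "long_mix_only"
    HN_HN = "hn_hn"
    SINGLE_DATASET_2_8 = "single_dataset_2_8"
    HBOND_DONOR_H = "hbond_donor_H"
    HBOND_DONOR_N = "hbond_donor_N"


class StateTag(str, Enum):
    UNASSIGNED = "unassigned"
    OPEN_SPECIFIC = "open_specific"
    CLOSED_SPECIFIC = "closed_specific"
    SHARED = "shared"


#: class -> (lower, upper) distance bounds in angstroms
_BOUNDS = {
    PeakClass.STRONG_SHORT_MIX: (2.0, 4.0),
    PeakClass.WEAK_SHORT_MIX: (4.0, 6.0),
    PeakClass.LONG_MIX_ONLY: (4.0, 8.0),
    PeakClass.HN_HN: (2.0, 6.0),
    PeakClass.SINGLE_DATASET_2_8: (2.0, 8.0),
    # H-bond restraints to acceptor oxygens: hydrogen donor atom within
    # 2 A, nitrogen donor atom within 3 A (geometric pairing of the 2/3 A
    # limits: the N sits one covalent bond further from the acceptor)
    PeakClass.HBOND_DONOR_H: (0.0, 2.0),
    PeakClass.HBOND_DONOR_N: (0.0, 3.0),
}


def derive_bounds(peak_class: PeakClass | str) -> tuple[float, float]:
    """Distance bounds (lower, upper) in A for an intensity class."""
    try:
        pc = PeakClass(peak_class)
    except ValueError:
        raise ValueError(f"unknown peak class {peak_class!r}") from None
    lo, up = _BOUNDS[pc]
    return lo, up


@dataclass(frozen=True)
class AtomGroup:
    """One restraint endpoint: a single atom or a methyl proton triplet."""

    residue_number: int
    residue_name: str
    atom_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        if len(self.atom_names) not in (1, 3):
            raise ValueError(
                f"atom group of residue {self.residue_number} must list 1 atom "
                f"or a 3-proton triplet; got {self.atom_names}"
            )

    @property
    def representation(self) -> str:
        return "proton_barycenter" if len(self.atom_names) == 3 else "single_atom"


@dataclass
class DistanceRestraint:
    """Distance restraint between two (pseudo-)atom groups."""

    id: str
    group_i: AtomGroup
    group_j: AtomGroup
    lower: float
    upper: float
    peak_class: PeakClass | None = None
    state_tag: StateTag = StateTag.UNASSIGNED

    def __post_init__(self) -> None:
        if self.peak_class is not None:
            self.peak_class = PeakClass(self.peak_class)
        self.state_tag = StateTag(self.state_tag)
        if not 0 <= self.lower < self.upper:
            raise ValueError(
                f"restraint {self.id}: need 0 <= lower < upper, got "
                f"({self.lower}, {self.upper})"
            )

    @classmethod
    def from_peak_class(
        cls, id: str, group_i: AtomGroup, group_j: AtomGroup,
        peak_class: PeakClass | str, **kw,
    ) -> "DistanceRestraint":
        lo, up = derive_bounds(peak_class)
        # H-bond classes carry lower = 0; the dataclass check wants lower < upper
        return cls(id, group_i, group_j, lo, up,
                   peak_class=PeakClass(peak_class), **kw)


@dataclass
class SatisfactionRecord:
    """Evaluation of one restraint against one state/ensemble."""

    restraint_id: str
    state_label: str
    distance: float  # on the representative model
    satisfied: bool
    margin: float  # upper - distance (negative when violated)
    per_model_distances: np.ndarray | None = field(default=None, repr=False)


@dataclass
class TwoStatePartition:
    """Restraints classified by satisfaction in two states A and B."""

    a_only: list[str]
    b_only: list[str]
    both: list[str]
    neither: list[str]
    records_a: list[SatisfactionRecord]
    records_b: list[SatisfactionRecord]

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (len(self.a_only), len(self.b_only), len(self.both),
                len(self.neither))


def group_position(model: Model, group: AtomGroup) -> np.ndarray:
    """Cartesian position of a group: the atom itself, or the proton
    barycenter (unweighted mean of the three methyl protons)."""
    resid = model.atoms["resid"].to_numpy()
    names = model.atoms["name"].to_numpy()
    coords = []
    for atom in group.atom_names:
        hit = np.flatnonzero((resid == group.residue_number) & (names == atom))
        if len(hit) == 0:
            raise KeyError(
                f"atom {atom} of residue {group.residue_number} "
                f"({group.residue_name}) not found in model"
            )
        coords.append(model.xyz[hit[0]])
    return np.mean(coords, axis=0)


def restraint_distance(
    model: Model, restraint: DistanceRestraint, averaging: str = "barycenter"
) -> float:
    """Distance between the restraint's groups in one model.

    ``averaging="barycenter"`` (default) measures between proton
    barycenters; ``"r6"`` applies r^-6 averaging over all proton-proton
    pairs, for sensitivity analysis.
    """
    if averaging == "barycenter":
        d = group_position(model, restraint.group_i) - group_position(
            model, restraint.group_j
        )
        return float(np.linalg.norm(d))
    if averaging == "r6":
        pos_i = [
            group_position(
                model,
                AtomGroup(restraint.group_i.residue_number,
                          restraint.group_i.residue_name, (a,)),
            )
            for a in restraint.group_i.atom_names
        ]
        pos_j = [
            group_position(
                model,
                AtomGroup(restraint.group_j.residue_number,
                          restraint.group_j.residue_name, (a,)),
            )
            for a in restraint.group_j.atom_names
        ]
        inv6 = [
            np.linalg.norm(pi - pj) ** -6.0 for pi in pos_i for pj in pos_j
        ]
        return float(np.mean(inv6) ** (-1.0 / 6.0))
    raise ValueError(f"unknown averaging mode {averaging!r}")


def evaluate_on_ensemble(
    ensemble: ConformerEnsemble,
    restraints: list[DistanceRestraint],
    tolerance: float = DEFAULT_TOLERANCE,
    mode: str = "representative",
    fraction: float = 0.5,
    check_lower: bool = False,
    averaging: str = "barycenter",
) -> list[SatisfactionRecord]:
    """Evaluate restraints against an ensemble.

    ``mode="representative"`` judges satisfaction on the medoid conformer;
    ``mode="fraction"`` requires satisfaction in at least ``fraction`` of
    the members.  A restraint is satisfied when its distance is at most
    ``upper + tolerance`` (and, with ``check_lower``, at least
    ``lower - tolerance``).  Per-model distances are always reported.
    """
    if ensemble.n_models == 0:
        raise ValueError("empty ensemble")
    if mode not in ("representative", "fraction"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    rep = representative_model(ensemble) if mode == "representative" else None
    records = []
    for r in restraints:
        dists = np.array(
            [
                restraint_distance(ensemble.model(i), r, averaging)
                for i in range(ensemble.n_models)
            ]
        )
        ok = dists <= r.upper + tolerance
        if check_lower:
            ok &= dists >= r.lower - tolerance
        if mode == "representative":
            satisfied = bool(ok[rep])
            dist = float(dists[rep])
        else:
            satisfied = bool(ok.mean() >= fraction)
            dist = float(np.median(dists))
        records.append(
            SatisfactionRecord(
                restraint_id=r.id,
                state_label=ensemble.label,
                distance=dist,
                satisfied=satisfied,
                margin=float(r.upper - dist),
                per_model_distances=dists,
            )
        )
    return records


def _check_resolvable(ensembles: list[ConformerEnsemble],
                      restraints: list[DistanceRestraint]) -> None:
    missing = []
    for ens in ensembles:
        model = ens.model(0)
        for r in restraints:
            for g in (r.group_i, r.group_j):
                try:
                    group_position(model, g)
                except KeyError:
                    missing.append(
                        f"{r.id}: residue {g.residue_number} "
                        f"({'/'.join(g.atom_names)}) absent from "
                        f"ensemble {ens.label or '?'}"
                    )
    if missing:
        raise ValueError("unresolvable restraints:\n" + "\n".join(sorted(set(missing))))


def partition_two_states(
    restraints: list[DistanceRestraint],
    ensemble_a: ConformerEnsemble,
    ensemble_b: ConformerEnsemble,
    tolerance: float = DEFAULT_TOLERANCE,
    **eval_kw,
) -> TwoStatePartition:
    """Classify restraints by satisfaction in two conformational states.

    Returns per-restraint records for both states and the four id lists
    (A-only, B-only, both, neither); the counts always sum to the number
    of restraints.
    """
    _check_resolvable([ensemble_a, ensemble_b], restraints)
    rec_a = evaluate_on_ensemble(ensemble_a, restraints, tolerance, **eval_kw)
    rec_b = evaluate_on_ensemble(ensemble_b, restraints, tolerance, **eval_kw)
    a_only, b_only, both, neither = [], [], [], []
    for ra, rb in zip(rec_a, rec_b):
        if ra.satisfied and rb.satisfied:
            both.append(ra.restraint_id)
        elif ra.satisfied:
            a_only.append(ra.restraint_id)
        elif rb.satisfied:
            b_only.append(ra.restraint_id)
        else:
            neither.append(ra.restraint_id)
    return TwoStatePartition(a_only, b_only, both, neither, rec_a, rec_b)
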