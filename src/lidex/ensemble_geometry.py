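"""Superposition, RMSD/RMSF and clustering of conformational ensembles.

Conventions follow standard NMR/MD ensemble analysis: structures are
superposed on a rigid core by least-squares (Kabsch, proper rotations
only), displacements are measured on a region of interest, pairwise-RMSD
matrices feed Ward hierarchical clustering with an automatically chosen
cluster number, and per-cluster centroids are medoids (the member
minimizing summed RMSD to its co-members).

Residue numbers throughout are the author numbering of the input
structures (1-based); atom selections are by residue range plus an atom
filter (CA_only / backbone / all).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "Model",
    "ConformerEnsemble",
    "Selection",
    "ClusterResult",
    "superpose",
    "region_rmsd",
    "pairwise_rmsd_matrix",
    "ward_cluster",
    "rmsf_profile",
    "representative_model",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Model:
    """A single conformer: an atom table plus coordinates in angstroms."""

    atoms: pd.DataFrame  # columns: resid, resname, name
    xyz: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate shape {self.xyz.shape} does not match "
                f"{len(self.atoms)} atoms"
            )


@dataclass
class ConformerEnsemble:
    """Ordered set of conformers sharing one atom table."""

    atoms: pd.DataFrame
    coords: np.ndarray  # (n_models, n_atoms, 3)
    label: str = ""
    times: np.ndarray | None = None  # optional frame times (trajectories)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords shape {self.coords.shape} incompatible with "
                f"{len(self.atoms)} atoms"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one model")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.coords.shape[0]:
                raise ValueError("times length must match the model count")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def model(self, i: int) -> Model:
        return Model(self.atoms, self.coords[i])


@dataclass(frozen=True)
class Selection:
    """Atom selection: inclusive residue ranges plus an atom filter."""

    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_filter: str = "all"  # CA_only | backbone | all

    def __post_init__(self) -> None:
        if self.atom_filter not in ("CA_only", "backbone", "all"):
            raise ValueError(f"unknown atom filter {self.atom_filter!r}")
        if self.residue_ranges is not None:
            ranges = tuple(tuple(r) for r in self.residue_ranges)
            object.__setattr__(self, "residue_ranges", ranges)
            spans = sorted(ranges)
            for (a1, b1), (a2, _b2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise ValueError(f"overlapping residue ranges {spans}")
            for a, b in spans:
                if a > b:
                    raise ValueError(f"empty residue range ({a}, {b})")

    def mask(self, atoms: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(atoms), dtype=bool)
        if self.residue_ranges is not None:
            resid = atoms["resid"].to_numpy()
            in_range = np.zeros(len(atoms), dtype=bool)
            for a, b in self.residue_ranges:
                in_range |= (resid >= a) & (resid <= b)
            m &= in_range
        name = atoms["name"].to_numpy()
        if self.atom_filter == "CA_only":
            m &= name == "CA"
        elif self.atom_filter == "backbone":
            m &= np.isin(name, BACKBONE_ATOMS)
        return m


@dataclass
class ClusterResult:
    """Ward clustering of an ensemble from its pairwise-RMSD matrix."""

    labels: np.ndarray  # per-model cluster id, 0-based
    n_clusters: int
    centroids: list[int]  # per-cluster medoid model index
    spreads: list[float]  # mean member-to-medoid RMSD per cluster, in A
    linkage: np.ndarray = field(repr=False, default=None)


def _matched_selection(a: Model, b: Model, sel: Selection):
    """Indices of selection atoms shared (by resid+name) between two models."""
    ma, mb = sel.mask(a.atoms), sel.mask(b.atoms)
    key_a = {
        (r, n): i
        for i, (r, n) in enumerate(
            zip(a.atoms["resid"].to_numpy(), a.atoms["name"].to_numpy())
        )
        if ma[i]
    }
    idx_a, idx_b = [], []
    for i, (r, n) in enumerate(
        zip(b.atoms["resid"].to_numpy(), b.atoms["name"].to_numpy())
    ):
        if mb[i] and (r, n) in key_a:
            idx_a.append(key_a[(r, n)])
            idx_b.append(i)
    return np.array(idx_a, dtype=int), np.array(idx_b, dtype=int)


def _check_selection(points: np.ndarray) -> None:
    if len(points) < 3:
        raise ValueError(f"selection resolves to {len(points)} atoms; need >= 3")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection: superposition "
                         "is not uniquely defined")


def superpose(mobile: Model, reference: Model, sel: Selection | None = None):
    """Least-squares rigid-body superposition of ``mobile`` onto ``reference``.

    Returns ``(transformed_model, rmsd)`` where the RMSD is over the
    selection after the optimal proper rotation + translation.
    """
    sel = sel or Selection()
    ia, ib = _matched_selection(mobile, reference, sel)
    x_mob = mobile.xyz[ia]
    x_ref = reference.xyz[ib]
    _check_selection(x_mob)
    _check_selection(x_ref)
    c_mob = x_mob.mean(axis=0)
    c_ref = x_ref.mean(axis=0)
    rot = _kabsch(x_mob - c_mob, x_ref - c_ref)
    new_xyz = (mobile.xyz - c_mob) @ rot.T + c_ref
    d = (x_mob - c_mob) @ rot.T + c_ref - x_ref
    rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    return Model(mobile.atoms, new_xyz), rmsd


def _kabsch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centered x onto centered y (SVD,
    reflection excluded by the determinant guard)."""
    u, _s, vt = np.linalg.svd(y.T @ x)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    return u @ d @ vt


def region_rmsd(
    a: Model,
    b: Model,
    fit_sel: Selection,
    measure_sel: Selection,
) -> float:
    """RMSD over ``measure_sel`` after superposing on ``fit_sel``."""
    a_fit, _ = superpose(a, b, fit_sel)
    ia, ib = _matched_selection(a_fit, b, measure_sel)
    if len(ia) == 0:
        raise ValueError("measurement selection resolves to no shared atoms")
    d = a_fit.xyz[ia] - b.xyz[ib]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def pairwise_rmsd_matrix(
    ens: ConformerEnsemble,
    fit_sel: Selection,
    measure_sel: Selection,
) -> np.ndarray:
    """Symmetric zero-diagonal matrix of region RMSDs between all models."""
    n = ens.n_models
    if n < 2:
        raise ValueError("pairwise matrix needs >= 2 models")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = region_rmsd(ens.model(i), ens.model(j), fit_sel, measure_sel)
            mat[i, j] = mat[j, i] = r
    return mat


def _medoid(matrix: np.ndarray, members: np.ndarray) -> tuple[int, float]:
    sub = matrix[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    k = int(np.argmin(sums))
    spread = float(sub[k].sum() / max(len(members) - 1, 1))
    return int(members[k]), spread


def ward_cluster(
    matrix: np.ndarray,
    n_clusters: int | None = None,
    method: str = "ward",
    distance_threshold: float | None = None,
) -> ClusterResult:
    """Hierarchical clustering of a pairwise-RMSD matrix (Ward by default).

    When ``n_clusters`` is omitted, k in [2, 10] maximizing the mean
    silhouette (precomputed-distance metric) is chosen, ties toward the
    smaller k; a matrix of (near-)identical conformers yields one cluster.
    Alternatively ``method="average"`` with a ``distance_threshold`` cuts
    the dendrogram at a fixed cophenetic distance instead.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or n < 2:
        raise ValueError("need a square matrix over >= 2 models")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    link = hierarchy.linkage(squareform(matrix, checks=False), method=method)
    if distance_threshold is not None:
        if n_clusters is not None:
            raise ValueError("give either n_clusters or distance_threshold")
        labels = _relabel_by_first_occurrence(
            hierarchy.fcluster(link, distance_threshold, criterion="distance") - 1
        )
        k = len(np.unique(labels))
        centroids, spreads = _centroids(matrix, labels, k)
        return ClusterResult(labels, k, centroids, spreads, link)
    if n_clusters is None:
        if matrix.max() < 1e-8:
            labels = np.zeros(n, dtype=int)
            return ClusterResult(labels, 1, *_centroids(matrix, labels, 1), link)
        best_k, best_score = 1, -np.inf
        for k in range(2, min(10, n - 1) + 1):
            lab = hierarchy.fcluster(link, k, criterion="maxclust")
            if len(np.unique(lab)) != k:
                continue
            score = silhouette_score(matrix, lab, metric="precomputed")
            if score > best_score + 1e-12:
                best_k, best_score = k, score
        n_clusters = best_k if best_k > 1 else 2
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters={n_clusters} out of range for {n} models")
    if n_clusters == n:
        labels = np.arange(n)
    else:
        labels = hierarchy.fcluster(link, n_clusters, criterion="maxclust") - 1
    labels = _relabel_by_first_occurrence(labels)
    k = len(np.unique(labels))
    centroids, spreads = _centroids(matrix, labels, k)
    return ClusterResult(labels, k, centroids, spreads, link)


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _centroids(matrix, labels, k):
    centroids, spreads = [], []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        m, s = _medoid(matrix, members)
        centroids.append(m)
        spreads.append(s)
    return centroids, spreads


def representative_model(
    ens: ConformerEnsemble,
    fit_sel: Selection | None = None,
    measure_sel: Selection | None = None,
) -> int:
    """Index of the medoid conformer (minimal summed RMSD to the others)."""
    if ens.n_models == 1:
        return 0
    sel = fit_sel or Selection()
    mat = pairwise_rmsd_matrix(ens, sel, measure_sel or sel)
    return _medoid(mat, np.arange(ens.n_models))[0]


def rmsf_profile(
    ens: ConformerEnsemble,
    fit_sel: Selection | None = None,
    atom_filter: str = "CA_only",
) -> pd.Series:
    """Per-residue RMSF about the mean structure after superposition.

    Every model is superposed on the ensemble mean over ``fit_sel``
    (one re-iteration of the mean), then for each residue the RMSF is the
    root mean squared deviation of its filtered atoms from their mean
    positions, averaged within the residue.
    """
    if ens.n_models < 2:
        raise ValueError("RMSF needs >= 2 models")
    fit_sel = fit_sel or Selection()
    ref = ens.model(0)
    aligned = np.array(
        [superpose(ens.model(i), ref, fit_sel)[0].xyz for i in range(ens.n_models)]
    )
    mean_model = Model(ens.atoms, aligned.mean(axis=0))
    aligned = np.array(
        [
            superpose(Model(ens.atoms, x), mean_model, fit_sel)[0].xyz
            for x in aligned
        ]
    )
    mean_xyz = aligned.mean(axis=0)
    sq_dev = np.sum((aligned - mean_xyz) ** 2, axis=2).mean(axis=0)  # per atom
    mask = Selection(atom_filter=atom_filter).mask(ens.atoms)
    resid = ens.atoms["resid"].to_numpy()
    out = {}
    for r in np.unique(resid[mask]):
        sel_atoms = mask & (resid == r)
        out[int(r)] = float(np.sqrt(sq_dev[sel_atoms].mean()))
    return pd.Series(out, name="rmsf_A").sort_index()
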