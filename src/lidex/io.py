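"""Readers and writers for the pipeline's plain-text formats.

* dispersion CSV — ``probe_id,nucleus,field_MHz,nu_cpmg_Hz,R2eff_s1,sigma_s1``
  with ``nucleus`` in {N15SQ, CH3MQ}; missing sigmas are filled via the 2%
  error floor;
* restraint TSV — tab-separated with semicolon-joined atom names, plus a
  read-only importer for simple CYANA-style ``.upl`` upper-limit lines;
* multi-model PDB (MODEL/ENDMDL) read through Biopython and written with
  fixed columns;
* strict YAML run configuration (unknown keys rejected).

All readers reject malformed input with the offending line number rather
than guessing; all writers are deterministic.  Comment lines starting
with ``#`` are allowed (and used by the generators to record their
parameters and seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser

from .dispersion_fit import DispersionCurve, DispersionDataset, apply_error_floor
from .ensemble_geometry import ConformerEnsemble
from .exchange_model import CpmgSchedule, DispersionPoint, NucleusMode, ProbeParameters
from .restraints import AtomGroup, DistanceRestraint, StateTag

__all__ = [
    "read_dispersion_csv",
    "write_dispersion_csv",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_restraints_tsv",
    "write_restraints_tsv",
    "read_upl",
    "load_trajectory",
    "RunConfig",
    "read_config",
]

DISPERSION_HEADER = ["probe_id", "nucleus", "field_MHz", "nu_cpmg_Hz",
                     "R2eff_s1", "sigma_s1"]
RESTRAINT_HEADER = ["id", "resid_i", "atoms_i", "resid_j", "atoms_j",
                    "lower_A", "upper_A", "class", "state_tag"]


def read_dispersion_csv(
    path: str | Path,
    schedules: dict[NucleusMode, CpmgSchedule] | None = None,
    temperature: float = 293.0,
    noise_figure: float = 0.0,
) -> DispersionDataset:
    """Read a dispersion CSV into a typed dataset.

    Rows with an empty or non-positive sigma get one from the 2% error
    floor applied to ``noise_figure * R2eff`` (default: pure floor).
    Default constant-time periods are 30 ms (CH3MQ) and 60 ms (N15SQ)
    unless ``schedules`` overrides them.
    """
    path = Path(path)
    rows_by_probe: dict[str, list[tuple[NucleusMode, DispersionPoint]]] = {}
    with path.open() as fh:
        reader = csv.reader(fh)
        header = None
        for ln, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if header is None:
                if [c.strip() for c in row] != DISPERSION_HEADER:
                    raise ValueError(
                        f"{path}:{ln}: bad header {row!r}; expected "
                        f"{','.join(DISPERSION_HEADER)}"
                    )
                header = row
                continue
            if len(row) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 fields, got {len(row)}")
            pid, nuc, f_mhz, nu, r2, sig = (c.strip() for c in row)
            try:
                mode = NucleusMode(nuc)
            except ValueError:
                raise ValueError(f"{path}:{ln}: unknown nucleus token {nuc!r}") from None
            try:
                f_mhz, nu, r2 = float(f_mhz), float(nu), float(r2)
                sig_val = float(sig) if sig else -1.0
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: {err}") from None
            if sig_val <= 0:
                sig_val = apply_error_floor(max(r2, 0.0), noise_figure * max(r2, 0.0))
                if sig_val <= 0:
                    raise ValueError(
                        f"{path}:{ln}: cannot assign a positive sigma to "
                        f"R2eff={r2}"
                    )
            try:
                point = DispersionPoint(f_mhz, nu, r2, sig_val)
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: {err}") from None
            rows_by_probe.setdefault(pid, []).append((mode, point))
    if header is None:
        raise ValueError(f"{path}: no header found")
    if not rows_by_probe:
        raise ValueError(f"{path}: no data rows")

    default_t = {NucleusMode.CH3_MQ: 0.030, NucleusMode.N15_SQ: 0.060}
    curves: dict[str, DispersionCurve] = {}
    modes_seen: dict[NucleusMode, set[float]] = {}
    for pid, entries in rows_by_probe.items():
        modes = {m for m, _ in entries}
        if len(modes) != 1:
            raise ValueError(f"{path}: probe {pid} mixes nucleus modes {modes}")
        mode = modes.pop()
        pts = [p for _, p in entries]
        modes_seen.setdefault(mode, set()).update(p.nu_cpmg for p in pts)
        probe = ProbeParameters(pid, mode, dw_X=0.0, dw_H=0.0,
                                r2_base={p.field_MHz: 0.0 for p in pts})
        curves[pid] = DispersionCurve(probe, pts)
    if schedules is None:
        schedules = {
            mode: CpmgSchedule(mode, default_t[mode], tuple(sorted(nus)))
            for mode, nus in modes_seen.items()
        }
    return DispersionDataset(curves, schedules, temperature)


def write_dispersion_csv(
    data: DispersionDataset, path: str | Path, comments: dict | None = None
) -> None:
    """Write a dataset back to CSV (deterministic ordering)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        for k, v in (comments or {}).items():
            fh.write(f"# {k} = {v}\n")
        writer = csv.writer(fh)
        writer.writerow(DISPERSION_HEADER)
        for pid in sorted(data.curves):
            curve = data.curves[pid]
            nuc = curve.probe.nucleus_mode.value
            for p in sorted(curve.points, key=lambda p: (p.field_MHz, p.nu_cpmg)):
                # repr gives the shortest exact round-trip representation
                writer.writerow(
                    [pid, nuc, repr(p.field_MHz), repr(p.nu_cpmg),
                     repr(p.r2eff), repr(p.sigma)]
                )


# ---------------------------------------------------------------------------
# multi-model PDB


def read_multimodel_pdb(path: str | Path) -> ConformerEnsemble:
    """Read a (multi-)model PDB into an ensemble with a shared atom table."""
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    tables, coords = [], []
    for model in models:
        rows, xyz = [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    rows.append((residue.id[1], residue.resname.strip(),
                                 atom.get_name()))
                    xyz.append(atom.coord)
        tables.append(rows)
        coords.append(np.asarray(xyz, dtype=float))
    ref = tables[0]
    for k, tab in enumerate(tables[1:], start=2):
        if tab != ref:
            diff = next(
                (a for a, b in zip(tab, ref) if a != b),
                tab[len(ref):][:1] or ref[len(tab):][:1],
            )
            raise ValueError(
                f"{path}: model {k} atom table differs from model 1 "
                f"(first difference near {diff})"
            )
    atoms = pd.DataFrame(ref, columns=["resid", "resname", "name"])
    return ConformerEnsemble(atoms, np.stack(coords), label=path.stem)


def _pdb_atom_name(name: str, element: str) -> str:
    # standard alignment: 1-char elements start in column 14
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_multimodel_pdb(
    ens: ConformerEnsemble, path: str | Path, comments: dict | None = None
) -> None:
    """Write an ensemble as a fixed-column multi-model PDB file."""
    path = Path(path)
    atoms = ens.atoms
    with path.open("w") as fh:
        for k, v in (comments or {}).items():
            fh.write(f"REMARK   6 {k} = {v}\n")
        for m in range(ens.n_models):
            fh.write(f"MODEL     {m + 1:4d}\n")
            xyz = ens.coords[m]
            for i, row in enumerate(atoms.itertuples(index=False)):
                element = row.name[0]
                fh.write(
                    "ATOM  {serial:5d} {name} {resname:<3s} A{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{element:>2s}\n".format(
                        serial=i + 1,
                        name=_pdb_atom_name(row.name, element),
                        resname=row.resname,
                        resid=int(row.resid),
                        x=xyz[i, 0], y=xyz[i, 1], z=xyz[i, 2],
                        occ=1.0, b=0.0, element=element,
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def load_trajectory(topology: str | Path, trajectory: str | Path) -> ConformerEnsemble:
    """Optional adapter for compressed MD formats (XTC/DCD) via MDAnalysis."""
    try:
        import MDAnalysis as mda
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "reading XTC/DCD trajectories requires the optional MDAnalysis "
            "dependency (pip install lidex[traj])"
        ) from err
    u = mda.Universe(str(topology), str(trajectory))
    sel = u.atoms
    atoms = pd.DataFrame(
        {"resid": sel.resids, "resname": sel.resnames, "name": sel.names}
    )
    coords = np.array([sel.positions.copy() for _ in u.trajectory])
    times = np.array([ts.time for ts in u.trajectory])
    return ConformerEnsemble(atoms, coords, label=Path(trajectory).stem,
                             times=times)


# ---------------------------------------------------------------------------
# restraint tables


def _parse_group(resid: str, atoms: str, ln: int, path) -> AtomGroup:
    names = tuple(a for a in atoms.split(";") if a)
    try:
        return AtomGroup(int(resid), "UNK", names)
    except ValueError as err:
        raise ValueError(f"{path}:{ln}: {err}") from None


def read_restraints_tsv(path: str | Path) -> list[DistanceRestraint]:
    """Read the tab-separated restraint table."""
    path = Path(path)
    out = []
    with path.open() as fh:
        header = None
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                if [c.strip() for c in cells] != RESTRAINT_HEADER:
                    raise ValueError(
                        f"{path}:{ln}: bad header; expected "
                        f"{chr(9).join(RESTRAINT_HEADER)!r}"
                    )
                header = cells
                continue
            if len(cells) != len(RESTRAINT_HEADER):
                raise ValueError(
                    f"{path}:{ln}: expected {len(RESTRAINT_HEADER)} fields, "
                    f"got {len(cells)}"
                )
            rid, ri, ai, rj, aj, lo, up, cls, tag = (c.strip() for c in cells)
            try:
                restraint = DistanceRestraint(
                    rid,
                    _parse_group(ri, ai, ln, path),
                    _parse_group(rj, aj, ln, path),
                    float(lo),
                    float(up),
                    peak_class=cls or None,
                    state_tag=tag or StateTag.UNASSIGNED,
                )
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: {err}") from None
            out.append(restraint)
    if header is None:
        raise ValueError(f"{path}: no header found")
    return out


def write_restraints_tsv(
    restraints: list[DistanceRestraint], path: str | Path,
    comments: dict | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (comments or {}).items():
            fh.write(f"# {k} = {v}\n")
        fh.write("\t".join(RESTRAINT_HEADER) + "\n")
        for r in restraints:
            fh.write(
                "\t".join(
                    [
                        r.id,
                        str(r.group_i.residue_number),
                        ";".join(r.group_i.atom_names),
                        str(r.group_j.residue_number),
                        ";".join(r.group_j.atom_names),
                        f"{r.lower:.3f}",
                        f"{r.upper:.3f}",
                        r.peak_class.value if r.peak_class else "",
                        r.state_tag.value,
                    ]
                )
                + "\n"
            )


def read_upl(path: str | Path) -> list[DistanceRestraint]:
    """Import simple CYANA-style upper-limit lines (read-only).

    Expected columns: resid_i resname_i atom_i resid_j resname_j atom_j
    upper_limit.
    """
    path = Path(path)
    out = []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(
                    f"{path}:{ln}: expected 7 whitespace-separated fields"
                )
            try:
                gi = AtomGroup(int(parts[0]), parts[1], (parts[2],))
                gj = AtomGroup(int(parts[3]), parts[4], (parts[5],))
                upper = float(parts[6])
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: {err}") from None
            out.append(
                DistanceRestraint(f"upl{ln:04d}", gi, gj, 0.0, upper)
            )
    return out


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Strictly parsed run configuration (flat sections of key-values)."""

    temperature: float = 293.0
    seed: int = 0
    fit_residue_ranges: tuple[tuple[int, int], ...] = ((40, 97), (137, 220))
    measure_residue_ranges: tuple[tuple[int, int], ...] = ((98, 136),)
    kex_grid: tuple[float, float, int] = (100.0, 10000.0, 25)
    p_grid: tuple[float, float, int] = (0.005, 0.20, 20)
    restraint_tolerance: float = 0.5
    eps_stable: float = 0.5
    eps_arrive: float = 0.5
    eps_depart: float = 1.0
    smoothing_window: int = 10
    final_fraction: float = 0.2
    monte_carlo_repeats: int = 40


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    flat: dict = {}
    for key, value in raw.items():
        if isinstance(value, dict):  # one level of sections is allowed
            flat.update(value)
        else:
            flat[key] = value
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(flat) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    for key in ("fit_residue_ranges", "measure_residue_ranges"):
        if key in flat:
            flat[key] = tuple(tuple(r) for r in flat[key])
    for key in ("kex_grid", "p_grid"):
        if key in flat:
            flat[key] = tuple(flat[key])
    return RunConfig(**flat)
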