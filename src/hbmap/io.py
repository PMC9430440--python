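"""Reading and writing atomic configurations and charge topologies.

Supported coordinate formats are the common text outputs of MD packages:

* GRO  — fixed-width columns, nanometre coordinates (converted to/from the
  internal Angstrom on the fly), orthorhombic box line; concatenated
  multi-frame files are supported.
* PDB  — ATOM/HETATM records in Angstrom, CRYST1 box, MODEL/ENDMDL frames.
* XYZ  — Angstrom, extended-XYZ ``Lattice="..."`` comment carrying the box;
  residues are reconstructed by matching site-label runs against the
  topology since plain XYZ carries no residue column.

Only orthorhombic boxes are accepted; triclinic box specifications raise.
Charges are attached on read by (residue, site) lookup in a TopologyTable.
"""
from __future__ import annotations

import csv
import importlib.resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .frames import AtomicFrame, TopologyTable, VirtualSiteRule

NM_PER_ANGSTROM = 0.1

_FORMATS = ("gro", "pdb", "xyz")


class FormatError(ValueError):
    """A coordinate file does not parse under the requested dialect."""


# ---------------------------------------------------------------------------
# topology tables
# ---------------------------------------------------------------------------

def load_topology(path: str | Path) -> TopologyTable:
    """Read a charge topology from CSV with columns
    ``residue,site,charge[,vsite_distance]``; ``#`` lines are comments."""
    residues: dict[str, list[tuple[str, float]]] = {}
    vsites: dict[str, VirtualSiteRule] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    header = [c.strip() for c in rows[0]]
    if header[:3] != ["residue", "site", "charge"]:
        raise FormatError(f"topology header must start residue,site,charge; got {header}")
    has_vsite = "vsite_distance" in header
    for row in rows[1:]:
        res, site, q = row[0].strip(), row[1].strip(), float(row[2])
        residues.setdefault(res, []).append((site, q))
        if has_vsite and len(row) > 3 and row[3].strip():
            vsites[res] = VirtualSiteRule(site=site, distance=float(row[3]))
    return TopologyTable(residues=residues, vsites=vsites)


def write_topology(topology: TopologyTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["residue", "site", "charge", "vsite_distance"])
        for res, sites in topology.residues.items():
            rule = topology.vsites.get(res)
            for site, q in sites:
                d = rule.distance if rule is not None and rule.site == site else ""
                w.writerow([res, site, repr(q), d])


def default_topology() -> TopologyTable:
    """The bundled water/DMSO charge table."""
    ref = importlib.resources.files("hbmap.data") / "water_dmso_charges.csv"
    with importlib.resources.as_file(ref) as p:
        return load_topology(p)


# ---------------------------------------------------------------------------
# reading frames
# ---------------------------------------------------------------------------

def read_frames(
    path: str | Path, format: str | None = None, topology: TopologyTable | None = None
) -> list[AtomicFrame]:
    """Read one or more configurations, attaching charges by residue+site
    lookup.  ``format`` defaults to the file extension."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if topology is None:
        topology = default_topology()
    lines = path.read_text().splitlines()
    if fmt == "gro":
        return _read_gro(lines, topology)
    if fmt == "pdb":
        return _read_pdb(lines, topology)
    return _read_xyz(lines, topology)


def _assemble(
    coords: list[list[float]],
    sites: list[str],
    resnames: list[str],
    resids: list[int],
    box: Sequence[float],
    topology: TopologyTable,
) -> AtomicFrame:
    # remap residue ids (which may wrap at format field width) to contiguous
    # molecule ids by run-length over (resid, resname)
    mids = np.zeros(len(resids), dtype=int)
    current = 0
    for i in range(1, len(resids)):
        if resids[i] != resids[i - 1] or resnames[i] != resnames[i - 1]:
            current += 1
        mids[i] = current
    charges = [topology.charge_of(res, site) for res, site in zip(resnames, sites)]
    return AtomicFrame(
        np.asarray(coords, dtype=float),
        np.asarray(box, dtype=float),
        np.array(sites, dtype=object),
        mids,
        np.array(resnames, dtype=object),
        np.array(charges, dtype=float),
    )


def _read_gro(lines: list[str], topology: TopologyTable) -> list[AtomicFrame]:
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i + 1].strip())
        except (IndexError, ValueError):
            raise FormatError(f"line {i + 2}: expected atom count") from None
        coords, sites, resnames, resids = [], [], [], []
        for k in range(natoms):
            ln = i + 2 + k
            try:
                line = lines[ln]
                resid = int(line[0:5])
                resname = line[5:10].strip()
                site = line[10:15].strip()
                xyz = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            except (IndexError, ValueError):
                raise FormatError(f"line {ln + 1}: malformed GRO atom record") from None
            coords.append([c / NM_PER_ANGSTROM for c in xyz])
            sites.append(site)
            resnames.append(resname)
            resids.append(resid)
        bl = i + 2 + natoms
        try:
            parts = lines[bl].split()
        except IndexError:
            raise FormatError(f"line {bl + 1}: missing box line") from None
        if len(parts) == 3:
            box = [float(p) / NM_PER_ANGSTROM for p in parts]
        elif len(parts) == 9:
            off = [float(p) for p in parts[3:]]
            if any(abs(v) > 1e-12 for v in off):
                raise FormatError(f"line {bl + 1}: triclinic GRO box not supported")
            box = [float(p) / NM_PER_ANGSTROM for p in parts[:3]]
        else:
            raise FormatError(f"line {bl + 1}: malformed GRO box line")
        frames.append(_assemble(coords, sites, resnames, resids, box, topology))
        i = bl + 1
    if not frames:
        raise FormatError("no frames found in GRO file")
    return frames


def _read_pdb(lines: list[str], topology: TopologyTable) -> list[AtomicFrame]:
    frames = []
    box: list[float] | None = None
    coords: list[list[float]] = []
    sites: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []

    def flush() -> None:
        nonlocal coords, sites, resnames, resids
        if coords:
            if box is None:
                raise FormatError("PDB file lacks a CRYST1 box record")
            frames.append(_assemble(coords, sites, resnames, resids, box, topology))
        coords, sites, resnames, resids = [], [], [], []

    for ln, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                box = [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                angles = [float(line[33:40]), float(line[40:47]), float(line[47:54])]
            except ValueError:
                raise FormatError(f"line {ln}: malformed CRYST1 record") from None
            if any(abs(a - 90.0) > 1e-6 for a in angles):
                raise FormatError(f"line {ln}: non-orthorhombic PDB cell not supported")
        elif rec in ("ATOM", "HETATM"):
            try:
                sites.append(line[12:16].strip())
                resnames.append(line[17:21].strip())
                resids.append(int(line[22:26]))
                coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except ValueError:
                raise FormatError(f"line {ln}: malformed {rec} record") from None
        elif rec == "ENDMDL":
            flush()
    flush()
    if not frames:
        raise FormatError("no frames found in PDB file")
    return frames


def _match_residues_by_sites(sites: list[str], topology: TopologyTable) -> tuple[list[str], list[int]]:
    """Greedy reconstruction of residue names / molecule boundaries from a
    bare site-label stream (for XYZ, which carries no residue column).
    DW is accepted in place of any HW* site of a water residue."""
    templates = {res: topology.site_sequence(res) for res in topology.residues}

    def matches(run: list[str], tmpl: list[str]) -> bool:
        if len(run) != len(tmpl):
            return False
        for got, want in zip(run, tmpl):
            if got == want:
                continue
            if got == "DW" and want.startswith("HW"):
                continue
            return False
        return True

    resnames: list[str] = []
    resids: list[int] = []
    i, rid = 0, 0
    while i < len(sites):
        for res, tmpl in sorted(templates.items(), key=lambda kv: -len(kv[1])):
            if matches(sites[i : i + len(tmpl)], tmpl):
                resnames.extend([res] * len(tmpl))
                resids.extend([rid] * len(tmpl))
                i += len(tmpl)
                rid += 1
                break
        else:
            raise FormatError(
                f"atom {i + 1}: site run starting at {sites[i]!r} matches no "
                "residue in the topology"
            )
    return resnames, resids


def _read_xyz(lines: list[str], topology: TopologyTable) -> list[AtomicFrame]:
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"line {i + 1}: expected atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box = _parse_xyz_box(comment, i + 2)
        coords, sites = [], []
        for k in range(natoms):
            ln = i + 2 + k
            try:
                parts = lines[ln].split()
                sites.append(parts[0])
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except (IndexError, ValueError):
                raise FormatError(f"line {ln + 1}: malformed XYZ atom record") from None
        resnames, resids = _match_residues_by_sites(sites, topology)
        frames.append(_assemble(coords, sites, resnames, resids, box, topology))
        i += 2 + natoms
    if not frames:
        raise FormatError("no frames found in XYZ file")
    return frames


def _parse_xyz_box(comment: str, lineno: int) -> list[float]:
    if "Lattice=" not in comment:
        raise FormatError(f'line {lineno}: XYZ comment lacks Lattice="..." box')
    raw = comment.split("Lattice=", 1)[1]
    quote = raw[0]
    vals = [float(v) for v in raw[1 : raw.index(quote, 1)].split()]
    if len(vals) != 9:
        raise FormatError(f"line {lineno}: Lattice must have 9 components")
    m = np.array(vals).reshape(3, 3)
    if np.abs(m - np.diag(np.diag(m))).max() > 1e-9:
        raise FormatError(f"line {lineno}: non-orthorhombic XYZ lattice not supported")
    return list(np.diag(m))


# ---------------------------------------------------------------------------
# writing frames
# ---------------------------------------------------------------------------

def write_frames(
    frames: Sequence[AtomicFrame] | AtomicFrame,
    path: str | Path,
    format: str | None = None,
    title: str = "hbmap configuration",
) -> Path:
    """Write frames to GRO / PDB / XYZ; the inverse of :func:`read_frames`.
    GRO is written without velocity columns."""
    if isinstance(frames, AtomicFrame):
        frames = [frames]
    if len(frames) == 0:
        raise ValueError("refusing to write an empty frame list")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    writer = {"gro": _write_gro, "pdb": _write_pdb, "xyz": _write_xyz}[fmt]
    with open(path, "w") as fh:
        for frame in frames:
            writer(fh, frame, title)
    return path


def _write_gro(fh, frame: AtomicFrame, title: str) -> None:
    fh.write(f"{title}\n{frame.n_atoms:5d}\n")
    for i in range(frame.n_atoms):
        resid = (int(frame.molecule_id[i]) + 1) % 100000
        x, y, z = frame.coordinates[i] * NM_PER_ANGSTROM
        fh.write(
            f"{resid:5d}{frame.residue_name[i]:<5s}{frame.atom_site[i]:>5s}"
            f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )
    bx, by, bz = frame.box * NM_PER_ANGSTROM
    fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def _write_pdb(fh, frame: AtomicFrame, title: str) -> None:
    bx, by, bz = frame.box
    fh.write(f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1\n")
    fh.write("MODEL     1\n")
    for i in range(frame.n_atoms):
        x, y, z = frame.coordinates[i]
        fh.write(
            f"ATOM  {(i + 1) % 100000:5d} {frame.atom_site[i]:<4.4s} "
            f"{frame.residue_name[i]:<4.4s} {(int(frame.molecule_id[i]) + 1) % 10000:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
        )
    fh.write("ENDMDL\n")


def _write_xyz(fh, frame: AtomicFrame, title: str) -> None:
    bx, by, bz = frame.box
    fh.write(f"{frame.n_atoms}\n")
    fh.write(f'Lattice="{bx} 0.0 0.0 0.0 {by} 0.0 0.0 0.0 {bz}" {title}\n')
    for i in range(frame.n_atoms):
        x, y, z = frame.coordinates[i]
        fh.write(f"{frame.atom_site[i]:<5s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


# ---------------------------------------------------------------------------
# virtual sites
# ---------------------------------------------------------------------------

def resolve_virtual_sites(frame: AtomicFrame, topology: TopologyTable) -> AtomicFrame:
    """Recompute massless M-site positions of 4-site waters from the O and H
    coordinates: the M site sits on the HOH bisector at the rule's distance
    from the oxygen, and carries the charge the topology assigns it.

    Waters whose residue has no virtual-site rule pass through unchanged.
    A water-family molecule with a rule but a hydrogen count other than two
    raises.
    """
    out = frame.copy()
    for mid in out.molecule_ids():
        idx = out.atoms_of(mid)
        res = out.residue_name[idx[0]]
        rule = topology.vsites.get(res)
        if rule is None:
            continue
        sites = out.atom_site[idx]
        o_idx = idx[np.array([s.startswith("OW") for s in sites], dtype=bool)]
        h_idx = idx[np.array([s.startswith(("HW", "DW")) for s in sites], dtype=bool)]
        m_idx = idx[np.array([s == rule.site for s in sites], dtype=bool)]
        if len(h_idx) != 2 or len(o_idx) != 1 or len(m_idx) != 1:
            raise ValueError(
                f"molecule {mid} ({res}): virtual-site rule needs 1 O, 2 H/D "
                f"and 1 {rule.site} site"
            )
        o = out.coordinates[o_idx[0]]
        bis = (out.coordinates[h_idx[0]] - o) + (out.coordinates[h_idx[1]] - o)
        norm = np.linalg.norm(bis)
        if norm == 0:
            raise ValueError(f"molecule {mid}: degenerate HOH bisector")
        out.coordinates[m_idx[0]] = o + rule.distance * bis / norm
        out.charge[m_idx[0]] = topology.charge_of(res, rule.site)
        out.charge[o_idx[0]] = topology.charge_of(res, "OW")
    return out
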