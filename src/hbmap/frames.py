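"""Core containers: atomic configurations and charge topologies.

All coordinates are stored internally in Angstrom with orthorhombic
periodic boxes.  Deuterium is distinguished from hydrogen purely by the
site label (``DW`` vs ``HW*``): it is an isotopic label, the charge and
position semantics are identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Bohr radius in Angstrom; the single place the unit conversion lives.
BOHR_ANGSTROM = 0.529177

#: Molar masses in g/mol used for composition mass balance.
MOLAR_MASS = {"H2O": 18.015, "D2O": 20.028, "DMSO": 78.13}

AVOGADRO = 6.02214076e23

#: Residue names treated as the water family (eligible to carry a DW label).
WATER_RESIDUES = frozenset({"SOL", "HOH", "WAT", "TIP4"})

CHARGE_TOL = 1e-10


@dataclass
class VirtualSiteRule:
    """Massless-site geometry: place the site on the H-O-H bisector at a
    fixed distance from the oxygen, carrying the oxygen's charge."""

    site: str
    distance: float  # Angstrom along the bisector, from O towards the H's


@dataclass
class TopologyTable:
    """Per-residue site labels and partial charges.

    ``residues`` maps residue name -> list of (site label, charge in e).
    ``vsites`` maps residue name -> VirtualSiteRule for 4-site waters.
    """

    residues: dict[str, list[tuple[str, float]]]
    vsites: dict[str, VirtualSiteRule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sites in self.residues.items():
            total = sum(q for _, q in sites)
            if abs(total) > CHARGE_TOL:
                raise ValueError(
                    f"residue {name!r} charges sum to {total:.3e} e, expected 0"
                )

    def charge_of(self, residue: str, site: str) -> float:
        try:
            sites = self.residues[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} not present in topology") from None
        # DW is an isotopic relabel of a hydrogen site; look up the H twin.
        for s, q in sites:
            if s == site:
                return q
        if site == "DW":
            for s, q in sites:
                if s.startswith("HW"):
                    return q
        raise KeyError(f"site {site!r} not defined for residue {residue!r}")

    def site_sequence(self, residue: str) -> list[str]:
        return [s for s, _ in self.residues[residue]]


@dataclass
class AtomicFrame:
    """One atomic configuration under orthorhombic periodic boundaries.

    coordinates : (n, 3) float array, Angstrom
    box         : (3,) float array, Angstrom, edges > 0
    atom_site   : (n,) site labels (OW, HW1, DW, S, M, ...)
    molecule_id : (n,) int, contiguous runs per molecule
    residue_name: (n,) residue names keying the topology
    charge      : (n,) partial charges in e
    """

    coordinates: np.ndarray
    box: np.ndarray
    atom_site: np.ndarray
    molecule_id: np.ndarray
    residue_name: np.ndarray
    charge: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        n = len(self.coordinates)
        self.atom_site = np.asarray(self.atom_site, dtype=object).reshape(n)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int).reshape(n)
        self.residue_name = np.asarray(self.residue_name, dtype=object).reshape(n)
        self.charge = np.asarray(self.charge, dtype=float).reshape(n)
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be positive, got {self.box}")
        self._check_contiguous_molecules()
        self._check_water_family_deuterium()
        self._check_molecular_neutrality()

    # -- validation -----------------------------------------------------

    def _check_contiguous_molecules(self) -> None:
        mid = self.molecule_id
        if len(mid) == 0:
            return
        boundaries = np.flatnonzero(np.diff(mid) != 0)
        seen = mid[np.concatenate(([0], boundaries + 1))]
        if len(np.unique(seen)) != len(seen):
            raise ValueError("molecule_id runs are not contiguous")

    def _check_water_family_deuterium(self) -> None:
        d_mask = self.atom_site == "DW"
        if d_mask.any():
            bad = set(self.residue_name[d_mask]) - WATER_RESIDUES
            if bad:
                raise ValueError(f"DW label on non-water residues: {sorted(bad)}")

    def _check_molecular_neutrality(self) -> None:
        if len(self.charge) == 0:
            return
        sums = np.zeros(self.molecule_id.max() + 1)
        np.add.at(sums, self.molecule_id, self.charge)
        worst = np.abs(sums).max()
        if worst > CHARGE_TOL:
            raise ValueError(
                f"per-molecule charge does not sum to zero (max |sum| {worst:.3e} e)"
            )

    # -- convenience ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_id))

    def molecule_ids(self) -> np.ndarray:
        return np.unique(self.molecule_id)

    def atoms_of(self, molecule_id: int) -> np.ndarray:
        """Indices of the atoms belonging to one molecule."""
        return np.flatnonzero(self.molecule_id == molecule_id)

    def select_site(self, site: str | Sequence[str]) -> np.ndarray:
        """Indices of atoms whose site label matches (exactly or by prefix
        for trailing-digit labels like HW1/HW2)."""
        wanted = [site] if isinstance(site, str) else list(site)
        mask = np.zeros(self.n_atoms, dtype=bool)
        for w in wanted:
            mask |= self.atom_site == w
            mask |= np.array(
                [s.rstrip("0123456789") == w for s in self.atom_site], dtype=bool
            )
        return np.flatnonzero(mask)

    def with_coordinates(self, coords: np.ndarray) -> "AtomicFrame":
        return replace(self, coordinates=np.array(coords, dtype=float))

    def copy(self) -> "AtomicFrame":
        return AtomicFrame(
            self.coordinates.copy(),
            self.box.copy(),
            self.atom_site.copy(),
            self.molecule_id.copy(),
            self.residue_name.copy(),
            self.charge.copy(),
        )


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the nearest periodic image."""
    v = np.asarray(vectors, dtype=float)
    return v - box * np.round(v / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distances between position arrays of equal shape."""
    d = minimum_image(np.asarray(a) - np.asarray(b), np.asarray(box))
    return np.linalg.norm(d, axis=-1)


def concatenate_molecules(
    parts: Iterable[tuple[np.ndarray, Sequence[str], str]],
    box: np.ndarray,
    topology: TopologyTable,
) -> AtomicFrame:
    """Assemble a frame from (coords, site labels, residue name) molecules,
    assigning contiguous molecule ids and charges from the topology."""
    coords, sites, mids, resnames, charges = [], [], [], [], []
    for mol_id, (xyz, site_labels, resname) in enumerate(parts):
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        coords.append(xyz)
        sites.extend(site_labels)
        mids.extend([mol_id] * len(xyz))
        resnames.extend([resname] * len(xyz))
        charges.extend(topology.charge_of(resname, s) for s in site_labels)
    return AtomicFrame(
        np.concatenate(coords) if coords else np.empty((0, 3)),
        np.asarray(box, dtype=float),
        np.array(sites, dtype=object),
        np.array(mids, dtype=int),
        np.array(resnames, dtype=object),
        np.array(charges, dtype=float),
    )
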