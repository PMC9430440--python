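"""Electrostatic frequency map for the O-D stretch of dilute HDO.

The instantaneous O-D stretch frequency of an HDO probe is modelled as an
affine function of the electrostatic potential that the surrounding partial
charges create at the probe's D, O and H atom positions:

    omega = omega0 + sum_site  c_site * phi(site)

with phi in atomic units (e/Bohr) summed over all atoms of other molecules
within a spherical cutoff under minimum image.  Strong hydrogen bonds place
the acceptor's negative charge close to the D atom, making phi(D) negative;
with the physical sign convention (c_D > 0) this red-shifts the frequency,
while weak or bifurcated hydrogen bonds blue-shift it.
"""
from __future__ import annotations

import csv
import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .frames import BOHR_ANGSTROM, AtomicFrame, minimum_image
from .io import default_topology
from .synthetic import HOH_ANGLE, OH_BOND, _water_template


@dataclass
class MapCoefficients:
    """Intercept frequency and per-site linear map coefficients.

    omega0      : unperturbed (zero-potential) O-D frequency, cm^-1
    site_coeffs : ordered (site, coefficient) pairs; site in {"D", "O", "H"},
                  coefficient in cm^-1 per atomic unit of potential
    cutoff      : electrostatics cutoff, Angstrom (abrupt truncation)
    """

    omega0: float
    site_coeffs: list[tuple[str, float]]
    cutoff: float = 7.8

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not self.site_coeffs:
            raise ValueError("at least one site coefficient is required")
        for site, _ in self.site_coeffs:
            if site not in ("D", "O", "H"):
                raise ValueError(f"unknown map site {site!r}")


@dataclass
class FrequencyRecord:
    """One HDO probe in one frame: instantaneous frequency, distance from
    the D atom to the nearest DMSO sulfur (NaN when no DMSO is present) and
    the solvation-shell label."""

    frame_index: int
    molecule_id: int
    omega: float
    r_s: float
    shell: str  # "first_shell" | "bulk" | "n/a"


def load_map(path: str | Path) -> MapCoefficients:
    """Read map coefficients from keyed CSV (rows: omega0, cutoff,
    coeff_D/coeff_O/coeff_H)."""
    omega0 = None
    cutoff = 7.8
    coeffs: list[tuple[str, float]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#") or row[0].strip() == "key":
                continue
            key, value = row[0].strip(), float(row[1])
            if key == "omega0":
                omega0 = value
            elif key == "cutoff":
                cutoff = value
            elif key.startswith("coeff_"):
                coeffs.append((key.removeprefix("coeff_"), value))
            else:
                raise ValueError(f"unknown map key {key!r}")
    if omega0 is None:
        raise ValueError("map file lacks omega0")
    return MapCoefficients(omega0=omega0, site_coeffs=coeffs, cutoff=cutoff)


def default_map() -> MapCoefficients:
    """The bundled O-D stretch map."""
    ref = importlib.resources.files("hbmap.data") / "synthetic_od_map.csv"
    with importlib.resources.as_file(ref) as p:
        return load_map(p)


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------

def electrostatic_potential(
    frame: AtomicFrame,
    site_position: np.ndarray,
    excluded_molecule: int,
    cutoff: float,
) -> float:
    """Coulomb potential (atomic units, e/Bohr) at a point from all atoms of
    non-excluded molecules within ``cutoff`` under minimum image.

    Truncation is by neutral group: a molecule contributes all of its atoms
    iff its reference atom (the molecule's first atom, i.e. the heavy atom
    of water/DMSO) lies within the cutoff.  An atom-based abrupt cutoff
    would slice molecules at the cutoff sphere and leave bare monopoles,
    making the potential pathologically sensitive to sub-0.1 A displacements
    in ordered phases; group-based truncation keeps the error at the much
    smaller dipole level.
    """
    if cutoff > 0.5 * float(frame.box.min()) + 1e-9:
        raise ValueError(
            f"cutoff {cutoff} A exceeds half the smallest box edge "
            f"({0.5 * frame.box.min():.3f} A); minimum image invalid"
        )
    site = np.asarray(site_position, dtype=float)
    mids, ref_idx = np.unique(frame.molecule_id, return_index=True)
    ref_disp = minimum_image(site - frame.coordinates[ref_idx], frame.box)
    ref_dist = np.linalg.norm(ref_disp, axis=1)
    included = mids[(ref_dist <= cutoff) & (mids != excluded_molecule)]
    mask = np.isin(frame.molecule_id, included)
    disp = minimum_image(site - frame.coordinates[mask], frame.box)
    r = np.linalg.norm(disp, axis=1)
    # q/r with r in Bohr  =  BOHR_ANGSTROM * q / r_Angstrom
    return float(BOHR_ANGSTROM * np.sum(frame.charge[mask] / r))


def _probe_sites(frame: AtomicFrame, hdo_molecule: int) -> dict[str, np.ndarray]:
    idx = frame.atoms_of(hdo_molecule)
    if len(idx) == 0:
        raise ValueError(f"molecule {hdo_molecule} not present")
    sites = {"D": [], "O": [], "H": []}
    for i in idx:
        label = str(frame.atom_site[i])
        if label == "DW":
            sites["D"].append(i)
        elif label.startswith("OW"):
            sites["O"].append(i)
        elif label.startswith("HW"):
            sites["H"].append(i)
    if len(sites["D"]) != 1:
        raise ValueError(
            f"molecule {hdo_molecule} has {len(sites['D'])} D sites; an HDO probe needs exactly 1"
        )
    if len(sites["O"]) != 1 or len(sites["H"]) != 1:
        raise ValueError(f"molecule {hdo_molecule} is not an HDO water (needs 1 O and 1 H)")
    return {k: frame.coordinates[v[0]] for k, v in sites.items()}


def od_frequency(frame: AtomicFrame, hdo_molecule: int, map: MapCoefficients) -> float:
    """Instantaneous O-D stretch frequency (cm^-1) of one HDO probe."""
    positions = _probe_sites(frame, hdo_molecule)
    omega = map.omega0
    for site, coeff in map.site_coeffs:
        phi = electrostatic_potential(frame, positions[site], hdo_molecule, map.cutoff)
        omega += coeff * phi
    return float(omega)


# ---------------------------------------------------------------------------
# records and distributions
# ---------------------------------------------------------------------------

def hdo_molecules(frame: AtomicFrame) -> np.ndarray:
    """Molecule ids carrying exactly one D label."""
    mids = frame.molecule_id[frame.atom_site == "DW"]
    return np.unique(mids)


def compute_frequency_records(
    frames: list[AtomicFrame],
    map: MapCoefficients | None = None,
    shell_cutoff: float = 3.6,
    sulfur_site: str = "S",
) -> list[FrequencyRecord]:
    """Per-HDO, per-frame frequency records with the distance from the D
    atom to the nearest DMSO sulfur (nearest image; ties broken by lowest
    molecule id through stable argmin) and the shell label."""
    if map is None:
        map = default_map()
    records: list[FrequencyRecord] = []
    for f_idx, frame in enumerate(frames):
        s_idx = np.flatnonzero(frame.atom_site == sulfur_site)
        order = np.argsort(frame.molecule_id[s_idx], kind="stable")
        s_pos = frame.coordinates[s_idx[order]] if len(s_idx) else None
        for mid in hdo_molecules(frame):
            omega = od_frequency(frame, int(mid), map)
            if s_pos is None:
                r_s, shell = float("nan"), "n/a"
            else:
                d_pos = _probe_sites(frame, int(mid))["D"]
                dists = np.linalg.norm(minimum_image(d_pos - s_pos, frame.box), axis=1)
                r_s = float(dists.min())
                shell = "first_shell" if r_s <= shell_cutoff else "bulk"
            records.append(FrequencyRecord(f_idx, int(mid), omega, r_s, shell))
    return records


def records_to_dataframe(records: list[FrequencyRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "frame": [r.frame_index for r in records],
            "molecule": [r.molecule_id for r in records],
            "omega": [r.omega for r in records],
            "r_S": [r.r_s for r in records],
            "shell": [r.shell for r in records],
        }
    )


def frequency_distribution(
    frames: list[AtomicFrame],
    map: MapCoefficients | None = None,
    bins: np.ndarray | None = None,
    **record_kwargs,
) -> tuple[np.ndarray, np.ndarray, list[FrequencyRecord]]:
    """Unit-area histogram of instantaneous frequencies over all HDO probes
    of all frames.  Returns (bin_centers, density, records)."""
    records = compute_frequency_records(frames, map=map, **record_kwargs)
    if not records:
        raise ValueError("no HDO probes present in any frame")
    omegas = np.array([r.omega for r in records])
    if bins is None:
        lo = math.floor(omegas.min()) - 10
        hi = math.ceil(omegas.max()) + 10
        bins = np.arange(lo, hi + 1.0, 2.0)
    density, edges = np.histogram(omegas, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density, records


# ---------------------------------------------------------------------------
# water-dimer frequency scan
# ---------------------------------------------------------------------------

def _dimer_frame(oo_distance: float, box_edge: float = 60.0) -> AtomicFrame:
    """Linear hydrogen-bonded HDO -> H2O dimer: donor O at the box centre,
    the O-D bond pointing along +x at the acceptor oxygen."""
    from .frames import concatenate_molecules

    topology = default_topology()
    centre = np.full(3, box_edge / 2.0)
    half = math.radians(HOH_ANGLE) / 2.0
    donor_o = centre
    donor_d = donor_o + np.array([OH_BOND, 0.0, 0.0])
    donor_h = donor_o + OH_BOND * np.array(
        [math.cos(math.radians(HOH_ANGLE)), math.sin(math.radians(HOH_ANGLE)), 0.0]
    )
    acceptor_o = donor_o + np.array([oo_distance, 0.0, 0.0])
    # acceptor hydrogens point away from the donor, bisector along +x
    acc = _water_template()  # O at origin, H's with bisector along +z
    rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])  # +z -> +x
    acc_xyz = acc @ rot.T + acceptor_o
    parts = [
        (np.array([donor_o, donor_d, donor_h]), ["OW", "DW", "HW2"], "SOL"),
        (acc_xyz, ["OW", "HW1", "HW2"], "SOL"),
    ]
    return concatenate_molecules(parts, np.full(3, box_edge), topology)


def hbond_frequency_scan(
    donor_acceptor_distances: list[float], map: MapCoefficients | None = None
) -> list[float]:
    """O-D frequencies along a linear water-dimer scan of the donor-acceptor
    O···O distance.  With physically signed map coefficients the frequency
    increases monotonically with distance: short, strong hydrogen bonds are
    red-shifted, long or broken ones blue-shifted."""
    if map is None:
        map = default_map()
    return [od_frequency(_dimer_frame(d), 0, map) for d in donor_acceptor_distances]
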