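"""Synthetic atomic configurations and spectra with known ground truth.

The generators emulate the three structural regimes the frequency/structure
analysis distinguishes — a near-perfect tetrahedral hydrogen-bond network
(hexagonal ice), a structureless random gas, and disordered DMSO/water
mixtures at cryoprotectant compositions — plus FTIR-like spectra built as
sums of Gaussian components with noise and baseline.  Every generator is
deterministic under a fixed integer seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .frames import (
    AVOGADRO,
    MOLAR_MASS,
    AtomicFrame,
    TopologyTable,
    concatenate_molecules,
    minimum_image,
)
from .io import default_topology
from .spectra import Spectrum

# Ideal wurtzite axial ratio: c/a = sqrt(8/3) makes all four O-O bonds equal.
_IDEAL_CA = math.sqrt(8.0 / 3.0)

#: default covalent O-H(D) bond length, Angstrom
OH_BOND = 0.9572
#: default H-O-H angle, degrees
HOH_ANGLE = 104.52


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class LatticeSpec:
    """Hexagonal-ice supercell: ``n_cells`` repeats of the 8-oxygen
    orthohexagonal cell.  ``a`` and ``c`` default to the ideal wurtzite
    values derived from ``oo_distance`` (nearest-neighbour O-O separation),
    which is what makes the interior tetrahedral order parameter exactly 1."""

    n_cells: tuple[int, int, int] = (2, 2, 2)
    oo_distance: float = 2.75
    a: float | None = None
    c: float | None = None
    proton_scheme: str = "ordered"  # or "bernal_fowler_random"
    oh_bond: float = OH_BOND
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_cells):
            raise ValueError("all cell repeats must be >= 1")
        if self.oo_distance <= 0:
            raise ValueError("oo_distance must be positive")
        if self.proton_scheme not in ("ordered", "bernal_fowler_random"):
            raise ValueError(f"unknown proton_scheme {self.proton_scheme!r}")
        if self.a is None:
            self.a = self.oo_distance * _IDEAL_CA  # = d / (3/8 * c/a ratio)
        if self.c is None:
            self.c = self.a * _IDEAL_CA
        if self.a <= 0 or self.c <= 0:
            raise ValueError("lattice constants must be positive")


@dataclass
class CompositionSpec:
    """DMSO/water mixture composition by mass.

    ``wt_dmso`` is the DMSO mass fraction of the whole mixture in percent;
    ``wt_d2o`` the heavy-water mass fraction of the aqueous part in percent
    (heavy water is realized as HDO probes, one D per selected water, since
    dilute D2O fully exchanges to HDO in excess H2O).
    """

    wt_dmso: float = 33.0
    wt_d2o: float = 5.0
    n_molecules_total: int = 200
    target_density: float = 1.1  # g/cm^3

    def __post_init__(self) -> None:
        if not (0 <= self.wt_dmso < 100):
            raise ValueError("wt_dmso must be in [0, 100)")
        if not (0 <= self.wt_d2o < 100):
            raise ValueError("wt_d2o must be in [0, 100)")
        if self.n_molecules_total < 1:
            raise ValueError("n_molecules_total must be >= 1")
        if self.target_density <= 0:
            raise ValueError("target_density must be positive")


@dataclass
class SpectrumSpec:
    """Sum-of-Gaussians spectrum: components are (center cm^-1, FWHM cm^-1,
    amplitude); grid is (min, max, step) cm^-1; baseline coefficients are in
    ascending polynomial order."""

    components: list[tuple[float, float, float]]
    grid: tuple[float, float, float] = (2300.0, 2700.0, 1.0)
    noise_sd: float = 0.0
    baseline: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for c, w, a in self.components:
            if w <= 0:
                raise ValueError("component FWHM must be positive")
            if a < 0:
                raise ValueError("component amplitude must be non-negative")
        lo, hi, step = self.grid
        if not (lo < hi and step > 0):
            raise ValueError("grid must satisfy min < max and step > 0")


# ---------------------------------------------------------------------------
# ice lattice
# ---------------------------------------------------------------------------

# Oxygen basis of the 8-molecule orthohexagonal ice cell, fractional
# coordinates in the (a, sqrt(3) a, c) box: the wurtzite positions of the two
# hexagonal cells the orthorhombic cell contains.
_ICE_BASIS = np.array(
    [
        [0.0, 1 / 3, 0.0],
        [0.0, 1 / 3, 3 / 8],
        [1 / 2, 1 / 6, 1 / 2],
        [1 / 2, 1 / 6, 7 / 8],
        [1 / 2, 5 / 6, 0.0],
        [1 / 2, 5 / 6, 3 / 8],
        [0.0, 2 / 3, 1 / 2],
        [0.0, 2 / 3, 7 / 8],
    ]
)


def _oxygen_sublattice(spec: LatticeSpec) -> tuple[np.ndarray, np.ndarray]:
    nx_, ny_, nz_ = spec.n_cells
    cell = np.array([spec.a, math.sqrt(3.0) * spec.a, spec.c])
    box = cell * np.array(spec.n_cells, dtype=float)
    shifts = np.array(
        [[i, j, k] for i in range(nx_) for j in range(ny_) for k in range(nz_)],
        dtype=float,
    )
    frac = (_ICE_BASIS[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    return frac / np.array(spec.n_cells) * box, box


def _bond_graph(oxy: np.ndarray, box: np.ndarray, d: float) -> nx.Graph:
    """O-O bonds at the nearest-neighbour distance, minimum image."""
    g = nx.Graph()
    g.add_nodes_from(range(len(oxy)))
    disp = minimum_image(oxy[None, :, :] - oxy[:, None, :], box)
    dist = np.linalg.norm(disp, axis=-1)
    ii, jj = np.nonzero((np.abs(dist - d) < 1e-4 * d) & (np.arange(len(oxy))[:, None] < np.arange(len(oxy))[None, :]))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def build_ice_lattice(spec: LatticeSpec, topology: TopologyTable | None = None) -> AtomicFrame:
    """Periodic hexagonal-ice configuration (wurtzite oxygen sublattice).

    Every oxygen has exactly four oxygen neighbours at ``oo_distance`` and
    two covalent hydrogens pointing along O···O axes; the Bernal-Fowler ice
    rules (two covalent H per O, one H per O···O link) hold by construction
    under both proton schemes.  The hydrogen assignment is an Eulerian-
    circuit orientation of the 4-regular bond graph: deterministic for
    ``ordered``, seed-shuffled for ``bernal_fowler_random``.
    """
    if topology is None:
        topology = default_topology()
    oxy, box = _oxygen_sublattice(spec)
    if box.min() < 2.5 * spec.oo_distance:
        raise ValueError(
            "supercell too small to define interior molecules under periodic "
            f"boundaries (min box edge {box.min():.2f} A < 2.5 x oo_distance); "
            "increase n_cells"
        )
    g = _bond_graph(oxy, box, spec.oo_distance)
    degrees = dict(g.degree())
    if any(d != 4 for d in degrees.values()):
        raise RuntimeError("ice bond graph is not 4-regular; lattice constants inconsistent")

    if spec.proton_scheme == "bernal_fowler_random":
        rng = np.random.default_rng(spec.seed)
        edges = list(g.edges())
        order = rng.permutation(len(edges))
        shuffled = nx.Graph()
        shuffled.add_nodes_from(rng.permutation(g.number_of_nodes()).tolist())
        for k in order:
            u, v = edges[k]
            if rng.random() < 0.5:
                u, v = v, u
            shuffled.add_edge(u, v)
        circuit = nx.eulerian_circuit(shuffled, source=int(rng.integers(len(oxy))))
    else:
        circuit = nx.eulerian_circuit(g, source=0)

    donors: dict[int, list[int]] = {i: [] for i in range(len(oxy))}
    for u, v in circuit:
        donors[u].append(v)

    parts = []
    for i in range(len(oxy)):
        assert len(donors[i]) == 2  # Eulerian orientation of a 4-regular graph
        o = oxy[i]
        hs = []
        for j in donors[i]:
            axis = minimum_image(oxy[j] - o, box)
            hs.append(o + spec.oh_bond * axis / np.linalg.norm(axis))
        parts.append((np.array([o, hs[0], hs[1]]), ["OW", "HW1", "HW2"], "SOL"))
    return concatenate_molecules(parts, box, topology)


# ---------------------------------------------------------------------------
# random gas
# ---------------------------------------------------------------------------

def build_random_gas(
    n: int, box: tuple[float, float, float], seed: int = 0,
    topology: TopologyTable | None = None,
) -> AtomicFrame:
    """``n`` single-site neutral particles uniformly distributed in the box —
    the zero-order-parameter reference state."""
    if n < 5:
        raise ValueError("need n >= 5 (each particle requires 4 neighbours)")
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    if topology is None:
        topology = default_topology()
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    parts = [(coords[i : i + 1], ["X"], "GAS") for i in range(n)]
    return concatenate_molecules(parts, box, topology)


# ---------------------------------------------------------------------------
# mixture boxes
# ---------------------------------------------------------------------------

def _water_template(oh: float = OH_BOND, angle: float = HOH_ANGLE) -> np.ndarray:
    half = math.radians(angle) / 2.0
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [oh * math.sin(half), 0.0, oh * math.cos(half)],
            [-oh * math.sin(half), 0.0, oh * math.cos(half)],
        ]
    )


def _dmso_template() -> np.ndarray:
    """United-atom DMSO: S at origin, S=O 1.53 A, S-C 1.80 A,
    O-S-C 106.75 deg, C-S-C 97.4 deg."""
    r_so, r_sc = 1.53, 1.80
    osc = math.radians(106.75)
    csc = math.radians(97.4)
    cz = math.cos(osc)
    s = math.sin(osc)
    # azimuthal separation giving the requested C-S-C angle
    cos_dphi = (math.cos(csc) - cz * cz) / (s * s)
    dphi = math.acos(np.clip(cos_dphi, -1.0, 1.0))
    c1 = np.array([s * math.cos(dphi / 2), s * math.sin(dphi / 2), cz]) * r_sc
    c2 = np.array([s * math.cos(dphi / 2), -s * math.sin(dphi / 2), cz]) * r_sc
    return np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r_so], c1, c2])


def mixture_counts(spec: CompositionSpec) -> tuple[int, int, int]:
    """Integer (n_dmso, n_hdo, n_h2o) minimizing the deviation of the
    realized DMSO mass fraction from ``wt_dmso``, with the HDO count set by
    the heavy-water mass fraction of the aqueous part."""
    n_tot = spec.n_molecules_total
    w = spec.wt_d2o / 100.0
    # mole fraction of D2O in the aqueous part implied by its mass fraction
    x_d2o = 0.0 if w == 0 else (w / MOLAR_MASS["D2O"]) / (
        w / MOLAR_MASS["D2O"] + (1 - w) / MOLAR_MASS["H2O"]
    )
    target = spec.wt_dmso / 100.0
    best = None
    for n_dmso in range(0, n_tot):  # keep at least one water
        n_aq = n_tot - n_dmso
        n_d2o = round(x_d2o * n_aq)
        mass = (
            n_dmso * MOLAR_MASS["DMSO"]
            + n_d2o * MOLAR_MASS["D2O"]
            + (n_aq - n_d2o) * MOLAR_MASS["H2O"]
        )
        err = abs(n_dmso * MOLAR_MASS["DMSO"] / mass - target)
        if best is None or err < best[0]:
            best = (err, n_dmso, n_d2o, n_aq)
    _, n_dmso, n_d2o, n_aq = best
    return n_dmso, n_d2o, n_aq - n_d2o


def build_mixture_box(
    spec: CompositionSpec,
    seed: int = 0,
    topology: TopologyTable | None = None,
    min_distance: float = 1.5,
    max_attempts: int = 100_000,
) -> AtomicFrame:
    """Random-insertion (rejection-sampled) DMSO/water mixture.

    Molecule counts follow the mass balance of the composition to within one
    molecule; the cubic box volume realizes ``target_density``; every
    intermolecular atom pair is at least ``min_distance`` apart under
    minimum image.  Heavy water is placed as HDO (one D-labelled hydrogen).
    """
    if topology is None:
        topology = default_topology()
    n_dmso, n_hdo, n_h2o = mixture_counts(spec)
    total_mass_g = (
        n_dmso * MOLAR_MASS["DMSO"]
        + n_hdo * MOLAR_MASS["D2O"]
        + n_h2o * MOLAR_MASS["H2O"]
    ) / AVOGADRO
    volume_cm3 = total_mass_g / spec.target_density
    edge = (volume_cm3 ** (1.0 / 3.0)) * 1e8  # cm -> Angstrom
    box = np.array([edge, edge, edge])

    rng = np.random.default_rng(seed)
    water = _water_template()
    dmso = _dmso_template()
    hdo_flags = [True] * n_hdo + [False] * n_h2o
    rng.shuffle(hdo_flags)

    templates: list[tuple[np.ndarray, list[str], str]] = []
    for _ in range(n_dmso):
        templates.append((dmso, ["S", "OS", "CM1", "CM2"], "DMS"))
    for is_hdo in hdo_flags:
        sites = ["OW", "DW", "HW2"] if is_hdo else ["OW", "HW1", "HW2"]
        templates.append((water, sites, "SOL"))

    placed: list[np.ndarray] = []
    parts = []
    attempts = 0
    occupied = np.empty((0, 3))
    for tmpl, sites, res in templates:
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"packing failed after {max_attempts} attempts; "
                    "lower target_density or min_distance"
                )
            quat = rng.normal(size=4)
            rot = _quat_to_matrix(quat / np.linalg.norm(quat))
            xyz = tmpl @ rot.T + rng.uniform(0.0, 1.0, size=3) * box
            if len(occupied):
                disp = minimum_image(xyz[:, None, :] - occupied[None, :, :], box)
                if np.min(np.linalg.norm(disp, axis=-1)) < min_distance:
                    continue
            break
        parts.append((xyz, sites, res))
        occupied = np.concatenate([occupied, xyz])
    return concatenate_molecules(parts, box, topology)


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# perturbation and isotope labelling
# ---------------------------------------------------------------------------

def perturb_frame(
    frame: AtomicFrame,
    sigma: float,
    seed: int = 0,
    rigid: bool = False,
    rotate_sigma: float = 0.0,
) -> AtomicFrame:
    """Gaussian thermal-disorder proxy.

    ``sigma`` displaces each atom (or each whole molecule when ``rigid``)
    i.i.d. by N(0, sigma) per component, in Angstrom.  ``rotate_sigma``
    additionally rotates every molecule rigidly about its first atom by a
    random axis and an N(0, rotate_sigma) angle in radians — orientational
    disorder, the ingredient that breaks hydrogen-bond alignment without
    compressing contacts.  ``sigma=0, rotate_sigma=0`` returns an identical
    copy.
    """
    if sigma < 0 or rotate_sigma < 0:
        raise ValueError("sigma and rotate_sigma must be >= 0")
    if sigma == 0 and rotate_sigma == 0:
        return frame.copy()
    rng = np.random.default_rng(seed)
    out = frame.copy()
    if rotate_sigma > 0:
        for mid in out.molecule_ids():
            idx = out.atoms_of(mid)
            if len(idx) < 2:
                continue
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.normal(0.0, rotate_sigma)
            pivot = out.coordinates[idx[0]]
            rel = out.coordinates[idx] - pivot
            k = axis
            rel_rot = (
                rel * math.cos(angle)
                + np.cross(k, rel) * math.sin(angle)
                + np.outer(rel @ k, k) * (1.0 - math.cos(angle))
            )
            out.coordinates[idx] = pivot + rel_rot
    if sigma > 0:
        if rigid:
            mids = out.molecule_ids()
            shifts = rng.normal(0.0, sigma, size=(len(mids), 3))
            lookup = {m: k for k, m in enumerate(mids)}
            rows = np.array([lookup[m] for m in out.molecule_id])
            out.coordinates = out.coordinates + shifts[rows]
        else:
            out.coordinates = out.coordinates + rng.normal(0.0, sigma, size=out.coordinates.shape)
    return out


def substitute_hdo(frame: AtomicFrame, fraction: float, seed: int = 0) -> AtomicFrame:
    """Relabel one hydrogen of ``round(fraction * n_waters)`` randomly chosen
    waters as D (site label only; charges untouched)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    out = frame.copy()
    water_mids = sorted(
        {
            int(m)
            for m, r in zip(out.molecule_id, out.residue_name)
            if r in ("SOL", "HOH", "WAT", "TIP4")
        }
    )
    if not water_mids:
        raise ValueError("frame contains no water molecules")
    n_label = round(fraction * len(water_mids))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(water_mids), size=n_label, replace=False)
    for k in chosen:
        idx = out.atoms_of(water_mids[int(k)])
        h_idx = [i for i in idx if str(out.atom_site[i]).startswith(("HW", "DW"))]
        already = [i for i in h_idx if out.atom_site[i] == "DW"]
        if already:
            continue
        pick = h_idx[int(rng.integers(len(h_idx)))]
        out.atom_site[pick] = "DW"
    return out


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

FOUR_LN2 = 4.0 * math.log(2.0)


def gaussian_profile(nu: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    """Amplitude-parameterized Gaussian band: value ``amplitude`` at the
    center, half that at center +/- FWHM/2."""
    return amplitude * np.exp(-FOUR_LN2 * (nu - center) ** 2 / fwhm**2)


def synth_spectrum(spec: SpectrumSpec, **metadata) -> Spectrum:
    """Sum-of-Gaussians spectrum on a uniform wavenumber grid with optional
    polynomial baseline and Gaussian noise; reproducible under the seed."""
    lo, hi, step = spec.grid
    nu = np.arange(lo, hi + step / 2.0, step)
    absorbance = np.zeros_like(nu)
    for center, fwhm, amp in spec.components:
        absorbance += gaussian_profile(nu, center, fwhm, amp)
    if spec.baseline:
        absorbance += np.polynomial.polynomial.polyval(nu, np.asarray(spec.baseline))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        absorbance = absorbance + rng.normal(0.0, spec.noise_sd, size=nu.shape)
    return Spectrum(wavenumber=nu, absorbance=absorbance, metadata=dict(metadata))
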