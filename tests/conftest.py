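import numpy as np
import pytest

from hbmap.frames import AtomicFrame, concatenate_molecules
from hbmap.io import default_topology
from hbmap.synthetic import (
    CompositionSpec,
    LatticeSpec,
    build_ice_lattice,
    build_mixture_box,
    perturb_frame,
    substitute_hdo,
)


@pytest.fixture(scope="session")
def topology():
    return default_topology()


@pytest.fixture(scope="session")
def ice_frame():
    """Small ideal hexagonal-ice supercell (periodic, q = 1 everywhere)."""
    return build_ice_lattice(LatticeSpec(n_cells=(3, 2, 2), oo_distance=2.75))


@pytest.fixture(scope="session")
def ice_hdo_frame():
    """Ice supercell large enough for the default 7.8 A electrostatics
    cutoff, with 30% of waters carrying an HDO probe."""
    frame = build_ice_lattice(
        LatticeSpec(n_cells=(4, 3, 3), oo_distance=2.75, proton_scheme="bernal_fowler_random", seed=9)
    )
    return substitute_hdo(frame, 0.3, seed=1)


@pytest.fixture(scope="session")
def liquid_like_frames(ice_hdo_frame):
    """Orientationally + translationally disordered variants of the ice
    fixture: the liquid-like reference state."""
    return [
        perturb_frame(ice_hdo_frame, 0.1, seed=k, rigid=True, rotate_sigma=0.35)
        for k in range(3)
    ]


@pytest.fixture(scope="session")
def mixture_frame():
    """Small 33 wt% DMSO box with HDO probes."""
    spec = CompositionSpec(wt_dmso=33.0, wt_d2o=5.0, n_molecules_total=150, target_density=1.1)
    return build_mixture_box(spec, seed=11)


def random_diatomic_frame(n_molecules: int, box, seed: int) -> AtomicFrame:
    """Random frame of +q/-q diatomics: generic charged content that still
    satisfies per-molecule neutrality (used by electrostatics oracles)."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    topology = default_topology()
    parts = []
    coords = rng.uniform(0, 1, size=(n_molecules, 3)) * box
    offsets = rng.normal(0, 0.6, size=(n_molecules, 3))
    for i in range(n_molecules):
        xyz = np.array([coords[i], coords[i] + offsets[i]])
        parts.append((xyz, ["X", "X"], "GAS"))
    frame = concatenate_molecules(parts, box, topology)
    q = rng.uniform(0.1, 1.0, size=n_molecules)
    frame.charge = np.repeat(q, 2) * np.tile([1.0, -1.0], n_molecules)
    return frame


def brute_force_potential(frame: AtomicFrame, site, excluded_molecule, cutoff) -> float:
    """Independent electrostatic-potential oracle: explicit double loop over
    atoms and the 27 periodic images, neutral-group inclusion by the
    molecule's first atom."""
    bohr = 0.529177
    site = np.asarray(site, dtype=float)
    shifts = [
        np.array([i, j, k]) * frame.box
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
    ]

    def nearest_image_dist(p):
        return min(np.linalg.norm(site - (p + s)) for s in shifts)

    phi = 0.0
    seen = []
    for mid in np.unique(frame.molecule_id):
        if mid == excluded_molecule:
            continue
        idx = np.flatnonzero(frame.molecule_id == mid)
        if nearest_image_dist(frame.coordinates[idx[0]]) > cutoff:
            continue
        for i in idx:
            phi += frame.charge[i] * bohr / nearest_image_dist(frame.coordinates[i])
        seen.append(mid)
    return phi
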