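"""Structural statistics under periodic boundaries.

Radial distribution functions, the Errington-Debenedetti tetrahedral order
parameter, solvation-shell partitioning around DMSO sulfur, the joint
frequency-distance population P(omega, r), and donor-bond orientational
distributions.  Pair searches use a periodic k-d tree above a size
threshold and direct minimum-image loops below it; both routes are exact
and give identical results.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .frames import AtomicFrame, minimum_image
from .freqmap import FrequencyRecord

#: above this atom count pair searches go through the periodic k-d tree
KDTREE_THRESHOLD = 500

#: default first-solvation-shell cutoff (S...D distance), Angstrom
SHELL_CUTOFF = 3.6

WATER_OXYGEN_SITES = ("OW", "X")


# ---------------------------------------------------------------------------
# pair distances
# ---------------------------------------------------------------------------

def _pair_distances(
    pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray, r_max: float, same: bool
) -> np.ndarray:
    """Minimum-image distances of all A-B pairs with r <= r_max.  Self pairs
    (identical index) are excluded when the selections coincide."""
    n_a, n_b = len(pos_a), len(pos_b)
    if n_a * n_b > KDTREE_THRESHOLD**2:
        wrapped_a = np.mod(pos_a, box)
        wrapped_b = np.mod(pos_b, box)
        # guard against mod returning == box through float rounding
        wrapped_a[wrapped_a >= box] = 0.0
        wrapped_b[wrapped_b >= box] = 0.0
        tree_a = cKDTree(wrapped_a, boxsize=box)
        tree_b = cKDTree(wrapped_b, boxsize=box)
        dm = tree_a.sparse_distance_matrix(tree_b, r_max, output_type="coo_matrix")
        d = dm.data
        if same:
            d = d[dm.row != dm.col]
        return d
    disp = minimum_image(pos_a[:, None, :] - pos_b[None, :, :], box)
    dist = np.linalg.norm(disp, axis=-1)
    if same:
        np.fill_diagonal(dist, np.inf)
    return dist[dist <= r_max]


@dataclass
class RDFResult:
    bin_centers: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    selections: tuple[str, str]
    dr: float
    density_b: float

    def first_minimum(self) -> float:
        """Position of the first local minimum after the first peak, refined
        by a quadratic through the minimum bin and its neighbours."""
        g = self.g
        peak = int(np.argmax(g))
        for i in range(peak + 1, len(g) - 1):
            if g[i] <= g[i - 1] and g[i] <= g[i + 1]:
                x = self.bin_centers[i - 1 : i + 2]
                y = g[i - 1 : i + 2]
                a, b, _ = np.polyfit(x, y, 2)
                return float(-b / (2 * a)) if a > 0 else float(self.bin_centers[i])
        raise ValueError("no local minimum found after the first peak")


def rdf(
    frames: list[AtomicFrame] | AtomicFrame,
    sel_a: str,
    sel_b: str,
    r_max: float | None = None,
    dr: float = 0.1,
) -> RDFResult:
    """Site-site pair correlation function g(r), minimum image, standard
    normalization  g(r) = <n_pairs(r, r+dr)> / (rho_b 4 pi r^2 dr N_a)."""
    if isinstance(frames, AtomicFrame):
        frames = [frames]
    if not frames:
        raise ValueError("no frames given")
    if r_max is None:
        r_max = 0.5 * float(min(f.box.min() for f in frames))
    if r_max > 0.5 * min(f.box.min() for f in frames) + 1e-9:
        raise ValueError("r_max exceeds half the smallest box edge")
    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts = np.zeros(len(edges) - 1)
    norm = 0.0
    for frame in frames:
        ia = frame.select_site(sel_a)
        ib = frame.select_site(sel_b)
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError(f"empty selection ({sel_a!r}: {len(ia)}, {sel_b!r}: {len(ib)})")
        same = sel_a == sel_b
        d = _pair_distances(frame.coordinates[ia], frame.coordinates[ib], frame.box, edges[-1], same)
        counts += np.histogram(d, bins=edges)[0]
        volume = float(np.prod(frame.box))
        norm += len(ia) * (len(ib) / volume)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_volumes = 4.0 * math.pi * centers**2 * dr
    g = counts / (shell_volumes * norm)
    rho_b = norm / len(frames) / max(len(frames[0].select_site(sel_a)), 1)
    return RDFResult(centers, g, counts, (sel_a, sel_b), dr, rho_b)


# ---------------------------------------------------------------------------
# tetrahedral order parameter
# ---------------------------------------------------------------------------

def _q_from_neighbors(center: np.ndarray, neighbors: np.ndarray, box: np.ndarray | None) -> float:
    vecs = neighbors - center if box is None else minimum_image(neighbors - center, box)
    units = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    total = 0.0
    for j in range(3):
        for k in range(j + 1, 4):
            total += (float(units[j] @ units[k]) + 1.0 / 3.0) ** 2
    return 1.0 - 3.0 / 8.0 * total


@dataclass
class OrderParameterResult:
    molecule_ids: np.ndarray
    q: np.ndarray
    neighbor_distances: np.ndarray  # (n, 4)
    shell: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def mean(self) -> float:
        return float(np.mean(self.q))


def _center_positions(frame: AtomicFrame, include_heavy: bool) -> tuple[np.ndarray, np.ndarray]:
    """Candidate neighbour centres: water oxygens (and single-site gas
    particles); with ``include_heavy`` also DMSO heavy atoms."""
    sites = list(WATER_OXYGEN_SITES) + (["S", "OS", "CM"] if include_heavy else [])
    idx = frame.select_site(sites)
    return idx, frame.coordinates[idx]


def tetrahedral_q(
    frame: AtomicFrame, molecule_id: int, include_heavy_neighbors: bool = False
) -> float:
    """Errington-Debenedetti order parameter of one molecule:
    q = 1 - 3/8 sum_{j<k} (cos psi_jk + 1/3)^2 over its 4 nearest
    neighbour centres (minimum image).  q = 1 for a perfect tetrahedron,
    averages 0 in a random gas, minimum -3."""
    result = tetrahedral_q_frame(frame, [molecule_id], include_heavy_neighbors)
    return float(result.q[0])


def tetrahedral_q_frame(
    frame: AtomicFrame,
    molecule_ids: list[int] | None = None,
    include_heavy_neighbors: bool = False,
) -> OrderParameterResult:
    """Order parameter for each requested molecule (default: every molecule
    owning a candidate centre site)."""
    idx, centers = _center_positions(frame, include_heavy_neighbors)
    center_mids = frame.molecule_id[idx]
    if molecule_ids is None:
        molecule_ids = sorted(set(int(m) for m in center_mids))
    if len(centers) < 5:
        raise ValueError("need at least 4 neighbour centres besides the central one")
    big = len(centers) > KDTREE_THRESHOLD
    tree = None
    if big:
        wrapped = np.mod(centers, frame.box)
        wrapped[wrapped >= frame.box] = 0.0
        tree = cKDTree(wrapped, boxsize=frame.box)
    qs, dists = [], []
    for mid in molecule_ids:
        own = np.flatnonzero(center_mids == mid)
        if len(own) == 0:
            raise ValueError(f"molecule {mid} has no neighbour-centre site")
        pos = centers[own[0]]
        others = center_mids != mid
        if big:
            # query enough neighbours to survive the self/same-molecule filter
            k = min(len(centers), 8)
            dd, ii = tree.query(np.mod(pos, frame.box), k=k)
            keep = [j for d_, j in zip(dd, ii) if others[j]][:4]
            if len(keep) < 4:
                raise ValueError(f"molecule {mid} has fewer than 4 neighbours")
            nb = centers[keep]
            nd = np.linalg.norm(minimum_image(nb - pos, frame.box), axis=1)
        else:
            cand = centers[others]
            nd_all = np.linalg.norm(minimum_image(cand - pos, frame.box), axis=1)
            if len(cand) < 4:
                raise ValueError(f"molecule {mid} has fewer than 4 neighbours")
            nearest = np.argsort(nd_all, kind="stable")[:4]
            nb = cand[nearest]
            nd = nd_all[nearest]
        qs.append(_q_from_neighbors(pos, nb, frame.box))
        dists.append(nd)
    return OrderParameterResult(
        np.asarray(molecule_ids, dtype=int), np.asarray(qs), np.asarray(dists)
    )


# ---------------------------------------------------------------------------
# solvation shells
# ---------------------------------------------------------------------------

def shell_partition(
    frame: AtomicFrame, cutoff: float = SHELL_CUTOFF, sulfur_site: str = "S"
) -> dict[int, str]:
    """Label each water ``first_shell`` iff the minimum-image distance from
    its D (or, lacking one, its first hydrogen) to any DMSO sulfur is at
    most ``cutoff``, else ``bulk``; all labels are ``n/a`` without DMSO."""
    water_mids = sorted(
        set(int(m) for m, r in zip(frame.molecule_id, frame.residue_name) if r in ("SOL", "HOH", "WAT", "TIP4"))
    )
    s_pos = frame.coordinates[frame.atom_site == sulfur_site]
    labels: dict[int, str] = {}
    for mid in water_mids:
        if len(s_pos) == 0:
            labels[mid] = "n/a"
            continue
        idx = frame.atoms_of(mid)
        sites = [str(s) for s in frame.atom_site[idx]]
        if "DW" in sites:
            probe = frame.coordinates[idx[sites.index("DW")]]
        else:
            h = [k for k, s in enumerate(sites) if s.startswith("HW")]
            probe = frame.coordinates[idx[h[0]]]
        r = np.linalg.norm(minimum_image(probe - s_pos, frame.box), axis=1).min()
        labels[mid] = "first_shell" if r <= cutoff else "bulk"
    return labels


# ---------------------------------------------------------------------------
# P(omega, r)
# ---------------------------------------------------------------------------

@dataclass
class Histogram2D:
    """Joint frequency-distance population: ``values[i, j]`` is the average
    number of probes per frame with frequency in omega-bin i found in the
    spherical shell of thickness dr at r-bin j (units: 1/Angstrom)."""

    omega_edges: np.ndarray
    r_edges: np.ndarray
    values: np.ndarray

    @property
    def dr(self) -> float:
        return float(self.r_edges[1] - self.r_edges[0])

    def omega_marginal_counts(self) -> np.ndarray:
        """Per-frame frequency histogram recovered by summing values*dr
        over r (the conservation the definition guarantees)."""
        return self.values.sum(axis=1) * self.dr


def omega_r_histogram(
    records: list[FrequencyRecord],
    omega_edges: np.ndarray,
    r_edges: np.ndarray,
    n_frames: int | None = None,
) -> Histogram2D:
    """P(omega, r) from frequency records carrying a defined S...D distance:
    raw 2D counts divided by (n_frames * dr)."""
    defined = [r for r in records if np.isfinite(r.r_s)]
    if not defined:
        raise ValueError("no records with a defined S...D distance")
    if n_frames is None:
        n_frames = len({r.frame_index for r in records})
    omega_edges = np.asarray(omega_edges, dtype=float)
    r_edges = np.asarray(r_edges, dtype=float)
    dr = float(r_edges[1] - r_edges[0])
    counts, _, _ = np.histogram2d(
        [r.omega for r in defined], [r.r_s for r in defined], bins=(omega_edges, r_edges)
    )
    return Histogram2D(omega_edges, r_edges, counts / (n_frames * dr))


# ---------------------------------------------------------------------------
# orientational distribution
# ---------------------------------------------------------------------------

def orientational_distribution(
    frames: list[AtomicFrame] | AtomicFrame,
    oo_cutoff: float = 3.5,
    bins: int = 40,
    mode: str = "bonded",
    shell_filter: str | None = None,
    shell_cutoff: float = SHELL_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of cos(theta), theta the angle between a donor O-H(D)
    bond and the O...O axis, over water pairs within ``oo_cutoff``.

    ``mode="bonded"`` keeps, per unordered pair, the single best-aligned
    bond over both molecules — the hydrogen that actually donates the
    hydrogen bond (cos theta = 1 for a linear bond).  ``mode="all"`` keeps,
    per ordered pair, both of the first molecule's bond cosines against the
    axis towards the partner.  ``shell_filter`` restricts to pairs whose
    first molecule is in the given solvation shell.
    Returns (bin_centers, unit-area density).
    """
    if isinstance(frames, AtomicFrame):
        frames = [frames]
    cosines: list[float] = []
    for frame in frames:
        labels = shell_partition(frame, cutoff=shell_cutoff) if shell_filter else {}
        o_idx = frame.select_site("OW")
        o_mids = frame.molecule_id[o_idx]
        o_pos = frame.coordinates[o_idx]
        bond_units = []
        for a, mid in enumerate(o_mids):
            atoms = frame.atoms_of(int(mid))
            h_atoms = [i for i in atoms if str(frame.atom_site[i]).startswith(("HW", "DW"))]
            units = [
                (frame.coordinates[h] - o_pos[a])
                / np.linalg.norm(frame.coordinates[h] - o_pos[a])
                for h in h_atoms
            ]
            bond_units.append(units)
        for a in range(len(o_mids)):
            if shell_filter and labels.get(int(o_mids[a])) != shell_filter:
                continue
            axis_disp = minimum_image(o_pos - o_pos[a], frame.box)
            dist = np.linalg.norm(axis_disp, axis=1)
            lower = np.arange(len(o_mids)) > a if mode == "bonded" else o_mids != o_mids[a]
            partners = np.flatnonzero((dist > 1e-9) & (dist <= oo_cutoff) & lower & (o_mids != o_mids[a]))
            for b in partners:
                axis_u = axis_disp[b] / dist[b]
                if mode == "bonded":
                    cos_all = [float(u @ axis_u) for u in bond_units[a]]
                    cos_all += [float(-(u @ axis_u)) for u in bond_units[b]]
                    cosines.append(max(cos_all))
                else:
                    cosines.extend(float(u @ axis_u) for u in bond_units[a])
    if not cosines:
        raise ValueError("no water pairs within the O...O cutoff")
    density, edges = np.histogram(cosines, bins=bins, range=(-1.0, 1.0), density=True)
    return 0.5 * (edges[:-1] + edges[1:]), density


# ---------------------------------------------------------------------------
# shell-resolved order parameter
# ---------------------------------------------------------------------------

def shell_resolved_q(
    frames: list[AtomicFrame] | AtomicFrame,
    cutoff: float = SHELL_CUTOFF,
    bins: np.ndarray | None = None,
    include_heavy_neighbors: bool = False,
) -> dict:
    """Tetrahedral-order histograms of first-shell vs bulk waters.

    Returns {"bin_edges", shell: {"histogram", "mean_q", "n"}} with an empty
    (flagged, not raised) histogram for an unpopulated shell; without DMSO a
    single "bulk" entry covers all waters.
    """
    if isinstance(frames, AtomicFrame):
        frames = [frames]
    if bins is None:
        bins = np.linspace(-3.0, 1.0, 81)
    per_shell: dict[str, list[float]] = {}
    for frame in frames:
        labels = shell_partition(frame, cutoff=cutoff)
        water_mids = [m for m in labels]
        result = tetrahedral_q_frame(frame, water_mids, include_heavy_neighbors)
        for mid, q in zip(result.molecule_ids, result.q):
            shell = labels[int(mid)]
            if shell == "n/a":
                shell = "bulk"
            per_shell.setdefault(shell, []).append(float(q))
    out: dict = {"bin_edges": np.asarray(bins)}
    for shell in ("first_shell", "bulk"):
        values = per_shell.get(shell, [])
        hist = np.histogram(values, bins=bins)[0] if values else np.zeros(len(bins) - 1, dtype=int)
        out[shell] = {
            "histogram": hist,
            "mean_q": float(np.mean(values)) if values else float("nan"),
            "n": len(values),
            "empty": len(values) == 0,
        }
    return out
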