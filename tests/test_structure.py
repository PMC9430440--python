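"""RDF vs brute-force oracle, tetrahedral order parameter closed forms,
shell partitioning, P(omega, r) conservation, orientational distributions,
and equality of the tree-based and direct pair-search paths."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hbmap.structure as structure
from hbmap.frames import concatenate_molecules, minimum_image
from hbmap.freqmap import FrequencyRecord
from hbmap.structure import (
    omega_r_histogram,
    orientational_distribution,
    rdf,
    shell_partition,
    shell_resolved_q,
    tetrahedral_q,
    tetrahedral_q_frame,
)
from hbmap.synthetic import (
    CompositionSpec,
    LatticeSpec,
    build_ice_lattice,
    build_mixture_box,
    build_random_gas,
    perturb_frame,
)


def _gas_like(points, box, topology):
    parts = [(np.asarray(p)[None, :], ["X"], "GAS") for p in points]
    return concatenate_molecules(parts, np.asarray(box, dtype=float), topology)


class TestTetrahedralQ:
    def test_square_planar_is_exactly_half(self, topology):
        c = np.full(3, 10.0)
        pts = [c, c + [3, 0, 0], c - [3, 0, 0], c + [0, 3, 0], c - [0, 3, 0]]
        frame = _gas_like(pts, [20, 20, 20], topology)
        # hand derivation: four 90-degree pairs contribute (1/3)^2 each, two
        # 180-degree pairs (-2/3)^2 each -> q = 1 - 3/8 * (4/9 + 8/9) = 0.5
        assert tetrahedral_q(frame, 0) == pytest.approx(0.5, abs=1e-14)

    def test_collinear_neighbors_reach_minus_three(self, topology):
        c = np.full(3, 10.0)
        u = np.array([1.0, 0.0, 0.0])
        pts = [c] + [c + d * u for d in (2.0, 2.5, 3.0, 3.5)]
        frame = _gas_like(pts, [40, 40, 40], topology)
        # six pairs at cos = 1: q = 1 - 3/8 * 6 * (4/3)^2 = -3
        assert tetrahedral_q(frame, 0) == pytest.approx(-3.0, abs=1e-12)

    def test_fewer_than_four_neighbors_raises(self, topology):
        frame = _gas_like([[1, 1, 1], [2, 2, 2], [3, 3, 3]], [20, 20, 20], topology)
        with pytest.raises(ValueError):
            tetrahedral_q_frame(frame, [0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_q_range_invariant(self, seed):
        frame = build_random_gas(30, (15, 15, 15), seed=seed)
        result = tetrahedral_q_frame(frame)
        assert np.all(result.q <= 1.0 + 1e-12)
        assert np.all(result.q > -3.0 - 1e-12)

    def test_tree_and_direct_paths_agree(self, monkeypatch):
        frame = build_random_gas(800, (25, 25, 25), seed=2)  # above threshold
        via_tree = tetrahedral_q_frame(frame).q
        monkeypatch.setattr(structure, "KDTREE_THRESHOLD", 10**9)
        via_direct = tetrahedral_q_frame(frame).q
        assert np.array_equal(via_tree, via_direct)


class TestRDF:
    def test_matches_brute_force_all_pairs_oracle(self, topology):
        rng = np.random.default_rng(8)
        box = np.array([14.0, 15.0, 16.0])
        pts = rng.uniform(0, 1, (30, 3)) * box
        frame = _gas_like(pts, box, topology)
        result = rdf(frame, "X", "X", r_max=6.5, dr=0.25)
        # independent oracle: explicit double loop, minimum image by hand
        edges = np.arange(0.0, 6.5 + 0.125, 0.25)
        counts = np.zeros(len(edges) - 1)
        for i in range(30):
            for j in range(30):
                if i == j:
                    continue
                d = pts[i] - pts[j]
                d -= box * np.round(d / box)
                r = np.linalg.norm(d)
                if r <= edges[-1]:
                    k = int(r / 0.25)
                    if k < len(counts):
                        counts[k] += 1
        assert np.array_equal(result.counts, counts)
        centers = 0.5 * (edges[:-1] + edges[1:])
        expected_g = counts / (4 * math.pi * centers**2 * 0.25) / (30 * 30 / box.prod())
        assert np.allclose(result.g, expected_g, atol=1e-12)

    def test_two_fixed_atoms(self, topology):
        frame = _gas_like([[5, 5, 5], [8.05, 5, 5]], [20, 20, 20], topology)
        result = rdf(frame, "X", "X", r_max=9.0, dr=0.2)
        hot = result.counts > 0
        assert hot.sum() == 1
        assert result.bin_centers[hot][0] == pytest.approx(3.05, abs=0.1)

    def test_sum_rule(self):
        frame = build_random_gas(500, (20, 20, 20), seed=1)
        result = rdf(frame, "X", "X", dr=0.05)
        rho = 500 / 20.0**3
        integral = np.sum(rho * result.g * 4 * math.pi * result.bin_centers**2 * 0.05)
        # half-box integral covers most neighbours of each particle
        expected = rho * 4 / 3 * math.pi * 10.0**3
        assert integral == pytest.approx(expected, rel=0.05)

    def test_empty_selection_raises(self, ice_frame):
        with pytest.raises(ValueError, match="empty selection"):
            rdf(ice_frame, "S", "OW")

    def test_tree_and_direct_paths_agree(self, monkeypatch):
        frame = build_random_gas(700, (24, 24, 24), seed=5)
        a = rdf(frame, "X", "X", r_max=10.0, dr=0.2)
        monkeypatch.setattr(structure, "KDTREE_THRESHOLD", 10**9)
        b = rdf(frame, "X", "X", r_max=10.0, dr=0.2)
        assert np.array_equal(a.counts, b.counts)


class TestShellPartition:
    @staticmethod
    def _water_near_sulfur(d_to_s, topology):
        s = np.full(3, 10.0)
        dmso = np.array([s, s + [0, 0, 1.53], s + [1.4, 0, -1.0], s + [-1.4, 0, -1.0]])
        d_atom = s + np.array([d_to_s, 0.0, 0.0])
        o = d_atom + np.array([0.9572, 0.0, 0.0])
        h = o + 0.9572 * np.array([-math.cos(math.radians(75.48)), math.sin(math.radians(75.48)), 0])
        parts = [
            (dmso, ["S", "OS", "CM1", "CM2"], "DMS"),
            (np.array([o, d_atom, h]), ["OW", "DW", "HW2"], "SOL"),
        ]
        return concatenate_molecules(parts, np.full(3, 30.0), topology)

    def test_cutoff_threshold(self, topology):
        assert shell_partition(self._water_near_sulfur(3.5, topology))[1] == "first_shell"
        assert shell_partition(self._water_near_sulfur(3.7, topology))[1] == "bulk"

    def test_no_dmso_gives_na(self, ice_frame):
        labels = shell_partition(ice_frame)
        assert set(labels.values()) == {"n/a"}

    def test_threshold_monotone(self, mixture_frame):
        lo = shell_partition(mixture_frame, cutoff=3.0)
        hi = shell_partition(mixture_frame, cutoff=4.5)
        for mid, label in lo.items():
            if label == "first_shell":
                assert hi[mid] == "first_shell"

    def test_idempotent(self, mixture_frame):
        assert shell_partition(mixture_frame) == shell_partition(mixture_frame)


class TestOmegaRHistogram:
    def test_single_record_definition(self):
        records = [FrequencyRecord(0, 0, 2500.0, 3.0, "bulk")]
        h = omega_r_histogram(records, np.arange(2400, 2601, 50.0), np.arange(0, 5.01, 0.2), n_frames=1)
        assert h.values.max() == pytest.approx(5.0)  # 1 count / (1 frame * 0.2 A)
        assert h.values.sum() == pytest.approx(5.0)

    def test_marginalization_conservation(self, mixture_frame):
        from hbmap.freqmap import compute_frequency_records

        frames = [perturb_frame(mixture_frame, 0.05, seed=k) for k in range(3)]
        records = compute_frequency_records(frames)
        omega_edges = np.arange(2000, 3201, 10.0)
        r_edges = np.arange(0.0, 9.01, 0.1)
        h = omega_r_histogram(records, omega_edges, r_edges, n_frames=3)
        in_range = [
            r for r in records
            if np.isfinite(r.r_s) and r.r_s < r_edges[-1]
            and omega_edges[0] <= r.omega < omega_edges[-1]
        ]
        direct = np.histogram([r.omega for r in in_range], bins=omega_edges)[0] / 3.0
        assert np.abs(h.omega_marginal_counts() - direct).max() < 1e-9

    def test_shell_dependent_broadening_visible(self):
        # constructed fixture: first-shell probes drawn from a wide band,
        # bulk probes from a narrow one
        rng = np.random.default_rng(0)
        records = []
        for i in range(4000):
            r = rng.uniform(2.6, 7.5)
            omega = rng.normal(2470, 90.0) if r <= 3.6 else rng.normal(2440, 25.0)
            records.append(FrequencyRecord(i % 10, i, float(omega), float(r), "?"))
        omega_edges = np.arange(2100, 2801, 10.0)
        r_edges = np.arange(2.5, 7.51, 0.5)
        h = omega_r_histogram(records, omega_edges, r_edges, n_frames=10)
        centers = 0.5 * (omega_edges[:-1] + omega_edges[1:])

        def row_sd(j):
            w = h.values[:, j]
            mu = np.average(centers, weights=w)
            return math.sqrt(np.average((centers - mu) ** 2, weights=w))

        r_centers = 0.5 * (r_edges[:-1] + r_edges[1:])
        inner = [row_sd(j) for j in range(len(r_centers)) if r_centers[j] < 3.6]
        outer = [row_sd(j) for j in range(len(r_centers)) if r_centers[j] > 3.6]
        assert min(inner) > max(outer)

    def test_no_defined_distances_raises(self):
        records = [FrequencyRecord(0, 0, 2500.0, float("nan"), "n/a")]
        with pytest.raises(ValueError, match="defined"):
            omega_r_histogram(records, np.arange(2400, 2601, 50.0), np.arange(0, 5, 0.2))


class TestOrientational:
    def test_ice_mass_at_linear_bonds(self, ice_frame):
        centers, density = orientational_distribution(ice_frame, oo_cutoff=3.0)
        assert centers[np.argmax(density)] > 0.95
        # essentially all mass in the last bin (cos theta = 1)
        width = centers[1] - centers[0]
        assert density[-1] * width == pytest.approx(1.0, abs=1e-9)

    def test_random_orientations_match_direct_sampling_oracle(self, topology):
        # per pair the statistic is the max over 4 bond cosines (2 rigidly
        # coupled bonds on each side); the oracle samples uniformly rotated
        # rigid waters on both sides of a fixed axis
        spec = CompositionSpec(wt_dmso=0.0, wt_d2o=0.0, n_molecules_total=400, target_density=0.9)
        frame = build_mixture_box(spec, seed=3)
        centers, density = orientational_distribution(frame, oo_cutoff=4.5, bins=10)
        rng = np.random.default_rng(1)
        half = math.radians(104.52) / 2
        bonds = np.array(
            [[math.sin(half), 0, math.cos(half)], [-math.sin(half), 0, math.cos(half)]]
        )
        n = 200_000
        from scipy.spatial.transform import Rotation

        # one rotation applies to both bonds of a side (rigid molecule)
        rot_a = Rotation.random(n, rng=rng)
        rot_b = Rotation.random(n, rng=rng)
        side_a = np.stack([rot_a.apply(bonds[0]), rot_a.apply(bonds[1])], axis=1)
        side_b = np.stack([rot_b.apply(bonds[0]), rot_b.apply(bonds[1])], axis=1)
        axis = np.array([0.0, 0.0, 1.0])
        cos_max = np.maximum(
            (side_a @ axis).max(axis=1), (-(side_b @ axis)).max(axis=1)
        )
        oracle, _ = np.histogram(cos_max, bins=10, range=(-1, 1), density=True)
        assert np.abs(density - oracle).max() < 0.12

    def test_perturbed_ice_broadened_but_peaked(self, ice_frame):
        frame = perturb_frame(ice_frame, 0.15, seed=6)
        centers, density = orientational_distribution(frame, oo_cutoff=3.3)
        assert centers[np.argmax(density)] > 0.8
        ice_centers, ice_density = orientational_distribution(ice_frame, oo_cutoff=3.0)
        assert (density > 0).sum() > (ice_density > 0).sum()


class TestShellResolvedQ:
    def test_scrambled_first_shell_scores_lower(self, topology):
        # construct: ice-like bulk, first-shell waters positionally scrambled
        frame = build_ice_lattice(LatticeSpec(n_cells=(3, 2, 2)))
        coords = frame.coordinates.copy()
        s_pos = np.full(3, 0.0) + frame.box / 2
        rng = np.random.default_rng(0)
        labels = {}
        for mid in frame.molecule_ids():
            idx = frame.atoms_of(mid)
            d = np.linalg.norm(minimum_image(coords[idx[0]] - s_pos, frame.box))
            if d < 5.0:
                coords[idx] += rng.normal(0, 0.8, size=(len(idx), 3))
        parts = [(coords[frame.atoms_of(m)], ["OW", "HW1", "HW2"], "SOL") for m in frame.molecule_ids()]
        dmso = np.array([s_pos, s_pos + [0, 0, 1.53], s_pos + [1.4, 0, -1], s_pos + [-1.4, 0, -1]])
        parts.append((dmso, ["S", "OS", "CM1", "CM2"], "DMS"))
        mixed = concatenate_molecules(parts, frame.box, topology)
        result = shell_resolved_q(mixed, cutoff=4.5)
        assert result["first_shell"]["n"] > 0 and result["bulk"]["n"] > 0
        assert result["first_shell"]["mean_q"] < result["bulk"]["mean_q"]

    def test_no_dmso_single_bulk_histogram(self, ice_frame):
        result = shell_resolved_q(ice_frame)
        assert result["first_shell"]["empty"]
        assert result["bulk"]["n"] == ice_frame.n_molecules
        assert result["bulk"]["mean_q"] == pytest.approx(1.0, abs=1e-9)
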