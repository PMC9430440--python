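"""Resolve how DMSO perturbs water structure: shell-resolved tetrahedral
order and the joint frequency-distance population P(omega, r).

Packs a 33 wt% DMSO / water box (heavy water as dilute HDO probes), jitters
it over a few frames, computes per-probe O-D frequencies with the distance
from each D atom to the nearest DMSO sulfur, and partitions waters at the
3.6 A first-solvation-shell cutoff.
"""
import numpy as np

from hbmap import compute_frequency_records, omega_r_histogram, rdf, shell_resolved_q
from hbmap.synthetic import CompositionSpec, build_mixture_box, perturb_frame

spec = CompositionSpec(wt_dmso=33.0, wt_d2o=8.0, n_molecules_total=150, target_density=1.1)
base = build_mixture_box(spec, seed=4)
frames = [perturb_frame(base, 0.06, seed=k) for k in range(4)]
print(f"box: {base.box[0]:.1f} A cube, {base.n_atoms} atoms, {base.n_molecules} molecules")

records = compute_frequency_records(frames)
first = [r.omega for r in records if r.shell == "first_shell"]
bulk = [r.omega for r in records if r.shell == "bulk"]
print(f"probes: {len(first)} first-shell, {len(bulk)} bulk (S...D cutoff 3.6 A)")

h = omega_r_histogram(records, np.arange(2000, 3401, 10.0), np.arange(0, 9.01, 0.2), n_frames=len(frames))
print(f"P(omega, r) grid: {h.values.shape[0]} x {h.values.shape[1]} cells, "
      f"total population {h.values.sum() * h.dr:.1f} probes/frame")

qs = shell_resolved_q(frames, cutoff=3.6)
print(f"mean tetrahedral q: first shell {qs['first_shell']['mean_q']:.3f} "
      f"(n={qs['first_shell']['n']}), bulk {qs['bulk']['mean_q']:.3f} (n={qs['bulk']['n']})")

g = rdf(frames, "S", "HW", dr=0.1)
print(f"S-H(water) RDF: first peak at {g.bin_centers[np.argmax(g.g)]:.1f} A")
print("A randomly packed box is disordered everywhere, so both shells score "
      "low q; in an equilibrated liquid only the first shell would.")
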