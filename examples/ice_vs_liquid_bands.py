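"""Compare the computed O-D stretch band of ideal hexagonal ice with an
orientationally disordered (liquid-like) variant of the same box.

Builds a periodic ice lattice, labels 30% of the waters as HDO probes,
computes instantaneous frequencies through the electrostatic map, then
disorders the box (rigid molecular rotations + translations) and repeats.
The ice band should come out narrower and red-shifted — the signature of a
regular tetrahedral hydrogen-bond network.
"""
import numpy as np

from hbmap import frequency_distribution
from hbmap.synthetic import LatticeSpec, build_ice_lattice, perturb_frame, substitute_hdo

ice = substitute_hdo(
    build_ice_lattice(
        LatticeSpec(n_cells=(4, 3, 3), oo_distance=2.75, proton_scheme="bernal_fowler_random", seed=9)
    ),
    fraction=0.3,
    seed=1,
)
liquid = [perturb_frame(ice, 0.1, seed=k, rigid=True, rotate_sigma=0.35) for k in range(3)]

_, _, rec_ice = frequency_distribution([ice])
_, _, rec_liq = frequency_distribution(liquid)
w_ice = np.array([r.omega for r in rec_ice])
w_liq = np.array([r.omega for r in rec_liq])

print(f"ice band:    mean {w_ice.mean():7.1f} cm^-1, sd {w_ice.std():6.1f} cm^-1  ({len(w_ice)} probes)")
print(f"liquid band: mean {w_liq.mean():7.1f} cm^-1, sd {w_liq.std():6.1f} cm^-1  ({len(w_liq)} probes)")
print(
    "The liquid-like band is blue-shifted by "
    f"{w_liq.mean() - w_ice.mean():.1f} cm^-1 and {w_liq.std() / w_ice.std():.1f}x broader: "
    "disorder weakens hydrogen bonds and diversifies their geometries."
)
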