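"""Hydrogen-bond strength vs O-D frequency on a water dimer.

Scans the donor-acceptor O...O distance of a linear HDO -> H2O hydrogen
bond and prints the mapped O-D frequency: short (strong) bonds are
red-shifted, long (weak) bonds approach the unperturbed frequency.
"""
from hbmap import default_map, hbond_frequency_scan

distances = [2.6, 2.8, 3.0, 3.2, 3.4]
omegas = hbond_frequency_scan(distances)
print(f"unperturbed O-D frequency: {default_map().omega0:.1f} cm^-1")
for d, w in zip(distances, omegas):
    print(f"  O...O {d:.1f} A  ->  {w:7.1f} cm^-1")
print(f"stretching the bond from 2.6 to 3.4 A blue-shifts the mode by "
      f"{omegas[-1] - omegas[0]:.0f} cm^-1.")
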