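# Synthetic O-D stretch frequency map for dilute HDO (SYNTHETIC STAND-IN).
# Provenance: this is NOT a transcription of a published map.  It is an
# affine potential map of the same functional form as literature O-D maps
# (omega = omega0 + sum_site c_site * phi_site, phi in atomic units at the
# probe's D, O and H atoms, neutral-group truncation at the cutoff):
#   - omega0 is the gas-phase O-D stretch fundamental of HDO (2723.6 cm^-1);
#   - coefficients carry the physical sign convention (a hydrogen-bond
#     acceptor near D lowers phi_D and red-shifts the band) and were
#     calibrated once against the package's own fixtures so that the ideal
#     hexagonal-ice band sits near 2430 cm^-1 and orientational disorder
#     broadens and blue-shifts it, as observed for real HDO spectra;
#   - cutoff in Angstrom, abrupt neutral-group truncation, no Ewald.
# Units: omega0 in cm^-1; coeff_* in cm^-1 per atomic unit of potential.
key,value
omega0,2723.6
cutoff,7.8
coeff_D,6500.0
coeff_O,-180.0
coeff_H,500.0
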