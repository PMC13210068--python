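"""Condense sigma-profiles into the 12-bin descriptor block.

Generates smooth synthetic sigma-profiles, mixes two solvent profiles at a
given composition, and prints the 36 named descriptors (solute, mixture,
difference) that enter the Set 2 feature configuration.
"""

from dooit2 import bin_profile, generate_sigma_profiles, mixture_profile, sigma_block

profiles = generate_sigma_profiles(3, seed=42)
solute, solv_a, solv_b = profiles.values()

# solvent mixture at 30 mol% organic (solute-free)
mixture = mixture_profile([solv_a, solv_b], [0.3, 0.7])

block = sigma_block(bin_profile(solute), bin_profile(mixture))
for region in ("HBD", "HH", "HBA"):
    row = "  ".join(f"{k}={block[k]:7.3f}" for k in block if k.startswith(f"d_{region}"))
    print(row)
print(
    "d_* values are solute-minus-mixture bin differences over the donor (HBD),"
    " hydrophobic (HH) and acceptor (HBA) regions of the charge-density axis;"
    " large magnitudes flag hydrogen-bonding mismatch between solute and medium."
)
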