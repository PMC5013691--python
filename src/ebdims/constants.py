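"""Physical constants and unit conversions.

The internal unit system is kcal·mol⁻¹ (energy), Å (length), fs (time) and
Da = g·mol⁻¹ (mass).  In these units Newton's second law picks up a scalar
conversion factor: an acceleration in Å·fs⁻² equals ``ACC_CONV`` times
force (kcal·mol⁻¹·Å⁻¹) over mass (Da).
"""

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹
KB = 0.0019872041

#: 1 kcal·mol⁻¹·Å⁻¹ / Da  ->  Å·fs⁻², i.e. 4184 J·mol⁻¹ expressed in Å²·fs⁻²·g⁻¹·mol
ACC_CONV = 4.184e-4

#: Uniform coarse-grained residue mass (average amino-acid mass), Da
RESIDUE_MASS = 100.0
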