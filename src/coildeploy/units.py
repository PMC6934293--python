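"""Unit system and centralized conversions.

The solver works in a consistent mm–kg–ms system:

======================  ==============  =======================
quantity                internal unit   relation to SI
======================  ==============  =======================
length                  mm              1e-3 m
mass                    kg              kg
time                    ms              1e-3 s
force                   kN              kg·mm/ms² = 1e3 N
stress / modulus        GPa             kN/mm² = 1e9 Pa
density                 kg/mm³          1e9 kg/m³
energy                  J               kN·mm = 1 J
velocity                mm/ms           m/s
======================  ==============  =======================

Elastic moduli are therefore carried in GPa with no conversion factor.
User-facing quantities keep the field's customary units — wire density in
mg/mm³, rigidities in N and N·mm², coil length in cm in spec files — and
every conversion lives here.
"""

#: GPa expressed in N/mm² (the factor tracked when rigidities are reported in N).
GPA_TO_N_PER_MM2 = 1.0e3

#: mg/mm³ → kg/mm³ (internal density unit).
MG_PER_MM3_TO_INTERNAL = 1.0e-6

#: N → kN (internal force unit).
N_TO_KN = 1.0e-3

#: cm → mm.
CM_TO_MM = 10.0

#: seconds → ms (Rayleigh α is quoted in 1/s, β in s).
S_TO_MS = 1.0e3

#: Platinum(92%)/tungsten(8%) alloy density, mg/mm³ (g/cm³ numerically equal).
RHO_PLATINUM_MG_MM3 = 21.45
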