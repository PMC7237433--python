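"""Physical constants and instrument defaults used across the package.

The force-constant coefficient converts the temperature slope of the mean
square displacement into an effective force constant (resilience),

    <k> = FORCE_CONSTANT_COEFF / (d<u2>/dT),

with <u2> in A^2, T in K and <k> in N/m.  Its units are therefore
N*A^2*m^-1*K^-1 and its value corresponds to ~2 k_B expressed in those
units (2 * 1.380649e-23 J/K = 2.76e-23 J/K = 0.00276 N*A^2/K, since
1 A^2 = 1e-20 m^2).

The Gaussian approximation used throughout is

    I(Q) ~ I0 * exp(-<u2> * Q^2 / 6),

i.e. the 1/6 convention.  The 0.00276 coefficient above is only correct
with this convention; the alternative exp(-<u2> Q^2 / 3) convention would
require half the coefficient.
"""

#: Coefficient of the effective-force-constant formula, N*A^2*m^-1*K^-1 (~2 k_B).
FORCE_CONSTANT_COEFF: float = 0.00276

#: Incident neutron wavelength of a thermal backscattering spectrometer
#: of the IN13 type, in Angstrom.  Used to map momentum transfer Q to a
#: scattering angle for absorption corrections.
DEFAULT_WAVELENGTH: float = 2.23

#: Accessible momentum-transfer range, A^-1.
Q_MIN: float = 0.3
Q_MAX: float = 4.9
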