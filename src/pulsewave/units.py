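"""Unit conventions: CGS internally, clinical units at the I/O boundary.

Internal solver units are g, cm, s (pressures in dyn/cm^2 = g cm^-1 s^-2).
Clinical quantities cross the boundary as mmHg, l/min, ml, ms, beats/min.
"""

MMHG_TO_CGS = 1333.22  # dyn/cm^2 per mmHg
LMIN_TO_CGS = 1000.0 / 60.0  # cm^3/s per l/min


def mmhg_to_dyn(p_mmhg):
    return p_mmhg * MMHG_TO_CGS


def dyn_to_mmhg(p_dyn):
    return p_dyn / MMHG_TO_CGS
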