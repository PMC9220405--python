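"""Unit conversions and global geometric tolerances.

The internal unit of length is the millimetre everywhere; litres and
centimetres appear only at the configuration / reporting boundary.
"""

#: Absolute snap tolerance for geometric predicates, in mm.
SNAP_TOL = 1e-6

#: Standard gravity, m/s^2, for kgf <-> N conversion.
G_STANDARD = 9.81

MM_PER_CM = 10.0
MM3_PER_LITRE = 1.0e6
MM3_PER_CM3 = 1.0e3


def cm_to_mm(x: float) -> float:
    return x * MM_PER_CM


def mm_to_cm(x: float) -> float:
    return x / MM_PER_CM


def litres_to_mm3(v: float) -> float:
    return v * MM3_PER_LITRE


def mm3_to_litres(v: float) -> float:
    return v / MM3_PER_LITRE


def kgf_to_newton(m: float) -> float:
    return m * G_STANDARD


def newton_to_kgf(f: float) -> float:
    return f / G_STANDARD
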