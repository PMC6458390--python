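"""Unit conversions at the package boundary.

Canonical internal units are mm (length), mm^2 (area), mm^3 (volume) and
days (time). Raw measurement files use the field-customary mixture of
µm^2 for cross-section areas and cm for longitudinal extension; these
helpers convert once, on input/output, so that every internal computation
is unit-consistent.
"""

UM2_PER_MM2 = 1.0e6
MM_PER_CM = 10.0
UM_PER_MM = 1000.0


def um2_to_mm2(area_um2):
    return area_um2 / UM2_PER_MM2


def mm2_to_um2(area_mm2):
    return area_mm2 * UM2_PER_MM2


def cm_to_mm(length_cm):
    return length_cm * MM_PER_CM


def mm_to_cm(length_mm):
    return length_mm / MM_PER_CM


def um_to_mm(length_um):
    return length_um / UM_PER_MM


def mm_to_um(length_mm):
    return length_mm * UM_PER_MM
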