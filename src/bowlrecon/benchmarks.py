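"""Published benchmark measurements of nine commercial round bowls.

For each bowl: the physically measured (actual) diameter, depth and
capacity, and the values calculated from the single-image reconstruction,
as reported in the original nine-bowl validation study.  Used to validate
the error-report arithmetic and as the acceptance reference.
"""

from __future__ import annotations

__all__ = [
    "NINE_BOWL_ROWS",
    "PRINTED_ERRORS",
    "SYNTHETIC_BOWL_GRID",
    "SYNTHETIC_FILLET_MM",
    "SYNTHETIC_SIM_KWARGS",
]

_DIAM_ACTUAL = [101, 110, 121, 157, 153, 135, 151, 152, 143]
_DIAM_CALC = [96.9, 110.6, 118.7, 154.6, 154.3, 135.2, 142.7, 145.4, 135.6]
_DEPTH_ACTUAL = [45, 42, 52, 44, 43, 70, 59, 61, 65]
_DEPTH_CALC = [47.3, 39.1, 52.5, 42.2, 42.9, 67.9, 62.3, 64.1, 68.7]
_CAP_ACTUAL = [288, 291, 371, 500, 500, 642, 773, 787, 810]
_CAP_CALC = [288.7, 288, 362.9, 496.9, 553, 661.4, 769.4, 803.4, 851.6]

#: rows consumable by :func:`bowlrecon.report.build_report`
NINE_BOWL_ROWS = [
    {
        "bowl": i + 1,
        "actual_diameter": _DIAM_ACTUAL[i],
        "calculated_diameter": _DIAM_CALC[i],
        "actual_depth": _DEPTH_ACTUAL[i],
        "calculated_depth": _DEPTH_CALC[i],
        "actual_capacity": _CAP_ACTUAL[i],
        "calculated_capacity": _CAP_CALC[i],
    }
    for i in range(9)
]

#: the relative-error cells as printed in the benchmark (1-decimal %)
PRINTED_ERRORS = {
    "diameter": [-4.1, 0.5, -1.9, -1.5, 0.8, 0.1, -5.5, -4.3, -5.2],
    "depth": [5.1, -6.9, 1.0, -4.1, -0.2, -3.0, 5.6, 5.1, 5.7],
    "capacity": [0.2, -1.0, -2.2, -0.6, 10.6, 3.0, -0.5, 2.1, 5.1],
}

#: synthetic validation grid: 3 families x 3 sizes spanning the benchmark's
#: capacity range (~290-850 mL), with rounded interior junctions as on real
#: bowls; (family, bottom radius, rim radius, depth, wall exponent)
SYNTHETIC_BOWL_GRID = [
    ("spherical-cap", 30, 52, 45, 2.0),
    ("spherical-cap", 35, 62, 50, 2.0),
    ("spherical-cap", 45, 75, 56, 2.0),
    ("power-wall", 30, 52, 46, 0.5),
    ("power-wall", 38, 64, 52, 0.5),
    ("power-wall", 48, 76, 58, 0.5),
    ("cone-frustum", 34, 55, 47, 1.0),
    ("cone-frustum", 40, 64, 52, 1.0),
    ("cone-frustum", 50, 78, 58, 1.0),
]

SYNTHETIC_FILLET_MM = 12.0

#: scene settings for the synthetic validation runs: overhead camera at
#: 450 mm, a 6 mm-wide tape printed every 5 mm (a narrow tape keeps the
#: wrap-around of the tape on the wall small relative to the bowl radius)
SYNTHETIC_SIM_KWARGS = dict(
    camera_height=450.0,
    ruler_width=6.0,
    marker_spacing=5.0,
    flat_label_tol=1.0,
)
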