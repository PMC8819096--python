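"""Literature constants used by the carpal model.

These are the published inputs the pipeline consumes: the ligament spring
stiffness table, wrist range-of-motion, the six experimental SLIL stiffness
samples and the literature stiffness ranges they are compared with.

Note: the "Short radiolunate" row connects Radius-Scaphoid, at odds with its
anatomical name, and the Volar Radioscapholunate row attaches to scaphoid
AND lunate with the same 50.75 N/mm each.  Both are kept as published;
callers may pass an edited table to override.
"""

from __future__ import annotations

# (ligament, connection 1, connection 2, stiffness N/mm)
LIGAMENT_ROWS: list[tuple[str, str, str, float]] = [
    ("Dorsal intercarpal (lunate)", "Capitate", "Lunate", 150.0),
    ("Dorsal intercarpal (scaphoid)", "Capitate", "Scaphoid", 150.0),
    ("Dorsal scapholunate", "Scaphoid", "Lunate", 230.0),
    ("Long radiolunate", "Lunate", "Radius", 75.0),
    ("Radial arcuate", "Capitate", "Scaphoid", 40.0),
    ("Radial collateral carpal", "Radius", "Scaphoid", 10.0),
    ("Radioscaphocapitate", "Radius", "Capitate", 50.0),
    ("Short radiolunate", "Radius", "Scaphoid", 75.0),
    ("Volar Radioscapholunate", "Radius", "Scaphoid+Lunate", 50.75),
]

#: wrist range of motion in degrees (lower, upper); pronation/supination is
#: carried for completeness but never simulated (it does not involve the
#: scapholunate joint).
ROM_DEGREES: dict[str, tuple[float, float]] = {
    "flexion": (65.0, 80.0),
    "extension": (55.0, 75.0),
    "radial": (15.0, 25.0),
    "ulnar": (30.0, 45.0),
    "pronation": (60.0, 80.0),
    "supination": (60.0, 85.0),
}

#: six cadaveric SLIL linear stiffness samples, N/mm
EXPERIMENTAL_SLIL_STIFFNESS: list[float] = [
    111.38, 24.44, 114.12, 35.36, 90.29, 53.44,
]

#: (mean, sample std) as published for the six samples above
EXPERIMENTAL_SUMMARY_PRINTED: tuple[float, float] = (71.50, 39.00)

#: literature SLIL stiffness: name -> point value or (low, high) range, N/mm
LITERATURE_SLIL_STIFFNESS: dict[str, float | tuple[float, float]] = {
    "Nikolopoulos et al.": (25.0, 36.0),
    "Wayne and Tremols": 66.0,
    "Eschweiler et al.": (50.0, 150.0),
}

#: pooled literature (mean, std) as published.  The mean matches the
#: midpoint-of-ranges reading ((30.5 + 66 + 100)/3 = 65.50) but the printed
#: std 34.70 is only approximately recoverable that way (34.75), so the pair
#: is stored as a reference constant and never used as a computed check.
LITERATURE_SUMMARY_PRINTED: tuple[float, float] = (65.50, 34.70)
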