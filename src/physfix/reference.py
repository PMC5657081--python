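"""Benchmark summary statistics from the cadaveric porcine torsion experiment
that the simulator emulates (12 immature right humeri, Salter-Harris I
proximal physeal fracture, three/two/one 3-mm K-wire fixation, +/-2 Nm at
0.5 Hz for 250 cycles under 20 N axial preload).

These numbers serve two roles: they are the default parameter levels of the
synthetic rig, and they are the inputs to the derived-arithmetic helpers
(ratios, percentage changes, implant area) whose outputs the original study
reports.  Values are (mean, SD) per pin group unless noted.
"""

# Torsional stiffness, Nm/degree (materials testing system, terminal slope)
GROUP_STIFFNESS = {"three": (1.18, 0.21), "two": (1.10, 0.23), "one": (1.16, 0.35)}

# Interfragmentary toggle, degrees (gap between terminal-line x-intercepts)
GROUP_TOGGLE = {"three": (4.25, 1.05), "two": (5.08, 1.63), "one": (6.41, 2.05)}

# Gross angular displacement, degrees, from the materials testing system
GROUP_GROSS_MTS = {"three": (6.64, 1.03), "two": (7.81, 1.73), "one": (9.74, 2.36)}

# Gross angular displacement, degrees, from motion-analysis marker tracking
GROUP_GROSS_MOTION = {"three": (2.34, 1.06), "two": (2.75, 1.26), "one": (4.22, 1.79)}

# Mean rotational displacement per epiphyseal marker site, degrees (all groups)
MARKER_ROTATION_MEANS = {"cranial": 2.08, "lateral": 3.12, "caudal": 3.84, "medial": 3.36}

# Machine-reported displacement exceeded marker-derived displacement ~2.6x,
# attributed to slippage at the Wood's-metal mould / epiphysis interface.
MTS_TO_MOTION_RATIO = 2.6

# Implant geometry used for the physeal cross-sectional-area estimate
PIN_DIAMETER_MM = 3.0
PHYSIS_DIAMETER_MM = 30.0
N_SPECIMENS = 12
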