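"""Parameter table for the body-cover vocal-fold model (SI units).

One flat, documented constant set: resting geometry, tissue mechanics,
muscle-rule gains, aerodynamics, and numerical thresholds.  The values
follow the canonical male body-cover configuration; the few free scale
factors (STIFFNESS_SCALE, CONVERGENCE_FACTOR, A_PGO) are calibrated once
so that the modal operating point (a_CT/a_TA on the 134-Hz contour,
a_LC = 0.5, P_s = 800 Pa) produces a male modal voice: baseline f_o near
134 Hz at roughly 75 dB SPL.  They are never tuned per-experiment.

Use :func:`as_dict` / :func:`dump` to serialize the table.
"""

from __future__ import annotations

import json
from typing import Any

# ---------------------------------------------------------------- geometry
L0 = 0.016          # resting membranous fold length [m]
T0 = 0.003          # resting fold thickness [m]
D_MUC = 0.002       # mucosa depth [m]
D_LIG = 0.002       # ligament depth [m]
D_MUS = 0.004       # TA muscle depth [m]

# ------------------------------------------------------------- muscle rules
G_STRAIN = 0.2      # elongation gain
R_TORQUE = 3.0      # CT/TA torque ratio
H_ADDUCT = 0.2      # adductory strain factor
CONVERGENCE_FACTOR = 0.1   # prephonatory convergence: xi01 = xi02 + c*T

# ------------------------------------------------------ tissue fiber stress
# passive model per tissue: linear ramp from EPS1 plus an exponential branch
# sigma_p = -(sigma0/EPS1)(eps-EPS1) + [eps>eps2] sigma2(e^{C(eps-eps2)}-1-C(eps-eps2))
EPS1 = -0.5
SIG0_MUC, EPS2_MUC, SIG2_MUC, C_MUC = 500.0, 0.35, 30000.0, 4.4
SIG0_LIG, EPS2_LIG, SIG2_LIG, C_LIG = 400.0, -0.35, 0.4, 17.0
SIG0_MUS, EPS2_MUS, SIG2_MUS, C_MUS = 1000.0, -0.05, 1500.0, 6.5
SIGMA_ACT_MAX = 105000.0   # maximum active TA stress [Pa]
EPS_ACT_MAX = 0.4          # strain of peak active force
B_ACT = 1.07               # width of the active length-tension parabola

# ------------------------------------------------------------ lumped tissue
RHO_TISSUE = 1040.0        # [kg/m^3]
MODAL_MASS_FACTOR = 0.5    # lumped mass = modal mass of the distributed layer
MU_COVER = 500.0           # cover shear modulus [Pa]
MU_BODY = 4000.0           # body shear modulus [Pa]
KC_SHEAR_FACTOR = 0.5      # cover-cover coupling: kc = f*mu_c*L*Dc/T
ZETA_COVER = 0.08
ZETA_BODY = 0.15
ZETA_COLLISION = 1.0       # added to cover damping ratio during contact
COLLISION_FACTOR = 3.0     # h_i = f*k_i
ETA_K = 1.0e6              # cubic spring coefficient [1/m^2]
ETA_H = 5.0e6              # cubic collision coefficient [1/m^2]

# male modal-voice calibration of the overall stiffness level (see module
# docstring); applied uniformly to k1, k2, kc, kb and collision springs.
STIFFNESS_SCALE = 1.0526

# ------------------------------------------------------------- aerodynamics
RHO_AIR = 1.14             # warm humid air [kg/m^3]
A_PGO = 2.0e-6             # posterior glottal gap area [m^2]

# ----------------------------------------------------------------- analysis
OSC_AREA_THRESHOLD = 1.0e-7   # steady-state peak-to-peak a_g for voicing [m^2]
ONSET_DISCARD_DEFAULT = 0.2   # [s]
Z_V = 45000.0                 # radiation impedance constant [kg/m^4]
P_REF = 2.0e-5                # SPL reference pressure [Pa]
SPL_FS_REF = 44100.0          # sampling rate the SPL derivative is referenced to
# effective depth converting glottal-area rate to the synthesizer flow signal
# (U_syn = K_FLOW * d a_g/dt); with SPL_FS_REF it fixes the absolute SPL
# level and is calibrated once at the modal baseline (Case-B configuration
# at P_s = 800 Pa -> 74 dB SPL)
K_FLOW = 1.8896e-3            # [m]


def as_dict() -> dict[str, Any]:
    """The full parameter table as a flat name -> value mapping."""
    return {k: v for k, v in globals().items()
            if k.isupper() and isinstance(v, (int, float))}


def dump(path: str) -> None:
    """Serialize the parameter table to a JSON file (documented units)."""
    with open(path, "w") as fh:
        json.dump(as_dict(), fh, indent=2, sort_keys=True)
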