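"""Named default configurations for the synthetic study conditions.

The experiment constants emulate a THP-1-style suspension-cell assay: a
~13 um cell (surface area 5.5e-10 m^2) at fractional coverage 0.3 in 1e-9 m^3
of media per cell dosed at u0 = 1e13 particles cell^-1 m^-3, i.e. 1e4
particles available per cell, so the number associated stays small relative
to the dose.  With these constants the three reference scenarios behave as
intended: the low-rate population stays far from capacity over 24 h, the
intermediate-rate population shows both the initial rise and saturation
within the measurement window, and the high-rate population is saturated at
every measured time.  All values are configuration, never hard-coded inside
operations.
"""

from __future__ import annotations

import numpy as np

from .flow import ControlFixtureSpec
from .model import ExperimentConstants, HyperParams

#: default experiment constants (C, S [m^2], V [m^3], u0 [particles/cell/m^3])
DEFAULT_CONSTANTS = ExperimentConstants(C=0.3, S=5.5e-10, V=1.0e-9, u0=1.0e13)

#: hyperparameters of the intermediate-rate parameter-recovery scenario
RECOVERY_HYPERPARAMS = HyperParams(m_r=2.96e-7, s_r=2.92e-6, m_K=51.2, s_K=53.3)

#: the three reference particle-cell scenarios (low / intermediate / high
#: association rate relative to capacity); the K distribution is shared
SCENARIO_HYPERPARAMS = {
    "low": HyperParams(m_r=3.86e-8, s_r=4.57e-8, m_K=10.0, s_K=2.0),
    "intermediate": HyperParams(m_r=3.86e-7, s_r=4.57e-7, m_K=10.0, s_K=2.0),
    "high": HyperParams(m_r=3.86e-5, s_r=4.57e-5, m_K=10.0, s_K=2.0),
}

#: standard measurement times [h] used by the reference experiments
STANDARD_TIMES = (1.0, 2.0, 4.0, 8.0, 16.0, 24.0)

#: candidate measurement times for the design search: 0.5 h, 1 h, then every
#: 2 h from 2 h to 24 h (14 values, giving C(14, 6) = 3003 designs)
DESIGN_CANDIDATES = (0.5, 1.0) + tuple(float(t) for t in range(2, 25, 2))

#: named fixture designs
NAMED_DESIGNS = {
    "expr": STANDARD_TIMES,
    "early": (0.5, 1.0, 2.0, 4.0, 6.0, 8.0),
    "middle": (6.0, 8.0, 10.0, 12.0, 14.0, 16.0),
    "late": (14.0, 16.0, 18.0, 20.0, 22.0, 24.0),
    "uniform": (0.5, 4.0, 8.0, 12.0, 18.0, 24.0),
}

#: default uniform prior bounds in natural units, wide enough to bracket all
#: reference-scenario hyperparameter values
DEFAULT_PRIOR_BOUNDS = {
    "m_r": (1e-9, 1e-4),
    "s_r": (1e-9, 1e-4),
    "m_K": (1.0, 500.0),
    "s_K": (0.1, 500.0),
}

#: default synthetic control fixture
DEFAULT_CONTROL_SPEC = ControlFixtureSpec()
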