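"""Synthetic outcome tables with known logistic + seasonal structure.

Generates replicate-level establishment outcomes whose true data-generating
process is a logistic model in propagule size, propagule number and site,
plus an optional sinusoidal timing-of-introduction effect entering through
the intercept on the logit scale:

    logit p = β₀ + β_PS·PS + β_SE·[SE=site2] + β_PS×SE·PS·[SE=site2]
              + β_PN2·[PN=2] + β_PN3·[PN=3] + A·cos(2π(d − φ)/365)

Every statistical stage of the pipeline is therefore testable against known
truth without running the simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .scenarios import PS_RANGE, PN_RANGE, INTRO_DAY_RANGE, SITES


@dataclass
class TruthParams:
    """True coefficients of the generating logistic model (logit scale)."""

    beta0: float = -2.0
    beta_ps: float = 0.25
    beta_se: float = -1.0       # site2 offset
    beta_ps_se: float = 0.0     # PS × site2 interaction
    beta_pn2: float = 0.0
    beta_pn3: float = 0.0
    amplitude: float = 0.0      # seasonal amplitude A (logit scale)
    phase_day: float = 45.0     # day of year of the seasonal peak φ

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 1 <= self.phase_day <= 365:
            raise ValueError("phase_day must lie in [1, 365]")

    def seasonal(self, intro_day) -> np.ndarray:
        d = np.asarray(intro_day, dtype=float)
        return self.amplitude * np.cos(2 * np.pi * (d - self.phase_day) / 365.0)

    def linpred(self, ps, pn, site2, intro_day) -> np.ndarray:
        ps = np.asarray(ps, dtype=float)
        pn = np.asarray(pn)
        site2 = np.asarray(site2, dtype=float)
        return (self.beta0 + self.beta_ps * ps + self.beta_se * site2
                + self.beta_ps_se * ps * site2
                + self.beta_pn2 * (pn == 2) + self.beta_pn3 * (pn == 3)
                + self.seasonal(intro_day))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def generate_outcomes(truth: TruthParams, n: int, seed) -> pd.DataFrame:
    """Sample an OutcomeTable of ``n`` rows under the truth model.

    Predictors follow the scenario design's marginals: PS uniform on [2, 20],
    PN uniform on {1, 2, 3}, SE uniform over the two sites, introduction day
    uniform on [1, 730]; outcomes are Bernoulli(inverse-logit(linear
    predictor)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ps = rng.integers(PS_RANGE[0], PS_RANGE[1] + 1, size=n)
    pn = rng.integers(PN_RANGE[0], PN_RANGE[1] + 1, size=n)
    se = rng.integers(0, 2, size=n)
    intro_day = rng.integers(INTRO_DAY_RANGE[0], INTRO_DAY_RANGE[1] + 1, size=n)
    eta = truth.linpred(ps, pn, se, intro_day)
    p = 1.0 / (1.0 + np.exp(-eta))
    established = (rng.random(n) < p).astype(int)
    return pd.DataFrame({
        "PS": ps, "PN": pn,
        "SE": np.asarray(SITES)[se],
        "intro_day": intro_day,
        "established": established,
    })
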