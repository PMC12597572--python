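"""Pharmacodynamic models: proportional-odds MOAA/S and sigmoidal BIS.

Both endpoints share one competitive-interaction drug-effect kernel in which
the remimazolam effect-site concentration Ce is the agonist and the
(pharmacologically inactive) metabolite CNS7054 competes via its arterial
concentration Ca.  Rising Ca at constant Ce attenuates the drug effect -- the
model's account of apparent tolerance.  With Ce = 0 the kernel is exactly 0
regardless of Ca, so the metabolite alone produces no effect.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import BISParams, MOAASParams
from .system import Timecourse

__all__ = [
    "drug_effect_fraction",
    "MOAASDistribution",
    "moaas_probabilities",
    "bis_predict",
    "tolerance_drift",
]


def drug_effect_fraction(ce, ca, ce50: float, ca50: float, gamma: float = 1.0):
    """Competitive Hill kernel ``(Ce/Ce50)^g / (1 + (Ce/Ce50)^g + (Ca/Ca50)^g)``.

    Returns a fraction in [0, 1); vectorised over ``ce`` and ``ca``.
    """
    ce = np.asarray(ce, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if np.any(ce < 0) or np.any(ca < 0):
        raise ValueError("concentrations must be >= 0")
    if ce50 <= 0 or ca50 <= 0 or gamma <= 0:
        raise ValueError("ce50, ca50 and gamma must be > 0")
    x = (ce / ce50) ** gamma
    y = (ca / ca50) ** gamma
    out = x / (1.0 + x + y)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MOAASDistribution:
    """Probabilities over MOAA/S scores 0..5 (last axis of ``probs``)."""

    probs: np.ndarray  # (..., 6)

    def __post_init__(self) -> None:
        if self.probs.shape[-1] != 6:
            raise ValueError("probs must have 6 categories on the last axis")

    @property
    def cumulative(self) -> np.ndarray:
        """P(S <= k) for k = 0..5."""
        return np.cumsum(self.probs, axis=-1)

    @property
    def mean_score(self) -> np.ndarray:
        """Probability-weighted MOAA/S score."""
        out = self.probs @ np.arange(6.0)
        return float(out) if np.ndim(out) == 0 else out

    def p(self, k: int) -> np.ndarray:
        out = self.probs[..., k]
        return float(out) if np.ndim(out) == 0 else out

    def p_leq(self, k: int) -> np.ndarray:
        out = self.cumulative[..., k]
        return float(out) if np.ndim(out) == 0 else out


def moaas_probabilities(
    ce, ca, params: MOAASParams, opioids: bool = False
) -> MOAASDistribution:
    """Full MOAA/S score distribution at effect-site/metabolite concentrations.

    The drug effect enters only the score-0 logit,
    ``l(S=0) = b0 + DEFF * f(Ce, Ca)``, and propagates to all cumulative
    logits through the additive cut-point chain.  With opioids present the
    (b0, d01) pair is replaced by the opioid-adjusted pair, which leaves
    P(S<=1) unchanged and moves probability from score 1 to score 0.
    """
    f = drug_effect_fraction(ce, ca, params.ce50, params.ca50, params.gamma)
    f = np.asarray(f, dtype=float)
    b0 = params.b0_op if opioids else params.b0
    d01 = params.d01_op if opioids else params.d01
    l0 = b0 + params.deff * f
    offsets = np.cumsum([0.0, d01, params.d12, params.d23, params.d34])
    logits = l0[..., None] + offsets  # cumulative logits for S<=0..S<=4
    cum = expit(logits)
    probs = np.empty(f.shape + (6,))
    probs[..., 0] = cum[..., 0]
    probs[..., 1:5] = np.diff(cum, axis=-1)
    probs[..., 5] = 1.0 - cum[..., 4]
    return MOAASDistribution(probs=probs)


def bis_predict(ce, ca, params: BISParams):
    """Noise-free BIS prediction ``baseline * (1 - f(Ce, Ca))``."""
    f = drug_effect_fraction(ce, ca, params.ce50, params.ca50, params.gamma)
    out = params.baseline * (1.0 - np.asarray(f))
    return float(out) if np.ndim(out) == 0 else out


def tolerance_drift(
    tc: Timecourse,
    moaas: MOAASParams,
    bis: BISParams,
    opioids: bool = False,
) -> pd.DataFrame:
    """Evaluate both PD models along a simulated timecourse.

    Uses the MOAA/S and BIS effect-site concentrations as agonist inputs and
    the arterial metabolite concentration as the competing species.  At
    constant Ce, accumulating metabolite drives predicted BIS and the
    probability-weighted MOAA/S score upward over time (apparent tolerance).
    Returns a frame with columns TIME, P0..P5, EWS, BIS.
    """
    dist = moaas_probabilities(tc.ce_moaas, tc.ca_metab, moaas, opioids=opioids)
    bis_vals = bis_predict(tc.ce_bis, tc.ca_metab, bis)
    out = pd.DataFrame({"TIME": tc.time})
    for k in range(6):
        out[f"P{k}"] = dist.probs[..., k]
    out["EWS"] = dist.mean_score
    out["BIS"] = bis_vals
    return out
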