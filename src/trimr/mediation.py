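"""Product-of-coefficients mediation over exposure -> mediator -> outcome triangles.

When a mediator (here, a gut-microbial taxon) is causally downstream of the
exposure and causally upstream of the outcome, the mediated effect is

    beta_i = beta1 * beta2 / beta_total

where beta1 is the exposure->mediator effect, beta2 the mediator->outcome
effect and beta_total the total exposure->outcome effect, all on the
log-odds (beta) scale.  A mediation pathway is only coherent when the sign
of the mediated path beta1*beta2 matches the sign of the total effect;
the ``consistent`` flag codifies that check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MediationResult:
    beta1: float
    beta2: float
    beta_total: float
    beta_i: float
    qualifies: bool
    consistent: bool


def mediation_effect(beta1: float, beta2: float, beta_total: float,
                     qualifies: bool = True) -> MediationResult:
    """Mediated proportion beta1*beta2/beta_total with the sign-coherence flag."""
    if beta_total == 0:
        raise ValueError("total effect zero: mediated proportion undefined")
    beta_i = beta1 * beta2 / beta_total
    consistent = np.sign(beta1 * beta2) == np.sign(beta_total)
    return MediationResult(beta1=float(beta1), beta2=float(beta2),
                           beta_total=float(beta_total), beta_i=float(beta_i),
                           qualifies=qualifies, consistent=bool(consistent))


def find_mediation_candidates(leg1: pd.DataFrame, leg2: pd.DataFrame,
                              alpha: float = 0.05,
                              id_col: str = "mediator",
                              p_col: str = "pval") -> list[str]:
    """Mediators nominally significant (p < alpha) in both MR legs.

    ``leg1`` holds exposure->mediator results, ``leg2`` mediator->outcome
    results; tables share the mediator identifier column.
    """
    sig1 = set(leg1.loc[leg1[p_col] < alpha, id_col])
    sig2 = set(leg2.loc[leg2[p_col] < alpha, id_col])
    both = sig1 & sig2
    # preserve leg1 row order for determinism
    return [m for m in leg1[id_col] if m in both]
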