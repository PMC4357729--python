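"""Per-protein exact enrichment test of NSC pull-downs against the negative control.

Each protein is scored by a one-sided exact test of the hypothesis that its
spectral-count rate in the two NSC purifications exceeds the rate in the
negative-control purification; a missing count is 0.  Proteins with
p < alpha (default 0.1) are the enriched set, and the enriched proteins
seen in both NSC samples feed the differential-abundance stage.

Two test variants are provided:

``conditional-binomial`` (default)
    The standard uniformly-most-powerful-unbiased exact comparison of
    Poisson rates.  Under equal per-sample rates, conditional on the
    total t = c + s_d + s_p over one control and two NSC samples, the
    control count follows Binomial(t, 1/3); the one-sided p-value is
    P(X <= c).  Uses both NSC counts without rounding and needs no
    pseudocount.

``poisson-tail``
    A literal Poisson-tail reading: p = P(Y >= round(m)) where
    m = (s_d + s_p)/2 is the mean NSC count and Y ~ Poisson(max(c, pc))
    with a pseudocount pc for the c = 0 case (a rate of exactly zero
    would make any observation infinitely significant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .iotables import CANONICAL_SAMPLES, CountMatrix, StateError

METHODS = ("conditional-binomial", "poisson-tail")


@dataclass(frozen=True)
class EnrichmentConfig:
    """Settings for the control-vs-NSC enrichment test.

    alpha_enrich: strict significance threshold ("below 0.1").
    method: "conditional-binomial" or "poisson-tail".
    pseudocount: control rate floor, used only by poisson-tail when c = 0.
    """

    alpha_enrich: float = 0.1
    method: str = "conditional-binomial"
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha_enrich < 1:
            raise ValueError("alpha_enrich must be in (0, 1)")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")


def enrichment_pvalue(c: int, s_d: int, s_p: int,
                      cfg: EnrichmentConfig = EnrichmentConfig()) -> float:
    """One-sided p-value for "NSC rate > control rate" from raw counts.

    Parameters are the merged spectral counts of the negative control (c),
    the differentiating sample (s_d) and the proliferating sample (s_p);
    counts absent upstream must already be imputed to 0.  All-zero input
    carries no evidence and returns 1.
    """
    if min(c, s_d, s_p) < 0:
        raise ValueError("counts must be nonnegative")
    if cfg.method == "conditional-binomial":
        t = c + s_d + s_p
        if t == 0:
            return 1.0
        return float(stats.binom.cdf(c, t, 1.0 / 3.0))
    # poisson-tail: P(Y >= round(m)) under the control rate
    m = (s_d + s_p) / 2.0
    k = math.floor(m + 0.5)  # round half up
    rate = c if c > 0 else cfg.pseudocount
    if rate == 0:
        return 0.0 if k > 0 else 1.0
    return float(stats.poisson.sf(k - 1, rate))


def enrichment_filter(cm: CountMatrix,
                      cfg: EnrichmentConfig = EnrichmentConfig()) -> pd.DataFrame:
    """Score every protein in a merged count matrix against the control.

    Returns one row per protein with columns protein_id, control,
    differentiating, proliferating, pvalue, enriched, in_both.  The
    ``enriched & in_both`` subset is the input to the differential stage.
    """
    if not cm.merged:
        raise StateError("enrichment_filter requires a fraction-merged matrix")
    missing = [s for s in CANONICAL_SAMPLES if s not in cm.samples]
    if missing:
        raise ValueError(f"count matrix lacks canonical sample(s): {', '.join(missing)}")
    ctrl = cm.counts("control")
    diff = cm.counts("differentiating")
    prol = cm.counts("proliferating")
    rows = []
    for prot in cm.proteins:
        c, s_d, s_p = int(ctrl[prot]), int(diff[prot]), int(prol[prot])
        p = enrichment_pvalue(c, s_d, s_p, cfg)
        rows.append({
            "protein_id": prot,
            "control": c,
            "differentiating": s_d,
            "proliferating": s_p,
            "pvalue": p,
            "enriched": p < cfg.alpha_enrich,
            "in_both": (s_d > 0) and (s_p > 0),
        })
    return pd.DataFrame(rows, columns=[
        "protein_id", "control", "differentiating", "proliferating",
        "pvalue", "enriched", "in_both",
    ])
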