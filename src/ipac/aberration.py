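"""Gain/loss calling from PCF values and selection of commonly aberrant genes.

A gene is called gained in a sample when its PCF value exceeds +tau and lost
when it falls below -tau (strict inequalities).  Commonly aberrant genes are
those whose aberration frequency exceeds a minimum (default 10%) *and* whose
gain/loss counts are significantly skewed toward one direction by an exact
binomial sign test: with G gains and L losses out of m = G + L aberrations,
gains modelled as X ~ Binomial(m, 1/2) and D = G - L = 2X - m, the gene is
commonly gained when D >= c and commonly lost when -D >= c, where c is the
least integer such that P(|D| >= c) <= alpha for every m up to the largest
aberration count observed at any gene.  By construction a gene is never both
commonly gained and commonly lost.  No multiple-testing correction is applied
at this step; it is a deliberately mild filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ipac.aberration")


@dataclass
class AberrationCalls:
    """Ternary gain/loss calls (genes x samples) at threshold tau."""

    calls: pd.DataFrame   # entries in {-1, 0, +1}
    tau: float

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def counts(self) -> pd.DataFrame:
        """Per-gene gain count G, loss count L, m = G + L and D = G - L."""
        arr = self.calls.to_numpy()
        gains = (arr == 1).sum(axis=1)
        losses = (arr == -1).sum(axis=1)
        return pd.DataFrame({"n_gain": gains, "n_loss": losses,
                             "m": gains + losses, "D": gains - losses},
                            index=self.calls.index)


def call_aberrations(gene_cn: pd.DataFrame, tau: float) -> AberrationCalls:
    """Call gains (+1) / losses (-1) from a genes x samples PCF-value matrix.

    Strict inequalities: a value exactly at +/-tau is called neutral.
    Missing values are neutral (no evidence of aberration).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    arr = gene_cn.to_numpy()
    calls = np.zeros(arr.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        calls[arr > tau] = 1
        calls[arr < -tau] = -1
    return AberrationCalls(calls=pd.DataFrame(calls, index=gene_cn.index,
                                              columns=gene_cn.columns), tau=tau)


def _tail_prob(m: int, c: int) -> float:
    """P(|2X - m| >= c) for X ~ Binomial(m, 1/2), by exact tail sums."""
    if c <= 0:
        return 1.0
    # |2x - m| >= c  <=>  x >= (m + c)/2 or x <= (m - c)/2
    hi = int(np.ceil((m + c) / 2.0))
    lo = int(np.floor((m - c) / 2.0))
    p = 0.0
    if hi <= m:
        p += float(stats.binom.sf(hi - 1, m, 0.5))
    if lo >= 0:
        p += float(stats.binom.cdf(lo, m, 0.5))
    return min(p, 1.0)


def sign_test_threshold(m_max: int, alpha: float) -> int:
    """Least integer c >= 1 with P(|2X - m| >= c) <= alpha for all m <= m_max.

    Exact binomial tail sums, no normal approximation.  The returned c can
    exceed m_max, in which case no gene with so few aberrations can ever be
    called skewed (the test is then vacuous — this happens for small cohorts).
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    c = 1
    while True:
        if all(_tail_prob(m, c) <= alpha for m in range(1, m_max + 1)):
            return c
        c += 1


def select_common_aberrant(calls: AberrationCalls, freq_min: float, c: int,
                           use_freq_filter: bool = True,
                           use_sign_test: bool = True) -> pd.DataFrame:
    """Flag commonly gained / lost genes.

    frequency = (G + L) / n_samples must strictly exceed ``freq_min``, and the
    skew D = G - L must reach the sign-test threshold: D >= c for gained,
    -D >= c for lost.  Both filters are applied conjunctively by default;
    either can be disabled.
    """
    if not 0 <= freq_min < 1:
        raise ValueError("freq_min must be in [0, 1)")
    if c < 1:
        raise ValueError("c must be >= 1")
    tab = calls.counts()
    n = calls.n_samples
    tab["frequency"] = (tab["n_gain"] + tab["n_loss"]) / n
    direction = np.where(tab["D"] >= c, "gained",
                         np.where(-tab["D"] >= c, "lost", "none"))
    tab["direction"] = direction
    freq_ok = (tab["frequency"] > freq_min) if use_freq_filter else True
    skew_ok = (tab["direction"] != "none") if use_sign_test else True
    tab["commonly_aberrant"] = np.asarray(freq_ok) & np.asarray(skew_ok)
    n_g = int(((tab["direction"] == "gained") & tab["commonly_aberrant"]).sum())
    n_l = int(((tab["direction"] == "lost") & tab["commonly_aberrant"]).sum())
    logger.info("commonly aberrant: %d genes (%d gained, %d lost) of %d",
                int(tab["commonly_aberrant"].sum()), n_g, n_l, len(tab))
    return tab
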