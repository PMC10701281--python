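"""Orthogonal-validation statistics.

Covers the arithmetic used to judge array-derived peptide picks against
independent assays: hypergeometric/binomial enrichment of validated
peptides among random draws, a sweep over assumed positive fractions, a
pooled two-proportion z-test, intraclass correlation from a crossed
random-effects fit with reliability bands, simple r-squared, and
ELISA positivity / validation calling (replicates averaged, OD >= 2,
validated when >= 25% of the sample group is positive).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger("episcope")

ICC_BANDS = (
    (0.5, "poor"),
    (0.75, "moderate"),
    (0.9, "good"),
    (1.0 + 1e-12, "excellent"),
)

OD_POSITIVE_THRESHOLD = 2.0
VALIDATION_FRACTION = 0.25


@dataclass(frozen=True)
class EnrichmentResult:
    N_pool: int
    K_pos: int
    n_draws: int
    x_min: int
    p_hypergeom: float
    p_binomial: float


def prob_at_least_hypergeometric(x: int, n: int, K: int, N: int) -> float:
    """P(X >= x) drawing n without replacement from N with K positives."""
    if x > n:
        raise ValueError("x cannot exceed the number of draws")
    if K > N:
        raise ValueError("K cannot exceed the pool size")
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def prob_at_least_binomial(x: int, n: int, p: float) -> float:
    """P(X >= x) for Binomial(n, p) — sampling with replacement."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if x <= 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, p))


def enrichment(x: int, n: int, K: int, N: int) -> EnrichmentResult:
    return EnrichmentResult(
        N_pool=N,
        K_pos=K,
        n_draws=n,
        x_min=x,
        p_hypergeom=prob_at_least_hypergeometric(x, n, K, N),
        p_binomial=prob_at_least_binomial(x, n, K / N),
    )


def fraction_sweep(
    fractions: Sequence[float], x: int, n: int, N: int
) -> pd.DataFrame:
    """Enrichment p-values over assumed positive fractions of the pool.

    The true count of reactive peptides in the pool is unknown; each
    row assumes ``K = round(fraction * N)`` positives and reports both
    tail probabilities.
    """
    rows = []
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError("fractions must be in (0, 1)")
        K = int(round(f * N))
        res = enrichment(x, n, K, N)
        rows.append(
            {
                "fraction": f,
                "K": K,
                "p_hypergeom": res.p_hypergeom,
                "p_binomial": res.p_binomial,
            }
        )
    return pd.DataFrame(rows)


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> tuple[float, float]:
    """Pooled two-sample proportion z-test (two-sided).

    ``z = (p2 - p1) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2))`` with the
    pooled ``p_hat = (k1 + k2) / (n1 + n2)``; optional Yates continuity
    correction.  Returns ``(z, p_two_sided)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    diff = p2 - p1
    if continuity:
        cc = 0.5 * (1 / n1 + 1 / n2)
        diff = np.sign(diff) * max(abs(diff) - cc, 0.0)
    z = diff / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def icc_band(icc: float) -> str:
    """Reliability band: poor [0,.5), moderate [.5,.75), good [.75,.9),
    excellent [.9,1]."""
    for upper, band in ICC_BANDS:
        if icc < upper:
            return band
    return "excellent"


def icc_from_variance_components(
    data: pd.DataFrame,
    reading: str,
    target: str = "instrument",
    random: Sequence[str] = ("instrument", "sample"),
    fixed: Sequence[str] = (),
) -> tuple[float, str, pd.Series]:
    """ICC of ``target`` from a crossed random-intercept fit.

    Readings (log-transformed upstream) are modelled with random
    intercepts for each factor in ``random`` (e.g. instrument and
    sample) and the given fixed effects; the ICC is the target factor's
    variance share: sigma^2_target / (sum of all random components +
    residual).  Returns ``(icc, reliability band, variance components)``
    with the residual included under ``"residual"``.
    """
    for col in (reading, target, *random, *fixed):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    if target not in random:
        raise ValueError("target must be one of the random factors")
    for factor in random:
        if data[factor].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {factor!r}")
    df = data.copy()
    df["_all"] = 1
    fixed_rhs = " + ".join([f"C({f})" for f in fixed]) or "1"
    vc = {f: f"0 + C({f})" for f in random}
    model = sm.MixedLM.from_formula(
        f"{reading} ~ {fixed_rhs}",
        groups="_all",
        vc_formula=vc,
        re_formula="0",
        data=df,
    )
    with np.errstate(all="ignore"):
        fit = model.fit(reml=True)
    if not np.isfinite(fit.params).all():
        raise RuntimeError(
            f"variance-components fit did not converge: {fit.summary()}"
        )
    comps = pd.Series(
        dict(zip(model.exog_vc.names, np.maximum(fit.vcomp, 0.0)))
    )
    if (fit.vcomp < 0).any():
        logger.info("negative variance estimates truncated at zero")
    comps["residual"] = float(fit.scale)
    icc = comps[target] / comps.sum()
    return float(icc), icc_band(float(icc)), comps


def simple_r2(x, y) -> float:
    """Squared Pearson correlation of y with its least-squares fit on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def average_elisa_replicates(
    od: pd.DataFrame, replicate_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Average replicate wells to one column per serum.

    By default replicate columns are recognized by a ``.r<No>`` suffix
    (``B2_immune.r1`` and ``B2_immune.r2`` average to ``B2_immune``);
    pass ``replicate_map`` (column -> serum id) to override.
    """
    if replicate_map is None:
        replicate_map = {
            c: re.sub(r"\.r\d+$", "", str(c)) for c in od.columns
        }
    groups = pd.Index([replicate_map[c] for c in od.columns], name="serum")
    return od.T.groupby(groups).mean().T


def elisa_call_positives(
    od: pd.DataFrame,
    sample_groups: Mapping[str, Sequence[str]],
    threshold: float = OD_POSITIVE_THRESHOLD,
    validation_fraction: float = VALIDATION_FRACTION,
    replicate_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-peptide ELISA positivity and validation calls.

    Replicates are averaged first; a serum is positive for a peptide
    when its averaged OD is at or above ``threshold`` (inclusive), and
    a peptide is validated within a sample group when the positive
    fraction reaches ``validation_fraction``.  One output row per
    (peptide, group).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    averaged = average_elisa_replicates(od, replicate_map)
    rows = []
    for group, sera in sample_groups.items():
        missing = [s for s in sera if s not in averaged.columns]
        if missing:
            raise KeyError(f"unknown serum in group {group!r}: {missing[0]!r}")
        sub = averaged[list(sera)]
        positive = sub >= threshold
        n_pos = positive.sum(axis=1)
        frac = n_pos / len(sera)
        for pep in averaged.index:
            rows.append(
                {
                    "peptide": pep,
                    "group": group,
                    "n_positive": int(n_pos[pep]),
                    "n_samples": len(sera),
                    "fraction": float(frac[pep]),
                    "validated": bool(frac[pep] >= validation_fraction),
                }
            )
    return pd.DataFrame(rows)
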