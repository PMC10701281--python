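"""Scoring fitted results against a simulated ground truth.

Used for parameter-recovery checks: a spiked truth epitope counts as
recovered when some fitted region on the same protein overlaps its
interval (Jaccard >= 0.5) and is called at the requested tier by a
serum of one of the spiked mice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calling
from .concordance import _jaccard
from .model import HeronResults
from .simulate import GroundTruthManifest, SpikedRegion


@dataclass
class RecoveryReport:
    n_regions: int
    n_recovered: int
    n_shared: int
    n_shared_k_exact: int

    @property
    def recovered_fraction(self) -> float:
        return self.n_recovered / self.n_regions if self.n_regions else np.nan

    @property
    def k_exact_fraction(self) -> float:
        return (
            self.n_shared_k_exact / self.n_shared if self.n_shared else np.nan
        )


def find_recovered_region(
    results: HeronResults,
    truth_region: SpikedRegion,
    tier: str = "moderate",
    min_jaccard: float = 0.5,
):
    """First fitted region recovering a truth epitope, or ``None``."""
    model = results.model
    for region in results.epitopes:
        if region.accession != truth_region.accession:
            continue
        hit = any(
            region.called[s]
            and calling.tier_at_least([region.tier[s]], tier).any()
            and model.sample_to_mouse[s] in truth_region.mice
            for s in model.immune_samples
        )
        if hit and _jaccard(
            region.interval, (truth_region.aa_start, truth_region.aa_end)
        ) >= min_jaccard:
            return region
    return None


def recovery_report(
    results: HeronResults,
    truth: GroundTruthManifest,
    tier: str = "moderate",
    min_jaccard: float = 0.5,
) -> RecoveryReport:
    """Score strong truth regions and shared-region K agreement."""
    targets = truth.strong_regions
    recovered = 0
    shared_exact = 0
    for region in targets:
        hit = find_recovered_region(results, region, tier, min_jaccard)
        if hit is not None:
            recovered += 1
            if region.shared and hit.k_of_n[0] == region.intended_k:
                shared_exact += 1
    return RecoveryReport(
        n_regions=len(targets),
        n_recovered=recovered,
        n_shared=len(truth.shared_regions),
        n_shared_k_exact=shared_exact,
    )


def pooled_concordance(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool count columns of several concordance tables and recompute
    the directional percentages."""
    allt = pd.concat(tables, ignore_index=True)
    g = (
        allt.groupby(["level", "tier"], observed=True)[
            ["n_only_A", "n_only_B", "n_both"]
        ]
        .sum()
        .reset_index()
    )
    g["pct_B_in_A"] = 100 * g.n_both / (g.n_both + g.n_only_B)
    g["pct_A_in_B"] = 100 * g.n_both / (g.n_both + g.n_only_A)
    return g


def no_significant_decrease(
    n_both_lo: int, n_total_lo: int, n_both_hi: int, n_total_hi: int,
    alpha: float = 0.01,
) -> bool:
    """True unless the higher stratum's concordance is significantly
    below the lower stratum's (one-sided pooled two-proportion test)."""
    from .validation import two_proportion_test

    if n_total_lo == 0 or n_total_hi == 0:
        return True
    z, _ = two_proportion_test(n_both_lo, n_total_lo, n_both_hi, n_total_hi)
    # z < 0 means the higher stratum is less concordant
    from scipy import stats

    p_one_sided = stats.norm.cdf(z)
    return p_one_sided > alpha
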