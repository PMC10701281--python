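"""Replicate-concordance analysis.

When the same serum is assayed on two chips, the fraction of items
(probes, epitopes or proteins) called in one assay that are also called
in the other measures reproducibility.  Concordance is reported
directionally (fraction of B's calls co-recognized in A, and the
converse) per signal tier; epitopes match by interval overlap
(Jaccard >= 0.5) rather than exact coordinates, proteins by accession.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import calling
from .model import HeronResults

LEVELS = ("probe", "epitope", "protein")


@dataclass
class ConcordanceReport:
    level: str
    tier: str
    n_only_a: int
    n_only_b: int
    n_both: int
    pct_b_in_a: float  # fraction of B's calls co-recognized in A, percent
    pct_a_in_b: float

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "tier": self.tier,
            "n_only_A": self.n_only_a,
            "n_only_B": self.n_only_b,
            "n_both": self.n_both,
            "pct_B_in_A": self.pct_b_in_a,
            "pct_A_in_B": self.pct_a_in_b,
        }


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    inter = max(0, hi - lo + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0


def match_intervals(
    a: Sequence[tuple[str, int, int]],
    b: Sequence[tuple[str, int, int]],
    min_jaccard: float = 0.5,
) -> tuple[int, int, int]:
    """Count (only_a, only_b, both) matching ``(accession, start, end)``
    intervals across two call sets by Jaccard overlap."""
    matched_b: set[int] = set()
    both = 0
    for acc_a, s_a, e_a in a:
        hit = None
        for j, (acc_b, s_b, e_b) in enumerate(b):
            if j in matched_b or acc_b != acc_a:
                continue
            if _jaccard((s_a, e_a), (s_b, e_b)) >= min_jaccard:
                hit = j
                break
        if hit is not None:
            matched_b.add(hit)
            both += 1
    return len(a) - both, len(b) - both, both


def replicate_concordance(
    calls_a,
    calls_b,
    level: str = "probe",
    tier: str = "inclusive",
    universe: Iterable | None = None,
    min_jaccard: float = 0.5,
) -> ConcordanceReport:
    """Directional co-recognition between two call sets of one serum.

    ``calls_a``/``calls_b`` are sets of item ids for probes/proteins, or
    sequences of ``(accession, start, end)`` intervals for epitopes.
    ``universe`` (optional, id-based levels only) checks both call sets
    come from the same item universe.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if level == "epitope":
        only_a, only_b, both = match_intervals(
            list(calls_a), list(calls_b), min_jaccard
        )
    else:
        a, b = set(calls_a), set(calls_b)
        if universe is not None:
            uni = set(universe)
            stray = (a | b) - uni
            if stray:
                raise ValueError(
                    f"calls outside the shared item universe: "
                    f"{sorted(stray)[:3]}"
                )
        both = len(a & b)
        only_a, only_b = len(a - b), len(b - a)
    pct_b_in_a = 100.0 * both / (both + only_b) if both + only_b else np.nan
    pct_a_in_b = 100.0 * both / (both + only_a) if both + only_a else np.nan
    return ConcordanceReport(
        level, tier, only_a, only_b, both, pct_b_in_a, pct_a_in_b
    )


def _probe_set(results: HeronResults, sample: str, tier: str, mode: str):
    # replicate scatter compares per-chip probe values before positional
    # smoothing, as chip-vs-chip probe reproducibility is measured
    z = (
        results.normalized[sample].to_numpy() - results.pool_mean
    ) / results.pool_sd
    cut = results.model.thresholds.sd_cutoff(tier)
    keep = z > cut
    if mode == "sd+fdr":
        keep = keep & results.called[sample].to_numpy()
    return set(results.normalized.index[keep])


def concordance_table(
    results: HeronResults,
    sample_a: str,
    sample_b: str,
    mode: str = "sd",
) -> pd.DataFrame:
    """Per-level, per-tier replicate concordance from fitted results.

    ``mode="sd"`` defines probe membership by signal tier alone (as in
    replicate scatter plots); ``mode="sd+fdr"`` additionally requires
    the FDR call.  Epitope and protein membership always combine the
    FDR call with the tier.
    """
    for s in (sample_a, sample_b):
        if s not in results.model.immune_samples:
            raise KeyError(f"{s!r} is not an immune sample of this fit")
    reports = []
    for tier in ("inclusive", "moderate", "restrictive"):
        a = _probe_set(results, sample_a, tier, mode)
        b = _probe_set(results, sample_b, tier, mode)
        reports.append(
            replicate_concordance(a, b, "probe", tier).as_dict()
        )
        epi_a = [
            (r.accession, *r.interval)
            for r in results.epitopes
            if r.called[sample_a]
            and calling.tier_at_least([r.tier[sample_a]], tier).any()
        ]
        epi_b = [
            (r.accession, *r.interval)
            for r in results.epitopes
            if r.called[sample_b]
            and calling.tier_at_least([r.tier[sample_b]], tier).any()
        ]
        reports.append(
            replicate_concordance(epi_a, epi_b, "epitope", tier).as_dict()
        )
        prot = results.proteins
        if prot.empty:
            pa, pb = set(), set()
        else:
            pa = set(
                prot.accession[
                    calling.tier_at_least(
                        prot[f"tier_{sample_a}"].to_numpy(), tier
                    )
                ]
            )
            pb = set(
                prot.accession[
                    calling.tier_at_least(
                        prot[f"tier_{sample_b}"].to_numpy(), tier
                    )
                ]
            )
        reports.append(
            replicate_concordance(pa, pb, "protein", tier).as_dict()
        )
    return pd.DataFrame(reports)


def scatter_export(
    results: HeronResults, sample_a: str, sample_b: str, tier: str = "inclusive"
) -> pd.DataFrame:
    """Per-probe signal pairs with co-recognition status for plotting."""
    a = _probe_set(results, sample_a, tier, "sd")
    b = _probe_set(results, sample_b, tier, "sd")
    status = []
    for occ in results.normalized.index:
        in_a, in_b = occ in a, occ in b
        status.append(
            "both" if in_a and in_b
            else "onlyA" if in_a
            else "onlyB" if in_b
            else "neither"
        )
    return pd.DataFrame(
        {
            "item": results.normalized.index,
            "signal_A": results.normalized[sample_a].to_numpy(),
            "signal_B": results.normalized[sample_b].to_numpy(),
            "status": status,
        }
    )
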