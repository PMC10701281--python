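"""Hierarchical antibody-binding call statistics.

Per immune sample, each probe gets a one-sided *global* z-test p-value
against the pooled mean/SD of the entire processed matrix and a
one-sided *differential* t-test p-value against the naive samples.  The
two are combined with Wilkinson's maximum method (p_max^2), adjusted by
Benjamini-Hochberg within each immune sample, and thresholded at an FDR
cutoff; singleton calls with no called neighbour and no replicate
support are removed.  Called probes are segmented into epitope regions
by recursive minimum-spanning-tree edge removal on the probe grid
(SKATER on a path graph), each region receives an order-statistic
(Beta) meta p-value from its second-highest member p, and proteins are
summarized with Tippett's (Wilkinson's minimum) method.

Antibody binding only elevates signal, hence all tests are upper-tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .arrays import PROBE_LENGTH

TIER_ORDER = ("none", "inclusive", "moderate", "restrictive")


@dataclass(frozen=True)
class CategoryThresholds:
    """Signal-strength tiers (pooled SDs above the pooled mean) and FDR.

    Tiers are nested: restrictive (>10 SD) within moderate (>6 SD)
    within inclusive (>3 SD); comparisons are strict.  Calls require
    FDR q <= ``fdr_cutoff``.
    """

    inclusive_sd: float = 3.0
    moderate_sd: float = 6.0
    restrictive_sd: float = 10.0
    fdr_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.inclusive_sd < self.moderate_sd < self.restrictive_sd):
            raise ValueError("tier cutoffs must satisfy 0 < incl < mod < restr")
        if not (0 < self.fdr_cutoff < 1):
            raise ValueError("fdr_cutoff must be in (0, 1)")

    def sd_cutoff(self, tier: str) -> float:
        return {
            "inclusive": self.inclusive_sd,
            "moderate": self.moderate_sd,
            "restrictive": self.restrictive_sd,
        }[tier]


def pooled_stats(matrix: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Mean and SD over the entire processed matrix (all samples x probes)."""
    values = np.asarray(matrix, dtype=float)
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate matrix: pooled SD is zero")
    return float(values.mean()), sd


def global_pvalue(signal, pool_mean: float, pool_sd: float):
    """Upper-tail z-test p of a probe signal against the pooled stats."""
    if pool_sd <= 0:
        raise ValueError("pool_sd must be positive")
    return stats.norm.sf((np.asarray(signal, dtype=float) - pool_mean) / pool_sd)


def differential_pvalue(
    immune_signal,
    naive_signals,
    var_floor: float = 0.01,
):
    """Upper-tail one-observation-vs-group t-test p-value.

    ``t = (x - mean_naive) / (sd_naive * sqrt(1 + 1/n))`` with
    ``df = n - 1``; a variance floor (in log2 units) guards degenerate
    naive SDs.  ``naive_signals`` may be 1-D (one probe) or 2-D
    (probes x naive samples) with ``immune_signal`` matching rows.
    """
    naive = np.asarray(naive_signals, dtype=float)
    x = np.asarray(immune_signal, dtype=float)
    n = naive.shape[-1]
    if n < 2:
        raise ValueError("need >= 2 naive samples")
    mean = naive.mean(axis=-1)
    sd = np.maximum(naive.std(axis=-1, ddof=1), var_floor)
    t = (x - mean) / (sd * np.sqrt(1.0 + 1.0 / n))
    return stats.t.sf(t, df=n - 1)


def combine_wilkinson_max(p_list) -> float | np.ndarray:
    """Wilkinson's maximum meta p-value: ``max(p)`` to the k-th power.

    Under k independent uniform nulls the maximum has CDF x^k, so the
    combined value is itself uniform.  1-D input gives a scalar; 2-D
    input combines along the last axis.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    k = p.shape[-1]
    return np.max(p, axis=-1) ** k


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def assign_sd_tier(
    signal,
    pool_mean: float,
    pool_sd: float,
    thresholds: CategoryThresholds = CategoryThresholds(),
):
    """Tier of each signal by pooled SDs above the pooled mean (strict >)."""
    z = (np.asarray(signal, dtype=float) - pool_mean) / pool_sd
    tiers = np.where(
        z > thresholds.restrictive_sd,
        "restrictive",
        np.where(
            z > thresholds.moderate_sd,
            "moderate",
            np.where(z > thresholds.inclusive_sd, "inclusive", "none"),
        ),
    )
    return tiers if tiers.ndim else tiers.item()


def tier_at_least(tiers, minimum: str):
    """Boolean mask for tiers at or above ``minimum`` in the nesting."""
    rank = {t: i for i, t in enumerate(TIER_ORDER)}
    t = np.asarray(tiers)
    need = rank[minimum]
    return np.vectorize(lambda x: rank[x] >= need)(t) if t.size else np.zeros(0, bool)


# ---------------------------------------------------------------------------
# probe-level calling


def remove_singletons(
    called: pd.DataFrame,
    occ_accessions: np.ndarray,
    occ_starts: np.ndarray,
    tiling_steps: Mapping[str, int],
    replicate_groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Drop isolated probe calls that lack neighbour or replicate support.

    A called occurrence with no called occurrence within one tiling step
    on either side (same protein, same sample) is uncalled, unless the
    same occurrence is also called in a replicate sample of the same
    serum.

    ``called``: occurrences x samples booleans, rows ordered
    protein-major / start-ascending.  ``replicate_groups`` maps each
    sample id to its co-replicate sample ids.
    """
    replicate_groups = replicate_groups or {}
    for sample, partners in replicate_groups.items():
        for p in list(partners) + [sample]:
            if p not in called.columns:
                raise KeyError(f"replicate map references unknown sample {p!r}")
    values = called.to_numpy(copy=True)
    n = len(called)
    same_prev = np.zeros(n, dtype=bool)
    same_next = np.zeros(n, dtype=bool)
    gap = np.array([tiling_steps.get(a, 2) for a in occ_accessions])
    if n > 1:
        same_prev[1:] = (occ_accessions[1:] == occ_accessions[:-1]) & (
            occ_starts[1:] - occ_starts[:-1] <= gap[1:]
        )
        same_next[:-1] = same_prev[1:]
    for j, sample in enumerate(called.columns):
        col = values[:, j]
        has_prev = np.zeros(n, dtype=bool)
        has_next = np.zeros(n, dtype=bool)
        has_prev[1:] = col[:-1] & same_prev[1:]
        has_next[:-1] = col[1:] & same_next[:-1]
        isolated = col & ~has_prev & ~has_next
        rescued = np.zeros(n, dtype=bool)
        for partner in replicate_groups.get(sample, []):
            jj = called.columns.get_loc(partner)
            rescued |= values[:, jj]
        values[:, j] = col & (~isolated | rescued)
    out = pd.DataFrame(values, index=called.index, columns=called.columns)
    return out


# ---------------------------------------------------------------------------
# epitope segmentation (SKATER on the 1-D probe grid)


@dataclass
class EpitopeRegion:
    """A maximal run of co-bound probes and its shared consensus.

    ``aa_start``/``aa_end`` span all member probe windows; the
    consensus is the stretch shared by every member
    (``[max start, min start + 15]``) when the members overlap, and the
    full span flagged ``no_common_core`` otherwise.
    """

    accession: str
    member_starts: list[int]
    aa_start: int = 0
    aa_end: int = 0
    consensus_seq: str = ""
    consensus_start: int = 0
    consensus_end: int = 0
    no_common_core: bool = False
    # filled in by the model
    p: dict[str, float] = field(default_factory=dict)
    q: dict[str, float] = field(default_factory=dict)
    called: dict[str, bool] = field(default_factory=dict)
    tier: dict[str, str] = field(default_factory=dict)
    k_of_n: tuple[int, int] = (0, 0)

    @property
    def member_ids(self) -> list[str]:
        return [f"{self.accession}:{s}" for s in self.member_starts]

    @property
    def interval(self) -> tuple[int, int]:
        """Best epitope estimate: consensus core, or span if no core."""
        if self.no_common_core or not self.consensus_seq:
            return (self.aa_start, self.aa_end)
        return (self.consensus_start, self.consensus_end)

    @property
    def consensus_length(self) -> int:
        if self.no_common_core:
            return self.aa_end - self.aa_start + 1
        return len(self.consensus_seq)


def _ssd(x: np.ndarray) -> float:
    """Total within-cluster sum of squared deviations from the mean."""
    if len(x) < 2:
        return 0.0
    return float(((x - x.mean(axis=0)) ** 2).sum())


def _best_cut(x: np.ndarray) -> tuple[int, float]:
    """Best single cut of an ordered segment; returns (cut index, gain)."""
    total = _ssd(x)
    best_i, best_gain = -1, -np.inf
    for i in range(1, len(x)):
        gain = total - _ssd(x[:i]) - _ssd(x[i:])
        if gain > best_gain:
            best_i, best_gain = i, gain
    return best_i, best_gain


def _split_chain(
    x: np.ndarray, min_gain: float, min_size: int
) -> list[tuple[int, int]]:
    """Recursive SSD-minimizing splitting of one contiguous chain.

    On a path graph the minimum spanning tree is the path itself, so
    SKATER's tree-edge removal is a recursive search for the single cut
    giving the largest decrease in within-cluster SSD, accepted while
    the decrease is at least ``min_gain`` and both sides have at least
    ``min_size`` members.
    """
    segments: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if hi - lo < 2 * min_size or hi - lo < 2:
            segments.append((lo, hi))
            return
        cut, gain = _best_cut(seg)
        if gain < min_gain or cut < min_size or (hi - lo) - cut < min_size:
            segments.append((lo, hi))
            return
        recurse(lo, lo + cut)
        recurse(lo + cut, hi)

    recurse(0, len(x))
    segments.sort()
    return segments


def _noise_penalty(chain_feats: np.ndarray, c: float) -> float:
    """Changepoint acceptance penalty from the local noise level.

    The feature noise variance is estimated robustly per sample column
    from successive differences along the chain (median of squared
    diffs, scaled for the chi-square median and the variance doubling
    of a difference), summed over columns, and scaled by ``c`` and a
    log-length factor.  Smoothed antibody-binding profiles are gentle
    hills, so an SSD threshold tied to the whole chain under-splits;
    a noise-scaled penalty accepts exactly the cuts that exceed what
    local jitter explains.
    """
    n = len(chain_feats)
    if n < 2:
        return np.inf
    d = np.diff(chain_feats, axis=0)
    sigma2 = np.median(d**2, axis=0) / (2 * 0.4549)  # median of chi2_1
    return float(c * max(sigma2.sum(), 1e-9) * np.log(max(n, 2)))


def segment_epitopes(
    accession: str,
    starts: Sequence[int],
    features: np.ndarray,
    tiling_step: int,
    max_gap_aa: int | None = None,
    min_gain_frac: float | None = None,
    split_penalty: float = 0.2,
    min_size: int = 1,
    probe_length: int = PROBE_LENGTH,
) -> list[EpitopeRegion]:
    """Segment the called occurrences of one protein into epitope regions.

    ``starts`` are the (ascending) start positions of called
    occurrences; ``features`` is the matched (n x n_samples) matrix of
    per-sample -log10 combined p-values.  Occurrences within
    ``max_gap_aa`` (default: the tiling step) form chains; each chain is
    then split by recursive SSD-reducing cuts.  A cut is accepted while
    its SSD decrease exceeds a noise-scaled penalty
    (``split_penalty`` x the robust feature-noise variance x log chain
    length); passing ``min_gain_frac`` instead thresholds at that
    fraction of the whole chain's SSD.
    """
    starts = list(starts)
    if starts != sorted(starts):
        raise ValueError("called occurrence starts must be ascending")
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    if max_gap_aa is None:
        max_gap_aa = tiling_step
    regions: list[EpitopeRegion] = []
    if not starts:
        return regions
    # chains of grid-adjacent called occurrences
    chain_bounds = [0]
    for i in range(1, len(starts)):
        if starts[i] - starts[i - 1] > max_gap_aa:
            chain_bounds.append(i)
    chain_bounds.append(len(starts))
    for lo, hi in zip(chain_bounds[:-1], chain_bounds[1:]):
        chain_feats = np.asarray(features[lo:hi], dtype=float)
        if min_gain_frac is not None:
            min_gain = min_gain_frac * _ssd(chain_feats)
        else:
            min_gain = _noise_penalty(chain_feats, split_penalty)
        for a, b in _split_chain(chain_feats, min_gain, min_size):
            regions.append(
                EpitopeRegion(
                    accession=accession,
                    member_starts=starts[lo + a : lo + b],
                )
            )
    return regions


def consensus_sequence(
    region: EpitopeRegion,
    protein_seq: str,
    probe_length: int = PROBE_LENGTH,
) -> EpitopeRegion:
    """Fill a region's span and shared consensus from the protein sequence.

    For k members on a step-s grid the consensus has length
    ``probe_length - s*(k-1)`` when positive; a longer region has no
    common core and reports its full spanned interval flagged.
    """
    s_min, s_max = min(region.member_starts), max(region.member_starts)
    region.aa_start = s_min
    region.aa_end = min(s_max + probe_length - 1, len(protein_seq))
    core_start, core_end = s_max, s_min + probe_length - 1
    if core_start <= core_end:
        region.consensus_start, region.consensus_end = core_start, core_end
        region.consensus_seq = protein_seq[core_start - 1 : core_end]
        region.no_common_core = False
    else:
        region.consensus_start, region.consensus_end = region.aa_start, region.aa_end
        region.consensus_seq = protein_seq[region.aa_start - 1 : region.aa_end]
        region.no_common_core = True
    return region


# ---------------------------------------------------------------------------
# meta p-values


def epitope_pvalue(member_p) -> float:
    """Order-statistic meta p-value from the 2nd highest member p.

    For n >= 2 members the (n-1)-th ascending order statistic of n
    uniforms is Beta(n-1, 2); the epitope p is that CDF evaluated at
    the observed 2nd-largest member p.  A singleton region keeps its
    member p.
    """
    p = np.sort(np.asarray(member_p, dtype=float))
    n = p.size
    if n == 0:
        raise ValueError("empty member p-value list")
    if n == 1:
        return float(p[0])
    return float(stats.beta.cdf(p[-2], n - 1, 2))


def protein_pvalue(epitope_p) -> float:
    """Tippett's (Wilkinson's minimum) method: 1 - (1 - min p)^m."""
    p = np.asarray(epitope_p, dtype=float)
    if p.size == 0:
        raise ValueError("empty epitope p-value list")
    return float(1.0 - (1.0 - p.min()) ** p.size)


# ---------------------------------------------------------------------------
# K-of-N and summaries


def tabulate_k_of_n(
    calls: pd.DataFrame, sample_to_mouse: Mapping[str, str]
) -> tuple[pd.Series, int]:
    """Count recognizing mice per item, collapsing replicate samples.

    ``calls``: items x samples booleans (immune samples only).  Returns
    per-item K and the total N of distinct immune mice; replicate
    assays of one serum count as one mouse.
    """
    mice = pd.Index([sample_to_mouse[c] for c in calls.columns], name="mouse")
    by_mouse = calls.T.groupby(mice).any().T
    k = by_mouse.sum(axis=1).astype(int)
    return k, by_mouse.shape[1]


def summarize_epitopes(
    regions: Sequence[EpitopeRegion], bin_width: int = 2
) -> pd.DataFrame:
    """Consensus-length histogram per mouse-level tier, in 2-aa bins.

    Returns a table with columns ``tier``, ``bin`` ("1-2", "3-4", ...)
    and ``count``; a region contributes to every tier it reaches in at
    least one sample (tiers nest).
    """
    rows = []
    for region in regions:
        length = region.consensus_length
        lo = ((length - 1) // bin_width) * bin_width + 1
        label = f"{lo}-{lo + bin_width - 1}"
        tiers = set(region.tier.values()) if region.tier else {"none"}
        rank = {t: i for i, t in enumerate(TIER_ORDER)}
        best = max(tiers, key=lambda t: rank[t])
        for tier in ("inclusive", "moderate", "restrictive"):
            if rank[best] >= rank[tier]:
                rows.append({"tier": tier, "bin": label, "length": length})
    if not rows:
        return pd.DataFrame(columns=["tier", "bin", "count"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["tier", "bin"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
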