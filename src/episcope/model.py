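"""Model/Results interface for hierarchical antibody-binding calls.

:class:`HeronModel` is built from a probe-level intensity matrix, a
sample sheet and a probe library; :meth:`HeronModel.fit` runs
preprocessing (log2, quantile normalization, redundant-peptide
restoration, +/-8 aa smoothing) and the hierarchical caller, returning
a :class:`HeronResults` with probe-, epitope- and protein-level calls,
signal tiers, K-of-N co-recognition statistics and a ``summary()``
table.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from . import calling, preprocess
from .arrays import ProbeLibrary, parse_occurrence_id
from .calling import CategoryThresholds, EpitopeRegion

logger = logging.getLogger("episcope")


def validate_sample_sheet(sheet: pd.DataFrame, columns) -> pd.DataFrame:
    required = {"sample_id", "mouse_id", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet.sample_id.duplicated().any():
        raise ValueError("duplicate sample_ids in sample sheet")
    bad = set(sheet.condition) - {"naive", "immune"}
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    unmatched = [c for c in columns if c not in set(sheet.sample_id)]
    if unmatched:
        raise ValueError(
            f"sample sheet does not cover matrix column(s): {unmatched}"
        )
    return sheet


def replicate_groups_from_sheet(sheet: pd.DataFrame) -> dict[str, list[str]]:
    """Map each sample to its co-replicate samples (same serum, != self)."""
    groups: dict[str, list[str]] = {}
    if "replicate_group" not in sheet.columns:
        return groups
    present = sheet.dropna(subset=["replicate_group"])
    for _, grp in present.groupby("replicate_group"):
        ids = list(grp.sample_id)
        if len(ids) < 2:
            continue
        for s in ids:
            groups[s] = [o for o in ids if o != s]
    return groups


class HeronModel:
    """Hierarchical binding-call model for one array experiment.

    Parameters
    ----------
    intensities
        Probe x sample matrix.  Rows are unique peptides for
        ``stage="raw"`` input (the usual case) or occurrence ids for an
        already-processed matrix (``stage="smoothed"``).
    sample_sheet
        One row per sample: ``sample_id``, ``mouse_id``, ``condition``
        (naive/immune), optional ``replicate_group`` and ``batch``.
    library
        The probe library the matrix was assayed against.
    thresholds
        Signal tiers and FDR cutoff.
    var_floor
        Minimum naive SD (log2 units) in the differential t-test.
    max_gap_aa, min_gain_frac, min_size
        Epitope segmentation parameters; ``max_gap_aa`` defaults to the
        protein's tiling step.
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        library: ProbeLibrary,
        thresholds: CategoryThresholds | None = None,
        stage: str | None = None,
        var_floor: float = 0.01,
        half_window_aa: int = 8,
        max_gap_aa: int | None = None,
        min_gain_frac: float | None = None,
        split_penalty: float = 0.2,
        min_size: int = 1,
        pseudocount: float | None = None,
    ) -> None:
        self.intensities = intensities
        self.sample_sheet = validate_sample_sheet(
            sample_sheet, intensities.columns
        )
        self.library = library
        self.thresholds = thresholds or CategoryThresholds()
        self.stage = stage or intensities.attrs.get("stage", "raw")
        self.var_floor = var_floor
        self.half_window_aa = half_window_aa
        self.max_gap_aa = max_gap_aa
        self.min_gain_frac = min_gain_frac
        self.split_penalty = split_penalty
        self.min_size = min_size
        self.pseudocount = pseudocount
        cond = dict(zip(sample_sheet.sample_id, sample_sheet.condition))
        self.naive_samples = [
            c for c in intensities.columns if cond[c] == "naive"
        ]
        self.immune_samples = [
            c for c in intensities.columns if cond[c] == "immune"
        ]
        if len(self.naive_samples) < 2:
            raise ValueError("need >= 2 naive samples for differential calls")
        if not self.immune_samples:
            raise ValueError("no immune samples in matrix")
        self.sample_to_mouse = dict(
            zip(sample_sheet.sample_id, sample_sheet.mouse_id)
        )
        self.replicate_groups = replicate_groups_from_sheet(sample_sheet)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "HeronResults":
        if self.stage == "smoothed":
            smoothed = self.intensities
        else:
            smoothed = preprocess.preprocess(
                self.intensities,
                self.library,
                half_window_aa=self.half_window_aa,
                pseudocount=self.pseudocount,
            )
        pool_mean, pool_sd = calling.pooled_stats(smoothed)
        parsed = [parse_occurrence_id(i) for i in smoothed.index]
        occ_accessions = np.array([a for a, _ in parsed])
        occ_starts = np.array([s for _, s in parsed])

        naive = smoothed[self.naive_samples].to_numpy()

        p_global, p_diff, p_comb, q, called, tiers = {}, {}, {}, {}, {}, {}
        for s in self.immune_samples:
            x = smoothed[s].to_numpy()
            pg = calling.global_pvalue(x, pool_mean, pool_sd)
            pd_ = calling.differential_pvalue(x, naive, self.var_floor)
            pc = np.maximum(pg, pd_) ** 2
            p_global[s], p_diff[s], p_comb[s] = pg, pd_, pc
            q[s] = calling.bh_adjust(pc)
            called[s] = q[s] <= self.thresholds.fdr_cutoff
            tiers[s] = calling.assign_sd_tier(
                x, pool_mean, pool_sd, self.thresholds
            )
        idx = smoothed.index
        called_df = pd.DataFrame(called, index=idx)
        called_df = calling.remove_singletons(
            called_df,
            occ_accessions,
            occ_starts,
            self.library.tiling_steps,
            self.replicate_groups,
        )
        results = HeronResults(
            model=self,
            smoothed=smoothed,
            pool_mean=pool_mean,
            pool_sd=pool_sd,
            p_global=pd.DataFrame(p_global, index=idx),
            p_diff=pd.DataFrame(p_diff, index=idx),
            p_combined=pd.DataFrame(p_comb, index=idx),
            q=pd.DataFrame(q, index=idx),
            called=called_df,
            tiers=pd.DataFrame(tiers, index=idx),
            occ_accessions=occ_accessions,
            occ_starts=occ_starts,
        )
        results._segment_and_summarize()
        return results


class HeronResults:
    """Fitted probe/epitope/protein calls and their summaries."""

    def __init__(
        self,
        model: HeronModel,
        smoothed: pd.DataFrame,
        pool_mean: float,
        pool_sd: float,
        p_global: pd.DataFrame,
        p_diff: pd.DataFrame,
        p_combined: pd.DataFrame,
        q: pd.DataFrame,
        called: pd.DataFrame,
        tiers: pd.DataFrame,
        occ_accessions: np.ndarray,
        occ_starts: np.ndarray,
    ) -> None:
        self.model = model
        self.smoothed = smoothed
        self.pool_mean = pool_mean
        self.pool_sd = pool_sd
        self.p_global = p_global
        self.p_diff = p_diff
        self.p_combined = p_combined
        self.q = q
        self.called = called
        self.tiers = tiers
        self.occ_accessions = occ_accessions
        self.occ_starts = occ_starts
        #: pre-smoothing per-chip values (falls back to smoothed)
        self.normalized: pd.DataFrame = smoothed.attrs.get(
            "normalized", smoothed
        )
        self.epitopes: list[EpitopeRegion] = []
        self.proteins: pd.DataFrame = pd.DataFrame()

    # -- hierarchy --------------------------------------------------------

    def _segment_and_summarize(self) -> None:
        model = self.model
        thresholds = model.thresholds
        samples = model.immune_samples
        any_called = self.called.to_numpy().any(axis=1)
        features_all = -np.log10(
            np.maximum(self.p_combined.to_numpy(), 1e-300)
        )
        regions: list[EpitopeRegion] = []
        for acc in pd.unique(self.occ_accessions):
            mask = (self.occ_accessions == acc) & any_called
            if not mask.any():
                continue
            order = np.argsort(self.occ_starts[mask], kind="stable")
            starts = self.occ_starts[mask][order]
            feats = features_all[mask][order]
            step = model.library.tiling_steps.get(acc, 2)
            regions.extend(
                calling.segment_epitopes(
                    acc,
                    starts.tolist(),
                    feats,
                    tiling_step=step,
                    max_gap_aa=model.max_gap_aa,
                    min_gain_frac=model.min_gain_frac,
                    split_penalty=model.split_penalty,
                    min_size=model.min_size,
                )
            )
        # consensus + per-sample meta p
        pos = {o: i for i, o in enumerate(self.smoothed.index)}
        for region in regions:
            calling.consensus_sequence(
                region, model.library.protein_sequence(region.accession)
            )
            rows = [pos[m] for m in region.member_ids]
            for s in samples:
                member_p = self.p_combined[s].to_numpy()[rows]
                region.p[s] = calling.epitope_pvalue(member_p)
        # per-sample BH across regions, calls and tiers
        for s in samples:
            ps = np.array([r.p[s] for r in regions])
            qs = calling.bh_adjust(ps) if len(ps) else ps
            sig = self.smoothed[s].to_numpy()
            for region, qv in zip(regions, qs):
                region.q[s] = float(qv)
                region.called[s] = bool(qv <= thresholds.fdr_cutoff)
                rows = [pos[m] for m in region.member_ids]
                peak = sig[rows].max()
                tier = calling.assign_sd_tier(
                    peak, self.pool_mean, self.pool_sd, thresholds
                )
                region.tier[s] = tier if region.called[s] else "none"
        if regions:
            epi_calls = pd.DataFrame(
                {s: [r.called[s] for r in regions] for s in samples}
            )
            k, n = calling.tabulate_k_of_n(
                epi_calls,
                {s: model.sample_to_mouse[s] for s in samples},
            )
            for region, kv in zip(regions, k):
                region.k_of_n = (int(kv), n)
        self.epitopes = regions
        self._summarize_proteins()

    def _summarize_proteins(self) -> None:
        model = self.model
        thresholds = model.thresholds
        samples = model.immune_samples
        by_acc: dict[str, list[EpitopeRegion]] = {}
        for r in self.epitopes:
            by_acc.setdefault(r.accession, []).append(r)
        rows = []
        p_cols: dict[str, list[float]] = {s: [] for s in samples}
        for acc, regs in by_acc.items():
            rows.append(
                {"accession": acc, "n_epitopes": len(regs)}
            )
            for s in samples:
                p_cols[s].append(
                    calling.protein_pvalue([r.p[s] for r in regs])
                )
        proteins = pd.DataFrame(rows)
        if proteins.empty:
            self.proteins = pd.DataFrame(
                columns=["accession", "n_epitopes", "K", "N"]
            )
            return
        call_cols = {}
        for s in samples:
            p = np.array(p_cols[s])
            q = calling.bh_adjust(p)
            called = q <= thresholds.fdr_cutoff
            tier = []
            for acc, c in zip(proteins.accession, called):
                if not c:
                    tier.append("none")
                    continue
                # protein tier from its strongest member epitope signal
                peak = max(
                    self.smoothed[s].loc[m]
                    for r in by_acc[acc]
                    for m in r.member_ids
                )
                tier.append(
                    calling.assign_sd_tier(
                        peak, self.pool_mean, self.pool_sd, thresholds
                    )
                )
            proteins[f"p_{s}"] = p
            proteins[f"q_{s}"] = q
            proteins[f"called_{s}"] = called
            proteins[f"tier_{s}"] = tier
            call_cols[s] = called
        k, n = calling.tabulate_k_of_n(
            pd.DataFrame(call_cols),
            {s: model.sample_to_mouse[s] for s in samples},
        )
        proteins["K"] = k.to_numpy()
        proteins["N"] = n
        self.proteins = proteins

    # -- views ------------------------------------------------------------

    @property
    def probe_calls(self) -> pd.DataFrame:
        """Tidy per-(occurrence, immune sample) call table."""
        frames = []
        for s in self.model.immune_samples:
            frames.append(
                pd.DataFrame(
                    {
                        "occurrence": self.smoothed.index,
                        "sample": s,
                        "signal": self.smoothed[s].to_numpy(),
                        "p_global": self.p_global[s].to_numpy(),
                        "p_diff": self.p_diff[s].to_numpy(),
                        "p_combined": self.p_combined[s].to_numpy(),
                        "q": self.q[s].to_numpy(),
                        "called": self.called[s].to_numpy(),
                        "tier": self.tiers[s].to_numpy(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @property
    def probe_k_of_n(self) -> tuple[pd.Series, int]:
        return calling.tabulate_k_of_n(
            self.called,
            {
                s: self.model.sample_to_mouse[s]
                for s in self.model.immune_samples
            },
        )

    def epitope_table(self) -> pd.DataFrame:
        rows = []
        for r in self.epitopes:
            row = {
                "accession": r.accession,
                "aa_start": r.aa_start,
                "aa_end": r.aa_end,
                "consensus_start": r.consensus_start,
                "consensus_end": r.consensus_end,
                "consensus_seq": r.consensus_seq,
                "no_common_core": r.no_common_core,
                "n_members": len(r.member_starts),
                "K": r.k_of_n[0],
                "N": r.k_of_n[1],
            }
            for s in self.model.immune_samples:
                row[f"p_{s}"] = r.p[s]
                row[f"q_{s}"] = r.q[s]
                row[f"called_{s}"] = r.called[s]
                row[f"tier_{s}"] = r.tier[s]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable per-level, per-tier call counts."""
        lines = [
            "Hierarchical antibody-binding calls",
            "=" * 51,
            f"samples: {len(self.model.naive_samples)} naive, "
            f"{len(self.model.immune_samples)} immune",
            f"occurrences: {len(self.smoothed)}   "
            f"pooled mean {self.pool_mean:.3f}, SD {self.pool_sd:.3f}",
            f"FDR cutoff: {self.model.thresholds.fdr_cutoff}",
            "",
            f"{'level':<10}{'tier':<14}{'calls':>8}",
            "-" * 32,
        ]
        k_probe, n = self.probe_k_of_n
        for tier in ("inclusive", "moderate", "restrictive"):
            count = int(
                (
                    self.called.to_numpy()
                    & calling.tier_at_least(self.tiers.to_numpy(), tier)
                ).sum()
            )
            lines.append(f"{'probe':<10}{tier:<14}{count:>8}")
        for tier in ("inclusive", "moderate", "restrictive"):
            count = sum(
                1
                for r in self.epitopes
                for s in self.model.immune_samples
                if r.called[s]
                and calling.tier_at_least([r.tier[s]], tier).any()
            )
            lines.append(f"{'epitope':<10}{tier:<14}{count:>8}")
        if not self.proteins.empty:
            for tier in ("inclusive", "moderate", "restrictive"):
                count = 0
                for s in self.model.immune_samples:
                    t = self.proteins[f"tier_{s}"].to_numpy()
                    count += int(calling.tier_at_least(t, tier).sum())
                lines.append(f"{'protein':<10}{tier:<14}{count:>8}")
        lines += [
            "",
            f"epitope regions: {len(self.epitopes)}   "
            f"proteins with calls: {len(self.proteins)}   N mice: "
            f"{self.probe_k_of_n[1]}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<HeronResults: {len(self.smoothed)} occurrences, "
            f"{len(self.epitopes)} epitope regions>"
        )
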