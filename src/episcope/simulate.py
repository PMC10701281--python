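"""Synthetic proteomes, array intensities and ELISA panels.

The generator emulates the structure of a whole-proteome serum-IgG
peptide-array experiment: a lognormal fluorescence background with
probe-specific affinities, a global multiplicative elevation of immune
(hyper-immune) sera, sparse naive autoantibody binding present in both
conditions of a mouse, and antibody epitopes spiked as consecutive-probe
elevations — a probe binds fully when its 16-mer window contains the
whole epitope interval and with steeply reduced avidity when it carries
at least half of it, so an 8-12 aa epitope lights up the few
overlapping probes that carry it, exactly the pattern a 2-aa tiling
produces around a linear epitope.  Each immune mouse receives private
epitopes plus membership in a minority of shared epitopes, giving the
heterogeneous per-mouse "fingerprint" with a co-recognized core that
the downstream K-of-N statistics quantify.

Every draw comes from a named substream of a single seed, so the same
config yields byte-identical FASTA, matrices and manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .arrays import (
    PROBE_LENGTH,
    ProbeLibrary,
    ProteinRecord,
    build_library,
)

# average amino-acid frequencies (UniProt-like), used for i.i.d. sequences
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_FREQS = np.array(
    [
        0.083, 0.014, 0.055, 0.067, 0.039, 0.071, 0.023, 0.059, 0.058,
        0.097, 0.024, 0.040, 0.047, 0.039, 0.055, 0.066, 0.053, 0.069,
        0.011, 0.029,
    ]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()

_STREAMS = {
    "proteome": 1,
    "layout": 2,
    "affinity": 3,
    "noise": 4,
    "naive_hits": 5,
    "elisa": 6,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stage],))
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the array study design at a size suitable for fast
    runs: 5 naive + 6 immune mice, one immune serum assayed on a
    replicate pair of chips, ~10-12k probes from 200 proteins.  The
    background is a tight lognormal (log2 SD 0.5, ~40% CV) with a
    sparse strong-binder tail: the spike amplitude is expressed in
    background log2-SD units, and the default of 16 puts fully bound
    probes 16 x 0.5 = 8 log2 units (256-fold) above background on the
    raw scale, the magnitude strong serum binders show on real arrays
    (100-1000-fold over baseline).
    """

    n_proteins: int = 200
    protein_length_mean: float = 120.0
    protein_length_min: int = 16
    n_naive: int = 5
    n_immune: int = 6
    n_replicate_pairs: int = 2
    background_log2_mean: float = 6.0
    background_log2_sd: float = 0.5
    probe_affinity_frac: float = 0.6  # share of background SD that is probe-specific
    floor_noise_log2_sd: float = 0.4  # optical background floor, per chip
    chip_noise_log2_sd: float = 0.08  # multiplicative chip noise (CV floor)
    #: sparse per-chip bright single-probe artifacts (dust, synthesis
    #: defects) — the error-prone single-peptide values real chips show
    artifact_rate: float = 0.005
    artifact_log2_range: tuple[float, float] = (1.0, 3.0)
    #: scanner ceiling (16-bit counts); strongest binders saturate here
    saturation_log2: float = 16.0
    immune_global_shift: float = 1.5  # multiplicative, raw scale
    naive_hit_rate: float = 0.001
    naive_hit_amplitude_sd: float = 8.0
    private_epitopes_per_mouse: int = 10
    shared_epitopes: int = 8
    #: per-mouse weak immune reactivities (the low end of the serum
    #: binding continuum); amplitudes below the strong-binder range
    weak_epitopes_per_mouse: int = 25
    weak_amplitude_range_sd: tuple[float, float] = (3.0, 13.2)
    #: power-law exponent of the titer continuum (many weak clones,
    #: few dominant ones); amplitudes are truncated-Pareto draws
    amplitude_decay: float = 1.2
    epitope_length_range: tuple[int, int] = (8, 12)
    #: per-region amplitude range in background log2-SD units (13.2-20
    #: SD x 0.5 log2/SD = 100- to 1000-fold raw); a scalar fixes it
    spike_amplitude_sd: float | tuple[float, float] = (13.2, 20.0)
    replicate_noise_sd: float = 0.08  # multiplicative log2 noise, replicate chips
    batch_shift: float = 0.2  # log2 units, added to batch-2 chips
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_proteins, self.n_naive, self.n_immune,
            self.n_replicate_pairs, self.private_epitopes_per_mouse,
            self.shared_epitopes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if min(self.amplitude_range) < 0 or self.background_log2_sd <= 0:
            raise ValueError("amplitudes must be positive")
        if self.n_replicate_pairs > self.n_immune:
            raise ValueError("more replicate pairs than immune mice")

    @property
    def amplitude_range(self) -> tuple[float, float]:
        a = self.spike_amplitude_sd
        return (a, a) if np.isscalar(a) else (a[0], a[1])


@dataclass
class SpikedRegion:
    """One ground-truth epitope: interval, amplitude and target mice."""

    accession: str
    aa_start: int
    aa_end: int
    amplitude_sd: float
    mice: list[str]
    shared: bool
    weak: bool = False
    probe_seqs: list[str] = field(default_factory=list)
    #: graded avidity per binding probe (1.0 = window contains epitope)
    probe_weights: dict[str, float] = field(default_factory=dict)

    @property
    def intended_k(self) -> int:
        return len(self.mice)

    @property
    def length(self) -> int:
        return self.aa_end - self.aa_start + 1


@dataclass
class GroundTruthManifest:
    """The simulator's spiked truth, for parameter-recovery testing."""

    regions: list[SpikedRegion] = field(default_factory=list)
    naive_background: dict[str, list[str]] = field(default_factory=dict)

    def regions_of(self, mouse: str) -> list[SpikedRegion]:
        return [r for r in self.regions if mouse in r.mice]

    @property
    def shared_regions(self) -> list[SpikedRegion]:
        return [r for r in self.regions if r.shared]

    @property
    def strong_regions(self) -> list[SpikedRegion]:
        """Full-amplitude truth epitopes (the recovery targets)."""
        return [r for r in self.regions if not r.weak]

    def to_json(self, path) -> None:
        payload = {
            "regions": [asdict(r) for r in self.regions],
            "naive_background": self.naive_background,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            regions=[SpikedRegion(**r) for r in payload["regions"]],
            naive_background=payload["naive_background"],
        )


def simulate_proteome(config: SimulationConfig) -> list[ProteinRecord]:
    """I.i.d.-residue proteins with gamma-distributed lengths (>= 16 aa)."""
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if config.protein_length_mean < config.protein_length_min:
        raise ValueError("degenerate length distribution: mean below minimum")
    rng = _rng(config.seed, "proteome")
    records = []
    shape = 4.0
    scale = config.protein_length_mean / shape
    for i in range(config.n_proteins):
        length = max(config.protein_length_min, int(round(rng.gamma(shape, scale))))
        seq = "".join(rng.choice(list(AA_ORDER), size=length, p=AA_FREQS))
        records.append(ProteinRecord(accession=f"SYN{i:05d}", sequence=seq))
    return records


def make_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Mice, conditions, replicate groups and batches for one run.

    Immune mice are M1..M{n_immune}; the first ``n_naive`` of them also
    contribute a naive (pre-implantation) serum, and the first
    ``n_replicate_pairs`` immune sera are assayed on a second chip
    (batch 2).
    """
    rows = []
    mice = [f"M{i + 1}" for i in range(max(config.n_immune, config.n_naive))]
    for m in mice[: config.n_naive]:
        rows.append((f"{m}_naive", m, "naive", None, 1))
    for i, m in enumerate(mice[: config.n_immune]):
        group = f"{m}_immune" if i < config.n_replicate_pairs else None
        rows.append((f"{m}_immune", m, "immune", group, 1))
        if i < config.n_replicate_pairs:
            rows.append((f"{m}_immune_r2", m, "immune", group, 2))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "mouse_id", "condition", "replicate_group", "batch"],
    )


def _draw_amplitude(
    rng: np.random.Generator, lo: float, hi: float, alpha: float
) -> float:
    """Truncated-Pareto amplitude draw (density ~ A^-alpha on [lo, hi])."""
    if hi <= lo:
        return float(lo)
    u = rng.uniform()
    a, b = lo ** (1 - alpha), hi ** (1 - alpha)
    return float((a - u * (a - b)) ** (1 / (1 - alpha)))


def _containing_probes(
    library: ProbeLibrary, accession: str, aa_start: int, aa_end: int
) -> list[str]:
    """Unique peptides whose window fully contains [aa_start, aa_end]."""
    seqs = []
    for start, probe_seq in library.protein_index.get(accession, []):
        if start <= aa_start and start + PROBE_LENGTH - 1 >= aa_end:
            seqs.append(probe_seq)
    return seqs


def _binding_weights(
    library: ProbeLibrary,
    accession: str,
    aa_start: int,
    aa_end: int,
    sharpness: float = 3.0,
) -> dict[str, float]:
    """Graded antibody avidity of each probe for one epitope.

    A probe whose window fully contains the epitope binds with weight 1;
    probes carrying at least half of the epitope bind with reduced
    avidity, falling off as ``((overlap - L/2) / (L - L/2))^sharpness``
    — truncating a linear epitope costs affinity steeply but not as an
    all-or-nothing step.  Probes with less than half the epitope do not
    bind.
    """
    length = aa_end - aa_start + 1
    half = -(-length // 2)  # ceil
    weights: dict[str, float] = {}
    for start, probe_seq in library.protein_index.get(accession, []):
        end = start + PROBE_LENGTH - 1
        overlap = min(end, aa_end) - max(start, aa_start) + 1
        if overlap < half:
            continue
        w = ((overlap - half) / (length - half)) ** sharpness if length > half else 1.0
        if w > 0:
            weights[probe_seq] = max(weights.get(probe_seq, 0.0), float(w))
    return weights


def _place_regions(
    library: ProbeLibrary, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Choose disjoint epitope intervals, well separated within proteins."""
    n_regions = (
        config.n_immune
        * (config.private_epitopes_per_mouse + config.weak_epitopes_per_mouse)
        + config.shared_epitopes
    )
    accessions = [
        a for a, p in library.proteins.items() if len(p) >= 3 * PROBE_LENGTH
    ]
    if n_regions and not accessions:
        raise ValueError("spike regions requested exceed available protein length")
    used: dict[str, list[tuple[int, int]]] = {}
    placements: list[tuple[str, int, int]] = []
    lo_len, hi_len = config.epitope_length_range
    pad = 2 * PROBE_LENGTH  # keep regions from sharing smoothing windows
    attempts = 0
    while len(placements) < n_regions:
        attempts += 1
        if attempts > 200 * n_regions:
            raise ValueError(
                "spike regions requested exceed available protein length"
            )
        acc = accessions[rng.integers(len(accessions))]
        protein_len = len(library.proteins[acc])
        length = int(rng.integers(lo_len, hi_len + 1))
        # interval must sit fully inside some probe window
        t = int(rng.integers(PROBE_LENGTH, protein_len - PROBE_LENGTH - length + 2))
        interval = (t, t + length - 1)
        if any(
            not (interval[1] + pad < a or b + pad < interval[0])
            for a, b in used.get(acc, [])
        ):
            continue
        if not _containing_probes(library, acc, *interval):
            continue
        used.setdefault(acc, []).append(interval)
        placements.append((acc, *interval))
    return placements


def simulate_intensities(
    library: ProbeLibrary, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthManifest]:
    """Raw probe x sample fluorescence with a known spiked truth.

    Raw intensity is 2**(log2 background + probe affinity + serum
    signal + chip noise): immune chips gain a global multiplicative
    shift, probes of a mouse's spiked epitopes gain
    ``spike_amplitude_sd`` background-SDs on the log2 scale in that
    mouse's immune samples, naive-background probes gain a smaller
    elevation in both conditions of their mouse, and replicate chips
    re-measure the same serum signal with chip noise
    ``replicate_noise_sd`` plus a batch shift.
    """
    if len(library) == 0:
        raise ValueError("empty probe library")
    sheet = make_sample_sheet(config)
    probe_seqs = sorted(library.probes.keys())
    probe_pos = {s: i for i, s in enumerate(probe_seqs)}
    n_probes = len(probe_seqs)
    sigma = config.background_log2_sd
    sd_affinity = config.probe_affinity_frac * sigma

    layout_rng = _rng(config.seed, "layout")
    placements = _place_regions(library, config, layout_rng)
    mice_immune = sorted(
        sheet.loc[sheet.condition == "immune", "mouse_id"].unique()
    )
    regions: list[SpikedRegion] = []
    amp_lo, amp_hi = config.amplitude_range
    idx = 0
    for m in mice_immune:
        for _ in range(config.private_epitopes_per_mouse):
            acc, a, b = placements[idx]
            idx += 1
            regions.append(
                SpikedRegion(
                    accession=acc, aa_start=a, aa_end=b,
                    amplitude_sd=_draw_amplitude(layout_rng, amp_lo, amp_hi, config.amplitude_decay),
                    mice=[m], shared=False,
                    probe_seqs=_containing_probes(library, acc, a, b),
                    probe_weights=_binding_weights(library, acc, a, b),
                )
            )
    weak_lo, weak_hi = config.weak_amplitude_range_sd
    for m in mice_immune:
        for _ in range(config.weak_epitopes_per_mouse):
            acc, a, b = placements[idx]
            idx += 1
            regions.append(
                SpikedRegion(
                    accession=acc, aa_start=a, aa_end=b,
                    amplitude_sd=_draw_amplitude(layout_rng, weak_lo, weak_hi, config.amplitude_decay),
                    mice=[m], shared=False, weak=True,
                    probe_seqs=_containing_probes(library, acc, a, b),
                    probe_weights=_binding_weights(library, acc, a, b),
                )
            )
    for _ in range(config.shared_epitopes):
        acc, a, b = placements[idx]
        idx += 1
        k = int(layout_rng.integers(2, config.n_immune + 1))
        chosen = sorted(
            layout_rng.choice(mice_immune, size=k, replace=False).tolist()
        )
        regions.append(
            SpikedRegion(
                accession=acc, aa_start=a, aa_end=b,
                amplitude_sd=_draw_amplitude(layout_rng, amp_lo, amp_hi, config.amplitude_decay),
                mice=chosen, shared=True,
                probe_seqs=_containing_probes(library, acc, a, b),
                probe_weights=_binding_weights(library, acc, a, b),
            )
        )

    hits_rng = _rng(config.seed, "naive_hits")
    naive_background: dict[str, list[str]] = {}
    all_mice = sorted(sheet.mouse_id.unique())
    n_hits = int(round(config.naive_hit_rate * n_probes))
    for m in all_mice:
        chosen = hits_rng.choice(n_probes, size=n_hits, replace=False)
        naive_background[m] = sorted(probe_seqs[i] for i in chosen)

    affinity = _rng(config.seed, "affinity").normal(0.0, sd_affinity, n_probes)
    noise_rng = _rng(config.seed, "noise")

    # per-serum biological signal (shared between replicate chips)
    serum_signal: dict[tuple[str, str], np.ndarray] = {}
    for (mouse, condition), _ in sheet.groupby(["mouse_id", "condition"]):
        s = np.zeros(n_probes)
        for seq in naive_background.get(mouse, []):
            s[probe_pos[seq]] += config.naive_hit_amplitude_sd * sigma
        if condition == "immune":
            for region in regions:
                if mouse in region.mice:
                    for seq, w in region.probe_weights.items():
                        s[probe_pos[seq]] += w * region.amplitude_sd * sigma
        serum_signal[(mouse, condition)] = s

    # two-component fluorescence error: a lognormal optical floor that
    # dominates near baseline plus a small multiplicative chip noise, so
    # log-scale scatter shrinks as binding signal rises above the floor
    columns = {}
    for row in sheet.itertuples(index=False):
        log2_signal = (
            config.background_log2_mean
            + affinity
            + serum_signal[(row.mouse_id, row.condition)]
        )
        if row.condition == "immune":
            log2_signal = log2_signal + np.log2(config.immune_global_shift)
        if row.batch != 1:
            log2_signal = log2_signal + config.batch_shift
        cv = (
            config.chip_noise_log2_sd
            if row.batch == 1
            else config.replicate_noise_sd
        )
        eta = noise_rng.normal(0.0, cv, n_probes)
        zeta = noise_rng.normal(0.0, config.floor_noise_log2_sd, n_probes)
        raw = 2.0 ** (log2_signal + eta) + 2.0 ** (
            config.background_log2_mean + zeta
        )
        n_artifacts = noise_rng.binomial(n_probes, config.artifact_rate)
        if n_artifacts:
            where = noise_rng.choice(n_probes, size=n_artifacts, replace=False)
            lo, hi = config.artifact_log2_range
            raw[where] *= 2.0 ** noise_rng.uniform(lo, hi, n_artifacts)
        columns[row.sample_id] = np.minimum(raw, 2.0**config.saturation_log2)
    matrix = pd.DataFrame(columns, index=pd.Index(probe_seqs, name="probe_seq"))
    matrix.attrs["stage"] = "raw"
    manifest = GroundTruthManifest(regions=regions, naive_background=naive_background)
    return matrix, sheet, manifest


def simulate_elisa(
    peptides: Sequence[str],
    sera: pd.DataFrame,
    truth: GroundTruthManifest,
    config: SimulationConfig,
    library: ProbeLibrary | None = None,
    replicates: int = 2,
    od_max: float = 3.5,
) -> pd.DataFrame:
    """Peptide ELISA optical densities matched to the spiked truth.

    OD is a saturating logistic function of the underlying titer (the
    spike amplitude for peptides belonging to one of the serum mouse's
    truth regions, a reduced titer for naive-background peptides, zero
    otherwise) plus noise, clipped to [0, od_max].  Columns are
    ``{sample_id}.r{i}`` replicate wells.
    """
    if library is not None:
        unknown = [p for p in peptides if p not in library]
        if unknown:
            raise KeyError(f"unknown peptide: {unknown[0]!r}")
    spiked_by_mouse: dict[str, set[str]] = {}
    for region in truth.strong_regions:
        for m in region.mice:
            spiked_by_mouse.setdefault(m, set()).update(region.probe_seqs)
    rng = _rng(config.seed, "elisa")
    out = {}
    for row in sera.itertuples(index=False):
        titer = np.zeros(len(peptides))
        for i, pep in enumerate(peptides):
            if (
                row.condition == "immune"
                and pep in spiked_by_mouse.get(row.mouse_id, ())
            ):
                titer[i] = max(config.amplitude_range)
            elif pep in truth.naive_background.get(row.mouse_id, ()):
                titer[i] = 0.25 * config.naive_hit_amplitude_sd
        for r in range(1, replicates + 1):
            od = od_max / (1.0 + np.exp(-(titer - 4.0))) + rng.normal(
                0.0, 0.15, len(peptides)
            )
            out[f"{row.sample_id}.r{r}"] = np.clip(od, 0.0, od_max)
    return pd.DataFrame(out, index=pd.Index(peptides, name="probe_seq"))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ProbeLibrary, pd.DataFrame, pd.DataFrame, GroundTruthManifest]:
    """Proteome -> library -> intensities in one call."""
    proteome = simulate_proteome(config)
    library = build_library(proteome)
    matrix, sheet, truth = simulate_intensities(library, config)
    return library, matrix, sheet, truth
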