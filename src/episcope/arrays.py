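"""In-silico peptide probe library design.

A whole-proteome peptide array is built by tiling every protein into
overlapping 16-mer peptides ("probes"), stepping 2 aa for reviewed
proteins and 4 aa for unreviewed ones.  Identical peptides arising at
several proteome positions are synthesized once; the library therefore
distinguishes the *unique peptide* (``probe_seq``, the key) from its
*occurrences* (``accession:start`` placements), and measured values are
later restored to every occurrence before any protein-coordinate
operation.

Coordinates are 1-based and inclusive throughout, matching UniProt
convention; a probe starting at ``s`` covers ``[s, s + 15]``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("episcope")

PROBE_LENGTH = 16

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues tolerated but flagged (selenocysteine, ambiguity codes, unknown)
NONSTANDARD_AA = frozenset("XUBZ")
VALID_AA = STANDARD_AA | NONSTANDARD_AA


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry.

    ``reviewed`` controls the tiling step (2 aa for reviewed, 4 aa for
    unreviewed proteins).
    """

    accession: str
    sequence: str
    reviewed: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProbeRecord:
    """A unique peptide and every proteome position that yields it."""

    probe_seq: str
    occurrences: list[tuple[str, int]] = field(default_factory=list)
    flagged: bool = False  # contains a nonstandard residue

    @property
    def probe_id(self) -> str:
        return self.probe_seq

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrences)


def occurrence_id(accession: str, start: int) -> str:
    return f"{accession}:{start}"


def parse_occurrence_id(occ_id: str) -> tuple[str, int]:
    accession, _, start = occ_id.rpartition(":")
    return accession, int(start)


def tile_protein(
    protein: ProteinRecord, step: int, length: int = PROBE_LENGTH
) -> list[tuple[int, str]]:
    """Tile one protein into overlapping ``length``-mers at ``step`` aa.

    Starts run 1, 1+step, 1+2*step, ... while a full probe fits.  If the
    last regular probe does not end exactly at the C-terminus, one extra
    probe anchored at ``len - length + 1`` is appended so the terminal
    residues are covered.

    Returns an ordered list of ``(start, subsequence)``; empty (with a
    logged warning) for proteins shorter than the probe length.
    """
    if step not in (2, 4):
        raise ValueError(f"tiling step must be 2 or 4, got {step}")
    if length < 1:
        raise ValueError("probe length must be >= 1")
    seq = protein.sequence
    if len(seq) < length:
        logger.warning(
            "skipping %s: length %d < probe length %d",
            protein.accession, len(seq), length,
        )
        return []
    last_start = len(seq) - length + 1
    starts = list(range(1, last_start + 1, step))
    if starts[-1] != last_start:
        starts.append(last_start)  # C-terminal anchor
    return [(s, seq[s - 1 : s - 1 + length]) for s in starts]


class ProbeLibrary:
    """Deduplicated probe set with probe <-> protein position mappings."""

    def __init__(
        self,
        probes: Mapping[str, ProbeRecord],
        tiling_steps: Mapping[str, int],
        proteins: Mapping[str, ProteinRecord] | None = None,
    ) -> None:
        self.probes: dict[str, ProbeRecord] = dict(probes)
        self.tiling_steps: dict[str, int] = dict(tiling_steps)
        self.proteins: dict[str, ProteinRecord] = dict(proteins or {})
        # per-protein ordered index of (start, probe_seq)
        self.protein_index: dict[str, list[tuple[int, str]]] = {}
        for rec in self.probes.values():
            for accession, start in rec.occurrences:
                self.protein_index.setdefault(accession, []).append(
                    (start, rec.probe_seq)
                )
        for idx in self.protein_index.values():
            idx.sort()

    def __len__(self) -> int:
        return len(self.probes)

    def __contains__(self, probe_seq: str) -> bool:
        return probe_seq in self.probes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeLibrary):
            return NotImplemented
        mine = {s: sorted(r.occurrences) for s, r in self.probes.items()}
        theirs = {s: sorted(r.occurrences) for s, r in other.probes.items()}
        return mine == theirs and self.tiling_steps == other.tiling_steps

    @property
    def n_occurrences(self) -> int:
        return sum(r.n_occurrences for r in self.probes.values())

    def occurrence_ids(self) -> list[str]:
        """All ``accession:start`` ids, protein-major, start-ascending."""
        out: list[str] = []
        for accession in self.protein_index:
            out.extend(
                occurrence_id(accession, s)
                for s, _ in self.protein_index[accession]
            )
        return out

    def protein_sequence(self, accession: str) -> str:
        return self.proteins[accession].sequence

    def restore_redundant(
        self, values: Mapping[str, float]
    ) -> dict[tuple[str, int], float]:
        """Broadcast per-unique-peptide values to every occurrence.

        Values measured once per unique peptide are restored verbatim to
        each protein position that contains the peptide.
        """
        out: dict[tuple[str, int], float] = {}
        for probe_seq, value in values.items():
            rec = self.probes.get(probe_seq)
            if rec is None:
                raise KeyError(f"unknown probe sequence: {probe_seq!r}")
            for occ in rec.occurrences:
                out[occ] = value
        return out

    def restore_matrix(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Map a probe_seq-indexed matrix to occurrence-id rows.

        Rows are ordered protein-major, start-ascending; each occurrence
        row carries its unique peptide's values verbatim.
        """
        unknown = matrix.index.difference(self.probes.keys())
        if len(unknown):
            raise KeyError(f"unknown probe sequence: {unknown[0]!r}")
        seq_by_occ: dict[str, str] = {}
        for accession, idx in self.protein_index.items():
            for start, probe_seq in idx:
                if probe_seq in matrix.index:
                    seq_by_occ[occurrence_id(accession, start)] = probe_seq
        out = matrix.loc[list(seq_by_occ.values())].copy()
        out.index = pd.Index(seq_by_occ.keys(), name="occurrence")
        out.attrs.update(matrix.attrs)
        out.attrs["row_level"] = "occurrence"
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in sorted(self.probes.values(), key=lambda r: r.probe_seq):
            occs = ";".join(
                occurrence_id(a, s) for a, s in sorted(rec.occurrences)
            )
            rows.append(
                {
                    "probe_seq": rec.probe_seq,
                    "n_occurrences": rec.n_occurrences,
                    "occurrences": occs,
                    "flags": "nonstandard" if rec.flagged else "",
                }
            )
        return pd.DataFrame(
            rows, columns=["probe_seq", "n_occurrences", "occurrences", "flags"]
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for accession, step in sorted(self.tiling_steps.items()):
                fh.write(f"#step\t{accession}\t{step}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProbeLibrary":
        steps: dict[str, int] = {}
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#step\t"):
                _, accession, step = line.rstrip("\n").split("\t")
                steps[accession] = int(step)
                body_start = i + 1
            else:
                break
        from io import StringIO

        df = pd.read_csv(
            StringIO("".join(lines[body_start:])),
            sep="\t",
            keep_default_na=False,
        )
        probes: dict[str, ProbeRecord] = {}
        for row in df.itertuples(index=False):
            occs = [parse_occurrence_id(o) for o in row.occurrences.split(";")]
            probes[row.probe_seq] = ProbeRecord(
                probe_seq=row.probe_seq,
                occurrences=occs,
                flagged=row.flags == "nonstandard",
            )
        return cls(probes, steps)


def build_library(
    proteome: Sequence[ProteinRecord],
    steps: Mapping[str, int] | None = None,
    cterm_anchor: bool = True,
    length: int = PROBE_LENGTH,
) -> ProbeLibrary:
    """Tile a proteome and deduplicate probes on sequence.

    ``steps`` overrides the per-protein tiling step; by default reviewed
    proteins tile at 2 aa and unreviewed ones at 4 aa.  With
    ``cterm_anchor=False`` the strict arithmetic tiling is used and
    trailing residues may go unprobed.
    """
    if not proteome:
        raise ValueError("empty proteome")
    accessions = [p.accession for p in proteome]
    if len(set(accessions)) != len(accessions):
        dupes = {a for a in accessions if accessions.count(a) > 1}
        raise ValueError(f"duplicate accessions: {sorted(dupes)}")
    probes: dict[str, ProbeRecord] = {}
    tiling_steps: dict[str, int] = {}
    any_tiled = False
    for protein in proteome:
        step = (steps or {}).get(
            protein.accession, 2 if protein.reviewed else 4
        )
        tiles = tile_protein(protein, step, length)
        if not cterm_anchor and tiles:
            last_regular = 1 + ((len(protein) - length) // step) * step
            tiles = [(s, q) for s, q in tiles if s <= last_regular]
        if not tiles:
            continue
        any_tiled = True
        tiling_steps[protein.accession] = step
        for start, seq in tiles:
            rec = probes.get(seq)
            if rec is None:
                rec = probes[seq] = ProbeRecord(
                    probe_seq=seq, flagged=bool(set(seq) & NONSTANDARD_AA)
                )
            rec.occurrences.append((protein.accession, start))
    if not any_tiled:
        raise ValueError(f"no protein of length >= {length} in proteome")
    return ProbeLibrary(
        probes, tiling_steps, {p.accession: p for p in proteome}
    )


def restore_redundant(
    library: ProbeLibrary, values: Mapping[str, float]
) -> dict[tuple[str, int], float]:
    """Functional alias for :meth:`ProbeLibrary.restore_redundant`."""
    return library.restore_redundant(values)


def read_review_status(path) -> dict[str, bool]:
    """Read a ``accession<TAB>reviewed`` table (true/false)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    return {
        str(row["accession"]): str(row["reviewed"]).strip().lower()
        in ("true", "1", "yes")
        for _, row in df.iterrows()
    }


def steps_from_review_status(
    proteome: Iterable[ProteinRecord], reviewed: Mapping[str, bool]
) -> dict[str, int]:
    """Tiling steps from a review-status table; absent entries tile densely."""
    return {
        p.accession: 2 if reviewed.get(p.accession, True) else 4
        for p in proteome
    }
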