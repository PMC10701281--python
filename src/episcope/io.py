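"""File formats and pipeline orchestration.

TSV/CSV tables carry a one-line ``#stage=`` header for intensity
matrices; FASTA wraps at 60 columns; epitope regions export as GFF3 on
protein coordinates (1-based inclusive).  ``run_pipeline`` ties the
stages into one reproducible run directory with a config manifest.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .arrays import ProteinRecord, build_library
from .calling import CategoryThresholds
from .concordance import concordance_table
from .model import HeronModel, HeronResults, replicate_groups_from_sheet

logger = logging.getLogger("episcope")


def _opener(path, mode: str):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


# -- FASTA -----------------------------------------------------------------


def read_fasta(path) -> list[ProteinRecord]:
    with _opener(path, "rt") as fh:
        records = [
            ProteinRecord(accession=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(proteome, path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description="")
        for p in proteome
    ]
    with _opener(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# -- matrices and tables ---------------------------------------------------


def write_matrix(m: pd.DataFrame, path) -> None:
    with _opener(path, "wt") as fh:
        fh.write(f"#stage={m.attrs.get('stage', 'raw')}\n")
        m.to_csv(fh, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    stage = "raw"
    with _opener(path, "rt") as fh:
        first = fh.readline()
        if first.startswith("#stage="):
            stage = first.strip().split("=", 1)[1]
            body = fh
        else:
            fh.seek(0)
            body = fh
        try:
            m = pd.read_csv(body, sep="\t", index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed matrix {path}: {exc}") from exc
    m.attrs["stage"] = stage
    return m


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, comment="#")
    sheet.columns = [c.strip().lower() for c in sheet.columns]
    return sheet


def write_gff3(epitopes, path) -> None:
    """Epitope regions as GFF3 features on protein coordinates."""
    with _opener(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(epitopes):
            attrs = (
                f"ID=epitope{i:05d};consensus={r.consensus_seq or '.'};"
                f"K={r.k_of_n[0]};N={r.k_of_n[1]};"
                f"no_common_core={str(r.no_common_core).lower()}"
            )
            fh.write(
                "\t".join(
                    [
                        r.accession, "episcope", "epitope_region",
                        str(r.aa_start), str(r.aa_end), ".", ".", ".", attrs,
                    ]
                )
                + "\n"
            )


# -- pipeline --------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for one end-to-end run."""

    proteome_fasta: str
    intensity_tsv: str
    sample_sheet_csv: str
    output_dir: str
    review_tsv: str | None = None
    thresholds: CategoryThresholds = field(default_factory=CategoryThresholds)
    half_window_aa: int = 8
    pseudocount: float | None = None
    max_gap_aa: int | None = None
    min_gain_frac: float | None = None
    split_penalty: float = 0.2
    min_size: int = 1
    var_floor: float = 0.01
    seed: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["thresholds"] = self.thresholds.__dict__.copy()
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = CategoryThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thresholds, **raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Validate inputs, fit the model, and write all result tables.

    The run directory receives probe/epitope/protein tables, K-of-N
    summaries, a GFF3 of epitope regions, a concordance report when
    replicate samples are present, and a manifest with the effective
    config and output checksums.  A ``FAILED`` marker is left behind if
    the run aborts after outputs were started.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    try:
        proteome = read_fasta(config.proteome_fasta)
        steps = None
        if config.review_tsv:
            from .arrays import read_review_status, steps_from_review_status

            steps = steps_from_review_status(
                proteome, read_review_status(config.review_tsv)
            )
        library = build_library(proteome, steps=steps)
        matrix = read_matrix(config.intensity_tsv)
        sheet = read_sample_sheet(config.sample_sheet_csv)
        unknown_rows = matrix.index.difference(library.probes.keys())
        if len(unknown_rows):
            raise ValueError(
                f"matrix rows not in probe library: {list(unknown_rows[:3])}"
            )
        model = HeronModel(
            matrix,
            sheet,
            library,
            thresholds=config.thresholds,
            var_floor=config.var_floor,
            half_window_aa=config.half_window_aa,
            max_gap_aa=config.max_gap_aa,
            min_gain_frac=config.min_gain_frac,
            split_penalty=config.split_penalty,
            min_size=config.min_size,
            pseudocount=config.pseudocount,
        )
        results = model.fit()
        write_results(results, out)
        reps = replicate_groups_from_sheet(sheet)
        pairs = sorted({tuple(sorted([a] + list(b))) for a, b in reps.items()})
        for pair in pairs:
            if len(pair) == 2:
                table = concordance_table(results, pair[0], pair[1])
                table.to_csv(
                    out / f"concordance_{pair[0]}_vs_{pair[1]}.tsv",
                    sep="\t",
                    index=False,
                )
        manifest = {
            "config": config.to_dict(),
            "version": __version__,
            "elapsed_s": round(time.time() - t0, 2),
            "outputs": {
                p.name: _checksum(p)
                for p in sorted(out.iterdir())
                if p.is_file() and p.name != "manifest.json"
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception:
        failed_marker.touch()
        raise
    if failed_marker.exists():
        failed_marker.unlink()
    return out


def write_results(results: HeronResults, out: Path) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    results.probe_calls.to_csv(out / "probe_calls.tsv", sep="\t", index=False)
    results.epitope_table().to_csv(
        out / "epitopes.tsv", sep="\t", index=False
    )
    results.proteins.to_csv(out / "proteins.tsv", sep="\t", index=False)
    write_gff3(results.epitopes, out / "epitopes.gff3")
    k, n = results.probe_k_of_n
    k.rename("K").to_frame().assign(N=n).to_csv(
        out / "probe_k_of_n.tsv", sep="\t"
    )
    (out / "summary.txt").write_text(results.summary() + "\n")
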