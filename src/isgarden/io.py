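"""File formats: FASTA sequences, TSV tables, YAML/JSON run configuration.

All tables are plain TSV with explicit headers; comment lines starting with
'#' are ignored on read and a coordinate-convention comment is written on
output.  Reads validate required columns and report the offending file and
column by name; configuration files reject unknown keys rather than
silently ignoring them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from isgarden.catalog import InsertionEvent, PlatingCount
from isgarden.config import RunConfig
from isgarden.seq_design import TSD, NucleotideSequence

COORD_COMMENT = "# coordinates: 1-based, closed intervals, TSS-relative (+1 = first transcribed nt)"

EVENT_COLUMNS = ["garden_id", "is_id", "position", "orientation", "tsd_seq", "n_clones"]
PLATING_COLUMNS = ["A", "a", "B", "b", "replicate"]


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    path = Path(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(
                NucleotideSequence(
                    id=rec.id, residues=str(rec.seq).upper(), origin_note=rec.description
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(seqs: list[NucleotideSequence], path: str | Path, wrap: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), wrap):
                fh.write(s.residues[i : i + wrap] + "\n")


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_events_tsv(path: str | Path) -> list[InsertionEvent]:
    df = _read_tsv(path, EVENT_COLUMNS)
    events = []
    for i, row in df.iterrows():
        tsd_seq = "" if pd.isna(row["tsd_seq"]) else str(row["tsd_seq"])
        try:
            events.append(
                InsertionEvent(
                    garden_id=str(row["garden_id"]),
                    is_id=str(row["is_id"]),
                    position=int(row["position"]),
                    orientation=str(row["orientation"]),
                    tsd=TSD(tsd_seq, len(tsd_seq)),
                    n_clones=int(row["n_clones"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return events


def write_events_tsv(events: list[InsertionEvent], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT + "\n")
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for e in events:
            fh.write(
                f"{e.garden_id}\t{e.is_id}\t{e.position}\t{e.orientation}\t"
                f"{e.tsd.sequence}\t{e.n_clones}\n"
            )


def read_plating_tsv(path: str | Path) -> list[PlatingCount]:
    df = _read_tsv(path, PLATING_COLUMNS)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                PlatingCount(
                    A=int(row["A"]), a=int(row["a"]), B=int(row["B"]), b=int(row["b"]),
                    replicate=str(row["replicate"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def read_matrix_tsv(path: str | Path, index_col: str) -> pd.DataFrame:
    """A numeric table (environment or abundance) indexed by ``index_col``."""
    df = _read_tsv(path, [index_col])
    return df.set_index(index_col)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration; unknown keys are an error."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s) {unknown}")
    return RunConfig(**raw)


def as_seqrecord(seq: NucleotideSequence) -> SeqRecord:
    return SeqRecord(Seq(seq.residues), id=seq.id, description=seq.origin_note)
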