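"""Readers and writers for the plain-text formats the pipeline touches.

FASTA carries contigs, predicted ORFs and simulated reads; tab-separated
tables carry feature-abundance matrices, hit tables and the differential-
abundance report.  Tab is the only delimiter dialect, the decimal point is
".", and scientific notation is emitted for small magnitudes so report
values survive a write/load round trip to 12 significant digits.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("metacompare")

NUCLEOTIDES = set("ACGTN")

#: Analysis thresholds, with defaults set to the values used throughout the
#: study this pipeline reproduces.  A YAML config file may override any key.
DEFAULT_CONFIG: dict = {
    # gene-catalogue clustering ("greater than 95% identity", "over 90% of
    # the shorter gene" -- strict inequalities)
    "catalogue_id_threshold": 95.0,
    "catalogue_cov_threshold": 0.90,
    "catalogue_min_length": 100,
    # non-redundant contig set ("90% identity and at least 30 bp overlap"
    # -- inclusive comparisons)
    "contig_id_threshold": 90.0,
    "contig_min_overlap": 30,
    # read-to-reference assignment ("cutoff of 95% sequence identity and
    # > 100 bp overlap" -- identity inclusive, overlap strict)
    "assign_id_threshold": 95.0,
    "assign_min_overlap": 100,
    # classifier confidence cutoff (inclusive)
    "confidence_cutoff": 0.7,
    # ortholog-group assignment ("e-value <= 1e-5", inclusive)
    "evalue_cutoff": 1e-5,
    # dual significance rule: p <= 0.05 AND q <= 0.1
    "alpha_p": 0.05,
    "alpha_q": 0.1,
    # rarefaction depth used on the full-scale data; desk-scale runs pass
    # an explicit depth scaled to the simulated library size
    "rarefaction_depth": 3_500_000,
    # seed-and-extend alignment
    "min_seed": 11,
}


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (contig, ORF or read)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_nucleotide(self) -> bool:
        return set(self.seq) <= NUCLEOTIDES


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


def _as_text_handle(stream: str | IO[str]) -> IO[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_fasta(stream: str | IO[str]) -> list[SequenceRecord]:
    """Parse FASTA text into :class:`SequenceRecord` objects.

    Sequence lines are concatenated and upper-cased; input order is
    preserved.  An empty stream yields an empty list.  Sequence data before
    the first header, or a duplicated identifier, is an error.
    """
    handle = _as_text_handle(stream)
    text = handle.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FastaFormatError("sequence data before first FASTA header")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    logger.debug("parsed %d FASTA records", len(records))
    return records


def write_fasta(records: Iterable[SequenceRecord], stream_or_path, width: int = 60) -> None:
    """Write records as multi-line FASTA (fixed line width)."""

    def _write(handle: IO[str]) -> None:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")

    if isinstance(stream_or_path, (str, bytes)) or hasattr(stream_or_path, "__fspath__"):
        with open(stream_or_path, "w") as fh:
            _write(fh)
    else:
        _write(stream_or_path)


def load_abundance_table(stream: str | IO[str], group_labels: Mapping[str, str], raw: bool = True):
    """Load a tab-delimited features x samples table into an AbundanceMatrix.

    The first column holds feature ids; every remaining column is a sample
    and must appear in ``group_labels``.  Values must be finite and
    non-negative.
    """
    from .ecology import AbundanceMatrix  # local import avoids a cycle

    handle = _as_text_handle(stream)
    df = pd.read_csv(handle, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if col not in group_labels:
            raise ValueError(f"sample {col!r} missing from group_labels")
        bad = df[col][~pd.to_numeric(df[col], errors="coerce").notna()]
        if len(bad):
            raise ValueError(f"non-numeric abundance in sample {col!r}: {bad.index[0]}")
    values = df.astype(float)
    neg = values < 0
    if neg.any().any():
        feat = values.index[neg.any(axis=1)][0]
        samp = values.columns[neg.loc[feat]][0]
        raise ValueError(f"negative abundance {feat}/{samp}")
    groups = pd.Series({s: group_labels[s] for s in values.columns})
    return AbundanceMatrix(values, groups, raw=raw)


def _fmt(x) -> str:
    """Format a number for report output.

    Scientific notation for small non-zero magnitudes (|x| < 1e-3), matching
    the style of published q-value columns; 12 significant digits so that
    write -> load round-trips.
    """
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, (int,)) or (isinstance(x, float) and x.is_integer() and abs(x) >= 1e-3):
        if float(x) == int(x):
            return f"{x:.12g}"
    if isinstance(x, float) and x != 0 and abs(x) < 1e-3:
        return f"{x:.11E}"
    if isinstance(x, float):
        return f"{x:.12g}"
    return str(x)


REPORT_COLUMNS = [
    "Taxon",
    "mean_groupA",
    "sd_groupA",
    "mean_groupB",
    "sd_groupB",
    "p-value",
    "q-value",
    "direction",
    "significant",
]


def write_report(table: pd.DataFrame, path, diversity: pd.DataFrame | None = None) -> None:
    """Write a differential-abundance table as a deterministic TSV.

    ``table`` is the frame produced by :func:`metacompare.diffstats.
    differential_table`.  Rows are sorted by ascending p-value with ties
    broken by feature id; columns follow the fixed report order.  If a
    diversity summary frame is given it is written alongside with suffix
    ``.diversity.tsv``.
    """
    required = {"feature", "p_value", "q_value", "direction", "significant"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"report table missing columns: {sorted(missing)}")
    if table[["p_value", "q_value"]].isna().any().any():
        raise ValueError("report table has missing p/q values")

    mean_cols = [c for c in table.columns if c.startswith("mean_")]
    sd_cols = [c for c in table.columns if c.startswith("sd_")]
    out = pd.DataFrame(
        {
            "Taxon": table["feature"].astype(str),
            "mean_groupA": table[mean_cols[0]],
            "sd_groupA": table[sd_cols[0]],
            "mean_groupB": table[mean_cols[1]],
            "sd_groupB": table[sd_cols[1]],
            "p-value": table["p_value"],
            "q-value": table["q_value"],
            "direction": table["direction"],
            "significant": table["significant"],
        }
    )
    out = out.sort_values(["p-value", "Taxon"], kind="mergesort").reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for _, row in out.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    if diversity is not None:
        div_path = str(path) + ".diversity.tsv"
        diversity.to_csv(div_path, sep="\t", float_format="%.12g")
    logger.info("wrote report with %d rows to %s", len(out), path)


def load_report(path) -> pd.DataFrame:
    """Load a report written by :func:`write_report`."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != REPORT_COLUMNS:
        raise ValueError(f"unexpected report columns: {list(df.columns)}")
    df["significant"] = df["significant"].astype(str) == "True"
    return df


def load_config(path=None) -> dict:
    """Return the analysis configuration, optionally overridden from YAML."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def write_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
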