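"""Taxonomic assignment of reads and per-rank abundance tables.

Two assignment routes are provided, mirroring common practice for shotgun
metagenomes: a strict alignment route (best hit at >= 95% identity over
> 100 bp, high confidence but low sensitivity) and a classifier route in
which every read receives a taxon path with per-rank confidences that are
filtered at a cutoff (default 0.7, inclusive).  Reads failing either route
are tracked explicitly as unassigned, because assigned fractions are
themselves a result of interest when comparing hosts against databases of
unequal coverage.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .io_formats import SequenceRecord

logger = logging.getLogger("metacompare")

RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxonAssignment:
    """One read's taxon path with assignment evidence.

    ``taxon_path`` is ordered phylum -> species; a truncated path means the
    deeper ranks could not be assigned (absence is always a contiguous
    suffix).  ``confidences`` aligns with ``taxon_path``; a scalar applies
    to every rank.
    """

    read_id: str
    taxon_path: tuple = ()
    identity: float | None = None
    overlap: int | None = None
    confidences: tuple = ()

    def __post_init__(self) -> None:
        if len(self.confidences) not in (0, len(self.taxon_path)):
            raise ValueError("confidences must align with taxon_path ranks")
        for c in self.confidences:
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"confidence {c} outside [0, 1]")

    @property
    def assigned(self) -> bool:
        return bool(self.taxon_path)

    def rank_taxon(self, rank: str) -> str | None:
        idx = RANKS.index(rank)
        return self.taxon_path[idx] if idx < len(self.taxon_path) else None


def parse_taxon_path(text: str) -> tuple:
    """Parse a ';'-separated taxon path (phylum;class;...;species).

    Absent ranks are only valid as a contiguous suffix, so the path is
    truncated at the first empty field.
    """
    raw = [p.strip() for p in text.split(";")]
    if len(raw) > len(RANKS):
        raise ValueError(f"taxon path deeper than {len(RANKS)} ranks: {text!r}")
    parts = []
    for p in raw:
        if not p:
            break
        parts.append(p)
    return tuple(parts)


def assign_strict(
    hits: pd.DataFrame,
    read_ids: Iterable[str] | None = None,
    id_threshold: float = 95.0,
    min_overlap: int = 100,
) -> tuple[dict, float]:
    """Best-hit assignment under the strict identity/overlap rule.

    ``hits`` needs columns read_id, subject_id, identity, aln_length,
    taxon_path (';'-separated).  A hit passes at identity >= ``id_threshold``
    (the cutoff is inclusive) and aligned length > ``min_overlap`` (strict).
    Among passing hits the winner has the highest identity, then the longest
    overlap, then the smallest subject id.  Returns assignments for the
    union of ``read_ids`` and reads seen in the table, plus the assigned
    fraction over that universe.
    """
    required = {"read_id", "subject_id", "identity", "aln_length", "taxon_path"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    for i, row in hits.iterrows():
        if not np.isfinite(row["identity"]) or not np.isfinite(row["aln_length"]):
            raise ValueError(f"malformed hit row at line {i}")

    universe = set(read_ids) if read_ids is not None else set()
    universe |= set(hits["read_id"].astype(str))
    passing = hits[(hits["identity"] >= id_threshold) & (hits["aln_length"] > min_overlap)]

    assignments: dict[str, TaxonAssignment] = {
        rid: TaxonAssignment(rid) for rid in universe
    }
    for rid, grp in passing.groupby("read_id"):
        grp = grp.sort_values(
            ["identity", "aln_length", "subject_id"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        best = grp.iloc[0]
        assignments[str(rid)] = TaxonAssignment(
            str(rid),
            taxon_path=parse_taxon_path(str(best["taxon_path"])),
            identity=float(best["identity"]),
            overlap=int(best["aln_length"]),
        )
    frac = sum(a.assigned for a in assignments.values()) / len(universe) if universe else 0.0
    logger.info("strict assignment: %.1f%% of %d reads", 100 * frac, len(universe))
    return assignments, frac


def filter_by_confidence(
    assignments: Mapping[str, TaxonAssignment] | Iterable[TaxonAssignment],
    cutoff: float = 0.7,
) -> dict:
    """Blank taxon ranks whose confidence falls below ``cutoff`` (inclusive keep).

    A rank is kept iff its confidence >= cutoff; because absent ranks must
    form a contiguous suffix, the path is truncated at the first failing
    rank.  Reads truncated to an empty path become unassigned.
    """
    if isinstance(assignments, Mapping):
        items = assignments.items()
    else:
        items = ((a.read_id, a) for a in assignments)
    out: dict[str, TaxonAssignment] = {}
    for rid, a in items:
        if not a.confidences:
            out[rid] = a
            continue
        keep = len(a.taxon_path)
        for i, c in enumerate(a.confidences):
            if c < cutoff:
                keep = i
                break
        out[rid] = replace(
            a, taxon_path=a.taxon_path[:keep], confidences=a.confidences[:keep]
        )
    return out


@dataclass
class RankAbundance:
    """Per-taxon read counts at one rank, with unassigned tracked per sample."""

    rank: str
    counts: pd.DataFrame  # taxa x samples
    unassigned: pd.Series  # per sample

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.unassigned

    def assigned_fraction(self) -> pd.Series:
        tot = self.totals()
        return self.counts.sum(axis=0) / tot

    def to_matrix(self, mode: str = "counts") -> pd.DataFrame:
        """Export in one of three conventions.

        ``counts``: assigned taxa only, raw counts.  ``fractions``: taxon
        shares renormalized over assigned reads only (composition-figure
        convention).  ``with_unclassified``: raw counts with the unassigned
        reads carried as an explicit "Unclassified" pseudo-taxon row, so
        differential tests can include it.
        """
        if mode == "counts":
            return self.counts.copy()
        if mode == "fractions":
            return self.counts / self.counts.sum(axis=0)
        if mode == "with_unclassified":
            out = self.counts.copy()
            out.loc["Unclassified"] = self.unassigned
            return out
        raise ValueError(f"unknown mode {mode!r}")


def build_rank_abundance(
    assignments_per_sample: Mapping[str, Iterable[TaxonAssignment]],
    rank: str,
) -> RankAbundance:
    """Count reads per taxon at one rank for each sample.

    Reads whose (filtered) path does not reach ``rank`` count as unassigned
    at that rank; per sample, taxon counts plus unassigned always equal the
    number of reads.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    samples = list(assignments_per_sample)
    counts: dict[str, Counter] = {s: Counter() for s in samples}
    unassigned = {s: 0 for s in samples}
    for sample, assignments in assignments_per_sample.items():
        for a in assignments:
            taxon = a.rank_taxon(rank)
            if taxon is None:
                unassigned[sample] += 1
            else:
                counts[sample][taxon] += 1
    taxa = sorted({t for c in counts.values() for t in c})
    mat = pd.DataFrame(
        {s: [counts[s].get(t, 0) for t in taxa] for s in samples},
        index=taxa,
        dtype=int,
    )
    return RankAbundance(rank, mat, pd.Series(unassigned, dtype=int))


class KmerClassifier:
    """Shared-k-mer read classifier against a set of reference genomes.

    A desk-scale classifier for synthetic communities: each read is scored
    by the number of its k-mers found in each reference (either strand),
    the best-scoring reference's taxon path is assigned, and the confidence
    is best / (best + runner-up) -- 1.0 when only one reference scores,
    0.5 on an exact tie.  Deterministic: ties break to the smallest
    reference id.
    """

    def __init__(self, references: Sequence[tuple[SequenceRecord, tuple]], k: int = 12):
        if not references:
            raise ValueError("no references")
        self.k = k
        self.ref_order = sorted(range(len(references)), key=lambda i: references[i][0].id)
        self.paths = [references[i][1] for i in self.ref_order]
        self.ids = [references[i][0].id for i in self.ref_order]
        self.index: dict[str, list[int]] = defaultdict(list)
        for pos, i in enumerate(self.ref_order):
            seq = references[i][0].seq
            kmers = set()
            for s in (seq, reverse_complement(seq)):
                for j in range(len(s) - k + 1):
                    kmers.add(s[j : j + k])
            for kmer in kmers:
                self.index[kmer].append(pos)

    def classify(self, read: SequenceRecord) -> TaxonAssignment:
        if self.k > len(read.seq):
            raise ValueError(f"k={self.k} larger than read {read.id} ({len(read.seq)} bp)")
        votes = [0] * len(self.paths)
        seq = read.seq
        k = self.k
        index = self.index
        for j in range(len(seq) - k + 1):
            for pos in index.get(seq[j : j + k], ()):
                votes[pos] += 1
        best_pos = max(range(len(votes)), key=lambda p: (votes[p], -p))
        best = votes[best_pos]
        if best == 0:
            return TaxonAssignment(read.id)
        runner = max((v for p, v in enumerate(votes) if p != best_pos), default=0)
        confidence = best / (best + runner) if (best + runner) else 0.0
        path = self.paths[best_pos]
        return TaxonAssignment(
            read.id,
            taxon_path=path,
            confidences=tuple([confidence] * len(path)),
        )

    def classify_all(self, reads: Iterable[SequenceRecord]) -> list[TaxonAssignment]:
        return [self.classify(r) for r in reads]


def naive_classifier(
    read: SequenceRecord,
    references: Sequence[tuple[SequenceRecord, tuple]],
    k: int = 12,
) -> TaxonAssignment:
    """One-shot convenience wrapper around :class:`KmerClassifier`."""
    return KmerClassifier(references, k=k).classify(read)
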