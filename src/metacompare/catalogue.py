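"""Non-redundant gene-catalogue construction and read-to-catalogue mapping.

Predicted ORFs are compared all-against-all; pairs exceeding an identity
threshold whose alignment covers most of the shorter gene are grouped, the
groups sharing genes are merged (single linkage), and the longest member
represents each merged group.  Representatives shorter than a length floor
are then discarded and the survivors translated with the bacterial/archaeal
genetic code (NCBI table 11).  Reads map back to the catalogue by best
identity above a cutoff with a minimum overlap length.

Pairwise identity is computed by a seed-and-extend scheme: a pair is only
aligned if the two sequences share at least one exact word of ``min_seed``
bases (in either orientation), after which a local alignment supplies the
identity over all alignment columns, gap columns counting as mismatch.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .io_formats import SequenceRecord

logger = logging.getLogger("metacompare")

_CODE_11 = CodonTable.unambiguous_dna_by_id[11]


@dataclass(frozen=True)
class GeneRecord:
    """A predicted ORF: nucleotide sequence plus provenance.

    ``complete`` flags ORFs bounded by a start and a stop codon; ``library``
    records the source sample.
    """

    id: str
    seq: str
    complete: bool = False
    library: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"gene {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PairwiseMatch:
    query: str
    subject: str
    identity: float  # percent in [0, 100]
    aligned_length: int  # alignment columns, gaps included
    coverage_shorter: float  # fraction of the shorter sequence spanned
    strand: str = "+"


@dataclass
class GeneCluster:
    members: frozenset
    representative: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty gene cluster")
        if self.representative not in self.members:
            raise ValueError("representative must be a cluster member")


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shares_seed(a: str, b: str, k: int) -> bool:
    """True iff the sequences share an exact k-mer in either orientation."""
    if len(a) < k or len(b) < k:
        return False
    ka = _kmer_set(a, k)
    if ka & _kmer_set(b, k):
        return True
    return bool(ka & _kmer_set(reverse_complement(b), k))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()

#: Extension reporting floor: after seeding, a pair whose banded edit
#: distance shows the shorter sequence cannot reach this identity (percent)
#: against the longer one is reported as no-match without a full alignment.
#: Well below every clustering/assignment threshold in use, so it only
#: prunes pairs that could never form an edge.
EXTENSION_FLOOR = 80.0


def _passes_screen(short_seq: str, long_seq: str) -> bool:
    """Cheap banded screen: can this pair possibly align near-identically?"""
    limit = int(len(short_seq) * (1.0 - EXTENSION_FLOOR / 100.0))
    for target in (long_seq, reverse_complement(long_seq)):
        res = edlib.align(short_seq, target, mode="HW", task="distance", k=limit)
        if res["editDistance"] != -1:
            return True
    return False


def _align_stats(short_seq: str, long_seq: str) -> tuple[float, float, int, float] | None:
    """Score, identity %, alignment columns and coverage of the shorter sequence."""
    alignments = _ALIGNER.align(short_seq, long_seq)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    sa, sb = aln[0], aln[1]
    columns = len(sa)
    matches = sum(
        1 for x, y in zip(sa, sb) if x == y and x != "-" and x != "N"
    )
    identity = 100.0 * matches / columns
    # span on the shorter sequence (first coordinate)
    blocks = aln.aligned[0]
    span = int(blocks[-1][1] - blocks[0][0])
    coverage = min(1.0, span / len(short_seq))
    return float(alignments.score), identity, columns, coverage


def pairwise_identity(
    a: SequenceRecord | GeneRecord,
    b: SequenceRecord | GeneRecord,
    min_seed: int = 11,
) -> PairwiseMatch | None:
    """Seed-and-extend identity between two nucleotide sequences.

    Returns ``None`` when the pair shares no exact ``min_seed``-mer in
    either orientation (no seed, no alignment), or when a banded screen
    shows the extension cannot reach :data:`EXTENSION_FLOOR` percent
    identity (extension failed).  Otherwise the shorter
    sequence is locally aligned against the longer one on both strands and
    the better-scoring orientation is kept.  Identity is matches divided by
    alignment columns (gap columns count as mismatch; N never matches), and
    coverage is the aligned span on the shorter sequence.  The result is
    symmetric under argument swap.
    """
    if min_seed < 8:
        raise ValueError("min_seed must be >= 8")
    if not a.seq or not b.seq:
        raise ValueError("empty sequence")
    # canonical orientation: shorter sequence is always the alignment query,
    # ties broken by id, so swap-symmetry holds exactly
    first, second = a, b
    if (len(a.seq), a.id) > (len(b.seq), b.id):
        first, second = b, a
    if not shares_seed(first.seq, second.seq, min_seed):
        return None
    if not _passes_screen(first.seq, second.seq):
        return None
    # the better orientation is the higher-scoring one (a short perfect
    # opposite-strand hit must not outrank a full-length true alignment)
    best = None
    for strand, target in (("+", second.seq), ("-", reverse_complement(second.seq))):
        stats = _align_stats(first.seq, target)
        if stats is None:
            continue
        score, identity, columns, coverage = stats
        key = (score, coverage, columns)
        if best is None or key > best[0]:
            best = (key, (identity, columns, coverage), strand)
    if best is None:
        return None
    (identity, columns, coverage), strand = best[1], best[2]
    return PairwiseMatch(
        query=a.id,
        subject=b.id,
        identity=identity,
        aligned_length=columns,
        coverage_shorter=coverage,
        strand=strand,
    )


class _DisjointSet:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _candidate_pairs(genes: Sequence[GeneRecord], min_seed: int):
    """Pairs sharing at least one k-mer (either orientation), via an index."""
    index: dict[str, list[int]] = defaultdict(list)
    for i, g in enumerate(genes):
        seen = set()
        for kmer in _kmer_set(g.seq, min_seed):
            if kmer not in seen:
                index[kmer].append(i)
                seen.add(kmer)
    pairs: set[tuple[int, int]] = set()
    for i, g in enumerate(genes):
        kmers = _kmer_set(g.seq, min_seed) | _kmer_set(reverse_complement(g.seq), min_seed)
        for kmer in kmers:
            for j in index.get(kmer, ()):
                if j != i:
                    pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


def build_gene_groups(
    genes: Sequence[GeneRecord],
    id_threshold: float = 95.0,
    cov_threshold: float = 0.90,
    min_seed: int = 11,
    inclusive: bool = False,
    min_overlap_bp: int | None = None,
) -> list[GeneCluster]:
    """Single-linkage clustering of genes by pairwise identity.

    An edge joins two genes when identity and coverage of the shorter gene
    exceed their thresholds (strictly by default, matching "greater than
    95%" / "over 90%"); clusters are the connected components, so groups
    sharing genes merge transitively.  Passing ``inclusive=True`` together
    with ``min_overlap_bp`` switches to the contig-set variant, where the
    comparisons are inclusive and the overlap requirement is an absolute
    aligned length ("90% identity and at least 30 bp overlap") instead of a
    coverage fraction.

    The result is deterministic and independent of input order: members are
    sorted and clusters ordered by their smallest member id.
    """
    ids = [g.id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("gene ids must be unique")
    by_id = {g.id: g for g in genes}
    dsu = _DisjointSet(ids)
    n_edges = 0
    for i, j in _candidate_pairs(list(genes), min_seed):
        match = pairwise_identity(genes[i], genes[j], min_seed=min_seed)
        if match is None:
            continue
        if inclusive:
            id_ok = match.identity >= id_threshold
            ov_ok = (
                match.aligned_length >= min_overlap_bp
                if min_overlap_bp is not None
                else match.coverage_shorter >= cov_threshold
            )
        else:
            id_ok = match.identity > id_threshold
            ov_ok = (
                match.aligned_length > min_overlap_bp
                if min_overlap_bp is not None
                else match.coverage_shorter > cov_threshold
            )
        if id_ok and ov_ok:
            dsu.union(genes[i].id, genes[j].id)
            n_edges += 1
    components: dict[str, set[str]] = defaultdict(set)
    for gid in ids:
        components[dsu.find(gid)].add(gid)
    clusters = []
    for root in sorted(components, key=lambda r: min(components[r])):
        members = components[root]
        rep = _longest_member(members, by_id)
        clusters.append(GeneCluster(frozenset(members), rep))
    logger.info("clustered %d genes into %d groups (%d edges)", len(ids), len(clusters), n_edges)
    return clusters


def _longest_member(members: Iterable[str], by_id: Mapping[str, GeneRecord]) -> str:
    return min(members, key=lambda gid: (-by_id[gid].length, gid))


def select_representatives(
    clusters: Sequence[GeneCluster],
    genes: Sequence[GeneRecord] | Mapping[str, GeneRecord],
    min_length: int = 100,
) -> tuple[list[GeneRecord], dict]:
    """Pick the longest member of each cluster, then apply the length floor.

    Ties on length break to the lexicographically smallest id.  The
    ``min_length`` filter runs after representative selection ("less than
    100 bp" are removed, so exactly 100 bp survives).  Returns the
    non-redundant gene set plus redundancy statistics.
    """
    by_id = genes if isinstance(genes, Mapping) else {g.id: g for g in genes}
    reps: list[GeneRecord] = []
    for cluster in clusters:
        if not cluster.members:
            raise ValueError("empty cluster")
        rep_id = _longest_member(cluster.members, by_id)
        reps.append(by_id[rep_id])
    retained = [r for r in reps if r.length >= min_length]
    retained.sort(key=lambda g: g.id)
    n_complete = sum(1 for r in retained if r.complete)
    stats = {
        "n_input_genes": sum(len(c.members) for c in clusters),
        "n_clusters": len(clusters),
        "n_representatives": len(retained),
        "n_length_filtered": len(reps) - len(retained),
        "pct_complete": 100.0 * n_complete / len(retained) if retained else 0.0,
    }
    return retained, stats


def translate_cds(seq: str, is_gene_start: bool = False) -> str:
    """Translate a coding sequence with NCBI genetic code 11.

    A trailing stop codon is removed; internal stops are retained as "*"
    with a warning (a fragmental or frameshifted ORF); codons containing N
    translate to "X".  When ``is_gene_start`` is set and the first codon is
    one of table 11's alternative initiators (GTG, TTG, ...), it is
    translated as M, as an initiator tRNA would read it.  Trailing leftover
    bases (length not a multiple of 3) are ignored with a warning.
    """
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if len(seq) % 3:
        warnings.warn(f"ignoring {len(seq) % 3} trailing bases beyond the last full codon")
        seq = seq[: len(seq) - len(seq) % 3]
    aas = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in _CODE_11.stop_codons:
            aas.append("*")
        else:
            aas.append(_CODE_11.forward_table[codon])
    if is_gene_start and seq[:3] in _CODE_11.start_codons:
        aas[0] = "M"
    if aas and aas[-1] == "*":
        aas.pop()
    protein = "".join(aas)
    if "*" in protein:
        warnings.warn("internal stop codon retained in translation")
    return protein


@dataclass
class ReadMappingResult:
    """Outcome of mapping reads against a gene catalogue."""

    assignments: dict  # read id -> gene id (assigned reads only)
    assigned_fraction: dict  # sample -> fraction of its reads assigned
    gene_counts: pd.DataFrame  # genes x samples read counts


def map_reads_to_catalogue(
    reads: Mapping[str, Sequence[SequenceRecord]] | Sequence[SequenceRecord],
    catalogue: Sequence[GeneRecord | SequenceRecord],
    id_threshold: float = 95.0,
    min_overlap: int = 100,
    min_seed: int = 11,
) -> ReadMappingResult:
    """Assign each read to its best-identity catalogue gene.

    A read is assigned to the gene with the highest identity among hits
    with identity >= ``id_threshold`` and aligned length > ``min_overlap``
    (identity inclusive, overlap strict, mirroring "cutoff of 95% sequence
    identity and > 100 bp overlap"); identity ties break to the longer
    overlap, then the smallest gene id.  ``reads`` may be a flat list (one
    unnamed sample) or a mapping sample -> reads, which supports
    cross-catalogue runs (reads of one host against the other's catalogue).
    """
    if not catalogue:
        raise ValueError("catalogue is empty")
    if not isinstance(reads, Mapping):
        reads = {"sample": list(reads)}
    min_read = min((len(r.seq) for rs in reads.values() for r in rs), default=None)
    if min_read is None:
        raise ValueError("no reads supplied")
    if min_overlap > min_read:
        raise ValueError(f"min_overlap {min_overlap} longer than shortest read ({min_read} bp)")

    index: dict[str, set[str]] = defaultdict(set)
    by_id: dict[str, GeneRecord | SequenceRecord] = {}
    for gene in catalogue:
        by_id[gene.id] = gene
        for kmer in _kmer_set(gene.seq, min_seed) | _kmer_set(reverse_complement(gene.seq), min_seed):
            index[kmer].add(gene.id)

    assignments: dict[str, str] = {}
    assigned_fraction: dict[str, float] = {}
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for sample, sample_reads in reads.items():
        n_assigned = 0
        for read in sample_reads:
            candidates: set[str] = set()
            for kmer in _kmer_set(read.seq, min_seed):
                candidates |= index.get(kmer, set())
            best = None
            for gid in sorted(candidates):
                match = pairwise_identity(read, by_id[gid], min_seed=min_seed)
                if match is None:
                    continue
                if match.identity >= id_threshold and match.aligned_length > min_overlap:
                    key = (-match.identity, -match.aligned_length, gid)
                    if best is None or key < best[0]:
                        best = (key, gid)
            if best is not None:
                gid = best[1]
                assignments[read.id] = gid
                counts[gid][sample] += 1
                n_assigned += 1
        assigned_fraction[sample] = n_assigned / len(sample_reads) if sample_reads else 0.0
        logger.info("sample %s: %d/%d reads assigned", sample, n_assigned, len(sample_reads))

    gene_ids = sorted(by_id)
    samples = list(reads)
    mat = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=int)
    for gid, per_sample in counts.items():
        for sample, n in per_sample.items():
            mat.loc[gid, sample] = n
    return ReadMappingResult(assignments, assigned_fraction, mat)


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    """Cluster membership as a TSV-ready frame (gene_id, cluster_id, is_representative)."""
    rows = []
    for ci, cluster in enumerate(clusters):
        for gid in sorted(cluster.members):
            rows.append(
                {
                    "gene_id": gid,
                    "cluster_id": f"cluster_{ci:06d}",
                    "is_representative": gid == cluster.representative,
                }
            )
    return pd.DataFrame(rows)
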