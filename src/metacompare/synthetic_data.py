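"""Synthetic two-host metagenome generator.

Emulates the statistical structure of a pooled-library comparative study:
one host group of 60 individuals pooled into 8 sequencing libraries of 7-8
individuals each, against a second group of single-individual samples.
Per-individual taxon abundances vary log-normally around group base
profiles, libraries average their members, and reads are drawn from
synthetic reference genomes with i.i.d. substitution errors.  Ground-truth
tables (read -> taxon / gene / ortholog group) accompany every output so
that classification accuracy, planted cluster counts and unassigned
fractions can be checked exactly.

The ``table1_preset`` builds a community whose group base abundances are
proportional to the published phylum-abundance pairs of the two hosts, so
differential-abundance runs on synthetic data face contrasts of realistic
magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import GeneRecord
from .io_formats import SequenceRecord

logger = logging.getLogger("metacompare")

_BASES = np.frombuffer(b"ACGT", dtype="S1")

GUINEA_PIG = "guinea_pig"
HUMAN = "human"
#: 60 individuals pooled into 8 libraries of 7 or 8
DEFAULT_POOLING = (8, 8, 8, 8, 7, 7, 7, 7)


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: taxon path and per-group base abundance."""

    name: str
    path: tuple  # phylum -> species path (any depth)
    abundance: Mapping[str, float]  # group -> base relative abundance
    sigma: float = 0.3  # log-normal inter-individual dispersion

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0 for taxon {self.name}")


@dataclass
class CommunitySpec:
    """Study design: taxa, group sizes, pooling, and sequencing parameters."""

    taxa: list
    groups: tuple = (GUINEA_PIG, HUMAN)
    n_individuals: Mapping[str, int] = field(
        default_factory=lambda: {GUINEA_PIG: 60, HUMAN: 124}
    )
    pooling: Mapping[str, tuple | None] = field(
        default_factory=lambda: {GUINEA_PIG: DEFAULT_POOLING, HUMAN: None}
    )
    reads_per_library: int = 5000
    read_length: int = 75
    error_rate: float = 0.01
    genome_length: int = 50_000

    def __post_init__(self) -> None:
        for group in self.groups:
            total = sum(t.abundance[group] for t in self.taxa)
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"group {group!r} base abundances sum to {total}, not 1")
            sizes = self.pooling.get(group)
            if sizes is not None and sum(sizes) != self.n_individuals[group]:
                raise ValueError(
                    f"pooling sizes {sizes} do not partition the "
                    f"{self.n_individuals[group]} individuals of group {group!r}"
                )

    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    def base_profile(self, group: str) -> pd.Series:
        return pd.Series({t.name: t.abundance[group] for t in self.taxa})

    def n_libraries(self, group: str) -> int:
        sizes = self.pooling.get(group)
        return len(sizes) if sizes is not None else self.n_individuals[group]


def sample_individuals(
    spec: CommunitySpec, group: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-individual taxon abundance vectors (taxa x individuals).

    abundance_i = base * exp(N(0, sigma)), renormalized to sum 1 per
    individual.  sigma = 0 reproduces the group base profile exactly.
    """
    n = spec.n_individuals[group]
    base = spec.base_profile(group).values[:, None]
    sigmas = np.array([t.sigma for t in spec.taxa])[:, None]
    noise = np.exp(rng.normal(0.0, 1.0, size=(len(spec.taxa), n)) * sigmas)
    raw = base * noise
    raw /= raw.sum(axis=0, keepdims=True)
    cols = [f"{group}_ind{i:03d}" for i in range(n)]
    return pd.DataFrame(raw, index=spec.taxon_names(), columns=cols)


def pool_libraries(
    individuals: pd.DataFrame, sizes: Sequence[int] | None, group: str = "lib"
) -> pd.DataFrame:
    """Pool individual vectors into library vectors (unweighted mean).

    ``sizes`` must partition the individuals in column order; ``None``
    keeps every individual as its own single-sample library.
    """
    if sizes is None:
        out = individuals.copy()
        out.columns = [f"{group}_s{i:03d}" for i in range(individuals.shape[1])]
        return out
    if sum(sizes) != individuals.shape[1]:
        raise ValueError(
            f"pooling sizes sum to {sum(sizes)} but there are {individuals.shape[1]} individuals"
        )
    vectors = {}
    start = 0
    for i, size in enumerate(sizes):
        block = individuals.iloc[:, start : start + size]
        vectors[f"{group}_lib{i:02d}"] = block.mean(axis=1)
        start += size
    return pd.DataFrame(vectors)


def random_genome(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at ``rate``; substituted bases always change."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = lut[codes]
    mask = rng.random(len(codes)) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    idx[mask] = (idx[mask] + shift) % 4
    return _BASES[idx].tobytes().decode()


@dataclass
class ReferenceSet:
    """Synthetic genomes with planted gene loci and ortholog labels."""

    genomes: dict  # taxon name -> SequenceRecord
    taxon_paths: dict  # taxon name -> rank path tuple
    genes: list  # GeneRecord, ids unique across genomes
    gene_truth: pd.DataFrame  # gene_id, taxon, start, end, ortholog (or "")

    def references(self) -> list[tuple[SequenceRecord, tuple]]:
        """(genome, taxon path) pairs, classifier-ready."""
        return [(self.genomes[t], self.taxon_paths[t]) for t in sorted(self.genomes)]


def make_reference_set(
    spec: CommunitySpec,
    rng: np.random.Generator,
    genes_per_genome: int = 8,
    gene_length: int = 600,
    unannotatable_fraction: float = 0.0,
) -> ReferenceSet:
    """One random genome per taxon with non-overlapping planted gene loci.

    Each gene locus carries an ortholog-group label (``KO``-style) unless it
    is drawn as unannotatable, supporting planted-truth checks of the
    functional-annotation stage.
    """
    genomes, paths, genes, rows = {}, {}, [], []
    stride = spec.genome_length // max(genes_per_genome, 1)
    if gene_length >= stride:
        raise ValueError("gene loci would overlap; lower genes_per_genome or gene_length")
    ko_counter = 0
    for t in spec.taxa:
        seq = random_genome(spec.genome_length, rng)
        genomes[t.name] = SequenceRecord(f"genome_{t.name}", seq)
        paths[t.name] = t.path
        for gi in range(genes_per_genome):
            start = gi * stride + int(rng.integers(0, stride - gene_length))
            end = start + gene_length
            gid = f"{t.name}_g{gi:03d}"
            genes.append(GeneRecord(gid, seq[start:end], complete=True, library=t.name))
            if rng.random() < unannotatable_fraction:
                ortholog = ""
            else:
                ortholog = f"KO{ko_counter:05d}"
                ko_counter += 1
            rows.append(
                {"gene_id": gid, "taxon": t.name, "start": start, "end": end,
                 "ortholog": ortholog}
            )
    return ReferenceSet(genomes, paths, genes, pd.DataFrame(rows))


def generate_reads(
    library_vector: pd.Series,
    refs: ReferenceSet,
    spec: CommunitySpec,
    rng: np.random.Generator,
    library_id: str = "lib",
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Draw error-bearing reads from reference genomes for one library.

    Source taxa follow a multinomial on the library abundance vector, start
    positions are uniform, and substitution errors are i.i.d. at the spec
    rate.  Returns the reads and a ground-truth frame with each read's
    source taxon, position and (when the read lies fully inside a planted
    locus) gene and ortholog group.
    """
    n, L = spec.reads_per_library, spec.read_length
    if n < 1:
        raise ValueError("reads_per_library must be >= 1")
    probs = library_vector / library_vector.sum()
    counts = rng.multinomial(n, probs.values)
    reads: list[SequenceRecord] = []
    truth_rows = []
    rid = 0
    for taxon, c in zip(probs.index, counts):
        if c == 0:
            continue
        genome = refs.genomes[taxon].seq
        if L > len(genome):
            raise ValueError(f"read length {L} exceeds genome of {taxon}")
        codes = np.frombuffer(genome.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        idx_genome = lut[codes]
        starts = rng.integers(0, len(genome) - L + 1, size=c)
        block = idx_genome[starts[:, None] + np.arange(L)[None, :]]
        if spec.error_rate > 0:
            mask = rng.random(block.shape) < spec.error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()))
            block[mask] = (block[mask] + shift) % 4
        # locate reads fully inside planted gene loci (loci are sorted and
        # non-overlapping, so a searchsorted suffices)
        loci = refs.gene_truth[refs.gene_truth["taxon"] == taxon].sort_values("start")
        lo_start = loci["start"].to_numpy()
        lo_end = loci["end"].to_numpy()
        lo_gene = loci["gene_id"].to_numpy()
        lo_ko = loci["ortholog"].to_numpy()
        pos = np.searchsorted(lo_start, starts, side="right") - 1
        pos_ok = pos >= 0
        inside = pos_ok & (starts + L <= lo_end[np.maximum(pos, 0)]) if len(loci) else np.zeros(c, bool)
        seqs = [_BASES[row].tobytes().decode() for row in block]
        for i, (seq, start) in enumerate(zip(seqs, starts)):
            read_id = f"{library_id}_r{rid:06d}"
            rid += 1
            reads.append(SequenceRecord(read_id, seq))
            hit = bool(inside[i])
            truth_rows.append(
                {"read_id": read_id, "taxon": taxon, "start": int(start),
                 "gene_id": lo_gene[pos[i]] if hit else "",
                 "ortholog": lo_ko[pos[i]] if hit else ""}
            )
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def make_redundant_gene_set(
    n_genes: int = 1000,
    duplicate_fraction: float = 0.2,
    length_range: tuple = (300, 600),
    exact_fraction: float = 0.5,
    copy_identity: float = 0.98,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneRecord], dict]:
    """Gene set with planted redundancy for catalogue tests.

    ``duplicate_fraction`` of the output genes are copies of distinct
    originals -- exact duplicates with probability ``exact_fraction``,
    otherwise high-identity copies (substitutions at 1 - ``copy_identity``,
    still clustering with their original at the >95%/90% rule).  Returns
    the genes plus the planted gene -> cluster-index truth; the number of
    planted clusters is ``n_genes - round(n_genes * duplicate_fraction)``.
    """
    rng = rng or np.random.default_rng(0)
    n_dup = int(round(n_genes * duplicate_fraction))
    n_orig = n_genes - n_dup
    if n_dup > n_orig:
        raise ValueError("duplicate_fraction too high: more copies than originals")
    genes: list[GeneRecord] = []
    truth: dict[str, int] = {}
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_orig)
    for i in range(n_orig):
        gid = f"orig_{i:05d}"
        genes.append(GeneRecord(gid, random_genome(int(lengths[i]), rng)))
        truth[gid] = i
    donors = rng.choice(n_orig, size=n_dup, replace=False)
    for j, donor in enumerate(donors):
        gid = f"dup_{j:05d}"
        src = genes[donor].seq
        if rng.random() < exact_fraction:
            seq = src
        else:
            seq = mutate(src, 1.0 - copy_identity, rng)
        genes.append(GeneRecord(gid, seq))
        truth[gid] = int(donor)
    order = rng.permutation(len(genes))
    genes = [genes[i] for i in order]
    return genes, truth


def make_ortholog_hits(
    gene_ids: Sequence[str],
    unannotatable_fraction: float = 0.4,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, set]:
    """Fabricate a protein-search hit table with planted annotatability.

    Annotatable genes receive one strong hit (e-value well under 1e-5) and
    one decoy above the cutoff; unannotatable genes get only the decoy.
    Returns the hit frame and the planted set of unannotatable gene ids.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    unannotatable: set = set()
    for i, gid in enumerate(gene_ids):
        decoy_e = 10.0 ** rng.uniform(-4.5, -1.0)
        rows.append({"gene_id": gid, "group_id": f"KOdecoy{i:05d}",
                     "evalue": decoy_e, "bitscore": 30.0})
        if rng.random() < unannotatable_fraction:
            unannotatable.add(gid)
        else:
            good_e = 10.0 ** rng.uniform(-30.0, -6.0)
            rows.append({"gene_id": gid, "group_id": f"KO{i:05d}",
                         "evalue": good_e, "bitscore": 200.0})
    return pd.DataFrame(rows), unannotatable


def load_table1() -> pd.DataFrame:
    """The published phylum-level comparison table shipped with the package.

    Columns: taxon, per-host mean and SD of relative abundance (percent),
    raw p-value and BH q-value as printed.  The "Unclassified" row is the
    explicit unassigned-read pseudo-taxon.
    """
    with resources.files("metacompare.data").joinpath("table1_phyla.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def table1_preset(
    n_human: int = 20,
    reads_per_library: int = 1000,
    sigma: float | None = None,
    read_length: int = 75,
    error_rate: float = 0.01,
    genome_length: int = 50_000,
) -> CommunitySpec:
    """Community spec shaped like the published two-host phylum contrast.

    Base abundances per group are the published per-host phylum means
    (named taxa only -- the unclassified fraction re-emerges downstream
    from classification, not from the community), renormalized to sum 1.
    With ``sigma=None`` the per-taxon dispersion is calibrated from the
    single-individual host group's SD/mean ratio via the log-normal CV
    relation sigma = sqrt(log(1 + cv^2)), capped at 1; passing a number
    fixes one dispersion for all taxa (e.g. a reduced-dispersion power
    run).  ``n_human`` defaults to a desk-scale 20 single-individual
    samples (the study compared against 124).
    """
    table = load_table1()
    table = table[table["taxon"] != "Unclassified"].reset_index(drop=True)
    gp = table["mean_guinea_pig"] / table["mean_guinea_pig"].sum()
    hu = table["mean_human"] / table["mean_human"].sum()
    taxa = []
    for i, row in table.iterrows():
        if sigma is None:
            cv = row["sd_human"] / row["mean_human"]
            s = min(float(np.sqrt(np.log1p(cv * cv))), 1.0)
        else:
            s = sigma
        taxa.append(
            TaxonSpec(
                name=row["taxon"],
                path=(row["taxon"],),
                abundance={GUINEA_PIG: float(gp[i]), HUMAN: float(hu[i])},
                sigma=s,
            )
        )
    return CommunitySpec(
        taxa=taxa,
        n_individuals={GUINEA_PIG: 60, HUMAN: n_human},
        pooling={GUINEA_PIG: DEFAULT_POOLING, HUMAN: None},
        reads_per_library=reads_per_library,
        read_length=read_length,
        error_rate=error_rate,
        genome_length=genome_length,
    )
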