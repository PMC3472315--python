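"""End-to-end synthetic study driver.

Wires the stages together for a two-host comparison on generated data:
sample individuals -> pool libraries -> draw reads -> classify ->
rank-abundance matrix (with the unassigned fraction carried as an explicit
"Unclassified" row) -> depth normalization -> Wilcoxon + BH differential
table, plus Bray-Curtis group separation on the log-transformed matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .diffstats import count_significant, differential_table
from .ecology import AbundanceMatrix, bray_curtis, group_separation, log_transform, normalize
from .taxonomy import KmerClassifier, build_rank_abundance, filter_by_confidence

logger = logging.getLogger("metacompare")


def build_sample_counts(
    spec: sd.CommunitySpec,
    refs: sd.ReferenceSet,
    classifier: KmerClassifier,
    rng: np.random.Generator,
    rank: str = "phylum",
    confidence_cutoff: float = 0.7,
):
    """Generate reads for every library of every group and classify them."""
    per_sample = {}
    groups = {}
    for group in spec.groups:
        individuals = sd.sample_individuals(spec, group, rng)
        libraries = sd.pool_libraries(individuals, spec.pooling.get(group), group=group)
        for lib in libraries.columns:
            reads, _truth = sd.generate_reads(libraries[lib], refs, spec, rng, library_id=lib)
            assigned = classifier.classify_all(reads)
            filtered = filter_by_confidence(assigned, cutoff=confidence_cutoff)
            per_sample[lib] = list(filtered.values())
            groups[lib] = group
    rank_ab = build_rank_abundance(per_sample, rank)
    return rank_ab, pd.Series(groups)


def run_synthetic_comparison(
    spec: sd.CommunitySpec,
    seed: int = 0,
    refs: sd.ReferenceSet | None = None,
    classifier: KmerClassifier | None = None,
    rank: str = "phylum",
    confidence_cutoff: float = 0.7,
    family_size: int | None = None,
) -> dict:
    """One full synthetic two-group comparison.

    Returns the differential table, significance counts and Bray-Curtis
    within/between-group separation.  A prebuilt reference set and
    classifier may be passed to amortize index construction over repeated
    runs with different community seeds.
    """
    rng = np.random.default_rng(seed)
    if refs is None:
        refs = sd.make_reference_set(spec, np.random.default_rng(2**20 + 11))
    if classifier is None:
        classifier = KmerClassifier(refs.references())
    rank_ab, groups = build_sample_counts(
        spec, refs, classifier, rng, rank=rank, confidence_cutoff=confidence_cutoff
    )
    counts = AbundanceMatrix(rank_ab.to_matrix("with_unclassified"), groups, raw=True)
    normalized = normalize(counts)
    table = differential_table(normalized, family_size=family_size)
    dist = bray_curtis(log_transform(normalized))
    sep = group_separation(dist, groups)
    return {
        "rank_abundance": rank_ab,
        "counts": counts,
        "normalized": normalized,
        "table": table,
        "significance": count_significant(table),
        "separation": sep,
        "distance": dist,
    }
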