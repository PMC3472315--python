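"""Ortholog-group assignment and hierarchical category aggregation.

Genes receive the ortholog group (KO / NOG) of their best protein-search
hit at an e-value cutoff (inclusive at 1e-5).  Group abundances roll up
into higher-order categories (COG categories, KEGG subcategories, SEED
families, MetaCyc pathways); a group mapped to several categories is split
evenly among them, and groups missing from a mapping fall into an explicit
"unmapped" bucket so that total mass is conserved and database-coverage
bias stays visible.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("metacompare")

UNMAPPED = "unmapped"


def assign_best_ortholog(
    hits: pd.DataFrame,
    evalue_cutoff: float = 1e-5,
) -> dict:
    """Best-hit ortholog group per gene.

    ``hits`` needs columns gene_id, group_id, evalue and optionally
    bitscore.  Hits with e-value <= ``evalue_cutoff`` (inclusive) compete;
    the winner has the smallest e-value, ties broken by larger bit-score
    then smaller group id.  Genes with no passing hit are absent from the
    returned mapping (i.e. unassigned).
    """
    required = {"gene_id", "group_id", "evalue"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    if (hits["evalue"] < 0).any():
        raise ValueError("negative e-value")
    passing = hits[hits["evalue"] <= evalue_cutoff].copy()
    if "bitscore" not in passing.columns:
        passing["bitscore"] = 0.0
    passing = passing.sort_values(
        ["evalue", "bitscore", "group_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    best = passing.drop_duplicates("gene_id", keep="first")
    return dict(zip(best["gene_id"].astype(str), best["group_id"].astype(str)))


def aggregate_categories(
    og_abundance: pd.DataFrame,
    category_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Roll ortholog-group abundances up into categories with even splitting.

    Each group's abundance is divided equally among the categories it maps
    to, then summed per category and sample.  Groups absent from the map
    contribute to the ``unmapped`` row.  Column totals are conserved:
    categories + unmapped == input total, per sample.
    """
    if (og_abundance.values < 0).any():
        raise ValueError("negative abundance")
    categories = sorted({c for cats in category_map.values() for c in cats})
    out = pd.DataFrame(
        0.0, index=categories + [UNMAPPED], columns=og_abundance.columns
    )
    for group in og_abundance.index:
        row = og_abundance.loc[group]
        cats = list(category_map.get(str(group), []))
        if str(group) in category_map and not cats:
            raise ValueError(f"group {group} mapped to an empty category set")
        if not cats:
            out.loc[UNMAPPED] += row
        else:
            share = row / len(cats)
            for c in cats:
                out.loc[c] += share
    return out


def compose_maps(
    lower: Mapping[str, Iterable[str]], upper: Mapping[str, Iterable[str]]
) -> dict:
    """Compose two hierarchy levels into a direct group -> top-category map.

    The composed weight of a top category is implicit in even splitting at
    each level; composition here keeps the category *set* so that direct
    aggregation with the composed map matches two-step aggregation only
    when each mid-level category maps to equally many top categories --
    callers verifying functoriality should aggregate stepwise.
    """
    out: dict[str, list] = {}
    for group, mids in lower.items():
        tops: list = []
        for mid in mids:
            tops.extend(upper.get(mid, [UNMAPPED]))
        out[group] = tops
    return out


def unassigned_fraction(
    assigned: Mapping[str, int] | pd.Series,
    universe: Mapping[str, int] | pd.Series,
) -> pd.Series:
    """Per-sample fraction of reads/genes not assigned at some database tier.

    (universe - assigned) / universe, sample-wise.  ``assigned`` may omit
    samples (treated as zero assigned).
    """
    uni = pd.Series(universe, dtype=float)
    if (uni == 0).any():
        raise ValueError(f"zero universe for sample {uni.index[uni == 0][0]}")
    ass = pd.Series(assigned, dtype=float).reindex(uni.index).fillna(0.0)
    if (ass > uni).any():
        raise ValueError("assigned count exceeds universe")
    return (uni - ass) / uni
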