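import numpy as np
import pytest

from metacompare.catalogue import (
    GeneCluster,
    GeneRecord,
    build_gene_groups,
    map_reads_to_catalogue,
    pairwise_identity,
    select_representatives,
    shares_seed,
    translate_cds,
)
from metacompare.io_formats import SequenceRecord
from metacompare.synthetic_data import make_redundant_gene_set, mutate, random_genome


def substitute(seq, positions, rng):
    """Substitute the given positions with a guaranteed-different base."""
    bases = "ACGT"
    out = list(seq)
    for pos in positions:
        out[pos] = bases[(bases.index(seq[pos]) + 1) % 4]
    return "".join(out)


def brute_force_clusters(genes, id_threshold=95.0, cov_threshold=0.90):
    """Independent oracle: all-pairs alignment + naive union-find."""
    parent = {g.id: g.id for g in genes}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            m = pairwise_identity(genes[i], genes[j])
            if m and m.identity > id_threshold and m.coverage_shorter > cov_threshold:
                ri, rj = find(genes[i].id), find(genes[j].id)
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for g in genes:
        groups.setdefault(find(g.id), set()).add(g.id)
    return {frozenset(v) for v in groups.values()}


def random_instance(rng, n_min=10, n_max=50):
    """Random gene set with planted copies, chains and unrelated genes."""
    n = int(rng.integers(n_min, n_max + 1))
    genes = [GeneRecord("g000", random_genome(int(rng.integers(150, 400)), rng))]
    for i in range(1, n):
        roll = rng.random()
        if roll < 0.5:  # unrelated
            seq = random_genome(int(rng.integers(150, 400)), rng)
        else:  # copy of a random earlier gene, sometimes near the threshold
            src = genes[int(rng.integers(0, len(genes)))].seq
            rate = rng.choice([0.0, 0.01, 0.03, 0.06, 0.12])
            seq = mutate(src, rate, rng)
        genes.append(GeneRecord(f"g{i:03d}", seq))
    return genes


class TestPairwiseIdentity:
    def test_self_match_is_perfect(self, rng):
        a = SequenceRecord("a", random_genome(200, rng))
        m = pairwise_identity(a, a)
        assert m.identity == 100.0
        assert m.coverage_shorter == 1.0

    def test_single_substitution_in_100mer(self, rng):
        s = random_genome(100, rng)
        m = pairwise_identity(
            SequenceRecord("x", s), SequenceRecord("y", substitute(s, [50], rng))
        )
        assert m.identity == pytest.approx(99.0)
        assert m.coverage_shorter == 1.0

    def test_random_pair_has_no_shared_seed_hence_no_match(self):
        a = SequenceRecord("a", random_genome(100, np.random.default_rng(1)))
        b = SequenceRecord("b", random_genome(100, np.random.default_rng(2)))
        # oracle: exhaustively confirm no 11-mer is shared in either orientation
        assert not shares_seed(a.seq, b.seq, 11)
        assert pairwise_identity(a, b, min_seed=11) is None

    def test_symmetric_under_swap(self, rng):
        s = random_genome(300, rng)
        a = SequenceRecord("a", s)
        b = SequenceRecord("b", mutate(s[:250], 0.02, rng))
        mab, mba = pairwise_identity(a, b), pairwise_identity(b, a)
        assert mab.identity == mba.identity
        assert mab.coverage_shorter == mba.coverage_shorter

    def test_reverse_complement_copy_is_found(self, rng):
        from Bio.Seq import reverse_complement

        s = random_genome(300, rng)
        m = pairwise_identity(
            SequenceRecord("f", s), SequenceRecord("r", reverse_complement(s))
        )
        assert m is not None and m.identity == 100.0 and m.strand == "-"

    def test_min_seed_floor(self, rng):
        a = SequenceRecord("a", random_genome(50, rng))
        with pytest.raises(ValueError, match="min_seed"):
            pairwise_identity(a, a, min_seed=4)


class TestBuildGeneGroups:
    def test_identical_pair_clusters_unrelated_stays_apart(self, rng):
        s = random_genome(300, rng)
        genes = [
            GeneRecord("A", s),
            GeneRecord("B", s),
            GeneRecord("C", random_genome(300, rng)),
        ]
        clusters = {frozenset(c.members) for c in build_gene_groups(genes)}
        assert clusters == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_groups_sharing_genes_merge_transitively(self, rng):
        # A and C overlap B from opposite ends; A-C share only 100/250 bp,
        # failing the coverage rule, yet all three merge through B
        b = random_genome(400, rng)
        genes = [
            GeneRecord("A", b[:250]),
            GeneRecord("B", b),
            GeneRecord("C", b[150:]),
        ]
        ac = pairwise_identity(genes[0], genes[2])
        assert ac is None or ac.coverage_shorter <= 0.9  # A-C alone is no edge
        clusters = build_gene_groups(genes)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset({"A", "B", "C"})

    def test_identity_exactly_95_is_excluded_by_strict_rule(self, rng):
        s = random_genome(100, rng)
        s5 = substitute(s, [20, 35, 50, 65, 80], rng)
        m = pairwise_identity(SequenceRecord("x", s), SequenceRecord("y", s5))
        assert m.identity == pytest.approx(95.0)
        genes = [GeneRecord("x", s), GeneRecord("y", s5)]
        strict = build_gene_groups(genes, id_threshold=95.0, cov_threshold=0.5)
        assert len(strict) == 2
        inclusive = build_gene_groups(genes, id_threshold=95.0, cov_threshold=0.5, inclusive=True)
        assert len(inclusive) == 1

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            genes = random_instance(rng, n_min=8, n_max=25)
            ours = {frozenset(c.members) for c in build_gene_groups(genes)}
            assert ours == brute_force_clusters(genes)

    def test_deterministic_under_input_shuffle(self, rng):
        genes = random_instance(rng, n_min=15, n_max=25)
        a = build_gene_groups(genes)
        shuffled = [genes[i] for i in rng.permutation(len(genes))]
        b = build_gene_groups(shuffled)
        assert [(c.members, c.representative) for c in a] == [
            (c.members, c.representative) for c in b
        ]

    def test_cluster_count_monotone_in_identity_threshold(self, rng):
        genes, _ = make_redundant_gene_set(
            60, 0.3, exact_fraction=0.3, copy_identity=0.97, rng=rng
        )
        counts = [
            len(build_gene_groups(genes, id_threshold=t)) for t in (99.0, 97.0, 95.0, 90.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_clusters_partition_the_input(self, rng):
        genes = random_instance(rng)
        clusters = build_gene_groups(genes)
        member_union = sorted(g for c in clusters for g in c.members)
        assert member_union == sorted(g.id for g in genes)

    def test_duplicate_ids_rejected(self, rng):
        g = GeneRecord("a", random_genome(100, rng))
        with pytest.raises(ValueError, match="unique"):
            build_gene_groups([g, g])


class TestSelectRepresentatives:
    def test_longest_wins_ties_break_to_smallest_id(self, rng):
        genes = [
            GeneRecord("x", random_genome(250, rng)),
            GeneRecord("b", random_genome(300, rng)),
            GeneRecord("a", random_genome(300, rng)),
        ]
        clusters = [GeneCluster(frozenset("xba"), "a")]
        reps, _ = select_representatives(clusters, genes, min_length=100)
        assert [r.id for r in reps] == ["a"]

    def test_length_filter_keeps_exactly_100bp(self, rng):
        genes = [
            GeneRecord(f"g{i}", random_genome(n, rng))
            for i, n in enumerate([99, 100, 150])
        ]
        clusters = [GeneCluster(frozenset({g.id}), g.id) for g in genes]
        reps, stats = select_representatives(clusters, genes, min_length=100)
        assert len(reps) == 2
        assert stats["n_length_filtered"] == 1

    def test_empty_cluster_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            GeneCluster(frozenset(), "a")

    def test_redundancy_statistics(self, rng):
        genes, truth = make_redundant_gene_set(50, 0.2, rng=rng)
        clusters = build_gene_groups(genes)
        reps, stats = select_representatives(clusters, genes)
        assert stats["n_input_genes"] == 50
        assert stats["n_clusters"] == len(set(truth.values()))
        assert len(reps) <= 50


class TestTranslateCds:
    @pytest.mark.parametrize(
        "seq,kwargs,expected",
        [
            ("ATGAAATAA", {}, "MK"),
            ("ATGNNNTAA", {}, "MX"),
            ("GTGAAATAA", {"is_gene_start": True}, "MK"),
            ("GTGAAATAA", {}, "VK"),  # not flagged as a gene start
            ("TTGGCC", {"is_gene_start": True}, "MA"),
        ],
    )
    def test_code_11_translation(self, seq, kwargs, expected):
        assert translate_cds(seq, **kwargs) == expected

    def test_internal_stop_retained_with_warning(self):
        with pytest.warns(UserWarning, match="internal stop"):
            assert translate_cds("ATGTAAAAA") == "M*K"

    def test_trailing_leftover_bases_ignored_with_warning(self):
        with pytest.warns(UserWarning, match="trailing"):
            assert translate_cds("ATGAAAG") == "MK"

    def test_too_short_is_an_error(self):
        with pytest.raises(ValueError):
            translate_cds("AT")


class TestMapReads:
    def test_exact_substring_read_is_assigned(self, rng):
        gene = GeneRecord("g1", random_genome(500, rng))
        read = SequenceRecord("r1", gene.seq[100:220])
        res = map_reads_to_catalogue([read], [gene], min_overlap=100)
        assert res.assignments == {"r1": "g1"}
        assert res.assigned_fraction["sample"] == 1.0

    def test_short_overlap_read_is_unassigned(self, rng):
        gene = GeneRecord("g1", random_genome(500, rng))
        # 120 bp read: only its first 90 bp come from the gene (with ~96%
        # identity); the aligned span stays at <= 100 bp
        head = substitute(gene.seq[200:290], [10, 40, 70], rng)
        read = SequenceRecord("r1", head + random_genome(30, rng))
        res = map_reads_to_catalogue([read], [gene], min_overlap=100)
        assert res.assignments == {}

    def test_best_identity_gene_wins(self, rng):
        s = random_genome(400, rng)
        g_exact = GeneRecord("g_exact", s)
        g_mut = GeneRecord("g_mut", mutate(s, 0.03, rng))
        read = SequenceRecord("r1", s[50:200])
        res = map_reads_to_catalogue([read], [g_mut, g_exact], min_overlap=100)
        assert res.assignments["r1"] == "g_exact"

    def test_min_overlap_longer_than_reads_is_an_error(self, rng):
        gene = GeneRecord("g1", random_genome(500, rng))
        read = SequenceRecord("r1", gene.seq[:75])
        with pytest.raises(ValueError, match="min_overlap"):
            map_reads_to_catalogue([read], [gene], min_overlap=100)

    def test_per_sample_fractions_and_counts(self, rng):
        gene = GeneRecord("g1", random_genome(500, rng))
        reads = {
            "s1": [SequenceRecord("r1", gene.seq[:150]), SequenceRecord("r2", random_genome(150, rng))],
            "s2": [SequenceRecord("r3", gene.seq[300:450])],
        }
        res = map_reads_to_catalogue(reads, [gene], min_overlap=100)
        assert res.assigned_fraction == {"s1": 0.5, "s2": 1.0}
        assert res.gene_counts.loc["g1", "s1"] == 1
        assert res.gene_counts.loc["g1", "s2"] == 1
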