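import networkx as nx
import numpy as np
import pytest

from promomine.candidate_mining import (
    collapse_clusters,
    detect_rbs,
    extract_upstream,
    function_similarity,
    select_candidates,
)
from promomine.io_formats import GenomeSequence, reverse_complement

from conftest import make_gene, make_genome, random_sorted_annotation


def genome_with_upstream(window: str, cds: str = "ATG" + "A" * 27):
    """Plus-strand gene whose upstream ends exactly at the window's right edge."""
    seq = "C" * 10 + window + cds
    gene = make_gene("g1", 10 + len(window), 10 + len(window) + len(cds))
    return make_genome(seq), gene


class TestDetectRbs:
    def test_aggag_at_minus_eight(self):
        window = "T" * 12 + "AGGAG" + "TTT"  # AGGAG starts 8 nt before codon
        genome, gene = genome_with_upstream(window)
        hit = detect_rbs(genome, gene)
        assert hit is not None
        assert hit.matched == "AGGAG"
        assert hit.score == 5
        assert hit.offset == -8

    def test_no_hit_in_poly_c(self):
        genome, gene = genome_with_upstream("C" * 20)
        assert detect_rbs(genome, gene) is None

    def test_longer_match_beats_closer_shorter_one(self):
        # AGGA early in the window and AGGAG later: length 5 wins over 4
        window = "T" * 4 + "AGGA" + "T" + "AGGAG" + "TTCCCC"
        assert len(window) == 20
        genome, gene = genome_with_upstream(window)
        hit = detect_rbs(genome, gene)
        assert hit.matched == "AGGAG"
        assert hit.score == 5

    def test_tie_broken_toward_start_codon(self):
        window = "AGGA" + "T" * 6 + "AGGA" + "T" * 6
        genome, gene = genome_with_upstream(window)
        hit = detect_rbs(genome, gene)
        assert hit.offset == -10  # the later (closer) of the two AGGA matches

    def test_minus_strand_window(self):
        # revcomp(AGGAGG) = CCTCCT placed just downstream of a minus-strand gene
        seq = "A" * 30 + "CC" + "CCTCCT" + "A" * 12
        gene = make_gene("g1", 0, 30, strand="-")
        hit = detect_rbs(make_genome(seq), gene)
        assert hit.matched == "AGGAGG"
        assert hit.offset == -8

    def test_short_upstream_uses_available_window(self):
        seq = "AGGAGG" + "ATG" + "A" * 20
        gene = make_gene("g1", 6, 29)
        hit = detect_rbs(make_genome(seq), gene)
        assert hit is not None and hit.offset == -6


class TestFunctionSimilarity:
    def test_identical_products(self):
        assert function_similarity("membrane-bound dehydrogenase",
                                   "Membrane-bound dehydrogenase!") == 1.0

    def test_empty_product_never_matches(self):
        assert function_similarity("", "dehydrogenase") == 0.0

    def test_partial_overlap(self):
        s = function_similarity("alcohol dehydrogenase subunit a",
                                "alcohol dehydrogenase subunit b")
        assert s == pytest.approx(3 / 5)


def cluster_oracle(features, spacer_max=50, similarity_min=0.5):
    """Brute force: adjacency graph + connected components under the predicate."""
    g = nx.Graph()
    g.add_nodes_from(f.gene_id for f in features)
    by_contig = {}
    for f in features:
        by_contig.setdefault(f.contig_id, []).append(f)
    for contig_feats in by_contig.values():
        contig_feats.sort(key=lambda f: f.start)
        for a, b in zip(contig_feats, contig_feats[1:]):
            if (
                a.strand == b.strand
                and b.start - a.end < spacer_max
                and function_similarity(a.product, b.product) >= similarity_min
            ):
                g.add_edge(a.gene_id, b.gene_id)
    comps = [sorted(c) for c in nx.connected_components(g)]
    clusters = sorted(tuple(c) for c in comps if len(c) > 1)
    singles = sorted(c[0] for c in comps if len(c) == 1)
    return clusters, singles


class TestCollapseClusters:
    def test_nearby_cooriented_similar_genes_join(self):
        feats = [
            make_gene("gA", 0, 300, "+", product="dehydrogenase, membrane-bound"),
            make_gene("gB", 330, 600, "+", product="dehydrogenase, membrane-bound"),
        ]
        clusters, singles = collapse_clusters(feats)
        assert len(clusters) == 1 and not singles
        assert clusters[0].member_ids == ["gA", "gB"]
        assert clusters[0].lead_id == "gA"

    def test_minus_strand_lead_is_downstream_member(self):
        feats = [
            make_gene("gA", 0, 300, "-", product="x y"),
            make_gene("gB", 330, 600, "-", product="x y"),
        ]
        (cluster,), _ = collapse_clusters(feats)
        assert cluster.lead_id == "gB"

    def test_spacer_exactly_fifty_does_not_join(self):
        feats = [
            make_gene("gA", 0, 300, "+", product="x y"),
            make_gene("gB", 350, 600, "+", product="x y"),
        ]
        clusters, singles = collapse_clusters(feats)
        assert not clusters and singles == ["gA", "gB"]

    def test_opposite_strands_do_not_join(self):
        feats = [
            make_gene("gA", 0, 300, "+", product="x y"),
            make_gene("gB", 330, 600, "-", product="x y"),
        ]
        clusters, _ = collapse_clusters(feats)
        assert not clusters

    def test_dissimilar_functions_do_not_join(self):
        feats = [
            make_gene("gA", 0, 300, "+", product="kinase"),
            make_gene("gB", 330, 600, "+", product="permease"),
        ]
        clusters, _ = collapse_clusters(feats)
        assert not clusters

    def test_unsorted_input_rejected(self):
        feats = [make_gene("gB", 330, 600), make_gene("gA", 0, 300)]
        with pytest.raises(ValueError, match="sorted"):
            collapse_clusters(feats)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        feats = random_sorted_annotation(rng, int(rng.integers(2, 50)))
        clusters, singles = collapse_clusters(feats)
        got = (
            sorted(tuple(sorted(c.member_ids)) for c in clusters),
            sorted(singles),
        )
        assert got == cluster_oracle(feats)


class TestExtractUpstream:
    def test_plus_strand_full_window(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        genome = make_genome(seq)
        cand = extract_upstream(genome, make_gene("g1", 1000, 2000))
        assert (cand.start, cand.end) == (500, 1000)
        assert cand.sequence == seq[500:1000]

    def test_minus_strand_truncated_at_edge(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        genome = make_genome(seq)
        cand = extract_upstream(genome, make_gene("g1", 9000, 9900, strand="-"))
        assert (cand.start, cand.end) == (9900, 10_000)
        assert len(cand.sequence) == 100
        assert cand.sequence == reverse_complement(seq[9900:10_000])

    def test_zero_length_window_rejected(self):
        genome = make_genome("ATG" + "A" * 100)
        assert extract_upstream(genome, make_gene("g1", 0, 30)) is None

    def test_candidate_id_from_gene_number(self):
        genome = make_genome("A" * 1000)
        cand = extract_upstream(genome, make_gene("gene2703", 600, 900))
        assert cand.candidate_id == "P_2703"

    @pytest.mark.parametrize("seed", range(10))
    def test_strand_symmetry(self, seed):
        """Extraction from the reverse-complemented genome with mirrored
        coordinates yields the identical candidate sequence."""
        rng = np.random.default_rng(seed)
        L = 5000
        seq = "".join(rng.choice(list("ACGT"), size=L))
        start = int(rng.integers(100, L - 400))
        end = start + int(rng.integers(100, 300))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = make_gene("g1", start, end, strand)
        mirror = make_gene(
            "g1", L - end, L - start, "-" if strand == "+" else "+"
        )
        a = extract_upstream(make_genome(seq), gene)
        b = extract_upstream(make_genome(reverse_complement(seq)), mirror)
        assert a.sequence == b.sequence


def build_toy_screen():
    """Six genes: g3 is a tRNA, g5 lacks an RBS, g1+g2 form an operon."""
    rng = np.random.default_rng(99)
    seq = list(rng.choice(list("ACGT"), size=12_000))
    feats = []
    specs = [
        ("g1", 1000, 1600, "CDS", "alcohol dehydrogenase subunit A", True),
        ("g2", 1630, 2200, "CDS", "alcohol dehydrogenase subunit B", True),
        ("g3", 3000, 3080, "tRNA", "tRNA-Ala", True),
        ("g4", 4500, 5200, "CDS", "transporter", True),
        ("g5", 6500, 7100, "CDS", "kinase", False),
        ("g6", 8500, 9100, "CDS", "permease", True),
    ]
    for gid, s, e, cls, prod, rbs in specs:
        # scrub the upstream window of chance Shine-Dalgarno matches first
        seq[s - 20 : s] = list("C" * 20)
        if rbs:
            seq[s - 9 : s - 3] = list("AGGAGG")
        feats.append(make_gene(gid, s, e, "+", feature_class=cls, product=prod))
    genome = make_genome("".join(seq))
    tpm = {"g1": 5000, "g2": 9000, "g3": 8000, "g4": 3000, "g5": 2000, "g6": 1500}
    return genome, feats, tpm


class TestSelectCandidates:
    def test_trna_and_rbs_exclusions(self):
        genome, feats, tpm = build_toy_screen()
        cands = select_candidates(genome, feats, tpm, top_n=10)
        sources = {c.source_gene for c in cands}
        assert "g3" not in sources  # tRNA
        assert "g5" not in sources  # no RBS

    def test_operon_collapses_to_lead(self):
        genome, feats, tpm = build_toy_screen()
        cands = select_candidates(genome, feats, tpm, top_n=10)
        sources = [c.source_gene for c in cands]
        # g2 has the top TPM but sits inside the g1-g2 operon: only the lead
        # g1 yields a candidate, ranked by the triggering member's TPM
        assert "g2" not in sources
        assert sources[0] == "g1"
        assert cands[0].source_tpm == 9000

    def test_middle_gene_operon_yields_single_lead_candidate(self):
        rng = np.random.default_rng(5)
        seq = list(rng.choice(list("ACGT"), size=8000))
        coords = [(1000, 1500), (1520, 2000), (2010, 2400)]
        feats = []
        for i, (s, e) in enumerate(coords):
            seq[s - 20 : s] = list("C" * 20)
            seq[s - 9 : s - 3] = list("AGGAGG")
            feats.append(
                make_gene(f"g{i}", s, e, "+", product="oxidase subunit")
            )
        genome = make_genome("".join(seq))
        tpm = {"g0": 100, "g1": 9000, "g2": 100}  # middle gene hottest
        cands = select_candidates(genome, feats, tpm, top_n=5)
        assert [c.source_gene for c in cands] == ["g0"]

    def test_top_n_zero(self):
        genome, feats, tpm = build_toy_screen()
        assert select_candidates(genome, feats, tpm, top_n=0) == []

    def test_top_n_beyond_survivors_warns_and_returns_all(self):
        genome, feats, tpm = build_toy_screen()
        with pytest.warns(UserWarning, match="survive"):
            cands = select_candidates(genome, feats, tpm, top_n=50)
        assert 0 < len(cands) < 50

    def test_candidates_sorted_by_tpm_and_sequences_match_genome(self):
        genome, feats, tpm = build_toy_screen()
        cands = select_candidates(genome, feats, tpm, top_n=10)
        tpms = [c.source_tpm for c in cands]
        assert tpms == sorted(tpms, reverse=True)
        for c in cands:
            assert c.sequence == genome.subsequence(c.start, c.end, c.strand)
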