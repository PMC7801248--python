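"""Homology search, colinearity chaining, tandem arrays, clusters, depth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skullcap.simulate import EvolutionScenario, TandemEvent, simulate_genome_pair
from skullcap.synteny import (Anchor, HomologyPair, align_proteins,
                              chain_all, chain_anchors,
                              detect_tandem_arrays, find_gene_clusters,
                              find_homolog_pairs, label_pairs, syntenic_depth)

from conftest import make_genome
from _oracles import oracle_best_chain_score, oracle_cluster_windows


def _anchor(oa, ob, chrom=("c1", "c1")):
    pair = HomologyPair(f"a{oa}", f"b{ob}", 100.0, 1.0, "cross_species")
    return Anchor(chrom[0], chrom[1], oa, ob, pair)


# ------------------------------------------------------------ protein homology


def test_align_identical_proteins():
    _, identity, cols = align_proteins("MAKTRWQED", "MAKTRWQED")
    assert identity == 100.0 and cols == 9


def test_align_two_thirds_identity():
    _, identity, _ = align_proteins("MAK", "MAR")
    assert identity == pytest.approx(66.67, abs=0.01)


def test_unrelated_random_proteins_below_threshold(rng):
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    a = "".join(rng.choice(aas, 100))
    b = "".join(rng.choice(aas, 100))
    _, identity, _ = align_proteins(a, b)
    assert identity < 40.0


def test_homolog_pairs_recover_true_orthologs(tiny_scenario):
    ga, gb, truth = simulate_genome_pair(tiny_scenario)
    pairs = find_homolog_pairs(ga, gb)
    found = {(p.gene_a, p.gene_b) for p in pairs}
    for a, b, _ in truth.ortholog_pairs:
        assert (a, b) in found


def test_homology_symmetric(tiny_scenario):
    ga, gb, _ = simulate_genome_pair(tiny_scenario)
    ab = {frozenset((p.gene_a, p.gene_b)) for p in find_homolog_pairs(ga, gb)}
    ba = {frozenset((p.gene_a, p.gene_b)) for p in find_homolog_pairs(gb, ga)}
    assert ab == ba


def test_self_search_without_duplications_is_empty(tiny_scenario):
    ga, _, _ = simulate_genome_pair(tiny_scenario)
    assert find_homolog_pairs(ga, ga) == []


def test_tandem_triplet_yields_all_three_pairs():
    sc = EvolutionScenario(n_chromosomes=1, genes_per_chromosome=10,
                           wgd_age=None, speciation_age=6.15e6, seed=8,
                           tandem_events=[TandemEvent("A", 1e6, 4, copies=2)])
    ga, _, truth = simulate_genome_pair(sc)
    pairs = find_homolog_pairs(ga, ga)
    members = {p[1] for p in truth.paralogs_of("A", "tandem")} | \
              {p[2] for p in truth.paralogs_of("A", "tandem")}
    assert len(members) == 3
    found = {frozenset((p.gene_a, p.gene_b)) for p in pairs}
    expect = {frozenset(x) for x in
              [(a, b) for a in members for b in members if a < b]}
    assert expect <= found


# ------------------------------------------------------------ chaining


def test_diagonal_anchors_chain_into_one_same_block():
    anchors = [_anchor(i, i) for i in range(6)]
    blocks = chain_anchors(anchors)
    assert len(blocks) == 1
    assert len(blocks[0]) == 6 and blocks[0].orientation == "same"


def test_antidiagonal_anchors_chain_into_one_inverted_block():
    anchors = [_anchor(i, 5 - i) for i in range(6)]
    blocks = chain_anchors(anchors)
    assert len(blocks) == 1
    assert len(blocks[0]) == 6 and blocks[0].orientation == "inverted"


def test_chain_score_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(17)
    for trial in range(25):
        n = int(rng.integers(4, 13))
        coords = set()
        while len(coords) < n:
            coords.add((int(rng.integers(0, 30)), int(rng.integers(0, 30))))
        coords = sorted(coords)
        # distinct ordinal_a so chains are unambiguous
        anchors = [_anchor(i, b) for i, (_, b) in enumerate(coords)]
        pts = [(a.ordinal_a, a.ordinal_b) for a in anchors]
        best_oracle = max(
            oracle_best_chain_score(pts, o, 25, 1.0, 0.05)
            for o in ("same", "inverted"))
        blocks = chain_anchors(anchors, min_anchors=1)
        assert blocks[0].score == pytest.approx(best_oracle)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_blocks_are_monotone(seed):
    rng = np.random.default_rng(seed)
    anchors = [_anchor(int(a), int(b)) for a, b in
               {(rng.integers(0, 40), rng.integers(0, 40)) for _ in range(30)}]
    for block in chain_anchors(anchors, min_anchors=2):
        oa = [x.ordinal_a for x in block.anchors]
        ob = [x.ordinal_b for x in block.anchors]
        assert oa == sorted(oa) and len(set(oa)) == len(oa)
        if block.orientation == "same":
            assert ob == sorted(ob) and len(set(ob)) == len(ob)
        else:
            assert ob == sorted(ob, reverse=True) and len(set(ob)) == len(ob)


def test_label_pairs_empty_blocks():
    assert label_pairs([], "cross_species") == []


def test_anchors_assigned_to_at_most_one_block():
    anchors = [_anchor(i, i) for i in range(6)] + \
              [_anchor(i + 6, 20 - i) for i in range(6)]
    blocks = chain_anchors(anchors, min_anchors=3)
    seen = []
    for b in blocks:
        seen.extend(id(a) for a in b.anchors)
    assert len(seen) == len(set(seen))


# ------------------------------------------------------------ tandem arrays

CDS = "ATGGCTAAAGATTGGCGCCTGCAC" * 15  # shared family sequence


def _family_genome(positions, chroms=None, name="g"):
    chroms = chroms or ["chr1"] * len(positions)
    specs = [(f"t{i}", chroms[i], p, CDS) for i, p in enumerate(positions)]
    # background genes between family members
    return make_genome(name, specs)


def _all_pairs(genome):
    return find_homolog_pairs(genome, genome)


def test_three_gene_tandem_within_30kb():
    g = _family_genome([0, 10_000, 20_000])
    arrays = detect_tandem_arrays(g, _all_pairs(g))
    assert len(arrays) == 1 and len(arrays[0].members) == 3


def test_distant_homologs_are_not_tandem():
    g = _family_genome([0, 50_000 + len(CDS)])
    assert detect_tandem_arrays(g, _all_pairs(g)) == []


def test_homologs_on_different_chromosomes_not_tandem():
    g = _family_genome([0, 5_000], chroms=["chr1", "chr2"])
    assert detect_tandem_arrays(g, _all_pairs(g)) == []


def test_intervening_gene_cap():
    from skullcap.simulate import _random_cds

    rng = np.random.default_rng(23)
    x1, x2 = _random_cds(80, rng), _random_cds(80, rng)
    specs = [("t0", "chr1", 0, CDS),
             ("x1", "chr1", 2_000, x1),
             ("x2", "chr1", 4_000, x2),
             ("t1", "chr1", 8_000, CDS)]
    g = make_genome("g", specs)
    arrays = detect_tandem_arrays(g, _all_pairs(g), max_intervening_genes=1)
    assert arrays == []  # two intervening non-members break the array
    arrays2 = detect_tandem_arrays(g, _all_pairs(g), max_intervening_genes=2)
    assert len(arrays2) == 1 and arrays2[0].members == ["t0", "t1"]


# ------------------------------------------------------------ clusters


def test_five_genes_in_400kb_form_one_cluster():
    g = _family_genome([i * 100_000 for i in range(5)])
    clusters = find_gene_clusters(g, [f"t{i}" for i in range(5)])
    assert len(clusters) == 1 and len(clusters[0].members) == 5


def test_four_genes_do_not_form_a_cluster():
    g = _family_genome([i * 25_000 for i in range(4)])
    assert find_gene_clusters(g, [f"t{i}" for i in range(4)]) == []


def test_clusters_match_bruteforce_window_scan():
    rng = np.random.default_rng(5)
    for _ in range(10):
        starts = np.sort(rng.integers(0, 3_000_000, 12))
        g = _family_genome([int(s) for s in starts])
        members = [f"t{i}" for i in range(12)]
        clusters = find_gene_clusters(g, members)
        genes = sorted((g.gene(m) for m in members), key=lambda x: x.start)
        runs = oracle_cluster_windows([(x.start, x.end) for x in genes],
                                      500_000, 5)
        got = sorted(tuple(sorted(c.members)) for c in clusters)
        want = sorted(tuple(sorted(genes[k].gene_id for k in range(i, j + 1)))
                      for i, j in runs)
        assert got == want


# ------------------------------------------------------------ syntenic depth


def _depth_scenario(wgd):
    return EvolutionScenario(
        n_chromosomes=1, genes_per_chromosome=40, cds_length_codons=(120, 200),
        wgd_age=5e6 if wgd else None, wgd_lineage="A", speciation_age=20e6,
        gene_loss_fraction_post_wgd=0.1, omega=0.05, seed=13)


def test_modal_depth_two_after_query_wgd():
    ga, gb, _ = simulate_genome_pair(_depth_scenario(wgd=True))
    pairs = find_homolog_pairs(ga, gb)
    blocks = chain_all(ga, gb, pairs)
    _, modal = syntenic_depth(blocks, gb, window_genes=10, side="b")
    assert modal == 2


def test_modal_depth_one_without_wgd():
    ga, gb, _ = simulate_genome_pair(_depth_scenario(wgd=False))
    blocks = chain_all(ga, gb, find_homolog_pairs(ga, gb))
    table, modal = syntenic_depth(blocks, gb, window_genes=10, side="b")
    assert modal == 1
    assert (table["depth"] >= 0).all()


def test_windows_without_blocks_count_depth_zero():
    ga, gb, _ = simulate_genome_pair(_depth_scenario(wgd=False))
    table, _ = syntenic_depth([], gb, window_genes=10)
    assert (table["depth"] == 0).all()
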