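import random

import dendropy
import numpy as np
import pytest

from ltrcraft import align, synth
from ltrcraft.domains import DomainHit
from ltrcraft.phylo import (
    RTDomainSequence,
    RTRejection,
    distance_matrix,
    extract_rt,
    nj_tree,
    progressive_msa,
)
from ltrcraft.seqio import PipelineConfig, PredictorRecord


def _element_with_rt(aa_len, seed=0, frame_shift=0, stop_at=None):
    """Element embedding a back-translated RT of aa_len residues."""
    rng = random.Random(seed)
    aa = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(aa_len))
    if stop_at is not None:
        aa = aa[:stop_at] + "*" + aa[stop_at + 1 :]
    nt = synth.back_translate(aa.replace("*", "W"))
    if stop_at is not None:
        nt = nt[: 3 * stop_at] + "TAA" + nt[3 * (stop_at + 1) :]
    flank5 = "".join(rng.choice("ACGT") for _ in range(100 + frame_shift))
    flank3 = "".join(rng.choice("ACGT") for _ in range(100))
    full = flank5 + nt + flank3
    start = len(flank5)
    hit = DomainHit(
        element_id="e",
        domain_kind="RT",
        superfamily_code="RLG",
        lineage="Del",
        family="F",
        score=500.0,
        evalue=1e-50,
        frame=(start % 3) + 1,
        element_nt_start=start,
        element_nt_end=start + len(nt),
        ref_id="RT_RLG_Del_F",
        aa_alignment=None,
    )
    el = PredictorRecord("e", full, full[:20], full[-20:], 100.0, len(full))
    return el, hit


class TestExtractRT:
    @pytest.mark.parametrize(
        "aa_len, mode, kept",
        [
            (199, "element", False),
            (200, "element", False),  # strictly larger than 200 required
            (201, "element", True),
            (149, "genome", False),
            (150, "genome", False),  # strictly larger than 150 required
            (151, "genome", True),
        ],
    )
    def test_strict_length_thresholds(self, cfg, aa_len, mode, kept):
        el, hit = _element_with_rt(aa_len)
        out = extract_rt(el, hit, cfg, mode=mode)
        assert isinstance(out, RTDomainSequence) == kept
        if kept:
            assert out.length_aa == aa_len

    def test_clean_embedded_rt_extracted_full_length(self, cfg):
        el, hit = _element_with_rt(250, frame_shift=2)
        out = extract_rt(el, hit, cfg)
        assert isinstance(out, RTDomainSequence)
        assert out.length_aa == 250
        assert "*" not in out.aa_seq

    def test_internal_stop_truncates(self, cfg):
        el, hit = _element_with_rt(300, stop_at=220)
        out = extract_rt(el, hit, cfg)
        assert isinstance(out, RTDomainSequence)
        assert out.length_aa == 220

    def test_internal_stop_rejecting_when_remainder_short(self, cfg):
        el, hit = _element_with_rt(300, stop_at=150)
        out = extract_rt(el, hit, cfg)
        assert isinstance(out, RTRejection)

    def test_negative_frame_hit(self, cfg):
        el, hit = _element_with_rt(250)
        rc = align.revcomp(el.full_seq)
        n = len(el.full_seq)
        start = n - hit.element_nt_end
        end = n - hit.element_nt_start
        rc_el = PredictorRecord("e", rc, rc[:20], rc[-20:], 100.0, n)
        rc_hit = DomainHit(
            "e", "RT", "RLG", "Del", "F", 500.0, 1e-50,
            frame=-((start % 3) + 1),
            element_nt_start=start, element_nt_end=end,
            ref_id="RT_RLG_Del_F", aa_alignment=None,
        )
        out = extract_rt(rc_el, rc_hit, cfg)
        fwd = extract_rt(el, hit, cfg)
        assert isinstance(out, RTDomainSequence)
        assert out.aa_seq == fwd.aa_seq


class TestProgressiveMSA:
    def test_two_identical_sequences_gap_free(self):
        msa = progressive_msa({"a": "MKLVATQQR", "b": "MKLVATQQR"})
        assert msa["a"] == msa["b"] == "MKLVATQQR"

    def test_single_insertion_gapped_in_other_rows(self):
        base = "MKLVATQQRDEFGHIKLMNP"
        withins = base[:10] + "WWW" + base[10:]
        msa = progressive_msa({"a": base, "b": withins, "c": base})
        width = len(msa["b"])
        assert all(len(row) == width for row in msa.values())
        assert msa["a"].count("-") == 3 and msa["c"].count("-") == 3
        assert "-" not in msa["b"]

    def test_rows_degap_to_inputs_and_width_at_least_longest(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(50, 90)))
            for i in range(4)
        }
        msa = progressive_msa(seqs)
        width = len(next(iter(msa.values())))
        assert width >= max(len(s) for s in seqs.values())
        for k, s in seqs.items():
            assert msa[k].replace("-", "") == s

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa({"a": "MKLV"})


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        d, labels = distance_matrix({"a": "MKLV", "b": "MKLV"})
        assert d[0, 1] == 0.0

    def test_hand_computed_case(self):
        msa = {"a": "MKLV-A", "b": "MKIV-A", "c": "MQ-VWA"}
        d, labels = distance_matrix(msa)
        # a vs b: columns 3 (L/I) differs; column 5 is a double gap ->
        # 5 comparable columns, 1 difference
        assert d[0, 1] == pytest.approx(1 / 5)
        # a vs c and b vs c: 4 comparable columns (cols 3 and 5 gapped),
        # 1 difference (K/Q)
        assert d[0, 2] == pytest.approx(1 / 4)
        assert d[1, 2] == pytest.approx(1 / 4)

    def test_symmetry_and_zero_diagonal(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice("ACDE") for _ in range(30)) for i in range(5)
        }
        msa = progressive_msa(seqs)
        d, _ = distance_matrix(msa)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


def _random_additive_tree(n_taxa, rng):
    """Random tree with positive branch lengths and its additive distances."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    # build by random sequential attachment
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    a = dendropy.Node()
    b = dendropy.Node()
    c = dendropy.Node()
    for node, t in zip((a, b, c), taxa[:3]):
        node.taxon = ns.get_taxon(t)
        node.edge.length = rng.uniform(0.05, 1.0)
        tree.seed_node.add_child(node)
        nodes.append(node)
    for t in taxa[3:]:
        target = rng.choice(nodes)
        # split target's edge and hang the new taxon off the midpoint
        parent = target.parent_node
        split = dendropy.Node()
        old_len = target.edge.length
        parent.remove_child(target)
        parent.add_child(split)
        split.edge.length = old_len * rng.uniform(0.2, 0.8)
        split.add_child(target)
        target.edge.length = old_len - split.edge.length + 0.01
        leaf = dendropy.Node()
        leaf.taxon = ns.get_taxon(t)
        leaf.edge.length = rng.uniform(0.05, 1.0)
        split.add_child(leaf)
        nodes.extend([leaf, target])
    pdm = tree.phylogenetic_distance_matrix()
    dist = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(n_taxa):
            dist[i, j] = pdm.patristic_distance(
                ns.get_taxon(taxa[i]), ns.get_taxon(taxa[j])
            )
    return tree, dist, taxa


def _rf_distance(newick_a, tree_b, ns):
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=ns)
    ta.encode_bipartitions()
    tree_b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tree_b)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(d, ["a", "b", "c"])
        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_star_distances_give_zero_internal_branches(self):
        n = 5
        d = np.full((n, n), 1.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(d, [f"t{i}" for i in range(n)])
        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        internal = [
            e.length
            for e in t.preorder_edge_iter()
            if e.head_node.is_internal() and e.length is not None
        ]
        assert all(abs(x) < 1e-9 for x in internal)

    def test_additive_matrix_recovers_topology_and_lengths(self):
        rng = random.Random(17)
        for trial in range(25):
            n = rng.randint(5, 8)
            true_tree, dist, taxa = _random_additive_tree(n, rng)
            result = nj_tree(dist, taxa)
            ns = true_tree.taxon_namespace
            assert _rf_distance(result.newick, true_tree, ns) == 0, f"trial {trial}"
            # additive distances are reproduced exactly by the NJ tree
            out = dendropy.Tree.get(
                data=result.newick, schema="newick", taxon_namespace=ns
            )
            pdm = out.phylogenetic_distance_matrix()
            for i in range(n):
                for j in range(i + 1, n):
                    got = pdm.patristic_distance(
                        ns.get_taxon(taxa[i]), ns.get_taxon(taxa[j])
                    )
                    assert got == pytest.approx(dist[i, j], abs=1e-4)

    def test_agrees_with_skbio_reference(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = random.Random(23)
        for _ in range(5):
            n = rng.randint(4, 7)
            _, dist, taxa = _random_additive_tree(n, rng)
            mine = nj_tree(dist, taxa)
            ref = skbio_nj(DistanceMatrix(dist, taxa))
            ns = dendropy.TaxonNamespace(taxa)
            a = dendropy.Tree.get(data=mine.newick, schema="newick", taxon_namespace=ns)
            b = dendropy.Tree.get(data=str(ref), schema="newick", taxon_namespace=ns)
            a.encode_bipartitions()
            b.encode_bipartitions()
            assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(d, ["a", "b", "c"])

    def test_negative_branch_clamped_and_flagged(self):
        # distances violating additivity can force negative estimates
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.02],
                [0.9, 0.9, 0.02, 0.0],
            ]
        )
        tree = nj_tree(d, list("abcd"))
        assert "-" not in tree.newick.replace("e-", "")  # no negative lengths printed
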