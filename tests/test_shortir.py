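"""Short-IR arm discovery, flip-flop inversion, junction references."""

import numpy as np
import pytest

import plastomekit as pk
from plastomekit.genome import revcomp


def _gc(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def test_homopolymer_has_no_pairs():
    g = pk.AnnotatedGenome("poly", "A" * 5000)
    assert pk.find_short_ir_pairs(g, min_segment=100) == []


def test_planted_arms_found_exactly(default_genome):
    g, truth = default_genome
    st = truth["structure"]
    pairs = pk.find_short_ir_pairs(g, structure=st)
    assert len(pairs) == 1
    p = pairs[0]
    tr = truth["short_ir"]
    assert p.left_arm == tr["left_arm"]
    assert p.right_arm == tr["right_arm"]
    assert p.arm_len == 29
    assert p.nearest_genes == ("trnS-GCU", "trnS-GGA")


def test_planted_arms_match_quadratic_scan():
    """Small genome: every reported pair also appears in a brute-force
    all-anti-diagonal scan of the match matrix, and is maximal."""
    spec = pk.SyntheticPlastomeSpec(
        lsc_len=6000, ssc_len=1200, ir_len=1300, gene_template=(
            pk.GeneTemplate("trnS-GCU", "tRNA", 80, "-", "LSC"),
            pk.GeneTemplate("trnS-GGA", "tRNA", 80, "+", "LSC"),
        ),
        short_ir=pk.ShortIRSpec(arm_len=29), seed=21,
    )
    g, truth = pk.build_synthetic_plastome(spec)
    pairs = pk.find_short_ir_pairs(g, min_segment=500, structure=truth["structure"])
    assert len(pairs) == 1
    p = pairs[0]
    seq = g.sequence
    # brute force: scan all start pairs at the reported arm length
    L = p.arm_len
    hits = []
    for i in range(len(seq) - L + 1):
        arm = seq[i : i + L]
        j = seq.find(revcomp(arm), i + L)
        while j != -1:
            hits.append((i + 1, j + 1))
            j = seq.find(revcomp(arm), j + 1)
    assert (p.left_arm[0], p.right_arm[0]) in hits
    # maximality: cannot extend outward or inward
    la, ra = p.left_arm, p.right_arm
    assert seq[la[0] - 2] != revcomp(seq[ra[1]])
    assert seq[la[1]] != revcomp(seq[ra[0] - 2])


def test_arm_reverse_complementarity_invariant(default_genome):
    g, truth = default_genome
    for p in pk.find_short_ir_pairs(g, structure=truth["structure"]):
        left = g.subseq(*p.left_arm)
        right = g.subseq(*p.right_arm)
        assert left == revcomp(right)


def test_pairs_invariant_under_rotation(default_genome):
    g, truth = default_genome
    offset = 40000
    rot = g.rotated(offset)
    base = pk.find_short_ir_pairs(g, structure=truth["structure"])
    n = len(g)
    rotated = pk.find_short_ir_pairs(rot)
    # map rotated arm starts back to the original frame; the left/right roles
    # may swap when the rotation origin falls inside the bounded segment
    shifted = {
        frozenset(
            ((p.left_arm[0] - 1 + offset) % n + 1, (p.right_arm[0] - 1 + offset) % n + 1)
        )
        for p in rotated
    }
    for p in base:
        assert frozenset((p.left_arm[0], p.right_arm[0])) in shifted


def test_flip_flop_is_involution(default_genome):
    g, truth = default_genome
    pair = pk.find_short_ir_pairs(g, structure=truth["structure"])[0]
    iso = pk.flip_flop_isomer(g, pair)
    assert iso.sequence != g.sequence
    back = pk.flip_flop_isomer(iso, pair)
    assert back.sequence == g.sequence
    assert back.features == g.features


def test_flip_flop_creates_expected_adjacencies(default_genome):
    """IPWC order psbI, trnS-GCU, trnG ... ycf3, trnS-GGA, rps4 becomes
    psbI-trnS-GGA and trnS-GCU-rps4 in the inverted isomer."""
    g, truth = default_genome
    pair = pk.find_short_ir_pairs(g, structure=truth["structure"])[0]
    iso = pk.flip_flop_isomer(g, pair)
    order = [f.name for f in sorted(iso.features, key=lambda f: f.start)]
    i = order.index("psbI")
    assert order[i + 1] == "trnS-GGA"
    assert order[i + 2] == "ycf3"
    j = order.index("trnS-GCU")
    assert order[j - 1] == "trnG-UCC"
    assert order[j + 1] == "rps4"


def test_flip_flop_conserves_composition(default_genome):
    g, truth = default_genome
    pair = pk.find_short_ir_pairs(g, structure=truth["structure"])[0]
    iso = pk.flip_flop_isomer(g, pair)
    s, e = pair.segment
    assert _gc(iso.subseq(s, e)) == _gc(g.subseq(s, e))
    assert _gc(iso.sequence) == _gc(g.sequence)


def test_flip_flop_rejects_foreign_pair(default_genome, plain_genome):
    _, truth = default_genome
    other, _ = plain_genome
    tr = truth["short_ir"]
    pair = pk.ShortIRPair(tr["left_arm"], tr["right_arm"], tr["arm_len"], (None, None))
    with pytest.raises(ValueError, match="not reverse-complementary"):
        pk.flip_flop_isomer(other, pair)


def test_junction_refs_substring_oracle(default_genome):
    g, truth = default_genome
    pair = pk.find_short_ir_pairs(g, structure=truth["structure"])[0]
    refs = pk.build_junction_refs(g, pair)
    iso = pk.flip_flop_isomer(g, pair)
    assert len(refs.references) == 4
    assert len(refs.by_conformation(pk.IPWI)) == 2
    assert len(refs.by_conformation(pk.IPWC)) == 2
    for r in refs.references:
        carrier = iso if r.conformation == pk.IPWI else g
        other = g if r.conformation == pk.IPWI else iso
        assert r.sequence in carrier.sequence
        assert r.sequence not in other.sequence
    # pairwise distinct
    seqs = [r.sequence for r in refs.references]
    assert len(set(seqs)) == 4


def test_junction_ref_labels(default_genome):
    g, truth = default_genome
    pair = pk.find_short_ir_pairs(g, structure=truth["structure"])[0]
    refs = pk.build_junction_refs(g, pair)
    labels = {r.conformation: set() for r in refs.references}
    for r in refs.references:
        labels[r.conformation].add(r.label)
    assert labels[pk.IPWI] == {"psbI-trnS-GGA-ycf3", "trnG-UCC-trnS-GCU-rps4"}
    assert labels[pk.IPWC] == {"psbI-trnS-GCU-trnG-UCC", "ycf3-trnS-GGA-rps4"}


def test_zero_flank_rejected(default_genome):
    g, truth = default_genome
    pair = pk.find_short_ir_pairs(g, structure=truth["structure"])[0]
    with pytest.raises(ValueError, match="flanks required"):
        pk.build_junction_refs(g, pair, flank_w=0)


def test_refs_fasta_roundtrip(default_genome, tmp_path):
    g, truth = default_genome
    pair = pk.find_short_ir_pairs(g, structure=truth["structure"])[0]
    refs = pk.build_junction_refs(g, pair)
    path = tmp_path / "refs.fasta"
    pk.write_junction_refs_fasta(refs, path)
    back = pk.read_junction_refs_fasta(path)
    assert back.references == refs.references
    assert back.arm_len == refs.arm_len
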