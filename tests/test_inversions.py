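"""Signed gene-order permutations, inversion calls, ortholog end comparison."""

import itertools

import numpy as np
import pytest

import plastomekit as pk
from plastomekit.genome import GeneFeature
from plastomekit.inversions import calls_explain_permutation


def test_identity_permutation(plain_genome):
    g, truth = plain_genome
    st = truth["structure"]
    perm = pk.shared_gene_permutation(g, g, st, st)
    assert perm.is_identity()
    assert all(s == 1 for s in perm.signs)
    assert pk.call_inversions(perm, g, g) == []


def test_too_few_shared_loci():
    a = pk.AnnotatedGenome("a", "ACGT" * 100, [GeneFeature("x", "PCG", "+", ((1, 9),))])
    b = pk.AnnotatedGenome("b", "ACGT" * 100, [GeneFeature("x", "PCG", "+", ((1, 9),))])
    with pytest.raises(ValueError, match="shared unique loci"):
        pk.shared_gene_permutation(a, b)


def test_planted_block_signs_and_order(plain_genome):
    g, truth = plain_genome
    st = truth["structure"]
    inv, tr = pk.plant_inversion(g, "rbcL", "petA")
    perm = pk.shared_gene_permutation(g, inv, st, st)
    flipped = {p for p, s in zip(perm.genes, perm.signs) if s == -1}
    assert flipped == set(tr["genes"])
    # flipped genes appear in reversed relative order along the query
    ranks = {g_: r for g_, r in zip(perm.genes, perm.query_rank)}
    ordered = [g_ for g_ in perm.genes if g_ in flipped]
    q = [ranks[g_] for g_ in ordered]
    assert q == sorted(q, reverse=True)


def test_tylosema_like_rbcl_peta_inversion(plain_genome):
    g, truth = plain_genome
    st = truth["structure"]
    inv, tr = pk.plant_inversion(g, "rbcL", "petA")
    perm = pk.shared_gene_permutation(g, inv, st, st)
    calls = pk.call_inversions(perm, g, inv)
    assert len(calls) == 1
    c = calls[0]
    assert (c.first_gene, c.last_gene) == ("rbcL", "petA")
    assert set(c.novel_adjacencies) == {("atpB", "petA"), ("psbJ", "rbcL")}
    assert c.span_bp == tr["span_bp"]
    assert calls_explain_permutation(perm, calls)


def _genome_from_order(order, seed=0):
    """Tiny genome with genes laid out in the given (name, strand) order."""
    rng = np.random.default_rng(seed)
    feats, chunks, pos = [], [], 0
    bases = "ACGT"
    for name, strand in order:
        gap = 50
        chunks.append("".join(rng.choice(list(bases), size=gap)))
        pos += gap
        length = 90
        chunks.append("".join(rng.choice(list(bases), size=length)))
        feats.append(GeneFeature(name, "PCG", strand, ((pos + 1, pos + length),)))
        pos += length
    chunks.append("A" * 50)
    return pk.AnnotatedGenome("toy", "".join(chunks), feats, "circular")


def test_griffonia_like_inversion_adjacencies():
    """A 24-kb-style rpl16..psaI reversal: the reference order carries
    accD, rpl16 ... psaI, rps3 so the inverted genome shows the
    accD-psaI and rpl16-rps3 adjacencies."""
    ref_order = [
        ("trnH-GUG", "+"), ("psbA", "-"), ("accD", "+"),
        ("rpl16", "-"), ("cemA", "+"), ("petA", "+"), ("psaI", "+"),
        ("rps3", "-"), ("rps19", "+"),
    ]
    ref = _genome_from_order(ref_order, seed=1)
    qry, _ = pk.plant_inversion(ref, "rpl16", "psaI")
    perm = pk.shared_gene_permutation(ref, qry)
    calls = pk.call_inversions(perm, ref, qry)
    assert len(calls) == 1
    c = calls[0]
    assert (c.first_gene, c.last_gene) == ("rpl16", "psaI")
    assert set(c.novel_adjacencies) == {("accD", "psaI"), ("rpl16", "rps3")}
    assert c.block_size == 4


def test_two_independent_inversions(plain_genome):
    """Two sign-flipped runs, as in a plastome carrying both the
    rbcL..petA and the short-IR-bounded inversions."""
    g, truth = plain_genome
    st = truth["structure"]
    step1, _ = pk.plant_inversion(g, "rbcL", "petA")
    step2, _ = pk.plant_inversion(step1, "psbD", "psaA")
    perm = pk.shared_gene_permutation(g, step2, st, st)
    calls = pk.call_inversions(perm, g, step2)
    assert len(calls) == 2
    blocks = {(c.first_gene, c.last_gene) for c in calls}
    assert blocks == {("rbcL", "petA"), ("psbD", "psaA")}
    assert calls_explain_permutation(perm, calls)


def test_symmetry_under_genome_swap(plain_genome):
    g, truth = plain_genome
    st = truth["structure"]
    inv, _ = pk.plant_inversion(g, "rbcL", "petA")
    fwd = pk.call_inversions(pk.shared_gene_permutation(g, inv, st, st), g, inv)
    rev = pk.call_inversions(pk.shared_gene_permutation(inv, g, st, st), inv, g)
    gene_sets = lambda calls: {frozenset((c.first_gene, c.last_gene)) for c in calls}
    assert gene_sets(fwd) == gene_sets(rev)


def test_exhaustive_enumeration_small_permutations():
    """For <= 8 genes, calls agree with exhaustive enumeration of all
    single-block reversals explaining the permutation."""
    names = ["g1", "g2", "g3", "g4", "g5", "g6", "g7"]
    ref = _genome_from_order([(n, "+") for n in names], seed=3)
    for a, b in itertools.combinations(range(len(names)), 2):
        qry, _ = pk.plant_inversion(ref, names[a], names[b])
        perm = pk.shared_gene_permutation(ref, qry)
        calls = pk.call_inversions(perm, ref, qry)
        # enumerate all single reversals of the reference order
        matches = []
        order = [(g_, s) for g_, s in perm.query_order]
        for i, j in itertools.combinations(range(len(names)), 2):
            cand = names[:i] + names[i : j + 1][::-1] + names[j + 1 :]
            signs = [1] * i + [-1] * (j - i + 1) + [1] * (len(names) - j - 1)
            if order == list(zip(cand, signs)):
                matches.append((names[i], names[j]))
        assert len(calls) == 1 and len(matches) == 1
        assert (calls[0].first_gene, calls[0].last_gene) == matches[0] == (names[a], names[b])


# ---------------------------------------------------------------------------
# ortholog ends
# ---------------------------------------------------------------------------


def test_identical_cds_zero_deltas(plain_genome):
    g, _ = plain_genome
    r = pk.compare_ortholog_ends(g, g, "accD")
    assert (r.delta_5prime_bp, r.delta_3prime_bp) == (0, 0)
    assert r.orf_intact


def _with_truncated_gene(genome, name, cut, make_start):
    """Copy of genome with `cut` bp removed from the 5' end of a gene's CDS."""
    feats = []
    for f in genome.features:
        if f.name != name:
            feats.append(f)
            continue
        assert len(f.parts) == 1
        s, e = f.parts[0]
        if f.strand == "+":
            parts = ((s + cut, e),)
        else:
            parts = ((s, e - cut),)
        feats.append(GeneFeature(name, f.category, f.strand, parts))
    g2 = pk.AnnotatedGenome(genome.id + "-trunc", genome.sequence, feats, genome.topology)
    if make_start:
        f = g2.feature_by_name(name)
        seq = list(g2.sequence)
        if f.strand == "+":
            seq[f.start - 1 : f.start + 2] = list("ATG")
        else:
            seq[f.end - 3 : f.end] = list("CAT")  # revcomp of ATG
        g2 = pk.AnnotatedGenome(g2.id, "".join(seq), feats, g2.topology)
    return g2


def test_five_prime_truncation_measured(plain_genome):
    g, _ = plain_genome
    qry = _with_truncated_gene(g, "matK", 131, make_start=True)
    r = pk.compare_ortholog_ends(g, qry, "matK")
    assert r.delta_5prime_bp == -131
    assert r.delta_3prime_bp == 0


def test_truncation_with_intact_orf(plain_genome):
    g, _ = plain_genome
    qry = _with_truncated_gene(g, "accD", 132, make_start=True)
    r = pk.compare_ortholog_ends(g, qry, "accD")
    assert r.delta_5prime_bp == -132
    assert r.orf_intact


def test_missing_gene_names_genome(plain_genome):
    g, _ = plain_genome
    empty = pk.AnnotatedGenome("noanno", g.sequence, [], g.topology)
    with pytest.raises(KeyError, match="noanno"):
        pk.compare_ortholog_ends(g, empty, "accD")
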