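"""Large-IR detection, junction reports, boundary-shift classification."""

import numpy as np
import pytest

import plastomekit as pk
from plastomekit.genome import GeneFeature
from plastomekit.irdetect import NoQuadripartiteError

from conftest import brute_force_best_ir


def _random_genome(rng, n):
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return pk.AnnotatedGenome("rand", seq, [], "circular")


def test_no_repeat_raises():
    rng = np.random.default_rng(0)
    g = _random_genome(rng, 20000)
    with pytest.raises(NoQuadripartiteError, match="no quadripartite"):
        pk.find_large_ir(g, min_len=1000)


def test_short_genome_raises():
    g = pk.AnnotatedGenome("tiny", "ACGT" * 100)
    with pytest.raises(NoQuadripartiteError):
        pk.find_large_ir(g, min_len=1000)


def test_planted_ir_detected_at_construction_coordinates():
    spec = pk.SyntheticPlastomeSpec(
        lsc_len=8000, ssc_len=2000, ir_len=3000, gene_template=(), seed=1
    )
    g, truth = pk.build_synthetic_plastome(spec)
    st = pk.find_large_ir(g)
    want = truth["structure"]
    assert st.ir_len == 3000
    assert (st.lsc, st.ir_b, st.ssc, st.ir_a) == (
        want.lsc, want.ir_b, want.ssc, want.ir_a,
    )
    assert st.junctions == want.junctions


def test_agrees_with_quadratic_oracle_on_small_instances():
    rng = np.random.default_rng(7)
    for _ in range(10):
        ir = int(rng.integers(200, 801))
        lsc = int(rng.integers(1000, 2000))
        ssc = int(rng.integers(300, 800))
        g, truth = pk.build_synthetic_plastome(
            pk.SyntheticPlastomeSpec(
                lsc_len=lsc, ssc_len=ssc, ir_len=ir, gene_template=(),
                seed=int(rng.integers(2**31)),
            )
        )
        st = pk.find_large_ir(g, min_len=200)
        best_len, best_pairs = brute_force_best_ir(g.sequence, 200)
        assert st.ir_len == best_len == ir
        assert (st.ir_b[0], st.ir_a[0]) in best_pairs


def test_detection_invariant_under_rotation_and_revcomp(default_genome):
    g, truth = default_genome
    want = (
        truth["structure"].lsc_len,
        truth["structure"].ir_len,
        truth["structure"].ssc_len,
    )
    for variant in (g.rotated(31337), g.reverse_complemented()):
        st = pk.find_large_ir(variant)
        assert (st.lsc_len, st.ir_len, st.ssc_len) == want


def test_mismatch_tolerance_absorbs_sparse_ir_differences():
    g, truth = pk.build_synthetic_plastome(
        pk.SyntheticPlastomeSpec(
            lsc_len=20000, ssc_len=5000, ir_len=8000, gene_template=(), seed=4
        )
    )
    # introduce 3 interior mismatches in IR_A (fraction 3/8000 < 0.001)
    st0 = truth["structure"]
    seq = list(g.sequence)
    rng = np.random.default_rng(5)
    for off in (2000, 4000, 6000):
        pos = st0.ir_a[0] - 1 + off
        old = seq[pos]
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
    g2 = pk.AnnotatedGenome(g.id, "".join(seq), [], "circular")
    st = pk.find_large_ir(g2, max_mismatch_frac=0.001)
    assert st.ir_len == 8000
    # with zero tolerance only a fragment is found
    st_exact = pk.find_large_ir(g2, max_mismatch_frac=0.0)
    assert st_exact.ir_len < 8000


# ---------------------------------------------------------------------------
# junction reports
# ---------------------------------------------------------------------------


def test_gene_inside_lsc_reported_adjacent(plain_genome):
    g, truth = plain_genome
    reports = pk.junction_report(g, truth["structure"])
    by_junction = {}
    for r in reports:
        by_junction.setdefault(r.junction, []).append(r)
    jlb = by_junction["J_LB"]
    assert all(r.placement != "spans_junction" for r in jlb)
    assert all(r.duplicated_bp == 0 for r in jlb)
    up = [r for r in jlb if r.placement == "adjacent_upstream"][0]
    assert up.gene == "rps19"  # last LSC gene in the template


@pytest.mark.parametrize("k", [1, 37, 151])
def test_straddling_gene_duplicated_bp(k):
    g, truth = pk.build_synthetic_plastome(
        pk.SyntheticPlastomeSpec(jlb_straddle=("rps19", k), seed=13)
    )
    st = truth["structure"]
    reports = pk.junction_report(g, st)
    span = [r for r in reports if r.junction == "J_LB" and r.placement == "spans_junction"]
    assert len(span) == 1
    assert span[0].gene == "rps19"
    assert span[0].duplicated_bp == k
    assert span[0].end_involved == "3prime"
    # independent interval-arithmetic check
    f = g.feature_by_name("rps19")
    overlap = max(0, min(f.end, st.ir_b[1]) - max(f.start, st.ir_b[0]) + 1)
    assert overlap == k


def test_unannotated_genome_reports_no_genes():
    g, truth = pk.build_synthetic_plastome(
        pk.SyntheticPlastomeSpec(
            lsc_len=8000, ssc_len=2000, ir_len=3000, gene_template=(), seed=2
        )
    )
    reports = pk.junction_report(g, truth["structure"])
    assert len(reports) == 4
    assert all(r.gene is None and r.duplicated_bp == 0 for r in reports)


# ---------------------------------------------------------------------------
# boundary shifts
# ---------------------------------------------------------------------------


def test_identical_genomes_no_shift(plain_genome):
    g, truth = plain_genome
    st = truth["structure"]
    shifts = pk.classify_boundary_shift(g, st, g, st)
    assert len(shifts) == 4
    assert all(s.direction == "none" and s.magnitude_bp == 0 for s in shifts)
    assert all(not s.genes_gained_by_ir and not s.genes_lost_by_ir for s in shifts)


def test_planted_ir_expansion_into_ssc(plain_genome):
    g, truth = plain_genome
    st = truth["structure"]
    # expand far enough to engulf the first SSC gene (ndhF analog) entirely
    ndhf = g.feature_by_name("ndhF")
    bp = ndhf.end - st.ir_b[1] + 10
    ext, est, etr = pk.extend_ir_into_ssc(g, st, bp)
    assert "ndhF" in etr["duplicated_genes"]
    shifts = {s.junction: s for s in pk.classify_boundary_shift(ext, est, g, st)}
    jsb = shifts["J_SB"]
    assert jsb.direction == "expansion_into_SSC"
    assert jsb.magnitude_bp == bp
    assert "ndhF" in jsb.genes_gained_by_ir
    assert shifts["J_LB"].direction == "none"


def test_small_expansion_magnitude_exact(plain_genome):
    g, truth = plain_genome
    st = truth["structure"]
    ext, est, _ = pk.extend_ir_into_ssc(g, st, 500)
    shifts = {s.junction: s for s in pk.classify_boundary_shift(ext, est, g, st)}
    assert shifts["J_SB"].direction == "expansion_into_SSC"
    assert shifts["J_SB"].magnitude_bp == 500
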