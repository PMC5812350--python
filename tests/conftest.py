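import numpy as np
import pytest

import plastomekit as pk
from plastomekit.synth import COMPACT_GENE_TEMPLATE


@pytest.fixture(scope="session")
def default_genome():
    """Full-scale synthetic plastome (86/26/18 kb) with planted short IR and
    an rps19 analog straddling J_LB by 151 bp."""
    spec = pk.SyntheticPlastomeSpec(
        short_ir=pk.ShortIRSpec(), jlb_straddle=("rps19", 151), seed=42
    )
    return pk.build_synthetic_plastome(spec)


@pytest.fixture(scope="session")
def plain_genome():
    """Full-scale synthetic plastome without planted short IR or straddle."""
    return pk.build_synthetic_plastome(pk.SyntheticPlastomeSpec(seed=8))


@pytest.fixture(scope="session")
def scaled_isomer_setup():
    """40-kb genome (segment analog of the 38-kb inversion, scaled down) with
    its short-IR pair, junction references and flip-flop isomer."""
    spec = pk.SyntheticPlastomeSpec(
        lsc_len=26000,
        ssc_len=4000,
        ir_len=5000,
        gene_template=COMPACT_GENE_TEMPLATE,
        short_ir=pk.ShortIRSpec(),
        seed=11,
    )
    g, truth = pk.build_synthetic_plastome(spec)
    pair = pk.find_short_ir_pairs(g, structure=truth["structure"])[0]
    refs = pk.build_junction_refs(g, pair)
    ipwi = pk.flip_flop_isomer(g, pair)
    return g, ipwi, pair, refs, truth


def brute_force_best_ir(sequence: str, min_len: int) -> tuple[int, set]:
    """Exhaustive quadratic oracle: longest exact disjoint reverse-complement
    interval pair.  Returns (length, set of (arm1_start, arm2_start) 1-based).

    Dynamic programme over the full match matrix M[i, j] = (s[i] == comp(s[j]))
    along anti-diagonals, independent of the seeded scan under test.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    s = np.frombuffer(sequence.encode(), dtype=np.uint8)
    c = np.frombuffer(sequence.translate(comp).encode(), dtype=np.uint8)
    n = len(s)
    best_len = 0
    best: set = set()
    prev = np.zeros(n, dtype=np.int32)
    for i in range(n):
        run = np.empty(n, dtype=np.int32)
        # run[j] = length of the complementary run ending at (i, j) moving (i+1, j-1)
        match = s[i] == c
        run[:-1] = np.where(match[:-1], prev[1:] + 1, 0)
        run[-1] = 1 if match[-1] else 0
        prev = run
        j = np.arange(n)
        r = run
        # disjoint arms: run ending at (i, j) covers s[i-r+1..i] and s[j..j+r-1];
        # truncate runs that cross the centre (palindromic self-overlap)
        allowed = r - np.maximum(0, (i - j) // 2 + 1)
        allowed = np.minimum(allowed, r)
        valid = (r > 0) & (allowed >= min_len)
        if not valid.any():
            continue
        m = int(allowed[valid].max())
        if m < best_len:
            continue
        if m > best_len:
            best_len, best = m, set()
        for jj in np.flatnonzero(valid & (allowed == m)):
            t = max(0, (i - int(jj)) // 2 + 1)
            i2, j2 = i - t, int(jj) + t
            best.add((i2 - m + 1 + 1, j2 + 1))  # 1-based arm starts
    return best_len, best
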