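"""Large inverted-repeat detection, quadripartite partition, junction analysis.

The large IR is found by exact k-mer seeding between the sequence and its
reverse complement, grouping seeds on anti-diagonals (a base pair (p, q)
with seq[p] complementary to seq[q] satisfies p + q = const for one repeat
pair), and extending along each candidate anti-diagonal under a mismatch
budget.  Circularity is handled by searching the doubled sequence and
rejecting self-overlapping pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome import (
    AnnotatedGenome,
    GeneFeature,
    QuadripartiteStructure,
    _ilen,
    _overlaps_ir,
    revcomp,
)

__all__ = [
    "NoQuadripartiteError",
    "ArmPair",
    "JunctionReport",
    "BoundaryShift",
    "find_large_ir",
    "find_inverted_repeats",
    "junction_report",
    "classify_boundary_shift",
]


class NoQuadripartiteError(ValueError):
    """Raised when no qualifying inverted repeat is found."""


@dataclass(frozen=True)
class ArmPair:
    """A pair of reverse-complementary intervals (1-based, first < second)."""

    arm1: tuple[int, int]
    arm2: tuple[int, int]
    length: int
    mismatches: int


_ENC = np.frombuffer(bytes(range(256)), dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b


def _candidate_diagonals(s: str, k: int, max_per_kmer: int = 64) -> set[int]:
    """Anti-diagonal constants c = i + j + k - 1 of exact seed matches
    between s and its reverse complement."""
    index: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        index.setdefault(s[i : i + k], []).append(i)
    diags: set[int] = set()
    rc = revcomp(s)
    L = len(s)
    for i in range(L - k + 1):
        key = rc[L - k - i : L - i]  # revcomp of s[i:i+k]
        hits = index.get(key)
        if hits is None or len(hits) > max_per_kmer:
            continue
        for j in hits:
            diags.add(i + j + k - 1)
    return diags


_MISMATCH_PENALTY = 30  # extension cost per mismatch (match scores +1)


def _best_on_diagonal(
    S: np.ndarray, C: np.ndarray, c: int, allow_mismatches: bool
) -> Optional[tuple[int, int, int]]:
    """Best repeat window on anti-diagonal c with disjoint arms.

    Seeds on the longest exact run, then (when mismatches are allowed)
    extends both ends to the maximum of a +1/-penalty score, so sparse
    interior mismatches are absorbed while random flanking sequence can
    never extend the repeat.  Returns (length, p_start, mismatches).
    """
    L = len(S)
    plo = max(0, c - (L - 1))
    # pair p with q = c - p; arms disjoint requires p < c - p  =>  p <= (c-1)//2
    pmax = min(L - 1, (c - 1) // 2)
    if pmax < plo:
        return None
    p = np.arange(plo, pmax + 1)
    match = S[p] == C[c - p]
    m = np.concatenate(([False], match, [False]))
    starts = np.flatnonzero(~m[:-1] & m[1:])
    ends = np.flatnonzero(m[:-1] & ~m[1:])
    if len(starts) == 0:
        return None
    runs = ends - starts
    k = int(np.argmax(runs))
    lo, hi = int(starts[k]), int(ends[k]) - 1  # inclusive indices into `match`
    nmm = 0
    if allow_mismatches:
        score = np.where(match, 1, -_MISMATCH_PENALTY)
        if hi + 1 <= len(match) - 1:
            right = np.cumsum(score[hi + 1 :])
            j = int(np.argmax(right))
            if right[j] > 0:
                hi = hi + 1 + j
        if lo > 0:
            left = np.cumsum(score[:lo][::-1])
            j = int(np.argmax(left))
            if left[j] > 0:
                lo = lo - 1 - j
        nmm = int((~match[lo : hi + 1]).sum())
    return hi - lo + 1, plo + lo, nmm


def find_inverted_repeats(
    sequence: str,
    min_len: int,
    max_mismatch_frac: float = 0.0,
    circular: bool = True,
    seed_k: int = 21,
    all_pairs: bool = False,
    max_len: Optional[int] = None,
) -> list[ArmPair]:
    """Maximal inverted-repeat interval pairs of length ≥ min_len.

    With ``all_pairs`` every maximal exact run on every candidate diagonal
    is reported (used for short-arm discovery); otherwise only the best
    pairs for the large-IR search are considered.
    """
    n = len(sequence)
    s = sequence + sequence if circular and n > seed_k else sequence
    k = min(seed_k, min_len)
    S = _encode(s)
    C = _COMP_TABLE[S]
    diags = _candidate_diagonals(s, k)
    pairs: dict[tuple[int, int], ArmPair] = {}

    for c in sorted(diags):
        if all_pairs:
            found = _exact_runs_on_diagonal(S, C, c, min_len)
        else:
            hit = _best_on_diagonal(S, C, c, allow_mismatches=max_mismatch_frac > 0)
            found = [hit] if hit is not None else []
        for blen, p1, nmm in found:
            if blen < min_len or (max_len is not None and blen > max_len):
                continue
            if nmm > max_mismatch_frac * blen:
                continue
            a1, a2 = p1, p1 + blen - 1  # first arm, ascending
            b1, b2 = c - a2, c - a1  # second arm
            pair = _normalize_pair(a1, a2, b1, b2, n, circular, nmm)
            if pair is None:
                continue
            key = (pair.arm1, pair.arm2)
            old = pairs.get(key)
            if old is None or pair.length > old.length:
                pairs[key] = pair
    out = sorted(
        pairs.values(), key=lambda p: (-p.length, p.arm1[0], p.arm2[0])
    )
    return out


def _exact_runs_on_diagonal(
    S: np.ndarray, C: np.ndarray, c: int, min_len: int
) -> list[tuple[int, int, int]]:
    L = len(S)
    plo = max(0, c - (L - 1))
    pmax = min(L - 1, (c - 1) // 2)
    if pmax < plo:
        return []
    p = np.arange(plo, pmax + 1)
    match = S[p] == C[c - p]
    runs = []
    # maximal True runs
    m = np.concatenate(([False], match, [False]))
    starts = np.flatnonzero(~m[:-1] & m[1:])
    ends = np.flatnonzero(m[:-1] & ~m[1:])
    for st, en in zip(starts, ends):
        blen = en - st
        if blen >= min_len:
            runs.append((int(blen), int(plo + st), 0))
    return runs


def _normalize_pair(
    a1: int, a2: int, b1: int, b2: int, n: int, circular: bool, nmm: int = 0
) -> Optional[ArmPair]:
    """Map doubled-sequence coordinates to 1-based circle coordinates;
    reject self-overlapping pairs."""
    blen = a2 - a1 + 1
    if b1 <= a2:  # arms overlap on the line
        return None
    if circular:
        if b2 - a1 + 1 > n:  # total footprint wraps onto itself
            return None
        # canonical representative: first arm start in [0, n)
        shift = (a1 // n) * n
        a1, a2, b1, b2 = a1 - shift, a2 - shift, b1 - shift, b2 - shift
        if a1 >= n:
            return None
        arm1 = (a1 % n + 1, a2 % n + 1)
        arm2 = (b1 % n + 1, b2 % n + 1)
    else:
        arm1 = (a1 + 1, a2 + 1)
        arm2 = (b1 + 1, b2 + 1)
    lo, hi = sorted([arm1, arm2])
    return ArmPair(lo, hi, blen, nmm)


def find_large_ir(
    genome: AnnotatedGenome,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.001,
) -> QuadripartiteStructure:
    """Detect the large IR and partition the genome into LSC/IR_B/SSC/IR_A.

    Returns the maximal-length pair of disjoint reverse-complementary
    intervals (mismatch fraction ≤ ``max_mismatch_frac``) found on the
    circular topology; the shorter inter-repeat gap becomes the SSC.
    Raises :class:`NoQuadripartiteError` when nothing qualifies.
    """
    n = len(genome)
    if n < 4 * min_len:
        raise NoQuadripartiteError(
            f"genome of {n} bp is shorter than 4 x min_len = {4 * min_len} bp"
        )
    pairs = find_inverted_repeats(
        genome.sequence,
        min_len=min_len,
        max_mismatch_frac=max_mismatch_frac,
        circular=genome.topology == "circular",
    )
    if not pairs:
        raise NoQuadripartiteError(
            f"no quadripartite structure: no inverted repeat >= {min_len} bp "
            f"at mismatch fraction <= {max_mismatch_frac} in {genome.id}"
        )
    best = pairs[0]
    (a1, a2), (b1, b2) = best.arm1, best.arm2
    # gap between arm1 end and arm2 start, and the complementary gap
    g1 = (b1 - a2 - 1) % n
    g2 = n - 2 * best.length - g1
    if g1 < 0 or g2 < 0:
        raise NoQuadripartiteError("degenerate repeat geometry")
    if g1 <= g2:
        # arm1 = IR_B, gap1 = SSC, arm2 = IR_A, gap2 = LSC (wrapping)
        ir_b, ssc, ir_a = (a1, a2), _gap_interval(a2, b1, n), (b1, b2)
        lsc = _gap_interval(b2, a1, n)
    else:
        ir_b, ssc, ir_a = (b1, b2), _gap_interval(b2, a1, n), (a1, a2)
        lsc = _gap_interval(a2, b1, n)
    return QuadripartiteStructure(lsc=lsc, ir_b=ir_b, ssc=ssc, ir_a=ir_a, genome_length=n)


def _gap_interval(after_end: int, before_start: int, n: int) -> tuple[int, int]:
    """Interval strictly between two positions on the circle (may wrap)."""
    s = after_end % n + 1
    e = (before_start - 2) % n + 1
    return (s, e)


# ---------------------------------------------------------------------------
# junction reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionReport:
    junction: str  # J_LB | J_SB | J_SA | J_LA
    gene: Optional[str]
    placement: str  # spans_junction | adjacent_upstream | adjacent_downstream | none
    duplicated_bp: int
    end_involved: Optional[str]  # 5prime | 3prime | None


def _feature_extent(f: GeneFeature, n: int) -> tuple[int, int]:
    """Overall [start, end] of a feature, unwrapped past the origin if needed
    (end may exceed n)."""
    if not f.wraps_origin:
        return f.start, f.end
    for s, e in f.parts:
        if e < s:  # single wrapping part
            return s, e + n
    # parts split around the origin: the feature occupies the complement of
    # the largest inter-part gap on the circle
    parts = sorted(f.parts)
    best_gap, gap_after = -1, 0
    for i, (_, e) in enumerate(parts):
        s_next = parts[(i + 1) % len(parts)][0] + (n if i == len(parts) - 1 else 0)
        gap = s_next - e - 1
        if gap > best_gap:
            best_gap, gap_after = gap, i
    s = parts[(gap_after + 1) % len(parts)][0]
    e = parts[gap_after][1]
    return (s, e + n) if e < s else (s, e)


def _circ_contains(s: int, e: int, pos: int, n: int) -> bool:
    for p in (pos, pos + n):
        if s <= p <= e:
            return True
    return False


def junction_report(
    genome: AnnotatedGenome, structure: QuadripartiteStructure
) -> list[JunctionReport]:
    """Per-junction gene placement and duplicated-bp accounting.

    A junction is the ordered pair (last base of the upstream region, first
    base downstream); a gene spans it when its extent contains both bases.
    For spanning genes duplicated_bp is the length of the gene's overlap
    with the adjacent IR, and end_involved says which gene end lies in the
    IR (that portion appears twice in the genome).
    """
    n = structure.genome_length
    ir_side = {
        "J_LB": structure.ir_b,
        "J_SB": structure.ir_b,
        "J_SA": structure.ir_a,
        "J_LA": structure.ir_a,
    }
    reports: list[JunctionReport] = []
    for jname, jpos in structure.junctions.items():
        down = jpos % n + 1
        spanning = [
            f
            for f in genome.features
            if _extent_contains(f, jpos, n) and _extent_contains(f, down, n)
        ]
        if not genome.features:
            reports.append(JunctionReport(jname, None, "none", 0, None))
            continue
        if spanning:
            f = min(spanning, key=lambda f: f.length)
            dup = _overlap_len(_feature_extent(f, n), ir_side[jname], n)
            end = _end_in_ir(f, ir_side[jname], n)
            reports.append(JunctionReport(jname, f.name, "spans_junction", dup, end))
        else:
            up_f = _nearest(genome.features, jpos, n, upstream=True)
            dn_f = _nearest(genome.features, down, n, upstream=False)
            if up_f is not None:
                reports.append(
                    JunctionReport(jname, up_f.name, "adjacent_upstream", 0, None)
                )
            if dn_f is not None:
                reports.append(
                    JunctionReport(jname, dn_f.name, "adjacent_downstream", 0, None)
                )
    return reports


def _extent_contains(f: GeneFeature, pos: int, n: int) -> bool:
    s, e = _feature_extent(f, n)
    return _circ_contains(s, e, pos, n)


def _overlap_len(extent: tuple[int, int], iv: tuple[int, int], n: int) -> int:
    s, e = extent
    a, b = iv
    ivs = [(a, b)] if a <= b else [(a, n), (1, b)]
    total = 0
    for aa, bb in ivs:
        for off in (0, n):
            lo = max(s, aa + off)
            hi = min(e, bb + off)
            if hi >= lo:
                total += hi - lo + 1
    return total


def _end_in_ir(f: GeneFeature, iv: tuple[int, int], n: int) -> Optional[str]:
    s, e = _feature_extent(f, n)
    a, b = iv
    in_ir_start = _circ_contains(a, b if b >= a else b + n, s % n or n, n)
    in_ir_end = _circ_contains(a, b if b >= a else b + n, e % n or n, n)
    if in_ir_start == in_ir_end:
        return None
    # genome-forward end that is inside the IR
    forward_end_in_ir = in_ir_end
    if f.strand == "+":
        return "3prime" if forward_end_in_ir else "5prime"
    return "5prime" if forward_end_in_ir else "3prime"


def _nearest(
    features: list[GeneFeature], pos: int, n: int, upstream: bool
) -> Optional[GeneFeature]:
    best, bestd = None, None
    for f in features:
        s, e = _feature_extent(f, n)
        d = (pos - e) % n if upstream else (s - pos) % n
        if bestd is None or d < bestd:
            best, bestd = f, d
    return best


# ---------------------------------------------------------------------------
# boundary shifts between two genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundaryShift:
    junction: str
    direction: str  # expansion_into_* | contraction_from_* | none | undetermined
    magnitude_bp: int
    genes_gained_by_ir: tuple[str, ...]
    genes_lost_by_ir: tuple[str, ...]


# single-copy region adjacent to each junction, and whether downstream
# junction movement (positive displacement) means IR contraction
_SC_SIDE = {
    "J_LB": ("LSC", "upstream"),
    "J_SB": ("SSC", "downstream"),
    "J_SA": ("SSC", "upstream"),
    "J_LA": ("LSC", "downstream"),
}


def _signed_offset(pos: float, jpos: int, n: int) -> float:
    d = (pos - jpos) % n
    return d if d <= n / 2 else d - n


def _sc_interval(structure: QuadripartiteStructure, region: str) -> tuple[int, int]:
    return structure.lsc if region == "LSC" else structure.ssc


def _in_interval(pos: float, iv: tuple[int, int], n: int) -> bool:
    a, b = iv
    if a <= b:
        return a <= pos <= b
    return pos >= a or pos <= b


def classify_boundary_shift(
    sample: AnnotatedGenome,
    sample_structure: QuadripartiteStructure,
    reference: AnnotatedGenome,
    reference_structure: QuadripartiteStructure,
    n_anchors: int = 2,
) -> list[BoundaryShift]:
    """IR boundary expansion/contraction of ``sample`` relative to ``reference``.

    Each junction's displacement is measured against the midpoint of the
    nearest shared single-copy anchor genes on the junction's single-copy
    side (anchors inside the IR would move with the boundary event itself).
    Genes whose IR membership differs between the genomes are listed as
    gained/lost at their nearest junction.
    """
    n_s, n_r = len(sample), len(reference)

    def single_copy_names(g: AnnotatedGenome) -> dict[str, GeneFeature]:
        counts: dict[str, list[GeneFeature]] = {}
        for f in g.features:
            counts.setdefault(f.name, []).append(f)
        return {k: v[0] for k, v in counts.items() if len(v) == 1}

    sc_s, sc_r = single_copy_names(sample), single_copy_names(reference)
    shared_sc = set(sc_s) & set(sc_r)

    # gained / lost gene names (any copy overlapping the IR)
    def ir_names(g: AnnotatedGenome, st: QuadripartiteStructure) -> set[str]:
        return {f.name for f in g.features if _overlaps_ir(f, st)}

    ir_sample, ir_ref = ir_names(sample, sample_structure), ir_names(reference, reference_structure)
    shared_all = {f.name for f in sample.features} & {f.name for f in reference.features}
    gained = (ir_sample - ir_ref) & shared_all
    lost = (ir_ref - ir_sample) & shared_all

    def nearest_junction(g: AnnotatedGenome, st: QuadripartiteStructure, name: str) -> str:
        f = next(f for f in g.features if f.name == name)
        mid = f.midpoint(len(g))
        return min(
            st.junctions.items(), key=lambda kv: abs(_signed_offset(mid, kv[1], len(g)))
        )[0]

    gained_at: dict[str, list[str]] = {}
    for name in sorted(gained):
        gained_at.setdefault(nearest_junction(sample, sample_structure, name), []).append(name)
    lost_at: dict[str, list[str]] = {}
    for name in sorted(lost):
        lost_at.setdefault(nearest_junction(reference, reference_structure, name), []).append(name)

    shifts: list[BoundaryShift] = []
    for jname, (region, side) in _SC_SIDE.items():
        j_s = sample_structure.junctions[jname]
        j_r = reference_structure.junctions[jname]
        iv_s = _sc_interval(sample_structure, region)
        iv_r = _sc_interval(reference_structure, region)
        candidates = []
        for name in shared_sc:
            f_s, f_r = sc_s[name], sc_r[name]
            m_s, m_r = f_s.midpoint(n_s), f_r.midpoint(n_r)
            if not (_in_interval(m_s, iv_s, n_s) and _in_interval(m_r, iv_r, n_r)):
                continue
            off_s = _signed_offset(m_s, j_s, n_s)
            off_r = _signed_offset(m_r, j_r, n_r)
            want_positive = side == "downstream"
            if (off_r > 0) != want_positive or (off_s > 0) != want_positive:
                continue
            candidates.append((abs(off_r), off_s, off_r))
        if not candidates:
            shifts.append(BoundaryShift(jname, "undetermined", 0,
                                        tuple(gained_at.get(jname, ())),
                                        tuple(lost_at.get(jname, ()))))
            continue
        candidates.sort()
        chosen = candidates[:n_anchors]
        off_s_mean = sum(c[1] for c in chosen) / len(chosen)
        off_r_mean = sum(c[2] for c in chosen) / len(chosen)
        delta = off_r_mean - off_s_mean  # junction displacement, + = downstream
        magnitude = int(round(abs(delta)))
        if magnitude == 0:
            direction = "none"
        else:
            into_sc_is_downstream = side == "downstream"
            moved_downstream = delta > 0
            expanding = moved_downstream == into_sc_is_downstream
            word = "expansion_into" if expanding else "contraction_from"
            direction = f"{word}_{region}"
        shifts.append(
            BoundaryShift(
                jname,
                direction,
                magnitude,
                tuple(gained_at.get(jname, ())),
                tuple(lost_at.get(jname, ())),
            )
        )
    return shifts
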