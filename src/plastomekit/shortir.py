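"""Short inverted-repeat arms, flip-flop inversion, breakpoint junction references.

A pair of short (tens of bp) perfectly reverse-complementary arms in a
single-copy region is the substrate of flip-flop recombination: the segment
they bound (arms inclusive) can invert intramolecularly, producing two
coexisting isomeric genome arrangements.  This module finds such arm pairs,
applies the inversion, and builds the four arm-plus-flank junction
references that distinguish the two conformations (IPWI: inverted
arrangement; IPWC: canonical arrangement) in read data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .genome import AnnotatedGenome, GeneFeature, QuadripartiteStructure, revcomp
from .irdetect import _feature_extent, find_inverted_repeats

__all__ = [
    "ShortIRPair",
    "JunctionReference",
    "JunctionReferenceSet",
    "find_short_ir_pairs",
    "flip_flop_isomer",
    "build_junction_refs",
]

IPWI = "IPWI"
IPWC = "IPWC"


@dataclass(frozen=True)
class ShortIRPair:
    """Two mutually reverse-complementary arms and the segment they bound.

    ``segment`` runs from the first base of the left arm to the last base of
    the right arm (arms inclusive), so inverting it preserves the boundary
    arms and the operation is an involution.
    """

    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    arm_len: int
    nearest_genes: tuple[Optional[str], Optional[str]]  # gene at/flanking each arm

    @property
    def segment(self) -> tuple[int, int]:
        return (self.left_arm[0], self.right_arm[1])

    @property
    def segment_len(self) -> int:
        return self.right_arm[1] - self.left_arm[0] + 1


def _arm_gene(genome: AnnotatedGenome, arm: tuple[int, int]) -> Optional[str]:
    """Gene containing the arm, else the nearest gene by midpoint distance."""
    n = len(genome)
    mid = (arm[0] + arm[1]) / 2.0
    containing = [
        f
        for f in genome.features
        if _feature_extent(f, n)[0] <= arm[0] and _feature_extent(f, n)[1] >= arm[1]
    ]
    if containing:
        return min(containing, key=lambda f: f.length).name
    if not genome.features:
        return None
    return min(genome.features, key=lambda f: abs(f.midpoint(n) - mid)).name


def _inside(iv: tuple[int, int], region: tuple[int, int], n: int) -> bool:
    a, b = region
    if a <= b:
        return a <= iv[0] and iv[1] <= b
    return iv[0] >= a or iv[1] <= b  # wrapping region: rough containment


def find_short_ir_pairs(
    genome: AnnotatedGenome,
    min_arm: int = 20,
    max_arm: int = 100,
    min_segment: int = 1000,
    region: Optional[tuple[int, int]] = None,
    structure: Optional[QuadripartiteStructure] = None,
) -> list[ShortIRPair]:
    """All maximal exact inverted-repeat arm pairs able to mediate a flip-flop.

    Arms must be perfect reverse complements, arm_len in [min_arm, max_arm],
    segment length ≥ min_segment.  When a quadripartite ``structure`` is
    given, arms falling inside the large IR are excluded (the repeat search
    is restricted to single-copy regions); ``region`` further restricts the
    search window.  Results are sorted by arm_len descending, then position;
    pairs nested inside a longer pair's arms are suppressed.
    """
    pairs = find_inverted_repeats(
        genome.sequence,
        min_len=min_arm,
        max_mismatch_frac=0.0,
        circular=genome.topology == "circular",
        seed_k=min_arm,
        all_pairs=True,
    )
    n = len(genome)
    out: list[ShortIRPair] = []
    for p in pairs:
        if p.length > max_arm:
            continue
        left, right = p.arm1, p.arm2
        seg_len = right[1] - left[0] + 1
        if seg_len < min_segment:
            continue
        if structure is not None:
            in_ir = any(
                _inside(arm, ir, n)
                for arm in (left, right)
                for ir in (structure.ir_a, structure.ir_b)
            )
            if in_ir:
                continue
        if region is not None and not (
            _inside(left, region, n) and _inside(right, region, n)
        ):
            continue
        out.append(
            ShortIRPair(
                left_arm=left,
                right_arm=right,
                arm_len=p.length,
                nearest_genes=(_arm_gene(genome, left), _arm_gene(genome, right)),
            )
        )
    # suppress pairs whose arms are nested inside a longer reported pair
    out.sort(key=lambda p: (-p.arm_len, p.left_arm, p.right_arm))
    kept: list[ShortIRPair] = []
    for p in out:
        nested = any(
            k.left_arm[0] <= p.left_arm[0]
            and p.left_arm[1] <= k.left_arm[1]
            and k.right_arm[0] <= p.right_arm[0]
            and p.right_arm[1] <= k.right_arm[1]
            for k in kept
        )
        if not nested:
            kept.append(p)
    return kept


def flip_flop_isomer(genome: AnnotatedGenome, pair: ShortIRPair) -> AnnotatedGenome:
    """Apply the flip-flop inversion: reverse-complement the arm-bounded segment.

    Features fully inside the segment are remapped with flipped strand;
    features straddling a segment boundary keep their coordinates (with a
    warning).  Applying the operation twice restores the genome exactly.
    """
    s, e = pair.segment
    seq = genome.sequence
    n = len(seq)
    if not (1 <= s <= e <= n):
        raise ValueError("pair does not fit this genome")
    left = seq[pair.left_arm[0] - 1 : pair.left_arm[1]]
    right = seq[pair.right_arm[0] - 1 : pair.right_arm[1]]
    if left != revcomp(right):
        raise ValueError("arm pair is not reverse-complementary on this genome")
    new_seq = seq[: s - 1] + revcomp(seq[s - 1 : e]) + seq[e:]
    feats: list[GeneFeature] = []
    for f in genome.features:
        fs, fe = _feature_extent(f, n)
        if fe < s or fs > e:
            feats.append(f)
            continue
        if fs < s or fe > e:
            warnings.warn(
                f"feature {f.name} straddles the inversion boundary; kept as-is",
                stacklevel=2,
            )
            feats.append(f)
            continue
        parts = tuple(sorted((s + e - pe, s + e - ps) for ps, pe in f.parts))
        feats.append(
            GeneFeature(
                f.name,
                f.category,
                "-" if f.strand == "+" else "+",
                parts,
                f.wraps_origin,
            )
        )
    feats.sort(key=lambda f: f.start)
    return AnnotatedGenome(genome.id, new_seq, feats, genome.topology)


@dataclass(frozen=True)
class JunctionReference:
    conformation: str  # IPWI | IPWC
    label: str  # e.g. psbI-trnS-GGA-ycf3
    sequence: str
    arm_interval: tuple[int, int]  # 1-based interval of the arm within sequence


@dataclass(frozen=True)
class JunctionReferenceSet:
    references: tuple[JunctionReference, ...]
    arm_len: int
    flank_w: int

    def by_conformation(self, conformation: str) -> list[JunctionReference]:
        return [r for r in self.references if r.conformation == conformation]


def _ref_at_arm(
    genome: AnnotatedGenome, arm: tuple[int, int], flank_w: int
) -> tuple[str, tuple[int, int]]:
    n = len(genome)
    a, b = arm
    if genome.topology == "circular":
        start = a - flank_w
        end = b + flank_w
        s1 = (start - 1) % n + 1
        e1 = (end - 1) % n + 1
        if b - a + 1 + 2 * flank_w >= n:
            raise ValueError("flanks would wrap the whole genome")
        seq = genome.subseq(s1, e1)
        left_w = flank_w
    else:
        s1 = max(1, a - flank_w)
        e1 = min(n, b + flank_w)
        if s1 != a - flank_w or e1 != b + flank_w:
            warnings.warn("flank truncated at genome boundary", stacklevel=2)
        seq = genome.subseq(s1, e1)
        left_w = a - s1
    arm_iv = (left_w + 1, left_w + (b - a + 1))
    return seq, arm_iv


def _label(genome: AnnotatedGenome, arm: tuple[int, int], flank_w: int) -> str:
    """left-flank gene, arm gene, right-flank gene, joined with dashes."""
    n = len(genome)
    mid_gene = _arm_gene(genome, arm)
    left_pos = (arm[0] - flank_w - 1) % n + 1
    right_pos = (arm[1] + flank_w - 1) % n + 1

    def nearest_named(pos: int, exclude: Optional[str]) -> Optional[str]:
        cands = [f for f in genome.features if f.name != exclude]
        if not cands:
            return None
        return min(cands, key=lambda f: abs(f.midpoint(n) - pos)).name

    left = nearest_named(left_pos, mid_gene)
    right = nearest_named(right_pos, mid_gene)
    return "-".join(x for x in (left, mid_gene, right) if x)


def build_junction_refs(
    genome_ipwc: AnnotatedGenome, pair: ShortIRPair, flank_w: int = 500
) -> JunctionReferenceSet:
    """Build the four breakpoint junction references (two per conformation).

    IPWC references come from the input genome at each arm; IPWI references
    from its flip-flop isomer.  Each reference is left flank (W bp) + arm +
    right flank (W bp); labels are derived from the genes at and flanking
    the arm.
    """
    if flank_w <= 0:
        raise ValueError(
            "flanks required: with flank_w = 0 the IPWI and IPWC references "
            "are identical bare arms"
        )
    isomer = flip_flop_isomer(genome_ipwc, pair)
    refs: list[JunctionReference] = []
    for conf, g in ((IPWC, genome_ipwc), (IPWI, isomer)):
        for arm in (pair.left_arm, pair.right_arm):
            seq, arm_iv = _ref_at_arm(g, arm, flank_w)
            refs.append(JunctionReference(conf, _label(g, arm, flank_w), seq, arm_iv))
    return JunctionReferenceSet(tuple(refs), pair.arm_len, flank_w)


def write_junction_refs_fasta(refs: JunctionReferenceSet, path) -> None:
    lines = []
    for i, r in enumerate(refs.references):
        lines.append(f">{r.conformation}|{r.label}|arm={r.arm_interval[0]}-{r.arm_interval[1]}")
        lines.append(r.sequence)
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def read_junction_refs_fasta(path) -> JunctionReferenceSet:
    from pathlib import Path

    refs = []
    header, chunks = None, []
    arm_len = 0

    def flush():
        nonlocal arm_len
        if header is None:
            return
        conf, label, armspec = header.split("|")
        a, b = armspec.removeprefix("arm=").split("-")
        arm_iv = (int(a), int(b))
        arm_len = arm_iv[1] - arm_iv[0] + 1
        refs.append(JunctionReference(conf, label, "".join(chunks), arm_iv))

    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            flush()
            header, chunks = line[1:], []
        elif line.strip():
            chunks.append(line.strip())
    flush()
    flank_w = refs[0].arm_interval[0] - 1 if refs else 0
    return JunctionReferenceSet(tuple(refs), arm_len, flank_w)
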