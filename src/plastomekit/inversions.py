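"""Gene-order inversion calling between two annotated plastomes.

Rearrangements are detected on the signed permutation of shared unique
loci: maximal runs that are contiguous in both genomes, reversed in order,
and uniformly strand-flipped are emitted as one inversion call each, with
the novel gene adjacencies created at the block edges and the block span in
the query.  This annotation-based comparison trades sub-gene breakpoint
precision for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from Bio.Align import PairwiseAligner

from .genome import AnnotatedGenome, GeneFeature, QuadripartiteStructure, revcomp
from .irdetect import _feature_extent, _overlaps_ir

__all__ = [
    "SignedPermutation",
    "InversionCall",
    "EndDiffReport",
    "shared_gene_permutation",
    "call_inversions",
    "calls_explain_permutation",
    "compare_ortholog_ends",
]

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SignedPermutation:
    """Shared loci of the query expressed against the reference gene order.

    ``genes``/``signs`` list the loci in reference order with sign +1 when
    the query copy lies on the same strand as the reference copy.
    ``query_rank[i]`` is the 0-based position of ``genes[i]`` along the
    query; anchor midpoints (bp) are kept for span measurements.
    """

    genes: tuple[str, ...]
    signs: tuple[int, ...]
    query_rank: tuple[int, ...]
    ref_mid: dict[str, float]
    query_mid: dict[str, float]

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def query_order(self) -> list[tuple[str, int]]:
        """(gene, sign) pairs in query order."""
        order = sorted(range(len(self.genes)), key=lambda i: self.query_rank[i])
        return [(self.genes[i], self.signs[i]) for i in order]

    def is_identity(self) -> bool:
        return all(s == 1 for s in self.signs) and self.query_rank == tuple(
            range(len(self.genes))
        )


def _usable_loci(
    genome: AnnotatedGenome, structure: Optional[QuadripartiteStructure]
) -> dict[str, GeneFeature]:
    """One representative feature per usable locus name.

    IR-duplicated genes are represented by their single-copy-region copy
    when a structure is supplied; without one, multi-copy names are dropped.
    """
    by_name: dict[str, list[GeneFeature]] = {}
    for f in genome.features:
        by_name.setdefault(f.name, []).append(f)
    out: dict[str, GeneFeature] = {}
    for name, fs in by_name.items():
        if len(fs) == 1:
            out[name] = fs[0]
        elif structure is not None:
            sc = [f for f in fs if not _overlaps_ir(f, structure)]
            if len(sc) == 1:
                out[name] = sc[0]
    return out


def shared_gene_permutation(
    reference: AnnotatedGenome,
    query: AnnotatedGenome,
    reference_structure: Optional[QuadripartiteStructure] = None,
    query_structure: Optional[QuadripartiteStructure] = None,
) -> SignedPermutation:
    """Signed permutation of the query's shared unique loci in reference order."""
    ref_loci = _usable_loci(reference, reference_structure)
    qry_loci = _usable_loci(query, query_structure)
    shared = sorted(set(ref_loci) & set(qry_loci))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared unique loci between {reference.id} "
            f"and {query.id}; need at least 3"
        )
    n_r, n_q = len(reference), len(query)
    ref_mid = {g: ref_loci[g].midpoint(n_r) for g in shared}
    qry_mid = {g: qry_loci[g].midpoint(n_q) for g in shared}
    ref_order = sorted(shared, key=lambda g: ref_mid[g])
    qry_order = sorted(shared, key=lambda g: qry_mid[g])
    qry_rank = {g: i for i, g in enumerate(qry_order)}
    signs = tuple(
        1 if ref_loci[g].strand == qry_loci[g].strand else -1 for g in ref_order
    )
    return SignedPermutation(
        genes=tuple(ref_order),
        signs=signs,
        query_rank=tuple(qry_rank[g] for g in ref_order),
        ref_mid=ref_mid,
        query_mid=qry_mid,
    )


@dataclass(frozen=True)
class InversionCall:
    """A contiguous reversed gene block in the query relative to the reference."""

    first_gene: str  # reference-order first gene of the block
    last_gene: str
    block_size: int
    span_bp: int  # outermost block feature boundaries in the query
    novel_adjacencies: tuple[tuple[str, str], ...]
    complex_region: bool = False

    @property
    def genes(self) -> tuple[str, str]:
        return (self.first_gene, self.last_gene)


def call_inversions(
    perm: SignedPermutation,
    reference: AnnotatedGenome,
    query: AnnotatedGenome,
) -> list[InversionCall]:
    """Emit one call per maximal uniformly sign-flipped reversed run.

    A run is a set of loci consecutive in query order whose reference ranks
    decrease by exactly one at each step and whose signs are all -1.  Novel
    adjacencies are the query gene pairs flanking the block that are not
    adjacent in the reference.
    """
    n = len(perm)
    ref_rank = {g: i for i, g in enumerate(perm.genes)}
    sign = dict(zip(perm.genes, perm.signs))
    qorder = [g for g, _ in perm.query_order]

    calls: list[InversionCall] = []
    i = 0
    while i < n:
        g = qorder[i]
        if sign[g] != -1:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and sign[qorder[j + 1]] == -1
            and ref_rank[qorder[j + 1]] == ref_rank[qorder[j]] - 1
        ):
            j += 1
        block = qorder[i : j + 1]  # query order; reference order is reversed
        first_gene = block[-1]
        last_gene = block[0]
        span = _block_span(query, block)
        adjacencies = []
        cplx = False
        for left, right in ((i - 1, i), (j, j + 1)):
            if left < 0 or right >= n:
                continue
            a, b = qorder[left], qorder[right]
            if abs(ref_rank[a] - ref_rank[b]) != 1:
                adjacencies.append(tuple(sorted((a, b))))
            neighbor = a if right == i else b
            if neighbor not in block and sign[neighbor] == -1:
                cplx = True
        calls.append(
            InversionCall(
                first_gene=first_gene,
                last_gene=last_gene,
                block_size=len(block),
                span_bp=span,
                novel_adjacencies=tuple(adjacencies),
                complex_region=cplx,
            )
        )
        i = j + 1
    if calls and not calls_explain_permutation(perm, calls):
        warnings.warn(
            "called inversions do not fully explain the permutation; "
            "complex rearrangement scenario",
            stacklevel=2,
        )
        calls = [
            InversionCall(
                c.first_gene, c.last_gene, c.block_size, c.span_bp,
                c.novel_adjacencies, True,
            )
            for c in calls
        ]
    return calls


def _block_span(query: AnnotatedGenome, block: list[str]) -> int:
    n = len(query)
    extents = []
    for name in block:
        f = query.feature_by_name(name)
        extents.append(_feature_extent(f, n))
    lo = min(s for s, _ in extents)
    hi = max(e for _, e in extents)
    return hi - lo + 1


def calls_explain_permutation(
    perm: SignedPermutation, calls: list[InversionCall]
) -> bool:
    """True when reversing each called block turns the query into the reference.

    Independent self-consistency check: apply each call as a block reversal
    with sign flip to the signed query-order sequence and test for identity.
    """
    ref_rank = {g: i for i, g in enumerate(perm.genes)}
    seq = [(ref_rank[g], s) for g, s in perm.query_order]
    for call in calls:
        a, b = ref_rank[call.first_gene], ref_rank[call.last_gene]
        lo, hi = min(a, b), max(a, b)
        pos = [i for i, (r, _) in enumerate(seq) if lo <= r <= hi]
        if not pos or pos != list(range(pos[0], pos[-1] + 1)):
            return False
        i0, i1 = pos[0], pos[-1]
        seq[i0 : i1 + 1] = [(r, -s) for r, s in reversed(seq[i0 : i1 + 1])]
    return seq == [(i, 1) for i in range(len(seq))]


# ---------------------------------------------------------------------------
# ortholog end comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndDiffReport:
    gene: str
    delta_5prime_bp: int  # query minus reference
    delta_3prime_bp: int
    orf_intact: bool


def extract_cds(genome: AnnotatedGenome, gene: str) -> str:
    """Coding sequence in transcription orientation (5'->3')."""
    f = genome.feature_by_name(gene)
    seq = "".join(genome.subseq(s, e) for s, e in f.parts)
    return revcomp(seq) if f.strand == "-" else seq


def _orf_intact(cds: str) -> bool:
    if len(cds) < 6 or len(cds) % 3 != 0:
        return False
    if cds[:3] not in START_CODONS or cds[-3:] not in STOP_CODONS:
        return False
    return all(cds[i : i + 3] not in STOP_CODONS for i in range(3, len(cds) - 3, 3))


def compare_ortholog_ends(
    reference: AnnotatedGenome, query: AnnotatedGenome, gene: str
) -> EndDiffReport:
    """End-length differences of one ortholog (query minus reference, bp).

    The two coding sequences are aligned globally with free end gaps (the 3'
    ends of the truncation cases anchor the alignment); the signed 5'/3'
    deltas are the differences in unaligned overhang.  ``orf_intact`` tests
    the query CDS for a start codon, terminal stop, and no internal in-frame
    stop.
    """
    cds_r = extract_cds(reference, gene)
    cds_q = extract_cds(query, gene)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    # free end gaps on both sequences (attribute names changed across releases)
    if hasattr(aligner, "open_end_insertion_score"):
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    else:  # pragma: no cover - older releases
        aligner.target_end_open_gap_score = 0
        aligner.target_end_extend_gap_score = 0
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    aln = aligner.align(cds_r, cds_q)[0]
    (rblocks, qblocks) = aln.aligned
    r0, q0 = int(rblocks[0][0]), int(qblocks[0][0])
    r1, q1 = int(rblocks[-1][1]), int(qblocks[-1][1])
    # overhangs: bases before the first aligned column / after the last
    delta5 = q0 - r0
    delta3 = (len(cds_q) - q1) - (len(cds_r) - r1)
    return EndDiffReport(
        gene=gene,
        delta_5prime_bp=delta5,
        delta_3prime_bp=delta3,
        orf_intact=_orf_intact(cds_q),
    )
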