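"""Synthetic plastome-like genomes, isomer pairs, planted rearrangements, read mixtures.

Generators with known planted truth stand in for real (undeposited) raw
sequencing data.  Background sequence is i.i.d. at the requested GC (no
repeat structure beyond what is planted, so brute-force oracles stay
valid); protein-coding gene sequences are random open reading frames; the
default gene template is a miniature of the canonical plastid gene order so
adjacency-level expectations read naturally.  Every generator is
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import gzip
import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genome import (
    AnnotatedGenome,
    GeneFeature,
    QuadripartiteStructure,
    canonical_structure,
    revcomp,
)
from .irdetect import _feature_extent

__all__ = [
    "GeneTemplate",
    "ShortIRSpec",
    "SyntheticPlastomeSpec",
    "ReadSimSpec",
    "DEFAULT_GENE_TEMPLATE",
    "build_synthetic_plastome",
    "simulate_read_mixture",
    "plant_inversion",
    "extend_ir_into_ssc",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
]


@dataclass(frozen=True)
class GeneTemplate:
    symbol: str
    category: str  # PCG | tRNA | rRNA
    length: int  # bp of coding/structural sequence (sum of parts)
    strand: str
    region: str  # LSC | IR | SSC
    n_parts: int = 1  # >1 encodes introns


def _t(symbol, category, length, strand, region, n_parts=1):
    return GeneTemplate(symbol, category, length, strand, region, n_parts)


#: miniature of the canonical plastid gene order; the trnS pair carries the
#: flip-flop arms, rps19/ycf1/ndhF sit at their usual junction-adjacent spots
DEFAULT_GENE_TEMPLATE: tuple[GeneTemplate, ...] = (
    # --- LSC ---
    _t("trnH-GUG", "tRNA", 75, "-", "LSC"),
    _t("psbA", "PCG", 1062, "-", "LSC"),
    _t("matK", "PCG", 1530, "-", "LSC"),
    _t("rps16", "PCG", 252, "-", "LSC", n_parts=2),
    _t("psbK", "PCG", 186, "+", "LSC"),
    _t("psbI", "PCG", 111, "+", "LSC"),
    _t("trnS-GCU", "tRNA", 88, "-", "LSC"),
    _t("trnG-UCC", "tRNA", 71, "+", "LSC"),
    _t("trnR-UCU", "tRNA", 72, "+", "LSC"),
    _t("atpA", "PCG", 1524, "-", "LSC"),
    _t("atpF", "PCG", 555, "-", "LSC", n_parts=2),
    _t("atpH", "PCG", 246, "-", "LSC"),
    _t("atpI", "PCG", 744, "-", "LSC"),
    _t("rps2", "PCG", 711, "-", "LSC"),
    _t("rpoC2", "PCG", 2100, "-", "LSC"),
    _t("rpoC1", "PCG", 2022, "-", "LSC", n_parts=2),
    _t("rpoB", "PCG", 2100, "-", "LSC"),
    _t("petN", "PCG", 90, "+", "LSC"),
    _t("psbM", "PCG", 105, "-", "LSC"),
    _t("psbD", "PCG", 1062, "+", "LSC"),
    _t("psbC", "PCG", 1386, "+", "LSC"),
    _t("psaB", "PCG", 1503, "+", "LSC"),
    _t("psaA", "PCG", 1503, "+", "LSC"),
    _t("ycf3", "PCG", 507, "-", "LSC", n_parts=3),
    _t("trnS-GGA", "tRNA", 87, "+", "LSC"),
    _t("rps4", "PCG", 606, "-", "LSC"),
    _t("ndhJ", "PCG", 477, "-", "LSC"),
    _t("ndhC", "PCG", 363, "-", "LSC"),
    _t("atpE", "PCG", 402, "-", "LSC"),
    _t("atpB", "PCG", 1497, "-", "LSC"),
    _t("rbcL", "PCG", 1428, "+", "LSC"),
    _t("accD", "PCG", 1530, "+", "LSC"),
    _t("psaI", "PCG", 111, "+", "LSC"),
    _t("ycf4", "PCG", 555, "+", "LSC"),
    _t("cemA", "PCG", 690, "+", "LSC"),
    _t("petA", "PCG", 963, "+", "LSC"),
    _t("psbJ", "PCG", 123, "-", "LSC"),
    _t("psbE", "PCG", 252, "-", "LSC"),
    _t("petL", "PCG", 96, "+", "LSC"),
    _t("psaJ", "PCG", 135, "+", "LSC"),
    _t("rpl33", "PCG", 201, "+", "LSC"),
    _t("rps18", "PCG", 306, "+", "LSC"),
    _t("rpl20", "PCG", 354, "-", "LSC"),
    _t("rps12", "PCG", 114, "-", "LSC"),  # trans-spliced 5' exon
    _t("clpP", "PCG", 591, "-", "LSC", n_parts=3),
    _t("psbB", "PCG", 1527, "+", "LSC"),
    _t("petB", "PCG", 648, "+", "LSC", n_parts=2),
    _t("petD", "PCG", 525, "+", "LSC", n_parts=2),
    _t("rpoA", "PCG", 1014, "-", "LSC"),
    _t("rps11", "PCG", 417, "-", "LSC"),
    _t("rpl14", "PCG", 369, "-", "LSC"),
    _t("rpl16", "PCG", 408, "-", "LSC", n_parts=2),
    _t("rps3", "PCG", 657, "-", "LSC"),
    _t("rps19", "PCG", 279, "+", "LSC"),
    # --- IR (IR_B orientation) ---
    _t("rpl2", "PCG", 822, "-", "IR", n_parts=2),
    _t("rpl23", "PCG", 282, "-", "IR"),
    _t("ycf2", "PCG", 2001, "+", "IR"),
    _t("ndhB", "PCG", 1533, "-", "IR", n_parts=2),
    _t("rps7", "PCG", 468, "-", "IR"),
    _t("rps12", "PCG", 234, "-", "IR", n_parts=2),  # trans-spliced 3' exons
    _t("rrn16", "rRNA", 1491, "+", "IR"),
    _t("trnI-GAU", "tRNA", 72, "+", "IR"),
    _t("trnA-UGC", "tRNA", 73, "+", "IR"),
    _t("rrn23", "rRNA", 2001, "+", "IR"),
    _t("rrn4.5", "rRNA", 103, "+", "IR"),
    _t("rrn5", "rRNA", 121, "+", "IR"),
    _t("trnR-ACG", "tRNA", 74, "+", "IR"),
    _t("trnN-GUU", "tRNA", 72, "-", "IR"),
    # --- SSC ---
    _t("ndhF", "PCG", 1500, "-", "SSC"),
    _t("rpl32", "PCG", 174, "+", "SSC"),
    _t("ccsA", "PCG", 960, "+", "SSC"),
    _t("ndhD", "PCG", 1500, "-", "SSC"),
    _t("psaC", "PCG", 246, "-", "SSC"),
    _t("ndhE", "PCG", 306, "-", "SSC"),
    _t("ndhG", "PCG", 531, "-", "SSC"),
    _t("ndhI", "PCG", 543, "-", "SSC"),
    _t("ndhA", "PCG", 1092, "-", "SSC", n_parts=2),
    _t("ndhH", "PCG", 1182, "-", "SSC"),
    _t("rps15", "PCG", 273, "-", "SSC"),
    _t("ycf1", "PCG", 1800, "+", "SSC"),
)


#: reduced gene set for scaled-down genomes (e.g. 40 kb read-simulation
#: substrates); keeps the flip-flop anchors and their breakpoint neighbours
COMPACT_GENE_TEMPLATE: tuple[GeneTemplate, ...] = (
    _t("psbA", "PCG", 1062, "-", "LSC"),
    _t("psbK", "PCG", 186, "+", "LSC"),
    _t("psbI", "PCG", 111, "+", "LSC"),
    _t("trnS-GCU", "tRNA", 88, "-", "LSC"),
    _t("trnG-UCC", "tRNA", 71, "+", "LSC"),
    _t("psaB", "PCG", 1503, "+", "LSC"),
    _t("psaA", "PCG", 1503, "+", "LSC"),
    _t("ycf3", "PCG", 507, "-", "LSC", n_parts=3),
    _t("trnS-GGA", "tRNA", 87, "+", "LSC"),
    _t("rps4", "PCG", 606, "-", "LSC"),
    _t("atpB", "PCG", 1497, "-", "LSC"),
    _t("rbcL", "PCG", 1428, "+", "LSC"),
    _t("petA", "PCG", 963, "+", "LSC"),
    _t("rps19", "PCG", 279, "+", "LSC"),
    _t("rrn16", "rRNA", 1491, "+", "IR"),
    _t("rrn23", "rRNA", 2001, "+", "IR"),
    _t("trnN-GUU", "tRNA", 72, "-", "IR"),
    _t("ndhF", "PCG", 1500, "-", "SSC"),
    _t("ycf1", "PCG", 1800, "+", "SSC"),
)


@dataclass(frozen=True)
class ShortIRSpec:
    """A planted pair of short inverted-repeat arms at two anchor genes.

    The left anchor must be a '-' gene (3' end at its left/genome-forward
    start) and the right anchor a '+' gene (3' end at its right edge), so
    both anchors terminate in the same arm sequence and the arm pair bounds
    a flip-flop-competent segment that contains both anchors entirely.
    """

    arm_len: int = 29
    arm_seq: Optional[str] = None  # random when None
    left_anchor: str = "trnS-GCU"
    right_anchor: str = "trnS-GGA"


@dataclass(frozen=True)
class SyntheticPlastomeSpec:
    lsc_len: int = 86000
    ssc_len: int = 18000
    ir_len: int = 26000
    gc: float = 0.36
    gene_template: tuple[GeneTemplate, ...] = DEFAULT_GENE_TEMPLATE
    short_ir: Optional[ShortIRSpec] = None
    jlb_straddle: Optional[tuple[str, int]] = None  # (last LSC gene, bp in IR_B)
    seed: int = 0
    id: str = "synthetic-plastome"


@dataclass(frozen=True)
class ReadSimSpec:
    read_len: int = 150
    insert_mean: int = 400
    insert_sd: int = 50
    n_pairs: int = 20000
    error_rate: float = 0.01
    ipwi_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ipwi_fraction <= 1.0:
            raise ValueError(f"invalid ipwi_fraction {self.ipwi_fraction}")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError(f"invalid error_rate {self.error_rate}")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def _random_orf(rng: np.random.Generator, length: int) -> str:
    if length % 3 or length < 9:
        raise ValueError(f"ORF length {length} must be a multiple of 3 and >= 9")
    n_mid = length // 3 - 2
    mid = rng.choice(len(_NON_STOP_CODONS), size=n_mid)
    return "ATG" + "".join(_NON_STOP_CODONS[i] for i in mid) + "TAA"


def _gene_forward_seq(rng: np.random.Generator, t: GeneTemplate) -> str:
    seq = _random_orf(rng, t.length) if t.category == "PCG" else _random_seq(rng, t.length, 0.5)
    return revcomp(seq) if t.strand == "-" else seq


def _split_parts(rng: np.random.Generator, length: int, n_parts: int) -> list[int]:
    if n_parts == 1:
        return [length]
    cuts = sorted(rng.choice(np.arange(30, length - 30), size=n_parts - 1, replace=False))
    sizes, prev = [], 0
    for c in cuts:
        sizes.append(int(c) - prev)
        prev = int(c)
    sizes.append(length - prev)
    return sizes


def _build_region(
    rng: np.random.Generator,
    genes: Sequence[GeneTemplate],
    region_len: int,
    gc: float,
    region_name: str,
    tail_reserved: int = 0,
) -> tuple[str, list[tuple[GeneTemplate, tuple[tuple[int, int], ...]]]]:
    """Assemble one region: genes in declared order with random spacers.

    Returns the region sequence and per-gene part intervals in local 1-based
    coordinates.  ``tail_reserved`` shortens the usable space at the region
    end (used when a junction-straddling gene claims the region boundary).
    """
    spans = []
    for t in genes:
        introns = [int(x) for x in rng.integers(120, 500, size=t.n_parts - 1)]
        part_sizes = _split_parts(rng, t.length, t.n_parts)
        spans.append((t, part_sizes, introns, t.length + sum(introns)))
    total = sum(s[3] for s in spans)
    n_gaps = len(genes) + 1
    free = region_len - tail_reserved - total - 2 * n_gaps
    if free < 0:
        raise ValueError(
            f"genes overflow region {region_name}: need {total + 2 * n_gaps + tail_reserved} bp, "
            f"have {region_len}"
        )
    gaps = rng.multinomial(free, [1.0 / n_gaps] * n_gaps) + 2 if n_gaps else []
    chunks: list[str] = []
    feats: list[tuple[GeneTemplate, tuple[tuple[int, int], ...]]] = []
    pos = 0  # 0-based length so far
    for (t, part_sizes, introns, span), gap in zip(spans, gaps[:-1]):
        chunks.append(_random_seq(rng, int(gap), gc))
        pos += int(gap)
        fwd = _gene_forward_seq(rng, t)
        # genome-forward part sizes: transcription order for '-' is reversed
        fwd_sizes = part_sizes if t.strand == "+" else part_sizes[::-1]
        fwd_introns = introns if t.strand == "+" else introns[::-1]
        intervals = []
        offset = 0
        for i, ps in enumerate(fwd_sizes):
            intervals.append((pos + 1, pos + ps))
            chunks.append(fwd[offset : offset + ps])
            offset += ps
            pos += ps
            if i < len(fwd_introns):
                chunks.append(_random_seq(rng, fwd_introns[i], gc))
                pos += fwd_introns[i]
        feats.append((t, tuple(intervals)))
    tail = region_len - tail_reserved - pos
    chunks.append(_random_seq(rng, tail, gc))
    return "".join(chunks), feats


def build_synthetic_plastome(
    spec: SyntheticPlastomeSpec,
) -> tuple[AnnotatedGenome, dict]:
    """Generate a canonical-frame quadripartite genome with planted truth.

    The genome is LSC | IR_B | SSC | IR_A with IR_A = revcomp(IR_B) exactly;
    IR genes are annotated in both copies.  The optional short-IR arm pair
    is written into the 3' ends of its two anchor genes; the optional
    ``jlb_straddle`` gene crosses J_LB with the stated number of bases
    duplicated in the IR.  Junction-adjacent spacer bases are adjusted so
    the planted IR cannot be extended by chance complementarity.
    """
    rng = np.random.default_rng(spec.seed)
    by_region = {r: [t for t in spec.gene_template if t.region == r] for r in ("LSC", "IR", "SSC")}

    straddle_gene: Optional[GeneTemplate] = None
    straddle_k = 0
    if spec.jlb_straddle is not None:
        name, straddle_k = spec.jlb_straddle
        lsc_genes = by_region["LSC"]
        if not lsc_genes or lsc_genes[-1].symbol != name:
            raise ValueError(f"jlb_straddle gene {name!r} must be the last LSC gene")
        straddle_gene = lsc_genes[-1]
        if straddle_gene.strand != "+" or straddle_gene.n_parts != 1:
            raise ValueError("jlb_straddle gene must be single-part on the + strand")
        if not 0 < straddle_k < straddle_gene.length:
            raise ValueError("straddle bp must lie inside the gene")
        by_region["LSC"] = lsc_genes[:-1]

    lsc_seq, lsc_feats = _build_region(
        rng, by_region["LSC"], spec.lsc_len, spec.gc, "LSC",
        tail_reserved=(straddle_gene.length - straddle_k) if straddle_gene else 0,
    )
    features: list[GeneFeature] = []
    straddle_feature = None
    if straddle_gene is not None:
        g_fwd = _gene_forward_seq(rng, straddle_gene)
        lsc_part = straddle_gene.length - straddle_k
        lsc_seq = lsc_seq + g_fwd[:lsc_part]
        straddle_feature = GeneFeature(
            straddle_gene.symbol,
            straddle_gene.category,
            "+",
            ((spec.lsc_len - lsc_part + 1, spec.lsc_len + straddle_k),),
        )
        ir_prefix = g_fwd[lsc_part:]
    else:
        ir_prefix = ""

    irb_seq, irb_feats = _build_region(
        rng, by_region["IR"], spec.ir_len - len(ir_prefix), spec.gc, "IR"
    )
    irb_seq = ir_prefix + irb_seq
    ssc_seq, ssc_feats = _build_region(rng, by_region["SSC"], spec.ssc_len, spec.gc, "SSC")

    L, I, S = spec.lsc_len, spec.ir_len, spec.ssc_len
    n = L + 2 * I + S

    for t, parts in lsc_feats:
        features.append(GeneFeature(t.symbol, t.category, t.strand, parts))
    if straddle_feature is not None:
        features.append(straddle_feature)
    irb_offset = L + len(ir_prefix)
    for t, parts in irb_feats:
        shifted = tuple((s + irb_offset, e + irb_offset) for s, e in parts)
        features.append(GeneFeature(t.symbol, t.category, t.strand, shifted))
    for t, parts in ssc_feats:
        shifted = tuple((s + L + I, e + L + I) for s, e in parts)
        features.append(GeneFeature(t.symbol, t.category, t.strand, shifted))

    seq = list(lsc_seq + irb_seq + ssc_seq)

    # --- plant the short inverted-repeat arm pair -------------------------
    truth: dict = {"seed": spec.seed}
    if spec.short_ir is not None:
        sir = spec.short_ir
        left = next((f for f in features if f.name == sir.left_anchor), None)
        right = next((f for f in features if f.name == sir.right_anchor), None)
        if left is None or right is None:
            raise ValueError("short-IR anchor genes missing from the template")
        if left.strand != "-" or right.strand != "+":
            raise ValueError(
                "short-IR anchors must be a '-' left gene and a '+' right gene "
                "(both 3' ends then face the bounded segment's boundaries)"
            )
        arm = sir.arm_seq
        while arm is None or arm == revcomp(arm):
            arm = _random_seq(rng, sir.arm_len, 0.5)
        la = (left.start, left.start + sir.arm_len - 1)  # genome-forward left arm
        ra = (right.end - sir.arm_len + 1, right.end)
        seq[la[0] - 1 : la[1]] = list(revcomp(arm))
        seq[ra[0] - 1 : ra[1]] = list(arm)
        # block chance extension of the planted arms on either side
        _break_pairing(seq, la[0] - 2, ra[1], rng)
        _break_pairing(seq, la[1], ra[0] - 2, rng)
        truth["short_ir"] = {
            "left_arm": la,
            "right_arm": ra,
            "arm_len": sir.arm_len,
            "arm_seq": arm,
            "segment": (la[0], ra[1]),
        }

    # --- IR_A mirror ------------------------------------------------------
    irb_full = "".join(seq[L : L + I])
    seq = seq + list(revcomp(irb_full))
    # IR_B position x maps to (2L + 2I + S + 1) - x in the appended IR_A copy
    mirror_const = n + L + 1
    for t, parts in irb_feats:
        mirrored = tuple(
            sorted((mirror_const - (e + irb_offset), mirror_const - (s + irb_offset)) for s, e in parts)
        )
        features.append(
            GeneFeature(t.symbol, t.category, "-" if t.strand == "+" else "+", mirrored)
        )

    # block chance single-base extension of the large IR at its junctions
    _break_pairing(seq, L - 1, 0, rng)  # J_LB vs position 1 (outer flanks)
    _break_pairing(seq, L + I, L + I + S - 1, rng)  # first vs last SSC base (inner)

    features.sort(key=lambda f: (f.start, f.name))
    genome = AnnotatedGenome(spec.id, "".join(seq), features, "circular")
    structure = canonical_structure(L, I, S)
    truth.update(
        {
            "structure": structure,
            "genes": {
                (f.name, f.start): {"parts": f.parts, "strand": f.strand}
                for f in features
            },
        }
    )
    return genome, truth


def _break_pairing(seq: list[str], i: int, j: int, rng: np.random.Generator) -> None:
    """Ensure seq[i] is not the complement of seq[j] (0-based); edit seq[j]."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if seq[j] == comp[seq[i]]:
        choices = [b for b in "ACGT" if b != comp[seq[i]] and b != seq[j]]
        seq[j] = choices[int(rng.integers(len(choices)))]


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _verify_isomers(a: AnnotatedGenome, b: AnnotatedGenome) -> None:
    if len(a) != len(b):
        raise ValueError("genomes differ in length; not flip-flop isomers")
    sa, sb = a.sequence, b.sequence
    if sa == sb:
        raise ValueError("genomes are identical; not distinct isomers")
    lo = next(i for i in range(len(sa)) if sa[i] != sb[i])
    hi = next(i for i in range(len(sa) - 1, -1, -1) if sa[i] != sb[i])
    if revcomp(sa[lo : hi + 1]) != sb[lo : hi + 1]:
        raise ValueError("genomes do not differ by one reverse-complemented segment")


def simulate_read_mixture(
    genome_ipwc: AnnotatedGenome,
    genome_ipwi: AnnotatedGenome,
    spec: ReadSimSpec,
) -> tuple[list[str], list[str], dict]:
    """Paired-end reads from a two-conformation isomer mixture.

    Each fragment is drawn from the IPWI genome with probability
    ``ipwi_fraction``, starts uniformly on the circle, has normal insert
    length (clamped to [read_len, genome length]), and receives i.i.d.
    substitution errors.  Returns (R1 sequences, R2 sequences, truth);
    truth records each fragment's source conformation, start and insert.
    """
    _verify_isomers(genome_ipwc, genome_ipwi)
    rng = np.random.default_rng(spec.seed)
    n = len(genome_ipwc)
    rl = spec.read_len
    sources = rng.random(spec.n_pairs) < spec.ipwi_fraction  # True = IPWI
    starts = rng.integers(0, n, size=spec.n_pairs)
    inserts = np.clip(
        np.rint(rng.normal(spec.insert_mean, spec.insert_sd, size=spec.n_pairs)),
        rl,
        n,
    ).astype(np.int64)

    arrs = {
        False: _CODE[np.frombuffer((genome_ipwc.sequence * 2).encode(), dtype=np.uint8)],
        True: _CODE[np.frombuffer((genome_ipwi.sequence * 2).encode(), dtype=np.uint8)],
    }
    r1 = np.empty((spec.n_pairs, rl), dtype=np.uint8)
    r2 = np.empty((spec.n_pairs, rl), dtype=np.uint8)
    offs = np.arange(rl)
    for src in (False, True):
        mask = sources == src
        if not mask.any():
            continue
        st = starts[mask]
        ins = inserts[mask]
        r1[mask] = arrs[src][st[:, None] + offs]
        r2_start = st + ins - rl
        r2[mask] = arrs[src][r2_start[:, None] + offs]
    # R2 is the reverse complement strand
    r2 = (3 - r2)[:, ::-1]

    for mat in (r1, r2):
        err = rng.random(mat.shape) < spec.error_rate
        shift = rng.integers(1, 4, size=mat.shape)
        mat[err] = (mat[err] + shift[err]) % 4

    reads1 = [_BASES[row].tobytes().decode() for row in r1]
    reads2 = [_BASES[row].tobytes().decode() for row in r2]
    truth = {
        "conformation": ["IPWI" if s else "IPWC" for s in sources],
        "start": (starts + 1).tolist(),
        "insert": inserts.tolist(),
        "spec": spec,
    }
    return reads1, reads2, truth


def write_fastq(path: str | Path, reads: Sequence[str], prefix: str = "read") -> None:
    """Write sequences as FASTQ with constant Q40 qualities (gzip by suffix)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# planted rearrangements
# ---------------------------------------------------------------------------


def plant_inversion(
    genome: AnnotatedGenome, first_gene: str, last_gene: str
) -> tuple[AnnotatedGenome, dict]:
    """Reverse-complement the block from first_gene's start to last_gene's end.

    Both genes must lie ahead of the origin-free block (first before last on
    the forward strand); features fully inside the block are remapped with
    flipped strands.  Applying the same plant twice restores the genome.
    """
    n = len(genome)
    f1 = genome.feature_by_name(first_gene)
    f2 = genome.feature_by_name(last_gene)
    e1, e2 = _feature_extent(f1, n), _feature_extent(f2, n)
    s = min(e1[0], e2[0])
    e = max(e1[1], e2[1])
    if not (1 <= s < e <= n):
        raise ValueError(
            f"block {first_gene}..{last_gene} is not a forward non-wrapping interval"
        )
    new_seq = genome.sequence[: s - 1] + revcomp(genome.sequence[s - 1 : e]) + genome.sequence[e:]
    feats: list[GeneFeature] = []
    inverted: list[str] = []
    for f in genome.features:
        fs, fe = _feature_extent(f, n)
        if fe < s or fs > e:
            feats.append(f)
            continue
        if fs < s or fe > e:
            raise ValueError(f"gene {f.name} spans the inversion boundary")
        parts = tuple(sorted((s + e - pe, s + e - ps) for ps, pe in f.parts))
        feats.append(
            GeneFeature(f.name, f.category, "-" if f.strand == "+" else "+", parts)
        )
        inverted.append(f.name)
    feats.sort(key=lambda f: (f.start, f.name))
    truth = {
        "block": (s, e),
        "span_bp": e - s + 1,
        "genes": inverted,
        "first_gene": first_gene,
        "last_gene": last_gene,
    }
    return AnnotatedGenome(genome.id, new_seq, feats, genome.topology), truth


def extend_ir_into_ssc(
    genome: AnnotatedGenome, structure: QuadripartiteStructure, bp: int
) -> tuple[AnnotatedGenome, QuadripartiteStructure, dict]:
    """IR expansion: duplicate the first ``bp`` of the SSC into the IR.

    Models a J_SB shift into the SSC on a canonical-frame genome: the IR
    gains the leading SSC segment (its reverse complement is inserted ahead
    of IR_A), genes fully inside that segment become IR-duplicated, and the
    genome grows by ``bp``.
    """
    L, I, S = structure.lsc_len, structure.ir_len, structure.ssc_len
    n = len(genome)
    if structure.lsc != (1, L) or n != L + 2 * I + S:
        raise ValueError("genome must be in the canonical frame")
    if not 0 < bp < S:
        raise ValueError("bp must be inside the SSC")
    seg = genome.sequence[L + I : L + I + bp]
    cut = L + I + S  # 0-based insertion point (before IR_A)
    new_seq = genome.sequence[:cut] + revcomp(seg) + genome.sequence[cut:]
    feats: list[GeneFeature] = []
    duplicated: list[str] = []
    for f in genome.features:
        fs, fe = _feature_extent(f, n)
        if fs > cut:
            feats.append(
                GeneFeature(
                    f.name, f.category, f.strand,
                    tuple((s + bp, e + bp) for s, e in f.parts), f.wraps_origin,
                )
            )
        else:
            feats.append(f)
        if L + I < fs and fe <= L + I + bp:  # fully inside the copied segment
            mirrored = tuple(
                sorted((2 * cut + bp + 1 - e, 2 * cut + bp + 1 - s) for s, e in f.parts)
            )
            feats.append(
                GeneFeature(
                    f.name, f.category, "-" if f.strand == "+" else "+", mirrored
                )
            )
            duplicated.append(f.name)
        elif fs <= L + I + bp and fe > L + I + bp and fs > L + I:
            warnings.warn(f"gene {f.name} straddles the expansion edge", stacklevel=2)
    feats.sort(key=lambda f: (f.start, f.name))
    new_structure = QuadripartiteStructure(
        lsc=(1, L),
        ir_b=(L + 1, L + I + bp),
        ssc=(L + I + bp + 1, L + I + S),
        ir_a=(L + I + S + 1, n + bp),
        genome_length=n + bp,
    )
    truth = {"bp": bp, "duplicated_genes": duplicated}
    return (
        AnnotatedGenome(genome.id, new_seq, feats, genome.topology),
        new_structure,
        truth,
    )
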