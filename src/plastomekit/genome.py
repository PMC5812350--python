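"""Plastome records: containers, GenBank/FASTA+GFF3 I/O, canonical frame, summary stats.

A plastome is modelled as a circular DNA string plus strand-aware gene
features.  All interface coordinates are 1-based inclusive (GenBank
convention).  The canonical frame places the genome as
LSC | IR_B | SSC | IR_A along the forward strand with position 1 being the
first LSC base after the J_LA junction, oriented so that ndhF lies in the
SSC next to J_SB.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "AnnotatedGenome",
    "PlastomeStats",
    "QuadripartiteStructure",
    "revcomp",
    "read_genome",
    "write_genbank",
    "write_fasta",
    "write_gff3",
    "canonicalize",
    "canonical_structure",
    "compute_stats",
    "stats_table",
    "round_half_away",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"

#: genes whose record is split across features but count as one two-intron gene
TRANS_SPLICED = frozenset({"rps12"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with halves away from zero (report convention, matches printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """A gene with 1-based inclusive part intervals.

    Multiple parts encode introns (intron count = parts - 1 for cis-spliced
    genes).  Parts are stored in ascending genome order; transcription order
    is ascending for '+' genes and descending for '-' genes.
    """

    name: str
    category: str  # PCG | tRNA | rRNA
    strand: str  # '+' | '-'
    parts: tuple[tuple[int, int], ...]
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be non-empty")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")
        for s, e in self.parts:
            if not (1 <= s) or (e < s and not self.wraps_origin):
                raise ValueError(f"bad interval [{s},{e}] for {self.name}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def n_introns(self) -> int:
        return len(self.parts) - 1

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.parts)

    def midpoint(self, genome_length: Optional[int] = None) -> float:
        if self.wraps_origin and genome_length:
            # unwrap across the origin before averaging
            lo, hi = self.start, self.end
            return ((hi + lo + genome_length) / 2.0) % genome_length or genome_length
        return (self.start + self.end) / 2.0


@dataclass
class AnnotatedGenome:
    """Circular (or linear) nucleotide sequence plus gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n and not f.wraps_origin:
                raise ValueError(
                    f"feature {f.name} interval [{f.start},{f.end}] exceeds length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> GeneFeature:
        hits = [f for f in self.features if f.name == name]
        if not hits:
            raise KeyError(f"gene {name!r} not annotated in {self.id}")
        return hits[0]

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps the origin on circular genomes."""
        n = len(self.sequence)
        if start <= end:
            return self.sequence[start - 1 : end]
        if self.topology != "circular":
            raise ValueError("wrapping slice on a linear genome")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def rotated(self, offset: int) -> "AnnotatedGenome":
        """Rotate so that old position ``offset+1`` becomes position 1."""
        n = len(self.sequence)
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = [_shift_feature(f, -offset, n) for f in self.features]
        return AnnotatedGenome(self.id, seq, feats, self.topology)

    def reverse_complemented(self) -> "AnnotatedGenome":
        n = len(self.sequence)
        feats = []
        for f in self.features:
            parts = tuple(
                sorted((n - e + 1, n - s + 1) for s, e in f.parts)
            )
            feats.append(
                GeneFeature(
                    f.name,
                    f.category,
                    "-" if f.strand == "+" else "+",
                    parts,
                    f.wraps_origin,
                )
            )
        return AnnotatedGenome(self.id, revcomp(self.sequence), feats, self.topology)


def _shift_feature(f: GeneFeature, delta: int, n: int) -> GeneFeature:
    parts = []
    wraps = False
    for s, e in f.parts:
        s2 = (s - 1 + delta) % n + 1
        e2 = (e - 1 + delta) % n + 1
        if e2 < s2:
            wraps = True
        parts.append((s2, e2))
    parts.sort()
    return GeneFeature(f.name, f.category, f.strand, tuple(parts), wraps)


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC / IR_B / SSC / IR_A intervals and the four junction positions.

    Intervals are 1-based inclusive in the coordinates of the genome the
    structure was computed on; a junction is reported as the last base of
    the upstream region in canonical order (J_LB = LSC end, J_SB = IR_B end,
    J_SA = SSC end, J_LA = IR_A end).
    """

    lsc: tuple[int, int]
    ir_b: tuple[int, int]
    ssc: tuple[int, int]
    ir_a: tuple[int, int]
    genome_length: int

    @property
    def lsc_len(self) -> int:
        return _ilen(self.lsc, self.genome_length)

    @property
    def ssc_len(self) -> int:
        return _ilen(self.ssc, self.genome_length)

    @property
    def ir_len(self) -> int:
        return _ilen(self.ir_b, self.genome_length)

    @property
    def j_lb(self) -> int:
        return self.lsc[1]

    @property
    def j_sb(self) -> int:
        return self.ir_b[1]

    @property
    def j_sa(self) -> int:
        return self.ssc[1]

    @property
    def j_la(self) -> int:
        return self.ir_a[1]

    @property
    def junctions(self) -> dict[str, int]:
        return {
            "J_LB": self.j_lb,
            "J_SB": self.j_sb,
            "J_SA": self.j_sa,
            "J_LA": self.j_la,
        }


def _ilen(iv: tuple[int, int], n: int) -> int:
    s, e = iv
    return e - s + 1 if s <= e else n - s + 1 + e


def canonical_structure(lsc_len: int, ir_len: int, ssc_len: int) -> QuadripartiteStructure:
    """Structure of an already-canonical genome given the three region lengths."""
    n = lsc_len + 2 * ir_len + ssc_len
    return QuadripartiteStructure(
        lsc=(1, lsc_len),
        ir_b=(lsc_len + 1, lsc_len + ir_len),
        ssc=(lsc_len + ir_len + 1, lsc_len + ir_len + ssc_len),
        ir_a=(lsc_len + ir_len + ssc_len + 1, n),
        genome_length=n,
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_GB_TYPE_TO_CATEGORY = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA}


def read_genome(
    path: str | Path,
    format: str = "genbank",
    gff3: Optional[str | Path] = None,
    circular: Optional[bool] = None,
) -> AnnotatedGenome:
    """Read an annotated plastome from GenBank or FASTA + GFF3.

    ``format`` is ``"genbank"`` or ``"fasta+gff3"`` (the latter requires
    ``gff3``).  Features are normalized to 1-based inclusive coordinates;
    origin-wrapping features are flagged.  Duplicate gene names (IR copies)
    are retained as distinct features.
    """
    path = Path(path)
    if format == "genbank":
        return _read_genbank(path, circular)
    if format == "fasta+gff3":
        if gff3 is None:
            raise ValueError("fasta+gff3 format requires a gff3 path")
        return _read_fasta_gff3(path, Path(gff3), circular)
    raise ValueError(f"unknown format {format!r}")


def _read_genbank(path: Path, circular: Optional[bool]) -> AnnotatedGenome:
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with locus context
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    topo = record.annotations.get("topology", "").lower()
    if topo != "circular":
        if circular is None:
            warnings.warn(
                f"{record.id}: record not flagged circular; treating as circular",
                stacklevel=2,
            )
        elif not circular:
            pass
    n = len(record.seq)
    feats: list[GeneFeature] = []
    for sf in record.features:
        cat = _GB_TYPE_TO_CATEGORY.get(sf.type)
        if cat is None:
            continue
        name = (
            sf.qualifiers.get("gene", [None])[0]
            or sf.qualifiers.get("locus_tag", [None])[0]
        )
        if not name:
            continue
        parts = tuple(
            sorted((int(p.start) + 1, int(p.end)) for p in sf.location.parts)
        )
        wraps = any(int(p.end) < int(p.start) + 1 for p in sf.location.parts) or (
            len(parts) > 1 and parts[0][0] == 1 and parts[-1][1] == n
            and sf.location.parts[0].start != 0
        )
        strand = "-" if sf.location.strand == -1 else "+"
        feats.append(GeneFeature(name, cat, strand, parts, wraps))
    topology = "circular" if (topo == "circular" or circular in (None, True)) else "linear"
    return AnnotatedGenome(record.id or path.stem, str(record.seq).upper(), feats, topology)


_GFF_TYPE_TO_CATEGORY = {
    "CDS": PCG,
    "gene": None,  # resolved via children / gene_biotype
    "tRNA": TRNA,
    "rRNA": RRNA,
}


def _read_fasta_gff3(fasta: Path, gff3: Path, circular: Optional[bool]) -> AnnotatedGenome:
    import gffutils

    try:
        record = SeqIO.read(str(fasta), "fasta")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed FASTA in {fasta}: {exc}") from exc
    text = Path(gff3).read_text()
    feats: list[GeneFeature] = []
    if text.strip():
        db = gffutils.create_db(
            text, ":memory:", from_string=True, merge_strategy="create_unique",
            keep_order=True,
        )
        for ftype, cat in (("CDS", PCG), ("tRNA", TRNA), ("rRNA", RRNA)):
            groups: dict[str, list] = {}
            for f in db.features_of_type(ftype, order_by="start"):
                name = f.attributes.get("gene", f.attributes.get("Name", [f.id]))[0]
                key = f.attributes.get("ID", [name])[0]
                groups.setdefault(key, []).append((f, name))
            for key, items in groups.items():
                name = items[0][1]
                strand = "-" if items[0][0].strand == "-" else "+"
                parts = tuple(sorted((f.start, f.end) for f, _ in items))
                feats.append(GeneFeature(name, cat, strand, parts, False))
    topology = "circular" if circular in (None, True) else "linear"
    return AnnotatedGenome(record.id or fasta.stem, str(record.seq).upper(), feats, topology)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _to_seqrecord(genome: AnnotatedGenome) -> SeqRecord:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16] or "plastome",
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    for f in genome.features:
        locs = [
            FeatureLocation(s - 1, e, strand=1 if f.strand == "+" else -1)
            for s, e in f.parts
        ]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(
            locs if f.strand == "+" else locs[::-1]
        )
        ftype = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA"}[f.category]
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers={"gene": [f.name]}))
    return rec


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    SeqIO.write([_to_seqrecord(genome)], str(path), "genbank")


def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    SeqIO.write([_to_seqrecord(genome)], str(path), "fasta")


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {len(genome)}"]
    ftype = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA"}
    for i, f in enumerate(genome.features):
        fid = f"feat{i}-{f.name}"
        for s, e in f.parts:
            lines.append(
                "\t".join(
                    [
                        genome.id,
                        "plastomekit",
                        ftype[f.category],
                        str(s),
                        str(e),
                        ".",
                        f.strand,
                        "0" if f.category == PCG else ".",
                        f"ID={fid};gene={f.name}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# canonical frame
# ---------------------------------------------------------------------------


def canonicalize(
    genome: AnnotatedGenome, structure: QuadripartiteStructure
) -> AnnotatedGenome:
    """Rotate/orient a genome into the canonical LSC|IR_B|SSC|IR_A frame.

    Position 1 becomes the first LSC base after J_LA.  The strand is chosen
    so that ndhF lies in the SSC adjacent to J_SB; without an annotated
    ndhF the orientation with the lexicographically smaller sequence wins.
    """
    if structure.genome_length != len(genome):
        raise ValueError("structure/genome length mismatch")
    fwd = _rotate_to_frame(genome, structure)
    rev = _rotate_to_frame(
        genome.reverse_complemented(), _reflect_structure(structure)
    )
    n = len(genome)
    ssc_start = structure.lsc_len + structure.ir_len + 1
    ssc_end = ssc_start + structure.ssc_len - 1

    def _ndhf_near_jsb(g: AnnotatedGenome) -> Optional[bool]:
        try:
            f = g.feature_by_name("ndhF")
        except KeyError:
            return None
        mid = f.midpoint(n)
        if not (ssc_start <= mid <= ssc_end):
            return None
        # nearer the SSC start (J_SB side) than the SSC end (J_SA side)?
        return (mid - ssc_start) <= (ssc_end - mid)

    ff, rf = _ndhf_near_jsb(fwd), _ndhf_near_jsb(rev)
    if ff:
        return fwd
    if rf:
        return rev
    return fwd if fwd.sequence <= rev.sequence else rev


def _rotate_to_frame(
    genome: AnnotatedGenome, structure: QuadripartiteStructure
) -> AnnotatedGenome:
    return genome.rotated(structure.lsc[0] - 1)


def _reflect_structure(s: QuadripartiteStructure) -> QuadripartiteStructure:
    """Structure of the reverse-complemented genome (IR_A/IR_B swap roles)."""
    n = s.genome_length

    def rc(iv: tuple[int, int]) -> tuple[int, int]:
        a, b = iv
        na = (n - b) % n + 1
        nb = (n - a) % n + 1
        return (na, nb)

    # reverse complement maps LSC->LSC (reversed), SSC->SSC, IR_A<->IR_B
    return QuadripartiteStructure(
        lsc=rc(s.lsc), ir_b=rc(s.ir_a), ssc=rc(s.ssc), ir_a=rc(s.ir_b),
        genome_length=n,
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlastomeStats:
    """Table-style plastome summary (sizes in bp, GC% to one decimal)."""

    id: str
    total_bp: int
    lsc_bp: Optional[int]
    ssc_bp: Optional[int]
    ir_bp: Optional[int]
    gc_percent: float
    n_genes: int
    n_pcg: int
    n_pcg_in_ir: int
    n_trna: int
    n_trna_in_ir: int
    n_rrna: int
    n_rrna_in_ir: int
    n_intron_genes: int
    n_two_intron_genes: int


def _overlaps_ir(f: GeneFeature, structure: QuadripartiteStructure) -> bool:
    n = structure.genome_length
    for s, e in f.parts:
        ivs = [(s, e)] if s <= e else [(s, n), (1, e)]
        for a, b in ivs:
            for ir in (structure.ir_a, structure.ir_b):
                ia, ib = ir
                if ia <= ib:
                    if a <= ib and b >= ia:
                        return True
                else:
                    if b >= ia or a <= ib:
                        return True
    return False


def compute_stats(
    genome: AnnotatedGenome, structure: Optional[QuadripartiteStructure] = None
) -> PlastomeStats:
    """Summary statistics on a canonical genome.

    Unique gene counts deduplicate IR-duplicated copies by name; a gene
    counts as "in IR" if any copy's part overlaps IR_A or IR_B; intron
    counts are parts-1 per gene name, with trans-spliced rps12 counted once
    as a two-intron gene when split across features.  GC% uses only
    A/C/G/T in the denominator and is rounded half-away-from-zero to one
    decimal.
    """
    seq = genome.sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    gc = sum(seq.count(b) for b in "GC")
    gc_percent = round_half_away(100.0 * gc / acgt, 1) if acgt else 0.0

    if structure is None:
        warnings.warn("no quadripartite structure given; region sizes unset", stacklevel=2)
        lsc = ssc = ir = None
    else:
        lsc, ssc, ir = structure.lsc_len, structure.ssc_len, structure.ir_len

    by_name: dict[str, list[GeneFeature]] = {}
    for f in genome.features:
        by_name.setdefault(f.name, []).append(f)

    def count(category: str) -> tuple[int, int]:
        total = in_ir = 0
        for name, fs in by_name.items():
            if fs[0].category != category:
                continue
            total += 1
            if structure is not None and any(_overlaps_ir(f, structure) for f in fs):
                in_ir += 1
        return total, in_ir

    n_pcg, n_pcg_ir = count(PCG)
    n_trna, n_trna_ir = count(TRNA)
    n_rrna, n_rrna_ir = count(RRNA)

    n_intron = n_two = 0
    for name, fs in by_name.items():
        if name in TRANS_SPLICED and len(fs) > 1:
            introns = 2
        else:
            introns = max(f.n_introns for f in fs)
        if introns >= 1:
            n_intron += 1
        if introns >= 2:
            n_two += 1

    return PlastomeStats(
        id=genome.id,
        total_bp=len(genome),
        lsc_bp=lsc,
        ssc_bp=ssc,
        ir_bp=ir,
        gc_percent=gc_percent,
        n_genes=len(by_name),
        n_pcg=n_pcg,
        n_pcg_in_ir=n_pcg_ir,
        n_trna=n_trna,
        n_trna_in_ir=n_trna_ir,
        n_rrna=n_rrna,
        n_rrna_in_ir=n_rrna_ir,
        n_intron_genes=n_intron,
        n_two_intron_genes=n_two,
    )


_TABLE_COLUMNS = [
    ("GenBank accession", "id"),
    ("Entire plastome size (bp)", "total_bp"),
    ("LSC size (bp)", "lsc_bp"),
    ("SSC size (bp)", "ssc_bp"),
    ("IR size (bp)", "ir_bp"),
    ("No. unique genes", "n_genes"),
    ("No. unique PCGs", "n_pcg"),
    ("No. unique PCGs in IR", "n_pcg_in_ir"),
    ("No. unique tRNAs", "n_trna"),
    ("No. unique tRNAs in IR", "n_trna_in_ir"),
    ("No. unique rRNAs", "n_rrna"),
    ("No. unique rRNAs in IR", "n_rrna_in_ir"),
    ("No. unique genes with introns", "n_intron_genes"),
    ("No. unique genes with two introns", "n_two_intron_genes"),
    ("GC content (%)", "gc_percent"),
]


def stats_table(stats: Sequence[PlastomeStats]):
    """One row per genome as a pandas DataFrame with report column names."""
    import pandas as pd

    rows = [{col: getattr(s, attr) for col, attr in _TABLE_COLUMNS} for s in stats]
    return pd.DataFrame(rows)


def stats_to_json(stats: PlastomeStats) -> str:
    return json.dumps(stats.__dict__, indent=2)
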