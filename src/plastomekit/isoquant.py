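"""Junction-spanning read classification and isomer frequency estimation.

A mate supports a conformation (IPWI or IPWC) when it aligns ungapped to one
of that conformation's two breakpoint references with at most
``max_mismatch`` mismatches, with its aligned span covering the full short
arm plus at least ``anchor_bp`` flanking bases on both sides.  Both read
orientations are tested; each mate is scored independently.  Mates scoring
equally well for both conformations are ambiguous; mates supporting neither
are nonspanning.  Conformation frequencies are the conformation-informative
read proportions, with a Wilson 95% score interval.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .genome import revcomp, round_half_away
from .shortir import IPWC, IPWI, JunctionReferenceSet

__all__ = [
    "ReadClassCounts",
    "IsomerFrequency",
    "classify_reads",
    "estimate_frequencies",
    "read_fastq",
]


@dataclass
class ReadClassCounts:
    per_reference: dict[str, int]
    n_ipwi: int
    n_ipwc: int
    n_ambiguous: int
    n_nonspanning: int
    anchor_bp: int
    max_mismatch: int

    @property
    def n_spanning(self) -> int:
        return self.n_ipwi + self.n_ipwc


@dataclass(frozen=True)
class IsomerFrequency:
    f_ipwi: float  # percent, two decimals
    f_ipwc: float
    ci95_ipwi: tuple[float, float]  # percent
    n_total_spanning: int


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from a FASTQ file (gzip allowed)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [seq.upper() for _, seq, _ in FastqGeneralIterator(fh)]


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _RefMatcher:
    """Precomputed sliding-window scorer for one junction reference."""

    def __init__(self, label: str, conformation: str, sequence: str,
                 arm_interval: tuple[int, int], anchor_bp: int) -> None:
        self.label = label
        self.conformation = conformation
        self.arr = _as_array(sequence)
        self.arm0 = (arm_interval[0] - 1, arm_interval[1] - 1)  # 0-based incl.
        self.anchor = anchor_bp

    def min_mismatches(self, read: np.ndarray) -> Optional[int]:
        L = len(read)
        a0, a1 = self.arm0
        lo = max(0, a1 + self.anchor - L + 1)
        hi = min(a0 - self.anchor, len(self.arr) - L)
        if hi < lo:
            return None
        windows = np.lib.stride_tricks.sliding_window_view(self.arr, L)[lo : hi + 1]
        return int((windows != read).sum(axis=1).min())


def classify_reads(
    reads: Iterable[str] | str | Path | Sequence[str | Path],
    refs: JunctionReferenceSet,
    anchor_bp: int = 10,
    max_mismatch: int = 2,
) -> ReadClassCounts:
    """Classify mates by isomeric conformation against the four references.

    ``reads`` may be FASTQ path(s) (each mate file given separately; pairs
    are not collapsed — the counting unit is the mate) or an iterable of
    read sequences.  Returns per-reference and pooled counts.
    """
    if len(refs.references) != 4:
        raise ValueError(
            f"reference set must contain exactly 4 references, got {len(refs.references)}"
        )
    seqs = _collect_reads(reads)
    matchers = [
        _RefMatcher(r.label, r.conformation, r.sequence, r.arm_interval, anchor_bp)
        for r in refs.references
    ]
    per_ref = {f"{m.conformation}|{m.label}": 0 for m in matchers}
    n_ipwi = n_ipwc = n_amb = n_non = 0

    arm_len = refs.arm_len
    # prefilter: any alignment within the mismatch budget keeps at least one
    # exact q-mer of an arm inside the read (pigeonhole over the arm span)
    q = max(4, arm_len // (max_mismatch + 1))
    kmers: set[str] = set()
    for r in refs.references:
        a, b = r.arm_interval
        arm = r.sequence[a - 1 : b]
        for s in (arm, revcomp(arm)):
            kmers.update(s[i : i + q] for i in range(len(s) - q + 1))
    kmer_list = sorted(kmers)

    checked_len = False
    for seq in seqs:
        if not checked_len:
            if len(seq) <= arm_len + 2 * anchor_bp:
                raise ValueError(
                    f"reads of {len(seq)} bp cannot span a {arm_len} bp arm "
                    f"plus {anchor_bp} bp anchors on both sides"
                )
            checked_len = True
        if not any(k in seq for k in kmer_list):
            n_non += 1
            continue
        fwd = _as_array(seq)
        rev = _as_array(revcomp(seq))
        best: dict[str, tuple[int, str]] = {}
        for m in matchers:
            score = None
            for arr in (fwd, rev):
                s = m.min_mismatches(arr)
                if s is not None and (score is None or s < score):
                    score = s
            if score is not None and score <= max_mismatch:
                cur = best.get(m.conformation)
                if cur is None or score < cur[0]:
                    best[m.conformation] = (score, f"{m.conformation}|{m.label}")
        if not best:
            n_non += 1
        elif len(best) == 2 and best[IPWI][0] == best[IPWC][0]:
            n_amb += 1
        else:
            conf = min(best, key=lambda c: best[c][0])
            per_ref[best[conf][1]] += 1
            if conf == IPWI:
                n_ipwi += 1
            else:
                n_ipwc += 1
    return ReadClassCounts(
        per_reference=per_ref,
        n_ipwi=n_ipwi,
        n_ipwc=n_ipwc,
        n_ambiguous=n_amb,
        n_nonspanning=n_non,
        anchor_bp=anchor_bp,
        max_mismatch=max_mismatch,
    )


def _collect_reads(reads) -> list[str]:
    if isinstance(reads, (str, Path)):
        return read_fastq(reads)
    reads = list(reads)
    if reads and isinstance(reads[0], (str, Path)) and Path(str(reads[0])).suffix in (
        ".fastq",
        ".fq",
        ".gz",
    ):
        out: list[str] = []
        for p in reads:
            out.extend(read_fastq(p))
        return out
    return [str(s).upper() for s in reads]


def estimate_frequencies(counts: ReadClassCounts) -> IsomerFrequency:
    """Point estimates (percent, two decimals) and Wilson 95% CI for IPWI.

    Only conformation-informative mates enter the denominator; ambiguous and
    nonspanning reads are excluded.
    """
    total = counts.n_ipwi + counts.n_ipwc
    if total == 0:
        raise ValueError("frequency undefined: zero conformation-informative reads")
    f_ipwi = round_half_away(100.0 * counts.n_ipwi / total, 2)
    f_ipwc = round_half_away(100.0 * counts.n_ipwc / total, 2)
    lo, hi = proportion_confint(counts.n_ipwi, total, alpha=0.05, method="wilson")
    return IsomerFrequency(
        f_ipwi=f_ipwi,
        f_ipwc=f_ipwc,
        ci95_ipwi=(100.0 * lo, 100.0 * hi),
        n_total_spanning=total,
    )
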