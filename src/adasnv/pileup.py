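"""Pileup engine: per-position cross-sections of aligned bases.

A *cross-section* at reference position ``i`` is the multiset of read
nucleotides aligned over ``i``, partitioned into matches ``M`` and
mismatches ``M̄`` against the reference base.  Every aligned base carries
the four site characteristics used by the caller:

``Q``
    probability that the base call is correct, ``1 - 10^(-phred/10)``;
``P``
    relative read position ``k / m`` where ``k`` is the 1-based offset of
    the base within the aligned portion of its read and ``m`` the aligned
    read length;
``R``
    the read's alignment edit distance (``NM`` tag by default);
``H``
    the read's reported alignment multiplicity (``NH`` tag by default).

Only aligned nucleotides contribute: inserted bases, deletion
placeholders, soft/hard-clipped bases, ``N`` calls and phred-0 bases are
excluded, so indels never enter the SNV model.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedBase",
    "CrossSection",
    "PileupConfig",
    "phred_to_quality",
    "iterate_cross_sections",
    "mismatch_rate",
]

_A, _C, _G, _T = 65, 67, 71, 84  # ASCII codes


def phred_to_quality(phred) -> np.ndarray:
    """Convert phred-scaled scores to probability of a correct base call."""
    return 1.0 - np.power(10.0, -np.asarray(phred, dtype=np.float64) / 10.0)


@dataclass(frozen=True)
class AlignedBase:
    """One read nucleotide aligned over a reference position."""

    base: str          # A/C/G/T
    quality: float     # probability the call is correct, in [0, 1]
    read_pos: int      # 1-based offset k within the aligned portion
    read_len: int      # aligned read length m
    read_errors: int   # R: alignment edit distance, >= 0
    read_hits: int     # H: number of reported alignments, >= 1

    def __post_init__(self):
        if not (1 <= self.read_pos <= self.read_len):
            raise ValueError(f"read_pos {self.read_pos} outside [1, {self.read_len}]")
        if not (0.0 <= self.quality <= 1.0):
            raise ValueError(f"quality {self.quality} outside [0, 1]")
        if self.read_errors < 0:
            raise ValueError("read_errors must be >= 0")
        if self.read_hits < 1:
            raise ValueError("read_hits must be >= 1")

    @property
    def rel_pos(self) -> float:
        """Relative read position P = k / m."""
        return self.read_pos / self.read_len


@dataclass
class CrossSection:
    """All aligned bases over one reference position.

    The per-base attributes are stored as parallel NumPy arrays; the
    ``bases`` property materialises :class:`AlignedBase` records on
    demand.
    """

    chrom: str
    pos: int            # 1-based reference coordinate
    ref_base: str
    base_codes: np.ndarray   # uint8 ASCII codes, A/C/G/T only
    quality: np.ndarray      # float64, probability of correct call
    read_pos: np.ndarray     # int32, 1-based k
    read_len: np.ndarray     # int32, m
    read_errors: np.ndarray  # int32, R
    read_hits: np.ndarray    # int32, H
    n_match: int = field(init=False)
    n_mismatch: int = field(init=False)

    def __post_init__(self):
        if self.base_codes.size < 1:
            raise ValueError("cross-section must contain at least one base")
        mm = self.base_codes != ord(self.ref_base)
        self.n_mismatch = int(mm.sum())
        self.n_match = int(self.base_codes.size - self.n_mismatch)

    @property
    def coverage(self) -> int:
        return int(self.base_codes.size)

    @property
    def mismatch_mask(self) -> np.ndarray:
        return self.base_codes != ord(self.ref_base)

    @property
    def delta(self) -> float:
        """Mismatch rate δ = |M̄| / |C|."""
        return self.n_mismatch / self.coverage

    @property
    def rel_pos(self) -> np.ndarray:
        """Relative read positions P = k / m for every base."""
        return self.read_pos / self.read_len

    @property
    def bases(self) -> list:
        return [
            AlignedBase(
                base=chr(self.base_codes[i]),
                quality=float(self.quality[i]),
                read_pos=int(self.read_pos[i]),
                read_len=int(self.read_len[i]),
                read_errors=int(self.read_errors[i]),
                read_hits=int(self.read_hits[i]),
            )
            for i in range(self.coverage)
        ]


def mismatch_rate(cs: CrossSection) -> float:
    """Observed mismatch rate δ = |M̄| / |C| at one site."""
    return cs.delta


@dataclass
class PileupConfig:
    """Knobs for cross-section construction.

    ``missing_tag_policy`` controls what happens when a read lacks the
    edit-distance or hit-count annotation: ``"default"`` substitutes
    R=0 / H=1 with a (once per file) logged warning, ``"fail"`` raises.
    """

    min_base_quality: int = 0          # phred; bases strictly below are dropped
    edit_distance_tag: str = "NM"
    hit_count_tag: str = "NH"
    missing_tag_policy: str = "default"   # "default" | "fail"
    max_flush_bases: int = 4_000_000      # buffered base observations before a flush

    def __post_init__(self):
        if self.missing_tag_policy not in ("default", "fail"):
            raise ValueError("missing_tag_policy must be 'default' or 'fail'")


_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def _parse_region(region: str):
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"cannot parse region {region!r}")
    chrom = m.group(1)
    if m.group(2) is None:
        return chrom, None, None
    start, end = int(m.group(2)), int(m.group(3))
    if start < 1 or end < start:
        raise ValueError(f"invalid region bounds in {region!r}")
    return chrom, start - 1, end  # 0-based half-open


class _ReadBuffer:
    """Accumulates per-base observations for one contig."""

    __slots__ = ("rpos", "codes", "qual", "k", "m", "r", "h", "n")

    def __init__(self):
        self.rpos, self.codes, self.qual = [], [], []
        self.k, self.m, self.r, self.h = [], [], [], []
        self.n = 0

    def add(self, rpos, codes, qual, k, m, r, h):
        self.rpos.append(rpos)
        self.codes.append(codes)
        self.qual.append(qual)
        self.k.append(k)
        nb = rpos.size
        self.m.append(np.full(nb, m, dtype=np.int32))
        self.r.append(np.full(nb, r, dtype=np.int32))
        self.h.append(np.full(nb, h, dtype=np.int32))
        self.n += nb

    def concat(self):
        return (
            np.concatenate(self.rpos) if self.rpos else np.empty(0, np.int64),
            np.concatenate(self.codes) if self.codes else np.empty(0, np.uint8),
            np.concatenate(self.qual) if self.qual else np.empty(0, np.float64),
            np.concatenate(self.k) if self.k else np.empty(0, np.int32),
            np.concatenate(self.m) if self.m else np.empty(0, np.int32),
            np.concatenate(self.r) if self.r else np.empty(0, np.int32),
            np.concatenate(self.h) if self.h else np.empty(0, np.int32),
        )

    def reset_with(self, arrays):
        rpos, codes, qual, k, m, r, h = arrays
        self.rpos, self.codes, self.qual = [rpos], [codes], [qual]
        self.k, self.m, self.r, self.h = [k], [m], [r], [h]
        self.n = rpos.size


def _emit(chrom, arrays, fasta, window):
    """Yield CrossSections for all buffered positions, in ascending order."""
    rpos, codes, qual, k, m, r, h = arrays
    if rpos.size == 0:
        return
    order = np.argsort(rpos, kind="stable")
    rpos, codes, qual = rpos[order], codes[order], qual[order]
    k, m, r, h = k[order], m[order], r[order], h[order]
    first, last = int(rpos[0]), int(rpos[-1])
    ref = fasta.fetch(chrom, first, last + 1).upper()
    # boundaries of runs of equal position
    bounds = np.flatnonzero(np.diff(rpos)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [rpos.size]))
    lo, hi = window
    for s, e in zip(starts, ends):
        p0 = int(rpos[s])
        if lo is not None and (p0 < lo or p0 >= hi):
            continue
        yield CrossSection(
            chrom=chrom,
            pos=p0 + 1,
            ref_base=ref[p0 - first],
            base_codes=codes[s:e],
            quality=qual[s:e],
            read_pos=k[s:e],
            read_len=m[s:e],
            read_errors=r[s:e],
            read_hits=h[s:e],
        )


def iterate_cross_sections(
    alignments: Union[str, Path, pysam.AlignmentFile],
    reference: Union[str, Path, pysam.FastaFile],
    region: Optional[str] = None,
    config: Optional[PileupConfig] = None,
) -> Iterator[CrossSection]:
    """Stream cross-sections from coordinate-sorted alignments.

    Parameters
    ----------
    alignments
        SAM/BAM path or an open :class:`pysam.AlignmentFile`, coordinate
        sorted.  An index is required only when ``region`` is given.
    reference
        FASTA path or an open :class:`pysam.FastaFile` covering every
        contig referenced by the alignments.
    region
        Optional ``chrom`` or ``chrom:start-end`` restriction (1-based,
        inclusive).

    Yields
    ------
    CrossSection
        One per reference position with at least one aligned A/C/G/T
        base, in ascending coordinate order per contig.
    """
    cfg = config or PileupConfig()
    own_af = not isinstance(alignments, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(alignments)) if own_af else alignments
    own_fa = not isinstance(reference, pysam.FastaFile)
    fa = pysam.FastaFile(str(reference)) if own_fa else reference
    try:
        if region is not None:
            chrom, lo, hi = _parse_region(region)
            if chrom not in fa.references:
                raise ValueError(f"chromosome {chrom!r} absent from reference FASTA")
            reads = af.fetch(chrom, lo, hi)
            yield from _pileup_stream(reads, fa, cfg, window=(lo, hi), contig=chrom)
        else:
            reads = af.fetch(until_eof=True)
            yield from _pileup_stream(reads, fa, cfg, window=(None, None), contig=None)
    finally:
        if own_af:
            af.close()
        if own_fa:
            fa.close()


def _pileup_stream(reads, fa, cfg, window, contig):
    buf = _ReadBuffer()
    cur_chrom = contig
    warned = {"nm": False, "nh": False, "qual": False}
    min_q = max(1, cfg.min_base_quality)  # phred 0 bases are always dropped
    flush_horizon = -1

    def check_chrom(name):
        if name not in fa.references:
            raise ValueError(f"chromosome {name!r} absent from reference FASTA")

    if cur_chrom is not None:
        check_chrom(cur_chrom)

    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_qcfail:
            continue
        rname = read.reference_name
        if rname != cur_chrom:
            if cur_chrom is not None:
                yield from _emit(cur_chrom, buf.concat(), fa, window)
                buf = _ReadBuffer()
            cur_chrom = rname
            check_chrom(cur_chrom)
            flush_horizon = -1
        start = read.reference_start
        if buf.n >= cfg.max_flush_bases and start > flush_horizon:
            # positions before this read's start are complete
            arrays = buf.concat()
            done = arrays[0] < start
            yield from _emit(cur_chrom, tuple(a[done] for a in arrays), fa, window)
            buf = _ReadBuffer()
            buf.reset_with(tuple(a[~done] for a in arrays))
            flush_horizon = start

        seq = read.query_sequence
        quals = read.query_qualities
        if seq is None or quals is None:
            if not warned["qual"]:
                logger.warning("skipping read(s) without sequence or base qualities")
                warned["qual"] = True
            continue
        ctuples = read.cigartuples
        if ctuples is None:
            continue
        if len(ctuples) == 1 and ctuples[0][0] == 0:  # single M run: the common case
            n = ctuples[0][1]
            qpos = np.arange(n, dtype=np.int64)
            rpos = start + qpos
        else:
            pairs = read.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            arr = np.asarray(pairs, dtype=np.int64)
            qpos, rpos = arr[:, 0], arr[:, 1]
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[qpos]
        ph = np.asarray(quals, dtype=np.int16)[qpos]
        keep = (
            ((codes == _A) | (codes == _C) | (codes == _G) | (codes == _T))
            & (ph >= min_q)
        )
        if not keep.any():
            continue
        qstart = read.query_alignment_start
        m = read.query_alignment_length
        k = (qpos - qstart + 1).astype(np.int32)

        try:
            r_val = int(read.get_tag(cfg.edit_distance_tag))
        except KeyError:
            if cfg.missing_tag_policy == "fail":
                raise ValueError(
                    f"read {read.query_name!r} lacks edit-distance tag "
                    f"{cfg.edit_distance_tag!r}"
                )
            if not warned["nm"]:
                logger.warning(
                    "missing %s tag; defaulting read_errors=0", cfg.edit_distance_tag
                )
                warned["nm"] = True
            r_val = 0
        try:
            h_val = int(read.get_tag(cfg.hit_count_tag))
        except KeyError:
            if cfg.missing_tag_policy == "fail":
                raise ValueError(
                    f"read {read.query_name!r} lacks hit-count tag "
                    f"{cfg.hit_count_tag!r}"
                )
            if not warned["nh"]:
                logger.warning(
                    "missing %s tag; defaulting read_hits=1", cfg.hit_count_tag
                )
                warned["nh"] = True
            h_val = 1

        buf.add(
            rpos[keep],
            codes[keep],
            phred_to_quality(ph[keep]),
            k[keep],
            m,
            r_val,
            h_val,
        )

    if cur_chrom is not None:
        yield from _emit(cur_chrom, buf.concat(), fa, window)
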