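"""Synthetic sequencing data with known variants for end-to-end testing.

The generator emulates a single-end, ungapped resequencing experiment:
reads of fixed length are placed uniformly over an i.i.d. random
reference.  At each simulated variant position every overlapping read
carries the alternative allele independently with probability β (the
variant allele fraction).  On top of that every base is corrupted to a
uniformly chosen other nucleotide with a per-base technical error
probability built from three factors:

* the overall error rate ε (genome-wide mean);
* a read-position profile (``flat`` or ``ramp``; the ramp grows
  linearly from 0.5·ε at the first cycle to 1.5·ε at the last,
  emulating the end-of-read degradation of short-read sequencers);
* a per-base weight drawn from a discrete quality class distribution,
  normalised to mean 1, so that errors concentrate on low-quality
  bases as they do in real data.

With ``calibrated=True`` (default) the written phred score is the true
per-base error probability on the phred scale, i.e. the qualities are
perfectly calibrated; with ``calibrated=False`` qualities are drawn
independently of the realised error process and carry no information.

Reads are written as already-aligned records at their true placements
(CIGAR ``<len>M``), bypassing a mapper: the edit-distance annotation NM
is the realised mismatch count against the reference (optionally
inflated for a configurable fraction of reads, standing in for
alignment error), and the hit-count annotation NH is 1 except for a
configurable fraction of multi-mapping reads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimResult",
    "FixtureSpec",
    "simulate_dataset",
    "standard_fixtures",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Default phred class distribution: mostly accurate calls with a small
# very-low-quality tail, as in short-read data.
DEFAULT_PHRED_CLASSES = (40, 35, 30, 25, 20, 12)
DEFAULT_PHRED_PROBS = (0.30, 0.30, 0.18, 0.12, 0.07, 0.03)


@dataclass
class SimConfig:
    """Parameters of one simulated resequencing experiment."""

    genome_length: int = 100_000
    coverage: float = 50.0
    read_length: int = 100
    n_variants: int = 100
    beta: Union[float, Sequence[float]] = 0.5   # variant allele fraction
    error_rate: float = 0.001                   # ε, genome-wide mean
    profile: str = "ramp"                       # "flat" | "ramp"
    phred_classes: Tuple[int, ...] = DEFAULT_PHRED_CLASSES
    phred_probs: Tuple[float, ...] = DEFAULT_PHRED_PROBS
    calibrated: bool = True
    extra_error_fraction: float = 0.0   # reads whose NM is inflated by 1-3
    multi_hit_fraction: float = 0.0     # reads annotated with NH > 1
    multi_hit_max: int = 10
    chrom: str = "sim1"
    seed: int = 0

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.beta, dtype=np.float64))
        if np.any(b <= 0) or np.any(b > 1):
            raise ValueError("beta must lie in (0, 1]")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.profile not in ("flat", "ramp"):
            raise ValueError("profile must be 'flat' or 'ramp'")
        if self.n_variants > self.genome_length:
            raise ValueError("n_variants exceeds genome_length")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["beta"], np.ndarray):
            d["beta"] = d["beta"].tolist()
        d["phred_classes"] = list(d["phred_classes"])
        d["phred_probs"] = list(d["phred_probs"])
        return d


@dataclass
class TruthSet:
    """Simulated variant positions with their allele fractions."""

    chrom: str
    positions: np.ndarray   # 1-based, unique, sorted
    ref: np.ndarray         # '<U1'
    alt: np.ndarray         # '<U1', != ref
    beta: np.ndarray        # per-site allele fraction

    def __len__(self) -> int:
        return int(self.positions.size)

    def position_set(self) -> set:
        return {(self.chrom, int(p)) for p in self.positions}

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for p, r, a, b in zip(self.positions, self.ref, self.alt, self.beta):
                fh.write(f"{self.chrom}\t{p - 1}\t{p}\t{r}>{a}\t{b}\n")

    def to_vcf(self, path, genome_length: Optional[int] = None) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if genome_length:
                fh.write(f"##contig=<ID={self.chrom},length={genome_length}>\n")
            fh.write('##INFO=<ID=AF,Number=1,Type=Float,'
                     'Description="Simulated variant allele fraction">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for p, r, a, b in zip(self.positions, self.ref, self.alt, self.beta):
                fh.write(f"{self.chrom}\t{p}\t.\t{r}\t{a}\t.\t.\tAF={b}\n")

    @classmethod
    def from_bed(cls, path) -> "TruthSet":
        chroms, pos, ref, alt, beta = [], [], [], [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                chroms.append(f[0])
                pos.append(int(f[2]))
                r, a = f[3].split(">")
                ref.append(r)
                alt.append(a)
                beta.append(float(f[4]) if len(f) > 4 else float("nan"))
        if len(set(chroms)) > 1:
            raise ValueError("truth BED spans multiple chromosomes")
        if not chroms:
            return cls(chrom="", positions=np.array([], dtype=int),
                       ref=np.array([], dtype="<U1"), alt=np.array([], dtype="<U1"),
                       beta=np.array([]))
        return cls(chrom=chroms[0], positions=np.array(pos),
                   ref=np.array(ref), alt=np.array(alt), beta=np.array(beta))


@dataclass
class SimResult:
    """Artifacts of one simulated dataset."""

    config: SimConfig
    truth: TruthSet
    fasta: Path
    alignments: Path
    truth_bed: Path
    truth_vcf: Path
    site_coverage: np.ndarray    # per reference position (0-based index)
    site_mismatch: np.ndarray    # realised mismatch counts vs reference

    @property
    def n_reads(self) -> int:
        return int(round(self.config.genome_length * self.config.coverage
                         / self.config.read_length))

    def site_table(self):
        """Realised (coverage, mismatch) counts for every covered position.

        Returns a dict mapping 1-based position to ``(coverage,
        n_mismatch)``; this is the generator's own cross-section
        bookkeeping and serves as the round-trip oracle for the pileup
        engine.
        """
        covered = np.flatnonzero(self.site_coverage)
        return {
            int(p) + 1: (int(self.site_coverage[p]), int(self.site_mismatch[p]))
            for p in covered
        }


def _position_profile(read_length: int, profile: str) -> np.ndarray:
    if profile == "flat":
        return np.ones(read_length)
    # linear ramp from 0.5 to 1.5, mean exactly 1
    if read_length == 1:
        return np.ones(1)
    return 0.5 + np.arange(read_length) / (read_length - 1)


def simulate_dataset(
    cfg: SimConfig,
    out_dir: Union[str, Path],
    alignment_format: str = "bam",
    chunk_reads: int = 50_000,
) -> SimResult:
    """Generate reference FASTA, aligned reads and truth set.

    ``alignment_format`` is ``"bam"`` (coordinate-sorted + indexed) or
    ``"sam"`` (plain text, e.g. for fixtures).  All randomness derives
    from ``cfg.seed``; identical configs reproduce identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    L, rl = cfg.genome_length, cfg.read_length

    ref_codes = rng.choice(_BASES, size=L)
    ref_path = out / "reference.fa"
    with open(ref_path, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        seq = ref_codes.tobytes().decode("ascii")
        for i in range(0, L, 70):
            fh.write(seq[i:i + 70] + "\n")
    pysam.faidx(str(ref_path))

    # variants: unique positions, alt drawn uniformly from the other bases
    var_pos0 = np.sort(rng.choice(L, size=cfg.n_variants, replace=False))
    var_ref = ref_codes[var_pos0]
    shift = rng.integers(1, 4, size=cfg.n_variants)
    var_alt = _BASES[(np.searchsorted(_BASES, var_ref) + shift) % 4]
    beta = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.beta, dtype=np.float64)), (cfg.n_variants,)
    ).copy()
    truth = TruthSet(
        chrom=cfg.chrom,
        positions=var_pos0 + 1,
        ref=np.array([chr(b) for b in var_ref]),
        alt=np.array([chr(b) for b in var_alt]),
        beta=beta,
    )

    n_reads = int(round(L * cfg.coverage / rl))
    starts = np.sort(rng.integers(0, L - rl + 1, size=n_reads))

    profile = _position_profile(rl, cfg.profile)
    phreds = np.asarray(cfg.phred_classes, dtype=np.float64)
    probs = np.asarray(cfg.phred_probs, dtype=np.float64)
    probs = probs / probs.sum()
    p0 = np.power(10.0, -phreds / 10.0)
    weights = p0 / float(p0 @ probs)  # mean-1 per-base error weights

    aln_path = out / ("alignments.bam" if alignment_format == "bam"
                      else "alignments.sam")
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.chrom, "LN": L}],
        "PG": [{"ID": "adasnv-sim", "PN": "adasnv-sim"}],
    }
    mode = "wb" if alignment_format == "bam" else "w"

    site_cov = np.zeros(L, dtype=np.int64)
    site_mm = np.zeros(L, dtype=np.int64)
    offsets = np.arange(rl)

    with pysam.AlignmentFile(str(aln_path), mode, header=header) as bam:
        for c0 in range(0, n_reads, chunk_reads):
            c1 = min(c0 + chunk_reads, n_reads)
            st = starts[c0:c1]
            nb = c1 - c0
            pos_mat = st[:, None] + offsets[None, :]
            base = ref_codes[pos_mat].copy()

            # variant alleles: each overlapping read carries alt w.p. beta
            lo = np.searchsorted(st, var_pos0 - rl + 1, side="left")
            hi = np.searchsorted(st, var_pos0, side="right")
            for v in range(cfg.n_variants):
                if lo[v] == hi[v]:
                    continue
                rows = np.arange(lo[v], hi[v])
                cols = var_pos0[v] - st[rows]
                carry = rng.random(rows.size) < beta[v]
                base[rows[carry], cols[carry]] = var_alt[v]

            # technical errors
            cls = rng.choice(phreds.size, size=(nb, rl), p=probs)
            p_err = np.minimum(
                cfg.error_rate * profile[None, :] * weights[cls], 0.75
            )
            err = rng.random((nb, rl)) < p_err
            if err.any():
                idx = np.searchsorted(_BASES, base[err])
                base[err] = _BASES[(idx + rng.integers(1, 4, size=idx.size)) % 4]

            if cfg.calibrated:
                with np.errstate(divide="ignore"):
                    ph = -10.0 * np.log10(p_err)
                phred_out = np.clip(np.rint(ph), 1, 60).astype(np.uint8)
            else:
                phred_out = phreds[cls].astype(np.uint8)

            nm = (base != ref_codes[pos_mat]).sum(axis=1)
            if cfg.extra_error_fraction > 0:
                extra = rng.random(nb) < cfg.extra_error_fraction
                nm = nm + np.where(extra, rng.integers(1, 4, size=nb), 0)
            nh = np.ones(nb, dtype=np.int64)
            if cfg.multi_hit_fraction > 0:
                multi = rng.random(nb) < cfg.multi_hit_fraction
                nh[multi] = rng.integers(2, cfg.multi_hit_max + 1, multi.sum())

            np.add.at(site_cov, pos_mat.ravel(), 1)
            np.add.at(site_mm, pos_mat.ravel(),
                      (base != ref_codes[pos_mat]).ravel().astype(np.int64))

            cigar = [(0, rl)]
            for i in range(nb):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"r{c0 + i:09d}"
                a.flag = 0
                a.reference_id = 0
                a.reference_start = int(st[i])
                a.mapping_quality = 60
                a.cigartuples = cigar
                a.query_sequence = base[i].tobytes().decode("ascii")
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in phred_out[i])
                )
                a.set_tags([("NM", int(nm[i]), "i"), ("NH", int(nh[i]), "i")])
                bam.write(a)

    if alignment_format == "bam":
        pysam.index(str(aln_path))

    truth_bed = out / "truth.bed"
    truth_vcf = out / "truth.vcf"
    truth.to_bed(truth_bed)
    truth.to_vcf(truth_vcf, genome_length=L)
    (out / "sim_config.json").write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")

    return SimResult(
        config=cfg,
        truth=truth,
        fasta=ref_path,
        alignments=aln_path,
        truth_bed=truth_bed,
        truth_vcf=truth_vcf,
        site_coverage=site_cov,
        site_mismatch=site_mm,
    )


@dataclass(frozen=True)
class FixtureSpec:
    """A named study cell with its recommended background sample size."""

    name: str
    sim: SimConfig
    background_sample_size: int


def standard_fixtures(
    genome_length: int = 1_000_000,
    n_variants: int = 1000,
    error_rate: float = 0.01,
    seed: int = 0,
) -> Dict[str, FixtureSpec]:
    """The desk-scale study grid on a toy genome.

    Returns the 12-cell main grid (coverage 10/20/30/50/100/200 crossed
    with allele fraction 0.2/0.5) plus a low-frequency grid (allele
    fractions 0.05 and 0.1).  Low-frequency cells carry a larger
    recommended background sample, since few sites then populate the
    positive score range.
    """
    fixtures: Dict[str, FixtureSpec] = {}
    coverages = (10, 20, 30, 50, 100, 200)
    for grid, sample in ((((0.2, 0.5)), 100_000), (((0.05, 0.1)), 300_000)):
        for beta in grid:
            for cov in coverages:
                name = f"cov{cov}_beta{beta}"
                fixtures[name] = FixtureSpec(
                    name=name,
                    sim=SimConfig(
                        genome_length=genome_length,
                        coverage=cov,
                        read_length=100,
                        n_variants=n_variants,
                        beta=beta,
                        error_rate=error_rate,
                        seed=seed,
                    ),
                    background_sample_size=sample,
                )
    return fixtures
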