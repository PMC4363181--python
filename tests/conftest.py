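"""Shared fixtures: hand-built alignments and small simulated datasets.

All fixture data is generated at test time; nothing binary is stored in
the repository.
"""

import numpy as np
import pysam
import pytest

from adasnv import (
    BackgroundModel,
    ConditionalTable,
    CrossSection,
    DeltaECDF,
    SimConfig,
    simulate_dataset,
)

# --- hand-built three-read alignment ------------------------------------
#
# Reference chr1 (20 bp):  ACGTACGTACGTACGTACGT
# r1  pos 1, 8M,   ACGTACGT          matches, q20,  NM=0, NH=1
# r2  pos 3, 8M,   GTCCGTAC          C at ref pos 5 (A->C), q30, NM=1, NH=2
# r3  pos 5, 2S8M, ttACGTACGT        soft-clipped, matches, q10, NM=0, NH=1
#
# Cross-section at pos 5 (ref A): r1 A, r2 C, r3 A -> |M|=2, |M̄|=1, δ=1/3.

TINY_REF = "ACGTACGTACGTACGTACGT"

TINY_SAM = "\n".join([
    "@HD\tVN:1.6\tSO:coordinate",
    "@SQ\tSN:chr1\tLN:20",
    "r1\t0\tchr1\t1\t60\t8M\t*\t0\t0\tACGTACGT\t" + "5" * 8 + "\tNM:i:0\tNH:i:1",
    "r2\t0\tchr1\t3\t60\t8M\t*\t0\t0\tGTCCGTAC\t" + "?" * 8 + "\tNM:i:1\tNH:i:2",
    "r3\t0\tchr1\t5\t60\t2S8M\t*\t0\t0\tTTACGTACGT\t" + "+" * 10 + "\tNM:i:0\tNH:i:1",
]) + "\n"


def write_fasta(path, name, seq):
    with open(path, "w") as fh:
        fh.write(f">{name}\n{seq}\n")
    pysam.faidx(str(path))
    return path


@pytest.fixture(scope="session")
def tiny_alignment(tmp_path_factory):
    """Paths (sam, fasta) of the hand-built three-read dataset."""
    d = tmp_path_factory.mktemp("tiny")
    sam = d / "tiny.sam"
    sam.write_text(TINY_SAM)
    fasta = write_fasta(d / "tiny.fa", "chr1", TINY_REF)
    return sam, fasta


def make_cross_section(bases, ref_base="A", chrom="chr1", pos=1):
    """Build a CrossSection from (base, quality, k, m, R, H) tuples."""
    b, q, k, m, r, h = zip(*bases)
    return CrossSection(
        chrom=chrom,
        pos=pos,
        ref_base=ref_base,
        base_codes=np.frombuffer("".join(b).encode(), dtype=np.uint8).copy(),
        quality=np.array(q, dtype=np.float64),
        read_pos=np.array(k, dtype=np.int32),
        read_len=np.array(m, dtype=np.int32),
        read_errors=np.array(r, dtype=np.int32),
        read_hits=np.array(h, dtype=np.int32),
    )


def make_table(kind, match, mismatch, pseudocount=0.5, **kw):
    return ConditionalTable(
        kind,
        np.asarray(match, dtype=np.int64),
        np.asarray(mismatch, dtype=np.int64),
        pseudocount=pseudocount,
        **kw,
    )


@pytest.fixture
def toy_model():
    """A small hand-built background model with known table counts."""
    rng = np.random.default_rng(42)
    p_match = rng.integers(50, 200, size=10)
    p_mismatch = rng.integers(1, 12, size=10)
    ecdf = DeltaECDF.from_values([0.0] * 6 + [0.05, 0.1, 0.1, 0.25, 0.4, 1.0])
    return BackgroundModel(
        ecdf=ecdf,
        tables={
            "P": make_table("P", p_match, p_mismatch, n_bins=10),
            "R": make_table("R", [400, 120, 40, 9], [4, 6, 4, 3], r_max=2),
            "H": make_table("H", [500, 50, 11], [5, 4, 2], h_max=2),
        },
        sample_size=100,
        n_sampled=12,
        n_qualifying=12,
        seed=0,
        contigs=["chr1"],
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 60 kb, 30x, β=0.5 dataset with 60 variants (ε=0.01)."""
    cfg = SimConfig(genome_length=60_000, coverage=30, n_variants=60,
                    beta=0.5, error_rate=0.01, seed=1301)
    return simulate_dataset(cfg, tmp_path_factory.mktemp("smallsim"))


@pytest.fixture(scope="session")
def small_model(small_sim):
    from adasnv import run_build

    return run_build(small_sim.alignments, small_sim.fasta,
                     sample_size=20_000, seed=1301)
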