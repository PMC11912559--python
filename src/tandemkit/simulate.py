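"""Seeded fixture generator: toy reference with implanted STRs and
pre-aligned reads under a tract-shift error model.

The generator emulates the salient features of long-read homopolymer data:
deletion-dominant tract-length errors, optional strand-asymmetric error
rates, and uniform per-base substitution noise.  Reads are emitted as
already-aligned SAM records (correct POS, CIGAR, FLAG, MAPQ 60) plus a
FASTQ, so every pipeline stage is testable without running an aligner.
Identical configurations (including the seed) produce identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .catalog import StrLocus
from .reads import reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the read simulator.

    Defaults describe a deletion-skewed homopolymer experiment: A-repeats
    of 10–14 copies (the MSI-relevant range), 30x coverage, balanced
    strands, per-repeat geometric shift decay p_del=0.3 / p_ins=0.05 and 1%
    substitution noise.
    """

    seed: int = 0
    n_loci: int = 50
    units: Sequence[str] = ("A",)
    allele_range: Tuple[int, int] = (10, 14)  # inclusive
    flank_length: int = 60
    coverage: int = 30
    strand_fraction_forward: float = 0.5
    p_del: float = 0.3
    p_ins: float = 0.05
    p_sub: float = 0.01
    max_shift: int = 5
    #: optional per-strand override {"forward": (p_del, p_ins), "reverse": ...}
    strand_error_rates: Optional[Mapping[str, Tuple[float, float]]] = None
    #: per-locus true-allele offset vs the reference (e.g. -2 for MSI loci)
    allele_offsets: Mapping[str, int] = field(default_factory=dict)
    low_complexity_flanks: bool = False
    chrom: str = "sim1"

    def rates_for(self, strand: str) -> Tuple[float, float]:
        if self.strand_error_rates and strand in self.strand_error_rates:
            return tuple(self.strand_error_rates[strand])
        return self.p_del, self.p_ins


def _random_flank(rng: np.random.Generator, length: int, forbid: str) -> str:
    """Random flank whose base adjacent to the tract differs from ``forbid``
    (keeps the implanted run maximal and its copy number exact)."""
    while True:
        seq = "".join(rng.choice(_BASES, size=length))
        if len(set(seq)) >= 3 and forbid not in (seq[0], seq[-1]):
            return seq


def make_reference(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], List[StrLocus], Dict[str, int]]:
    """Build the toy reference.

    Returns (contig sequences, truth catalog with flanks attached, truth
    table locus_id -> true allele).  Loci are separated by at least
    2 x flank_length of random spacer; in ``low_complexity_flanks`` mode the
    left flank is a near-copy of the tract (fails the complexity filters).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.allele_range
    chrom = config.chrom
    parts: List[str] = []
    loci: List[StrLocus] = []
    truth: Dict[str, int] = {}
    pos = 0
    for i in range(config.n_loci):
        unit = config.units[i % len(config.units)]
        count = int(rng.integers(lo, hi + 1))
        if config.low_complexity_flanks:
            # tract-like flank ending one base short of the tract (the
            # classic failure mode: an A-tract preceded by A...AC)
            filler = _random_flank(rng, config.flank_length - 12, unit[-1])
            near = (unit * 12)[:11] + _other_base(rng, unit[-1])
            left = filler + near
        else:
            left = _random_flank(rng, config.flank_length, unit[-1])
        right = _random_flank(rng, config.flank_length, unit[0])
        spacer = "".join(rng.choice(_BASES, size=config.flank_length))
        block = spacer + left
        start = pos + len(block)
        end = start + count * len(unit)
        locus_id = f"L{i:04d}"
        loci.append(
            StrLocus(
                locus_id=locus_id,
                chrom=chrom,
                start=start,
                end=end,
                unit=unit,
                ref_repeat_count=count,
                left_flank=left,
                right_flank=right,
                flank_window=config.flank_length,
            )
        )
        truth[locus_id] = count
        parts.append(block + unit * count + right)
        pos += len(block) + count * len(unit) + len(right)
    tail = "".join(rng.choice(_BASES, size=config.flank_length))
    parts.append(tail)
    return {chrom: "".join(parts)}, loci, truth


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(len(choices)))]


def _sample_shift(
    rng: np.random.Generator,
    p_del: float,
    p_ins: float,
    max_shift: int,
    true_allele: int,
) -> int:
    """Draw a tract-shift from the truncated two-sided geometric kernel."""
    shifts = [0]
    mass = [1.0]
    for d in range(1, max_shift + 1):
        if p_del > 0 and true_allele - d >= 0:
            shifts.append(-d)
            mass.append(p_del ** d)
        if p_ins > 0:
            shifts.append(d)
            mass.append(p_ins ** d)
    probs = np.asarray(mass) / sum(mass)
    return int(rng.choice(shifts, p=probs))


def _substitute(rng: np.random.Generator, seq: str, p_sub: float) -> str:
    if p_sub <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < p_sub
    for i in np.nonzero(hits)[0]:
        arr[i] = _other_base(rng, arr[i])
    return "".join(arr)


def simulate_reads(
    config: SimulationConfig,
    reference: Mapping[str, str],
    loci: Sequence[StrLocus],
    truth: Mapping[str, int],
    sam_path: str,
    fastq_path: Optional[str] = None,
) -> None:
    """Write ``config.coverage`` reads per locus as aligned SAM (+ FASTQ).

    Each read spans the locus plus both full flanks.  Its tract carries
    ``truth`` copies (the reference count unless overridden by
    ``allele_offsets``) shifted by a kernel draw; substitutions are applied
    at ``p_sub`` per base.  The CIGAR records the tract contraction or
    expansion as a D/I run at the tract's 3' end; SEQ is stored in
    reference orientation with FLAG 16 for reverse reads, and the FASTQ
    carries the strand-native (reverse-complemented) sequence.
    """
    import pysam

    rng = np.random.default_rng(config.seed + 1)
    chrom_lengths = {c: len(s) for c, s in reference.items()}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": n} for c, n in sorted(chrom_lengths.items())
        ],
    }
    fastq_lines: List[str] = []
    with pysam.AlignmentFile(sam_path, "wh", header=header) as sam:
        tid = {c: sam.get_tid(c) for c in chrom_lengths}
        for locus in sorted(loci, key=lambda l: (l.chrom, l.start)):
            seq = reference[locus.chrom]
            true_allele = truth[locus.locus_id] + config.allele_offsets.get(
                locus.locus_id, 0
            )
            true_allele = max(0, true_allele)
            left_start = locus.start - len(locus.left_flank)
            right_end = locus.end + len(locus.right_flank)
            left = seq[left_start : locus.start]
            right = seq[locus.end : right_end]
            ulen = len(locus.unit)
            ref_count = locus.ref_repeat_count
            for r in range(config.coverage):
                strand = (
                    "forward"
                    if rng.random() < config.strand_fraction_forward
                    else "reverse"
                )
                p_del, p_ins = config.rates_for(strand)
                shift = _sample_shift(
                    rng, p_del, p_ins, config.max_shift, true_allele
                )
                obs_count = true_allele + shift
                read_seq = left + locus.unit * obs_count + right
                read_seq = _substitute(rng, read_seq, config.p_sub)
                cigar = _tract_cigar(
                    len(left), len(right), ulen, ref_count, obs_count
                )
                a = pysam.AlignedSegment(sam.header)
                a.query_name = f"{locus.locus_id}_r{r:04d}"
                a.query_sequence = read_seq
                a.flag = 16 if strand == "reverse" else 0
                a.reference_id = tid[locus.chrom]
                a.reference_start = left_start
                a.mapping_quality = 60
                a.cigartuples = cigar
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(read_seq)
                )
                sam.write(a)
                if fastq_path is not None:
                    native = (
                        reverse_complement(read_seq)
                        if strand == "reverse"
                        else read_seq
                    )
                    fastq_lines.append(
                        f"@{a.query_name}\n{native}\n+\n{'I' * len(native)}\n"
                    )
    if fastq_path is not None:
        Path(fastq_path).write_text("".join(fastq_lines))


def _tract_cigar(
    left_len: int, right_len: int, ulen: int, ref_count: int, obs_count: int
) -> List[Tuple[int, int]]:
    """CIGAR for a read whose tract has obs_count copies vs ref_count."""
    M, I, D = 0, 1, 2
    common = min(ref_count, obs_count) * ulen
    ops: List[Tuple[int, int]] = [(M, left_len + common)]
    if obs_count > ref_count:
        ops.append((I, (obs_count - ref_count) * ulen))
    elif obs_count < ref_count:
        ops.append((D, (ref_count - obs_count) * ulen))
    if ops[-1][0] == D:
        ops.append((M, right_len))
    else:
        last_op, last_n = ops[-1]
        if last_op == M:
            ops[-1] = (M, last_n + right_len)
        else:
            ops.append((M, right_len))
    return ops


def write_reference_fasta(reference: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_truth_table(
    loci: Sequence[StrLocus], truth: Mapping[str, int], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\tunit\tref_repeat_count\ttrue_allele\n")
        for l in loci:
            fh.write(
                f"{l.locus_id}\t{l.chrom}\t{l.start}\t{l.end}\t{l.unit}\t"
                f"{l.ref_repeat_count}\t{truth[l.locus_id]}\n"
            )


def run_pipeline(
    config: SimulationConfig,
    workdir: str,
    kernel=None,
    strand_mode: str = "all",
    min_coverage: int = 1,
    max_distance: int = 4,
):
    """Simulate, extract, correct, and genotype in one call.

    Convenience driver used by the tests and the acceptance checks; returns
    (loci, truth, allele_table, locus_table).
    """
    from .correction import build_allele_table
    from .genotyping import ErrorKernel, build_locus_table
    from .reads import extract_segments

    if kernel is None:
        kernel = ErrorKernel(
            p_del=config.p_del, p_ins=config.p_ins, max_shift=config.max_shift
        )
    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    reference, loci, truth = make_reference(config)
    sam_path = str(wd / "reads.sam")
    simulate_reads(config, reference, loci, truth, sam_path)
    segments = extract_segments(sam_path, loci)
    allele_table = build_allele_table(segments, loci, max_distance=max_distance)
    locus_table = build_locus_table(
        allele_table,
        loci,
        kernel=kernel,
        strand_mode=strand_mode,
        min_coverage=min_coverage,
    )
    return loci, truth, allele_table, locus_table
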