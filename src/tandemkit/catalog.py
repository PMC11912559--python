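"""STR locus catalog: perfect-repeat discovery and flank-complexity filters.

A catalog entry is a maximal run of a primitive repeat unit (1–6 nt) in the
reference, annotated with its flanking sequences and two flank-complexity
metrics derived from k-mer counts.  Low-complexity flanks resemble the
repeat tract itself and make tract boundaries ambiguous in noisy reads, so
the catalog can be filtered on flank complexity, on strand-specific
coverage, and on a Levenshtein flank-vs-tract criterion that isolates the
pathological subset of A-repeats embedded in homopolymer-like context.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .correction import levenshtein

_ACGT = frozenset("ACGT")

#: complexity thresholds by unit size: loci whose flank metric is <= the
#: threshold on either side are removed (effective k-mer count metric).
DEFAULT_COMPLEXITY_THRESHOLDS: Dict[int, float] = {1: 2.5, 2: 2.0, 3: 5.0}

#: minimum total repeat length (nt) by unit size; 1-bp repeats require 10 nt.
DEFAULT_MIN_LENGTHS: Dict[int, int] = {1: 10, 2: 12, 3: 12, 4: 16, 5: 20, 6: 24}

DEFAULT_FLANK_WINDOW = 12


@dataclass(frozen=True)
class StrLocus:
    """One perfect tandem-repeat region on the reference strand."""

    locus_id: str
    chrom: str
    start: int
    end: int
    unit: str
    ref_repeat_count: int
    left_flank: str = ""
    right_flank: str = ""
    flank_window: int = 0
    truncated_flank: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != self.ref_repeat_count * len(self.unit):
            raise ValueError(
                f"{self.locus_id}: span {self.end - self.start} != "
                f"{self.ref_repeat_count} x {len(self.unit)}-nt unit"
            )

    @property
    def tract(self) -> str:
        """The repeat tract sequence (unit repeated ref_repeat_count times)."""
        return self.unit * self.ref_repeat_count

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def _is_primitive(unit: str) -> bool:
    """True if ``unit`` is not itself a repetition of a shorter unit."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def find_perfect_repeats(
    sequence: str,
    unit_size: int,
    min_total_length_nt: int,
    chrom: str = "seq",
    offset: int = 0,
) -> List[StrLocus]:
    """Exhaustively scan ``sequence`` for maximal perfect repeats of period
    ``unit_size``.

    A run is reported when a primitive unit of length ``unit_size`` occurs in
    at least two whole copies totalling ``min_total_length_nt`` nucleotides
    or more, and the run cannot be extended by a further whole copy in either
    direction.  Non-ACGT characters terminate runs.  Returned loci carry no
    flanks (see :func:`build_catalog`).
    """
    if not 1 <= unit_size <= 6:
        raise ValueError("unit_size must be in 1..6")
    if min_total_length_nt < 2 * unit_size:
        raise ValueError("min_total_length_nt must be >= 2 x unit_size")
    seq = sequence.upper()
    n = len(seq)
    p = unit_size
    loci: List[StrLocus] = []
    if n < 2 * p:
        return loci

    def valid(i: int) -> bool:
        return seq[i] in _ACGT

    # maximal periodicity runs: intervals [a, b) where seq[j] == seq[j-p]
    # for all j in [a+p, b), split at non-ACGT characters; overlapping runs
    # (possible for p >= 2, sharing < p chars) resolved greedily left-to-right
    a = 0
    j = p
    last_end = 0
    while j <= n:
        if j == n or not valid(j) or seq[j] != seq[j - p]:
            b = j
            if (
                b - a >= 2 * p
                and a >= last_end
                and all(valid(i) for i in range(a, min(a + p, n)))
            ):
                count = (b - a) // p
                unit = seq[a : a + p]
                if count * p >= min_total_length_nt and _is_primitive(unit):
                    loci.append(
                        StrLocus(
                            locus_id=f"{chrom}:{offset + a}-{offset + a + count * p}:{unit}",
                            chrom=chrom,
                            start=offset + a,
                            end=offset + a + count * p,
                            unit=unit,
                            ref_repeat_count=count,
                        )
                    )
                    last_end = a + count * p
            if j < n and not valid(j):
                a = j + 1
                j = a + p
            else:
                a = b - p + 1
                j = b + 1
        else:
            j += 1
    return loci


def count_kmers(sequence: str, k: int) -> Dict[str, int]:
    """Count every length-``k`` substring of ``sequence`` (sliding by 1 nt).

    Counts sum to ``L - k + 1``; sequences shorter than ``k`` yield an empty
    map.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper()
    return dict(Counter(seq[i : i + k] for i in range(len(seq) - k + 1)))


def kmer_diversity(sequence: str, k: int) -> float:
    """k-mer diversity: ``(L - (k-1)) / sum_i F_i**2`` over distinct k-mers.

    Bounded in ``[1/(L-k+1), 1]``: 1 when every k-mer is unique, the lower
    bound for a homopolymer.
    """
    counts = count_kmers(sequence, k)
    if not counts:
        raise ValueError(f"sequence length {len(sequence)} < k={k}")
    n_windows = len(sequence) - (k - 1)
    return n_windows / sum(f * f for f in counts.values())


def effective_kmer_count(sequence: str, k: int) -> float:
    """Effective number of distinct k-mers (inverse-Simpson / Hill number).

    ``(L-k+1)**2 / sum_i F_i**2``; equals the number of distinct k-mers when
    all are equally frequent, and 1 for a homopolymer.  This is the metric
    the catalog complexity filter uses by default, since its range matches
    per-unit-size thresholds greater than 1.
    """
    counts = count_kmers(sequence, k)
    if not counts:
        raise ValueError(f"sequence length {len(sequence)} < k={k}")
    n_windows = len(sequence) - (k - 1)
    return n_windows * n_windows / sum(f * f for f in counts.values())


def build_catalog(
    sequences: Mapping[str, str],
    unit_sizes: Sequence[int] = (1, 2, 3),
    min_lengths: Optional[Mapping[int, int]] = None,
    flank_window: int = DEFAULT_FLANK_WINDOW,
) -> List[StrLocus]:
    """Build an STR catalog from contig sequences.

    ``sequences`` maps contig name to sequence (e.g. from
    ``pysam.FastaFile``).  Flanks of ``flank_window`` nt are attached;
    loci whose flanks are truncated by a contig end are flagged.
    """
    min_lengths = dict(DEFAULT_MIN_LENGTHS, **(min_lengths or {}))
    catalog: List[StrLocus] = []
    for chrom, seq in sequences.items():
        for p in unit_sizes:
            for locus in find_perfect_repeats(seq, p, min_lengths[p], chrom=chrom):
                left = seq[max(0, locus.start - flank_window) : locus.start]
                right = seq[locus.end : locus.end + flank_window]
                catalog.append(
                    replace(
                        locus,
                        left_flank=left.upper(),
                        right_flank=right.upper(),
                        flank_window=flank_window,
                        truncated_flank=(
                            len(left) < flank_window or len(right) < flank_window
                        ),
                    )
                )
    catalog.sort(key=lambda l: (l.chrom, l.start, len(l.unit)))
    return catalog


def catalog_from_fasta(fasta_path: str, **kwargs) -> List[StrLocus]:
    """Build a catalog directly from a FASTA file (uses pysam)."""
    import pysam

    with pysam.FastaFile(fasta_path) as fa:
        seqs = {name: fa.fetch(name) for name in fa.references}
    return build_catalog(seqs, **kwargs)


def filter_catalog(
    loci: Iterable[StrLocus],
    complexity_thresholds: Optional[Mapping[int, float]] = None,
    coverage_by_strand: Optional[Mapping[str, Tuple[int, int]]] = None,
    min_strand_coverage: int = 20,
    k: int = 2,
    metric: str = "effective",
) -> List[StrLocus]:
    """Apply the catalog-level complexity and coverage filters.

    A locus is removed when either flank's complexity metric is <= the
    threshold for its unit size, or when neither strand reaches
    ``min_strand_coverage`` reads (a single strand meeting the minimum
    suffices).  Loci with contig-truncated flanks are excluded from the
    complexity test rather than judged on partial sequence.  Loci absent
    from ``coverage_by_strand`` count as zero coverage.
    """
    thresholds = dict(
        DEFAULT_COMPLEXITY_THRESHOLDS, **(complexity_thresholds or {})
    )
    metric_fn = {"effective": effective_kmer_count, "diversity": kmer_diversity}[
        metric
    ]
    kept: List[StrLocus] = []
    for locus in loci:
        thr = thresholds.get(len(locus.unit))
        if thr is not None and not locus.truncated_flank:
            if (
                metric_fn(locus.left_flank, k) <= thr
                or metric_fn(locus.right_flank, k) <= thr
            ):
                continue
        if coverage_by_strand is not None:
            fwd, rev = coverage_by_strand.get(locus.locus_id, (0, 0))
            if fwd < min_strand_coverage and rev < min_strand_coverage:
                continue
        kept.append(locus)
    return kept


def select_low_complexity_subset(
    loci: Iterable[StrLocus], max_lev: int = 7, invert: bool = False
) -> List[StrLocus]:
    """Select loci whose repeat tract resembles a flank by edit distance.

    A locus is selected when ``min(lev(left_flank, tract), lev(right_flank,
    tract)) < max_lev`` — the low-complexity-flank subset excluded from the
    main analyses.  ``invert=True`` returns the complement (the retained
    set).
    """
    selected: List[StrLocus] = []
    for locus in loci:
        tract = locus.tract
        d = min(
            levenshtein(locus.left_flank, tract),
            levenshtein(locus.right_flank, tract),
        )
        if (d < max_lev) != invert:
            selected.append(locus)
    return selected


_CATALOG_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "unit",
    "ref_repeat_count",
    "left_flank",
    "right_flank",
    "diversity_left",
    "diversity_right",
    "effective_k_left",
    "effective_k_right",
]


def catalog_to_frame(loci: Sequence[StrLocus], k: int = 2) -> pd.DataFrame:
    """Catalog as a DataFrame with both complexity metrics per flank."""
    rows = []
    for l in loci:
        def _metrics(flank: str) -> Tuple[float, float]:
            if len(flank) < k:
                return math.nan, math.nan
            return kmer_diversity(flank, k), effective_kmer_count(flank, k)

        div_l, eff_l = _metrics(l.left_flank)
        div_r, eff_r = _metrics(l.right_flank)
        rows.append(
            (
                l.locus_id,
                l.chrom,
                l.start,
                l.end,
                l.unit,
                l.ref_repeat_count,
                l.left_flank,
                l.right_flank,
                div_l,
                div_r,
                eff_l,
                eff_r,
            )
        )
    return pd.DataFrame(rows, columns=_CATALOG_COLUMNS)


def catalog_from_frame(frame: pd.DataFrame) -> List[StrLocus]:
    """Rebuild :class:`StrLocus` records from a catalog DataFrame."""
    loci = []
    for row in frame.itertuples(index=False):
        left = "" if pd.isna(row.left_flank) else str(row.left_flank)
        right = "" if pd.isna(row.right_flank) else str(row.right_flank)
        window = max(len(left), len(right))
        loci.append(
            StrLocus(
                locus_id=str(row.locus_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                unit=str(row.unit),
                ref_repeat_count=int(row.ref_repeat_count),
                left_flank=left,
                right_flank=right,
                flank_window=window,
                truncated_flank=len(left) != len(right),
            )
        )
    return loci
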