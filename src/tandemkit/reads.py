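"""Read loading and flank-anchored tract extraction.

Aligners place indels inside repeat tracts inconsistently, and the reference
tract length biases where an alignment opens gaps.  To sidestep this, the
read bases over a locus are delimited not by the reference alignment alone
but by locating the two flanking sequences directly in the read: the bases
strictly between the right end of the left-flank match and the left end of
the right-flank match form the observed tract segment.  Flank matches are
found with edlib infix (semi-global) search; an anchor is accepted when its
edit distance is at most 30% of the anchor length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple

import edlib
import pysam

from .catalog import StrLocus

DEFAULT_MIN_MAPQ = 60
#: reference nt per side used for flank anchoring (wider than the 12-nt
#: complexity window: short anchors are fragile in noisy reads)
DEFAULT_ANCHOR_WINDOW = 30
#: anchor rejected when edit distance exceeds this fraction of its length
ANCHOR_MAX_ERROR_FRAC = 0.30

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def as_sequenced_unit(unit: str, strand: str) -> str:
    """The repeat unit the sequencer physically read.

    Forward-strand alignments sequenced the reference unit itself; reverse
    strand alignments sequenced its reverse complement (an A-repeat locus is
    read as a T-repeat by reverse-strand molecules).
    """
    if strand == "forward":
        return unit.upper()
    if strand == "reverse":
        return reverse_complement(unit.upper())
    raise ValueError(f"strand must be 'forward' or 'reverse', got {strand!r}")


@dataclass(frozen=True)
class ReadSegment:
    """Read bases between the two flank anchors of one locus."""

    read_id: str
    locus_id: str
    strand: str
    segment: str  # reference orientation
    mapq: int
    anchored: bool
    base_quals: Optional[Tuple[int, ...]] = None


def _passes_filters(
    read: "pysam.AlignedSegment", min_mapq: int, drop_supplementary: bool
) -> bool:
    if read.is_unmapped or read.is_secondary:
        return False
    if drop_supplementary and read.is_supplementary:
        return False
    return read.mapping_quality >= min_mapq


def load_reads(
    alignment_path: str,
    loci: Sequence[StrLocus],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    drop_supplementary: bool = True,
    anchor_window: int = DEFAULT_ANCHOR_WINDOW,
) -> Iterator[Tuple[StrLocus, "pysam.AlignedSegment"]]:
    """Yield (locus, read) pairs for primary alignments overlapping each
    locus window.

    Uses indexed random access when an index is available; otherwise (plain
    SAM input) makes a single pass and assigns reads to loci by interval
    overlap.  Loci on contigs absent from the header yield nothing.
    """
    mode = "rb" if alignment_path.endswith(".bam") else "r"
    with pysam.AlignmentFile(alignment_path, mode) as af:
        refs = set(af.references)
        windows = {
            l.locus_id: (max(0, l.start - anchor_window), l.end + anchor_window)
            for l in loci
        }
        if af.has_index():
            for locus in loci:
                if locus.chrom not in refs:
                    continue
                lo, hi = windows[locus.locus_id]
                for read in af.fetch(locus.chrom, lo, hi):
                    if _passes_filters(read, min_mapq, drop_supplementary):
                        yield locus, read
        else:
            by_chrom: dict = {}
            for l in loci:
                if l.chrom in refs:
                    by_chrom.setdefault(l.chrom, []).append(l)
            for read in af:
                if not _passes_filters(read, min_mapq, drop_supplementary):
                    continue
                for locus in by_chrom.get(read.reference_name, ()):
                    lo, hi = windows[locus.locus_id]
                    if read.reference_start < hi and read.reference_end > lo:
                        yield locus, read


def _locate_flank(
    flank: str, read_seq: str, expect: Optional[int], side: str
) -> Optional[Tuple[int, int]]:
    """Find ``flank`` in ``read_seq`` by infix edit-distance search.

    Returns the (start, end) half-open interval of the best hit, preferring
    the hit nearest ``expect`` (a read coordinate from the coarse CIGAR
    projection: the anchor's inner edge).  None if the best hit exceeds the
    error budget.
    """
    max_err = int(len(flank) * ANCHOR_MAX_ERROR_FRAC)
    res = edlib.align(flank, read_seq, mode="HW", task="locations", k=max_err)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    hits = [(s if s is not None else 0, e + 1) for s, e in res["locations"]]
    if expect is None:
        return hits[0]
    inner = (lambda h: h[1]) if side == "left" else (lambda h: h[0])
    return min(hits, key=lambda h: abs(inner(h) - expect))


def extract_segment(
    read: "pysam.AlignedSegment",
    locus: StrLocus,
    anchor_window: int = DEFAULT_ANCHOR_WINDOW,
) -> ReadSegment:
    """Extract the read's tract segment for ``locus``.

    The reference alignment provides a coarse projection of the tract
    boundaries into read coordinates; the precise boundaries are then
    refined by locating each reference flank (``anchor_window`` nt adjacent
    to the tract) within the read.  Reads that do not span both flanks, or
    whose flank matches are too diverged, come back ``anchored=False``.
    """
    strand = "reverse" if read.is_reverse else "forward"
    read_seq = (read.query_sequence or "").upper()
    locus_out = lambda anchored, seg="": ReadSegment(
        read_id=read.query_name,
        locus_id=locus.locus_id,
        strand=strand,
        segment=seg,
        mapq=read.mapping_quality,
        anchored=anchored,
    )
    if not read_seq:
        return locus_out(False)
    # read must span the whole anchor window on both sides
    if (
        read.reference_start > max(0, locus.start - anchor_window)
        or read.reference_end < locus.end + anchor_window
    ):
        return locus_out(False)

    # coarse projection: nearest aligned read positions outside the tract
    expect_left = expect_right = None
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos < locus.start:
            expect_left = qpos + 1
        elif rpos >= locus.end and expect_right is None:
            expect_right = qpos
            break

    ref = _reference_flanks(read, locus, anchor_window)
    if ref is None:
        return locus_out(False)
    left_anchor, right_anchor = ref
    lhit = _locate_flank(left_anchor, read_seq, expect_left, "left")
    rhit = _locate_flank(right_anchor, read_seq, expect_right, "right")
    if lhit is None or rhit is None or rhit[0] < lhit[1]:
        return locus_out(False)
    return locus_out(True, read_seq[lhit[1] : rhit[0]])


def _reference_flanks(
    read: "pysam.AlignedSegment", locus: StrLocus, anchor_window: int
) -> Optional[Tuple[str, str]]:
    """Reference sequence of the two anchor windows, via catalog flanks or
    the read's MD-free reference window when flanks are long enough."""
    if locus.flank_window >= anchor_window:
        return (
            locus.left_flank[-anchor_window:],
            locus.right_flank[:anchor_window],
        )
    if locus.left_flank and locus.right_flank:
        return locus.left_flank, locus.right_flank
    return None


def extract_segments(
    alignment_path: str,
    loci: Sequence[StrLocus],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    drop_supplementary: bool = True,
    anchor_window: int = DEFAULT_ANCHOR_WINDOW,
) -> List[ReadSegment]:
    """Load, filter, and extract tract segments for every locus."""
    return [
        extract_segment(read, locus, anchor_window)
        for locus, read in load_reads(
            alignment_path, loci, min_mapq, drop_supplementary, anchor_window
        )
    ]
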