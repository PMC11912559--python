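"""Per-read STR allele correction by Levenshtein minimisation.

Noisy long reads mostly shrink (and occasionally grow) homopolymer and
dinucleotide tracts.  Each read's observed tract sequence is compared
against every candidate allele — the unit repeated n times, for n between 0
and the largest pre-correction repeat count at the locus plus a buffer of 5
— and the allele with the minimum unit-cost edit distance is taken as the
read's corrected allele.  Reads whose minimum distance exceeds a threshold
are considered excessively erroneous and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import edlib
import pandas as pd

DEFAULT_MAX_DISTANCE = 4
DEFAULT_BUFFER = 5


@dataclass(frozen=True)
class AlleleCall:
    """One corrected per-read allele observation (an Allele Table row)."""

    locus_id: str
    read_id: str
    strand: str  # "forward" | "reverse"
    corrected_allele: int
    edit_distance: int
    observed_length_nt: int
    sequenced_unit: str


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b)["editDistance"]


def candidate_alleles(max_observed: int, buffer: int = DEFAULT_BUFFER) -> range:
    """Candidate repeat counts 0..max_observed+buffer (inclusive)."""
    if max_observed < 0:
        raise ValueError("max_observed must be >= 0")
    return range(0, max_observed + buffer + 1)


def correct_read_allele(
    segment: str,
    unit: str,
    candidates: Iterable[int],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> Optional[Tuple[int, int]]:
    """Pick the candidate allele minimising edit distance to ``segment``.

    Returns ``(allele, distance)`` or ``None`` when the minimum distance
    exceeds ``max_distance`` (read discarded).  Ties are broken toward the
    candidate whose tract length is closest to the observed length, then
    toward the smaller allele — deletions dominate long-read tract errors,
    so the shorter interpretation is the likelier one.
    """
    cands = sorted(set(candidates))
    if not cands:
        raise ValueError("candidates must be nonempty")
    ulen = len(unit)
    best: Optional[Tuple[int, int, int]] = None  # (dist, |len diff|, allele)
    for n in cands:
        d = levenshtein(segment, unit * n)
        key = (d, abs(n * ulen - len(segment)), n)
        if best is None or key < best:
            best = key
    assert best is not None
    dist, _, allele = best
    if dist > max_distance:
        return None
    return allele, dist


ALLELE_TABLE_COLUMNS = [
    "locus_id",
    "read_id",
    "strand",
    "corrected_allele",
    "edit_distance",
    "observed_length_nt",
    "sequenced_unit",
]


def build_allele_table(
    segments,
    loci,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    buffer: int = DEFAULT_BUFFER,
) -> pd.DataFrame:
    """Correct every anchored read segment and assemble the Allele Table.

    ``segments`` is an iterable of :class:`~tandemkit.reads.ReadSegment`;
    ``loci`` the catalog (list of StrLocus).  Unanchored segments and reads
    whose best distance exceeds ``max_distance`` are dropped.  The candidate
    lattice upper bound is the locus's largest pre-correction repeat count
    (``floor(len(segment)/len(unit))``) plus ``buffer``.
    """
    from .reads import as_sequenced_unit

    by_locus = {l.locus_id: l for l in loci}
    grouped: dict = {}
    for seg in segments:
        if not seg.anchored:
            continue
        grouped.setdefault(seg.locus_id, []).append(seg)

    rows: List[tuple] = []
    for locus_id, segs in grouped.items():
        locus = by_locus[locus_id]
        ulen = len(locus.unit)
        max_obs = max(len(s.segment) // ulen for s in segs)
        cands = candidate_alleles(max_obs, buffer)
        for seg in segs:
            result = correct_read_allele(
                seg.segment, locus.unit, cands, max_distance
            )
            if result is None:
                continue
            allele, dist = result
            rows.append(
                (
                    locus_id,
                    seg.read_id,
                    seg.strand,
                    allele,
                    dist,
                    len(seg.segment),
                    as_sequenced_unit(locus.unit, seg.strand),
                )
            )
    return pd.DataFrame(rows, columns=ALLELE_TABLE_COLUMNS)
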