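"""Descriptive tract error statistics.

Sequencing accuracy is defined as the percentage of errorless reads: reads
whose extracted tract segment equals the reference tract exactly.  Each
erroneous read is typed by a unit-cost global alignment of its segment
against the reference tract — gaps in the read are deletions, gaps in the
reference insertions, mismatched columns substitutions.  When several
alignments are co-optimal the traceback prefers deletions, matching the
deletion dominance of long-read tract errors.  Accuracy is aggregated per
locus, per (sequenced unit, length) class, and per flanking motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

DELETION = "deletion"
INSERTION = "insertion"
SUBSTITUTION = "substitution"


def classify_read_errors(segment: str, reference_str: str) -> FrozenSet[str]:
    """Error types present in one optimal global alignment of ``segment``
    against the reference tract; empty set means errorless."""
    if segment == reference_str:
        return frozenset()
    n, m = len(segment), len(reference_str)
    # unit-cost global alignment DP; D[i][j] = distance(segment[:i], ref[:j])
    D = np.zeros((n + 1, m + 1), dtype=np.int32)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        si = segment[i - 1]
        row, prev = D[i], D[i - 1]
        for j in range(1, m + 1):
            row[j] = min(
                prev[j - 1] + (si != reference_str[j - 1]),
                prev[j] + 1,
                row[j - 1] + 1,
            )
    types: set = set()
    i, j = n, m
    while i > 0 or j > 0:
        # traceback preference: deletion (gap in segment), insertion, diagonal
        if j > 0 and i >= 0 and D[i, j] == D[i, j - 1] + 1:
            types.add(DELETION)
            j -= 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            types.add(INSERTION)
            i -= 1
        else:
            if segment[i - 1] != reference_str[j - 1]:
                types.add(SUBSTITUTION)
            i -= 1
            j -= 1
    return frozenset(types)


@dataclass(frozen=True)
class ErrorProfileRecord:
    locus_id: str
    n_reads: int
    n_errorless: int
    n_with_deletion: int
    n_with_insertion: int
    n_with_substitution: int

    @property
    def accuracy(self) -> float:
        return self.n_errorless / self.n_reads


def profile_loci(
    segments, catalog, allele_table: Optional[pd.DataFrame] = None
) -> List[ErrorProfileRecord]:
    """Classify every anchored segment against its locus's reference tract.

    When ``allele_table`` is given, only reads retained by correction are
    profiled (the discarded excessively erroneous reads are excluded, as in
    the polished error analyses).
    """
    by_locus = {l.locus_id: l for l in catalog}
    retained = None
    if allele_table is not None:
        retained = set(
            zip(allele_table["locus_id"], allele_table["read_id"])
        )
    tallies: Dict[str, List[int]] = {}
    for seg in segments:
        if not seg.anchored or seg.locus_id not in by_locus:
            continue
        if retained is not None and (seg.locus_id, seg.read_id) not in retained:
            continue
        types = classify_read_errors(seg.segment, by_locus[seg.locus_id].tract)
        t = tallies.setdefault(seg.locus_id, [0, 0, 0, 0, 0])
        t[0] += 1
        t[1] += not types
        t[2] += DELETION in types
        t[3] += INSERTION in types
        t[4] += SUBSTITUTION in types
    return [
        ErrorProfileRecord(lid, *counts) for lid, counts in sorted(tallies.items())
    ]


def profile_frame(records: Sequence[ErrorProfileRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.locus_id,
                r.n_reads,
                r.n_errorless,
                r.n_with_deletion,
                r.n_with_insertion,
                r.n_with_substitution,
                r.accuracy,
            )
            for r in records
        ],
        columns=[
            "locus_id",
            "n_reads",
            "n_errorless",
            "n_with_deletion",
            "n_with_insertion",
            "n_with_substitution",
            "accuracy",
        ],
    )


def locus_accuracy(
    records: Sequence[ErrorProfileRecord],
    catalog,
    sequenced_units: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Mean per-locus accuracy within (unit, ref_repeat_count) classes.

    ``sequenced_units`` optionally maps locus_id to the as-sequenced unit
    (majority over reads) to aggregate by the unit the pore actually read;
    otherwise the reference unit is used.  Per-locus accuracies are averaged
    within each class (classes with zero loci are absent).
    """
    by_locus = {l.locus_id: l for l in catalog}
    rows = []
    for r in records:
        locus = by_locus.get(r.locus_id)
        if locus is None:
            continue
        unit = (
            sequenced_units.get(r.locus_id, locus.unit)
            if sequenced_units
            else locus.unit
        )
        rows.append((unit, locus.ref_repeat_count, r.accuracy))
    frame = pd.DataFrame(rows, columns=["unit", "ref_repeat_count", "accuracy"])
    return (
        frame.groupby(["unit", "ref_repeat_count"])["accuracy"]
        .agg(mean_accuracy="mean", n_loci="size")
        .reset_index()
    )


def motif_accuracy_table(
    records: Sequence[ErrorProfileRecord],
    catalog,
    motif_width: int = 2,
    lengths: Iterable[int] = range(10, 15),
    min_loci_per_length: int = 10,
    unit: str = "A",
) -> pd.DataFrame:
    """Mean accuracy per flanking motif and tract length, for motifs
    consistently represented across lengths.

    A-repeat loci are grouped by their (left, right) ``motif_width``-nt
    tract-adjacent flanking bases.  Only motifs present in more than
    ``min_loci_per_length`` loci at EVERY length in ``lengths`` are kept,
    so a motif's accuracy effect can be compared across lengths.  The
    result is ranked by overall mean accuracy (descending).
    """
    lengths = sorted(set(lengths))
    by_locus = {l.locus_id: l for l in catalog}
    rows = []
    for r in records:
        locus = by_locus.get(r.locus_id)
        if locus is None or locus.unit != unit:
            continue
        if locus.ref_repeat_count not in lengths:
            continue
        motif = (
            locus.left_flank[-motif_width:],
            locus.right_flank[:motif_width],
        )
        rows.append(
            ("/".join(motif), locus.ref_repeat_count, r.accuracy)
        )
    frame = pd.DataFrame(rows, columns=["motif", "length", "accuracy"])
    if frame.empty:
        return pd.DataFrame(
            columns=["motif", "length", "mean_accuracy", "n_loci"]
        )
    counts = frame.groupby(["motif", "length"]).size().unstack(fill_value=0)
    qualifying = [
        m
        for m in counts.index
        if all(
            length in counts.columns and counts.loc[m, length] > min_loci_per_length
            for length in lengths
        )
    ]
    sub = frame[frame["motif"].isin(qualifying)]
    table = (
        sub.groupby(["motif", "length"])["accuracy"]
        .agg(mean_accuracy="mean", n_loci="size")
        .reset_index()
    )
    order = (
        sub.groupby("motif")["accuracy"].mean().sort_values(ascending=False).index
    )
    table["motif"] = pd.Categorical(table["motif"], categories=order, ordered=True)
    return table.sort_values(["motif", "length"]).reset_index(drop=True)
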