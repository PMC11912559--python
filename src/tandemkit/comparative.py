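"""Paired-sample informative-locus scoring and MSI summarisation.

Microsatellite instability (MSI) manifests as net contractions of
mononucleotide repeats.  Two complementary analyses are provided: (i) with
a matched normal, each commonly covered locus is scored by
``distance(H_n, H_t) x prominence(H_n)`` — a large histogram shift at a
locus whose normal histogram has a confident peak is informative; (ii)
without a matched normal, the per-locus relative allele size
``sum_i (A_i - R_i) f_i`` (frequency-weighted mean signed shift from the
reference allele R_i, in repeat units) is summarised across loci, after
the homopolymer locus-selection filters: A-repeats of reference length
10–14, minimum coverage, cohort-coverage support, no guanine adjacent to
the tract, and a mid-prominence exclusion band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotyping import (
    AlleleHistogram,
    build_histogram,
    histogram_distance,
    peak_prominence,
)

MSI_MIN_COVERAGE = 30
MSI_REPEAT_RANGE = (10, 14)
OVERLAP_GRID_STEP = 0.25


@dataclass(frozen=True)
class LocusComparison:
    locus_id: str
    distance: float
    prominence_n: float

    @property
    def score(self) -> float:
        return self.distance * self.prominence_n


@dataclass(frozen=True)
class CohortStats:
    """Mean and standard deviation of peak prominences in one sample."""

    mu: float
    sigma: float

    @classmethod
    def from_prominences(cls, prominences: Sequence[float]) -> "CohortStats":
        arr = np.asarray(list(prominences), dtype=float)
        return cls(mu=float(arr.mean()), sigma=float(arr.std(ddof=0)))


def find_common_loci(
    table_n: pd.DataFrame, table_t: pd.DataFrame
) -> List[str]:
    """Locus ids genotyped in both samples (commonly covered loci)."""
    common = set(table_n["locus_id"]) & set(table_t["locus_id"])
    return sorted(common)


def score_locus(
    hist_n: AlleleHistogram, hist_t: AlleleHistogram, locus_id: str = ""
) -> LocusComparison:
    """Informative-locus score: histogram distance times normal prominence."""
    return LocusComparison(
        locus_id=locus_id,
        distance=histogram_distance(hist_n, hist_t),
        prominence_n=peak_prominence(hist_n),
    )


def informative_loci(
    allele_table_n: pd.DataFrame,
    allele_table_t: pd.DataFrame,
    strand_mode: str = "all",
) -> pd.DataFrame:
    """Score every commonly covered locus, ranked by descending score."""
    rows = []
    groups_n = dict(tuple(allele_table_n.groupby("locus_id")))
    groups_t = dict(tuple(allele_table_t.groupby("locus_id")))
    for locus_id in sorted(set(groups_n) & set(groups_t)):
        try:
            hn = build_histogram(groups_n[locus_id], strand_mode)
            ht = build_histogram(groups_t[locus_id], strand_mode)
        except ValueError:
            continue
        cmp_ = score_locus(hn, ht, locus_id)
        rows.append(
            (locus_id, cmp_.distance, cmp_.prominence_n, cmp_.score)
        )
    frame = pd.DataFrame(
        rows, columns=["locus_id", "distance", "prominence_n", "score"]
    )
    return frame.sort_values(
        ["score", "locus_id"], ascending=[False, True]
    ).reset_index(drop=True)


def relative_allele_size(hist: AlleleHistogram, ref_allele: int) -> float:
    """Frequency-weighted mean signed shift from the reference allele."""
    return float(
        sum((a - ref_allele) * f for a, f in hist.normalized.items())
    )


def _g_adjacent(locus) -> bool:
    """True when a guanine sits immediately next to the tract on either side."""
    left = locus.left_flank[-1:] if locus.left_flank else ""
    right = locus.right_flank[:1] if locus.right_flank else ""
    return left == "G" or right == "G"


def msi_locus_filter(
    locus_table: pd.DataFrame,
    catalog,
    cohort: Optional[Sequence[pd.DataFrame]] = None,
    min_coverage: int = MSI_MIN_COVERAGE,
    min_samples_covered: int = 0,
    exclude_g_adjacent: bool = True,
    prominence_band: bool = True,
    invert_band: bool = False,
    repeat_range: Tuple[int, int] = MSI_REPEAT_RANGE,
) -> List[str]:
    """Locus ids passing the MSI locus-selection rules for one sample.

    Keeps A-repeat loci with reference repeat count in ``repeat_range`` and
    coverage >= ``min_coverage``; drops loci genotyped in fewer than
    ``min_samples_covered`` cohort samples, loci with a tract-adjacent
    guanine, and — when ``prominence_band`` — loci whose peak prominence
    falls inside [mu - sigma/2, mu + sigma/2] of the sample's prominence
    distribution (``invert_band`` keeps only that band instead).
    """
    by_locus = {l.locus_id: l for l in catalog}
    lo, hi = repeat_range
    cohort_counts: Dict[str, int] = {}
    if cohort is not None:
        for tab in cohort:
            for lid in set(tab["locus_id"]):
                cohort_counts[lid] = cohort_counts.get(lid, 0) + 1

    table = locus_table
    band_stats = CohortStats.from_prominences(table["peak_prominence"])
    kept: List[str] = []
    for row in table.itertuples(index=False):
        locus = by_locus.get(row.locus_id)
        if locus is None or locus.unit != "A":
            continue
        if not lo <= locus.ref_repeat_count <= hi:
            continue
        if row.coverage_used < min_coverage:
            continue
        if (
            min_samples_covered
            and cohort_counts.get(row.locus_id, 0) < min_samples_covered
        ):
            continue
        if exclude_g_adjacent and _g_adjacent(locus):
            continue
        if prominence_band:
            in_band = (
                band_stats.mu - band_stats.sigma / 2
                <= row.peak_prominence
                <= band_stats.mu + band_stats.sigma / 2
            )
            if in_band != invert_band:
                continue
        kept.append(row.locus_id)
    return kept


def relative_allele_sizes(
    allele_table: pd.DataFrame,
    catalog,
    locus_ids: Iterable[str],
    strand_mode: str = "all",
) -> pd.DataFrame:
    """Per-locus relative allele size for the selected loci of one sample."""
    by_locus = {l.locus_id: l for l in catalog}
    groups = dict(tuple(allele_table.groupby("locus_id")))
    rows = []
    for lid in sorted(set(locus_ids)):
        if lid not in groups or lid not in by_locus:
            continue
        try:
            hist = build_histogram(groups[lid], strand_mode)
        except ValueError:
            continue
        rows.append(
            (
                lid,
                relative_allele_size(hist, by_locus[lid].ref_repeat_count),
            )
        )
    return pd.DataFrame(rows, columns=["locus_id", "relative_allele_size"])


def distribution_overlap(
    values_a: Sequence[float],
    values_b: Sequence[float],
    step: float = OVERLAP_GRID_STEP,
) -> float:
    """Shared area of two relative-allele-size distributions.

    Both samples are binned on a common fixed grid of width ``step`` repeat
    units; the overlap is ``sum_bin min(p_a, p_b)`` of the normalised
    histograms — 1 for identical distributions, 0 for disjoint ones.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples need at least one value")
    lo = np.floor(min(a.min(), b.min()) / step) * step
    hi = np.ceil(max(a.max(), b.max()) / step) * step + step
    edges = np.arange(lo, hi + step / 2, step)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(
        np.minimum(pa / pa.sum(), pb / pb.sum()).sum()
    )


def msi_summary(
    samples: Mapping[str, Tuple[pd.DataFrame, pd.DataFrame]],
    catalog,
    strand_mode: str = "all",
    min_coverage: int = MSI_MIN_COVERAGE,
    min_samples_covered: int = 0,
    exclude_g_adjacent: bool = True,
    prominence_band: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cross-sample MSI summary.

    ``samples`` maps sample name to its (allele table, locus table) pair.
    Returns (per-locus relative sizes, per-sample summary stats, pairwise
    distribution-overlap matrix).
    """
    if not samples:
        raise ValueError("at least one sample required")
    cohort = [loc for _, loc in samples.values()]
    per_locus_frames = []
    per_sample_rows = []
    sizes_by_sample: Dict[str, np.ndarray] = {}
    for name, (allele_tab, locus_tab) in samples.items():
        kept = msi_locus_filter(
            locus_tab,
            catalog,
            cohort=cohort if min_samples_covered else None,
            min_coverage=min_coverage,
            min_samples_covered=min_samples_covered,
            exclude_g_adjacent=exclude_g_adjacent,
            prominence_band=prominence_band,
        )
        if not kept:
            raise ValueError(f"sample {name}: no loci survive the MSI filters")
        sizes = relative_allele_sizes(allele_tab, catalog, kept, strand_mode)
        sizes.insert(0, "sample", name)
        per_locus_frames.append(sizes)
        vals = sizes["relative_allele_size"].to_numpy()
        sizes_by_sample[name] = vals
        per_sample_rows.append(
            (name, len(vals), float(np.mean(vals)), float(np.median(vals)))
        )
    per_locus = pd.concat(per_locus_frames, ignore_index=True)
    per_sample = pd.DataFrame(
        per_sample_rows, columns=["sample", "n_loci", "mean", "median"]
    )
    names = list(samples)
    overlap = pd.DataFrame(
        [
            [
                distribution_overlap(sizes_by_sample[a], sizes_by_sample[b])
                for b in names
            ]
            for a in names
        ],
        index=names,
        columns=names,
    )
    return per_locus, per_sample, overlap
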