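"""Scoring of spin-system grouping against ground truth.

For simulated (or assigned) peak lists every peak carries a true
spin-system id, so a grouping can be audited system by system:

* **identified** — a cluster contains exactly the peaks of one true system;
* **partial** — a cluster is a strict subset of one system's peaks;
* **overlapped** — all of a system's clustered peaks sit in a single
  cluster that also contains another system's peaks;
* **split** — a system's peaks are distributed over two or more clusters
  (absorbed into neighboring spin systems);
* **missing** — none of a system's peaks were grouped.

Every groupable true system (at least two observed peaks) falls in exactly
one category; singleton systems are reported separately as
expected-ungrouped rather than missing.  Peak-level percentages
are reported with two denominators: all truth-labeled peaks, and only
"groupable" peaks (those of systems with at least two peaks — a glycine's
lone CA peak in an HN(CO)CACB list can never form a ``min_points = 2``
cluster, and the headline benchmark percentages use this
denominator, since such singletons can never satisfy the cluster minimum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grouping import GroupingResult
from .peaklist import PeakList
from .pipeline import PipelineResult
from .spectra import SpectrumDescription, builtin_description

__all__ = ["EvaluationReport", "expected_counts", "score_grouping", "aggregate_curve"]


@dataclass
class EvaluationReport:
    observed_peaks: int
    ungrouped_peaks: int
    expected_spin_systems: int  # groupable systems (>= 2 observed peaks)
    singleton_systems: int
    identified: int
    missing: int
    overlapped: int
    split: int
    partial: int
    pct_grouped: float
    pct_overlapped: float
    pct_grouped_groupable: float
    pct_overlapped_groupable: float

    def category_total(self) -> int:
        return self.identified + self.missing + self.overlapped + self.split + self.partial


def expected_counts(
    sequence: str,
    spectrum_type: str | SpectrumDescription = "HNcoCACB",
    exact: bool = False,
) -> tuple[int, int]:
    """Expected peak and spin-system counts for a protein sequence.

    With ``exact=False`` (HN(CO)CACB only) the closed-form estimates are
    used: peaks = (L − nPro − nGly)·2 + nGly − 1 and systems =
    L − 1 − nGly − nPro; degenerate sequences are floored at 0 with a
    warning.  With ``exact=True`` the generation rule is enumerated for any
    spectrum description (an atom is available unless it is glycine's CB or
    proline's amide H), and "systems" counts anchors with at least two
    peaks, i.e. systems that can form a cluster.
    """
    seq = sequence.upper()
    spec = (
        spectrum_type
        if isinstance(spectrum_type, SpectrumDescription)
        else builtin_description(spectrum_type)
    )
    if not exact:
        if spec.name != "HNcoCACB":
            raise ValueError(
                "closed-form expected counts are defined for HN(CO)CACB; "
                "use exact=True for other spectrum types"
            )
        L = len(seq)
        n_pro = seq.count("P")
        n_gly = seq.count("G")
        peaks = (L - n_pro - n_gly) * 2 + n_gly - 1
        systems = L - 1 - n_gly - n_pro
        if peaks < 0 or systems < 0:
            warnings.warn(
                f"expected-count formula degenerate for sequence of length {L} "
                f"({n_pro} Pro, {n_gly} Gly); flooring at 0",
                stacklevel=2,
            )
        return max(peaks, 0), max(systems, 0)

    def has(pos: int, atom: str) -> bool:
        if pos < 0 or pos >= len(seq):
            return False
        aa = seq[pos]
        if atom == "CB" and aa == "G":
            return False
        if atom == "H" and aa == "P":
            return False
        return True

    peaks = 0
    systems = 0
    for anchor in range(len(seq)):
        per_anchor = set()
        for pattern in spec.peak_patterns():
            if all(has(anchor + alt.relative_position, alt.resonance_class) for alt in pattern):
                per_anchor.add(
                    tuple((alt.resonance_class, alt.relative_position) for alt in pattern)
                )
        peaks += len(per_anchor)
        if len(per_anchor) >= 2:
            systems += 1
    return peaks, systems


def score_grouping(
    result: GroupingResult | PipelineResult,
    truth: PeakList | Sequence[int | None],
) -> EvaluationReport:
    """Score a grouping (or full pipeline) result against true spin-system
    labels (a :class:`PeakList` whose peaks carry ``truth_group``, or a
    per-peak label sequence)."""
    if isinstance(result, PipelineResult):
        result = result.as_grouping_result()
    labels = truth.truth_groups() if isinstance(truth, PeakList) else list(truth)
    labeled = {i for i, g in enumerate(labels) if g is not None}
    if not labeled:
        raise ValueError(
            "no truth_group labels present; evaluation needs simulated or "
            "assigned peak lists"
        )

    systems: dict[int, set[int]] = {}
    for i in labeled:
        systems.setdefault(labels[i], set()).add(i)
    groupable = {g for g, peaks in systems.items() if len(peaks) >= 2}

    cluster_sets = [set(c.member_indices) for c in result.clusters]
    cluster_of: dict[int, int] = {}
    for ci, members in enumerate(cluster_sets):
        for i in members:
            cluster_of[i] = ci
    mixed_clusters = {
        ci
        for ci, members in enumerate(cluster_sets)
        if len({labels[i] for i in members & labeled}) >= 2
    }

    identified = missing = overlapped = split = partial = 0
    identified_peaks: set[int] = set()
    for g in groupable:  # singleton systems are expected-ungrouped, not missing
        peaks = systems[g]
        clusters_of_g = {cluster_of[i] for i in peaks if i in cluster_of}
        if not clusters_of_g:
            missing += 1
        elif len(clusters_of_g) >= 2:
            split += 1
        else:
            (ci,) = clusters_of_g
            members = cluster_sets[ci]
            if members == peaks:
                identified += 1
                identified_peaks |= peaks
            elif members < peaks:
                partial += 1
            else:
                overlapped += 1

    overlapped_peaks = {
        i for ci in mixed_clusters for i in cluster_sets[ci] & labeled
    }
    groupable_peaks = {i for i in labeled if labels[i] in groupable}
    ungrouped = labeled - set(cluster_of)

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    return EvaluationReport(
        observed_peaks=len(labeled),
        ungrouped_peaks=len(ungrouped),
        expected_spin_systems=len(groupable),
        singleton_systems=len(systems) - len(groupable),
        identified=identified,
        missing=missing,
        overlapped=overlapped,
        split=split,
        partial=partial,
        pct_grouped=pct(len(identified_peaks), len(labeled)),
        pct_overlapped=pct(len(overlapped_peaks), len(labeled)),
        pct_grouped_groupable=pct(
            len(identified_peaks & groupable_peaks), len(groupable_peaks)
        ),
        pct_overlapped_groupable=pct(
            len(overlapped_peaks & groupable_peaks), len(groupable_peaks)
        ),
    )


def aggregate_curve(
    reports_by_sigma: Mapping[float, Sequence[EvaluationReport]],
    groupable: bool = True,
) -> pd.DataFrame:
    """Mean and standard error of the grouped/overlapped percentages at each
    noise level, across peak lists (SEM = sample std / sqrt(n); a single
    list per level yields SEM 0 with ``sem_defined`` False)."""
    rows = []
    for sigma in sorted(reports_by_sigma):
        reports = list(reports_by_sigma[sigma])
        if not reports:
            continue
        if groupable:
            g = np.array([r.pct_grouped_groupable for r in reports])
            o = np.array([r.pct_overlapped_groupable for r in reports])
        else:
            g = np.array([r.pct_grouped for r in reports])
            o = np.array([r.pct_overlapped for r in reports])
        n = len(reports)
        sem = lambda x: float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "sigma": sigma,
                "n_lists": n,
                "mean_pct_grouped": float(g.mean()),
                "sem_pct_grouped": sem(g),
                "mean_pct_overlapped": float(o.mean()),
                "sem_pct_overlapped": sem(o),
                "sem_defined": n > 1,
            }
        )
    return pd.DataFrame(rows)
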