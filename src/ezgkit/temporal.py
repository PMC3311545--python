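"""Presence/absence classification over the four time bins and EZG calls.

A transcript is "present" in a bin when it has at least one read hit.
Transcripts present at 0-2 hr are maternal; candidate early zygotic
transcripts are absent at 0-2 hr and present at 2-4 hr; the remaining
transcripts are grouped by the bin of first presence.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .mars import MarsResult
from .quantify import BIN_LABELS, TimeCourseCounts

MATERNAL = "maternal"
CANDIDATE_2_4 = "candidate_2_4"
FIRST_4_8 = "first_4_8"
FIRST_8_12 = "first_8_12"
ABSENT = "absent"

CLASS_LABELS = (MATERNAL, CANDIDATE_2_4, FIRST_4_8, FIRST_8_12, ABSENT)

#: First-presence groups and the bin where their transcripts first appear.
GROUP_BINS = {"2-4": 1, "4-8": 2, "8-12": 3}


class TemporalError(ValueError):
    """Raised for invalid classification inputs."""


def classify_transcript(counts_row: Sequence[int]) -> str:
    """Label one transcript from its four bin counts (presence = count >= 1)."""
    if len(counts_row) != 4:
        raise TemporalError(
            f"expected 4 bin counts, got {len(counts_row)}"
        )
    b1, b2, b3, b4 = (int(c) for c in counts_row)
    if min(b1, b2, b3, b4) < 0:
        raise TemporalError("counts must be non-negative")
    if b1 >= 1:
        return MATERNAL
    if b2 >= 1:
        return CANDIDATE_2_4
    if b3 >= 1:
        return FIRST_4_8
    if b4 >= 1:
        return FIRST_8_12
    return ABSENT


def classify_all(counts: TimeCourseCounts) -> dict[str, str]:
    """Classify every transcript in the matrix."""
    return {
        tid: classify_transcript(counts.counts[i])
        for i, tid in enumerate(counts.transcript_ids)
    }


@dataclass
class EzgCallSet:
    """Candidate transcripts and the significant subsets per threshold."""

    candidates: set[str]
    significant: dict[float, set[str]]

    def counts(self) -> dict[str, int]:
        out = {"candidates": len(self.candidates)}
        for thr in sorted(self.significant):
            out[f"p<{thr}"] = len(self.significant[thr])
        return out


def call_ezgs(
    counts: TimeCourseCounts,
    mars_results: Sequence[MarsResult],
    thresholds: Sequence[float] = (0.001, 0.05),
) -> EzgCallSet:
    """Intersect the 2-4 hr presence filter with test significance.

    ``mars_results`` must come from the (0-2, 2-4) bin pair, with the
    earlier bin as library 1. A significant increase at 2-4 hr then means
    p < threshold together with m below its null conditional expectation
    (the later library drew relatively more reads).
    """
    thresholds = sorted(thresholds)
    by_id = {r.transcript_id: r for r in mars_results}
    if set(by_id) != set(counts.transcript_ids):
        raise TemporalError(
            "mars results and count matrix cover different transcripts"
        )
    labels = classify_all(counts)
    candidates = {t for t, lab in labels.items() if lab == CANDIDATE_2_4}
    significant: dict[float, set[str]] = {}
    for thr in thresholds:
        significant[thr] = {
            t
            for t in candidates
            if by_id[t].p_value < thr and by_id[t].delta < 0
        }
    return EzgCallSet(candidates=candidates, significant=significant)


def group_by_first_presence(
    counts: TimeCourseCounts,
    mars_results_by_pair: Mapping[str, Sequence[MarsResult]],
    threshold: float = 0.001,
) -> dict[str, set[str]]:
    """Disjoint 2-4 / 4-8 / 8-12 hr groups of first-presence transcripts.

    ``mars_results_by_pair`` maps the group label to results computed on
    (preceding bin, first-presence bin). Membership requires the presence
    filter (first hit in the group's bin) plus p < threshold with an
    increase in the later bin.
    """
    labels = classify_all(counts)
    label_for_group = {
        "2-4": CANDIDATE_2_4,
        "4-8": FIRST_4_8,
        "8-12": FIRST_8_12,
    }
    groups: dict[str, set[str]] = {}
    for group, want in label_for_group.items():
        if group not in mars_results_by_pair:
            raise TemporalError(f"missing mars results for group {group}")
        by_id = {r.transcript_id: r for r in mars_results_by_pair[group]}
        members = set()
        for tid, lab in labels.items():
            if lab != want:
                continue
            if tid not in by_id:
                raise TemporalError(
                    f"no mars result for transcript {tid} in group {group}"
                )
            r = by_id[tid]
            if r.p_value < threshold and r.delta < 0:
                members.add(tid)
        groups[group] = members
    return groups


def default_group_pairs() -> dict[str, tuple[str, str]]:
    """Adjacent-preceding-bin comparison pairs for each group."""
    return {
        group: (BIN_LABELS[idx - 1], BIN_LABELS[idx])
        for group, idx in GROUP_BINS.items()
    }


def collapse_to_genes(
    transcript_ids: Sequence[str], transcript_to_gene: Mapping[str, str]
) -> dict[str, str]:
    """Map a transcript set to genes, first-listed transcript as representative."""
    genes: dict[str, str] = {}
    for tid in transcript_ids:
        try:
            gene = transcript_to_gene[tid]
        except KeyError:
            raise TemporalError(f"transcript {tid} has no gene mapping")
        genes.setdefault(gene, tid)
    return genes


def classification_frame(
    counts: TimeCourseCounts,
    mars_results: Sequence[MarsResult],
    thresholds: Sequence[float] = (0.001, 0.05),
) -> pd.DataFrame:
    """Per-transcript class, p-value and threshold membership table."""
    calls = call_ezgs(counts, mars_results, thresholds)
    labels = classify_all(counts)
    by_id = {r.transcript_id: r for r in mars_results}
    rows = []
    for tid in counts.transcript_ids:
        row = {
            "transcript_id": tid,
            "class": labels[tid],
            "p_value": by_id[tid].p_value,
        }
        for thr in sorted(thresholds):
            row[f"ezg_p<{thr}"] = tid in calls.significant[thr]
        rows.append(row)
    return pd.DataFrame(rows)
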