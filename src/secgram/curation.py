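"""Dataset curation: shared-label resolution, length/ambiguity filtering,
duplicate and substring collapse, and low-complexity (DUST) removal.

The four steps run in a fixed order — shared labels, then length/N, then
duplicates+substrings, then DUST — and each step's attrition is recorded so
dataset shrinkage is auditable. A sequence observed in both the EC and IC
compartments is kept as EC: exported small RNAs necessarily also exist
intracellularly, so an EC observation dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import SmallRNARecord

MIN_LEN = 18
MAX_LEN = 50
DUST_THRESHOLD = 2.0
DUST_WINDOW = 64


@dataclass
class CurationReport:
    """Ordered per-step attrition: (step, n_in, n_removed, n_out)."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"step {name}: output {n_out} exceeds input {n_in}")
        if self.steps and self.steps[-1][3] != n_in:
            raise ValueError(f"step {name}: input {n_in} != previous output {self.steps[-1][3]}")
        self.steps.append((name, n_in, n_in - n_out, n_out))

    def as_rows(self) -> list[tuple[str, int, int, int]]:
        return list(self.steps)


def resolve_shared_labels(records: Sequence[SmallRNARecord]) -> list[SmallRNARecord]:
    """Keep one EC copy of any sequence seen under both labels; drop the IC copy."""
    ec_seqs = {r.sequence for r in records if r.label == "EC"}
    out: list[SmallRNARecord] = []
    seen_ec: set[str] = set()
    n_unlabeled = 0
    for r in records:
        if r.label == "IC" and r.sequence in ec_seqs:
            continue
        if r.label == "EC":
            if r.sequence in seen_ec:
                out.append(r)  # exact EC duplicates fall to the dedup step
            else:
                seen_ec.add(r.sequence)
                out.append(r)
        else:
            if r.label == "unlabeled":
                n_unlabeled += 1
            out.append(r)
    if n_unlabeled:
        warnings.warn(f"{n_unlabeled} unlabeled records passed through untouched", stacklevel=2)
    return out


def filter_length_ambiguity(
    records: Sequence[SmallRNARecord], min_len: int = MIN_LEN, max_len: int = MAX_LEN
) -> list[SmallRNARecord]:
    """Retain records with min_len <= len <= max_len (inclusive) and no N."""
    return [
        r
        for r in records
        if min_len <= len(r.sequence) <= max_len and "N" not in r.sequence
    ]


def collapse_duplicates_substrings(records: Sequence[SmallRNARecord]) -> list[SmallRNARecord]:
    """Collapse exact duplicates and drop sequences contained in a longer one.

    Label-blind (label conflicts were already resolved). Duplicates keep the
    lexicographically smallest id for determinism; containment keeps the longer
    sequence.
    """
    # dedup: keep smallest id per sequence, preserve first-occurrence order
    best: dict[str, SmallRNARecord] = {}
    order: list[str] = []
    for r in records:
        cur = best.get(r.sequence)
        if cur is None:
            best[r.sequence] = r
            order.append(r.sequence)
        elif r.id < cur.id:
            best[r.sequence] = r
    unique = [best[s] for s in order]

    # substring removal: a sequence dies if it occurs inside any longer
    # sequence. Equal lengths cannot contain each other after dedup, so
    # process length groups longest-first and scan each candidate against a
    # single '#'-joined haystack of everything longer (C-speed substring
    # search instead of a quadratic pairwise loop).
    by_len: dict[int, list[SmallRNARecord]] = {}
    for r in unique:
        by_len.setdefault(len(r.sequence), []).append(r)
    kept_ids: set[str] = set()
    haystack_parts: list[str] = []
    haystack = ""
    for L in sorted(by_len, reverse=True):
        for r in by_len[L]:
            if not haystack or r.sequence not in haystack:
                kept_ids.add(r.id)
        survivors = [r.sequence for r in by_len[L] if r.id in kept_ids]
        if survivors:
            haystack_parts.append("#".join(survivors))
            haystack = "#".join(haystack_parts)
    return [r for r in unique if r.id in kept_ids]


def dust_score(sequence: str, window: int = DUST_WINDOW) -> float:
    """Triplet-repetition statistic: sum c_t(c_t - 1)/2 over triplet counts,
    normalized by (w - 2), maximized over windows of length min(len, window)."""
    n = len(sequence)
    if n < 3:
        return 0.0
    w = min(n, window)
    best = 0.0
    for start in range(0, n - w + 1):
        chunk = sequence[start : start + w]
        counts: dict[str, int] = {}
        for i in range(len(chunk) - 2):
            t = chunk[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        score = sum(c * (c - 1) / 2 for c in counts.values()) / (w - 2)
        best = max(best, score)
    return best


def mask_low_complexity(
    records: Sequence[SmallRNARecord], dust_threshold: float = DUST_THRESHOLD
) -> list[SmallRNARecord]:
    """Remove records whose DUST score exceeds the threshold."""
    if dust_threshold <= 0:
        raise ValueError("dust_threshold must be positive")
    return [r for r in records if dust_score(r.sequence) <= dust_threshold]


def curate(
    records: Sequence[SmallRNARecord],
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    dust_threshold: float = DUST_THRESHOLD,
) -> tuple[list[SmallRNARecord], CurationReport]:
    """Run the four curation steps in order and report per-step attrition."""
    report = CurationReport()
    cur = list(records)

    n = len(cur)
    cur = resolve_shared_labels(cur)
    report.add("shared_labels", n, len(cur))

    n = len(cur)
    cur = filter_length_ambiguity(cur, min_len, max_len)
    report.add("length_ambiguity", n, len(cur))

    n = len(cur)
    cur = collapse_duplicates_substrings(cur)
    report.add("duplicates_substrings", n, len(cur))

    n = len(cur)
    cur = mask_low_complexity(cur, dust_threshold)
    report.add("dust", n, len(cur))

    return cur, report


__all__ = [
    "CurationReport",
    "resolve_shared_labels",
    "filter_length_ambiguity",
    "collapse_duplicates_substrings",
    "dust_score",
    "mask_low_complexity",
    "curate",
]
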