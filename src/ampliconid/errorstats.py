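"""Reference-based per-base error rates and variant spectra.

Given dereplicated reads from a single-template run and the known reference
target, this module estimates the per-base error rate two ways and
classifies each sequence variant's edits.

``error_rate_simple`` is the field arithmetic for quick run QC:
(erroneous reads) / (reads × mean length), i.e. it charges one error per
erroneous read. ``error_rate_edit`` is the exact alternative: total edit
distance over total sequenced bases. The two agree exactly when every
erroneous read carries a single error.

Indel classification is template-relative: an inserted or deleted base is a
homopolymer artifact iff it matches an adjacent reference base that sits in
a run of length >= 2 — the signature over/under-call of flow-based
(pyrosequencing) chemistry, e.g. a 5-adenosine stretch read as 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import edlib

from .readpipe import CollapsedSequence

__all__ = [
    "ErrorSummary",
    "VariantRecord",
    "identical_fraction",
    "error_rate_simple",
    "error_rate_edit",
    "variant_spectrum",
    "summarize_errors",
]


@dataclass(frozen=True)
class VariantRecord:
    """One erroneous collapsed sequence and the classification of its edits.

    ``events`` holds one label per edit operation: ``homopolymer_indel``,
    ``other_indel`` or ``substitution``.
    """

    sequence: str
    count: int
    distance: int
    events: tuple[str, ...]

    @property
    def all_homopolymer(self) -> bool:
        return bool(self.events) and all(e == "homopolymer_indel" for e in self.events)


@dataclass
class ErrorSummary:
    n_reads: int
    n_identical: int
    fraction_identical: float
    mean_read_length: float
    error_rate_simple: float
    error_rate_edit: float
    n_variants: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _counts(collapsed: Sequence[CollapsedSequence]) -> int:
    return sum(c.count for c in collapsed)


def identical_fraction(
    collapsed: Sequence[CollapsedSequence], reference: str
) -> float:
    """Fraction of reads byte-identical to the reference sequence."""
    if not reference:
        raise ValueError("empty reference")
    total = _counts(collapsed)
    if total == 0:
        raise ValueError("no reads")
    identical = sum(c.count for c in collapsed if c.sequence == reference)
    return identical / total


def error_rate_simple(n_reads: int, n_identical: int, mean_length: float) -> float:
    """Per-base error rate charging one error per erroneous read.

    rate = (n_reads - n_identical) / (n_reads * mean_length). Report to
    2 significant figures for run summaries; full precision is returned.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if n_identical > n_reads:
        raise ValueError("n_identical exceeds n_reads")
    if mean_length <= 0:
        raise ValueError("mean_length must be positive")
    return (n_reads - n_identical) / (n_reads * mean_length)


def error_rate_edit(
    collapsed: Sequence[CollapsedSequence], reference: str
) -> float:
    """Exact per-base error rate: total edit distance / total bases."""
    if not reference:
        raise ValueError("empty reference")
    total_bases = 0
    total_errors = 0
    for c in collapsed:
        total_bases += c.count * len(c.sequence)
        if c.sequence != reference:
            d = edlib.align(c.sequence, reference, mode="NW", task="distance")[
                "editDistance"
            ]
            total_errors += c.count * d
    if total_bases == 0:
        raise ValueError("no bases")
    return total_errors / total_bases


def _run_lengths(reference: str) -> list[int]:
    """Per-position length of the maximal homopolymer run covering it."""
    n = len(reference)
    out = [1] * n
    i = 0
    while i < n:
        j = i + 1
        while j < n and reference[j] == reference[i]:
            j += 1
        for k in range(i, j):
            out[k] = j - i
        i = j
    return out


def _classify_events(variant: str, reference: str) -> tuple[int, tuple[str, ...]]:
    """Edit distance and per-op classification of variant vs reference.

    Uses the optimal global alignment; each aligned column that is not a
    match yields one event. Indels are homopolymer artifacts when the
    affected base equals an adjacent reference base inside a run >= 2.
    """
    res = edlib.align(variant, reference, mode="NW", task="path")
    aln = edlib.getNiceAlignment(res, variant, reference)
    q, t = aln["query_aligned"], aln["target_aligned"]
    runlen = _run_lengths(reference)
    events: list[str] = []
    ref_pos = 0  # next reference position
    for qc, tc in zip(q, t):
        if tc == "-":
            # insertion of qc between ref_pos-1 and ref_pos
            neighbours = []
            if ref_pos > 0:
                neighbours.append((reference[ref_pos - 1], runlen[ref_pos - 1]))
            if ref_pos < len(reference):
                neighbours.append((reference[ref_pos], runlen[ref_pos]))
            homo = any(base == qc and rl >= 2 for base, rl in neighbours)
            events.append("homopolymer_indel" if homo else "other_indel")
        elif qc == "-":
            homo = runlen[ref_pos] >= 2
            events.append("homopolymer_indel" if homo else "other_indel")
            ref_pos += 1
        else:
            if qc != tc:
                events.append("substitution")
            ref_pos += 1
    return res["editDistance"], tuple(events)


def variant_spectrum(
    collapsed: Sequence[CollapsedSequence], reference: str
) -> tuple[list[VariantRecord], float | None]:
    """Classify every erroneous collapsed sequence against the reference.

    Returns the variant records (input order) and the homopolymer share:
    the fraction of erroneous reads whose edits are exclusively homopolymer
    indels, or None when there are no erroneous reads.
    """
    if not reference:
        raise ValueError("empty reference")
    records: list[VariantRecord] = []
    for c in collapsed:
        if c.sequence == reference:
            continue
        distance, events = _classify_events(c.sequence, reference)
        records.append(VariantRecord(c.sequence, c.count, distance, events))
    erroneous = sum(r.count for r in records)
    if erroneous == 0:
        return records, None
    homo = sum(r.count for r in records if r.all_homopolymer)
    return records, homo / erroneous


def summarize_errors(
    collapsed: Sequence[CollapsedSequence], reference: str
) -> ErrorSummary:
    """Full error summary for one single-template run.

    Mean read length is the count-weighted mean over the collapsed
    sequences (the trimmed targets).
    """
    total = _counts(collapsed)
    if total == 0:
        raise ValueError("no reads")
    frac = identical_fraction(collapsed, reference)
    n_identical = round(frac * total)
    mean_len = sum(c.count * len(c.sequence) for c in collapsed) / total
    return ErrorSummary(
        n_reads=total,
        n_identical=n_identical,
        fraction_identical=frac,
        mean_read_length=mean_len,
        error_rate_simple=error_rate_simple(total, n_identical, mean_len),
        error_rate_edit=error_rate_edit(collapsed, reference),
        n_variants=sum(1 for c in collapsed if c.sequence != reference),
    )
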