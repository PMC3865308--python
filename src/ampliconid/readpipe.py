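"""Sample-to-answer pipeline for mixed-species amplicon reads.

Stages, in order: mean-quality filter → barcode demultiplexing (with
re-orientation) → primer trimming → dereplication (collapsing identical
targets) → minimum-read-count filter → species assignment against a local
reference database → per-sample mixture report.

The minimum-count filter (default: keep sequences supported by >= 20
identical reads) is what suppresses sequencing-error variants, so that
every surviving sequence represents a real template in the sample. Species
assignment is exact-match first, then nearest edit distance against the
reference database; several species tying at the minimal distance yield an
ambiguous call reported under a common group label (e.g. two canids sharing
one target).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .amplicondb import Primer, ReferenceDB, find_primer_sites, reverse_complement

__all__ = [
    "Read",
    "SampleSheet",
    "CollapsedSequence",
    "Assignment",
    "MixtureReport",
    "read_fastq",
    "write_fastq",
    "quality_filter",
    "demultiplex",
    "trim_and_orient",
    "collapse",
    "filter_min_count",
    "assign",
    "mixture_report",
    "run_pipeline",
    "PipelineResult",
    "SampleResult",
]


@dataclass(frozen=True, slots=True)
class Read:
    """A sequencing read with Phred qualities (stored FASTQ-encoded)."""

    id: str
    sequence: str
    qual: str  # Sanger/Phred+33 encoded, same length as sequence

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    @property
    def qualities(self) -> np.ndarray:
        return np.frombuffer(self.qual.encode("ascii"), dtype=np.uint8) - 33

    def mean_quality(self) -> float:
        return float(self.qualities.mean()) if self.qual else 0.0

    def reverse_complement(self) -> "Read":
        return Read(self.id, reverse_complement(self.sequence), self.qual[::-1])


def read_fastq(path: str | Path) -> list[Read]:
    """Read a FASTQ file (Sanger quality encoding)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        return [Read(title.split()[0], seq.upper(), qual)
                for title, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qual}\n")


@dataclass
class SampleSheet:
    """Sample label → forward barcode (fixed-length, unique)."""

    barcodes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("empty sample sheet")
        lengths = {len(b) for b in self.barcodes.values()}
        if len(lengths) != 1:
            raise ValueError(f"barcodes have mixed lengths: {sorted(lengths)}")
        seen: dict[str, str] = {}
        for sample, bc in self.barcodes.items():
            bc = bc.upper()
            if bc in seen:
                raise ValueError(f"barcode {bc} shared by {seen[bc]!r} and {sample!r}")
            seen[bc] = sample
        self.barcodes = {s: b.upper() for s, b in self.barcodes.items()}

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes.values())))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        """TSV with columns sample, fwd_barcode (header optional)."""
        barcodes: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() in ("sample", "label"):
                    continue
                barcodes[parts[0]] = parts[1]
        return cls(barcodes=barcodes)


@dataclass(frozen=True, slots=True)
class CollapsedSequence:
    """A dereplicated target sequence and its read support."""

    sequence: str
    count: int


@dataclass(frozen=True)
class Assignment:
    """Species call for one collapsed sequence.

    ``taxa`` lists the reference species at the minimal edit distance.
    ``resolved_label`` is the species name for exact/near calls and a group
    label (shared genus where possible) for ambiguous ones.
    """

    collapsed: CollapsedSequence
    status: str  # exact | near | ambiguous | unassigned
    taxa: tuple[tuple[str, int], ...]
    resolved_label: str | None


@dataclass
class MixtureReport:
    """Per-taxon composition of one sample, over assigned reads."""

    taxon_counts: dict[str, int]
    fractions: dict[str, float]
    unassigned_count: int
    detected: dict[str, bool]

    @property
    def total_assigned(self) -> int:
        return sum(self.taxon_counts.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "taxon_counts": self.taxon_counts,
                "fractions": self.fractions,
                "unassigned_count": self.unassigned_count,
                "detected": self.detected,
            },
            indent=2,
        )


def quality_filter(reads: Sequence[Read], min_mean_q: float = 20.0) -> list[Read]:
    """Keep reads with mean Phred quality >= ``min_mean_q``; order preserved."""
    if min_mean_q < 0:
        raise ValueError("min_mean_q must be >= 0")
    return [r for r in reads if r.mean_quality() >= min_mean_q]


def demultiplex(
    reads: Sequence[Read], sheet: SampleSheet
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Route reads to samples by exact 5'-barcode match.

    If the forward barcode is not at the 5' end, the reverse complement of
    the read is tried; matched reads are routed already re-oriented.
    Everything else lands in the unmatched bin.
    """
    bl = sheet.barcode_length
    by_barcode = {b: s for s, b in sheet.barcodes.items()}
    out: dict[str, list[Read]] = {s: [] for s in sheet.barcodes}
    unmatched: list[Read] = []
    for r in reads:
        sample = by_barcode.get(r.sequence[:bl])
        if sample is not None:
            out[sample].append(r)
            continue
        rc = r.reverse_complement()
        sample = by_barcode.get(rc.sequence[:bl])
        if sample is not None:
            out[sample].append(rc)
        else:
            unmatched.append(r)
    return out, unmatched


def _best_site(hits, strand: str, min_start: int = 0):
    """Best hit on a strand at/after min_start: fewest mismatches, then leftmost."""
    cands = [h for h in hits if h.strand == strand and h.start >= min_start]
    if not cands:
        return None
    return min(cands, key=lambda h: (h.mismatches, h.start))


class _Trimmer:
    """Primer trimming with an exact-match fast path.

    The degenerate primers expand to a handful of concrete strings; exact
    ``str.find`` handles the (vast majority of) error-free primer sites, and
    the mismatch-tolerant scan only runs when exact matching fails.
    """

    def __init__(self, fwd: Primer, rev: Primer, max_mismatches: int = 2):
        self.fwd = fwd
        self.rev = rev
        self.max_mismatches = max_mismatches
        self._fwd_exact = fwd.expansions() if fwd.degeneracy <= 8 else []
        self._rev_rc_exact = (
            [reverse_complement(s) for s in rev.expansions()]
            if rev.degeneracy <= 8
            else []
        )
        self._cache: dict[str, str | None] = {}

    def trim(self, sequence: str) -> str | None:
        seq = sequence.upper()
        cached = self._cache.get(seq, "?")
        if cached != "?":
            return cached
        result = self._trim_uncached(seq)
        if len(self._cache) < 2_000_000:
            self._cache[seq] = result
        return result

    def _trim_uncached(self, seq: str) -> str | None:
        # fast path: exact primer copies
        fstart = fend = -1
        for p in self._fwd_exact:
            i = seq.find(p)
            if i >= 0 and (fstart < 0 or i < fstart):
                fstart, fend = i, i + len(p)
        if fend >= 0:
            rstart = -1
            for p in self._rev_rc_exact:
                j = seq.find(p, fend)
                if j >= 0 and (rstart < 0 or j < rstart):
                    rstart = j
            if rstart >= 0:
                return seq[fend:rstart]
        # slow path: mismatch-tolerant ungapped scan
        fhit = _best_site(find_primer_sites(seq, self.fwd, self.max_mismatches), "+")
        if fhit is None:
            return None
        rhit = _best_site(
            find_primer_sites(seq, self.rev, self.max_mismatches), "-", fhit.end
        )
        if rhit is None:
            return None
        return seq[fhit.end : rhit.start]


def trim_and_orient(
    read: Read | str, fwd: Primer, rev: Primer, max_mismatches: int = 2
) -> str | None:
    """Remove primers from an already-oriented read; return the target.

    Locates the forward primer (within ``max_mismatches``, ungapped) and
    then the reverse-primer site downstream; returns the in-between
    sequence uppercased, or None when either site is missing.
    """
    seq = read.sequence if isinstance(read, Read) else read
    return _Trimmer(fwd, rev, max_mismatches).trim(seq)


def collapse(targets: Iterable[str]) -> list[CollapsedSequence]:
    """Dereplicate: group identical sequences, sort by count desc then sequence."""
    counts = Counter(targets)
    return [
        CollapsedSequence(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def filter_min_count(
    collapsed: Sequence[CollapsedSequence], min_count: int = 20
) -> list[CollapsedSequence]:
    """Keep collapsed sequences supported by at least ``min_count`` reads."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [c for c in collapsed if c.count >= min_count]


def _group_label(species: list[str]) -> str:
    """Common label for several tied species: the shared genus if any."""
    genera = {s.split()[0] for s in species}
    if len(genera) == 1:
        return f"{genera.pop()} ({len(species)} spp.)"
    return f"multiple taxa ({len(species)} spp.)"


def assign(
    collapsed: Sequence[CollapsedSequence],
    db: ReferenceDB,
    max_distance: int = 3,
    min_margin: int = 1,
) -> list[Assignment]:
    """Assign each collapsed sequence to reference species.

    Exact index hits are status ``exact`` (or ``ambiguous`` when several
    species share that target). Otherwise the minimal edit distance over
    the database decides: within ``max_distance`` and separated from the
    second-best species by at least ``min_margin`` → ``near``; several
    species tied at the minimum → ``ambiguous``; anything else →
    ``unassigned``.
    """
    if len(db) == 0:
        raise ValueError("empty reference database")
    k = max_distance + min_margin  # distances beyond k are irrelevant
    out: list[Assignment] = []
    for c in collapsed:
        hits = db.lookup_exact(c.sequence)
        if hits:
            species = sorted({e.species for e in hits})
            taxa = tuple((s, 0) for s in species)
            if len(species) == 1:
                out.append(Assignment(c, "exact", taxa, species[0]))
            else:
                out.append(Assignment(c, "ambiguous", taxa, _group_label(species)))
            continue
        # nearest-reference search, bounded at k (beyond k treated as k+1)
        best: dict[str, int] = {}
        for e in db.entries:
            d = edlib.align(c.sequence, e.target, mode="NW", task="distance", k=k)[
                "editDistance"
            ]
            d = k + 1 if d == -1 else d
            if e.species not in best or d < best[e.species]:
                best[e.species] = d
        dmin = min(best.values())
        tied = sorted(s for s, d in best.items() if d == dmin)
        second = min((d for s, d in best.items() if s not in tied), default=k + 1)
        taxa = tuple((s, dmin) for s in tied)
        if dmin > max_distance:
            out.append(Assignment(c, "unassigned", (), None))
        elif len(tied) > 1:
            out.append(Assignment(c, "ambiguous", taxa, _group_label(tied)))
        elif second - dmin >= min_margin:
            out.append(Assignment(c, "near", taxa, tied[0]))
        else:
            out.append(Assignment(c, "unassigned", taxa, None))
    return out


def mixture_report(assignments: Sequence[Assignment]) -> MixtureReport:
    """Aggregate assignments into per-taxon counts and fractions.

    Fractions are computed over assigned reads only; unassigned reads are
    reported separately. A taxon is flagged detected when it appears here
    at all (it has, by construction, survived the minimum-count filter).
    """
    counts: dict[str, int] = {}
    unassigned = 0
    for a in assignments:
        if a.status == "unassigned" or a.resolved_label is None:
            unassigned += a.collapsed.count
        else:
            counts[a.resolved_label] = counts.get(a.resolved_label, 0) + a.collapsed.count
    total = sum(counts.values())
    fractions = {t: n / total for t, n in counts.items()} if total else {}
    detected = {t: True for t in counts}
    return MixtureReport(
        taxon_counts=counts,
        fractions=fractions,
        unassigned_count=unassigned,
        detected=detected,
    )


@dataclass
class SampleResult:
    """Per-sample pipeline output with stage-by-stage read accounting."""

    sample: str
    collapsed: list[CollapsedSequence]
    kept: list[CollapsedSequence]
    assignments: list[Assignment]
    report: MixtureReport
    accounting: dict[str, int]


@dataclass
class PipelineResult:
    samples: dict[str, SampleResult]
    accounting: dict[str, int]  # run-level: input, low_quality, unmatched

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(
                {
                    "run": self.accounting,
                    "samples": {s: r.accounting for s, r in self.samples.items()},
                },
                fh,
                indent=2,
            )
        for name, res in self.samples.items():
            safe = name.replace(" ", "_")
            with open(outdir / f"{safe}.collapsed.tsv", "w") as fh:
                fh.write("sequence\tcount\tstatus\ttaxon\tdistance\n")
                by_seq = {a.collapsed.sequence: a for a in res.assignments}
                for c in res.collapsed:
                    a = by_seq.get(c.sequence)
                    status = a.status if a else "below_min_count"
                    taxon = (a.resolved_label or "") if a else ""
                    dist = str(a.taxa[0][1]) if a and a.taxa else ""
                    fh.write(f"{c.sequence}\t{c.count}\t{status}\t{taxon}\t{dist}\n")
            with open(outdir / f"{safe}.mixture.json", "w") as fh:
                fh.write(res.report.to_json() + "\n")


def run_pipeline(
    reads: Sequence[Read],
    db: ReferenceDB,
    fwd: Primer,
    rev: Primer,
    sheet: SampleSheet | None = None,
    min_mean_q: float = 20.0,
    trim_max_mismatches: int = 2,
    min_count: int = 20,
    max_distance: int = 3,
    min_margin: int = 1,
) -> PipelineResult:
    """Run the full pipeline; without a sample sheet all reads form one
    sample named "sample" (no demultiplexing)."""
    n_input = len(reads)
    good = quality_filter(reads, min_mean_q)
    n_low_q = n_input - len(good)

    if sheet is not None:
        routed, unmatched = demultiplex(good, sheet)
        n_unmatched = len(unmatched)
    else:
        routed, n_unmatched = {"sample": list(good)}, 0

    trimmer = _Trimmer(fwd, rev, trim_max_mismatches)
    samples: dict[str, SampleResult] = {}
    for name, sample_reads in routed.items():
        targets: list[str] = []
        n_fail = 0
        for r in sample_reads:
            t = trimmer.trim(r.sequence)
            if t is None:
                n_fail += 1
            else:
                targets.append(t)
        collapsed = collapse(targets)
        kept = filter_min_count(collapsed, min_count)
        assignments = assign(kept, db, max_distance, min_margin)
        report = mixture_report(assignments)
        samples[name] = SampleResult(
            sample=name,
            collapsed=collapsed,
            kept=kept,
            assignments=assignments,
            report=report,
            accounting={
                "input": len(sample_reads),
                "trim_failed": n_fail,
                "trimmed": len(targets),
                "collapsed_unique": len(collapsed),
                "kept_unique": len(kept),
                "kept_reads": sum(c.count for c in kept),
                "below_min_count_reads": sum(c.count for c in collapsed)
                - sum(c.count for c in kept),
                "assigned_reads": report.total_assigned,
                "unassigned_reads": report.unassigned_count,
            },
        )

    return PipelineResult(
        samples=samples,
        accounting={
            "input": n_input,
            "low_quality": n_low_q,
            "unmatched": n_unmatched,
        },
    )
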