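"""Degenerate-primer handling and reference amplicon database construction.

A universal primer pair delimits a short variable target region (the
mini-barcode) on the mitochondrial 16S rRNA gene. This module locates the
primer sites in reference sequences (16S genes or whole mitogenomes),
extracts the inter-primer target, builds a species-labelled reference
database, and reports how well the primer sites are conserved across a
reference panel.

Coordinates are 0-based half-open throughout. Primer matching is ungapped
with IUPAC-aware mismatch counting; an ``N`` in the subject always counts
as a mismatch so that N-runs cannot create spurious primer sites.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CODES",
    "Primer",
    "PrimerHit",
    "ReferenceAmplicon",
    "ReferenceDB",
    "ConservationReport",
    "ExtractionResult",
    "PrimerError",
    "AmbiguousAmpliconError",
    "reverse_complement",
    "parse_primer",
    "find_primer_sites",
    "extract_amplicon",
    "build_reference_db",
    "primer_conservation_report",
    "read_reference_fasta",
]

#: IUPAC nucleotide codes mapped to the set of bases each represents.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

SUBJECT_ALPHABET = frozenset("ACGTN")


class PrimerError(ValueError):
    """Raised for invalid primer sequences."""


class AmbiguousAmpliconError(ValueError):
    """Raised when several non-overlapping amplicons survive tie-breaking."""

    def __init__(self, candidates: list["ExtractionResult"]):
        self.candidates = candidates
        desc = "; ".join(
            f"strand {c.strand} [{c.start}, {c.end}) {c.mismatches} mm"
            for c in candidates
        )
        super().__init__(f"ambiguous amplicon extraction: {desc}")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def concretize(seq: str) -> str:
    """Replace each degenerate IUPAC code with its alphabetically first base
    (R → A, Y → C, ...); concrete bases pass through unchanged."""
    return "".join(min(IUPAC_CODES[c]) for c in seq.upper())


@dataclass(frozen=True)
class Primer:
    """A (possibly degenerate) PCR primer in 5'→3' orientation.

    ``degeneracy`` is the number of distinct concrete sequences the primer
    represents: the product of per-position code cardinalities.
    """

    name: str
    sequence: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.role not in ("forward", "reverse"):
            raise PrimerError(f"role must be forward or reverse, got {self.role!r}")
        if not self.sequence:
            raise PrimerError("primer sequence is empty")
        for i, base in enumerate(self.sequence):
            if base not in IUPAC_CODES:
                raise PrimerError(
                    f"primer {self.name!r}: non-IUPAC character {base!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        d = 1
        for base in self.sequence:
            d *= len(IUPAC_CODES[base])
        return d

    def expansions(self) -> list[str]:
        """All concrete sequences the degenerate primer represents."""
        seqs = [""]
        for base in self.sequence:
            seqs = [s + b for s in seqs for b in sorted(IUPAC_CODES[base])]
        return seqs


@dataclass(frozen=True)
class PrimerHit:
    """An ungapped primer match on a subject sequence.

    Coordinates always refer to the forward strand of the subject;
    ``strand`` records which strand the primer annealed to.
    """

    start: int
    end: int
    strand: str  # "+" | "-"
    mismatches: int


@dataclass(frozen=True)
class ExtractionResult:
    """Outcome of amplicon extraction from one reference sequence."""

    target: str
    start: int  # forward-strand start of the inter-primer region
    end: int  # forward-strand end (exclusive)
    strand: str  # strand on which fwd primer precedes the rev site
    mismatches: int  # total mismatches over both primer sites


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A species-labelled target region (primers excluded)."""

    species: str
    target: str
    source_id: str = ""
    taxon_id: str | None = None

    def __len__(self) -> int:
        return len(self.target)


def parse_primer(name: str, raw_sequence: str, role: str) -> Primer:
    """Validate and canonicalise a primer sequence.

    Lowercase input is accepted and uppercased; any non-IUPAC character
    raises :class:`PrimerError` naming the offending position.
    """
    if not raw_sequence:
        raise PrimerError(f"primer {name!r}: empty sequence")
    return Primer(name=name, sequence=raw_sequence.upper(), role=role)


def _compat_table(primer_seq: str) -> np.ndarray:
    """(L, 128) bool table: table[i, ord(c)] == subject char c matches position i.

    N in the subject never matches (conservative mismatch counting).
    """
    L = len(primer_seq)
    table = np.zeros((L, 128), dtype=bool)
    for i, code in enumerate(primer_seq):
        for b in IUPAC_CODES[code]:
            table[i, ord(b)] = True
    return table


def _scan(seq_bytes: np.ndarray, primer_seq: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All ungapped (start, mismatches) with mismatches <= max on one strand."""
    L = len(primer_seq)
    n = seq_bytes.size
    if n < L:
        return []
    table = _compat_table(primer_seq)
    windows = np.lib.stride_tricks.sliding_window_view(seq_bytes, L)
    matches = table[np.arange(L)[None, :], windows]
    mismatches = L - matches.sum(axis=1)
    idx = np.nonzero(mismatches <= max_mismatches)[0]
    return [(int(i), int(mismatches[i])) for i in idx]


def find_primer_sites(
    sequence: str, primer: Primer, max_mismatches: int = 3
) -> list[PrimerHit]:
    """Locate all ungapped primer occurrences on both strands.

    A subject position matches a primer position when the subject base is
    one of the bases the IUPAC code represents; ``N`` in the subject counts
    as a mismatch. Hit coordinates refer to the forward strand of the
    subject. Hits are sorted by (start, strand), "+" before "-".
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    seq = sequence.upper()
    seq_bytes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64)
    L = len(primer)
    hits = [
        PrimerHit(start, start + L, "+", mm)
        for start, mm in _scan(seq_bytes, primer.sequence, max_mismatches)
    ]
    rc = reverse_complement(primer.sequence)
    hits += [
        PrimerHit(start, start + L, "-", mm)
        for start, mm in _scan(seq_bytes, rc, max_mismatches)
    ]
    hits.sort(key=lambda h: (h.start, 0 if h.strand == "+" else 1))
    return hits


def extract_amplicon(
    sequence: str,
    fwd: Primer,
    rev: Primer,
    max_mismatches: int = 3,
    length_bounds: tuple[int, int] = (40, 160),
) -> ExtractionResult | None:
    """Extract the inter-primer target region from a reference sequence.

    Both orientations of the subject are considered; the target is reported
    on the strand where the forward primer precedes the reverse-primer site
    (so it always reads 5'→3' from the forward primer). Primers are
    excluded from the target. The best pairing has the fewest total
    mismatches, then the shortest amplicon, then the leftmost start.

    Returns None when no compatible primer pair exists within
    ``length_bounds``; raises :class:`AmbiguousAmpliconError` when several
    equally good non-overlapping candidates remain.
    """
    lo, hi = length_bounds
    seq = sequence.upper()
    fwd_hits = find_primer_sites(seq, fwd, max_mismatches)
    rev_hits = find_primer_sites(seq, rev, max_mismatches)

    candidates: list[ExtractionResult] = []
    # Forward-strand amplicons: fwd on '+' upstream of the rev site, which
    # appears on the forward strand as the reverse complement of rev ('-' hit).
    for fh in fwd_hits:
        if fh.strand != "+":
            continue
        for rh in rev_hits:
            if rh.strand != "-" or rh.start < fh.end:
                continue
            target = seq[fh.end : rh.start]
            if lo <= len(target) <= hi:
                candidates.append(
                    ExtractionResult(
                        target, fh.end, rh.start, "+", fh.mismatches + rh.mismatches
                    )
                )
    # Reverse-strand amplicons: rev site on '+' upstream of fwd on '-';
    # the target is the reverse complement of the in-between region.
    for fh in fwd_hits:
        if fh.strand != "-":
            continue
        for rh in rev_hits:
            if rh.strand != "+" or fh.start < rh.end:
                continue
            target = reverse_complement(seq[rh.end : fh.start])
            if lo <= len(target) <= hi:
                candidates.append(
                    ExtractionResult(
                        target, rh.end, fh.start, "-", fh.mismatches + rh.mismatches
                    )
                )

    if not candidates:
        return None
    candidates.sort(key=lambda c: (c.mismatches, len(c.target), c.start))
    best = candidates[0]
    ties = [
        c
        for c in candidates
        if c.mismatches == best.mismatches and len(c.target) == len(best.target)
    ]
    # Equally good candidates that do not overlap the winner are a genuine
    # ambiguity (two amplicons in one record) and must be surfaced.
    disjoint = [c for c in ties[1:] if c.end <= best.start or c.start >= best.end]
    if disjoint:
        raise AmbiguousAmpliconError([best, *disjoint])
    return best


_SPECIES_KEY_RE = re.compile(r"species=([^;|\t]+)")


def _species_from_record(rec: SeqRecord, species_regex: str | None = None) -> str | None:
    """Species label from a FASTA header.

    Convention: a ``species=<binomial>`` key anywhere in the description
    wins; otherwise the first two whitespace-separated words after the
    record id. A custom regex (first group = label) overrides both.
    """
    desc = rec.description or ""
    if species_regex is not None:
        m = re.search(species_regex, desc)
        return m.group(1).strip() if m else None
    m = _SPECIES_KEY_RE.search(desc)
    if m:
        return m.group(1).strip()
    words = desc.split()
    # description starts with the id itself in Biopython
    if words and words[0] == rec.id:
        words = words[1:]
    if len(words) >= 2:
        return f"{words[0]} {words[1]}"
    return None


@dataclass
class ReferenceDB:
    """Species-labelled reference amplicons with exact-sequence lookup."""

    entries: list[ReferenceAmplicon] = field(default_factory=list)
    index: dict[str, list[ReferenceAmplicon]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.index and self.entries:
            self._reindex()

    def _reindex(self) -> None:
        idx: dict[str, list[ReferenceAmplicon]] = defaultdict(list)
        for e in self.entries:
            idx[e.target].append(e)
        self.index = dict(idx)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ReferenceAmplicon]:
        return iter(self.entries)

    @property
    def species(self) -> list[str]:
        return [e.species for e in self.entries]

    def lookup_exact(self, target: str) -> list[ReferenceAmplicon]:
        """All entries whose target equals ``target`` exactly."""
        return list(self.index.get(target, ()))

    def identical_groups(self) -> list[list[str]]:
        """Groups of >= 2 species sharing one target, each sorted alphabetically."""
        groups = [
            sorted(e.species for e in entries)
            for entries in self.index.values()
            if len(entries) >= 2
        ]
        return sorted(groups)

    # ------------------------------------------------------------------ IO
    def write(self, outdir: str | Path) -> None:
        """Write the DB as TSV (species, target, length, source_id) + target FASTA."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "reference_db.tsv", "w") as fh:
            fh.write("species\ttarget\tlength\tsource_id\n")
            for e in self.entries:
                fh.write(f"{e.species}\t{e.target}\t{len(e.target)}\t{e.source_id}\n")
        with open(outdir / "targets.fasta", "w") as fh:
            for e in self.entries:
                fh.write(f">{e.source_id or e.species.replace(' ', '_')} species={e.species}\n")
                fh.write(e.target + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "ReferenceDB":
        """Load a DB from a directory written by :meth:`write` or from its TSV."""
        path = Path(path)
        tsv = path / "reference_db.tsv" if path.is_dir() else path
        entries = []
        with open(tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {c: i for i, c in enumerate(header)}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                entries.append(
                    ReferenceAmplicon(
                        species=parts[cols["species"]],
                        target=parts[cols["target"]],
                        source_id=parts[cols.get("source_id", -1)] if "source_id" in cols else "",
                    )
                )
        return cls(entries=entries)


def read_reference_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a reference FASTA file into SeqRecords."""
    return list(SeqIO.parse(str(path), "fasta"))


def build_reference_db(
    fasta_records: Iterable[SeqRecord | tuple[str, str, str]],
    fwd: Primer,
    rev: Primer,
    max_mismatches: int = 3,
    length_bounds: tuple[int, int] = (40, 160),
    species_regex: str | None = None,
    allow_multiple: bool = False,
) -> tuple[ReferenceDB, list[tuple[str, str]]]:
    """Build a reference database by extracting the target from each record.

    Records may be Biopython SeqRecords or ``(id, description, sequence)``
    tuples. Records with no species label, no valid extraction, or an
    ambiguous extraction are skipped and listed in the returned skip log as
    ``(record_id, reason)`` pairs. Lowercase reference letters are
    uppercased on ingest.

    A species seen twice with differing targets raises ValueError unless
    ``allow_multiple`` is set (entries are then kept side by side).
    """
    entries: list[ReferenceAmplicon] = []
    skip_log: list[tuple[str, str]] = []
    seen: dict[str, str] = {}

    for rec in fasta_records:
        if isinstance(rec, tuple):
            rid, desc, seq = rec
            rec = SeqRecord(Seq(seq), id=rid, description=f"{rid} {desc}".strip())
        rid = rec.id
        species = _species_from_record(rec, species_regex)
        if not species:
            skip_log.append((rid, "no species label in header"))
            continue
        seq = str(rec.seq).upper()
        try:
            result = extract_amplicon(seq, fwd, rev, max_mismatches, length_bounds)
        except AmbiguousAmpliconError as exc:
            skip_log.append((rid, f"ambiguous: {exc}"))
            continue
        if result is None:
            skip_log.append((rid, "no compatible primer pair within length bounds"))
            continue
        if species in seen and not allow_multiple:
            if seen[species] != result.target:
                raise ValueError(
                    f"species {species!r} occurs with differing targets; "
                    "pass allow_multiple=True to keep both"
                )
            skip_log.append((rid, "duplicate species with identical target"))
            continue
        seen[species] = result.target
        entries.append(ReferenceAmplicon(species=species, target=result.target, source_id=rid))

    return ReferenceDB(entries=entries), skip_log


@dataclass
class ConservationReport:
    """Per-position base composition of primer-site sequences and the
    fraction of references matching the primer within k mismatches."""

    primer: Primer
    composition: "np.ndarray"  # (L, 5) percentages, columns A C G T -
    universality: float
    k: int
    n_sites: int

    BASES = ("A", "C", "G", "T", "-")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.composition.T,
            index=list(self.BASES),
            columns=list(self.primer.sequence),
        )


def _site_mismatches(site: str, primer: Primer) -> int:
    """Ungapped IUPAC-aware mismatch count of an aligned primer-site sequence.

    Gap characters count as mismatches: a reference whose primer site has a
    deletion cannot be a perfect template for the primer.
    """
    mm = 0
    for s, p in zip(site, primer.sequence):
        if s == "N" or s == "-" or s not in IUPAC_CODES[p]:
            mm += 1
    return mm


def primer_conservation_report(
    primer_site_sequences: Sequence[str], primer: Primer, k: int = 1
) -> ConservationReport:
    """Summarise primer-site conservation across a reference panel.

    ``primer_site_sequences`` are the extracted primer-site sequences, one
    per reference, aligned to the primer length ('-' marks an alignment
    gap). Returns the per-position A/C/G/T/gap percentages and the
    universality: the fraction of references whose site matches the primer
    with at most ``k`` mismatches.
    """
    L = len(primer)
    sites = [s.upper() for s in primer_site_sequences]
    for s in sites:
        if len(s) != L:
            raise ValueError(f"site length {len(s)} != primer length {L}: {s!r}")
    if not sites:
        raise ValueError("no primer-site sequences given")

    comp = np.zeros((L, 5))
    base_idx = {b: i for i, b in enumerate(ConservationReport.BASES)}
    for s in sites:
        for pos, b in enumerate(s):
            comp[pos, base_idx.get(b, base_idx["-"])] += 1
    comp = comp / len(sites) * 100.0

    n_ok = sum(1 for s in sites if _site_mismatches(s, primer) <= k)
    return ConservationReport(
        primer=primer,
        composition=comp,
        universality=n_ok / len(sites),
        k=k,
        n_sites=len(sites),
    )
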