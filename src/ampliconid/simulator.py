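"""Pyrosequencing-style amplicon read simulator.

Generates mixed-species FASTQ reads — [barcode +] [forward primer +]
mutated target [+ reverse-complemented reverse primer] — with a truth table
(read id → source species, error counts), so the pipeline and the error
statistics can be exercised without instrument data.

Error model
-----------
Two independent error channels, applied to the target region:

* substitutions: i.i.d. per base at ``substitution_rate``, uniform among
  the three alternative bases;
* homopolymer indels: for each maximal run of identical bases of length
  L >= 2 in the template, with probability min(1, indel_rate * (L - 1))
  the run is shortened or lengthened by one base (equal odds, at most one
  event per run). This linear-in-run-length caricature of flow-value noise
  reproduces the dominant real-world artifact: a 5-base adenosine stretch
  collapsing to 4 bases.

Species composition is a single seeded multinomial draw over
weight × amplification-bias products; the truth table therefore matches the
draw exactly. Identical (config, seed) pairs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .amplicondb import ReferenceDB, concretize, reverse_complement
from .readpipe import Read

__all__ = ["SimConfig", "TruthRecord", "sample_composition", "find_runs", "mutate", "simulate"]

_BASES = "ACGT"
_ALTERNATIVES = {b: _BASES.replace(b, "") for b in _BASES}
_DEFAULT_BARCODE = "ACGAGTGCGT"


@dataclass
class SimConfig:
    """Simulation settings.

    ``weights`` are relative template copy numbers (e.g. {major: 99,
    minor: 1} for a 99:1 mixture); ``bias`` multiplies them per species to
    emulate amplification efficiency differences (1.0 = none; ~0.05–0.1
    emulates the strong under-recovery seen for human templates in
    mixtures). Rates are per base (substitutions) and per run-length unit
    (homopolymer indels).
    """

    weights: dict[str, float]
    n_reads: int
    substitution_rate: float = 0.0010
    homopolymer_indel_rate: float = 0.004
    bias: dict[str, float] = field(default_factory=dict)
    decorate: bool = True
    barcode: str | None = _DEFAULT_BARCODE
    fwd_primer: str | None = None
    rev_primer: str | None = None
    quality: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not self.weights or any(w <= 0 for w in self.weights.values()):
            raise ValueError("species weights must be positive")
        for name, r in (
            ("substitution_rate", self.substitution_rate),
            ("homopolymer_indel_rate", self.homopolymer_indel_rate),
        ):
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")

    def effective_probs(self) -> dict[str, float]:
        """Read-generation probabilities ∝ weight × bias."""
        eff = {s: w * self.bias.get(s, 1.0) for s, w in self.weights.items()}
        total = sum(eff.values())
        return {s: v / total for s, v in eff.items()}


@dataclass(frozen=True, slots=True)
class TruthRecord:
    read_id: str
    species: str
    n_sub: int
    n_indel: int


def sample_composition(config: SimConfig, rng: np.random.Generator | None = None) -> list[str]:
    """Species label per read: one multinomial draw over weight × bias,
    shuffled into a seeded read order."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    species = sorted(config.weights)
    probs = config.effective_probs()
    counts = rng.multinomial(config.n_reads, [probs[s] for s in species])
    labels = np.repeat(np.arange(len(species)), counts)
    rng.shuffle(labels)
    return [species[i] for i in labels]


def find_runs(seq: str) -> list[tuple[int, int, str]]:
    """Maximal homopolymer runs as (start, length, base), length >= 2."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i, seq[i]))
        i = j
    return runs


def mutate(
    target: str,
    substitution_rate: float,
    homopolymer_indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Apply the error model to one template; returns (sequence, n_sub, n_indel).

    Homopolymer events are decided on the template's runs first (shorten or
    lengthen by one, equal odds, at most one event per run); substitutions
    are then drawn i.i.d. over the resulting sequence.
    """
    n_indel = 0
    if homopolymer_indel_rate > 0:
        pieces: list[str] = []
        prev = 0
        for start, length, base in find_runs(target):
            p = min(1.0, homopolymer_indel_rate * (length - 1))
            if rng.random() < p:
                n_indel += 1
                new_len = length + (1 if rng.random() < 0.5 else -1)
                pieces.append(target[prev:start])
                pieces.append(base * new_len)
                prev = start + length
        pieces.append(target[prev:])
        seq = "".join(pieces)
    else:
        seq = target

    n_sub = 0
    if substitution_rate > 0:
        hits = np.nonzero(rng.random(len(seq)) < substitution_rate)[0]
        if hits.size:
            chars = list(seq)
            for i in hits:
                old = chars[i]
                alts = _ALTERNATIVES.get(old)
                if alts is None:  # N or other: substitute to a random base
                    alts = _BASES
                chars[i] = alts[rng.integers(len(alts))]
                n_sub += 1
            seq = "".join(chars)
    return seq, n_sub, n_indel


def _decoration(config: SimConfig) -> tuple[str, str]:
    """Constant 5'/3' additions per read. Degenerate primer positions are
    realized to a concrete base (R → A etc.): a sequenced molecule carries
    one realization, and the majority synthesis variant is used here."""
    prefix = ""
    suffix = ""
    if config.decorate:
        if config.barcode:
            prefix += config.barcode.upper()
        if config.fwd_primer:
            prefix += concretize(config.fwd_primer)
        if config.rev_primer:
            suffix = reverse_complement(concretize(config.rev_primer))
    return prefix, suffix


def simulate(
    config: SimConfig, db: ReferenceDB
) -> tuple[list[Read], pd.DataFrame]:
    """Generate reads and their truth table.

    Every species in ``config.weights`` must be present in ``db``; each
    read's target is that species' reference sequence passed through the
    error model, then decorated with barcode/primers per config. Output is
    deterministic given (config, seed).
    """
    targets = {e.species: e.target for e in db.entries}
    missing = sorted(set(config.weights) - set(targets))
    if missing:
        raise ValueError(f"species not in reference DB: {missing}")

    rng = np.random.default_rng(config.seed)
    labels = sample_composition(config, rng)
    prefix, suffix = _decoration(config)
    qchar = chr(config.quality + 33)

    # fast path: with no error events the read is the cached decorated template
    clean: dict[str, str] = {
        s: prefix + t + suffix for s, t in targets.items() if s in config.weights
    }
    run_probs = {
        s: np.array(
            [
                min(1.0, config.homopolymer_indel_rate * (length - 1))
                for _, length, _ in find_runs(targets[s])
            ]
        )
        for s in config.weights
    }

    runs_by_species = {s: find_runs(targets[s]) for s in config.weights}

    reads: list[Read] = []
    truth_rows: list[TruthRecord] = []
    for idx, species in enumerate(labels):
        rid = f"read_{idx:06d}"
        template = targets[species]
        probs = run_probs[species]
        events = rng.random(probs.size) < probs if probs.size else np.zeros(0, bool)
        if events.any():
            mutated = _apply_run_indels(template, runs_by_species[species], events, rng)
            n_indel = int(events.sum())
        else:
            mutated = template
            n_indel = 0
        n_sub = (
            int(rng.binomial(len(mutated), config.substitution_rate))
            if config.substitution_rate > 0
            else 0
        )
        if n_sub:
            mutated, n_sub = _apply_substitutions(mutated, n_sub, rng)
        if n_sub == 0 and n_indel == 0:
            seq = clean[species]
        else:
            seq = prefix + mutated + suffix
        reads.append(Read(rid, seq, qchar * len(seq)))
        truth_rows.append(TruthRecord(rid, species, n_sub, n_indel))

    truth = pd.DataFrame(
        [(t.read_id, t.species, t.n_sub, t.n_indel) for t in truth_rows],
        columns=["read_id", "species", "n_sub", "n_indel"],
    )
    return reads, truth


def _apply_run_indels(
    template: str,
    runs: list[tuple[int, int, str]],
    events: np.ndarray,
    rng: np.random.Generator,
) -> str:
    """Lengthen/shorten by one base (equal odds) each run flagged in events."""
    pieces: list[str] = []
    prev = 0
    for (start, length, base), hit in zip(runs, events):
        if hit:
            new_len = length + (1 if rng.random() < 0.5 else -1)
            pieces.append(template[prev:start])
            pieces.append(base * new_len)
            prev = start + length
    pieces.append(template[prev:])
    return "".join(pieces)


def _apply_substitutions(
    seq: str, n_sub: int, rng: np.random.Generator
) -> tuple[str, int]:
    """Substitute at n_sub distinct uniform positions (binomial count was
    drawn by the caller; positions given the count are uniform w/o replacement)."""
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_sub, len(chars)), replace=False)
    for i in positions:
        alts = _ALTERNATIVES.get(chars[i], _BASES)
        chars[i] = alts[rng.integers(len(alts))]
    return "".join(chars), len(positions)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
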