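"""Bundled mammal 16S mini-barcode reference set.

Fifteen Sanger-verified target sequences (the region between the universal
primer sites, primers excluded) for common European mammal species plus
human, together with the universal primer pair that delimits them. These
are the sequences used throughout the tests and the worked examples; a
full-scale reference panel is built from user FASTA with
:func:`ampliconid.amplicondb.build_reference_db`.

Common-name aliases: harbour seal, European beaver, brown bear, red fox,
otter, lynx, wolverine, pig/wild boar, horse, cow, ringed seal, porpoise,
polecat, wolf (the Canis lineage including domestic dog), human.
"""

from __future__ import annotations

from .amplicondb import Primer, ReferenceAmplicon, ReferenceDB, parse_primer

__all__ = [
    "FORWARD_PRIMER_SEQ",
    "REVERSE_PRIMER_SEQ",
    "MAMMAL_TARGETS",
    "forward_primer",
    "reverse_primer",
    "mammal_reference_db",
]

#: Universal forward primer annealing upstream of the 16S target (5'→3').
FORWARD_PRIMER_SEQ = "GACGAGAAGACCCTATGGAGC"
#: Universal reverse primer (5'→3' on the opposite strand); one degenerate
#: position (R = A/G).
REVERSE_PRIMER_SEQ = "TCCGAGGTCRCCCCAACC"

#: Species → target region sequence (uppercased; 73–81 nt).
MAMMAL_TARGETS: dict[str, str] = {
    "Phoca vitulina": "TTTAATTAACTAACTCAACAGAGCAAATCCAGTCAACCAACAGGGAATAAAAACTTCTACAATGAGTTAGCAATTTA",
    "Castor fiber": "TTTAATTTTTCAACCACAATTATACAATAACTCCTACCCCTAATTGGCCCAACCCTATAATTTCTGGTTTAATAATTTT",
    "Ursus arctos": "TTCAATTAATTAGCTCAAAAGGATTTATTTACCAGACCGACAGGAACAACATATTCCTTCCATGAGCTAGCAATTTA",
    "Vulpes vulpes": "TTTAATTAATTAGCCCAAACTTATGAACTTTAAACCCCACTGGGAATAACATACTACCATTGTTATGGGCTGACAATTTA",
    "Lutra lutra": "TTTAATTAACTAACCCATAATAACTTACTAAATCACCGATCAGGCCTAACACAATCCTATTAATGGGTTAGCAATTTA",
    "Lynx lynx": "TTTAATTAACCGACCCAAAGAGACCCCATTTATCCAACCGACAGGAACAACAAACCTCCACTATGGGTCGACAATTTA",
    "Gulo gulo": "TTTAATTAACTAACCCATAATAAGTCTACTTAATCACCAACCGGGTCTAACACAACCTTATTAATGGATTAGTAATTTA",
    "Sus scrofa": "TTTAATTAACTATTCCAAAAGTTAAACAACTCAACCACAAAGGGATAAAACATAACTTAACATGGACTAGCAATTTC",
    "Equus caballus": "TTTAATTAACTGATTCACAAAAAACAATACACAAACCTAACCTTCAGGGACAACAAAACTTTTGATTGAATCAGCAATTTC",
    "Bos taurus": "TTTAACTAACCAACCCAAAGAGAATAGATTTAACCATTAAGGAATAACAACAATCTCCATGAGTTGGTAGTTTC",
    "Phoca hispida": "TTTAATTAACTAACTCAACAGAACAAATCCAGTCAACCAACAGGGAATAAAAACTTCTATAATGAGTTAGCAATTTA",
    "Phocoena phocoena": "TTTAATTAATCAACTCAAAAAAATCGTAAAACAGTACCACTAAGGGATAACAAAATTTTATATGGGTTGACAATTTC",
    "Mustela putorius": "TTCAATTAACTAACCCACAATAACCAATCAATATGCCAACCAGGCCTAACATAATCTTATTTCTGGGTTAGCAATTTA",
    "Canis lupus": "TTTAATTAACTAACCCAAACTTATGGATACTAGATACCTACAAGGCATAACATAACACCATTATTATGGGTTAGCAATTTA",
    "Homo sapiens": "TTTAATTTATTAATGCAAACAGTACCTAACAAACCCACAGGTCCTAAACTACCAAACCTGCATTAAAAATTTC",
}


def forward_primer() -> Primer:
    """The universal forward primer as a parsed :class:`Primer`."""
    return parse_primer("16S-fwd", FORWARD_PRIMER_SEQ, "forward")


def reverse_primer() -> Primer:
    """The universal reverse primer as a parsed :class:`Primer`."""
    return parse_primer("16S-rev", REVERSE_PRIMER_SEQ, "reverse")


def mammal_reference_db() -> ReferenceDB:
    """The bundled 15-species reference database."""
    entries = [
        ReferenceAmplicon(species=sp, target=t, source_id=sp.replace(" ", "_"))
        for sp, t in MAMMAL_TARGETS.items()
    ]
    return ReferenceDB(entries=entries)
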