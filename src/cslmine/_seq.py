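"""Low-level sequence utilities shared across the pipeline.

Translation uses the standard nuclear genetic code; any codon containing a
character outside ACGT translates as ``X``.  Back-translation uses one fixed
codon per amino acid so that simulated transcripts are deterministic.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD = unambiguous_dna_by_id[1]

#: codon -> single-letter amino acid, stops as '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: fixed back-translation table (one codon per residue)
AA_TO_CODON: dict[str, str] = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAC", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTC", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAC", "V": "GTG",
}

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate a 3-mer; stops give '*', anything with non-ACGT gives 'X'."""
    return CODON_TO_AA.get(codon, "X")


def translate_frame(seq: str, frame: int = 0) -> str:
    """Plain single-frame translation (no frameshift handling)."""
    out = []
    for i in range(frame, len(seq) - 2, 3):
        out.append(translate_codon(seq[i : i + 3]))
    return "".join(out)


def back_translate(protein: str) -> str:
    """Deterministic nucleotide encoding of ``protein``."""
    try:
        return "".join(AA_TO_CODON[a] for a in protein)
    except KeyError as exc:  # pragma: no cover - guarded by generators
        raise ValueError(f"cannot back-translate residue {exc}") from exc


def check_dna(seq: str) -> str:
    """Uppercase and validate a nucleotide string (ACGTN only)."""
    up = seq.upper()
    bad = set(up) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in nucleotide sequence: {sorted(bad)}")
    return up
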