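"""Reference panel of pre-classified CesA/Csl proteins and domain alignments.

The classification stages of the pipeline place newly mined peptides relative
to a panel of proteins whose family membership (CesA, CslA-CslK, or other GT2)
is already known.  This module loads and validates that panel, loads the two
domain reference alignments that stand in for the Cellulose_synt and
Glycos_transf_2 profiles, and scans amino-acid sequences for the dispersed
D,D,D,QXXRW catalytic motif characteristic of processive GT2 enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

#: closed vocabulary of panel family labels
FAMILY_VOCABULARY: tuple[str, ...] = (
    "CesA", "CslA", "CslB", "CslC", "CslD", "CslE", "CslF",
    "CslG", "CslH", "CslJ", "CslK", "GT2other",
)

DOMAIN_NAMES: tuple[str, ...] = ("Cellulose_synt", "Glycos_transf_2")

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ReferenceProtein:
    """A family-labelled amino-acid sequence from the classification panel."""

    id: str
    species: str
    family: str
    sequence: str

    def __post_init__(self) -> None:
        if self.family not in FAMILY_VOCABULARY:
            raise ValueError(
                f"unknown family label {self.family!r} for {self.id!r}; "
                f"allowed: {', '.join(FAMILY_VOCABULARY)}"
            )
        if not self.sequence:
            raise ValueError(f"empty sequence for panel protein {self.id!r}")
        bad = set(self.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"non amino-acid characters {sorted(bad)} in panel protein {self.id!r}"
            )


@dataclass(frozen=True)
class DomainReferenceAlignment:
    """An aligned set of domain sequences used to build a scoring profile."""

    name: str
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.name not in DOMAIN_NAMES:
            raise ValueError(
                f"domain alignment name must be one of {DOMAIN_NAMES}, got {self.name!r}"
            )
        if len(self.rows) < 2:
            raise ValueError(f"domain alignment {self.name!r} needs >= 2 rows")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"rows of domain alignment {self.name!r} differ in length")
        ncols = widths.pop()
        for c in range(ncols):
            if all(r[c] == "-" for r in self.rows):
                raise ValueError(
                    f"column {c} of domain alignment {self.name!r} is all-gap"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class MotifSpec:
    """Ordered D, D, D, QXXRW element list with minimum inter-element spacing.

    ``spacing`` gives, for each consecutive element pair (D1-D2, D2-D3, D3-Q),
    the minimum number of residues strictly between the two anchors.
    """

    spacing: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.spacing):
            raise ValueError("motif spacing values must be >= 0")


def load_panel(fasta_path: str | Path, labels_path: str | Path) -> list[ReferenceProtein]:
    """Load a reference panel from FASTA plus a 2-column (id, family) TSV.

    A third TSV column, when present, is taken as the species name; otherwise
    the species is parsed from the id's leading ``species|`` component or left
    empty.  Raises on duplicate FASTA ids and on FASTA records missing from
    the label table.  FASTA order is preserved.
    """
    labels: dict[str, tuple[str, str]] = {}
    with open(labels_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{labels_path}:{lineno}: expected id<TAB>family")
            pid, family = parts[0], parts[1]
            species = parts[2] if len(parts) > 2 else ""
            if pid in labels:
                raise ValueError(f"duplicate id {pid!r} in label table")
            labels[pid] = (family, species)

    panel: list[ReferenceProtein] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in panel FASTA")
        seen.add(rec.id)
        if rec.id not in labels:
            raise ValueError(f"panel FASTA id {rec.id!r} missing from label table")
        family, species = labels[rec.id]
        panel.append(
            ReferenceProtein(
                id=rec.id,
                species=species,
                family=family,
                sequence=str(rec.seq).upper(),
            )
        )
    return panel


def write_panel(
    panel: Sequence[ReferenceProtein], fasta_path: str | Path, labels_path: str | Path
) -> None:
    """Inverse of :func:`load_panel` (used by the simulator and the CLI)."""
    with open(fasta_path, "w") as fa:
        for p in panel:
            fa.write(f">{p.id}\n{p.sequence}\n")
    with open(labels_path, "w") as tsv:
        tsv.write("# id\tfamily\tspecies\n")
        for p in panel:
            tsv.write(f"{p.id}\t{p.family}\t{p.species}\n")


def load_domain_alignment(path: str | Path, name: str) -> DomainReferenceAlignment:
    """Load an aligned-FASTA domain reference alignment."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return DomainReferenceAlignment(name=name, ids=tuple(ids), rows=tuple(rows))


def write_domain_alignment(aln: DomainReferenceAlignment, path: str | Path) -> None:
    with open(path, "w") as fa:
        for rid, row in zip(aln.ids, aln.rows):
            fa.write(f">{rid}\n{row}\n")


def scan_motif(
    sequence: str, spec: MotifSpec = MotifSpec()
) -> tuple[bool, Optional[tuple[int, int, int, int]]]:
    """Search for the D,D,D,QXXRW motif.

    Returns ``(present, anchors)`` where anchors are 0-based positions of the
    three D residues and the Q; among all valid position tuples the
    lexicographically smallest is returned.  The QXXRW element requires
    Q.x.x.R.W exactly (any residues at the x positions).
    """
    seq = sequence.upper()
    n = len(seq)
    s1, s2, s3 = spec.spacing
    d_positions = [i for i, c in enumerate(seq) if c == "D"]
    q_positions = [
        i
        for i in range(n - 4)
        if seq[i] == "Q" and seq[i + 3] == "R" and seq[i + 4] == "W"
    ]
    if not q_positions:
        return False, None
    for p1 in d_positions:
        for p2 in d_positions:
            if p2 - p1 < s1 + 1:
                continue
            for p3 in d_positions:
                if p3 - p2 < s2 + 1:
                    continue
                for p4 in q_positions:
                    if p4 - p3 >= s3 + 1:
                        return True, (p1, p2, p3, p4)
    return False, None
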