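"""Synthetic gene families, transcripts, error-laden reads and decoys.

The generator emulates the statistical structure of a multi-species
transcriptome mining study: several homologous gene families derived from a
common GT2-like ancestor, species-level copies within each family, 454-style
reads tiled over back-translated transcripts with substitution and
frameshift-inducing indel errors, and a bulk of non-homologous decoy reads.

Two disjoint column ranges of the (gap-free) family alignment double as the
domain reference alignments, mirroring how the Cellulose_synt and
Glycos_transf_2 profiles cover distinct regions of real CesA/Csl proteins.
The six residues of the D,D,D,QXXRW catalytic motif are pinned in every
homologous protein, so motif scanning behaves as it does on real panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import AMINO_ACIDS, back_translate, revcomp
from .refpanel import (
    DomainReferenceAlignment,
    FAMILY_VOCABULARY,
    ReferenceProtein,
)

_FAMILY_ORDER = [f for f in FAMILY_VOCABULARY if f != "GT2other"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data set.

    Defaults describe the standard desk-scale simulation: six families in
    four species, 300-residue proteins at 80% within-family / 35%
    between-family identity, 400-nt reads at 10x coverage with 1%
    substitutions and 0.5% frameshift-inducing indels, plus 1,000 decoys.
    """

    n_families: int = 6
    n_species: int = 4
    within_family_identity: float = 0.8
    between_family_identity: float = 0.35
    protein_length: int = 300
    read_length: int = 400
    coverage: float = 10.0
    substitution_rate: float = 0.01
    indel_rate: float = 0.005
    n_decoys: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.within_family_identity <= 1):
            raise ValueError("within_family_identity must be in (0, 1]")
        if not (0 <= self.between_family_identity < 1):
            raise ValueError("between_family_identity must be in [0, 1)")
        if self.within_family_identity <= self.between_family_identity:
            raise ValueError(
                "within_family_identity must exceed between_family_identity"
            )
        for name in ("substitution_rate", "indel_rate"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.n_families > len(_FAMILY_ORDER):
            raise ValueError(f"at most {len(_FAMILY_ORDER)} families supported")


@dataclass
class ReadTruth:
    """Provenance of one simulated read."""

    read_id: str
    species: str
    family: str
    source_id: str  # transcript / protein of origin ("-" for decoys)
    strand: str
    start: int  # 0-based start on the source transcript (-1 for decoys)
    is_decoy: bool
    frameshifts: tuple[tuple[int, str, int], ...] = ()
    """(position-in-read, 'ins'|'del', length) for each planted indel."""


@dataclass
class SimTruth:
    """Per-read and per-transcript provenance for a simulated study."""

    reads: dict[str, ReadTruth] = field(default_factory=dict)
    transcripts: dict[str, tuple[str, str]] = field(default_factory=dict)
    """transcript id -> (species, family)"""

    def merge(self, other: "SimTruth") -> None:
        self.reads.update(other.reads)
        self.transcripts.update(other.transcripts)


@dataclass
class FastqRead:
    id: str
    sequence: str

    def fastq(self) -> str:
        return f"@{self.id}\n{self.sequence}\n+\n{'I' * len(self.sequence)}\n"


# positions (relative to protein length) of the pinned D,D,D,QXXRW anchors
_MOTIF_FRACTIONS = (0.25, 0.45, 0.62, 0.80)


def _motif_anchor_positions(length: int) -> dict[int, str]:
    """Residues pinned in every homologous protein of the simulation."""
    d1, d2, d3, q = (int(f * length) for f in _MOTIF_FRACTIONS)
    return {d1: "D", d2: "D", d3: "D", q: "Q", q + 3: "R", q + 4: "W"}


def _retention_for_identity(target: float) -> float:
    """Per-copy fraction of unmutated sites giving a pairwise identity target.

    Two copies independently retain a fraction r of ancestral sites;
    substituted sites draw uniformly from the other 19 residues, so the
    expected pairwise identity is r^2 + (1 - r)^2 / 19.  Solve for r.
    """
    a = 1.0 + 1.0 / 19.0
    b = -2.0 / 19.0
    c = 1.0 / 19.0 - target
    disc = b * b - 4 * a * c
    r = (-b + math.sqrt(disc)) / (2 * a)
    return min(1.0, max(0.0, r))


def _mutate(
    sequence: str,
    retention: float,
    rng: np.random.Generator,
    pinned: dict[int, str],
) -> str:
    out = list(sequence)
    for i in range(len(out)):
        if i in pinned:
            continue
        if rng.random() >= retention:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    seq = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length)]
    for pos, res in _motif_anchor_positions(length).items():
        seq[pos] = res
    return "".join(seq)


def species_names(config: SimConfig, query: bool = False) -> list[str]:
    prefix = "qsp" if query else "refsp"
    return [f"{prefix}{i + 1}" for i in range(config.n_species)]


def make_panel(
    config: SimConfig,
) -> tuple[list[ReferenceProtein], dict[str, str]]:
    """Generate the pre-classified reference panel.

    A common ancestor is mutated into one ancestor per family (hitting the
    between-family identity target), then into one copy per reference
    species (hitting the within-family target).  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 101])
    ancestor = _random_protein(config.protein_length, rng)
    pinned = _motif_anchor_positions(config.protein_length)
    r_within = _retention_for_identity(config.within_family_identity)
    # species copies mutate again after the family split, so the retention on
    # the ancestor->family branch must be deflated by the within retention
    # for cross-family pairs of species copies to hit the between target
    r_between = min(1.0, _retention_for_identity(config.between_family_identity) / r_within)
    families = _FAMILY_ORDER[: config.n_families]
    family_ancestors: dict[str, str] = {
        fam: _mutate(ancestor, r_between, rng, pinned) for fam in families
    }
    panel: list[ReferenceProtein] = []
    for fam in families:
        for sp in species_names(config):
            seq = _mutate(family_ancestors[fam], r_within, rng, pinned)
            panel.append(
                ReferenceProtein(
                    id=f"{fam}_{sp}", species=sp, family=fam, sequence=seq
                )
            )
    return panel, family_ancestors


def make_query_proteins(
    config: SimConfig, family_ancestors: dict[str, str]
) -> list[ReferenceProtein]:
    """Per-query-species homologs of each family (the planted 'new' genes)."""
    rng = np.random.default_rng([config.seed, 202])
    pinned = _motif_anchor_positions(config.protein_length)
    r_within = _retention_for_identity(config.within_family_identity)
    out = []
    for fam in sorted(family_ancestors):
        for sp in species_names(config, query=True):
            seq = _mutate(family_ancestors[fam], r_within, rng, pinned)
            out.append(
                ReferenceProtein(
                    id=f"{fam}_{sp}", species=sp, family=fam, sequence=seq
                )
            )
    return out


def _apply_errors(
    window: str, config: SimConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, int]]]:
    """Apply substitutions then 1-2 nt indels; return sequence and indels."""
    bases = "ACGT"
    seq = list(window)
    for i in range(len(seq)):
        if config.substitution_rate and rng.random() < config.substitution_rate:
            alt = [b for b in bases if b != seq[i]]
            seq[i] = alt[rng.integers(3)]
    out: list[str] = []
    shifts: list[tuple[int, str, int]] = []
    i = 0
    while i < len(seq):
        if config.indel_rate and rng.random() < config.indel_rate:
            length = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                shifts.append((len(out), "ins", length))
                for _ in range(length):
                    out.append(bases[rng.integers(4)])
                out.append(seq[i])
                i += 1
            else:
                shifts.append((len(out), "del", length))
                i += length  # current base plus (length-1) more removed
        else:
            out.append(seq[i])
            i += 1
    return "".join(out), shifts


def transcript_of(protein: ReferenceProtein) -> str:
    return back_translate(protein.sequence)


def make_reads(
    panel_member: ReferenceProtein, config: SimConfig
) -> tuple[list[FastqRead], SimTruth]:
    """Tile error-laden reads over the back-translated transcript.

    Read starts are evenly spaced so that the mean coverage matches
    ``config.coverage``; each read is drawn from a random strand.
    """
    transcript = transcript_of(panel_member)
    tlen = len(transcript)
    rlen = min(config.read_length, tlen)
    if config.read_length > 3 * config.protein_length:
        raise ValueError("read_length must be <= 3 * protein_length")
    rng = np.random.default_rng(
        [config.seed, 303, _stable_hash(panel_member.id)]
    )
    n_reads = max(1, round(config.coverage * tlen / rlen))
    if n_reads == 1:
        starts = [0]
    else:
        starts = [round(k * (tlen - rlen) / (n_reads - 1)) for k in range(n_reads)]
    truth = SimTruth()
    tid = f"t_{panel_member.id}"
    truth.transcripts[tid] = (panel_member.species, panel_member.family)
    reads: list[FastqRead] = []
    for k, start in enumerate(starts):
        window = transcript[start : start + rlen]
        strand = "+" if rng.random() < 0.5 else "-"
        errored, shifts = _apply_errors(window, config, rng)
        if strand == "-":
            errored = revcomp(errored)
            shifts = [
                (len(errored) - pos - (length if kind == "ins" else 0), kind, length)
                for pos, kind, length in shifts
            ]
        rid = f"{panel_member.species}_{panel_member.id}_r{k:04d}"
        reads.append(FastqRead(rid, errored))
        truth.reads[rid] = ReadTruth(
            read_id=rid,
            species=panel_member.species,
            family=panel_member.family,
            source_id=tid,
            strand=strand,
            start=start,
            is_decoy=False,
            frameshifts=tuple(shifts),
        )
    return reads, truth


def plant_single_indel(
    transcript: str,
    read_length: int,
    rng: np.random.Generator,
) -> tuple[str, int, str]:
    """A read window carrying exactly one 1-nt indel (healing fixtures).

    Returns ``(read, window_start, kind)`` with kind 'ins' or 'del'.  The
    indel is planted at least 6 codons away from either read end: a
    frameshift closer to an end than the alignment's frameshift penalty can
    recoup is information-theoretically indistinguishable from alignment
    truncation, for this or any local aligner.
    """
    tlen = len(transcript)
    rlen = min(read_length, tlen)
    start = int(rng.integers(0, tlen - rlen + 1))
    window = transcript[start : start + rlen]
    pos = int(rng.integers(18, rlen - 18))
    if rng.random() < 0.5:
        base = "ACGT"[rng.integers(4)]
        read = window[:pos] + base + window[pos:]
        kind = "ins"
    else:
        read = window[:pos] + window[pos + 1 :]
        kind = "del"
    return read, start, kind


def make_decoys(
    config: SimConfig, transcripts: Sequence[str] = ()
) -> tuple[list[FastqRead], SimTruth]:
    """Uniform-random reads plus shuffled-transcript reads, labelled decoy."""
    rng = np.random.default_rng([config.seed, 404])
    reads: list[FastqRead] = []
    truth = SimTruth()
    n_uniform = config.n_decoys - config.n_decoys // 2 if transcripts else config.n_decoys
    shuffled_pool = ""
    if transcripts:
        pool = list("".join(transcripts))
        rng.shuffle(pool)
        shuffled_pool = "".join(pool)
    for k in range(config.n_decoys):
        if k < n_uniform or not shuffled_pool:
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, config.read_length))
        else:
            start = int(rng.integers(0, max(1, len(shuffled_pool) - config.read_length)))
            seq = shuffled_pool[start : start + config.read_length]
        rid = f"decoy_r{k:04d}"
        reads.append(FastqRead(rid, seq))
        truth.reads[rid] = ReadTruth(
            read_id=rid,
            species="decoy",
            family="-",
            source_id="-",
            strand="+",
            start=-1,
            is_decoy=True,
        )
    return reads, truth


def make_domain_alignments(
    panel: Sequence[ReferenceProtein], config: SimConfig
) -> tuple[DomainReferenceAlignment, DomainReferenceAlignment]:
    """Slice two conserved regions of the panel as domain alignments.

    Panel proteins are generated without indels, so column slices are already
    aligned.  The regions mirror the layout of the real Pfam domains on CesA
    proteins, where the Glycos_transf_2 core falls inside the long central
    span of Cellulose_synt: both stand-ins cover the catalytic core, with
    the shorter Glycos_transf_2 block nested in the Cellulose_synt block.
    """
    length = config.protein_length
    cs_start = int(0.30 * length)
    cs_span = (cs_start, cs_start + min(100, length // 3))
    gt2_start = int(0.40 * length)
    gt2_span = (gt2_start, gt2_start + min(60, length // 5))
    rows_gt2 = tuple(p.sequence[gt2_span[0] : gt2_span[1]] for p in panel)
    rows_cs = tuple(p.sequence[cs_span[0] : cs_span[1]] for p in panel)
    ids = tuple(p.id for p in panel)
    return (
        DomainReferenceAlignment(name="Cellulose_synt", ids=ids, rows=rows_cs),
        DomainReferenceAlignment(name="Glycos_transf_2", ids=ids, rows=rows_gt2),
    )


@dataclass
class SimBundle:
    """Everything a full pipeline run needs, generated from one SimConfig."""

    config: SimConfig
    panel: list[ReferenceProtein]
    family_ancestors: dict[str, str]
    query_proteins: list[ReferenceProtein]
    reads: list[FastqRead]
    truth: SimTruth
    domains: tuple[DomainReferenceAlignment, DomainReferenceAlignment]

    @property
    def transcripts(self) -> dict[str, str]:
        return {f"t_{p.id}": transcript_of(p) for p in self.query_proteins}


def simulate_study(config: SimConfig) -> SimBundle:
    """Generate panel, query transcript reads, decoys and domain alignments."""
    panel, ancestors = make_panel(config)
    queries = make_query_proteins(config, ancestors)
    truth = SimTruth()
    reads: list[FastqRead] = []
    for prot in queries:
        r, t = make_reads(prot, config)
        reads.extend(r)
        truth.merge(t)
    decoys, dtruth = make_decoys(
        config, [transcript_of(p) for p in queries]
    )
    reads.extend(decoys)
    truth.merge(dtruth)
    domains = make_domain_alignments(panel, config)
    return SimBundle(
        config=config,
        panel=panel,
        family_ancestors=ancestors,
        query_proteins=queries,
        reads=reads,
        truth=truth,
        domains=domains,
    )


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.fastq())


def read_fastq(path: str | Path) -> list[FastqRead]:
    from Bio import SeqIO

    return [FastqRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_truth(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# read_id\tspecies\tfamily\tsource_id\tstrand\tstart\tis_decoy\tframeshifts\n"
        )
        for rid in sorted(truth.reads):
            t = truth.reads[rid]
            fs = ";".join(f"{p}:{k}:{l}" for p, k, l in t.frameshifts) or "-"
            fh.write(
                f"{t.read_id}\t{t.species}\t{t.family}\t{t.source_id}\t"
                f"{t.strand}\t{t.start}\t{int(t.is_decoy)}\t{fs}\n"
            )
        for tid in sorted(truth.transcripts):
            sp, fam = truth.transcripts[tid]
            fh.write(f"#transcript\t{tid}\t{sp}\t{fam}\n")


def _stable_hash(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode()) & 0x7FFFFFFF
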