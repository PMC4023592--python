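"""Greedy overlap assembly of pre-screened reads into contigs and singletons.

A deliberately simple stand-in for a full overlap-layout-consensus
assembler: reads (or growing contigs) are merged best-overlap-first, where
an overlap is an ungapped suffix-prefix match longer than ``min_overlap``
nucleotides at identity above ``min_overlap_identity`` (the classic
``-o 60 -p 97`` operating point).  Consensus is per-column majority over the
member reads.  Small indels are left in place; the frameshift-tolerant
translated alignment downstream is the stage responsible for healing them.
Under-assembly (one transcript split over several contigs) is tolerated; the
qualitative conclusions drawn from contigs do not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import revcomp

_BASE_IDX = {b: i for i, b in enumerate("ACGTN")}


@dataclass(frozen=True)
class AssemblyConfig:
    min_overlap: int = 60
    min_overlap_identity: float = 0.97

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not (0 < self.min_overlap_identity <= 1):
            raise ValueError("min_overlap_identity must be in (0, 1]")


@dataclass(frozen=True)
class Overlap:
    length: int
    identity: float
    orientation: str  # orientation of b relative to a
    offset: int  # start of b on a


@dataclass
class Contig:
    id: str
    consensus: str
    members: list[tuple[str, int, str]]  # (read_id, offset, strand)

    @property
    def n_members(self) -> int:
        return len(self.members)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX.get(c, 4) for c in seq], dtype=np.int8)


def best_overlap(a: str, b: str, config: AssemblyConfig) -> Optional[Overlap]:
    """Best qualifying ungapped suffix(a)-prefix(b) overlap, both orientations.

    Both thresholds are strict: length must exceed ``min_overlap`` and
    identity must exceed ``min_overlap_identity``.  Ties prefer higher
    identity, then longer overlap, then the plus orientation, then the
    smaller offset.
    """
    ea = _encode(a)
    best: Optional[tuple] = None
    for orientation, bs in (("+", b), ("-", revcomp(b))):
        eb = _encode(bs)
        # match counts for every offset of b on a, via per-base correlation
        matches = np.zeros(len(a) + len(eb) - 1, dtype=np.float64)
        for base in range(4):
            matches += np.correlate(
                (ea == base).astype(np.float64), (eb == base).astype(np.float64), "full"
            )
        for offset in range(0, len(a) - config.min_overlap):
            ovl = min(len(a) - offset, len(eb))
            if ovl <= config.min_overlap:
                break
            identity = matches[offset + len(eb) - 1] / ovl
            if identity <= config.min_overlap_identity:
                continue
            key = (-identity, -ovl, 0 if orientation == "+" else 1, offset)
            if best is None or key < best[0]:
                best = (key, Overlap(ovl, identity, orientation, offset))
    return best[1] if best else None


class _Unit:
    __slots__ = ("uid", "members", "consensus")

    def __init__(self, uid: str, members: list[tuple[str, int, str, str]], consensus: str):
        self.uid = uid
        self.members = members  # (read_id, offset, strand, oriented_seq)
        self.consensus = consensus


def _consensus(members: list[tuple[str, int, str, str]]) -> str:
    length = max(off + len(seq) for _, off, _, seq in members)
    counts = np.zeros((length, 5), dtype=np.int32)
    for _, off, _, seq in members:
        enc = _encode(seq)
        counts[np.arange(off, off + len(seq)), enc] += 1
    winners = counts.argmax(axis=1)
    maxc = counts.max(axis=1)
    # tie columns: take the base of the earliest-offset covering member
    ordered = sorted(members, key=lambda m: (m[1], m[0]))
    bases = "ACGTN"
    out = [bases[w] for w in winners]
    tie_cols = np.where((counts == maxc[:, None]).sum(axis=1) > 1)[0]
    for c in tie_cols:
        for _, off, _, seq in ordered:
            if off <= c < off + len(seq):
                base = seq[c - off]
                if counts[c, _BASE_IDX.get(base, 4)] == maxc[c]:
                    out[c] = base
                    break
    return "".join(out)


def _merge(a: _Unit, b: _Unit, ov: Overlap) -> _Unit:
    members = list(a.members)
    blen = len(b.consensus)
    for rid, off, strand, seq in b.members:
        if ov.orientation == "-":
            off = blen - off - len(seq)
            strand = "-" if strand == "+" else "+"
            seq = revcomp(seq)
        members.append((rid, off + ov.offset, strand, seq))
    uid = min(a.uid, b.uid)
    return _Unit(uid, members, _consensus(members))


def greedy_assemble(
    reads: Iterable[tuple[str, str]], config: AssemblyConfig = AssemblyConfig()
) -> tuple[list[Contig], list[Contig]]:
    """Merge reads best-overlap-first; returns (contigs, singletons).

    The caller is expected to group reads by species beforehand.  The merge
    order is fully determined by (identity, overlap length, unit id pair),
    so permuting the input reads yields the same consensus multiset.
    """
    units: dict[str, _Unit] = {}
    for rid, seq in reads:
        if rid in units:
            raise ValueError(f"duplicate read id {rid!r}")
        units[rid] = _Unit(rid, [(rid, 0, "+", seq)], seq)
    if not units:
        return [], []
    cache: dict[tuple[str, str], Optional[Overlap]] = {}

    def pair_overlap(ua: str, ub: str) -> Optional[Overlap]:
        key = (ua, ub)
        if key not in cache:
            cache[key] = best_overlap(units[ua].consensus, units[ub].consensus, config)
        return cache[key]

    while True:
        best_key = None
        best_pair = None
        for ua in units:
            for ub in units:
                if ua == ub:
                    continue
                ov = pair_overlap(ua, ub)
                if ov is None:
                    continue
                key = (-ov.identity, -ov.length, min(ua, ub), max(ua, ub), ua)
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (ua, ub, ov)
        if best_pair is None:
            break
        ua, ub, ov = best_pair
        merged = _merge(units[ua], units[ub], ov)
        for stale in (ua, ub):
            del units[stale]
        cache = {
            k: v for k, v in cache.items() if ua not in k and ub not in k
        }
        units[merged.uid] = merged

    contigs: list[Contig] = []
    singletons: list[Contig] = []
    for uid in sorted(units):
        u = units[uid]
        c = Contig(
            id=uid,
            consensus=u.consensus,
            members=[(rid, off, strand) for rid, off, strand, _ in u.members],
        )
        (contigs if c.n_members > 1 else singletons).append(c)
    return contigs, singletons


def member_identity(contig: Contig, read_seqs: dict[str, str]) -> dict[str, float]:
    """Per-member identity of each read against the consensus (diagnostics)."""
    out = {}
    for rid, off, strand in contig.members:
        seq = read_seqs[rid]
        if strand == "-":
            seq = revcomp(seq)
        span = contig.consensus[off : off + len(seq)]
        n = min(len(span), len(seq))
        if n == 0:
            out[rid] = 0.0
            continue
        out[rid] = sum(a == b for a, b in zip(span[:n], seq[:n])) / n
    return out


def write_contigs(
    contigs: Sequence[Contig],
    singletons: Sequence[Contig],
    fasta_path,
    members_path,
) -> None:
    with open(fasta_path, "w") as fa:
        for c in list(contigs) + list(singletons):
            fa.write(f">{c.id}\n{c.consensus}\n")
    with open(members_path, "w") as tsv:
        tsv.write("# contig_id\tread_id\toffset\tstrand\n")
        for c in list(contigs) + list(singletons):
            for rid, off, strand in c.members:
                tsv.write(f"{c.id}\t{rid}\t{off}\t{strand}\n")
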