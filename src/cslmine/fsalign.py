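"""Frameshift-tolerant local alignment of nucleotide queries against proteins.

The aligner is a Smith-Waterman-style dynamic program in which one subject
residue can be consumed together with 3 nt (an ordinary codon), 4 nt (a +1
frameshift, emitted as ``/``) or 2 nt (a -1 frameshift, emitted as ``\\``),
in the spirit of the translated-search programs fasty/tfasty.  Frameshifted
codons are translated error-tolerantly: a 4-nt window is read as the best of
its four delete-one triplets, and a 2-nt window as the best amino acid whose
codon contains the observed dinucleotide in order.  For a genuine 1-nt
sequencing indel this recovers the original residue whenever the aligned
subject carries it, which is what makes alignment-guided translation
"healing" work downstream.

Stop codons align to subject residues at a fixed ``stop_score`` and are
emitted as ``*``.  Gaps are affine: the first gap column costs ``gap_open``,
each further column ``gap_extend``.  Both strands are searched; coordinates
on the minus strand refer to the reverse-complemented query.

E-values follow a Karlin-Altschul-shaped model
``E = K * (m/3) * n * exp(-lambda * S)`` with fixed default parameters; only
threshold crossings matter downstream, and the model preserves score order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from ._seq import check_dna, revcomp, translate_codon
from .refpanel import ReferenceProtein

NEG = -1e30
_SEG_OFFSET = 1e9

FRAMESHIFT_FWD = "/"  # +1: codon read from a 4-nt window
FRAMESHIFT_REV = "\\"  # -1: codon read from a 2-nt window
STOP_SYMBOL = "*"
GAP = "-"
_SPECIALS = frozenset((FRAMESHIFT_FWD, FRAMESHIFT_REV, STOP_SYMBOL, GAP))


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for the translated search."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    frameshift_penalty: int = -15
    stop_score: int = -5
    evalue_K: float = 0.1
    evalue_lambda: float = 0.27

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0 or self.frameshift_penalty >= 0:
            raise ValueError("gap and frameshift penalties must be negative")
        if self.evalue_K <= 0 or self.evalue_lambda <= 0:
            raise ValueError("E-value parameters must be positive")


@dataclass
class TranslatedHit:
    """A local DNA-vs-protein alignment with frameshift and stop symbols."""

    query_id: str
    subject_id: str
    subject_family: str
    strand: str
    score: int
    evalue: float
    identity: float
    query_span: tuple[int, int]  # 0-based half-open, nt, on the given strand
    subject_span: tuple[int, int]  # 0-based half-open, aa
    aligned_query_aa: str
    aligned_subject_aa: str

    def __post_init__(self) -> None:
        if len(self.aligned_query_aa) != len(self.aligned_subject_aa):
            raise ValueError("aligned strings differ in length")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")


def evalue(
    score: float, query_len_nt: int, db_residues: int, params: AlignParams
) -> float:
    """Karlin-Altschul-shaped E-value; strictly decreasing in score."""
    if score < 0:
        raise ValueError("score must be >= 0")
    return (
        params.evalue_K
        * (query_len_nt / 3.0)
        * db_residues
        * math.exp(-params.evalue_lambda * score)
    )


# ---------------------------------------------------------------------------
# scoring tables


class _Tables:
    """Per-params lookup tables for codon candidate sets.

    Every (move kind, k-mer) pair maps to a set of candidate symbols; a set
    maps to a per-subject-residue score row (max over candidates) and a
    per-subject-residue best emission symbol.
    """

    def __init__(self, params: AlignParams) -> None:
        mat = substitution_matrices.load(params.matrix_name)
        self.alphabet: str = str(mat.alphabet)
        self.aa_idx: dict[str, int] = {c: i for i, c in enumerate(self.alphabet)}
        self.x_idx = self.aa_idx["X"]
        self.sub = np.asarray(mat, dtype=np.float64)
        self.stop_score = float(params.stop_score)
        self._set_ids: dict[frozenset, int] = {}
        self._rows: list[np.ndarray] = []
        self._best: list[np.ndarray] = []
        self._scores_arr: Optional[np.ndarray] = None
        self._best_arr: Optional[np.ndarray] = None
        self._kmer_cache: dict[tuple[int, str], int] = {}
        for bases in _iter_kmers(3):
            self._kmer_id(3, bases)
        for bases in _iter_kmers(2):
            self._kmer_id(2, bases)
        for bases in _iter_kmers(4):
            self._kmer_id(4, bases)

    # -- candidate sets ----------------------------------------------------
    def _candidates(self, kind: int, kmer: str) -> frozenset:
        if kind == 3:
            return frozenset((translate_codon(kmer),))
        if kind == 4:
            return frozenset(
                translate_codon(kmer[:p] + kmer[p + 1 :]) for p in range(4)
            )
        # kind == 2: one unknown position inside the codon
        return frozenset(
            translate_codon(kmer[:p] + b + kmer[p:])
            for p in range(3)
            for b in "ACGT"
        )

    def _symbol_row(self, sym: str) -> np.ndarray:
        if sym == STOP_SYMBOL:
            return np.full(len(self.alphabet), self.stop_score)
        return self.sub[self.aa_idx.get(sym, self.x_idx)]

    def _register(self, symbols: frozenset) -> int:
        if symbols in self._set_ids:
            return self._set_ids[symbols]
        ordered = sorted(symbols)
        rows = np.stack([self._symbol_row(s) for s in ordered])
        scores = rows.max(axis=0)
        best_pos = rows.argmax(axis=0)  # first (sorted) argmax: deterministic
        best = np.array([ordered[p] for p in best_pos], dtype="<U1")
        sid = len(self._rows)
        self._set_ids[symbols] = sid
        self._rows.append(scores)
        self._best.append(best)
        self._scores_arr = None
        self._best_arr = None
        return sid

    def _kmer_id(self, kind: int, kmer: str) -> int:
        key = (kind, kmer)
        if key not in self._kmer_cache:
            self._kmer_cache[key] = self._register(self._candidates(kind, kmer))
        return self._kmer_cache[key]

    @property
    def scores_arr(self) -> np.ndarray:
        if self._scores_arr is None:
            self._scores_arr = np.stack(self._rows)
        return self._scores_arr

    @property
    def best_arr(self) -> np.ndarray:
        if self._best_arr is None:
            self._best_arr = np.stack(self._best)
        return self._best_arr

    # -- sequence encoding -------------------------------------------------
    def encode_query(self, seq: str) -> dict[int, np.ndarray]:
        """set-id arrays for each move kind; index i = nt consumed so far."""
        n = len(seq)
        codes = {k: np.full(n + 1, -1, dtype=np.int64) for k in (2, 3, 4)}
        for k in (2, 3, 4):
            arr = codes[k]
            for i in range(k, n + 1):
                arr[i] = self._kmer_id(k, seq[i - k : i])
        return codes

    def encode_protein(self, seq: str) -> np.ndarray:
        return np.array(
            [self.aa_idx.get(c, self.x_idx) for c in seq.upper()], dtype=np.int64
        )


@lru_cache(maxsize=8)
def _tables(params: AlignParams) -> _Tables:
    return _Tables(params)


def _iter_kmers(k: int):
    from itertools import product

    for tup in product("ACGT", repeat=k):
        yield "".join(tup)


# ---------------------------------------------------------------------------
# fast score-only pass over a concatenated panel


class PanelIndex:
    """Concatenated, sentinel-separated panel for the score-only DP pass."""

    def __init__(self, panel: Sequence[ReferenceProtein], params: AlignParams):
        if not panel:
            raise ValueError("panel must be non-empty")
        tab = _tables(params)
        self.params = params
        self.panel = list(panel)
        self.db_residues = sum(len(p.sequence) for p in panel)
        cols: list[int] = []
        sent: list[bool] = []
        segid: list[int] = []
        self.segments: list[tuple[int, int]] = []
        for k, prot in enumerate(panel):
            cols.append(0)
            sent.append(True)
            segid.append(k)
            start = len(cols)
            cols.extend(tab.encode_protein(prot.sequence).tolist())
            sent.extend([False] * len(prot.sequence))
            segid.extend([k] * len(prot.sequence))
            self.segments.append((start, len(cols)))
        self.prot_idx = np.array(cols, dtype=np.int64)
        self.sentinel = np.array(sent, dtype=bool)
        self.segbase = _SEG_OFFSET * np.array(segid, dtype=np.float64)


def _score_pass(
    seq: str, pidx: PanelIndex, params: AlignParams
) -> np.ndarray:
    """Best local score per panel subject for one query strand."""
    tab = _tables(params)
    codes = tab.encode_query(seq)
    scores_arr = tab.scores_arr
    n = len(seq)
    C = len(pidx.prot_idx)
    go, ge, fs = (
        float(params.gap_open),
        float(params.gap_extend),
        float(params.frameshift_penalty),
    )
    neg_row = np.full(C, NEG)
    Hbuf = [neg_row.copy() for _ in range(5)]
    Fbuf = [neg_row.copy() for _ in range(4)]
    Hbuf[0] = np.zeros(C)
    colmax = np.zeros(C)
    arange = np.arange(C, dtype=np.float64)
    ge_ar = ge * arange
    sent = pidx.sentinel
    moves = ((3, 0.0), (2, fs), (4, fs))
    for i in range(1, n + 1):
        m_cand = neg_row
        for k, pen in moves:
            code = codes[k][i]
            if code < 0:
                continue
            hprev = Hbuf[(i - k) % 5] if i - k >= 0 else None
            if hprev is None:
                continue
            vec = scores_arr[code][pidx.prot_idx]
            cand = np.empty(C)
            cand[0] = NEG
            np.add(hprev[:-1], vec[1:], out=cand[1:])
            if pen:
                cand[1:] += pen
            m_cand = np.maximum(m_cand, cand)
        if i >= 3:
            F_new = np.maximum(Hbuf[(i - 3) % 5] + go, Fbuf[(i - 3) % 4] + ge)
        else:
            F_new = neg_row
        Htmp = np.maximum(m_cand, F_new)
        np.maximum(Htmp, 0.0, out=Htmp)
        Htmp[sent] = 0.0
        # gap-in-query scan, blocked at segment boundaries
        B = Htmp - ge_ar + pidx.segbase
        R = np.maximum.accumulate(B)
        E = np.empty(C)
        E[0] = NEG
        E[1:] = (go - ge) + ge_ar[1:] + (R[:-1] - pidx.segbase[1:])
        H_new = np.maximum(Htmp, E)
        H_new[sent] = 0.0
        np.maximum(colmax, H_new, out=colmax)
        Hbuf[i % 5] = H_new
        Fbuf[i % 4] = F_new
    out = np.empty(len(pidx.segments))
    for k, (s, e) in enumerate(pidx.segments):
        out[k] = colmax[s:e].max() if e > s else 0.0
    return out


# ---------------------------------------------------------------------------
# full single-pair DP with traceback


@dataclass
class _Alignment:
    score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    qstr: str
    sstr: str


def _align_detail(seq: str, prot: str, params: AlignParams) -> Optional[_Alignment]:
    tab = _tables(params)
    codes = tab.encode_query(seq)
    scores_arr = tab.scores_arr
    best_arr = tab.best_arr
    pidx = tab.encode_protein(prot)
    n, m = len(seq), len(prot)
    go, ge, fs = (
        float(params.gap_open),
        float(params.gap_extend),
        float(params.frameshift_penalty),
    )
    H = np.full((n + 1, m + 1), NEG)
    Htmp = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H[0] = 0.0
    Htmp[0] = 0.0
    arange = np.arange(m + 1, dtype=np.float64)
    ge_ar = ge * arange
    moves = ((3, 0.0), (2, fs), (4, fs))
    for i in range(1, n + 1):
        m_cand = np.full(m + 1, NEG)
        for k, pen in moves:
            code = codes[k][i]
            if code < 0 or i - k < 0:
                continue
            vec = scores_arr[code][pidx]
            m_cand[1:] = np.maximum(m_cand[1:], H[i - k, :-1] + vec + pen)
        if i >= 3:
            F[i] = np.maximum(H[i - 3] + go, F[i - 3] + ge)
        row = np.maximum(m_cand, F[i])
        np.maximum(row, 0.0, out=row)
        Htmp[i] = row
        B = row - ge_ar
        R = np.maximum.accumulate(B)
        E[i, 1:] = (go - ge) + ge_ar[1:] + R[:-1]
        H[i] = np.maximum(row, E[i])
    best = float(H.max())
    if best <= 0:
        return None
    # deterministic argmax: smallest i, then smallest j
    flat = int(np.argmax(H.ravel()))
    bi, bj = divmod(flat, m + 1)
    qcols: list[str] = []
    scols: list[str] = []
    i, j = bi, bj
    state = "TOP"
    while True:
        if state == "TOP":
            state = "B" if H[i, j] == Htmp[i, j] else "E"
            continue
        if state == "B":
            val = Htmp[i, j]
            if val == 0.0:
                break
            matched = False
            for k, pen in moves:
                code = codes[k][i]
                if code < 0 or j < 1:
                    continue
                sc = scores_arr[code][pidx[j - 1]] + pen
                if val == H[i - k, j - 1] + sc:
                    sym = str(best_arr[code][pidx[j - 1]])
                    qcols.append(sym)
                    scols.append(prot[j - 1])
                    if k == 4:
                        qcols.append(FRAMESHIFT_FWD)
                        scols.append(GAP)
                    elif k == 2:
                        qcols.append(FRAMESHIFT_REV)
                        scols.append(GAP)
                    i, j = i - k, j - 1
                    state = "TOP"
                    matched = True
                    break
            if matched:
                continue
            if val == F[i, j]:
                state = "F"
                continue
            raise AssertionError("traceback failed in block state")
        if state == "F":
            qcols.append(translate_codon(seq[i - 3 : i]))
            scols.append(GAP)
            if F[i, j] == H[i - 3, j] + go:
                i, state = i - 3, "TOP"
            elif F[i, j] == F[i - 3, j] + ge:
                i = i - 3
            else:
                raise AssertionError("traceback failed in F state")
            continue
        if state == "E":
            qcols.append(GAP)
            scols.append(prot[j - 1])
            if E[i, j] == Htmp[i, j - 1] + go:
                j, state = j - 1, "B"
            elif E[i, j] == E[i, j - 1] + ge:
                j = j - 1
            else:
                raise AssertionError("traceback failed in E state")
            continue
    qcols.reverse()
    scols.reverse()
    return _Alignment(
        score=best,
        query_span=(i, bi),
        subject_span=(j, bj),
        qstr="".join(qcols),
        sstr="".join(scols),
    )


def alignment_identity(qstr: str, sstr: str) -> float:
    """Match fraction over columns where both sides are amino-acid letters."""
    pairs = [
        (q, s)
        for q, s in zip(qstr, sstr)
        if q not in _SPECIALS and s != GAP
    ]
    if not pairs:
        return 0.0
    return sum(q == s for q, s in pairs) / len(pairs)


def align_dna_protein(
    dna: str,
    protein: ReferenceProtein,
    params: AlignParams = AlignParams(),
    db_residues: Optional[int] = None,
    query_id: str = "query",
) -> Optional[TranslatedHit]:
    """Best frameshift-tolerant local alignment over both strands.

    Returns ``None`` when no alignment scores above zero.  ``db_residues``
    defaults to the subject length; pass the panel total when the alignment
    is part of a database search so that E-values share one scale.
    """
    seq = check_dna(dna)
    if len(seq) < 3:
        raise ValueError("query must be at least 3 nt")
    best: Optional[_Alignment] = None
    best_strand = "+"
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        aln = _align_detail(s, protein.sequence, params)
        if aln is not None and (best is None or aln.score > best.score):
            best = aln
            best_strand = strand
    if best is None:
        return None
    n_db = db_residues if db_residues is not None else len(protein.sequence)
    return TranslatedHit(
        query_id=query_id,
        subject_id=protein.id,
        subject_family=protein.family,
        strand=best_strand,
        score=int(best.score),
        evalue=evalue(best.score, len(seq), n_db, params),
        identity=alignment_identity(best.qstr, best.sstr),
        query_span=best.query_span,
        subject_span=best.subject_span,
        aligned_query_aa=best.qstr,
        aligned_subject_aa=best.sstr,
    )


def search_best_hits(
    queries: Iterable[tuple[str, str]],
    panel: Sequence[ReferenceProtein],
    params: AlignParams = AlignParams(),
    evalue_cap: float = 1e-3,
) -> dict[str, TranslatedHit]:
    """Best panel hit per query under an E-value cap.

    Ties on E-value (hence score) are broken toward the lexicographically
    smallest subject id, then the plus strand.  Queries without a qualifying
    hit are absent from the result.
    """
    pidx = PanelIndex(panel, params)
    hits: dict[str, TranslatedHit] = {}
    for qid, raw in queries:
        seq = check_dna(raw)
        if len(seq) < 3:
            continue
        best_key = None
        best_choice = None
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            per_subject = _score_pass(s, pidx, params)
            for k, sc in enumerate(per_subject):
                if sc <= 0:
                    continue
                key = (-sc, pidx.panel[k].id, 0 if strand == "+" else 1)
                if best_key is None or key < best_key:
                    best_key = key
                    best_choice = (k, strand, sc)
        if best_choice is None:
            continue
        k, strand, sc = best_choice
        ev = evalue(sc, len(seq), pidx.db_residues, params)
        if ev > evalue_cap:
            continue
        subject = pidx.panel[k]
        s = seq if strand == "+" else revcomp(seq)
        aln = _align_detail(s, subject.sequence, params)
        if aln is None or aln.score != sc:  # pragma: no cover - internal check
            raise AssertionError(
                f"score pass ({sc}) and detailed alignment disagree for {qid}"
            )
        hits[qid] = TranslatedHit(
            query_id=qid,
            subject_id=subject.id,
            subject_family=subject.family,
            strand=strand,
            score=int(aln.score),
            evalue=ev,
            identity=alignment_identity(aln.qstr, aln.sstr),
            query_span=aln.query_span,
            subject_span=aln.subject_span,
            aligned_query_aa=aln.qstr,
            aligned_subject_aa=aln.sstr,
        )
    return hits


def write_hits_tsv(hits: Mapping[str, TranslatedHit], path) -> None:
    cols = (
        "query",
        "subject",
        "family",
        "strand",
        "score",
        "evalue",
        "identity",
        "q_start",
        "q_end",
        "s_start",
        "s_end",
        "aligned_query",
        "aligned_subject",
    )
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(cols) + "\n")
        for qid in sorted(hits):
            h = hits[qid]
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.subject_family}\t{h.strand}\t"
                f"{h.score}\t{h.evalue:.6g}\t{h.identity:.4f}\t"
                f"{h.query_span[0]}\t{h.query_span[1]}\t"
                f"{h.subject_span[0]}\t{h.subject_span[1]}\t"
                f"{h.aligned_query_aa}\t{h.aligned_subject_aa}\n"
            )
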