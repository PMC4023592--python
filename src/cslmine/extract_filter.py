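"""Alignment-guided translation healing and candidate qualification filters.

Contigs and singletons are translated "according to the alignment with their
best hit": the query side of the frameshift-tolerant alignment is taken and
the frameshift (``/``, ``\\``), stop (``*``) and gap (``-``) symbols are
deleted, yielding a clean peptide.  Candidates must then pass three filters
to qualify: (i) best-hit E-value below ``best_hit_evalue_max``; (ii) both
domain profiles matched below ``domain_evalue_max``; (iii) length strictly
greater than ``min_peptide_length``.  All inequalities are strict.  Short
peptides can be rescued only through an explicit allowlist, mirroring manual
inspection of sub-length homologs.

Domain profiles are per-column log-odds matrices built from the packaged
domain reference alignments; significance is calibrated empirically against
shuffled-peptide nulls with an exponential tail fit, so only the threshold
crossing (not HMMER's exact statistics) is reproduced.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import AMINO_ACIDS
from .fsalign import TranslatedHit, _SPECIALS
from .refpanel import DomainReferenceAlignment

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_BACKGROUND = 1.0 / 20.0
_SCORE_FLOOR = -10.0
_MIN_PEPTIDE_FOR_SCAN = 10


@dataclass(frozen=True)
class FilterConfig:
    best_hit_evalue_max: float = 1e-10
    domain_evalue_max: float = 1e-2
    min_peptide_length: int = 150  # documented alternates: 100, 200
    require_both_domains: bool = True

    def __post_init__(self) -> None:
        if self.best_hit_evalue_max <= 0 or self.domain_evalue_max <= 0:
            raise ValueError("E-value thresholds must be positive")
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")


@dataclass
class DomainProfile:
    """Position-specific log-odds scores over the 20 amino acids."""

    name: str
    columns: np.ndarray  # (length, 20)

    def __post_init__(self) -> None:
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise ValueError("profile columns must be (length, 20)")
        if len(self.columns) < 10:
            raise ValueError("profile needs >= 10 columns")
        if not np.isfinite(self.columns).all():
            raise ValueError("profile scores must be finite")

    @property
    def length(self) -> int:
        return len(self.columns)

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.columns.argmax(axis=1))


@dataclass
class CandidatePeptide:
    id: str
    species: str
    peptide: str
    source: str
    best_hit: TranslatedHit
    length: int = 0
    passed_filters: Optional[tuple[bool, bool, bool]] = None
    domain_evalues: dict = field(default_factory=dict)
    has_motif: Optional[bool] = None

    def __post_init__(self) -> None:
        if any(c in self.peptide for c in "/\\*-"):
            raise ValueError(f"peptide {self.id!r} contains alignment symbols")
        self.length = len(self.peptide)


def heal_translate(hit: TranslatedHit) -> str:
    """Strip frameshift, stop and gap symbols from the aligned query string."""
    if not hit.aligned_query_aa:
        raise ValueError("hit has empty aligned strings")
    return "".join(c for c in hit.aligned_query_aa if c not in _SPECIALS)


def build_profile(
    alignment: DomainReferenceAlignment, pseudocount: float = 1.0
) -> DomainProfile:
    """Per-column log-odds of residue frequencies against a uniform background.

    Columns with more than 50% gaps are dropped.  With ``pseudocount -> 0`` a
    single-residue column scores ``ln(1/0.05)`` for that residue and the
    floor value for all others.
    """
    if len(alignment.rows) < 2:
        raise ValueError("alignment must have >= 2 rows")
    nrow = len(alignment.rows)
    keep_cols = []
    for c in range(alignment.n_columns):
        column = [r[c] for r in alignment.rows]
        gaps = sum(ch == "-" for ch in column)
        if gaps / nrow > 0.5:
            continue
        keep_cols.append(column)
    scores = np.empty((len(keep_cols), 20))
    for k, column in enumerate(keep_cols):
        counts = np.zeros(20)
        for ch in column:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        total = counts.sum() + pseudocount
        freqs = (counts + pseudocount / 20.0) / total
        with np.errstate(divide="ignore"):
            col = np.log(freqs / _BACKGROUND)
        scores[k] = np.maximum(col, _SCORE_FLOOR)
    return DomainProfile(name=alignment.name, columns=scores)


def _encode_peptide(peptide: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, -1) for c in peptide.upper()], dtype=np.int64)


def profile_score(peptide: str, profile: DomainProfile) -> float:
    """Best ungapped placement of the profile on the peptide.

    The profile may hang off either end as long as at least 10 columns
    overlap; residues outside the 20-letter alphabet (e.g. X) score 0.
    """
    if len(peptide) < _MIN_PEPTIDE_FOR_SCAN:
        return -math.inf
    enc = _encode_peptide(peptide)
    L = profile.length
    pad = L - _MIN_PEPTIDE_FOR_SCAN
    padded = np.concatenate(
        [np.full(pad, -1, dtype=np.int64), enc, np.full(pad, -1, dtype=np.int64)]
    )
    n_off = len(padded) - L + 1
    cols = np.concatenate([profile.columns, np.zeros((L, 1))], axis=1)  # -1 -> 0
    total = np.zeros(n_off)
    for c in range(L):
        total += cols[c][padded[c : c + n_off]]
    return float(total.max())


@dataclass
class ProfileCalibration:
    """Empirical null distribution of profile scores on shuffled peptides."""

    profile_name: str
    scores: np.ndarray  # sorted ascending
    tail_threshold: float
    tail_mean_excess: float

    @property
    def n(self) -> int:
        return len(self.scores)


def calibrate_profile(
    profile: DomainProfile,
    peptide: str,
    n_shuffles: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> ProfileCalibration:
    """Score ``n_shuffles`` residue shuffles of ``peptide`` against the profile."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    chars = np.array(list(peptide))
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        rng.shuffle(chars)
        scores[k] = profile_score("".join(chars), profile)
    scores.sort()
    u = float(np.quantile(scores, 0.9))
    tail = scores[scores >= u]
    beta = float(np.mean(tail - u)) if len(tail) else 0.0
    return ProfileCalibration(
        profile_name=profile.name,
        scores=scores,
        tail_threshold=u,
        tail_mean_excess=beta,
    )


def profile_search(
    peptide: str, profile: DomainProfile, calibration: ProfileCalibration
) -> tuple[float, float]:
    """Best profile score and its empirical E-value.

    The E-value is the expected count of null scores at least as large,
    extrapolated beyond the observed null range with an exponential tail fit
    (mean-excess estimate over the top decile).  Peptides shorter than 10
    residues get an infinite E-value sentinel.
    """
    if calibration.n == 0:
        raise ValueError("empty calibration")
    if calibration.profile_name != profile.name:
        raise ValueError("calibration was built for a different profile")
    if len(peptide) < _MIN_PEPTIDE_FOR_SCAN:
        return -math.inf, math.inf
    score = profile_score(peptide, profile)
    n = calibration.n
    u, beta = calibration.tail_threshold, calibration.tail_mean_excess
    if score > u and beta > 0:
        p_tail = float((calibration.scores >= u).sum()) / n
        return score, n * p_tail * math.exp(-(score - u) / beta)
    count = n - int(np.searchsorted(calibration.scores, score, side="left"))
    if count > 0:
        return score, float(count)
    # degenerate null (all scores equal) with a score above it: no tail to
    # fit, report a conservative sub-unit expected count
    return score, 0.5


def default_calibration_rng(seed: int, peptide_id: str) -> np.random.Generator:
    """Deterministic per-peptide RNG for calibration shuffles."""
    return np.random.default_rng([seed, zlib.crc32(peptide_id.encode()) & 0x7FFFFFFF])


def apply_filters(
    candidates: Sequence[CandidatePeptide],
    profiles: Sequence[DomainProfile],
    config: FilterConfig = FilterConfig(),
    allowlist: frozenset[str] = frozenset(),
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[CandidatePeptide]:
    """Apply the three qualification filters; returns the qualified subset.

    Every candidate gets its ``passed_filters`` flags and per-domain E-values
    recorded regardless of the outcome, so the full ledger can be reported.
    ``allowlist`` ids bypass only the length filter (the manual-inspection
    rescue path).
    """
    qualified = []
    for cand in candidates:
        f1 = cand.best_hit.evalue < config.best_hit_evalue_max
        domain_pass = []
        for profile in profiles:
            rng = default_calibration_rng(seed, cand.id)
            calib = calibrate_profile(profile, cand.peptide, n_shuffles, rng)
            _, ev = profile_search(cand.peptide, profile, calib)
            cand.domain_evalues[profile.name] = ev
            domain_pass.append(ev < config.domain_evalue_max)
        f2 = all(domain_pass) if config.require_both_domains else any(domain_pass)
        f3 = cand.length > config.min_peptide_length or cand.id in allowlist
        cand.passed_filters = (f1, f2, f3)
        if f1 and f2 and f3:
            qualified.append(cand)
    return qualified


def write_filter_ledger(
    candidates: Sequence[CandidatePeptide], path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# id\tspecies\tbest_hit_family\tbest_hit_evalue\t"
            "Cellulose_synt_evalue\tGlycos_transf_2_evalue\tlength\t"
            "pass_similarity\tpass_domains\tpass_length\thas_motif\n"
        )
        for cand in sorted(candidates, key=lambda c: c.id):
            flags = cand.passed_filters or (False, False, False)
            d1 = cand.domain_evalues.get("Cellulose_synt", math.inf)
            d2 = cand.domain_evalues.get("Glycos_transf_2", math.inf)
            motif = "-" if cand.has_motif is None else str(int(cand.has_motif))
            fh.write(
                f"{cand.id}\t{cand.species}\t{cand.best_hit.subject_family}\t"
                f"{cand.best_hit.evalue:.6g}\t{d1:.6g}\t{d2:.6g}\t{cand.length}\t"
                f"{int(flags[0])}\t{int(flags[1])}\t{int(flags[2])}\t{motif}\n"
            )


def write_peptides_fasta(candidates: Iterable[CandidatePeptide], path) -> None:
    with open(path, "w") as fh:
        for cand in sorted(candidates, key=lambda c: c.id):
            fh.write(f">{cand.id}\n{cand.peptide}\n")


def load_allowlist(path) -> frozenset[str]:
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return frozenset(ids)
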