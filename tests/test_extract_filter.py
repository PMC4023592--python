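"""Healed translation, domain profiles and the three qualification filters."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cslmine.extract_filter import (
    CandidatePeptide,
    FilterConfig,
    ProfileCalibration,
    apply_filters,
    build_profile,
    calibrate_profile,
    heal_translate,
    profile_score,
    profile_search,
)
from cslmine.fsalign import AlignParams, TranslatedHit, align_dna_protein
from cslmine.refpanel import DomainReferenceAlignment, ReferenceProtein
from cslmine.simdata import SimConfig, make_panel, plant_single_indel, transcript_of

from conftest import random_protein


def _hit(qaa: str, saa: str, ev: float = 1e-20) -> TranslatedHit:
    return TranslatedHit(
        query_id="q",
        subject_id="s",
        subject_family="CesA",
        strand="+",
        score=100,
        evalue=ev,
        identity=0.9,
        query_span=(0, 3 * len(qaa)),
        subject_span=(0, len(saa)),
        aligned_query_aa=qaa,
        aligned_subject_aa=saa,
    )


class TestHealTranslate:
    def test_symbol_stripping(self):
        hit = _hit("MKL/VDQ*RW", "MKLQVDQARW")
        assert heal_translate(hit) == "MKLVDQRW"

    def test_identity_when_clean(self):
        hit = _hit("MKLV", "MKLV")
        assert heal_translate(hit) == "MKLV"

    def test_gap_columns_removed(self):
        hit = _hit("MK-LV", "MKQLV")
        assert heal_translate(hit) == "MKLV"

    def test_planted_indel_read_heals_to_substring(self):
        cfg = SimConfig(n_families=2, n_species=2, protein_length=150,
                        read_length=300, seed=41)
        panel, _ = make_panel(cfg)
        rng = np.random.default_rng(5)
        prot = panel[1]
        read, _, _ = plant_single_indel(transcript_of(prot), 300, rng)
        hit = align_dna_protein(read, prot, AlignParams())
        assert heal_translate(hit) in prot.sequence

    def test_error_free_read_equals_plain_translation(self):
        from cslmine._seq import back_translate, translate_frame

        pep = random_protein(np.random.default_rng(9), 60)
        dna = back_translate(pep)
        prot = ReferenceProtein(id="p", species="s", family="CesA", sequence=pep)
        hit = align_dna_protein(dna, prot, AlignParams())
        assert heal_translate(hit) == translate_frame(dna)


class TestBuildProfile:
    def test_single_residue_column_log_odds(self):
        aln = DomainReferenceAlignment(
            name="Cellulose_synt",
            ids=tuple("abcd"),
            rows=("A" * 12, "A" * 12, "A" * 12, "A" * 12),
        )
        profile = build_profile(aln, pseudocount=1e-9)
        a_idx = 0  # 'A' is first in the amino-acid ordering used
        col = profile.columns[0]
        assert col[a_idx] == pytest.approx(math.log(20), abs=1e-4)
        assert all(c == -10.0 for k, c in enumerate(col) if k != a_idx)

    def test_uniform_column_scores_near_zero(self):
        aas = "ARNDCQEGHILKMFPSTWYV"
        rows = tuple(a * 12 for a in aas)
        aln = DomainReferenceAlignment(name="Cellulose_synt", ids=tuple(aas), rows=rows)
        profile = build_profile(aln, pseudocount=0.0)
        assert np.abs(profile.columns).max() < 1e-9

    def test_majority_gap_columns_dropped(self):
        aln = DomainReferenceAlignment(
            name="Cellulose_synt",
            ids=tuple("abc"),
            rows=("A" * 10 + "-A", "A" * 10 + "-A", "A" * 10 + "AA"),
        )
        profile = build_profile(aln)
        assert profile.length == 11

    def test_consensus_outscores_any_member(self, small_panel):
        from cslmine.simdata import make_domain_alignments

        panel, _ = small_panel
        cfg = SimConfig(n_families=3, n_species=2, protein_length=150,
                        read_length=200, seed=11)
        aln, _ = make_domain_alignments(panel, cfg)
        profile = build_profile(aln)
        cons = profile_score(profile.consensus, profile)
        assert all(cons >= profile_score(r, profile) for r in aln.rows)

    def test_too_few_rows_rejected(self):
        aln = DomainReferenceAlignment(
            name="Cellulose_synt", ids=("a", "b"), rows=("A" * 12, "A" * 12)
        )
        object.__setattr__(aln, "rows", ("A" * 12,))
        with pytest.raises(ValueError):
            build_profile(aln)


class TestProfileSearch:
    def _profile(self, seed=13):
        cfg = SimConfig(n_families=3, n_species=2, protein_length=150,
                        read_length=200, seed=seed)
        panel, _ = make_panel(cfg)
        from cslmine.simdata import make_domain_alignments

        return build_profile(make_domain_alignments(panel, cfg)[0])

    def test_consensus_is_significant_against_its_own_shuffles(self):
        profile = self._profile()
        pep = profile.consensus
        calib = calibrate_profile(profile, pep, 1000, np.random.default_rng(3))
        _, ev = profile_search(pep, profile, calib)
        assert ev < 1e-2

    def test_random_peptide_is_insignificant(self):
        profile = self._profile()
        rng = np.random.default_rng(4)
        evs = []
        for _ in range(30):
            pep = random_protein(rng, 120)
            calib = calibrate_profile(profile, pep, 200, rng)
            evs.append(profile_search(pep, profile, calib)[1])
        assert np.mean(evs) >= 0.5

    def test_short_peptide_gets_infinite_sentinel(self):
        profile = self._profile()
        calib = calibrate_profile(profile, "MKLVAAAGHRTW", 50, np.random.default_rng(1))
        _, ev = profile_search("MKLV", profile, calib)
        assert math.isinf(ev)

    def test_empty_calibration_rejected(self):
        profile = self._profile()
        with pytest.raises(ValueError):
            calibrate_profile(profile, "MKLVAAAGHRTW", 0)
        calib = ProfileCalibration(
            profile_name=profile.name,
            scores=np.array([]),
            tail_threshold=0.0,
            tail_mean_excess=0.0,
        )
        with pytest.raises(ValueError, match="empty"):
            profile_search("MKLVAAAGHRTW" * 3, profile, calib)


class TestApplyFilters:
    def _candidate(self, pep_len=200, ev=1e-11, cid="c1") -> CandidatePeptide:
        rng = np.random.default_rng(hash(cid) % 2**31)
        return CandidatePeptide(
            id=cid,
            species="sp1",
            peptide=random_protein(rng, pep_len),
            source="ctg1",
            best_hit=_hit("MKLV", "MKLV", ev=ev),
        )

    def _profiles(self):
        cfg = SimConfig(n_families=3, n_species=2, protein_length=150,
                        read_length=200, seed=13)
        panel, _ = make_panel(cfg)
        from cslmine.simdata import make_domain_alignments

        return [build_profile(a) for a in make_domain_alignments(panel, cfg)]

    def test_similarity_boundary_is_strict(self):
        profiles = self._profiles()
        at = self._candidate(ev=1e-10, cid="at")
        inside = self._candidate(ev=0.99e-10, cid="in")
        kept = apply_filters([at, inside], profiles, FilterConfig(), n_shuffles=50)
        assert at.passed_filters[0] is False
        assert inside.passed_filters[0] is True
        assert at not in kept

    def test_length_boundary_is_strict(self):
        profiles = self._profiles()
        at = self._candidate(pep_len=150, cid="len150")
        inside = self._candidate(pep_len=151, cid="len151")
        apply_filters([at, inside], profiles, FilterConfig(), n_shuffles=50)
        assert at.passed_filters[2] is False
        assert inside.passed_filters[2] is True

    def test_domain_boundary_is_strict(self):
        profiles = self._profiles()
        cand = self._candidate(cid="dom")
        apply_filters([cand], profiles, FilterConfig(), n_shuffles=50)
        measured = max(cand.domain_evalues.values())
        # thresholds exactly at / just above a measured E-value
        at = FilterConfig(domain_evalue_max=measured)
        above = FilterConfig(domain_evalue_max=measured * 1.01)
        apply_filters([cand], profiles, at, n_shuffles=50)
        rejected = cand.passed_filters[1]
        apply_filters([cand], profiles, above, n_shuffles=50)
        accepted = cand.passed_filters[1]
        assert rejected is False and accepted is True

    def test_planted_peptide_qualifies_and_random_does_not(self):
        profiles = self._profiles()
        cfg = SimConfig(n_families=3, n_species=2, protein_length=150,
                        read_length=200, seed=13)
        panel, _ = make_panel(cfg)
        good = CandidatePeptide(
            id="good", species="sp1", peptide=panel[0].sequence,
            source="ctg", best_hit=_hit("MKLV", "MKLV", ev=1e-12),
        )
        junk = self._candidate(cid="junk", ev=1e-12)
        kept = apply_filters(
            [good, junk], profiles, FilterConfig(min_peptide_length=100),
            n_shuffles=300,
        )
        assert kept == [good]

    def test_allowlist_rescues_short_peptide_only(self):
        profiles = self._profiles()
        cfg = SimConfig(n_families=3, n_species=2, protein_length=150,
                        read_length=200, seed=13)
        panel, _ = make_panel(cfg)
        short = CandidatePeptide(
            id="short", species="sp1", peptide=panel[0].sequence[:120],
            source="ctg", best_hit=_hit("MKLV", "MKLV", ev=1e-12),
        )
        kept = apply_filters([short], profiles, FilterConfig(), n_shuffles=300)
        assert kept == []
        kept = apply_filters(
            [short], profiles, FilterConfig(), allowlist=frozenset({"short"}),
            n_shuffles=300,
        )
        assert kept == [short]

    def test_qualified_set_shrinks_as_thresholds_tighten(self):
        profiles = self._profiles()
        cfg = SimConfig(n_families=3, n_species=2, protein_length=150,
                        read_length=200, seed=13)
        panel, _ = make_panel(cfg)
        cands = [
            CandidatePeptide(
                id=f"c{k}", species="sp1", peptide=p.sequence[: 110 + 20 * k],
                source="ctg", best_hit=_hit("MKLV", "MKLV", ev=10.0 ** (-9 - k)),
            )
            for k, p in enumerate(panel)
        ]
        loose = FilterConfig(best_hit_evalue_max=1e-8, min_peptide_length=100)
        tight = FilterConfig(best_hit_evalue_max=1e-11, min_peptide_length=140)
        kept_loose = {c.id for c in apply_filters(cands, profiles, loose, n_shuffles=100)}
        kept_tight = {c.id for c in apply_filters(cands, profiles, tight, n_shuffles=100)}
        assert kept_tight <= kept_loose

    def test_peptide_with_symbols_rejected(self):
        with pytest.raises(ValueError, match="symbols"):
            CandidatePeptide(
                id="bad", species="s", peptide="MK/LV", source="x",
                best_hit=_hit("MKLV", "MKLV"),
            )
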