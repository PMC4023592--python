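"""Scoring a pipeline run against the simulation truth tables.

Only meaningful for simulated studies: reads the truth TSV written by the
simulate stage plus the pipeline outputs, and reports planted-transcript
recovery, family-verdict accuracy and decoy leakage.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO


def _read_truth(path: Path):
    reads: dict[str, dict] = {}
    transcripts: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#transcript\t"):
                _, tid, sp, fam = line.split("\t")
                transcripts[tid] = (sp, fam)
                continue
            if line.startswith("#") or not line:
                continue
            f = line.split("\t")
            reads[f[0]] = {
                "species": f[1],
                "family": f[2],
                "source": f[3],
                "is_decoy": f[6] == "1",
            }
    return reads, transcripts


def _read_members(path: Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            unit, rid, *_ = line.rstrip("\n").split("\t")
            out.setdefault(unit, []).append(rid)
    return out


def evaluate_run(outdir: str | Path) -> dict:
    """Compare a finished simulated run with its own truth tables.

    Returns planted-transcript recovery, member-verdict accuracy,
    wrong-family member count and decoy leakage, plus the raw sizes needed
    to interpret them.
    """
    outdir = Path(outdir)
    read_truth, transcripts = _read_truth(outdir / "truth.tsv")
    members = _read_members(outdir / "contig_members.tsv")

    source_unit: dict[str, str] = {}
    with open(outdir / "candidate_meta.tsv") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            source_unit[f[0]] = f[2]

    qualified = [rec.id for rec in SeqIO.parse(str(outdir / "qualified.fasta"), "fasta")]

    def unit_truth(unit: str) -> tuple[set, bool]:
        """(source transcripts, any_decoy) over a unit's member reads."""
        srcs, decoy = set(), False
        for rid in members.get(unit, []):
            t = read_truth.get(rid)
            if t is None:
                continue
            if t["is_decoy"]:
                decoy = True
            elif t["source"] != "-":
                srcs.add(t["source"])
        return srcs, decoy

    recovered: set = set()
    decoys_qualified = 0
    peptide_family: dict[str, str] = {}
    for pid in qualified:
        unit = source_unit[pid]
        srcs, decoy = unit_truth(unit)
        if decoy and not srcs:
            decoys_qualified += 1
            continue
        recovered |= srcs
        fams = {transcripts[s][1] for s in srcs}
        if len(fams) == 1:
            peptide_family[pid] = fams.pop()

    verdicts: dict[str, tuple[str, tuple[str, ...]]] = {}
    assignments_path = outdir / "assignments.tsv"
    if assignments_path.exists():
        with open(assignments_path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                fams = tuple(f[3].split(",")) if f[3] not in ("-",) else ()
                verdicts[f[0]] = (f[2], fams)

    correct = wrong_family = 0
    for pid, true_family in peptide_family.items():
        verdict, fams = verdicts.get(pid, ("missing", ()))
        if verdict == "member":
            if fams == (true_family,):
                correct += 1
            else:
                wrong_family += 1

    n_scored = len(peptide_family)
    n_transcripts = len(transcripts)
    return {
        "n_transcripts": n_transcripts,
        "n_qualified": len(qualified),
        "n_scored_peptides": n_scored,
        "transcript_recovery_pct": 100.0 * len(recovered) / n_transcripts
        if n_transcripts
        else 0.0,
        "member_accuracy_pct": 100.0 * correct / n_scored if n_scored else 0.0,
        "wrong_family_members": wrong_family,
        "decoys_qualified": decoys_qualified,
    }
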