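"""End-to-end orchestration of the mining pipeline, stage by stage.

Each stage reads its inputs from disk and writes its outputs to disk, so a
single stage can be re-run in isolation and ``run_all`` is simply the
stages chained in order.  All outputs are plain text (FASTA/FASTQ/TSV/
newick/JSON) with fully deterministic ordering, so a repeated run with the
same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import asm, classify, extract_filter, fsalign, phylo, refpanel, simdata


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    align: fsalign.AlignParams = field(default_factory=fsalign.AlignParams)
    assembly: asm.AssemblyConfig = field(default_factory=asm.AssemblyConfig)
    filters: extract_filter.FilterConfig = field(
        default_factory=extract_filter.FilterConfig
    )
    tree: phylo.TreeConfig = field(default_factory=phylo.TreeConfig)
    classify: classify.ClassifyConfig = field(
        default_factory=classify.ClassifyConfig
    )
    prescreen_evalue_max: float = 1e-3
    contig_evalue_max: float = 1.0
    calibration_shuffles: int = 1000
    skip_assembly: bool = False  # pre-assembled transcript input
    msa_method: str = "linsi"

    def __post_init__(self) -> None:
        # one seed drives every stochastic stage
        self.sim = simdata.SimConfig(
            **{**_cfg_dict(self.sim), "seed": self.seed}
        )
        self.tree = phylo.TreeConfig(
            **{**_cfg_dict(self.tree), "seed": self.seed}
        )


def _cfg_dict(obj) -> dict:
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}


# ---------------------------------------------------------------------------
# stage: simulate


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simdata.simulate_study(config.sim)
    refpanel.write_panel(
        bundle.panel, outdir / "panel.fasta", outdir / "panel_labels.tsv"
    )
    for aln in bundle.domains:
        refpanel.write_domain_alignment(aln, outdir / f"domain_{aln.name}.fasta")
    simdata.write_fastq(bundle.reads, outdir / "reads.fastq")
    simdata.write_truth(bundle.truth, outdir / "truth.tsv")
    with open(outdir / "transcripts.fasta", "w") as fh:
        for tid in sorted(bundle.transcripts):
            fh.write(f">{tid}\n{bundle.transcripts[tid]}\n")
    with open(outdir / "species_manifest.tsv", "w") as fh:
        fh.write("# read_id\tspecies\n")
        for rid in sorted(bundle.truth.reads):
            fh.write(f"{rid}\t{bundle.truth.reads[rid].species}\n")
    return {
        "n_reads": len(bundle.reads),
        "n_panel": len(bundle.panel),
        "n_query_proteins": len(bundle.query_proteins),
        "n_decoys": config.sim.n_decoys,
    }


# ---------------------------------------------------------------------------
# stage: pre-screening search of reads


def _load_manifest(path: Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, species = line.split("\t")[:2]
            out[rid] = species
    return out


def stage_search(config: PipelineConfig, outdir: Path) -> dict:
    panel = refpanel.load_panel(
        outdir / "panel.fasta", outdir / "panel_labels.tsv"
    )
    reads = simdata.read_fastq(outdir / "reads.fastq")
    hits = fsalign.search_best_hits(
        ((r.id, r.sequence) for r in reads),
        panel,
        config.align,
        evalue_cap=config.prescreen_evalue_max,
    )
    fsalign.write_hits_tsv(hits, outdir / "prescreen_hits.tsv")
    by_id = {r.id: r for r in reads}
    with open(outdir / "prescreen_pass.fastq", "w") as fh:
        for rid in sorted(hits):
            fh.write(by_id[rid].fastq())
    return {"n_reads": len(reads), "n_prescreen_pass": len(hits)}


# ---------------------------------------------------------------------------
# stage: per-species assembly


def stage_assemble(config: PipelineConfig, outdir: Path) -> dict:
    manifest = _load_manifest(outdir / "species_manifest.tsv")
    reads = simdata.read_fastq(outdir / "prescreen_pass.fastq")
    by_species: dict[str, list[tuple[str, str]]] = {}
    for r in reads:
        by_species.setdefault(manifest.get(r.id, "unknown"), []).append(
            (r.id, r.sequence)
        )
    contigs_all: list[asm.Contig] = []
    singletons_all: list[asm.Contig] = []
    species_of_unit: dict[str, str] = {}
    for species in sorted(by_species):
        if config.skip_assembly:
            contigs, singletons = [], [
                asm.Contig(id=rid, consensus=seq, members=[(rid, 0, "+")])
                for rid, seq in sorted(by_species[species])
            ]
        else:
            contigs, singletons = asm.greedy_assemble(
                sorted(by_species[species]), config.assembly
            )
        for c in contigs:
            c.id = f"ctg_{c.id}"
        for s in singletons:
            s.id = f"sgl_{s.id}"
        for unit in contigs + singletons:
            species_of_unit[unit.id] = species
        contigs_all.extend(contigs)
        singletons_all.extend(singletons)
    asm.write_contigs(
        contigs_all, singletons_all, outdir / "contigs.fasta", outdir / "contig_members.tsv"
    )
    with open(outdir / "contig_species.tsv", "w") as fh:
        fh.write("# unit_id\tspecies\n")
        for uid in sorted(species_of_unit):
            fh.write(f"{uid}\t{species_of_unit[uid]}\n")
    return {
        "n_contigs": len(contigs_all),
        "n_singletons": len(singletons_all),
    }


# ---------------------------------------------------------------------------
# stage: re-search contigs and heal translations


def stage_extract(config: PipelineConfig, outdir: Path) -> dict:
    panel = refpanel.load_panel(
        outdir / "panel.fasta", outdir / "panel_labels.tsv"
    )
    units = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(outdir / "contigs.fasta"), "fasta")
    ]
    hits = fsalign.search_best_hits(
        units, panel, config.align, evalue_cap=config.contig_evalue_max
    )
    fsalign.write_hits_tsv(hits, outdir / "contig_hits.tsv")
    species_of = _load_manifest(outdir / "contig_species.tsv")
    candidates = []
    for uid in sorted(hits):
        hit = hits[uid]
        peptide = extract_filter.heal_translate(hit)
        if not peptide:
            continue
        cand = extract_filter.CandidatePeptide(
            id=f"pep_{uid}",
            species=species_of.get(uid, "unknown"),
            peptide=peptide,
            source=uid,
            best_hit=hit,
        )
        cand.has_motif = refpanel.scan_motif(peptide)[0]
        candidates.append(cand)
    extract_filter.write_peptides_fasta(candidates, outdir / "candidates.fasta")
    with open(outdir / "candidate_meta.tsv", "w") as fh:
        fh.write("# id\tspecies\tsource\tbest_family\tbest_evalue\thas_motif\n")
        for cand in sorted(candidates, key=lambda c: c.id):
            fh.write(
                f"{cand.id}\t{cand.species}\t{cand.source}\t"
                f"{cand.best_hit.subject_family}\t{cand.best_hit.evalue:.6g}\t"
                f"{int(bool(cand.has_motif))}\n"
            )
    return {"n_units_searched": len(units), "n_candidates": len(candidates)}


def _load_candidates(outdir: Path) -> list[extract_filter.CandidatePeptide]:
    hits = _load_hits_tsv(outdir / "contig_hits.tsv")
    meta = {}
    with open(outdir / "candidate_meta.tsv") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            pid, species, source, fam, ev, motif = line.rstrip("\n").split("\t")
            meta[pid] = (species, source, bool(int(motif)))
    out = []
    for rec in SeqIO.parse(str(outdir / "candidates.fasta"), "fasta"):
        species, source, motif = meta[rec.id]
        cand = extract_filter.CandidatePeptide(
            id=rec.id,
            species=species,
            peptide=str(rec.seq).upper(),
            source=source,
            best_hit=hits[source],
        )
        cand.has_motif = motif
        out.append(cand)
    return out


def _load_hits_tsv(path: Path) -> dict[str, fsalign.TranslatedHit]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out[f[0]] = fsalign.TranslatedHit(
                query_id=f[0],
                subject_id=f[1],
                subject_family=f[2],
                strand=f[3],
                score=int(f[4]),
                evalue=float(f[5]),
                identity=float(f[6]),
                query_span=(int(f[7]), int(f[8])),
                subject_span=(int(f[9]), int(f[10])),
                aligned_query_aa=f[11],
                aligned_subject_aa=f[12],
            )
    return out


# ---------------------------------------------------------------------------
# stage: qualification filters


def stage_filter(config: PipelineConfig, outdir: Path) -> dict:
    candidates = _load_candidates(outdir)
    profiles = [
        extract_filter.build_profile(
            refpanel.load_domain_alignment(outdir / f"domain_{name}.fasta", name)
        )
        for name in refpanel.DOMAIN_NAMES
    ]
    allowlist_path = outdir / "allowlist.txt"
    allowlist = (
        extract_filter.load_allowlist(allowlist_path)
        if allowlist_path.exists()
        else frozenset()
    )
    qualified = extract_filter.apply_filters(
        candidates,
        profiles,
        config.filters,
        allowlist=allowlist,
        n_shuffles=config.calibration_shuffles,
        seed=config.seed,
    )
    extract_filter.write_filter_ledger(candidates, outdir / "filter_ledger.tsv")
    extract_filter.write_peptides_fasta(qualified, outdir / "qualified.fasta")
    return {"n_candidates": len(candidates), "n_qualified": len(qualified)}


# ---------------------------------------------------------------------------
# stage: alignment + tree


def stage_tree(config: PipelineConfig, outdir: Path) -> dict:
    panel = refpanel.load_panel(
        outdir / "panel.fasta", outdir / "panel_labels.tsv"
    )
    sequences = {p.id: p.sequence for p in panel}
    for rec in SeqIO.parse(str(outdir / "qualified.fasta"), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    msa = phylo.build_msa(sequences, method=config.msa_method)
    phylo.write_msa_fasta(msa, outdir / "msa.fasta")
    dist = phylo.pairwise_distance(
        msa, config.tree.distance_correction, on_disjoint="cap"
    )
    tree = phylo.nj_tree(dist, msa.ids)
    tree = phylo.support_values(msa, tree, config.tree)
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(phylo.to_newick(tree) + "\n")
    return {"n_tree_leaves": len(msa.ids)}


# ---------------------------------------------------------------------------
# stage: classification


def stage_classify(config: PipelineConfig, outdir: Path) -> dict:
    with open(outdir / "tree.nwk") as fh:
        tree = phylo.parse_newick(fh.read())
    panel = refpanel.load_panel(
        outdir / "panel.fasta", outdir / "panel_labels.tsv"
    )
    panel_labels = {p.id: p.family for p in panel}
    query_ids = sorted(set(tree.leaf_names()) - set(panel_labels))
    assignments = classify.classify_all(
        tree, panel_labels, query_ids, config.classify
    )
    species_of = {}
    meta = {}
    with open(outdir / "candidate_meta.tsv") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            meta[f[0]] = f[1]
    for qid in query_ids:
        species_of[qid] = meta.get(qid, "unknown")
    classify.write_assignments_tsv(
        assignments, species_of, outdir / "assignments.tsv"
    )
    families = sorted({p.family for p in panel})
    matrix = classify.occurrence_matrix(assignments, species_of, families)
    classify.write_occurrence_tsv(matrix, outdir / "occurrence.tsv")
    verdicts: dict[str, int] = {}
    for a in assignments:
        verdicts[a.verdict] = verdicts.get(a.verdict, 0) + 1
    return {"n_assigned": len(assignments), "verdicts": verdicts}


# ---------------------------------------------------------------------------
# run-all


STAGES = (
    ("simulate", stage_simulate),
    ("search", stage_search),
    ("assemble", stage_assemble),
    ("extract", stage_extract),
    ("filter", stage_filter),
    ("tree", stage_tree),
    ("classify", stage_classify),
)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, simulate: bool = True
) -> dict:
    """Run every stage in order; returns the per-stage count report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    for name, fn in STAGES:
        if name == "simulate" and not simulate:
            continue
        try:
            report["stages"][name] = fn(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
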