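# cslmine

Mining and phylogenetic classification of cellulose synthase (CesA)
superfamily homologs from short-read sequence data.

## The problem

Celluloses and hemicelluloses are synthesized by enzymes of the CesA family
and the cellulose-synthase-like (Csl) families — CslA through CslK within
glycosyltransferase family 2 (GT2). Mapping which Csl families exist in
which plant and algal lineages is central to understanding cell-wall
evolution, but many key lineages (ferns, liverworts, charophytic green
algae, gymnosperms) lack finished genomes and are represented only by
short-read transcriptome or genome archives. `cslmine` implements the
classic mining recipe for exactly this situation, as a tested, seeded,
fully reproducible package:

1. **Pre-screen** reads against a panel of pre-classified Csl proteins with
   a frameshift-tolerant translated search (a fasty/tfasty-style dynamic
   program), so only homologous reads are assembled.
2. **Assemble** the surviving reads per species with a greedy
   overlap assembler (overlap length > 60 nt, identity > 97%).
3. **Re-search** contigs and singletons against the panel and **heal** the
   translations: the query side of the best alignment is taken and the
   frameshift (`/`, `\`), stop (`*`) and gap symbols are deleted, giving a
   clean peptide even across sequencing indels.
4. **Filter**: keep peptides that (i) hit a known Csl protein at
   E < 1e-10, (ii) match both domain profiles (Cellulose_synt and
   Glycos_transf_2 stand-ins) at E < 1e-2, and (iii) are longer than 150
   amino acids (100/200 are first-class alternates; shorter peptides can
   be rescued only via an explicit allowlist).
5. **Tree**: align qualified peptides with the panel (MAFFT L-INS-i),
   build a neighbor-joining tree on Poisson-corrected distances, and
   attach column-bootstrap support values.
6. **Classify** each peptide from its placement: `member` of a family,
   `basal` to one or more families, part of a `novel_cluster`, or
   `unclassified`, using a 0.70 support threshold; summarize everything in
   a species × family occurrence matrix (`+` found, `?` uncertain).

A first-class synthetic-data module generates diverged gene families,
error-laden reads and decoys with known truth, so the entire pipeline can
be exercised and scored without downloading anything.

## The core alignment

For a nucleotide query *x* and protein *y*, the aligner maximizes a local
alignment score where one subject residue is consumed together with 3 nt
(codon, score `s(aa, y_j)` from BLOSUM62), 4 nt (+1 frameshift, emitted
`/`) or 2 nt (−1 frameshift, emitted `\`), each frameshift charged a
penalty (default −15); stop codons score a constant (−5, emitted `*`);
gaps are affine (−11 first column, −1 thereafter). Frameshifted codons are
translated error-tolerantly — a 4-nt window is read as the best of its
four delete-one triplets, a 2-nt window as the best residue whose codon
contains the dinucleotide in order — so a genuine 1-nt indel heals back to
the original residue. Significance uses a Karlin–Altschul-shaped model

```
E = K · (m/3) · n · exp(−λ·S)        (K = 0.1, λ = 0.27 per score unit)
```

with *m* the query length in nt and *n* the database residue count. The
dynamic program is verified exhaustively against an independent
brute-force oracle in the test-suite.

## Worked example

Run the whole pipeline on a small simulated study — 3 families × 2
species, 150-aa proteins, 200-nt reads at 6× coverage with 1%
substitutions and 0.5% indels, plus 100 decoy reads:

```bash
cat > example.cfg <<EOF
seed=7
sim.n_families=3
sim.n_species=2
sim.protein_length=150
sim.read_length=200
sim.coverage=6.0
sim.n_decoys=100
filters.min_peptide_length=60
tree.n_resamples=200
calibration_shuffles=300
EOF
cslmine run-all --config example.cfg --outdir out/
```

This prints the per-stage report (reformatted):

```json
{"seed": 7, "stages": {
  "simulate": {"n_reads": 184, "n_panel": 6, "n_query_proteins": 6, "n_decoys": 100},
  "search":   {"n_reads": 184, "n_prescreen_pass": 84},
  "assemble": {"n_contigs": 19, "n_singletons": 33},
  "extract":  {"n_units_searched": 52, "n_candidates": 52},
  "filter":   {"n_candidates": 52, "n_qualified": 38},
  "tree":     {"n_tree_leaves": 44},
  "classify": {"n_assigned": 38, "verdicts": {"member": 38}}}}
```

Reading it: of 184 reads, the translated pre-screen keeps 84 — every
homologous read and none of the 100 decoys. Assembly produces 19 contigs
and 33 singletons; all 52 get a best hit and a healed candidate peptide,
38 survive the three filters, and on the 44-leaf tree (6 panel proteins +
38 peptides) every qualified peptide lands inside its family's supported
clade. The occurrence matrix (`out/occurrence.tsv`) then shows every
planted family recovered in both simulated species:

```
species  CesA  CslA  CslB
qsp1     +     +     +
qsp2     +     +     +
```

and `out/assignments.tsv` holds the per-peptide verdicts with supports:

```
pep_ctg_qsp1_CesA_qsp1_r0001  qsp1  member  CesA  0.940
pep_ctg_qsp1_CslA_qsp1_r0001  qsp1  member  CslA  0.990
```

The same stages are available as individual subcommands (`simulate`,
`search`, `assemble`, `extract`, `filter`, `tree`, `classify`), each
re-runnable from its on-disk inputs; `--no-simulate` lets `run-all` start
from your own FASTQ and panel files. Pre-assembled transcripts (EST
contigs and the like) skip assembly with `skip_assembly=true`.

## Layout

| module | role |
| --- | --- |
| `cslmine.refpanel` | reference panel + domain alignments + motif scan |
| `cslmine.simdata` | synthetic families, reads, decoys, truth tables |
| `cslmine.fsalign` | frameshift-tolerant translated search + E-values |
| `cslmine.asm` | greedy overlap assembly |
| `cslmine.extract_filter` | healed translation, profiles, filters |
| `cslmine.phylo` | MSA (MAFFT), distances, NJ, supports, newick |
| `cslmine.classify` | family verdicts + occurrence matrix |
| `cslmine.pipeline` / `cslmine.cli` | stage orchestration + CLI |
| `cslmine.evaluate` | scoring a simulated run against its truth |

See `docs/methods.md` for the models, defaults and design decisions.
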