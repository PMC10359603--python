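# duf-scout

Toolkit for discovering and characterizing a family of bacterial
transcriptional activators whose coding sequence is split across two
overlapping reading frames joined by a +1 programmed ribosomal frameshift
(PRF) at a slippery site (DNA `TGGGGG`), together with their lone-domain
antiactivator paralogues. The package covers the full computational
workflow:

| stage | module | what it does |
|---|---|---|
| simulate | `duf_scout.synthetic_data` | generates loci with planted frameshift genes, promoter windows with planted inverted repeats, and gel-shift binding curves — all with ground truth |
| reconstruct | `duf_scout.prf_reconstruct` | six-frame ORF finding, +1 PRF site detection in overlapping ORF pairs, frame-edited fusion into full-length polypeptides |
| curate | `duf_scout.homolog_curation` | AWEFLRRN-motif classification (activator-like vs antiactivator-like) and ordered curation filters with a reconciling report |
| irscan | `duf_scout.irbox_scan` | inverted-repeat promoter-box scanning (6 + 15/16 + 6 geometry), greedy redundancy filtering, split-anchor conservation profiles |
| charge | `duf_scout.charge_profile` | formal net charge and sliding-window charge profiles |
| emsafit | `duf_scout.emsa_fit` | constant co-purified band exclusion and specific-binding-with-Hill-slope fitting (K_D, Hill slope, Bmax) |
| rmsd | `duf_scout.struct_ensemble` | multi-model PDB reading, Kabsch superposition, ensemble RMSD (to-mean and pairwise conventions) |
| run | `duf_scout.pipeline` | end-to-end orchestration with a config file, seed determinism, and a provenance manifest |

## CLI

```bash
duf-scout simulate --out sim --seed 1 --n-fsea 10 --n-qsem 10 --n-decoys 5
duf-scout reconstruct --fasta sim/loci.fa --motif TGGGGG --max-mismatch 0 --window 45
duf-scout curate --proteins reconstruct.proteins.fa --max-mismatch 2 --max-len 400
duf-scout irscan --windows upstreams.fa --spacers 15,16 --max-mismatch 1
duf-scout charge --fasta domains.fa --window 20 --count-c-term
duf-scout emsafit --tsv lanes.tsv --exclude-constant-unbound
duf-scout rmsd --pdb 7uqt.pdb --residues 6:72 --atoms N,CA,C,O
duf-scout run --config config.json --out runs/r1
```

`duf-scout run` executes simulate → reconstruct → curate → irscan → emsafit
from a flat JSON config (every threshold has a documented default in
`duf_scout.pipeline.PipelineConfig`); the output directory gains a
`manifest.json` recording the config hash, tool version and per-stage record
counts, and reruns are byte-identical.

## File formats

FASTA (loci, windows, proteins), GFF3 (1-based inclusive), TSV (EMSA lanes:
`concentration_nM, rep, bound, unbound[, copurified]`; call/classification
tables), JSON (truth files, reports, manifests), MEME-minimal PFMs, and
multi-model PDB. All internal coordinates are 0-based half-open; protein
residues are 1-based.
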