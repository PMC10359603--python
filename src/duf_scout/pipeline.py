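"""End-to-end orchestration: simulate -> reconstruct -> curate (plus the
optional promoter-box and binding-curve stages) under one flat config, with
a provenance manifest and full seed determinism."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .emsa_fit import exclude_constant_unbound, fit_hill, fit_report
from .homolog_curation import Candidate, curate
from .irbox_scan import profile_from_probs, scan, split_profile, write_meme_minimal
from .prf_reconstruct import NucleotideLocus, reconstruct_locus
from .synthetic_data import (
    SimLocusSpec, gen_emsa, gen_loci, gen_upstreams, write_emsa_tsv,
    write_fasta, write_gff3, write_truth_json,
)

log = logging.getLogger("duf_scout")


@dataclass
class PipelineConfig:
    seed: int = 1
    # simulate
    n_fsea_like: int = 10
    n_qsem_like: int = 10
    n_decoys: int = 5
    orf1_len_codons: int = 80
    orf2_len_codons: int = 60
    overlap_nt: int = 14
    slippery_motif: str = "TGGGGG"
    background_gc: float = 0.5
    mutation_rate: float = 0.0
    drop_orf1_start: bool = False
    n_upstreams: int = 50
    spacer_p15: float = 0.5
    window_len: int = 80
    emsa_kd: float = 30.0
    emsa_hill: float = 1.5
    emsa_noise_sd: float = 0.05
    emsa_constant_unbound: float = 0.2
    # reconstruct
    min_len_codons: int = 30
    max_mismatch_prf: int = 0
    window_nt: int = 45
    # curate
    max_len: int = 400
    max_mismatch_motif: int = 2
    region_end: int = 60
    # irscan
    hexamer_len: int = 6
    spacers: tuple = (15, 16)
    max_mismatch_ir: int = 1
    # emsafit
    cv_threshold: float = 0.10
    # stage toggles
    do_simulate: bool = True
    do_reconstruct: bool = True
    do_curate: bool = True
    do_irscan: bool = True
    do_emsafit: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "spacers" in raw:
            raw["spacers"] = tuple(raw["spacers"])
        return cls(**raw)

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _consensus_pfm(hexamer: str = "GTCGAC", strength: float = 0.9):
    """Probability matrix concentrated on a consensus hexamer."""
    from .irbox_scan import BASES

    probs = np.full((len(hexamer), 4), (1 - strength) / 3)
    for i, b in enumerate(hexamer):
        probs[i, BASES.index(b)] = strength
    return profile_from_probs(probs, anchor="consensus")


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    Identical config + inputs produce byte-identical outputs.  Any stage
    error is re-raised annotated with the stage name.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "duf-scout",
        "version": __version__,
        "config_sha256": config.digest(),
        "config": asdict(config),
        "stages": {},
    }
    stage = "simulate"
    try:
        loci, truth = [], None
        if config.do_simulate:
            log.info("stage %s", stage)
            spec = SimLocusSpec(
                seed=config.seed, n_fsea_like=config.n_fsea_like,
                n_qsem_like=config.n_qsem_like, n_decoys=config.n_decoys,
                orf1_len_codons=config.orf1_len_codons,
                orf2_len_codons=config.orf2_len_codons,
                overlap_nt=config.overlap_nt,
                slippery_motif=config.slippery_motif,
                background_gc=config.background_gc,
                mutation_rate=config.mutation_rate,
                drop_orf1_start=config.drop_orf1_start,
            )
            loci, gff_rows, truth = gen_loci(spec)
            write_fasta(loci, out / "loci.fa")
            write_gff3(gff_rows, out / "loci.gff3")
            write_truth_json(truth, out / "truth.json")
            windows, wtruth = gen_upstreams(
                config.n_upstreams,
                {15: config.spacer_p15, 16: 1 - config.spacer_p15},
                _consensus_pfm(), seed=config.seed,
                window_len=config.window_len,
            )
            write_fasta([(t[0], w) for w, t in zip(windows, wtruth)],
                        out / "upstreams.fa")
            with open(out / "upstreams_truth.json", "w") as fh:
                json.dump([list(t) for t in wtruth], fh)
            lanes = gen_emsa(
                concentrations=list(np.geomspace(4, 500, 7)),
                kd=config.emsa_kd, hill=config.emsa_hill,
                noise_sd=config.emsa_noise_sd,
                constant_unbound_frac=config.emsa_constant_unbound,
                seed=config.seed,
            )
            write_emsa_tsv(lanes, out / "emsa.tsv")
            manifest["stages"][stage] = {
                "n_loci": len(loci), "n_upstreams": len(windows),
                "n_lanes": len(lanes),
            }

        stage = "reconstruct"
        proteins = []
        if config.do_reconstruct:
            log.info("stage %s", stage)
            if not loci:
                loci = read_fasta_loci(out / "loci.fa")
            call_rows = []
            for locus in loci:
                recs, calls = reconstruct_locus(
                    locus, min_len_codons=config.min_len_codons,
                    motif=config.slippery_motif,
                    max_mismatch=config.max_mismatch_prf,
                    window_nt=config.window_nt,
                )
                fused_ids = set()
                for k, (rec, call) in enumerate(zip(recs, calls)):
                    pid = f"{locus.id}.fusion{k}"
                    proteins.append((pid, rec))
                    fused_ids.add((call.upstream.start, call.upstream.end))
                    call_rows.append(dict(
                        locus=locus.id, protein=pid,
                        motif_start=call.motif_start,
                        motif_seq=call.motif_seq, strand=call.strand,
                        overlap_nt=call.overlap_nt,
                        mismatches=call.motif_mismatches,
                        junction_residue=rec.junction_residue,
                    ))
                # single-ORF products for loci without any fusion
                if not recs:
                    from .prf_reconstruct import find_orfs, fuse
                    orfs = [o for o in find_orfs(locus, config.min_len_codons)
                            if o.strand == "+"]
                    if orfs:
                        longest = max(orfs, key=lambda o: len(o.translation))
                        rec = fuse(locus, orf=longest)
                        proteins.append((f"{locus.id}.orf", rec))
            with open(out / "proteins.fa", "w") as fh:
                for pid, rec in proteins:
                    j = rec.junction_residue if rec.junction_residue else ""
                    fh.write(f">{pid} provenance={rec.provenance} junction={j}\n")
                    fh.write(rec.sequence + "\n")
            pd.DataFrame(call_rows).to_csv(out / "calls.tsv", sep="\t",
                                           index=False)
            manifest["stages"][stage] = {
                "n_proteins": len(proteins), "n_calls": len(call_rows),
            }

        stage = "curate"
        if config.do_curate:
            log.info("stage %s", stage)
            candidates = [
                Candidate(id=pid, sequence=rec.sequence,
                          provenance=rec.provenance)
                for pid, rec in proteins
            ]
            results, report = curate(
                candidates, max_len=config.max_len,
                max_mismatch=config.max_mismatch_motif,
                region_end=config.region_end,
            )
            rows = []
            for cand, cls in results:
                call = cls.call
                rows.append(dict(
                    id=cand.id, label=cls.label, reason=cls.reject_reason,
                    motif_start=call.start if call else "",
                    mismatches=call.mismatches if call else "",
                    provenance=cand.provenance,
                ))
            pd.DataFrame(rows).to_csv(out / "classification.tsv", sep="\t",
                                      index=False)
            with open(out / "curation_report.json", "w") as fh:
                json.dump(asdict(report), fh, indent=1)
            manifest["stages"][stage] = {
                "input": report.input_count, "kept": report.surviving,
                "removed": report.removed,
            }

        stage = "irscan"
        if config.do_irscan and (out / "upstreams.fa").exists():
            log.info("stage %s", stage)
            windows = read_fasta(out / "upstreams.fa")
            boxes_rows = []
            best_boxes = []
            for wid, seq in windows:
                hits = scan(seq, hexamer_len=config.hexamer_len,
                            spacers=config.spacers,
                            max_mismatch=config.max_mismatch_ir, window_id=wid)
                best_boxes.append(hits[0] if hits else None)
                for b in hits:
                    boxes_rows.append(dict(
                        window=wid, start=b.hex1_start,
                        end=b.hex2_start + b.hexamer_len, spacer=b.spacer,
                        mismatches=b.mismatches, total_span=b.total_span,
                    ))
            pd.DataFrame(boxes_rows).to_csv(out / "irboxes.tsv", sep="\t",
                                            index=False)
            profile = split_profile([s for _, s in windows], best_boxes)
            write_meme_minimal(profile, "ir_box", out / "ir_profile.meme")
            pd.DataFrame({
                "column": profile.labels,
                "information_bits": profile.information,
            }).to_csv(out / "ir_information.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "n_windows": len(windows), "n_boxes": len(boxes_rows),
                "skipped": profile.skipped,
            }

        stage = "emsafit"
        if config.do_emsafit and (out / "emsa.tsv").exists():
            log.info("stage %s", stage)
            df = pd.read_csv(out / "emsa.tsv", sep="\t")
            curve = exclude_constant_unbound(df, cv_threshold=config.cv_threshold)
            fit = fit_hill(curve)
            with open(out / "emsa_fit.json", "w") as fh:
                json.dump(fit_report(fit, curve), fh, indent=1)
            manifest["stages"][stage] = {
                "n_lanes": len(df), "converged": fit.converged,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def read_fasta_loci(path) -> list[NucleotideLocus]:
    return [NucleotideLocus(id=i, sequence=s) for i, s in read_fasta(path)]
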