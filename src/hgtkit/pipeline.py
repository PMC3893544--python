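"""End-to-end orchestration of the screen and its evolutionary validation.

``run_all`` executes, on the bundled synthetic benchmark: simulation ->
screening -> intron diagnostics -> NJ/bootstrap placement -> type-I
divergence -> codon-model selection -> expression, writing per-stage
outputs and a manifest JSON recording inputs, outputs, checksums and the
seed.  Any stage can be toggled off; a failed stage is recorded and its
dependents skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, comparative, divergence, expression, phylo, screen, selection, synth
from .io import MSA, SeqRecord, write_alignment, write_count_table, write_fasta, write_newick

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "hgtkit_run"
    n_native: int = 20
    n_hgt: int = 3
    n_contaminants: int = 5
    depth: float = 8.0
    stages: dict = field(default_factory=lambda: {
        "screen": True, "introns": True, "phylo": True,
        "divergence": True, "selection": True, "expression": True,
    })


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Run the full synthetic-benchmark pipeline; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    written: list[Path] = []

    def record(stage: str, status: str, **extra):
        manifest["stages"][stage] = {"status": status, **extra}

    rng_seed = config.seed
    # --- simulate ------------------------------------------------------
    ref = synth.simulate_reference_db(seed=rng_seed)
    txm = synth.simulate_recipient_transcriptome(
        ref, n_native=config.n_native, n_hgt=config.n_hgt,
        n_contaminants=config.n_contaminants, seed=rng_seed + 1)
    reads = synth.simulate_reads(txm, depth=config.depth, seed=rng_seed + 2)
    fa = out / "transcripts.fasta"
    write_fasta(txm.transcripts, fa)
    written.append(fa)
    record("simulate", "ok", n_transcripts=len(txm.transcripts))

    cfg = screen.ScreenConfig(sister_taxon_name=ref.taxonomy.sister)
    screen_result = None
    if config.stages.get("screen", True):
        try:
            hits = synth.build_hit_table(
                [screen.predict_orf(t).protein for t in txm.transcripts], ref)
            hits = {k.replace("_orf", ""): v for k, v in hits.items()}
            for k, hs in hits.items():
                for h in hs:
                    h.query_id = k
            cdna_hits = synth.build_cdna_hit_table(txm.transcripts, txm.truth, ref.taxonomy)
            host_free = [s.name for s in synth.DEFAULT_STAGES if s.host_free]
            screen_result = screen.run_screen(
                txm.transcripts, reads, host_free, hits, cdna_hits, cfg, trim=False)
            rep = out / "screen_report.tsv"
            screen_result.report.to_csv(rep, sep="\t", index=False)
            written.append(rep)
            record("screen", "ok", candidates=screen_result.candidates)
        except Exception as exc:
            logger.error("screen failed: %s", exc)
            record("screen", "failed", error=str(exc), trace=traceback.format_exc())
    else:
        record("screen", "skipped")

    # --- introns -------------------------------------------------------
    if config.stages.get("introns", True):
        try:
            rows = []
            for gid, (sp_id, re_id, pos, length) in txm.truth.retention.items():
                iso_a = next(t for t in txm.transcripts if t.id == sp_id)
                iso_b = next(t for t in txm.transcripts if t.id == re_id)
                repn = comparative.detect_intron_retention(iso_a, iso_b)
                rows.append({"gene": gid, "insert_length": repn.insert_length,
                             "position": repn.insert_position})
            structs = {}
            for gid, g in txm.genomic.items():
                cdna = next(t for t in txm.transcripts if t.id == gid)
                structs[gid] = comparative.map_introns(cdna, g)
            p = out / "intron_structures.tsv"
            with open(p, "w") as fh:
                fh.write("gene\ttype\tstart\tend\n")
                for gid, st in structs.items():
                    for (s, e) in st.exons:
                        fh.write(f"{gid}\texon\t{s + 1}\t{e}\n")
                    for (s, e) in st.introns:
                        fh.write(f"{gid}\tintron\t{s + 1}\t{e}\n")
            written.append(p)
            record("introns", "ok", n_structures=len(structs), retention=rows)
        except Exception as exc:
            record("introns", "failed", error=str(exc))
    else:
        record("introns", "skipped")

    # --- phylo ---------------------------------------------------------
    if config.stages.get("phylo", True):
        try:
            verdicts = {}
            donor_sp = ref.taxonomy.donor_species
            fam_of = {}
            hgt_ids = [t for t, lab in txm.truth.labels.items()
                       if lab == "hgt" and not t.endswith("_iso1")]
            for i, tid in enumerate(sorted(hgt_ids)):
                fam = ref.families[config.n_native + i]
                rows = [SeqRecord(tid, txm.truth.proteins[tid], moltype="protein")]
                rows += [SeqRecord(sp, fam.sequences[sp], moltype="protein")
                         for sp in ref.taxonomy.reference_species()]
                aligned = _align_to_family(rows, fam)
                boot = phylo.bootstrap_support(aligned, n_replicates=100,
                                               seed=config.seed + 10 + i)
                verdicts[tid] = phylo.placement_test(
                    boot.tree, tid, donor_sp,
                    [ref.taxonomy.sister], min_support=75)
                write_newick(boot.tree, out / f"tree_{tid}.nwk")
                written.append(out / f"tree_{tid}.nwk")
            record("phylo", "ok", placements=verdicts)
        except Exception as exc:
            record("phylo", "failed", error=str(exc), trace=traceback.format_exc())
    else:
        record("phylo", "skipped")

    # --- divergence ----------------------------------------------------
    if config.stages.get("divergence", True):
        try:
            t1 = synth.read_newick("((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):0.2);")
            t2 = synth.read_newick("((e:0.3,f:0.3):0.2,(g:0.3,h:0.3):0.2);")
            msa, truth_state = synth.simulate_divergence_alignment(
                t1, t2, theta_true=0.3, alpha=0.5, n_sites=600, seed=config.seed + 20)
            counts = divergence.count_substitutions(msa, t1, t2)
            res = divergence.estimate_theta1(counts)
            record("divergence", "ok", theta1=res.theta1, lrt=res.lrt,
                   p_value=res.p_value, true_fraction=float(truth_state.mean()))
        except Exception as exc:
            record("divergence", "failed", error=str(exc))
    else:
        record("divergence", "skipped")

    # --- selection -----------------------------------------------------
    if config.stages.get("selection", True):
        try:
            tree = synth.read_newick(
                "((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1,(e:0.2,f:0.2):0.1);")
            msa, _ = synth.simulate_codon_alignment(
                tree, kappa=2.0, site_classes=[(0.2, 1.0)], n_sites=300,
                seed=config.seed + 30)
            fit = selection.fit_model(msa, tree, "M0")
            record("selection", "ok", omega=fit.params["omega"],
                   kappa=fit.params["kappa"], lnl=fit.lnl)
        except Exception as exc:
            record("selection", "failed", error=str(exc))
    else:
        record("selection", "skipped")

    # --- expression ----------------------------------------------------
    if config.stages.get("expression", True):
        try:
            sub_ok = screen_result is not None
            if sub_ok:
                fp = expression.fpkm(screen_result.counts)
                fp.to_csv(out / "fpkm.tsv", sep="\t")
                written.append(out / "fpkm.tsv")
            ct = synth.simulate_qpcr(synth.QpcrDesign(),
                                     {"1h": 1.3, "24h": 3.2},
                                     noise_sd=0.1, seed=config.seed + 40)
            stab = expression.stability_rank(ct)
            folds = expression.ddct(ct, "target", stab.best_gene, "0h")
            record("expression", "ok", best_reference=stab.best_gene,
                   folds={f.condition: round(f.fold, 3) for f in folds})
        except Exception as exc:
            record("expression", "failed", error=str(exc))
    else:
        record("expression", "skipped")

    manifest["outputs"] = {str(p.relative_to(out)): _checksum(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _align_to_family(rows: list[SeqRecord], fam: synth.FamilySim) -> MSA:
    """Quick profile alignment of a query onto a family's true alignment.

    The family rows keep their simulated alignment; the query (first row) is
    aligned against its closest family member and gaps are projected.  Good
    enough for placement testing on desk-scale synthetic families.
    """
    query = rows[0]
    best_id, best_score = None, -np.inf
    for rec in fam.alignment.records:
        aln = comparative.pairwise_align(query.seq, rec.seq.replace("-", ""),
                                         mode="global", moltype="protein")
        if aln.score > best_score:
            best_score, best_id, best_aln = aln.score, rec.id, aln
    anchor_row = fam.alignment.row(best_id)
    # project query into alignment coordinates via the anchor
    qa, aa = best_aln.aligned_a, best_aln.aligned_b
    # map anchor ungapped position -> query char
    q_at: dict[int, str] = {}
    ai = 0
    for x, y in zip(qa, aa):
        if y != "-":
            if x != "-":
                q_at[ai] = x
            ai += 1
    out_row = []
    ai = 0
    for ch in anchor_row:
        if ch == "-":
            out_row.append("-")
        else:
            out_row.append(q_at.get(ai, "-"))
            ai += 1
    aligned_query = SeqRecord(query.id, "".join(out_row), moltype="protein")
    return MSA([aligned_query] + list(fam.alignment.records))
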