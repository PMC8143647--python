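"""End-to-end orchestration: simulate -> annotate -> enrich -> train ->
scan -> filter -> assay, with provenance logging.

Stages communicate only through files in a run directory so that every
intermediate is inspectable, and a manifest (config snapshot, per-stage row
counts, SHA-256 digest of every file written) is emitted last.  Re-running
with the same seed and configuration reproduces every byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from . import __version__
from . import amp as _amp
from . import annotation as _ann
from . import assay as _assay
from . import enrichment as _enr
from . import io as _io
from . import synthetic as _syn

log = logging.getLogger(__name__)


def demo_spec(seed: int = 42) -> _syn.SimulationSpec:
    """Desk-scale simulation used by the end-to-end run.

    Small enough that the full pipeline, including the proteome-wide window
    scan, completes in about a minute, while keeping every planted signal
    recoverable.
    """
    return _syn.SimulationSpec(
        n_proteins=60,
        mean_length=120.0,
        sd_length=40.0,
        planted_enriched=10,
        n_amp=120,
        n_background=120,
        seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _overlaps(window: _amp.PeptideWindow, loci) -> bool:
    for pid, start in (window.occurrences or ((window.parent_id,
                                               window.start),)):
        end = start + window.length
        for lid, lstart, lend in loci:
            if pid == lid and start < lend and lstart < end:
                return True
    return False


def run_all(
    config: _io.RunConfig,
    outdir: str | Path,
    spec: _syn.SimulationSpec | None = None,
    n_planted_motifs: int = 12,
) -> dict:
    """Execute every stage on synthetic inputs; returns the manifest dict.

    Any stage failure aborts with the failing stage named.  The manifest is
    written last, to ``<outdir>/manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec if spec is not None else demo_spec(config.rng_seed)
    counts: dict[str, int] = {}
    stage = "simulate"
    try:
        # ------------------------------------------------ simulate
        proteome = _syn.simulate_proteome(spec)
        proteome, planted_loci = _syn.plant_amp_motifs(
            proteome, spec, n_motifs=n_planted_motifs)
        _io.write_fasta(proteome, outdir / "proteome.fasta")
        matrix, planted_enriched = _syn.simulate_intensity_matrix(spec, proteome)
        _io.write_intensity_matrix(matrix, outdir / "intensities.tsv")
        _io.write_roles(matrix.roles, outdir / "roles.tsv")
        hits, orthology = _syn.simulate_hit_table(proteome, spec)
        _io.write_hit_table(hits, outdir / "hits.tsv")
        contam_hits, contam_truth = _syn.simulate_contaminant_table(
            proteome, spec)
        _io.write_hit_table(contam_hits, outdir / "contaminants.tsv")
        corpus_raw = _syn.simulate_amp_corpus(spec)
        _io.write_fasta(
            [_io.ProteinRecord(sid, s) for sid, s, y in corpus_raw if y == 1],
            outdir / "amp_positives.fasta")
        _io.write_fasta(
            [_io.ProteinRecord(sid, s) for sid, s, y in corpus_raw if y == 0],
            outdir / "amp_negatives.fasta")
        truth = {
            "planted_enriched": sorted(planted_enriched),
            "planted_amp_loci": sorted(planted_loci),
            "planted_contaminants": sorted(contam_truth),
            "planted_orthology": {k: orthology[k]
                                  for k in sorted(orthology) if orthology[k]},
        }
        (outdir / "truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True))
        counts["proteins"] = len(proteome)
        counts["hits"] = len(hits)
        counts["training_sequences"] = len(corpus_raw)

        # ------------------------------------------------ annotate
        stage = "annotate"
        results = _ann.annotate_all(
            _io.read_hit_table(outdir / "hits.tsv"),
            cutoff=config.evalue_cutoff,
            bounds=config.confidence_bounds,
            query_ids=[p.id for p in proteome],
        )
        results = _ann.flag_contaminants(
            results, _io.read_hit_table(outdir / "contaminants.tsv"),
            cutoff=config.evalue_cutoff)
        _ann.write_annotation_report(results, outdir / "annotation.tsv")
        summary = _ann.annotation_summary(results)
        counts["annotated"] = summary.annotated

        # ------------------------------------------------ enrich
        stage = "enrich"
        matrix_in = _io.read_intensity_matrix(
            outdir / "intensities.tsv", roles=_io.read_roles(outdir / "roles.tsv"))
        enrichment = _enr.call_enrichment(
            matrix_in,
            k=config.kmeans_k,
            loading_quantile=config.loading_quantile,
            downshift=config.missing_downshift,
            seed=config.rng_seed,
        )
        _enr.write_enrichment_report(enrichment, matrix_in,
                                     outdir / "enrichment.tsv")
        counts["fg_unique"] = len(enrichment.unique_set)
        counts["fg_enriched"] = len(enrichment.enriched_set)
        counts["fg_combined"] = len(enrichment.combined_set)

        # ------------------------------------------------ train
        stage = "train"
        pos = _io.read_fasta(outdir / "amp_positives.fasta")
        neg = _io.read_fasta(outdir / "amp_negatives.fasta")
        corpus = _amp.curate_corpus(
            [(r.id, r.sequence, 1) for r in pos]
            + [(r.id, r.sequence, 0) for r in neg])
        classifier = _amp.train_classifiers(
            corpus, seed=config.rng_seed,
            lam=config.pseaac_lambda, weight=config.pseaac_weight)
        _amp.save_model(classifier, outdir / "model.json")
        counts["curated_sequences"] = len(corpus.sequences)

        # ------------------------------------------------ scan + filter
        stage = "scan"
        windows = _amp.window_digest(
            _io.read_fasta(outdir / "proteome.fasta"),
            config.window_min, config.window_max)
        candidates = _amp.scan_proteome(
            windows, classifier, threshold=config.amp_probability_threshold)
        candidates = _amp.filter_candidates(
            candidates, lam=config.pseaac_lambda, weight=config.pseaac_weight)
        selected = [c for c in candidates if c.selected]
        _write_candidates(candidates, outdir / "candidates.tsv")
        counts["windows"] = len(windows)
        counts["amp_candidates"] = len(candidates)
        counts["amp_selected"] = len(selected)

        # ------------------------------------------------ assay
        stage = "assay"
        series = [float(c) for c in _assay.dilution_series(1000.0, 2.0, 31.0)]
        assay_rng = spec.rng(_syn._STREAM_PLATE)
        to_test = sorted({c.window.sequence for c in selected})[:4] or ["none"]
        plates = []
        for i, seq in enumerate(to_test, start=1):
            plates.append(_syn.simulate_plate(
                spec, series,
                emax=0.75 if i == 1 else 0.95,
                peptide_id=f"candidate_{i:02d}",
                strain="E_coli_K12",
                rng=assay_rng,
            ))
        _io.write_plate_csv(plates, outdir / "plates.csv")
        curves = [
            _assay.analyze_plate(a, mic_threshold=config.mic_threshold)
            for a in _io.read_plate_csv(outdir / "plates.csv")
        ]
        _assay.write_curves_tsv(curves, outdir / "curves.tsv")
        counts["assays"] = len(curves)

        # ------------------------------------------------ combined report
        stage = "report"
        report = _build_report(summary, enrichment, truth, windows,
                               candidates, selected, curves)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "tool": "glandscreen",
        "version": __version__,
        "seed": config.rng_seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "simulation": asdict(spec),
        "counts": counts,
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_candidates(candidates, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tparent_id\tstart\tlength\tdecision_value\t"
                 "probability\tsoluble\tstable\tselected\n")
        for c in sorted(candidates, key=lambda c: (-c.probability,
                                                   c.window.sequence)):
            w = c.window
            fh.write(
                f"{w.sequence}\t{w.parent_id}\t{w.start}\t{w.length}\t"
                f"{c.score:.6g}\t{c.probability:.6g}\t{int(c.soluble)}\t"
                f"{int(c.stable)}\t{int(c.selected)}\n"
            )


def _build_report(summary, enrichment, truth, windows, candidates, selected,
                  curves) -> dict:
    """Combined end-of-run report with both planted-signal recoveries."""
    planted = set(truth["planted_enriched"])
    sel_set = set(enrichment.enriched_set)
    inter = planted & sel_set
    union = planted | sel_set
    jaccard = len(inter) / len(union) if union else 0.0

    loci = [tuple(l) for l in truth["planted_amp_loci"]]
    recovered = sum(
        1 for l in loci
        if any(_overlaps(c.window, [l]) for c in candidates)
    )
    n_windows = len(windows)
    n_hits_in_truth = sum(1 for w in windows if _overlaps(w, loci))
    n_sel = len(candidates)
    n_sel_in_truth = sum(1 for c in candidates if _overlaps(c.window, loci))
    if n_sel and n_hits_in_truth:
        p_enrich = float(hypergeom.sf(n_sel_in_truth - 1, n_windows,
                                      n_hits_in_truth, n_sel))
    else:
        p_enrich = 1.0
    return {
        "annotation": {
            "total": summary.total,
            "annotated": summary.annotated,
            "efficiency_percent": summary.efficiency_percent,
            "class_counts": {str(k): v for k, v in
                             summary.class_counts.items()},
            "contaminants_flagged": len(summary.contaminants),
        },
        "enrichment_recovery": {
            "planted": len(planted),
            "selected": len(sel_set),
            "unique": len(enrichment.unique_set),
            "combined": len(enrichment.combined_set),
            "jaccard_vs_planted": jaccard,
        },
        "amp_recovery": {
            "planted_loci": len(loci),
            "loci_overlapped_by_candidates": recovered,
            "recovery_fraction": recovered / len(loci) if loci else 0.0,
            "candidates": len(candidates),
            "selected_for_synthesis": len(selected),
            "hypergeometric_p": p_enrich,
        },
        "assays": [
            {
                "peptide_id": c.peptide_id,
                "strain": c.strain,
                "max_inhibition": c.max_inhibition,
                "mic_ug_ml": c.mic,
                "dose_dependent": c.dose_dependent,
            }
            for c in curves
        ],
    }
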