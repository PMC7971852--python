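"""End-to-end orchestration: simulate -> quantify -> call peaks -> integrate
-> motifs (-> PLA), with a reproducible run manifest.

Every output is a pure function of (config, master seed); the manifest
records parameters, per-stage row counts, and SHA-256 checksums of all
written files so a rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import annotation, integrate, motif, peakcall, pla, quantify, simulate

log = logging.getLogger("m6ate")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the pipeline's fixed constants
    (10-nt windows, 90/200-nt event bounds, 10,000-event tuning target, 70th
    percentile rank cut, 2-peak loss cut, 2-RPKM retention, mapq 20,
    4-fold miRNA screen, <=1 seed mismatch)."""

    sim: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)
    target_events: int = peakcall.DEFAULT_TARGET_EVENTS
    grid_min: float = 1e-40
    grid_max: float = 1e-3
    fixed_threshold: float | None = None  # bypass tuning when set
    rank_cut: float = integrate.DEFAULT_RANK_CUT
    loss_cut: float = integrate.DEFAULT_LOSS_CUT
    rpkm_cut: float = quantify.DEFAULT_RPKM_CUT
    mapq_cut: int = quantify.DEFAULT_MAPQ_MIN
    fc_cut: float = motif.DEFAULT_FC_CUT
    max_mismatch: int = motif.DEFAULT_MAX_MISMATCH
    pla_images: int = 0
    pla_spots: tuple[int, ...] = (5, 10, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        self.sim.seed = self.seed
        for name in ("target_events", "rank_cut", "loss_cut", "rpkm_cut",
                     "mapq_cut", "fc_cut"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def grid(self) -> list[float]:
        lo = int(round(-np.log10(self.grid_max)))
        hi = int(round(-np.log10(self.grid_min)))
        return [10.0 ** -e for e in range(lo, hi + 1)]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("exon_length_range", "n_exons_range", "peak_length_range",
                    "enrichment_range"):
            if key in sim_raw and sim_raw[key] is not None:
                sim_raw[key] = tuple(sim_raw[key])
        if "pla_spots" in raw:
            raw["pla_spots"] = tuple(raw["pla_spots"])
        return cls(sim=simulate.SimulationConfig(**sim_raw), **raw)


def threshold_calibration_study(seed: int,
                                target_events: int = peakcall.DEFAULT_TARGET_EVENTS,
                                grid=peakcall.DEFAULT_GRID) -> pd.DataFrame:
    """Run the p-value threshold tuner over six synthetic MeRIP samples.

    Generates one calibration cohort (on the order of 1e4 planted enriched
    regions per sample, enrichments spanning 2x-16x) and tunes the adjusted-p
    threshold for each of the six samples independently. Returns a DataFrame
    with one row per sample: sample, threshold, event_count, n_windows.
    """
    cfg = simulate.calibration_config(seed)
    models, _, truth = simulate.generate_transcriptome(cfg,
                                                       with_sequences=False)
    windows = peakcall.partition_windows(models)
    gsc, dgc = cfg.sample_names()
    rows = []
    for sample in gsc + dgc:
        track = simulate.generate_merip_counts(
            cfg, models, truth, windows=windows, samples=[sample])[sample]
        peakcall.window_test(track)
        track.windows["p_adjusted"] = peakcall.adjust_pvalues(
            track.windows["p_value"])
        cal = peakcall.tune_threshold(track, grid=grid,
                                      target_events=target_events)
        rows.append({"sample": sample, "threshold": cal.threshold,
                     "event_count": cal.event_count,
                     "n_windows": len(track.windows)})
        del track
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic demonstration; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"seed": config.seed, "stages": {}}

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    # --- simulate ------------------------------------------------------
    log.info("stage simulate: generating synthetic cohort")
    models, sequences, truth = simulate.generate_transcriptome(config.sim)
    mirnas, sites, sequences = simulate.generate_mirna_targets(
        config.sim, sequences, models, truth)
    tracks = simulate.generate_merip_counts(config.sim, models, truth)
    expr = simulate.generate_expression_counts(config.sim, models, truth)
    annotation.write_gtf(models, emit(outdir / "annotation.gtf"))
    annotation.write_annotation_tsv(models, emit(outdir / "annotation.tsv"))
    annotation.write_fasta(sequences, emit(outdir / "transcripts.fa"))
    mirnas.to_csv(emit(outdir / "mirnas.tsv"), sep="\t", index=False)
    sites.to_csv(emit(outdir / "mirna_sites.tsv"), sep="\t", index=False)
    expr_out = expr.counts.copy()
    expr_out.to_csv(emit(outdir / "expression_counts.tsv"), sep="\t")
    for sample, track in tracks.items():
        simulate.write_merip_tsv(track, emit(outdir / f"merip_{sample}.tsv"))
    truth.to_json(emit(outdir / "truth.json"))
    manifest["stages"]["simulate"] = {
        "n_transcripts": len(models),
        "n_planted_peaks": len(truth.peaks),
        "n_mirnas": len(mirnas),
        "n_sites": len(sites),
    }

    gsc_names, dgc_names = config.sim.sample_names()

    # --- quantify ------------------------------------------------------
    log.info("stage quantify: RPKM and translation efficiency")
    lengths = quantify.gene_lengths(models)
    te_tables: dict[str, pd.DataFrame] = {}
    for s in gsc_names + dgc_names:
        tab = quantify.te_table(expr, lengths, f"{s}_total", f"{s}_polysome",
                                rpkm_cut=config.rpkm_cut)
        te_tables[s] = tab
        tab.to_csv(emit(outdir / f"te_{s}.tsv"), sep="\t")
    manifest["stages"]["quantify"] = {
        s: int(t["retained"].sum()) for s, t in te_tables.items()
    }

    # --- call peaks ----------------------------------------------------
    log.info("stage callpeaks: windowed MeRIP event calling")
    events_by_sample: dict[str, list] = {}
    peaks_per_sample: dict[str, pd.Series] = {}
    calls_meta = {}
    for sample, track in tracks.items():
        peakcall.window_test(track)
        track.windows["p_adjusted"] = peakcall.adjust_pvalues(
            track.windows["p_value"])
        if config.fixed_threshold is not None:
            thr = config.fixed_threshold
        else:
            cal = peakcall.tune_threshold(track, grid=config.grid(),
                                          target_events=config.target_events)
            cal.table.to_csv(
                emit(outdir / f"calibration_{sample}.tsv"), sep="\t",
                index=False)
            thr = cal.threshold
        events = peakcall.call_events(track, thr)
        events_by_sample[sample] = events
        annotation.write_events_bed(events,
                                    emit(outdir / f"events_{sample}.bed"))
        counts = pd.Series([e.gene_id for e in events]).value_counts()
        peaks_per_sample[sample] = counts
        calls_meta[sample] = {"threshold": thr, "n_events": len(events)}
    manifest["stages"]["callpeaks"] = calls_meta

    # --- integrate -----------------------------------------------------
    log.info("stage integrate: filter cascade and common set")
    pair_tables = {}
    for g, d in zip(gsc_names, dgc_names):
        pair_tables[f"{g}-{d}"] = integrate.build_pair_table(
            te_tables[g], te_tables[d],
            peaks_per_sample[g], peaks_per_sample[d])
    candidates, common = integrate.filter_cascade(
        pair_tables, rank_cut=config.rank_cut, loss_cut=config.loss_cut)
    for pair, tab in pair_tables.items():
        tab.to_csv(emit(outdir / f"pair_{pair}.tsv"), sep="\t")
    pd.Series(sorted(common), name="gene_id").to_csv(
        emit(outdir / "common_set.tsv"), sep="\t", index=False)
    master = integrate.master_table(pair_tables, gsc_names, dgc_names,
                                    peaks_per_sample)
    master.to_csv(emit(outdir / "master_table.tsv"), sep="\t")
    manifest["stages"]["integrate"] = {
        "per_pair_candidates": {p: len(c) for p, c in candidates.items()},
        "common_set": len(common),
    }

    # --- motifs --------------------------------------------------------
    log.info("stage motifs: RRACH scan and seed overlap")
    motifs = {tid: motif.scan_rrach(seq) for tid, seq in sequences.items()}
    by_tid = {m.transcript_id: m for m in models}
    events_tx = {}
    for sample, events in events_by_sample.items():
        per = {}
        for ev in events:
            proj = by_tid[ev.transcript_id].to_transcript_coords(ev.interval)
            if proj is not None:
                per.setdefault(ev.transcript_id, []).append(proj)
        events_tx[sample] = per
    annotated, summary = motif.overlap_sites_with_peaks(sites, motifs,
                                                        events_tx)
    annotated.to_csv(emit(outdir / "sites_annotated.tsv"), sep="\t",
                     index=False)
    records = [motif.MiRNARecord(r.mirna_id, r.sequence, r.expression_fc)
               for r in mirnas.itertuples()]
    selected = motif.candidate_mirnas(records, annotated, sequences,
                                      max_mismatch=config.max_mismatch,
                                      fc_cut=config.fc_cut)
    edges = motif.mirna_target_edges(annotated, selected)
    edges.to_csv(emit(outdir / "mirna_target_edges.tsv"), sep="\t",
                 index=False)
    manifest["stages"]["motifs"] = {
        "selected_mirnas": selected, **summary,
    }

    # --- pla (optional) ------------------------------------------------
    if config.pla_images > 0:
        log.info("stage pla: spot counting on synthetic images")
        images = {}
        for i in range(config.pla_images):
            n = config.pla_spots[i % len(config.pla_spots)]
            img, entry = simulate.generate_pla_image(
                n_spots=n, seed=config.seed * 1000 + i)
            image_id = f"pla{i:02d}"
            truth.spot_counts[image_id] = entry["n_spots"]
            path = emit(outdir / f"{image_id}.png")
            iio.imwrite(path, np.clip(img, 0, 255).astype(np.uint8))
            images[image_id] = img
        results = pla.count_spots_batch(images)
        results.to_csv(emit(outdir / "pla_counts.tsv"), sep="\t", index=False)
        manifest["stages"]["pla"] = {
            "n_images": len(images),
            "planted": truth.spot_counts,
            "counted": dict(zip(results["image_id"],
                                results["n_components"].astype(int))),
        }

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(written)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
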