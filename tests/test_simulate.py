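"""Generator determinism, planted structure, and moment checks."""

import re

import numpy as np
import pytest
from scipy import stats

from m6ate import quantify
from m6ate.simulate import (
    ConfigError,
    SimulationConfig,
    generate_expression_counts,
    generate_merip_counts,
    generate_mirna_targets,
    generate_pla_image,
    generate_transcriptome,
    reverse_complement,
)
from m6ate.motif import MiRNARecord, seed_complement_check

RRACH_RE = re.compile(r"(?=([AG][AG]AC[ACU]))")


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"frac_lost_peaks": 1.5},
        {"depth": 0},
        {"nb_dispersion": -1},
        {"peak_enrichment": 0.5},
        {"peak_length_range": (100, 600), "exon_length_range": (500, 900)},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs).validate()

    def test_infeasible_peak_count_rejected(self):
        cfg = SimulationConfig(peaks_per_transcript=50)
        with pytest.raises(ConfigError, match="infeasible"):
            cfg.validate()


class TestTranscriptome:
    def test_requested_number_of_transcripts(self):
        cfg = SimulationConfig(n_transcripts=50, seed=2)
        models, seqs, truth = generate_transcriptome(cfg)
        assert len(models) == 50 and len(seqs) == 50

    def test_same_seed_byte_identical(self, small_cfg, small_cohort):
        models2, seqs2, truth2 = generate_transcriptome(small_cfg)
        assert seqs2 == small_cohort["pristine_sequences"]
        assert models2 == small_cohort["models"]

    def test_count_only_mode_preserves_geometry(self, small_cfg, small_cohort):
        models2, seqs2, truth2 = generate_transcriptome(small_cfg,
                                                        with_sequences=False)
        assert models2 == small_cohort["models"]
        assert [p.interval for p in truth2.peaks] == [
            p.interval for p in small_cohort["truth"].peaks]
        assert seqs2 == {}

    def test_every_planted_peak_contains_rrach(self, small_cohort):
        seqs = small_cohort["sequences"]
        for p in small_cohort["truth"].peaks:
            inside = seqs[p.transcript_id][p.tx_start:p.tx_end]
            assert RRACH_RE.search(inside), (
                f"no RRACH inside planted peak on {p.transcript_id}")

    def test_zero_background_density_confines_motifs_to_peaks(self):
        cfg = SimulationConfig(n_transcripts=15, seed=4,
                               background_rrach_density=0.0)
        models, seqs, truth = generate_transcriptome(cfg)
        peak_ranges = {}
        for p in truth.peaks:
            peak_ranges.setdefault(p.transcript_id, []).append(
                (p.tx_start, p.tx_end))
        for tid, seq in seqs.items():
            for m in RRACH_RE.finditer(seq):
                s = m.start(1)
                assert any(a <= s and s + 5 <= b
                           for a, b in peak_ranges[tid]), (
                    f"motif at {s} outside peaks on {tid}")

    def test_truth_invariant(self, small_cohort):
        t = small_cohort["truth"]
        assert t.expected_common_set <= (
            t.lost_peak_transcripts & t.te_shifted_transcripts)

    def test_peaks_window_aligned_within_one_exon(self, small_cohort):
        by_tid = {m.transcript_id: m for m in small_cohort["models"]}
        for p in small_cohort["truth"].peaks:
            assert p.interval.length % 10 == 0
            assert 90 <= p.interval.length <= 200
            model = by_tid[p.transcript_id]
            host = [e for e in model.exons
                    if e.start <= p.interval.start and p.interval.end <= e.end]
            assert len(host) == 1, "peak must lie within a single exon"
            assert (p.interval.start - host[0].start) % 10 == 0


class TestMeripCounts:
    def test_fixed_seed_reproducible(self, small_cfg, small_cohort,
                                     merip_tracks):
        again = generate_merip_counts(small_cfg, small_cohort["models"],
                                      small_cohort["truth"])
        for s in merip_tracks:
            assert (again[s].windows["ip_count"].to_numpy()
                    == merip_tracks[s].windows["ip_count"].to_numpy()).all()

    def test_sample_subset_bit_identical(self, small_cfg, small_cohort,
                                         merip_tracks):
        sub = generate_merip_counts(small_cfg, small_cohort["models"],
                                    small_cohort["truth"], samples=["DGC2"])
        assert (sub["DGC2"].windows["input_count"].to_numpy()
                == merip_tracks["DGC2"].windows["input_count"].to_numpy()).all()

    def test_input_mean_matches_depth(self):
        cfg = SimulationConfig(n_transcripts=60, seed=9, depth=50.0)
        models, _, truth = generate_transcriptome(cfg, with_sequences=False)
        tracks = generate_merip_counts(cfg, models, truth, samples=["GSC1"])
        counts = tracks["GSC1"].windows["input_count"].to_numpy()
        assert counts.size > 10_000
        assert abs(counts.mean() - 50.0) / 50.0 < 0.05

    def test_unit_enrichment_ip_indistinguishable_from_input(self):
        """With peak_enrichment = 1 the IP and input marginals agree (KS)."""
        cfg = SimulationConfig(n_transcripts=60, seed=10, peak_enrichment=1.0)
        models, _, truth = generate_transcriptome(cfg, with_sequences=False)
        tracks = generate_merip_counts(cfg, models, truth, samples=["GSC1"])
        w = tracks["GSC1"].windows
        ks = stats.ks_2samp(w["ip_count"].to_numpy()[:10_000],
                            w["input_count"].to_numpy()[:10_000])
        assert ks.pvalue > 0.01


class TestExpressionCounts:
    def test_fixed_seed_reproducible(self, small_cfg, small_cohort,
                                     expression):
        again = generate_expression_counts(small_cfg, small_cohort["models"],
                                           small_cohort["truth"])
        assert again.counts.equals(expression.counts)

    def test_null_te_effect_gives_null_median_delta(self):
        cfg = SimulationConfig(n_transcripts=400, seed=12, te_effect=0.0)
        models, _, truth = generate_transcriptome(cfg, with_sequences=False)
        table = generate_expression_counts(cfg, models, truth)
        lengths = quantify.gene_lengths(models)
        g = quantify.te_table(table, lengths, "GSC1_total", "GSC1_polysome")
        d = quantify.te_table(table, lengths, "DGC1_total", "DGC1_polysome")
        assert abs((d["te"] - g["te"]).median()) < 0.05


class TestMirnaTargets:
    def test_planted_sites_pass_seed_check(self, small_cohort):
        seqs = small_cohort["sequences"]
        mirnas = small_cohort["mirnas"]
        truth = small_cohort["truth"]
        sites = small_cohort["sites"]
        seq_of = dict(zip(mirnas.mirna_id, mirnas.sequence))
        planted_ids = set(truth.planted_sites)
        for _, row in sites.iterrows():
            if row.mirna_id not in planted_ids:
                continue
            planted_ivs = [tuple(iv) for _, iv, _ in
                           truth.planted_sites[row.mirna_id]]
            if (row.start, row.end) not in planted_ivs:
                continue  # decoy site
            rec = MiRNARecord(row.mirna_id, seq_of[row.mirna_id])
            site_seq = seqs[row.transcript_id][row.start:row.end]
            ok, mm = seed_complement_check(rec, site_seq, max_mismatch=1)
            assert ok and mm == 0

    def test_two_mismatch_planting_fails_one_mismatch_check(self):
        cfg = SimulationConfig(n_transcripts=15, seed=6, mirna_mismatches=2)
        models, seqs, truth = generate_transcriptome(cfg)
        mirnas, sites, seqs = generate_mirna_targets(cfg, seqs, models, truth)
        seq_of = dict(zip(mirnas.mirna_id, mirnas.sequence))
        checked = 0
        for mid, planted in truth.planted_sites.items():
            rec = MiRNARecord(mid, seq_of[mid])
            for gene_id, (s, e), mm in planted:
                tid = sites[(sites.mirna_id == mid)
                            & (sites.start == s)].transcript_id.iloc[0]
                ok, got = seed_complement_check(rec, seqs[tid][s:e],
                                                max_mismatch=1)
                assert not ok and got == 2 == mm
                checked += 1
        assert checked > 0

    def test_decoy_sites_never_overlap_rrach(self, small_cohort):
        seqs = small_cohort["sequences"]
        truth = small_cohort["truth"]
        sites = small_cohort["sites"]
        planted = {(r, tuple(iv)) for r, ivs in truth.planted_sites.items()
                   for _, iv, _ in ivs}
        decoys = [row for _, row in sites.iterrows()
                  if (row.mirna_id, (row.start, row.end)) not in planted]
        assert decoys, "expected some decoy sites"
        for row in decoys:
            seq = seqs[row.transcript_id]
            motif_hits = [m.start(1) for m in RRACH_RE.finditer(seq)]
            assert not any(row.start < h + 5 and row.end > h
                           for h in motif_hits)

    def test_planted_mirnas_pass_expression_screen_decoys_fail(
            self, small_cohort):
        mirnas = small_cohort["mirnas"]
        planted = mirnas[~mirnas.mirna_id.str.startswith("decoy")]
        decoys = mirnas[mirnas.mirna_id.str.startswith("decoy")]
        assert (planted.expression_fc >= 4).all()
        assert (decoys.expression_fc < 4).all()


class TestPlaImages:
    def test_zero_spots_is_noise_only(self):
        img, entry = generate_pla_image(0, noise_sd=3.0, seed=1)
        assert entry["n_spots"] == 0
        assert img.std() < 10  # no bright blobs

    def test_fixed_seed_reproducible(self):
        a, _ = generate_pla_image(5, seed=3)
        b, _ = generate_pla_image(5, seed=3)
        assert np.array_equal(a, b)

    def test_infeasible_separation_raises(self):
        with pytest.raises(ConfigError):
            generate_pla_image(500, min_separation=100.0, shape=(64, 64),
                               seed=0)


def test_reverse_complement_involution():
    assert reverse_complement("ACGU") == "ACGU"[::-1].translate(
        str.maketrans("ACGU", "UGCA"))
    assert reverse_complement(reverse_complement("GGACUUA")) == "GGACUUA"
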