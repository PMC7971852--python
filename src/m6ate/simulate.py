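"""Synthetic data with planted ground truth for the whole pipeline.

The generators emulate the structure the analysis assumes: negative-binomial
IP/input window counts with enriched regions planted at known, window-aligned
positions; paired stem (GSC) / differentiated (DGC) polysome and total RNA
counts with a planted coupling between m6A peak loss and increased
translation efficiency; transcript sequences carrying RRACH motifs inside
planted peaks; miRNAs whose seeds reverse-complement a subset of those motif
sites; and fluorescence images with a known number of well-separated spots.

Every generator is a pure function of (config, seed). Each one draws from its
own RNG stream spawned from the master seed at a fixed offset, so adding or
re-running one generator never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CountTable, GenomicInterval, TranscriptModel
from .peakcall import WINDOW_SIZE, WindowCountTrack, partition_windows

# fixed RNG stream offsets, one per generator
_STREAM_TRANSCRIPTOME = 0
_STREAM_MERIP = 1
_STREAM_EXPRESSION = 2
_STREAM_MIRNA = 3
_STREAM_PLA = 4
_STREAM_SEQUENCE = 5

_RNA_BASES = np.array(list("ACGU"))


class ConfigError(ValueError):
    """Raised for invalid or geometrically infeasible simulation configs."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the paired design the pipeline targets: three stem (GSC)
    and three differentiated (DGC) samples, ~50 input reads per 10-nt window,
    moderate negative-binomial overdispersion, strongly enriched planted
    peaks that are lost in the differentiated state for a subset of
    transcripts, and a +2 log2-unit translation-efficiency shift coupled to
    that peak loss.
    """

    n_transcripts: int = 300
    exon_length_range: tuple[int, int] = (1000, 2500)
    n_exons_range: tuple[int, int] = (1, 3)
    n_samples_per_state: int = 3
    depth: float = 50.0            # mean input reads per 10-nt window
    nb_dispersion: float = 20.0    # NB size parameter (larger = less dispersed)
    peak_enrichment: float = 8.0   # IP/input fold inside planted peaks
    enrichment_range: tuple[float, float] | None = None  # per-peak Uniform draw
    peaks_per_transcript: int = 3
    peak_length_range: tuple[int, int] = (100, 200)
    frac_lost_peaks: float = 0.2   # per-peak probability of absence in DGCs
    te_effect: float = 2.0         # log2 TE shift for coupled transcripts
    coupling_fraction: float = 1.0  # fraction of peak-loss transcripts shifted
    expression_depth: float = 500.0  # mean total-RNA reads per gene
    expression_log_sd: float = 0.5
    expression_nb_dispersion: float = 50.0  # gene-level NB size
    te_baseline_sd: float = 0.25
    frac_rna_de: float = 0.05      # fraction of genes with a total-RNA change
    rna_de_log2fc: float = 1.0
    rrach_density: float = 10.0    # motifs per kb inside planted peaks
    background_rrach_density: float = 2.0  # motifs per kb outside peaks
    n_mirnas: int = 8
    n_decoy_mirnas: int = 4
    targets_per_mirna: int = 4
    mirna_mismatches: int = 0
    decoy_site_fraction: float = 0.5  # decoy sites per planted site
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_lost_peaks", "coupling_fraction", "frac_rna_de"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.depth <= 0 or self.expression_depth <= 0:
            raise ConfigError("depth parameters must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.peak_enrichment < 1:
            raise ConfigError("peak_enrichment must be >= 1")
        if self.enrichment_range is not None and self.enrichment_range[0] < 1:
            raise ConfigError("enrichment_range lower bound must be >= 1")
        if self.peak_length_range[0] > self.peak_length_range[1]:
            raise ConfigError("invalid peak_length_range")
        if self.peak_length_range[1] > self.exon_length_range[0]:
            raise ConfigError(
                "longest peak exceeds shortest exon: peaks could not be "
                "placed within a single exon"
            )
        lo10 = max(self.peak_length_range[0] // 10, 9)
        worst_capacity = self.n_exons_range[0] * (self.exon_length_range[0] // 10 - 3)
        if worst_capacity < self.peaks_per_transcript * (lo10 + 4):
            raise ConfigError(
                "peak geometry infeasible: shortest possible transcript "
                f"cannot host {self.peaks_per_transcript} peaks with spacers"
            )
        if self.n_transcripts <= 0 or self.n_samples_per_state <= 0:
            raise ConfigError("counts must be positive")

    def sample_names(self) -> tuple[list[str], list[str]]:
        k = self.n_samples_per_state
        return ([f"GSC{i+1}" for i in range(k)],
                [f"DGC{i+1}" for i in range(k)])


@dataclass
class PlantedPeak:
    gene_id: str
    transcript_id: str
    interval: GenomicInterval       # genomic, window-aligned
    tx_start: int                   # transcript-space
    tx_end: int
    enrichment: float
    lost: bool                      # absent in every DGC sample


@dataclass
class GroundTruth:
    """Planted structure; the acceptance surface for recovery tests."""

    peaks: list[PlantedPeak] = field(default_factory=list)
    planted_peaks: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    lost_peak_transcripts: set[str] = field(default_factory=set)
    te_shifted_transcripts: set[str] = field(default_factory=set)
    planted_sites: dict[str, list[tuple[str, tuple[int, int], int]]] = field(
        default_factory=dict)
    expected_common_set: set[str] = field(default_factory=set)
    spot_counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        inter = self.lost_peak_transcripts & self.te_shifted_transcripts
        if not self.expected_common_set <= inter:
            raise ConfigError(
                "expected_common_set must be contained in "
                "lost_peak_transcripts & te_shifted_transcripts"
            )

    def to_json(self, path) -> None:
        obj = {
            "planted_peaks": {
                s: [[iv.chrom, iv.start, iv.end, iv.strand] for iv in ivs]
                for s, ivs in self.planted_peaks.items()
            },
            "lost_peak_transcripts": sorted(self.lost_peak_transcripts),
            "te_shifted_transcripts": sorted(self.te_shifted_transcripts),
            "planted_sites": {
                m: [[g, list(iv), mm] for g, iv, mm in sites]
                for m, sites in self.planted_sites.items()
            },
            "expected_common_set": sorted(self.expected_common_set),
            "spot_counts": self.spot_counts,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg_seed), int(stream)])


def _nb_draw(rng, mean, size_param, n=None):
    """Negative binomial parameterized by (mean, size)."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n if n is not None else mean.shape)


# ---------------------------------------------------------------------------
# RRACH planting helpers
# ---------------------------------------------------------------------------

_R = "AG"
_H = "ACU"


def _is_rrach(s: str, i: int) -> bool:
    return (
        i + 5 <= len(s)
        and s[i] in _R and s[i + 1] in _R and s[i + 2] == "A"
        and s[i + 3] == "C" and s[i + 4] in _H
    )


def _find_rrach(s: str) -> list[int]:
    return [i for i in range(len(s) - 4) if _is_rrach(s, i)]


def _random_rrach(rng) -> str:
    return (rng.choice(list(_R)) + rng.choice(list(_R)) + "AC"
            + rng.choice(list(_H)))


# characters that can never satisfy the RRACH pattern at each motif slot
_SLOT_INVALID = {0: "CU", 1: "CU", 2: "CGU", 3: "AGU", 4: "G"}


def _scrub_outside(seq: list[str], allowed: np.ndarray, rng,
                   max_rounds: int = 500) -> None:
    """Destroy every RRACH occurrence not fully inside an allowed region.

    Motifs are broken by rewriting one of their bases that lies *outside*
    the allowed mask (falling back to the central A when the whole motif is
    outside), so planted motifs inside allowed regions are never touched.
    The replacement slot and character are randomized: rewrites can create
    fresh motifs nearby, and randomization breaks the rewrite cycles a fixed
    substitution rule can fall into.
    """
    for _ in range(max_rounds):
        s = "".join(seq)
        dirty = [i for i in _find_rrach(s) if not allowed[i:i + 5].all()]
        if not dirty:
            return
        for i in dirty:
            if not _is_rrach("".join(seq[i:i + 5]), 0):
                continue  # already broken by a previous rewrite
            outside = [j for j in range(5) if not allowed[i + j]]
            j = outside[int(rng.integers(len(outside)))] if outside else 2
            seq[i + j] = str(rng.choice(list(_SLOT_INVALID[j])))
    raise RuntimeError("RRACH scrubbing did not converge")


def _plant_motifs(seq: list[str], lo: int, hi: int, n: int, rng,
                  reserved: list[tuple[int, int]]) -> int:
    """Plant up to ``n`` non-overlapping RRACH motifs inside [lo, hi)."""
    planted = 0
    tries = 0
    while planted < n and tries < 50 * max(n, 1):
        tries += 1
        if hi - lo < 5:
            break
        pos = int(rng.integers(lo, hi - 4))
        if any(pos < e and pos + 5 > s for s, e in reserved):
            continue
        motif = _random_rrach(rng)
        seq[pos:pos + 5] = list(motif)
        reserved.append((pos, pos + 5))
        planted += 1
    return planted


# ---------------------------------------------------------------------------
# Transcriptome + planted peaks + sequences
# ---------------------------------------------------------------------------


def generate_transcriptome(cfg: SimulationConfig, with_sequences: bool = True):
    """Generate transcript models, sequences, and the planted-peak truth.

    Returns ``(models, sequences, truth)`` where ``sequences`` maps
    transcript_id to its spliced RNA sequence (5'->3'). Every planted peak is
    window-aligned within a single exon and contains at least one RRACH
    motif; outside peaks, RRACH occurs at ``background_rrach_density``.
    ``with_sequences=False`` skips sequence synthesis (for count-only
    simulations); the RNG stream consumed by the geometry is unchanged, so
    models and peaks are identical either way.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STREAM_TRANSCRIPTOME)
    rng_seq = _rng(cfg.seed, _STREAM_SEQUENCE)
    models: list[TranscriptModel] = []
    truth = GroundTruth()
    sequences: dict[str, str] = {}
    chrom_cursor: dict[str, int] = {}
    gsc_names, dgc_names = cfg.sample_names()

    for i in range(cfg.n_transcripts):
        gene_id = f"gene{i:05d}"
        transcript_id = f"tx{i:05d}"
        chrom = f"chr{(i % 8) + 1}"
        strand = "+" if rng.random() < 0.8 else "-"
        n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
        cursor = chrom_cursor.get(chrom, 1000)
        exon_list = []
        for _ in range(n_exons):
            length = int(rng.integers(cfg.exon_length_range[0],
                                      cfg.exon_length_range[1] + 1))
            exon_list.append((cursor, cursor + length))
            cursor += length + int(rng.integers(200, 2000))  # intron / gap
        chrom_cursor[chrom] = cursor + int(rng.integers(500, 3000))
        genomic_exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_list]
        if strand == "-":
            genomic_exons = genomic_exons[::-1]  # transcript orientation
        seq_len = sum(e.length for e in genomic_exons)
        cds_start = int(round(seq_len * rng.uniform(0.1, 0.2)))
        cds_end = int(round(seq_len * rng.uniform(0.75, 0.9)))
        model = TranscriptModel(gene_id, transcript_id, tuple(genomic_exons),
                                cds_start, cds_end)
        models.append(model)

        # --- plant window-aligned peaks, each within a single exon ---
        # greedy per-exon cursor: peaks fill exons left-to-right with >= 2
        # spacer windows, keeping clear of the merged terminal window
        n_peaks = cfg.peaks_per_transcript
        lo10 = max(cfg.peak_length_range[0] // WINDOW_SIZE, 9)
        hi10 = cfg.peak_length_range[1] // WINDOW_SIZE
        capacity = [e.length // WINDOW_SIZE - 1 for e in model.exons]
        cursor = [int(rng.integers(0, 3)) for _ in model.exons]
        peaks: list[PlantedPeak] = []
        for _ in range(n_peaks):
            free = [capacity[ei] - cursor[ei] for ei in range(len(model.exons))]
            ei = int(np.argmax(free))
            remaining = n_peaks - len(peaks)
            total_free = sum(f for f in free if f >= lo10)
            # reserve room (peak + spacer) for the peaks still to be placed
            k_max = min(hi10, free[ei], total_free - (remaining - 1) * (lo10 + 4))
            if k_max < lo10:
                raise ConfigError(
                    f"could not place {n_peaks} peaks on {transcript_id}: "
                    "peak geometry infeasible for the configured exon lengths"
                )
            k = int(rng.integers(lo10, k_max + 1))
            exon = model.exons[ei]
            w0 = cursor[ei]
            cursor[ei] += k + 2 + int(rng.integers(0, 3))
            g0 = exon.start + WINDOW_SIZE * w0
            g1 = g0 + WINDOW_SIZE * k
            iv = GenomicInterval(chrom, g0, g1, strand)
            tx_start, tx_end = model.to_transcript_coords(iv)
            if cfg.enrichment_range is not None:
                enr = float(rng.uniform(*cfg.enrichment_range))
            else:
                enr = cfg.peak_enrichment
            lost = bool(rng.random() < cfg.frac_lost_peaks)
            peaks.append(PlantedPeak(gene_id, transcript_id, iv,
                                     tx_start, tx_end, enr, lost))
        truth.peaks.extend(peaks)
        if sum(p.lost for p in peaks) >= 2:
            truth.lost_peak_transcripts.add(gene_id)

        # --- sequence with controlled RRACH content ---
        if with_sequences:
            seq = list(rng_seq.choice(_RNA_BASES, size=seq_len))
            allowed = np.zeros(seq_len, dtype=bool)
            for p in peaks:
                allowed[p.tx_start:p.tx_end] = True
            reserved: list[tuple[int, int]] = []
            for p in peaks:
                n_inside = max(1, int(round(cfg.rrach_density
                                            * (p.tx_end - p.tx_start) / 1000.0)))
                got = _plant_motifs(seq, p.tx_start, p.tx_end - 5, n_inside,
                                    rng_seq, reserved)
                if got == 0:
                    raise ConfigError(f"could not plant RRACH inside peak on "
                                      f"{transcript_id}")
            if cfg.background_rrach_density > 0:
                outside_nt = seq_len - int(allowed.sum())
                n_bg = int(round(cfg.background_rrach_density * outside_nt / 1000.0))
                bg_planted = 0
                bg_tries = 0
                while bg_planted < n_bg and bg_tries < 50 * max(n_bg, 1):
                    bg_tries += 1
                    pos = int(rng_seq.integers(0, seq_len - 4))
                    if allowed[pos:pos + 5].any():
                        continue
                    if any(pos < e and pos + 5 > s for s, e in reserved):
                        continue
                    seq[pos:pos + 5] = list(_random_rrach(rng_seq))
                    reserved.append((pos, pos + 5))
                    allowed[pos:pos + 5] = True  # keep background plants intact
                    bg_planted += 1
            _scrub_outside(seq, allowed, rng_seq)
            sequences[transcript_id] = "".join(seq)

    # per-sample planted-peak map: GSCs carry all peaks, DGCs the non-lost
    for s in gsc_names:
        truth.planted_peaks[s] = [p.interval for p in truth.peaks]
    for s in dgc_names:
        truth.planted_peaks[s] = [p.interval for p in truth.peaks if not p.lost]

    # TE coupling
    lost = sorted(truth.lost_peak_transcripts)
    n_coupled = int(round(cfg.coupling_fraction * len(lost)))
    coupled = set(rng.choice(lost, size=n_coupled, replace=False)) if n_coupled else set()
    truth.te_shifted_transcripts = {str(g) for g in coupled}
    truth.expected_common_set = set(truth.te_shifted_transcripts)
    truth.validate()
    return models, sequences, truth


# ---------------------------------------------------------------------------
# MeRIP window counts
# ---------------------------------------------------------------------------


def generate_merip_counts(cfg: SimulationConfig,
                          models: list[TranscriptModel],
                          truth: GroundTruth,
                          windows: pd.DataFrame | None = None,
                          samples: list[str] | None = None,
                          ) -> dict[str, WindowCountTrack]:
    """Per-sample NB window counts with IP enrichment inside planted peaks.

    Input counts are NB(depth, size) everywhere; IP counts are
    NB(depth * enrichment, size) inside planted peaks carried by the sample
    and NB(depth, size) elsewhere. Per-sample totals are the sums over all
    windows. Pass a precomputed ``windows`` skeleton to avoid re-tiling, and
    ``samples`` to generate a subset; each sample has its own RNG stream, so
    a subset is bit-identical to the same samples from a full run.
    """
    cfg.validate()
    if windows is None:
        windows = partition_windows(models)
    n = len(windows)
    w_start = windows["start"].to_numpy()
    w_end = windows["end"].to_numpy()
    w_tid = windows["transcript_id"].to_numpy()

    # per-window enrichment lookup, per state (peaks are window-aligned, so
    # containment of the window midpoint suffices)
    mid = (w_start + w_end) // 2
    enr_gsc = np.ones(n)
    enr_dgc = np.ones(n)
    by_tid: dict[str, list[PlantedPeak]] = {}
    for p in truth.peaks:
        by_tid.setdefault(p.transcript_id, []).append(p)
    order = np.argsort(w_tid, kind="stable")
    sorted_tid = w_tid[order]
    for tid, peaks in by_tid.items():
        rows = order[np.searchsorted(sorted_tid, tid, side="left"):
                     np.searchsorted(sorted_tid, tid, side="right")]
        for p in peaks:
            inside = rows[(mid[rows] >= p.interval.start)
                          & (mid[rows] < p.interval.end)]
            enr_gsc[inside] = p.enrichment
            if not p.lost:
                enr_dgc[inside] = p.enrichment

    gsc_names, dgc_names = cfg.sample_names()
    plan = [(s, i, enr_gsc) for i, s in enumerate(gsc_names)] + [
        (s, len(gsc_names) + i, enr_dgc) for i, s in enumerate(dgc_names)]
    if samples is not None:
        unknown = set(samples) - {s for s, _, _ in plan}
        if unknown:
            raise ConfigError(f"unknown samples {sorted(unknown)}")
        plan = [p for p in plan if p[0] in samples]
    out: dict[str, WindowCountTrack] = {}
    for sample, sample_idx, enr in plan:
        rng = np.random.default_rng([int(cfg.seed), _STREAM_MERIP, sample_idx])
        w = windows.copy()
        w["input_count"] = _nb_draw(rng, np.full(n, cfg.depth), cfg.nb_dispersion)
        w["ip_count"] = _nb_draw(rng, cfg.depth * enr, cfg.nb_dispersion)
        out[sample] = WindowCountTrack(
            sample_id=sample,
            windows=w,
            ip_total=int(w["ip_count"].sum()),
            input_total=int(w["input_count"].sum()),
        )
    return out


# ---------------------------------------------------------------------------
# Polysome / total RNA counts
# ---------------------------------------------------------------------------


def generate_expression_counts(cfg: SimulationConfig,
                               models: list[TranscriptModel],
                               truth: GroundTruth) -> CountTable:
    """Paired polysome/total counts for both states.

    Total-RNA expected counts are equal across states except for a small
    ``frac_rna_de`` subset; the polysome:total ratio of coupled (TE-shifted)
    transcripts is 2**te_effect higher in the differentiated state.
    Columns are named ``<sample>_total`` / ``<sample>_polysome``.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STREAM_EXPRESSION)
    genes = [m.gene_id for m in models]
    n = len(genes)
    base = np.exp(rng.normal(np.log(cfg.expression_depth),
                             cfg.expression_log_sd, size=n))
    te0 = rng.normal(0.0, cfg.te_baseline_sd, size=n)
    de_mask = rng.random(n) < cfg.frac_rna_de
    de_sign = rng.choice([-1.0, 1.0], size=n)
    mean_total_dgc = base * np.where(de_mask,
                                     2.0 ** (de_sign * cfg.rna_de_log2fc), 1.0)
    shifted = np.array([m.gene_id in truth.te_shifted_transcripts
                        for m in models])
    te_dgc = te0 + np.where(shifted, cfg.te_effect, 0.0)

    gsc_names, dgc_names = cfg.sample_names()
    data = {}
    size = cfg.expression_nb_dispersion
    for s in gsc_names:
        data[f"{s}_total"] = _nb_draw(rng, base, size)
        data[f"{s}_polysome"] = _nb_draw(rng, base * 2.0 ** te0, size)
    for s in dgc_names:
        data[f"{s}_total"] = _nb_draw(rng, mean_total_dgc, size)
        data[f"{s}_polysome"] = _nb_draw(rng, mean_total_dgc * 2.0 ** te_dgc,
                                         size)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    lib = counts.sum(axis=0)
    return CountTable(counts=counts, library_sizes=lib)


# ---------------------------------------------------------------------------
# miRNA seeds and predicted target sites
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _mutate(seq: str, k: int, rng) -> str:
    """Substitute ``k`` distinct positions with a different base."""
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        choices = [b for b in "ACGU" if b != s[pos]]
        s[pos] = str(rng.choice(choices))
    return "".join(s)


def generate_mirna_targets(cfg: SimulationConfig,
                           sequences: dict[str, str],
                           models: list[TranscriptModel],
                           truth: GroundTruth):
    """Plant miRNAs complementary to in-peak RRACH sites, plus decoys.

    Returns ``(mirnas, sites, sequences_out)``: ``mirnas`` is a DataFrame
    (mirna_id, sequence, expression_fc); ``sites`` a BED-like DataFrame
    (mirna_id, gene_id, transcript_id, start, end) in transcript
    coordinates; ``sequences_out`` the input sequences with the site
    7-mers implanted (the input dict is left untouched). Planted
    miRNAs have a seed (positions 2-8) reverse-complementary to a 7-nt site
    covering an RRACH motif inside a planted peak, with exactly
    ``mirna_mismatches`` mismatches, and an expression fold change >= 4.
    Decoy sites avoid RRACH entirely; decoy miRNAs fail the expression
    screen.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STREAM_MIRNA)
    gene_of = {m.transcript_id: m.gene_id for m in models}
    seqs = {tid: list(s) for tid, s in sequences.items()}
    peaks_by_tid: dict[str, list[PlantedPeak]] = {}
    for p in truth.peaks:
        peaks_by_tid.setdefault(p.transcript_id, []).append(p)
    tids = sorted(peaks_by_tid)
    reserved: dict[str, list[tuple[int, int]]] = {t: [] for t in seqs}

    mirna_rows = []
    site_rows = []
    for j in range(cfg.n_mirnas):
        mid_ = f"mir{j + 1:03d}"
        # 7-nt site template: x + RRACH + y (motif fully inside the site)
        site_seq = (str(rng.choice(list("ACGU"))) + _random_rrach(rng)
                    + str(rng.choice(list("ACGU"))))
        seed = reverse_complement(site_seq)
        if cfg.mirna_mismatches:
            seed = _mutate(seed, cfg.mirna_mismatches, rng)
        mismatches = sum(a != b for a, b in
                         zip(site_seq, reverse_complement(seed)))
        tail = "".join(rng.choice(_RNA_BASES, size=14))
        mirna_seq = str(rng.choice(list("ACGU"))) + seed + tail
        fc = float(rng.uniform(4.5, 12.0))
        mirna_rows.append({"mirna_id": mid_, "sequence": mirna_seq,
                           "expression_fc": round(fc, 3)})
        truth.planted_sites[mid_] = []
        targets = rng.choice(tids, size=min(cfg.targets_per_mirna, len(tids)),
                             replace=False)
        for tid in targets:
            placed = False
            for _ in range(100):
                p = peaks_by_tid[tid][int(rng.integers(0, len(peaks_by_tid[tid])))]
                if p.tx_end - p.tx_start < 17:
                    continue
                s = int(rng.integers(p.tx_start + 5, p.tx_end - 12))
                if any(s < e and s + 7 > a for a, e in reserved[tid]):
                    continue
                seqs[tid][s:s + 7] = list(site_seq)
                reserved[tid].append((s, s + 7))
                site_rows.append({"mirna_id": mid_, "gene_id": gene_of[tid],
                                  "transcript_id": tid, "start": s, "end": s + 7})
                truth.planted_sites[mid_].append(
                    (gene_of[tid], (s, s + 7), mismatches))
                placed = True
                break
            if not placed:
                raise ConfigError(f"could not place site for {mid_} on {tid}")
        # decoy sites: off-RRACH placements of a motif-free 7-mer
        n_decoy = int(round(cfg.decoy_site_fraction * len(targets)))
        for _ in range(n_decoy):
            for _try in range(200):
                tid = str(rng.choice(tids))
                seq = seqs[tid]
                s = int(rng.integers(5, len(seq) - 12))
                if any(s < e and s + 7 > a for a, e in reserved[tid]):
                    continue
                # never overwrite peak interiors: a decoy must not destroy a
                # peak's planted RRACH content
                if any(s < p.tx_end and s + 7 > p.tx_start
                       for p in peaks_by_tid[tid]):
                    continue
                decoy = _decoy_7mer(rng, site_seq)
                old = seq[s:s + 7]
                seq[s:s + 7] = list(decoy)
                ctx = "".join(seq[max(0, s - 4):s + 11])
                hits = [h for h in _find_rrach(ctx)
                        if h + max(0, s - 4) + 5 > s and h + max(0, s - 4) < s + 7]
                if hits:
                    seq[s:s + 7] = old  # would overlap RRACH; retry
                    continue
                reserved[tid].append((s, s + 7))
                site_rows.append({"mirna_id": mid_, "gene_id": gene_of[tid],
                                  "transcript_id": tid, "start": s, "end": s + 7})
                break
    for j in range(cfg.n_decoy_mirnas):
        mid_ = f"decoymir{j + 1:03d}"
        seq = "".join(rng.choice(_RNA_BASES, size=22))
        fc = float(rng.uniform(0.3, 3.5))
        mirna_rows.append({"mirna_id": mid_, "sequence": seq,
                           "expression_fc": round(fc, 3)})
    sequences_out = {tid: "".join(chars) for tid, chars in seqs.items()}
    mirnas = pd.DataFrame(mirna_rows)
    sites = pd.DataFrame(site_rows,
                         columns=["mirna_id", "gene_id", "transcript_id",
                                  "start", "end"])
    return mirnas, sites, sequences_out


def _decoy_7mer(rng, avoid_site_seq: str) -> str:
    """A 7-mer with no internal RRACH and >= 2 mismatches to the planted site."""
    while True:
        s = "".join(rng.choice(np.array(list("CGU")), size=7))  # no A: no RRACH
        if sum(a != b for a, b in zip(s, avoid_site_seq)) >= 2:
            return s


# ---------------------------------------------------------------------------
# PLA spot images
# ---------------------------------------------------------------------------


def generate_pla_image(n_spots: int,
                       spot_sigma: float = 2.0,
                       min_separation: float = 12.0,
                       noise_sd: float = 5.0,
                       seed: int = 0,
                       shape: tuple[int, int] = (256, 256),
                       amplitude: float = 150.0,
                       background: float = 20.0,
                       centers: np.ndarray | None = None):
    """An image with ``n_spots`` Gaussian blobs and additive Gaussian noise.

    Blob centroids keep a pairwise distance >= ``min_separation`` and stay
    ``3*spot_sigma`` clear of the borders. Returns ``(image, truth_entry)``
    where the truth entry records the planted count. Raises ``ConfigError``
    when the requested separation cannot be achieved in the given shape.
    """
    rng = _rng(seed, _STREAM_PLA)
    h, w = shape
    margin = 3.0 * spot_sigma
    if centers is None:
        centers_list: list[tuple[float, float]] = []
        tries = 0
        while len(centers_list) < n_spots:
            tries += 1
            if tries > 20000:
                raise ConfigError(
                    f"cannot place {n_spots} spots with separation "
                    f">= {min_separation} in a {h}x{w} image"
                )
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if all((y - cy) ** 2 + (x - cx) ** 2 >= min_separation ** 2
                   for cy, cx in centers_list):
                centers_list.append((y, x))
        centers = np.array(centers_list).reshape(-1, 2)
    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx in centers:
        img += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                                  / (2.0 * spot_sigma ** 2))
    img += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(img, 0.0, 255.0), {"n_spots": int(n_spots)}


# ---------------------------------------------------------------------------
# Bundled writer
# ---------------------------------------------------------------------------


def write_merip_tsv(track: WindowCountTrack, path) -> None:
    df = track.windows.copy()
    df.attrs = {}
    df.to_csv(path, sep="\t", index=False)


def calibration_config(seed: int) -> SimulationConfig:
    """Study conditions for the event-count calibration of the threshold
    tuner: a large transcriptome planting ~1.5e4 enriched regions per sample
    over a 2x-16x enrichment range, so the number of called events sweeps
    through the ~1e4 target as the threshold grid moves from 1e-03 to
    1e-40."""
    return SimulationConfig(
        n_transcripts=2500,
        peaks_per_transcript=5,
        exon_length_range=(2000, 3600),
        n_exons_range=(2, 2),
        enrichment_range=(2.0, 16.0),
        frac_lost_peaks=0.0,
        n_mirnas=0,
        n_decoy_mirnas=0,
        seed=seed,
    )
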