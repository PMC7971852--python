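"""RRACH motif scanning, miRNA seed complementarity, and site overlap.

RRACH (R = A/G, H = A/C/U) is the canonical sequence context of m6A. Seed
complementarity is assessed over the 7mer-m8 frame: miRNA positions 2-8
(0-based ``sequence[1:8]``) against the reverse complement of the 7-nt site
sequence, tolerating at most one mismatch by default. All site coordinates
are transcript-space, 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import (
    REGION_3UTR,
    REGION_5UTR,
    REGION_CDS,
    REGIONS,
    RNA_ALPHABET,
    TranscriptModel,
)
from .simulate import reverse_complement

DEFAULT_MAX_MISMATCH = 1
DEFAULT_FC_CUT = 4.0

MOTIF_LEN = 5
SEED_LEN = 7


@dataclass
class MiRNARecord:
    """A miRNA: 5'->3' RNA sequence plus its DGC/GSC expression fold change."""

    mirna_id: str
    sequence: str
    expression_fc: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError(f"{self.mirna_id}: sequence shorter than 8 nt")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.mirna_id}: invalid bases {sorted(bad)}")

    @property
    def seed(self) -> str:
        """Seed region: positions 2-8 (1-based), i.e. sequence[1:8]."""
        return self.sequence[1:8]


def scan_rrach(sequence: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) RRACH matches as 5-nt half-open intervals."""
    bad = [(i, ch) for i, ch in enumerate(sequence) if ch not in RNA_ALPHABET]
    if bad:
        i, ch = bad[0]
        raise ValueError(f"invalid character {ch!r} at position {i}")
    if len(sequence) < MOTIF_LEN:
        return []
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_r = (arr == ord("A")) | (arr == ord("G"))
    is_h = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("U"))
    hit = (
        is_r[:-4] & is_r[1:-3]
        & (arr[2:-2] == ord("A")) & (arr[3:-1] == ord("C")) & is_h[4:]
    )
    return [(int(i), int(i) + MOTIF_LEN) for i in np.flatnonzero(hit)]


def seed_complement_check(mirna: MiRNARecord,
                          site_seq: str,
                          max_mismatch: int = DEFAULT_MAX_MISMATCH):
    """Does the site reverse-complement the miRNA seed within ``max_mismatch``?

    Returns ``(ok, mismatches)`` where ``mismatches`` is the Hamming distance
    between the site sequence and the reverse complement of the seed.
    """
    if len(site_seq) != SEED_LEN:
        raise ValueError(
            f"site sequence must be {SEED_LEN} nt, got {len(site_seq)}"
        )
    target = reverse_complement(mirna.seed)
    mismatches = sum(a != b for a, b in zip(site_seq, target))
    return mismatches <= max_mismatch, mismatches


def overlap_sites_with_peaks(sites: pd.DataFrame,
                             motifs: dict[str, list[tuple[int, int]]],
                             events_tx: dict[str, dict[str, list[tuple[int, int]]]]):
    """Annotate target sites with RRACH and peak overlap.

    ``sites`` needs columns (mirna_id, gene_id, transcript_id, start, end)
    in transcript coordinates. ``motifs`` maps transcript_id to RRACH
    intervals; ``events_tx`` maps sample -> transcript_id -> event intervals
    (already projected to transcript space). Adds ``overlaps_rrach``,
    per-sample ``in_peak_<sample>`` columns, and ``overlaps_peak`` (true when
    the site lies inside an event in *every* sample). Returns
    ``(annotated sites, summary)`` where the summary counts transcripts with
    at least one all-sample in-peak site.
    """
    out = sites.copy()
    ov_rrach = []
    per_sample = {s: [] for s in events_tx}
    for _, row in out.iterrows():
        s, e, tid = int(row["start"]), int(row["end"]), row["transcript_id"]
        ms = motifs.get(tid, [])
        ov_rrach.append(any(s < me and e > ms_ for ms_, me in ms))
        for sample, by_tid in events_tx.items():
            evs = by_tid.get(tid, [])
            per_sample[sample].append(
                any(s < ee and e > es for es, ee in evs))
    out["overlaps_rrach"] = ov_rrach
    for sample, flags in per_sample.items():
        out[f"in_peak_{sample}"] = flags
    flag_cols = [f"in_peak_{s}" for s in events_tx]
    out["overlaps_peak"] = out[flag_cols].all(axis=1) if flag_cols else False
    n_transcripts = out.loc[out["overlaps_peak"], "transcript_id"].nunique()
    summary = {
        "transcripts_with_in_peak_site": int(n_transcripts),
        "sites_in_peak_all_samples": int(out["overlaps_peak"].sum()),
    }
    return out, summary


def site_region_fractions(sites: pd.DataFrame,
                          models: list[TranscriptModel]):
    """Per-miRNA region fractions and per-region RRACH-overlap fractions.

    Sites are classified against the 5'UTR/CDS/3'UTR segmentation by
    majority overlap. Returns ``(region_fractions, rrach_fractions,
    n_excluded)``: region fractions sum to 1 per miRNA; the RRACH fraction of
    a region is the share of that region's sites overlapping a motif
    (requires an ``overlaps_rrach`` column). Sites outside transcript bounds
    are excluded and counted.
    """
    by_tid = {m.transcript_id: m for m in models}
    rows = []
    excluded = 0
    for _, row in sites.iterrows():
        model = by_tid.get(row["transcript_id"])
        if model is None:
            excluded += 1
            continue
        s, e = int(row["start"]), int(row["end"])
        if not (0 <= s < e <= model.sequence_length):
            excluded += 1
            continue
        rows.append({
            "mirna_id": row["mirna_id"],
            "region": model.region_of(s, e),
            "overlaps_rrach": bool(row.get("overlaps_rrach", False)),
        })
    classified = pd.DataFrame(rows, columns=["mirna_id", "region",
                                             "overlaps_rrach"])
    region_fractions = {}
    for mid, grp in classified.groupby("mirna_id"):
        n = len(grp)
        region_fractions[mid] = {
            r: float((grp["region"] == r).sum()) / n for r in REGIONS
        }
    rrach_fractions = {}
    for r in REGIONS:
        in_region = classified[classified["region"] == r]
        rrach_fractions[r] = (
            float(in_region["overlaps_rrach"].sum()) / len(in_region)
            if len(in_region) else float("nan")
        )
    return region_fractions, rrach_fractions, excluded


def mirna_expression_screen(records: list[MiRNARecord],
                            fc_cut: float = DEFAULT_FC_CUT) -> list[MiRNARecord]:
    """miRNAs whose expression increases >= ``fc_cut``-fold with
    differentiation (boundary inclusive)."""
    return [r for r in records if r.expression_fc >= fc_cut]


def candidate_mirnas(records: list[MiRNARecord],
                     annotated_sites: pd.DataFrame,
                     sequences: dict[str, str],
                     max_mismatch: int = DEFAULT_MAX_MISMATCH,
                     fc_cut: float = DEFAULT_FC_CUT) -> list[str]:
    """miRNAs passing both the seed-complementarity-in-peak check and the
    expression screen.

    A miRNA qualifies when at least one of its sites lies inside a
    methylation event in every sample (``overlaps_peak``) and the site
    sequence reverse-complements its seed within ``max_mismatch``.
    """
    screened = {r.mirna_id: r for r in
                mirna_expression_screen(records, fc_cut=fc_cut)}
    hits = []
    for mid, grp in annotated_sites.groupby("mirna_id"):
        rec = screened.get(mid)
        if rec is None:
            continue
        for _, row in grp[grp["overlaps_peak"]].iterrows():
            seq = sequences[row["transcript_id"]]
            site_seq = seq[int(row["start"]):int(row["end"])]
            ok, _ = seed_complement_check(rec, site_seq,
                                          max_mismatch=max_mismatch)
            if ok:
                hits.append(mid)
                break
    return sorted(hits)


def mirna_target_edges(annotated_sites: pd.DataFrame,
                       selected: list[str]) -> pd.DataFrame:
    """Bipartite miRNA-target edge list restricted to in-peak sites of the
    selected miRNAs."""
    sel = annotated_sites[
        annotated_sites["mirna_id"].isin(selected)
        & annotated_sites["overlaps_peak"]
    ]
    return (sel[["mirna_id", "gene_id"]]
            .drop_duplicates()
            .sort_values(["mirna_id", "gene_id"])
            .reset_index(drop=True))
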