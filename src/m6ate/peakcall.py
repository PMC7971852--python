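"""Windowed MeRIP-seq methylation-event calling.

Each exon is partitioned into contiguous 10-nt windows (a terminal remainder
shorter than 10 nt is merged into the preceding window). Per window, IP
enrichment over the input control is assessed with a one-sided Fisher exact
test whose control cell is the mean input count over the whole parent exon —
this damps local fluctuations in the input track. P-values are
Benjamini-Hochberg adjusted across all windows of a sample, runs of adjacent
significant windows are joined into candidate regions, regions of at least
90 nt become methylation events, and regions longer than 200 nt are split
into consecutive 200-nt events from the 5' end (a terminal remainder is kept
only if it is itself at least 90 nt). The significance threshold is tuned on
a log-spaced grid so that each sample yields approximately a target number of
events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .annotation import GenomicInterval, MethylationEvent, TranscriptModel

WINDOW_SIZE = 10
MIN_EVENT_NT = 90
MAX_EVENT_NT = 200
DEFAULT_TARGET_EVENTS = 10_000

#: 38 log-spaced thresholds from 1e-03 down to 1e-40, one per decade.
DEFAULT_GRID = tuple(10.0 ** -e for e in range(3, 41))


@dataclass
class WindowCountTrack:
    """Window skeleton plus per-sample IP/input counts and totals.

    ``windows`` has one row per window with columns: window_id, gene_id,
    transcript_id, exon_index, chrom, start, end, strand, tx_start, tx_end,
    length, and (once counts are attached) ip_count, input_count,
    input_exon_mean.
    """

    sample_id: str
    windows: pd.DataFrame
    ip_total: int = 0
    input_total: int = 0


def partition_windows(models: list[TranscriptModel]) -> pd.DataFrame:
    """Tile every exon with contiguous 10-nt windows, left-to-right in genome
    coordinates; a terminal remainder < 10 nt is merged into the last window."""
    meta: list[tuple[str, str, int, str, str]] = []  # per-exon metadata
    counts: list[int] = []                            # windows per exon
    starts_all, ends_all, tx_s_all, tx_e_all = [], [], [], []
    for m in models:
        offset = 0
        for ei, exon in enumerate(m.exons):
            n_windows = max(1, exon.length // WINDOW_SIZE)
            starts = exon.start + WINDOW_SIZE * np.arange(n_windows)
            ends = starts + WINDOW_SIZE
            ends[-1] = exon.end  # absorb remainder (or short exon)
            if m.strand == "+":
                tx_s = offset + (starts - exon.start)
                tx_e = offset + (ends - exon.start)
            else:
                tx_s = offset + (exon.end - ends)
                tx_e = offset + (exon.end - starts)
            meta.append((m.gene_id, m.transcript_id, ei, exon.chrom,
                         exon.strand))
            counts.append(n_windows)
            starts_all.append(starts)
            ends_all.append(ends)
            tx_s_all.append(tx_s)
            tx_e_all.append(tx_e)
            offset += exon.length
    reps = np.array(counts, dtype=int)
    n = int(reps.sum()) if len(reps) else 0
    df = pd.DataFrame(
        {
            "gene_id": pd.Categorical(
                np.repeat([m[0] for m in meta], reps)) if n else [],
            "transcript_id": pd.Categorical(
                np.repeat([m[1] for m in meta], reps)) if n else [],
            "exon_index": np.repeat([m[2] for m in meta], reps) if n else [],
            "chrom": pd.Categorical(
                np.repeat([m[3] for m in meta], reps)) if n else [],
            "start": np.concatenate(starts_all) if n else [],
            "end": np.concatenate(ends_all) if n else [],
            "strand": pd.Categorical(
                np.repeat([m[4] for m in meta], reps)) if n else [],
            "tx_start": np.concatenate(tx_s_all) if n else [],
            "tx_end": np.concatenate(tx_e_all) if n else [],
            # global running exon counter: run joining never crosses it
            "exon_key": np.repeat(np.arange(len(reps)), reps) if n else [],
        }
    )
    df["length"] = df["end"] - df["start"]
    df.insert(0, "window_id", np.arange(n))
    return df


def fisher_greater(a, b, c, d, rel_tol: float = 1e-15, max_iter: int = 10_000):
    """Vectorized one-sided (enrichment) Fisher exact p-value.

    For 2x2 tables [[a, b], [c, d]] with fixed margins, returns
    P(X >= a) where X is hypergeometric. Computed exactly via the log-pmf at
    ``a`` and the multiplicative term recurrence along the upper tail, which
    stays fast for the very large margins of genome-wide window tests.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("negative cell in 2x2 table")
    M = a + b + c + d
    K = a + c          # first-column margin (successes)
    n1 = a + b         # first-row margin (draws)
    kmax = np.minimum(K, n1)
    lp0 = (
        gammaln(K + 1) - gammaln(a + 1) - gammaln(K - a + 1)
        + gammaln(M - K + 1) - gammaln(n1 - a + 1) - gammaln(M - K - (n1 - a) + 1)
        - (gammaln(M + 1) - gammaln(n1 + 1) - gammaln(M - n1 + 1))
    )
    term = np.ones(lp0.shape)
    acc = np.ones(lp0.shape)
    k = a.astype(np.float64).copy()
    Mf, Kf, nf = (x.astype(np.float64) for x in (M, K, n1))
    active = k < kmax
    it = 0
    while active.any() and it < max_iter:
        ratio = np.where(active, (Kf - k) * (nf - k) /
                         ((k + 1) * (Mf - Kf - nf + k + 1)), 0.0)
        term = term * ratio
        acc += term
        k += 1
        active = (k < kmax) & (term > rel_tol * acc)
        it += 1
    return np.minimum(np.exp(lp0) * acc, 1.0)


def attach_exon_means(track: WindowCountTrack) -> WindowCountTrack:
    """Add the per-exon mean input window count used as the control cell."""
    w = track.windows
    key = "exon_key" if "exon_key" in w.columns else None
    if key is None:
        w["exon_key"] = pd.factorize(
            w["transcript_id"].astype(str) + ":"
            + w["exon_index"].astype(str))[0]
    w["input_exon_mean"] = w.groupby(
        "exon_key", sort=False)["input_count"].transform("mean")
    return track


def window_test(track: WindowCountTrack) -> np.ndarray:
    """One-sided Fisher exact p per window.

    Table: [[ip_count, ip_total - ip_count],
            [round(input_exon_mean), input_total - round(input_exon_mean)]].
    The control cell substitutes the exon-mean input count (rounded to the
    nearest integer, since the hypergeometric support is integral).
    """
    if track.ip_total <= 0 or track.input_total <= 0:
        raise ValueError("sample totals must be positive")
    w = track.windows
    if "input_exon_mean" not in w.columns:
        attach_exon_means(track)
    a = w["ip_count"].to_numpy(dtype=np.int64)
    if (a > track.ip_total).any():
        raise ValueError("ip_count exceeds ip_total")
    c = np.rint(w["input_exon_mean"].to_numpy()).astype(np.int64)
    p = fisher_greater(a, track.ip_total - a, c, track.input_total - c)
    w["p_value"] = p
    return p


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _run_boundaries(windows: pd.DataFrame, significant: np.ndarray):
    """Start/end row indices of maximal runs of significant windows.

    Runs never cross exon (or transcript) boundaries; windows are assumed to
    be in partition order (contiguous within each exon).
    """
    sig = np.asarray(significant, dtype=bool)
    n = sig.size
    if n == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    if "exon_key" in windows.columns:
        exon_key = windows["exon_key"].to_numpy()
    else:
        exon_key = pd.factorize(
            windows["transcript_id"].astype(str) + ":" +
            windows["exon_index"].astype(str))[0]
    new_block = np.empty(n, dtype=bool)
    new_block[0] = True
    new_block[1:] = exon_key[1:] != exon_key[:-1]
    start_of_run = sig & (new_block | ~np.roll(sig, 1))
    start_of_run[0] = sig[0]
    next_new_block = np.empty(n, dtype=bool)
    next_new_block[:-1] = new_block[1:]
    next_new_block[-1] = True
    end_of_run = sig & (next_new_block | ~np.roll(sig, -1))
    end_of_run[-1] = sig[-1]
    return np.flatnonzero(start_of_run), np.flatnonzero(end_of_run) + 1


def _events_in_run(run_len: int) -> int:
    """Number of events a joined run of ``run_len`` nt produces under the
    90-nt minimum and 200-nt splitting rules."""
    if run_len < MIN_EVENT_NT:
        return 0
    full, rem = divmod(run_len, MAX_EVENT_NT)
    return full + (1 if rem >= MIN_EVENT_NT else 0)


def count_events(track: WindowCountTrack, threshold: float,
                 p_column: str = "p_adjusted") -> int:
    """Fast event count at a threshold (no event objects built)."""
    w = track.windows
    sig = w[p_column].to_numpy() < threshold
    starts, ends = _run_boundaries(w, sig)
    if starts.size == 0:
        return 0
    gstart = w["start"].to_numpy()
    gend = w["end"].to_numpy()
    run_nt = gend[ends - 1] - gstart[starts]
    full, rem = np.divmod(run_nt, MAX_EVENT_NT)
    return int(np.sum(np.where(run_nt < MIN_EVENT_NT, 0,
                               full + (rem >= MIN_EVENT_NT))))


def call_events(track: WindowCountTrack, threshold: float,
                p_column: str = "p_adjusted") -> list[MethylationEvent]:
    """Join significant windows into methylation events.

    Maximal runs of adjacent windows with p < threshold are joined; runs of
    at least 90 nt become events; runs longer than 200 nt are split into
    consecutive 200-nt events starting from the transcript 5' end, keeping a
    terminal remainder only if it is itself >= 90 nt.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    w = track.windows
    sig = w[p_column].to_numpy() < threshold
    starts, ends = _run_boundaries(w, sig)
    gstart = w["start"].to_numpy()
    gend = w["end"].to_numpy()
    pvals = w[p_column].to_numpy()
    events: list[MethylationEvent] = []
    for s, e in zip(starts, ends):
        run_start, run_end = int(gstart[s]), int(gend[e - 1])
        run_len = run_end - run_start
        if run_len < MIN_EVENT_NT:
            continue
        strand = w["strand"].iat[s]
        pieces = []
        # split from the 5' end in transcript orientation
        if strand == "+":
            pos = run_start
            while run_end - pos >= MIN_EVENT_NT:
                pieces.append((pos, min(pos + MAX_EVENT_NT, run_end)))
                pos += MAX_EVENT_NT
        else:
            pos = run_end
            while pos - run_start >= MIN_EVENT_NT:
                pieces.append((max(pos - MAX_EVENT_NT, run_start), pos))
                pos -= MAX_EVENT_NT
        for a, b in pieces:
            if b - a < MIN_EVENT_NT:
                continue
            in_piece = (gstart[s:e] < b) & (gend[s:e] > a)
            events.append(
                MethylationEvent(
                    interval=GenomicInterval(w["chrom"].iat[s], a, b, strand),
                    sample_id=track.sample_id,
                    gene_id=w["gene_id"].iat[s],
                    transcript_id=w["transcript_id"].iat[s],
                    n_windows=int(in_piece.sum()),
                    min_window_p=float(pvals[s:e][in_piece].min()),
                    threshold_used=threshold,
                )
            )
    return events


@dataclass
class ThresholdCalibration:
    threshold: float
    event_count: int
    table: pd.DataFrame  # columns: threshold, event_count
    warning: bool = False


def tune_threshold(track: WindowCountTrack,
                   grid=DEFAULT_GRID,
                   target_events: int = DEFAULT_TARGET_EVENTS,
                   p_column: str = "p_adjusted") -> ThresholdCalibration:
    """Pick the grid threshold whose event count is closest to the target.

    Ties are broken toward the larger (more permissive) threshold. The full
    count-vs-threshold table is returned for inspection. When no threshold
    yields any event, the most permissive grid value is returned with a
    warning flag.
    """
    grid = sorted(grid, reverse=True)  # permissive -> stringent
    if not grid:
        raise ValueError("empty threshold grid")
    counts = [count_events(track, t, p_column=p_column) for t in grid]
    table = pd.DataFrame({"threshold": grid, "event_count": counts})
    if max(counts) == 0:
        return ThresholdCalibration(grid[0], 0, table, warning=True)
    best_i = int(np.argmin([abs(c - target_events) for c in counts]))
    # ties toward more permissive: grid is sorted permissive-first and argmin
    # returns the first minimum, which is the most permissive.
    return ThresholdCalibration(grid[best_i], counts[best_i], table)


def metagene_distribution(events: list[MethylationEvent],
                          models: list[TranscriptModel]) -> dict:
    """Fraction of events per transcript region (5'UTR / CDS / 3'UTR).

    Each event is assigned to the region containing the majority of its
    bases. Events that do not project onto their transcript (wholly
    intronic) are excluded and reported in the ``excluded`` entry.
    """
    by_tid = {m.transcript_id: m for m in models}
    tally = {r: 0 for r in ("5'UTR", "CDS", "3'UTR")}
    excluded = 0
    for ev in events:
        model = by_tid.get(ev.transcript_id)
        if model is None:
            excluded += 1
            continue
        proj = model.to_transcript_coords(ev.interval)
        if proj is None:
            excluded += 1
            continue
        tally[model.region_of(*proj)] += 1
    total = sum(tally.values())
    fractions = {r: (c / total if total else 0.0) for r, c in tally.items()}
    fractions["excluded"] = excluded
    return fractions
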