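"""Δm6A / ΔTE integration, classification, filter cascade, common set.

The per-transcript methylation change (Δm6A) is the mean number of called
methylation events in the differentiated samples minus the mean in the stem
samples. Transcripts are classified as m6A *gain* (Δm6A >= 1), *loss*
(Δm6A <= -1) or *unchanged*. The filter cascade works per stem/differentiated
sample pair: a transcript is a candidate when its TE-change percentile rank
is at or above the rank cutoff (70th by default) and it loses at least
``loss_cut`` peaks (2 by default) in that pair; the cross-sample common set
is the intersection of the per-pair candidate sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

M6A_GAIN = "gain"
M6A_LOSS = "loss"
M6A_UNCHANGED = "unchanged"

DEFAULT_RANK_CUT = 70.0
DEFAULT_LOSS_CUT = 2


def delta_m6a(peaks_per_sample: dict[str, float],
              gsc_samples: list[str],
              dgc_samples: list[str]) -> float:
    """Mean peak difference: mean(DGC event counts) - mean(GSC event counts)."""
    if not gsc_samples or not dgc_samples:
        raise ValueError("sample groups must be non-empty")
    try:
        g = [peaks_per_sample[s] for s in gsc_samples]
        d = [peaks_per_sample[s] for s in dgc_samples]
    except KeyError as exc:
        raise ValueError(f"missing peak count for sample {exc}")
    return float(np.mean(d) - np.mean(g))


def te_change_rank(delta_te) -> np.ndarray:
    """Percentile rank of ΔTE: 100 * rank / n, average ranks for ties."""
    delta_te = np.asarray(delta_te, dtype=float)
    if delta_te.size == 0:
        raise ValueError("empty ΔTE vector")
    if not np.isfinite(delta_te).all():
        raise ValueError("ΔTE vector must be finite (exclude sentinels first)")
    ranks = stats.rankdata(delta_te, method="average")
    return 100.0 * ranks / delta_te.size


def rna_log2fc(mean_gsc, mean_dgc, pseudocount: float = 1.0):
    """log2 fold change of library-size-normalized total-RNA means."""
    mean_gsc = np.asarray(mean_gsc, dtype=float)
    mean_dgc = np.asarray(mean_dgc, dtype=float)
    out = np.log2(mean_dgc + pseudocount) - np.log2(mean_gsc + pseudocount)
    return float(out) if out.ndim == 0 else out


def classify_m6a_status(delta: float) -> str:
    """gain if Δm6A >= 1, loss if <= -1, else unchanged (boundaries inclusive)."""
    if not np.isfinite(delta):
        raise ValueError("Δm6A must be finite")
    if delta >= 1.0:
        return M6A_GAIN
    if delta <= -1.0:
        return M6A_LOSS
    return M6A_UNCHANGED


def pct_loss_bins(gsc_peaks: int, dgc_peaks: int) -> str | None:
    """Bin percent peak loss: A (<50%), B ([50%, 75%]), C (>75%).

    Both boundaries belong to the middle bin. Undefined (None) when the stem
    state has no peaks.
    """
    if gsc_peaks == 0:
        return None
    if gsc_peaks < 0 or dgc_peaks < 0 or dgc_peaks > gsc_peaks:
        raise ValueError("expected loss context: 0 <= dgc_peaks <= gsc_peaks")
    pct = 100.0 * (gsc_peaks - dgc_peaks) / gsc_peaks
    if pct < 50.0:
        return "A"
    if pct <= 75.0:
        return "B"
    return "C"


def filter_cascade(pair_tables: dict[str, pd.DataFrame],
                   rank_cut: float = DEFAULT_RANK_CUT,
                   loss_cut: float = DEFAULT_LOSS_CUT):
    """Per-pair candidate sets and their cross-sample intersection.

    Each value of ``pair_tables`` is a DataFrame indexed by gene_id with
    columns ``te_rank_pct``, ``gsc_peaks`` and ``dgc_peaks``. A gene is a
    candidate in a pair when te_rank_pct >= rank_cut and
    (gsc_peaks - dgc_peaks) >= loss_cut. Genes absent from any pair are
    excluded from the common set and reported via a warning.
    """
    if not pair_tables:
        raise ValueError("no sample pairs")
    candidates: dict[str, set[str]] = {}
    universes = []
    for pair, tab in pair_tables.items():
        for col in ("te_rank_pct", "gsc_peaks", "dgc_peaks"):
            if col not in tab.columns:
                raise ValueError(f"pair {pair}: missing column {col!r}")
        sel = (tab["te_rank_pct"] >= rank_cut) & (
            (tab["gsc_peaks"] - tab["dgc_peaks"]) >= loss_cut)
        candidates[pair] = set(tab.index[sel])
        universes.append(set(tab.index))
    shared = set.intersection(*universes)
    dropped = set.union(*universes) - shared
    if dropped:
        warnings.warn(
            f"{len(dropped)} genes missing from at least one pair were "
            "excluded from the common set"
        )
    common = set.intersection(*candidates.values()) & shared
    return candidates, common


def abundance_m6a_correlation(rna_fc, delta) -> float:
    """Pearson correlation between total-RNA log2 fold change and Δm6A."""
    rna_fc = np.asarray(rna_fc, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if rna_fc.shape != delta.shape or rna_fc.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(rna_fc).all() and np.isfinite(delta).all()):
        raise ValueError("inputs must be finite")
    if np.std(rna_fc) == 0 or np.std(delta) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(stats.pearsonr(rna_fc, delta).statistic)


def compare_groups_wilcoxon(values_a, values_b):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when there are no ties, the normal
    approximation otherwise. Returns ``(statistic, p_value)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def build_pair_table(te_gsc: pd.DataFrame,
                     te_dgc: pd.DataFrame,
                     peaks_gsc: pd.Series,
                     peaks_dgc: pd.Series) -> pd.DataFrame:
    """Assemble one pair's ΔTE/rank/peak table.

    ``te_gsc``/``te_dgc`` are TE tables (index gene_id, columns retained,
    te); ``peaks_*`` are per-gene event counts. Genes must be retained with
    finite TE in both libraries of the pair to enter the ranking; peak
    counts default to 0 for genes without events.
    """
    ok = (
        te_gsc["retained"] & te_dgc["retained"]
        & np.isfinite(te_gsc["te"]) & np.isfinite(te_dgc["te"])
    )
    genes = te_gsc.index[ok]
    tab = pd.DataFrame(index=genes)
    tab["te_gsc"] = te_gsc.loc[genes, "te"]
    tab["te_dgc"] = te_dgc.loc[genes, "te"]
    tab["delta_te"] = tab["te_dgc"] - tab["te_gsc"]
    tab["te_rank_pct"] = te_change_rank(tab["delta_te"].to_numpy())
    tab["gsc_peaks"] = peaks_gsc.reindex(genes).fillna(0).astype(int)
    tab["dgc_peaks"] = peaks_dgc.reindex(genes).fillna(0).astype(int)
    return tab


def master_table(pair_tables: dict[str, pd.DataFrame],
                 gsc_samples: list[str],
                 dgc_samples: list[str],
                 peaks_per_sample: dict[str, pd.Series]) -> pd.DataFrame:
    """Status-annotated cross-sample summary.

    One row per gene present in every pair: mean Δm6A over group means,
    m6A status class, mean ΔTE, mean TE rank percentile, and the percent
    peak-loss bin computed from mean group event counts.
    """
    shared = set.intersection(*[set(t.index) for t in pair_tables.values()])
    genes = sorted(shared)
    peak_df = pd.DataFrame(
        {s: ser.reindex(genes).fillna(0) for s, ser in peaks_per_sample.items()}
    )
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["delta_m6a"] = (
        peak_df[dgc_samples].mean(axis=1) - peak_df[gsc_samples].mean(axis=1)
    )
    out["m6a_status"] = [classify_m6a_status(d) for d in out["delta_m6a"]]
    out["delta_te"] = np.mean(
        [t["delta_te"].reindex(genes) for t in pair_tables.values()], axis=0)
    out["te_rank_pct"] = np.mean(
        [t["te_rank_pct"].reindex(genes) for t in pair_tables.values()], axis=0)
    bins = []
    for g in genes:
        gsc_mean = peak_df.loc[g, gsc_samples].mean()
        dgc_mean = peak_df.loc[g, dgc_samples].mean()
        if gsc_mean > 0 and dgc_mean <= gsc_mean:
            bins.append(pct_loss_bins(int(round(gsc_mean * 100)),
                                      int(round(dgc_mean * 100))))
        else:
            bins.append(None)
    out["pct_loss_bin"] = bins
    return out
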