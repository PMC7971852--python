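"""Gene-level read summarization, RPKM, and translation efficiency.

Translation efficiency (TE) is the base-2 logarithm of the ratio of
polysome-fraction RPKM to total-RNA RPKM. Genes with total-RNA RPKM below 2
are discarded from TE analysis; retained genes with zero polysome signal
carry a -inf sentinel (flagged, excluded from rank statistics) rather than a
pseudocounted value, so ranks are never shifted silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import CountTable, TranscriptModel

DEFAULT_MAPQ_MIN = 20
DEFAULT_RPKM_CUT = 2.0


@dataclass
class TEProfile:
    gene_id: str
    rpkm_total: float
    rpkm_polysome: float
    te: float
    retained: bool


def summarize_counts(reads: pd.DataFrame,
                     models: list[TranscriptModel],
                     mapq_min: int = DEFAULT_MAPQ_MIN):
    """Count reads with mapq >= ``mapq_min`` overlapping exons, per gene.

    ``reads`` needs columns (chrom, pos, mapq); a read is assigned to the
    gene whose exon contains its position. Returns ``(counts, unassigned)``:
    a per-gene Series (zero-filled over all genes) and the number of
    quality-passing reads that hit no exon or an unknown chromosome.
    """
    for col in ("chrom", "pos", "mapq"):
        if col not in reads.columns:
            raise ValueError(f"reads table missing column {col!r}")
    genes = sorted({m.gene_id for m in models})
    counts = pd.Series(0, index=pd.Index(genes, name="gene_id"), dtype=int)
    # flat exon arrays per chromosome for vectorized interval lookup
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {m.chrom for m in models}:
        rows = []
        for m in models:
            if m.chrom != chrom:
                continue
            for e in m.exons:
                rows.append((e.start, e.end, m.gene_id))
        rows.sort()
        starts = np.array([r[0] for r in rows])
        ends = np.array([r[1] for r in rows])
        gids = np.array([r[2] for r in rows])
        per_chrom[chrom] = (starts, ends, gids)

    passing = reads[reads["mapq"] >= mapq_min]
    unassigned = 0
    for chrom, grp in passing.groupby("chrom"):
        if chrom not in per_chrom:
            unassigned += len(grp)
            continue
        starts, ends, gids = per_chrom[chrom]
        pos = grp["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        unassigned += int((~ok).sum())
        hit = pd.Series(gids[idx[ok]]).value_counts()
        counts.loc[hit.index] += hit.astype(int)
    return counts, unassigned


def rpkm(count, gene_length, library_size):
    """Reads per kilobase of transcript per million mapped reads."""
    count = np.asarray(count, dtype=float)
    gene_length = np.asarray(gene_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if (gene_length <= 0).any():
        raise ValueError("gene_length must be positive")
    if (library_size <= 0).any():
        raise ValueError("library_size must be positive")
    out = count / (gene_length / 1e3) / (library_size / 1e6)
    return float(out) if out.ndim == 0 else out


def translation_efficiency(table: pd.DataFrame,
                           rpkm_cut: float = DEFAULT_RPKM_CUT) -> pd.DataFrame:
    """TE per gene from a table with columns rpkm_total and rpkm_polysome.

    Adds ``retained`` (rpkm_total >= rpkm_cut) and ``te``
    (log2(rpkm_polysome / rpkm_total); -inf sentinel for retained genes with
    zero polysome signal; NaN for non-retained genes).
    """
    for col in ("rpkm_total", "rpkm_polysome"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    out = table.copy()
    tot = out["rpkm_total"].to_numpy(dtype=float)
    pol = out["rpkm_polysome"].to_numpy(dtype=float)
    retained = tot >= rpkm_cut
    with np.errstate(divide="ignore"):
        te = np.where(retained & (pol > 0), np.log2(np.maximum(pol, 1e-300))
                      - np.log2(np.maximum(tot, 1e-300)), np.nan)
        te = np.where(retained & (pol == 0), -np.inf, te)
    out["retained"] = retained
    out["te"] = te
    return out


def te_table(counts: CountTable,
             gene_lengths: pd.Series,
             total_col: str,
             polysome_col: str,
             rpkm_cut: float = DEFAULT_RPKM_CUT) -> pd.DataFrame:
    """Build a TE table for one (total, polysome) library pair.

    ``gene_lengths`` is indexed by gene_id (exonic nt). Returns a DataFrame
    indexed by gene_id with rpkm_total, rpkm_polysome, retained, te.
    """
    genes = counts.counts.index
    lengths = gene_lengths.reindex(genes)
    if lengths.isna().any():
        missing = list(genes[lengths.isna()][:3])
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    tab = pd.DataFrame(index=genes)
    tab["rpkm_total"] = rpkm(counts.counts[total_col], lengths,
                             counts.library_sizes[total_col])
    tab["rpkm_polysome"] = rpkm(counts.counts[polysome_col], lengths,
                                counts.library_sizes[polysome_col])
    return translation_efficiency(tab, rpkm_cut=rpkm_cut)


def gene_lengths(models: list[TranscriptModel]) -> pd.Series:
    """Exonic length per gene (sum over the gene's transcripts' exons)."""
    acc: dict[str, int] = {}
    for m in models:
        acc[m.gene_id] = acc.get(m.gene_id, 0) + m.sequence_length
    s = pd.Series(acc)
    s.index.name = "gene_id"
    return s.sort_index()
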