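import numpy as np
import pandas as pd
import pytest

from m6ate import peakcall, quantify
from m6ate.simulate import (
    SimulationConfig,
    generate_expression_counts,
    generate_merip_counts,
    generate_mirna_targets,
    generate_transcriptome,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_transcripts=40, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """One fully generated small cohort shared across tests (read-only)."""
    models, sequences, truth = generate_transcriptome(small_cfg)
    mirnas, sites, seq_with_sites = generate_mirna_targets(
        small_cfg, sequences, models, truth)
    return {
        "cfg": small_cfg,
        "models": models,
        "sequences": seq_with_sites,
        "pristine_sequences": sequences,
        "truth": truth,
        "mirnas": mirnas,
        "sites": sites,
    }


@pytest.fixture(scope="session")
def merip_tracks(small_cohort):
    cfg = small_cohort["cfg"]
    return generate_merip_counts(cfg, small_cohort["models"],
                                 small_cohort["truth"])


@pytest.fixture(scope="session")
def called_tracks(merip_tracks):
    """Tracks with p-values attached and events called at adj p < 1e-3."""
    out = {}
    for sample, track in merip_tracks.items():
        peakcall.window_test(track)
        track.windows["p_adjusted"] = peakcall.adjust_pvalues(
            track.windows["p_value"])
        out[sample] = (track, peakcall.call_events(track, 1e-3))
    return out


@pytest.fixture(scope="session")
def expression(small_cohort):
    cfg = small_cohort["cfg"]
    return generate_expression_counts(cfg, small_cohort["models"],
                                      small_cohort["truth"])


@pytest.fixture(scope="session")
def te_tables(small_cohort, expression):
    cfg = small_cohort["cfg"]
    lengths = quantify.gene_lengths(small_cohort["models"])
    gsc, dgc = cfg.sample_names()
    return {
        s: quantify.te_table(expression, lengths, f"{s}_total",
                             f"{s}_polysome")
        for s in gsc + dgc
    }
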