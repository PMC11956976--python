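"""Shared fixtures: a small codebook with short synthetic references and an
error-free simulated screen reused by several test modules."""

import numpy as np
import pandas as pd
import pytest

from nicrseq import (
    BarcodeLayout,
    GrowthConfig,
    IcrLibraryConfig,
    simulate_icr_library,
    simulate_nicr_pool,
    simulate_timecourse,
    synthetic_codebook,
)

SHORT_REFS = {
    name: 300
    for name in [
        "RAD1", "ERCC4", "RAD1-neg",
        "RAD10", "ERCC1", "RAD10-neg",
        "RAD14", "XPA", "RAD14-neg",
    ]
}


@pytest.fixture(scope="session")
def layout():
    return BarcodeLayout()


@pytest.fixture(scope="session")
def codebook():
    """Nine-cargo codebook with 300-nt synthetic references (fast alignment)."""
    return synthetic_codebook(seed=11, ref_lengths=SHORT_REFS)


@pytest.fixture(scope="session")
def clean_libraries(codebook, layout):
    """Error-free libraries for all nine cargos: reads + truth per cargo."""
    cfg_base = dict(
        n_barcodes_per_cargo=60,
        reads_per_barcode=14.0,
        per_base_error=0.0,
    )
    out = {}
    for i, spec in enumerate(codebook):
        cfg = IcrLibraryConfig(seed=100 + i, **cfg_base)
        out[spec.name] = simulate_icr_library(spec, codebook, cfg, layout)
    return out


@pytest.fixture(scope="session")
def library_truths(clean_libraries):
    return {name: truth for name, (_, truth) in clean_libraries.items()}


@pytest.fixture(scope="session")
def pool_truth(library_truths, codebook, layout):
    set_truths = {
        s: pd.concat(
            [library_truths[c.name] for c in codebook.by_set(s)], ignore_index=True
        )
        for s in (1, 2, 3)
    }
    truth, _ = simulate_nicr_pool(set_truths, codebook, n_per_genotype=40,
                                  layout=layout, rng=7)
    return truth


@pytest.fixture(scope="session")
def screen(pool_truth):
    """Simulated time course under the default dose-response rates."""
    cfg = GrowthConfig(depth_per_sample=200_000, seed=8)
    counts, meta = simulate_timecourse(pool_truth, cfg)
    return counts, meta, cfg
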