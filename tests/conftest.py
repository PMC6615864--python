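import numpy as np
import pandas as pd
import pytest

import dropscreen as ds


@pytest.fixture(scope="session")
def toy_library() -> ds.ShRNALibrary:
    """3 hairpins / 2 genes with 4-nt guides (small enough to enumerate)."""
    return ds.ShRNALibrary(
        pd.DataFrame(
            {
                "hairpin_id": ["h1", "h2", "h3"],
                "guide_seq": ["ACGT", "ACGA", "TTTT"],
                "gene": ["TP53", "TP53", "BRCA1"],
                "pool": ["1", "1", "1"],
                "class": ["target", "target", "target"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_screen():
    """Seeded 50-gene screen plus its differential table and gene calls.

    Session-scoped because several modules exercise different facets of the
    same end-to-end run.
    """
    params = ds.ScreenSimParams(n_genes=50, seed=1)
    lib, truth = ds.make_library(params)
    cm, ss = ds.simulate_screen(lib, truth, params)
    dr = ds.run_differential(cm, ss, lib=lib)
    calls = ds.classify_screen(dr, lib=lib)
    return {
        "params": params,
        "lib": lib,
        "truth": truth,
        "cm": cm,
        "ss": ss,
        "dr": dr,
        "calls": calls,
    }


@pytest.fixture()
def sample_sheet_12() -> ds.SampleSheet:
    """The canonical 12-sample design: t0/DMSO/PDS/PhenDC3 x 3 replicates."""
    rows = []
    for treatment, timepoint in [
        ("none", "t0"),
        ("DMSO", "tF"),
        ("PDS", "tF"),
        ("PhenDC3", "tF"),
    ]:
        for rep in (1, 2, 3):
            label = "t0" if timepoint == "t0" else treatment
            rows.append((f"p1_{label}_r{rep}", "1", timepoint, treatment, rep))
    return ds.SampleSheet(
        pd.DataFrame(
            rows, columns=["sample_id", "pool", "timepoint", "treatment", "replicate"]
        )
    )
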