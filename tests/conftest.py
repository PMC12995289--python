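import numpy as np
import pandas as pd
import pytest

import synerseq as ss


@pytest.fixture(scope="session")
def design7():
    """Balanced 2x2 design, 7 per cell, spread size factors."""
    return ss.make_design(7, (0.7, 1.4), seed=101)


@pytest.fixture(scope="session")
def default_sim(design7):
    """Default simulation scenario: 200 genes per archetype, e=1.5, alpha=0.05.

    Session-scoped because the per-gene NB fits are the expensive step and
    several end-to-end checks share the same scenario.
    """
    truth = ss.plant_archetypes(200, effect_size=1.5, dispersion=0.05, seed=11)
    cm = ss.simulate_counts(truth, design7, seed=12)
    de = ss.run_de(cm)
    return truth, cm, de


@pytest.fixture(scope="session")
def null_sim(design7):
    """2000 genes with no planted effects for calibration checks."""
    truth = ss.plant_archetypes({"null": 2000}, effect_size=1.5, dispersion=0.05, seed=21)
    cm = ss.simulate_counts(truth, design7, seed=22)
    de = ss.run_de(cm)
    return truth, cm, de


def toy_de_table(records):
    """Tidy DE table from {gene: {contrast: (log2fc, padj)}} shorthand."""
    rows = []
    for gid, contrasts in records.items():
        for contrast, (fc, padj) in contrasts.items():
            rows.append(
                {
                    "gene_id": gid,
                    "contrast": contrast,
                    "log2fc": fc,
                    "se": 0.1,
                    "wald": 0.0 if np.isnan(fc) else fc / 0.1,
                    "pvalue": padj,
                    "padj": padj,
                }
            )
    return pd.DataFrame(rows)
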