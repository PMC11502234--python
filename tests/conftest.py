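import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dysnet import degflow, modulenet, synthio

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_sim():
    """One simulated experiment with two trait-linked modules, carried
    through the DEG pipeline; shared by module-level tests."""
    cfg = synthio.SimConfig(
        n_genes=1000,
        de_fraction=0.0,
        seed=0,
        modules=(
            synthio.ModuleSpec(150, 0.9),
            synthio.ModuleSpec(150, -0.75),
        ),
    )
    counts, meta, truth = synthio.simulate_bulk_counts(cfg)
    result, expr, _ = degflow.run_deg_pipeline(counts, meta, drop_outliers=False)
    return {"config": cfg, "counts": counts, "meta": meta, "truth": truth, "expr": expr}


@pytest.fixture(scope="session")
def planted_network(planted_sim):
    """Soft power, TOM and detected modules for the planted simulation."""
    X = planted_sim["expr"].values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta, _ = modulenet.pick_soft_power(X)
    network = modulenet.build_tom(X, beta)
    assignment, eigengenes = modulenet.detect_modules(network)
    return {"beta": beta, "network": network, "assignment": assignment,
            "eigengenes": eigengenes}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def string_file(tmp_path):
    """Write a STRING-dialect edge list and return its path."""

    def _write(rows):
        cols = ["protein1", "protein2", *synthio.STRING_CHANNELS, "combined_score"]
        path = tmp_path / "edges.tsv"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        return path

    return _write
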