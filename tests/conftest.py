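"""Shared fixtures: small synthetic experiments and toy matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lnctox.core import ExpressionMatrix
from lnctox.diffexpr import gate_de, run_contrasts
from lnctox.preprocess import preprocess_chain
from lnctox.simulate import SimulationConfig, simulate_experiment

# desk-scale study conditions used across the suite: full 16+2 group
# design, 3 replicates, probe counts reduced from the array scale
SMALL_SIM = dict(
    n_lnc=120,
    n_mrna=480,
    n_negctrl=60,
    module_size=(20, 60),
    effect_size_log2=2.0,
    noise_sd=0.3,
)


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    kwargs = {**SMALL_SIM, **overrides}
    return SimulationConfig(seed=seed, **kwargs)


def make_expr(X, biotypes=None, scale="log2", probe_ids=None) -> ExpressionMatrix:
    """Toy ExpressionMatrix from an array; default biotype mRNA."""
    X = np.asarray(X, dtype=float)
    n, s = X.shape
    probes = probe_ids or [f"p{i}" for i in range(n)]
    biotypes = biotypes or ["mRNA"] * n
    ann = pd.DataFrame(
        {"accession": [f"ACC_{p}" for p in probes], "biotype": biotypes},
        index=pd.Index(probes, name="probe_id"),
    )
    vals = pd.DataFrame(
        X, index=pd.Index(probes, name="probe_id"), columns=[f"s{j}" for j in range(s)]
    )
    return ExpressionMatrix(vals, ann, scale=scale)


def make_two_group_design(n1: int, n2: int) -> pd.DataFrame:
    """Design with one exposed group (CuO-Core) and its PBS control."""
    rows = []
    for i in range(n1 + n2):
        exposed = i < n1
        rows.append(
            {
                "sample_id": f"s{i}",
                "material": "CuO" if exposed else "control",
                "surface": "Core" if exposed else "none",
                "dispersant": "PBS",
                "batch_label": "L1",
                "batch_array": "A1",
                "replicate": (i % n1 if exposed else i - n1) + 1,
                "group": "CuO-Core" if exposed else "control-PBS",
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_experiment():
    cfg = small_config(seed=11)
    return simulate_experiment(cfg), cfg


@pytest.fixture(scope="session")
def preprocessed(small_experiment):
    (m, design, annotation, truth), cfg = small_experiment
    return preprocess_chain(m, design), design, truth, cfg


@pytest.fixture(scope="session")
def small_contrasts(preprocessed):
    m, design, truth, cfg = preprocessed
    contrasts = run_contrasts(m, design)
    gated = {g: gate_de(r) for g, r in contrasts.items()}
    return contrasts, gated
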