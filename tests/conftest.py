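"""Shared fixtures: small simulated cohorts and one trained signal run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from comos.modeling import ComosModel
from comos.pipeline import DataBundle, PipelineConfig, extract_features
from comos.simulate import make_fixture

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-chromosome cohort with planted effects (deterministic)."""
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def tiny_tables(tiny_cohort):
    data = DataBundle.from_cohort(tiny_cohort)
    config = PipelineConfig(out_dir="unused", preset="tiny")
    return extract_features(data, config)


@pytest.fixture(scope="session")
def signal_run():
    """One signal cohort, extracted and fully trained (shared)."""
    cohort = make_fixture("signal", seed=11)
    data = DataBundle.from_cohort(cohort)
    config = PipelineConfig(out_dir="unused", preset="signal")
    tables = extract_features(data, config)
    model = ComosModel(tables, data.samples, task="early_dx", config=config.model_config())
    results = model.fit()
    return {"cohort": cohort, "data": data, "tables": tables, "model": model,
            "results": results}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_fragments(rng, chrom_sizes, n, min_len=80, max_len=250) -> pd.DataFrame:
    """Random fragment intervals over a ChromSizes frame (test helper)."""
    names = chrom_sizes.names
    chroms = [names[i] for i in rng.integers(0, len(names), n)]
    lengths = rng.integers(min_len, max_len + 1, n)
    starts = np.array([rng.integers(0, chrom_sizes[c] - l) for c, l in zip(chroms, lengths)])
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + lengths})
    df["length"] = df["end"] - df["start"]
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)
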