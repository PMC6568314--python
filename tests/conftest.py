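"""Shared fixtures: a reduced-depth simulated scenario reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pamscreen.counting import count_pams
from pamscreen.simulate import (
    SimulationConfig,
    default_config,
    emit_fastq,
    simulate_frequencies,
)

SCENARIO_SEED = 7
SCENARIO_READS = 20_000


def counts_from_frequencies(
    freqs: dict[str, pd.DataFrame],
    reads: int,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial count matrix drawn directly from true frequencies,
    bypassing FASTQ emission (for stages downstream of counting)."""
    rng = np.random.default_rng(seed)
    rows, index = [], []
    for condition, table in sorted(freqs.items()):
        for rep in range(1, n_replicates + 1):
            for time in table.index:
                rows.append(rng.multinomial(reads, table.loc[time].to_numpy()))
                index.append((condition, rep, float(time)))
    out = pd.DataFrame(rows, columns=table.columns)
    out.index = pd.MultiIndex.from_tuples(
        index, names=["condition", "replicate", "time"]
    )
    return out


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """A complete reduced-depth scenario: simulated FASTQ set, planted truth
    and the counted PAM table."""
    outdir = tmp_path_factory.mktemp("scenario")
    cfg = default_config(seed=SCENARIO_SEED, reads_per_sample=SCENARIO_READS)
    freqs = simulate_frequencies(cfg)
    manifest, truth_counts = emit_fastq(freqs, cfg, outdir)
    counts, qc = count_pams(manifest, cfg.protospacer)
    return {
        "cfg": cfg,
        "freqs": freqs,
        "manifest": manifest,
        "truth_counts": truth_counts,
        "counts": counts,
        "qc": qc,
    }


@pytest.fixture()
def tiny_cfg() -> SimulationConfig:
    """A fast, low-depth configuration for I/O-level tests."""
    return default_config(
        seed=3, reads_per_sample=500, n_replicates=1, time_points=(0.0, 1.0, 24.0)
    )
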