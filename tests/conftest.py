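"""Shared fixtures: the trained paired-benchmark run used by the end-to-end
alignment and regulatory-inference checks (trained once per session)."""

import pytest


@pytest.fixture(scope="session")
def trained_paired_run():
    """Full pipeline on the seeded synthetic paired benchmark with the
    reduced 100/300-epoch training profile."""
    from cootalign.pipeline import RunConfig, integrate
    from cootalign.synthetic import SyntheticConfig, generate_paired

    ds = generate_paired(SyntheticConfig(seed=0))
    out = integrate(ds.rna_counts, ds.atac_counts, ds.gene_records,
                    ds.peak_records, ds.gene_activity,
                    RunConfig(seed=0, warmup_epochs=100, tuning_epochs=300))
    return ds, out
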