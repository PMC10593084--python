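import pytest

from exocnv import synth
from exocnv.classify import ScoringScheme
from exocnv.pipeline import RunConfig, run_pipeline_in_memory


@pytest.fixture(scope="session")
def synth_cfg():
    return synth.SynthConfig(seed=1)


@pytest.fixture(scope="session")
def reference(synth_cfg):
    return synth.generate_reference(synth_cfg)


@pytest.fixture(scope="session")
def cohort(reference, synth_cfg):
    return synth.generate_cohort(reference, synth_cfg)


@pytest.fixture(scope="session")
def pipeline_result(reference, cohort):
    cfg = RunConfig(segments="in-memory.tsv", gene_models=[])
    return run_pipeline_in_memory(
        cohort.callset,
        reference.models,
        reference.probes,
        reference.panel,
        reference.dosage,
        cohort.observations,
        ScoringScheme(),
        cfg,
    )
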