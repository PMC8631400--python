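"""Shared fixtures: tiny ontology files and a default synthetic study."""

import pytest

from inflamark.simulate import (
    SynthConfig,
    gen_biomarker_db,
    gen_cohort,
    gen_evidence,
    gen_ontology_and_annotations,
    gen_tissue_atlas,
)

CHAIN_OBO = """format-version: 1.2
ontology: syn

[Term]
id: GO:0000001
name: tissue process
namespace: biological_process

[Term]
id: GO:0000002
name: liver development
namespace: biological_process
is_a: GO:0000001 ! tissue process

[Term]
id: GO:0000003
name: hepatocyte differentiation
namespace: biological_process
is_a: GO:0000002 ! liver development
"""


@pytest.fixture
def chain_obo(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(CHAIN_OBO)
    return path


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def synth_study(synth_cfg):
    """One fully generated synthetic study (seed 1), shared read-only."""
    ontology, annotations, truth = gen_ontology_and_annotations(synth_cfg)
    atlas = gen_tissue_atlas(synth_cfg, truth)
    db = gen_biomarker_db(synth_cfg, truth)
    matrices, samples = gen_cohort(synth_cfg, truth)
    evidence = gen_evidence(synth_cfg, truth)
    return {
        "ontology": ontology,
        "annotations": annotations,
        "truth": truth,
        "atlas": atlas,
        "db": db,
        "matrices": matrices,
        "samples": samples,
        "evidence": evidence,
    }
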