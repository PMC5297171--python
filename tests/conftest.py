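import numpy as np
import pandas as pd
import pytest

from sexbias.expression import ExpressionMatrix
from sexbias.simulate import (
    SimulationConfig,
    build_spectra,
    generate_expression,
    generate_transcriptome,
    generate_variants,
    plant_deleteriousness,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=40,
        n_tissues=4,
        samples_per_tissue_per_sex=10,
        cds_length_range=(90, 300),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_transcripts(small_config):
    return generate_transcriptome(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_transcripts):
    """Full synthetic bundle: matrix, truth, spectra, variants."""
    matrix, truth = generate_expression(small_config, small_transcripts)
    ns_truth = plant_deleteriousness(small_config, small_transcripts)
    truth.deleterious = ns_truth
    spectra = build_spectra(small_transcripts, ns_truth)
    variants = generate_variants(small_config, small_transcripts, spectra, truth)
    return {
        "config": small_config,
        "transcripts": small_transcripts,
        "matrix": matrix,
        "truth": truth,
        "spectra": spectra,
        "variants": variants,
    }


@pytest.fixture
def toy_matrix():
    """Hand-built 3-gene matrix: 2 tissues x 2 sexes x 4 samples, plus a
    women-only tissue."""
    rng = np.random.default_rng(0)
    samples, meta = [], []
    for tissue, sexes in [("liver", "FM"), ("skin", "FM"), ("uterus", "F")]:
        for sex in sexes:
            for i in range(4):
                sid = f"{tissue}_{sex}{i}"
                samples.append(sid)
                meta.append((sid, sex, tissue, 30 + i))
    values = pd.DataFrame(
        rng.uniform(1, 10, size=(3, len(samples))),
        index=["g1", "g2", "g3"],
        columns=samples,
    )
    metadata = pd.DataFrame(meta, columns=["sample_id", "sex", "tissue", "age"]).set_index(
        "sample_id"
    )
    return ExpressionMatrix(values, metadata)
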