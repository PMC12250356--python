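import numpy as np
import pytest

from sexsatkit.pipeline import run_pipeline

BASES = list("ACGT")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_dna(rng, n):
    return "".join(rng.choice(BASES, size=n))


def study_shaped_config(seed=11):
    """Synthetic design mirroring the study layout: four libraries (two
    karyomorphs x two sexes), one Y-accumulated satDNA carrying
    male-exclusive haplotypes, one neutral satDNA, and a genotype matrix
    with planted XY loci."""
    bias_y = {"karF_male": 3.0, "karF_female": 1.0, "karG_male": 1.0, "karG_female": 1.0}
    bias_flat = dict.fromkeys(bias_y, 1.0)
    return {
        "seed": seed,
        "reads": {"read_length": 150, "n_reads_per_library": 1500, "genome_size": 50_000},
        "families": [
            {
                "family_id": "satY",
                "rul": 28,
                "n_variants": 3,
                "mutation_rate": 0.08,
                "array_copies_per_genome": 300,
                "sex_bias": bias_y,
                "exclusive_haplotypes": {"karF_male": 5},
            },
            {
                "family_id": "satB",
                "rul": 35,
                "n_variants": 2,
                "mutation_rate": 0.08,
                "array_copies_per_genome": 300,
                "sex_bias": bias_flat,
            },
        ],
        "genotypes": {
            "n_loci": 500,
            "n_males": 5,
            "n_females": 5,
            "het_prob": 0.3,
            "n_planted_xy": 4,
            "missing_rate": 0.05,
        },
        "haplotypes": {"target_family": "satY"},
        "slm": {"het_prob": "auto"},
    }


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """One full pipeline run on the study-shaped design, shared by tests."""
    config = study_shaped_config()
    out = tmp_path_factory.mktemp("e2e")
    state: dict = {}
    manifest = run_pipeline(config, out, state=state)
    return {"config": config, "out": out, "manifest": manifest, "state": state}
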