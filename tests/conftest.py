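import pathlib
import sys

import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from gwasrep.pipeline import RunConfig, run_pipeline
from gwasrep.synthetic_data import CorpusConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """One small mixed-dialect corpus plus its pipeline run, shared
    across tests that only read from it."""
    root = tmp_path_factory.mktemp("corpus")
    cfg = CorpusConfig(seed=11, papers_per_year=6, years=(2010, 2016))
    truth = generate_corpus(cfg, root)
    run_cfg = RunConfig(
        ancestry_path=str(root / "ancestry.tsv"),
        publications_path=str(root / "publications.xml"),
        dict_a_path=str(root / "name_gender_source_a.tsv"),
        dict_b_path=str(root / "name_gender_source_b.tsv"),
        outdir=str(root / "out"),
    )
    result = run_pipeline(run_cfg)
    return {"dir": root, "config": cfg, "truth": truth,
            "run_config": run_cfg, "result": result}


@pytest.fixture(scope="session")
def income_table():
    from importlib import resources

    from gwasrep.representation_stats import load_income_table

    return load_income_table(
        resources.files("gwasrep.data").joinpath("worldbank_income_fy2022.tsv")
    )
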