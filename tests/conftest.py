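import numpy as np
import pandas as pd
import pytest

from immunomet.expression import ExpressionMatrix
from immunomet.preprocess import combat_adjust
from immunomet.signatures import score_all_metagenes
from immunomet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20140915)


@pytest.fixture
def small_matrix(rng):
    """12 probes x 8 samples of random log2-scale intensities."""
    values = pd.DataFrame(
        rng.normal(7.0, 1.0, (12, 8)),
        index=[f"p{i:02d}_at" for i in range(12)],
        columns=[f"S{j}" for j in range(8)],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def mini_signature_tsv(tmp_path):
    """Miniature signature table: 2 genes x 2 probes per metagene."""
    rows = []
    for tag, name in [("BP", "B/P"), ("TNK", "T/NK"), ("MD", "M/D"), ("PRO", "P")]:
        for g in (1, 2):
            for p in ("a", "b"):
                rows.append(f"{tag.lower()}_{g}{p}_at\t{tag}G{g}\t{name}")
    path = tmp_path / "signatures.tsv"
    path.write_text("probe_id\tgene_symbol\tmetagene\n" + "\n".join(rows) + "\n")
    return path


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across the session."""
    return simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def scored_default_cohort(default_cohort):
    """Default cohort scored through batch adjustment."""
    adjusted = combat_adjust(default_cohort.matrix)
    scores = score_all_metagenes(adjusted, default_cohort.signatures)
    return default_cohort, scores


@pytest.fixture(scope="session")
def calibrated_config():
    """Default config with the intercept pre-calibrated (reused by loops)."""
    from immunomet.simulate import calibrate_intercept

    cfg = SimulationConfig()
    cfg.intercept = calibrate_intercept(cfg)
    return cfg
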