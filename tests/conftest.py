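import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    # fixtures used inside @given are read-only frames; not resetting them is fine
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def toy_cq() -> pd.DataFrame:
    """3 genes x 4 samples: one linear dilution pair and one constant gene.

    Gene A and B fall one cycle per sample in lockstep (constant ratio);
    gene C is flat.  All hand-computable downstream values derive from it.
    """
    return pd.DataFrame(
        {
            "A": [20.0, 21.0, 22.0, 23.0],
            "B": [25.0, 26.0, 27.0, 28.0],
            "C": [30.0, 30.0, 30.0, 30.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def measurement_csv(tmp_path):
    """Factory writing a long-format replicate file and returning its path."""

    def _write(rows, header="sample_id,gene,replicate,cq", name="meas.csv", sep=","):
        lines = [header] + [sep.join(str(v) for v in r) for r in rows]
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def random_cq_matrix(rng: np.random.Generator, n_samples: int, n_genes: int) -> pd.DataFrame:
    return pd.DataFrame(
        rng.uniform(18.0, 32.0, size=(n_samples, n_genes)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"g{j}" for j in range(n_genes)],
    )
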