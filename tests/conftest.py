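import numpy as np
import pandas as pd
import pytest

from ricenet import ExpressionCompendium


def make_meta(n_samples: int, n_categories: int) -> pd.DataFrame:
    rows = []
    per = max(n_samples // n_categories, 1)
    for j in range(n_samples):
        cat = f"T{min(j // per, n_categories - 1) + 1:02d}"
        rows.append((f"S{j + 1:03d}", cat, j % per + 1))
    return pd.DataFrame(rows, columns=["sample_id", "category", "replicate"]
                        ).set_index("sample_id")


def make_compendium(n_genes: int, n_samples: int, seed: int = 0,
                    n_categories: int = 4) -> ExpressionCompendium:
    rng = np.random.default_rng(seed)
    meta = make_meta(n_samples, n_categories)
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(n_genes, n_samples)),
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=meta.index,
    )
    return ExpressionCompendium(values, meta)


@pytest.fixture
def small_comp() -> ExpressionCompendium:
    return make_compendium(30, 12, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
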