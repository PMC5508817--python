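import numpy as np
import pytest

from axanet.matrix import CellValue, CharacterDefinition, CharacterMatrix
from axanet.synthetic_data import fixture_suite


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite(seed=0)


@pytest.fixture
def toy_matrix():
    """3 taxa x 4 characters with missing and ambiguous cells."""
    chars = [CharacterDefinition(index=i + 1, max_state=2) for i in range(4)]
    cells = [
        [CellValue.defined(0), CellValue.defined(1), CellValue.missing(), CellValue.defined(2)],
        [CellValue.defined(0), CellValue.ambiguous({0, 1}), CellValue.defined(1), CellValue.defined(2)],
        [CellValue.defined(1), CellValue.defined(1), CellValue.defined(1), CellValue.missing()],
    ]
    return CharacterMatrix(["tax1", "tax2", "tax3"], chars, cells)


def random_matrix(rng: np.random.Generator, n_taxa: int, n_chars: int,
                  missing_p: float = 0.2, ambiguous_p: float = 0.05) -> CharacterMatrix:
    """Random ternary matrix with injected missing/ambiguous cells."""
    chars = [CharacterDefinition(index=j + 1, max_state=2) for j in range(n_chars)]
    cells = []
    for i in range(n_taxa):
        row = []
        for j in range(n_chars):
            u = rng.random()
            if u < missing_p:
                row.append(CellValue.missing())
            elif u < missing_p + ambiguous_p:
                row.append(CellValue.ambiguous({0, 1}))
            else:
                row.append(CellValue.defined(int(rng.integers(0, 3))))
        cells.append(row)
    return CharacterMatrix([f"t{i}" for i in range(n_taxa)], chars, cells)
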