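import numpy as np
import pandas as pd
import pytest

from loopdms import MutationWindow, build_library
from loopdms.library import AMINO_ACIDS, LibraryConfig


# ---- brute-force oracles: generate every candidate string, then set-dedup ----

def brute_deletions(seq: str, min_len: int = 1, max_len: int | None = None) -> set[str]:
    max_len = max_len if max_len is not None else len(seq) - 1
    return {
        seq[:i] + seq[i + k:]
        for k in range(min_len, max_len + 1)
        for i in range(len(seq) - k + 1)
    }


def brute_substitutions(seq: str, order: int) -> set[str]:
    if order == 1:
        return {
            seq[:i] + aa + seq[i + 1:]
            for i in range(len(seq))
            for aa in AMINO_ACIDS
            if aa != seq[i]
        }
    return {
        seq[:i] + a + b + seq[i + 2:]
        for i in range(len(seq) - 1)
        for a in AMINO_ACIDS
        for b in AMINO_ACIDS
        if a != seq[i] and b != seq[i + 1]
    }


def brute_insertions(seq: str, order: int) -> set[str]:
    inserted = (
        list(AMINO_ACIDS)
        if order == 1
        else [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
    )
    return {seq[:s] + ins + seq[s:] for s in range(1, len(seq) + 1) for ins in inserted}


def random_window(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


# ---- fixtures ----------------------------------------------------------------

@pytest.fixture(scope="session")
def window() -> MutationWindow:
    return MutationWindow()  # GISIPRR @307


@pytest.fixture(scope="session")
def full_library(window):
    return build_library(window, LibraryConfig(scramble_seed=7))


@pytest.fixture(scope="session")
def tiny_library():
    """Deletions + controls only: 25 + 5 scrambles + WT = 31 members."""
    return build_library(
        MutationWindow(),
        LibraryConfig(
            include_single_substitutions=False,
            include_double_substitutions=False,
            include_single_insertions=False,
            include_double_insertions=False,
            n_scrambles=5,
            scramble_seed=3,
            named_indels=(),
        ),
    )


def make_count_table(variant_ids, sample_specs, counts, unassigned=None):
    """sample_specs: list of (sample_id, condition, replicate)."""
    index = pd.Index([s[0] for s in sample_specs], name="sample_id")
    samples = pd.DataFrame(
        {
            "condition": [s[1] for s in sample_specs],
            "replicate": [s[2] for s in sample_specs],
        },
        index=index,
    )
    from loopdms import CountTable

    table = CountTable(
        counts=pd.DataFrame(np.asarray(counts), index=index, columns=list(variant_ids)),
        samples=samples,
    )
    if unassigned is not None:
        table.unassigned = pd.Series(unassigned, index=index)
    return table
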