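import numpy as np
import pandas as pd
import pytest

from pedmap.model import GenotypeMatrix, Individual, MarkerMap, Pedigree


def make_map(n_markers: int, chrom: str = "C2", spacing: int = 50_000,
             start: int = 1_000_000) -> MarkerMap:
    pos = start + spacing * np.arange(n_markers)
    return MarkerMap(pd.DataFrame({
        "chrom": chrom,
        "id": [f"{chrom}_m{i}" for i in range(n_markers)],
        "pos": pos,
        "a1": "A",
        "a2": "G",
    }))


def make_multi_map(chrom_sizes: dict[str, int], spacing: int = 50_000) -> MarkerMap:
    frames = []
    for chrom, n in chrom_sizes.items():
        frames.append(make_map(n, chrom=chrom, spacing=spacing).table)
    return MarkerMap(pd.concat(frames, ignore_index=True))


def matrix_from_rows(rows: dict[str, list[int]], marker_map: MarkerMap) -> GenotypeMatrix:
    ids = list(rows)
    calls = np.array([rows[i] for i in ids], dtype=np.int8)
    return GenotypeMatrix(ids, marker_map, calls)


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree([
        Individual("SIRE", sex="male"),
        Individual("DAM", sex="female"),
        Individual("KID", sire="SIRE", dam="DAM", sex="male", phenotype="affected"),
    ])


@pytest.fixture
def small_map() -> MarkerMap:
    return make_map(10)
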