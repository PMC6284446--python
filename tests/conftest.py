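import numpy as np
import pytest

from barcodegap import AlignedBarcode, TaxonomyRecord, build_dataset, distance_matrix

BASE = "ACGT" * 50  # 200-site reference barcode


def _mutate(seq: str, changes: dict[int, str]) -> str:
    s = list(seq)
    for pos, ch in changes.items():
        s[pos] = ch
    return "".join(s)


@pytest.fixture
def toy_dataset():
    """Five specimens, three species, two genera, one subfamily.

    Mutations follow a true tree with positive internal branches so the
    distance matrix is additive in mismatch counts (all over 200 sites):
    species A carries 2 shared transitions plus 1 private transition per
    specimen (a1-a2: 2 ts); species B is 5 transitions from the base;
    species C carries 6 shared changes (3 ts + 3 tv) plus 1 private
    transition per specimen (c1-c2: 2 ts).  Hence a1-b1 = a2-b1 = 8 ts,
    the congeneric minimum.
    """
    shared_a = {100: "G", 101: "T"}  # A->G, C->T transitions
    a1 = AlignedBarcode("a1", _mutate(BASE, {**shared_a, 20: "G"}))
    a2 = AlignedBarcode("a2", _mutate(BASE, {**shared_a, 24: "G"}))
    b1 = AlignedBarcode("b1", _mutate(BASE, {0: "G", 4: "G", 8: "G", 12: "G", 16: "G"}))
    shared_c = {1: "T", 5: "T", 9: "T", 2: "T", 6: "T", 10: "T"}
    c1 = AlignedBarcode("c1", _mutate(BASE, {**shared_c, 40: "G"}))
    c2 = AlignedBarcode("c2", _mutate(BASE, {**shared_c, 3: "C"}))
    taxonomy = [
        TaxonomyRecord("a1", "Apolygus lucorum", "Apolygus", "Mirinae"),
        TaxonomyRecord("a2", "Apolygus lucorum", "Apolygus", "Mirinae"),
        TaxonomyRecord("b1", "Apolygus spinolae", "Apolygus", "Mirinae"),
        TaxonomyRecord("c1", "Lygus rugulipennis", "Lygus", "Mirinae"),
        TaxonomyRecord("c2", "Lygus rugulipennis", "Lygus", "Mirinae"),
    ]
    return build_dataset([a1, a2, b1, c1, c2], taxonomy)


@pytest.fixture
def toy_dm(toy_dataset):
    return distance_matrix(toy_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
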