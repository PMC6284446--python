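"""Kimura 2-parameter (K2P) distances over an aligned barcode dataset.

The K2P model distinguishes transitions (purine<->purine: A<->G;
pyrimidine<->pyrimidine: C<->T) from transversions (purine<->pyrimidine).
With P and Q the observed proportions of transitional and transversional
differences over the L sites compared, the distance in expected
substitutions per site is the Kimura (1980) closed form

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]
      = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q).

Sites where either sequence carries a gap, N, or an IUPAC ambiguity code are
excluded; by default each pair uses its own L (pairwise deletion), with
complete deletion available as an option.  When the argument of either
logarithm is non-positive the distance is saturated and reported as
*undefined* (NaN in the matrix), never clamped to a number.

Distances are stored as substitutions/site throughout; report writers
convert to percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_taxa import AlignedBarcode, Dataset

__all__ = [
    "SitePairCounts",
    "DistanceMatrix",
    "count_site_pairs",
    "k2p_distance",
    "k2p_from_counts",
    "distance_matrix",
    "encode_alignment",
]

logger = logging.getLogger("barcodegap.distances")

# Base encoding: A=0, G=1 (purines); C=2, T=3 (pyrimidines); 4 = excluded
# (gap, N, IUPAC ambiguity).  Purine/pyrimidine class is then code // 2.
_CODE = np.full(256, 4, dtype=np.uint8)
for _ch, _c in (("A", 0), ("G", 1), ("C", 2), ("T", 3)):
    _CODE[ord(_ch)] = _c

DELETION_POLICIES = ("pairwise", "complete")


@dataclass(frozen=True)
class SitePairCounts:
    """Classified site differences between one pair of aligned sequences."""

    L: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.transitions + self.transversions > self.L:
            raise ValueError("more differences than compared sites")
        if min(self.L, self.transitions, self.transversions) < 0:
            raise ValueError("negative site counts")

    @property
    def P(self) -> float:
        """Proportion of transitional differences (0 if no sites compared)."""
        return self.transitions / self.L if self.L else 0.0

    @property
    def Q(self) -> float:
        """Proportion of transversional differences (0 if no sites compared)."""
        return self.transversions / self.L if self.L else 0.0


def encode_alignment(barcodes: Sequence[AlignedBarcode]) -> np.ndarray:
    """Encode sequences as an (n, L) uint8 matrix (A=0,G=1,C=2,T=3, other=4)."""
    n, L = len(barcodes), len(barcodes[0])
    out = np.empty((n, L), dtype=np.uint8)
    for i, b in enumerate(barcodes):
        out[i] = _CODE[np.frombuffer(b.sequence.encode("ascii"), dtype=np.uint8)]
    return out


def count_site_pairs(a: AlignedBarcode, b: AlignedBarcode) -> SitePairCounts:
    """Classify the site differences between two aligned sequences.

    Excluded sites (gap/N/ambiguity in either sequence) do not count toward
    L.  Raises ``ValueError`` on unequal lengths.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequences {a.specimen_id!r} ({len(a)} bp) and {b.specimen_id!r} "
            f"({len(b)} bp) are not aligned"
        )
    x = _CODE[np.frombuffer(a.sequence.encode("ascii"), dtype=np.uint8)]
    y = _CODE[np.frombuffer(b.sequence.encode("ascii"), dtype=np.uint8)]
    valid = (x < 4) & (y < 4)
    diff = valid & (x != y)
    ts = diff & ((x >> 1) == (y >> 1))
    return SitePairCounts(
        L=int(valid.sum()),
        transitions=int(ts.sum()),
        transversions=int(diff.sum() - ts.sum()),
    )


def k2p_from_counts(L: int, transitions: int, transversions: int) -> float:
    """K2P distance from raw counts; NaN when undefined (L=0 or saturated)."""
    if L == 0:
        return float("nan")
    P = transitions / L
    Q = transversions / L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * float(np.log(w1)) - 0.25 * float(np.log(w2))


def k2p_distance(c: SitePairCounts) -> float:
    """Evaluate the K2P closed form; NaN signals an undefined comparison."""
    return k2p_from_counts(c.L, c.transitions, c.transversions)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of K2P distances over specimens.

    ``values`` holds substitutions/site; undefined (saturated or
    zero-overlap) entries are NaN, distinct from any numeric distance.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match number of ids")
        self.values = v
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def n_undefined(self) -> int:
        """Number of undefined unordered pairs (NaN entries above the diagonal)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        """Square TSV with ID header row/column; undefined entries as NA."""
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def distance_matrix(
    dataset: Dataset | Sequence[AlignedBarcode], deletion: str = "pairwise"
) -> DistanceMatrix:
    """Compute the K2P distance matrix over all specimen pairs.

    Parameters
    ----------
    dataset:
        A :class:`~barcodegap.io_taxa.Dataset` or a plain sequence of
        barcodes (>= 2 specimens, equal lengths).
    deletion:
        ``"pairwise"`` (default): each pair uses its own compared-site count
        L.  ``"complete"``: alignment columns containing any gap/N/ambiguity
        in any sequence are removed once for all pairs.

    Undefined entries are stored as NaN and counted in the log; a specimen
    whose every comparison is undefined is named in a warning.
    """
    barcodes = dataset.barcodes if isinstance(dataset, Dataset) else list(dataset)
    if len(barcodes) < 2:
        raise ValueError("need at least 2 specimens for a distance matrix")
    if deletion not in DELETION_POLICIES:
        raise ValueError(f"unknown deletion policy {deletion!r}")

    codes = encode_alignment(barcodes)
    if deletion == "complete":
        codes = codes[:, (codes < 4).all(axis=0)]
    valid = codes < 4
    purine = codes >> 1  # 0 = purine, 1 = pyrimidine (excluded cols irrelevant)

    n = len(barcodes)
    d = np.zeros((n, n), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n - 1):
            both = valid[i] & valid[i + 1 :]
            diff = both & (codes[i] != codes[i + 1 :])
            ts = diff & (purine[i] == purine[i + 1 :])
            L = both.sum(axis=1).astype(float)
            n_ts = ts.sum(axis=1)
            n_tv = diff.sum(axis=1) - n_ts
            P = np.where(L > 0, n_ts / np.maximum(L, 1), np.nan)
            Q = np.where(L > 0, n_tv / np.maximum(L, 1), np.nan)
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            row = np.where(
                (w1 > 0) & (w2 > 0), -0.5 * np.log(w1) - 0.25 * np.log(w2), np.nan
            )
            d[i, i + 1 :] = row
            d[i + 1 :, i] = row

    dm = DistanceMatrix([b.specimen_id for b in barcodes], d)
    if dm.n_undefined:
        logger.info("distance matrix: %d undefined pair(s)", dm.n_undefined)
        off_diag = ~np.eye(n, dtype=bool)
        for i in range(n):
            if np.isnan(d[i][off_diag[i]]).all():
                logger.warning(
                    "specimen %s: all comparisons undefined", barcodes[i].specimen_id
                )
    return dm
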