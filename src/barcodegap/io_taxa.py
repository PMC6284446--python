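"""Reading, writing and validation of barcode alignments and taxonomy tables.

The pipeline consumes two plain-text inputs: a FASTA multiple sequence
alignment of COI barcodes (equal-length rows, no indels required) and a
tab-separated taxonomy table mapping each specimen to its species, genus and
subfamily.  Trees are serialized as Newick.  All validation that downstream
modules rely on (equal lengths, unique IDs, a consistent species -> genus ->
subfamily hierarchy, a one-to-one alignment/taxonomy join) happens here, so
the statistics and tree modules never see an unlabeled or malformed specimen.

IUPAC ambiguity codes and gaps are accepted and retained verbatim at parse
time; how they are treated (pairwise exclusion) is decided in
:mod:`barcodegap.distances`, not at I/O.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignedBarcode",
    "TaxonomyRecord",
    "Dataset",
    "ValidationError",
    "AlignmentError",
    "HierarchyError",
    "JoinError",
    "read_alignment",
    "write_alignment",
    "read_taxonomy",
    "write_taxonomy",
    "taxonomy_from_headers",
    "build_dataset",
    "read_newick",
    "write_newick",
]

#: Characters accepted in an aligned barcode: the four bases, the IUPAC
#: ambiguity codes, N, and the gap symbol.
ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-")

TAXONOMY_COLUMNS = ("specimen_id", "species", "genus", "subfamily")


class ValidationError(ValueError):
    """Input data violates a structural requirement."""


class AlignmentError(ValidationError):
    """Sequences do not form an equal-length alignment."""


class HierarchyError(ValidationError):
    """Taxonomy table is not a consistent species -> genus -> subfamily map."""


class JoinError(ValidationError):
    """Alignment and taxonomy do not join one-to-one on specimen_id."""


@dataclass(frozen=True)
class AlignedBarcode:
    """One aligned COI sequence with its specimen identifier."""

    specimen_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - ALLOWED_CHARS
        if bad:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: characters outside IUPAC+gap "
                f"alphabet: {sorted(bad)}"
            )
        if not seq:
            raise ValidationError(f"specimen {self.specimen_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyRecord:
    """Assignment of one specimen to species, genus and subfamily."""

    specimen_id: str
    species: str
    genus: str
    subfamily: str


@dataclass
class Dataset:
    """A validated join of an alignment with its taxonomy.

    Invariants: every barcode has exactly one taxonomy record and vice versa,
    all sequences share one alignment length, and there are at least two
    specimens.
    """

    barcodes: list[AlignedBarcode]
    taxonomy: dict[str, TaxonomyRecord] = field(repr=False)

    @property
    def specimen_ids(self) -> list[str]:
        return [b.specimen_id for b in self.barcodes]

    @property
    def alignment_length(self) -> int:
        return len(self.barcodes[0])

    def record(self, specimen_id: str) -> TaxonomyRecord:
        return self.taxonomy[specimen_id]

    def summary(self) -> dict:
        """Counts of specimens and taxa, and mean specimens per species."""
        species = {r.species for r in self.taxonomy.values()}
        genera = {r.genus for r in self.taxonomy.values()}
        subfamilies = {r.subfamily for r in self.taxonomy.values()}
        n = len(self.barcodes)
        return {
            "n_specimens": n,
            "n_species": len(species),
            "n_genera": len(genera),
            "n_subfamilies": len(subfamilies),
            "specimens_per_species": n / len(species),
        }


def _validate_equal_lengths(barcodes: Sequence[AlignedBarcode]) -> None:
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        ref = len(barcodes[0])
        offenders = [b.specimen_id for b in barcodes if len(b) != ref]
        raise AlignmentError(
            f"unequal sequence lengths {sorted(lengths)}; records differing "
            f"from first ({ref} bp): {offenders}"
        )


def _validate_unique_ids(ids: Iterable[str]) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate specimen IDs: {sorted(set(dups))}")


def read_alignment(path: str | Path) -> list[AlignedBarcode]:
    """Read a FASTA alignment into a list of :class:`AlignedBarcode`.

    Sequences are uppercase-normalized; file order is preserved.  Raises
    :class:`AlignmentError` if lengths differ, :class:`ValidationError` on
    duplicate IDs, an empty file, or characters outside the IUPAC alphabet.
    """
    path = Path(path)
    records = [
        AlignedBarcode(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    _validate_unique_ids(b.specimen_id for b in records)
    _validate_equal_lengths(records)
    return records


def write_alignment(barcodes: Sequence[AlignedBarcode], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in barcodes:
            fh.write(f">{b.specimen_id}\n{b.sequence}\n")


def _check_hierarchy(df: pd.DataFrame) -> None:
    sp2gen = df.groupby("species")["genus"].nunique()
    bad_sp = sp2gen[sp2gen > 1].index.tolist()
    if bad_sp:
        raise HierarchyError(f"species mapped to more than one genus: {bad_sp}")
    gen2sub = df.groupby("genus")["subfamily"].nunique()
    bad_gen = gen2sub[gen2sub > 1].index.tolist()
    if bad_gen:
        raise HierarchyError(f"genus mapped to more than one subfamily: {bad_gen}")


def read_taxonomy(path: str | Path) -> list[TaxonomyRecord]:
    """Read a taxonomy TSV with columns specimen_id, species, genus, subfamily."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing taxonomy columns {missing}")
    if df[list(TAXONOMY_COLUMNS)].isna().any().any():
        raise ValidationError(f"{path}: empty cells in taxonomy table")
    _validate_unique_ids(df["specimen_id"])
    _check_hierarchy(df)
    return [
        TaxonomyRecord(r.specimen_id, r.species, r.genus, r.subfamily)
        for r in df.itertuples(index=False)
    ]


def write_taxonomy(records: Sequence[TaxonomyRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.specimen_id, r.species, r.genus, r.subfamily) for r in records],
        columns=list(TAXONOMY_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


_HEADER_RE = re.compile(r"^(?P<genus>[A-Z][a-z]+)_(?P<epithet>[a-z]+)_(?P<voucher>.+)$")


def taxonomy_from_headers(
    barcodes: Sequence[AlignedBarcode], subfamily: str = "unknown"
) -> list[TaxonomyRecord]:
    """Convenience parser for ``Genus_species_voucher`` FASTA headers.

    Produces one record per barcode; the subfamily is not encoded in such
    headers and must be supplied (or corrected from a TSV, which always wins
    on conflict).
    """
    out = []
    for b in barcodes:
        m = _HEADER_RE.match(b.specimen_id)
        if not m:
            raise ValidationError(
                f"header {b.specimen_id!r} does not match Genus_species_voucher"
            )
        genus = m.group("genus")
        out.append(
            TaxonomyRecord(
                b.specimen_id, f"{genus} {m.group('epithet')}", genus, subfamily
            )
        )
    return out


def build_dataset(
    barcodes: Sequence[AlignedBarcode], taxonomy: Sequence[TaxonomyRecord]
) -> Dataset:
    """Join alignment and taxonomy one-to-one; raises :class:`JoinError` on mismatch."""
    if len(barcodes) < 2:
        raise ValidationError("a dataset needs at least 2 specimens")
    _validate_unique_ids(b.specimen_id for b in barcodes)
    _validate_equal_lengths(list(barcodes))
    tax = {r.specimen_id: r for r in taxonomy}
    align_ids = {b.specimen_id for b in barcodes}
    unlabeled = sorted(align_ids - tax.keys())
    if unlabeled:
        raise JoinError(f"specimens in alignment but not in taxonomy: {unlabeled}")
    extra = sorted(tax.keys() - align_ids)
    if extra:
        raise JoinError(f"specimens in taxonomy but not in alignment: {extra}")
    df = pd.DataFrame(
        [(r.species, r.genus, r.subfamily) for r in tax.values()],
        columns=["species", "genus", "subfamily"],
    )
    _check_hierarchy(df)
    return Dataset(barcodes=list(barcodes), taxonomy=tax)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick tree, preserving underscores in labels."""
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize a tree to Newick.

    Branch lengths are written with 12 significant digits so that a
    write/parse round trip preserves them to at least 10 significant digits;
    labels containing spaces are quoted per Newick rules, while underscores
    are written unquoted and left untouched.
    """
    if len(tree.leaf_nodes()) < 2:
        raise ValidationError("refusing to serialize a tree with fewer than 2 leaves")
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,  # labels with spaces are quoted, not mangled
        real_value_format_specifier=".12g",
    )
    Path(path).write_text(text)
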