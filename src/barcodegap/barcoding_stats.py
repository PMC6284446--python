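"""Barcoding-gap statistics and per-species discrimination assessment.

The headline statistic follows the strict form of the barcoding gap: the
average over species of the *maximum* intraspecific K2P distance, the
average over species of the *minimum* interspecific K2P distance to a
congener, and their ratio.  A ratio >= 10 is the conventional criterion for
a significant gap.  Level summaries aggregate all pairwise distances per
comparison class (intraspecific; congeneric interspecific; interspecific
within a subfamily), and the discrimination assessment flags species whose
barcodes are not separable from a heterospecific neighbour.

All distances handled here are substitutions/site; report-facing containers
(:class:`GapReport`, :class:`LevelSummary`) carry percentages, matching how
barcoding studies print them.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .io_taxa import TaxonomyRecord

__all__ = [
    "SpeciesGapRow",
    "GapReport",
    "LevelSummary",
    "PAIR_CLASSES",
    "pair_classes",
    "species_gap_rows",
    "barcoding_gap_report",
    "level_summaries",
    "subset_stats",
    "discrimination_assessment",
    "gap_rows_to_frame",
    "summaries_to_frame",
]

logger = logging.getLogger("barcodegap.stats")

#: Exclusive pair classes.  The within-subfamily *summary* class is the union
#: of "congeneric" and "intrasubfamilial" (congeners are inside their
#: subfamily), which is why the latter label covers only non-congeneric pairs.
PAIR_CLASSES = ("intraspecific", "congeneric", "intrasubfamilial", "other")

DISCRIMINATION_CRITERIA = ("nearest-neighbor", "local-gap", "both")


@dataclass
class SpeciesGapRow:
    """Per-species extremes of the intra/inter distance distributions.

    ``max_intra`` is defined only for species with >= 2 specimens;
    ``min_inter_congeneric`` only when the genus holds >= 2 species.
    ``discriminated`` is "yes", "no", or "not-assessable".
    Distances in substitutions/site.
    """

    species: str
    n_specimens: int
    max_intra: float = math.nan
    min_inter_congeneric: float = math.nan
    discriminated: str = "not-assessable"
    failure_partners: list[str] = field(default_factory=list)


@dataclass
class GapReport:
    """The headline barcoding-gap statistics, in percent.

    ``gap_ratio`` is computed from the unrounded means;
    ``infinite_gap`` flags a zero average maximum intraspecific distance
    (ratio undefined); ``gap_criterion_met`` applies the conventional
    10x rule to the ratio.
    """

    avg_max_intra: float
    avg_min_inter_congeneric: float
    gap_ratio: float
    n_species_intra: int
    n_species_inter: int
    infinite_gap: bool
    gap_criterion_met: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GapReport":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class LevelSummary:
    """Mean/min/max (percent) of one comparison class, overall or per taxon."""

    level: str
    group: str
    mean: float
    min: float
    max: float
    n_pairs: int


def _taxon_arrays(ids: Sequence[str], taxonomy: dict[str, TaxonomyRecord]):
    species = np.array([taxonomy[s].species for s in ids])
    genus = np.array([taxonomy[s].genus for s in ids])
    subfamily = np.array([taxonomy[s].subfamily for s in ids])
    return species, genus, subfamily


def pair_classes(
    dm: DistanceMatrix, taxonomy: dict[str, TaxonomyRecord]
) -> pd.DataFrame:
    """Assign every unordered specimen pair to exactly one comparison class.

    Returns a DataFrame with columns ``id_a, id_b, distance, pair_class``
    where ``pair_class`` is one of :data:`PAIR_CLASSES` ("intrasubfamilial"
    covers same-subfamily, different-genus pairs only; congeners are labeled
    "congeneric").
    """
    ids = dm.ids
    species, genus, subfamily = _taxon_arrays(ids, taxonomy)
    iu, ju = np.triu_indices(len(ids), k=1)
    same_sp = species[iu] == species[ju]
    same_gen = genus[iu] == genus[ju]
    same_sub = subfamily[iu] == subfamily[ju]
    labels = np.select(
        [same_sp, same_gen, same_sub],
        ["intraspecific", "congeneric", "intrasubfamilial"],
        default="other",
    )
    arr = np.asarray(ids)
    return pd.DataFrame(
        {
            "id_a": arr[iu],
            "id_b": arr[ju],
            "distance": dm.values[iu, ju],
            "pair_class": labels,
        }
    )


def _nan_extremum(values: np.ndarray, fn) -> float:
    finite = values[~np.isnan(values)]
    if finite.size == 0:
        return math.nan
    return float(fn(finite))


def species_gap_rows(
    dm: DistanceMatrix,
    taxonomy: dict[str, TaxonomyRecord],
    criterion: str = "both",
) -> list[SpeciesGapRow]:
    """Per-species maximum intraspecific and minimum congeneric distances.

    Undefined (NaN) distances are skipped with a logged count.  The
    ``discriminated`` flag and ``failure_partners`` come from
    :func:`discrimination_assessment` under ``criterion``.
    """
    ids = dm.ids
    species, genus, _ = _taxon_arrays(ids, taxonomy)
    flags = discrimination_assessment(dm, taxonomy, criterion=criterion)
    rows: list[SpeciesGapRow] = []
    n_skipped = 0
    for sp in pd.unique(species):
        mask = species == sp
        idx = np.flatnonzero(mask)
        row = SpeciesGapRow(species=str(sp), n_specimens=int(mask.sum()))
        if idx.size >= 2:
            sub = dm.values[np.ix_(idx, idx)]
            vals = sub[np.triu_indices(idx.size, k=1)]
            n_skipped += int(np.isnan(vals).sum())
            row.max_intra = _nan_extremum(vals, np.max)
        congeners = (genus == genus[idx[0]]) & ~mask
        if congeners.any():
            vals = dm.values[np.ix_(idx, np.flatnonzero(congeners))].ravel()
            n_skipped += int(np.isnan(vals).sum())
            row.min_inter_congeneric = _nan_extremum(vals, np.min)
        row.discriminated, row.failure_partners = flags[str(sp)]
        rows.append(row)
    if n_skipped:
        logger.info("species_gap_rows: skipped %d undefined distance(s)", n_skipped)
    return rows


def barcoding_gap_report(rows: Sequence[SpeciesGapRow]) -> GapReport:
    """Aggregate per-species extremes into the headline gap statistics.

    Means are taken over species with a defined value only; single-specimen
    species and single-species genera are excluded (not counted as zero).
    """
    intra = [r.max_intra for r in rows if not math.isnan(r.max_intra)]
    inter = [r.min_inter_congeneric for r in rows if not math.isnan(r.min_inter_congeneric)]
    if not inter:
        raise ValueError("no species has a defined congeneric distance")
    avg_inter = float(np.mean(inter)) * 100.0
    if not intra:
        raise ValueError("no species has a defined intraspecific distance")
    avg_intra = float(np.mean(intra)) * 100.0
    infinite = avg_intra == 0.0
    ratio = math.inf if infinite else avg_inter / avg_intra
    return GapReport(
        avg_max_intra=avg_intra,
        avg_min_inter_congeneric=avg_inter,
        gap_ratio=ratio,
        n_species_intra=len(intra),
        n_species_inter=len(inter),
        infinite_gap=infinite,
        gap_criterion_met=bool(ratio >= 10.0),
    )


def _summary(level: str, group: str, values: np.ndarray) -> LevelSummary:
    finite = values[~np.isnan(values)] * 100.0
    if finite.size == 0:
        return LevelSummary(level, group, math.nan, math.nan, math.nan, 0)
    return LevelSummary(
        level,
        group,
        float(finite.mean()),
        float(finite.min()),
        float(finite.max()),
        int(finite.size),
    )


def level_summaries(
    dm: DistanceMatrix, taxonomy: dict[str, TaxonomyRecord]
) -> list[LevelSummary]:
    """Distance summaries per comparison class (percent).

    Overall rows for the intraspecific and congeneric-interspecific classes,
    plus the within-subfamily interspecific class (congeneric pairs
    included — its range can reach 0 when congeners share haplotypes) both
    overall and per subfamily.
    """
    pc = pair_classes(dm, taxonomy)
    d = pc["distance"].to_numpy()
    out = [
        _summary("intraspecific", "overall", d[pc["pair_class"] == "intraspecific"]),
        _summary(
            "interspecific-congeneric", "overall", d[pc["pair_class"] == "congeneric"]
        ),
    ]
    within = pc["pair_class"].isin(["congeneric", "intrasubfamilial"]).to_numpy()
    out.append(_summary("interspecific-within-subfamily", "overall", d[within]))
    sub_of = {s: taxonomy[s].subfamily for s in dm.ids}
    subfam_a = pc["id_a"].map(sub_of).to_numpy()
    for sub in sorted(set(sub_of.values())):
        sel = within & (subfam_a == sub)
        out.append(_summary("interspecific-within-subfamily", sub, d[sel]))
    return out


def subset_stats(
    dm: DistanceMatrix,
    taxonomy: dict[str, TaxonomyRecord],
    species_list: Sequence[str],
) -> dict[str, float]:
    """Mean intraspecific and mean interspecific distance within a species set.

    Percent values; ``mean_inter`` is NaN for a single-species list,
    ``mean_intra`` is NaN when every listed species has one specimen.
    """
    wanted = set(species_list)
    if not wanted:
        raise ValueError("species_list is empty")
    present = {taxonomy[s].species for s in dm.ids}
    missing = sorted(wanted - present)
    if missing:
        raise ValueError(f"species not in dataset: {missing}")
    keep = [s for s in dm.ids if taxonomy[s].species in wanted]
    sub = dm.submatrix(keep)
    pc = pair_classes(sub, taxonomy)
    d = pc["distance"].to_numpy()
    intra = d[(pc["pair_class"] == "intraspecific").to_numpy()]
    inter = d[(pc["pair_class"] != "intraspecific").to_numpy()]
    return {
        "mean_intra": _nan_extremum(intra, np.mean) * 100.0 if intra.size else math.nan,
        "mean_inter": _nan_extremum(inter, np.mean) * 100.0 if inter.size else math.nan,
    }


def discrimination_assessment(
    dm: DistanceMatrix,
    taxonomy: dict[str, TaxonomyRecord],
    criterion: str = "both",
) -> dict[str, tuple[str, list[str]]]:
    """Flag species whose barcodes fail to separate from heterospecifics.

    Criteria
    --------
    ``"nearest-neighbor"``
        A species fails if any of its specimens has a heterospecific specimen
        at a distance less than or equal to that specimen's nearest
        conspecific.  A single-specimen species fails only on an exact
        haplotype tie (distance 0).
    ``"local-gap"``
        A species fails if its maximum intraspecific distance is >= its
        minimum distance to any heterospecific specimen.
    ``"both"`` (default)
        Pass requires passing every assessable criterion above.

    A zero distance to a heterospecific specimen always fails, regardless of
    criterion.  Returns ``{species: (flag, failure_partners)}`` with flag in
    {"yes", "no", "not-assessable"}.
    """
    if criterion not in DISCRIMINATION_CRITERIA:
        raise ValueError(
            f"unknown criterion {criterion!r}; expected one of {DISCRIMINATION_CRITERIA}"
        )
    ids = dm.ids
    species, _, _ = _taxon_arrays(ids, taxonomy)
    d = dm.values
    out: dict[str, tuple[str, list[str]]] = {}
    for sp in pd.unique(species):
        mask = species == sp
        idx = np.flatnonzero(mask)
        hetero = np.flatnonzero(~mask)
        if hetero.size == 0:
            out[sp] = ("not-assessable", [])
            continue
        hd = d[np.ix_(idx, hetero)]  # specimens x heterospecific specimens
        partners: set[str] = set()
        sp = str(sp)

        # zero-distance haplotype ties always fail
        tie = np.nan_to_num(hd, nan=np.inf) == 0.0
        failed = bool(tie.any())
        if failed:
            partners.update(str(species[hetero[j]]) for j in np.flatnonzero(tie.any(axis=0)))

        use_nn = criterion in ("nearest-neighbor", "both")
        use_gap = criterion in ("local-gap", "both")

        if use_nn and idx.size >= 2 and not failed:
            intra_block = d[np.ix_(idx, idx)].copy()
            np.fill_diagonal(intra_block, np.nan)
            nearest_con = np.nanmin(intra_block, axis=1)  # per specimen
            with np.errstate(invalid="ignore"):
                viol = hd <= nearest_con[:, None]
            viol &= ~np.isnan(hd)
            if viol.any():
                failed = True
                partners.update(
                    str(species[hetero[j]]) for j in np.flatnonzero(viol.any(axis=0))
                )
        if use_gap and idx.size >= 2 and not failed:
            intra_vals = d[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)]
            max_intra = _nan_extremum(intra_vals, np.max)
            min_hetero = _nan_extremum(hd.ravel(), np.min)
            if not math.isnan(max_intra) and not math.isnan(min_hetero):
                if max_intra >= min_hetero:
                    failed = True
                    with np.errstate(invalid="ignore"):
                        viol = hd <= max_intra
                    viol &= ~np.isnan(hd)
                    partners.update(
                        str(species[hetero[j]]) for j in np.flatnonzero(viol.any(axis=0))
                    )
        out[sp] = ("no" if failed else "yes", sorted(partners))
    return out


def gap_rows_to_frame(rows: Sequence[SpeciesGapRow], percent: bool = True) -> pd.DataFrame:
    """Tabulate gap rows; distances converted to percent by default."""
    scale = 100.0 if percent else 1.0
    return pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "n_specimens": [r.n_specimens for r in rows],
            "max_intra": [r.max_intra * scale for r in rows],
            "min_inter_congeneric": [r.min_inter_congeneric * scale for r in rows],
            "discriminated": [r.discriminated for r in rows],
            "failure_partners": [";".join(r.failure_partners) for r in rows],
        }
    )


def summaries_to_frame(summaries: Sequence[LevelSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])
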