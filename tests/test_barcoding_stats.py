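import itertools
import math

import numpy as np
import pytest

from barcodegap import (
    AlignedBarcode,
    TaxonomyRecord,
    barcoding_gap_report,
    build_dataset,
    discrimination_assessment,
    distance_matrix,
    level_summaries,
    pair_classes,
    species_gap_rows,
    subset_stats,
)
from barcodegap.barcoding_stats import SpeciesGapRow
from barcodegap.distances import DistanceMatrix
from barcodegap.synthetic_data import SimulationConfig, simulate_dataset

D_INTRA = -0.5 * math.log(0.98)  # 2 transitions / 200 sites
D_INTER = -0.5 * math.log(0.92)  # 8 transitions / 200 sites


def matrix_from(ids, entries):
    n = len(ids)
    d = np.zeros((n, n))
    pos = {s: i for i, s in enumerate(ids)}
    for (a, b), v in entries.items():
        d[pos[a], pos[b]] = d[pos[b], pos[a]] = v
    return DistanceMatrix(ids, d)


def taxdict(rows):
    return {r[0]: TaxonomyRecord(*r) for r in rows}


class TestPairClasses:
    def test_single_conspecific_pair(self):
        dm = matrix_from(["x", "y"], {("x", "y"): 0.001})
        tax = taxdict([("x", "S1", "G1", "F1"), ("y", "S1", "G1", "F1")])
        pc = pair_classes(dm, tax)
        assert list(pc["pair_class"]) == ["intraspecific"]

    def test_three_specimens_two_genera_enumeration(self):
        # A.x, A.y congeneric; B.z in the other genus, same subfamily
        dm = matrix_from(["x", "y", "z"], {("x", "y"): 0.1, ("x", "z"): 0.2, ("y", "z"): 0.2})
        tax = taxdict(
            [("x", "A x", "A", "F"), ("y", "A y", "A", "F"), ("z", "B z", "B", "F")]
        )
        pc = pair_classes(dm, tax).set_index(["id_a", "id_b"])
        assert pc.loc[("x", "y"), "pair_class"] == "congeneric"
        assert pc.loc[("x", "z"), "pair_class"] == "intrasubfamilial"
        assert pc.loc[("y", "z"), "pair_class"] == "intrasubfamilial"

    def test_cross_subfamily_pairs_are_other(self):
        dm = matrix_from(["x", "y"], {("x", "y"): 0.3})
        tax = taxdict([("x", "A x", "A", "F1"), ("y", "B y", "B", "F2")])
        assert list(pair_classes(dm, tax)["pair_class"]) == ["other"]

    def test_classes_partition_all_pairs(self, toy_dm, toy_dataset):
        pc = pair_classes(toy_dm, toy_dataset.taxonomy)
        n = len(toy_dm)
        assert len(pc) == n * (n - 1) // 2
        counts = pc["pair_class"].value_counts()
        assert counts.sum() == len(pc)


class TestSpeciesGapRows:
    def test_toy_enumeration(self):
        dm = matrix_from(
            ["a", "b", "c"],
            {("a", "b"): 0.002, ("a", "c"): 0.11, ("b", "c"): 0.12},
        )
        tax = taxdict(
            [("a", "S1", "G", "F"), ("b", "S1", "G", "F"), ("c", "S2", "G", "F")]
        )
        rows = {r.species: r for r in species_gap_rows(dm, tax)}
        assert rows["S1"].max_intra == pytest.approx(0.002)
        assert rows["S1"].min_inter_congeneric == pytest.approx(0.11)
        assert rows["S2"].min_inter_congeneric == pytest.approx(0.11)
        assert math.isnan(rows["S2"].max_intra)  # single specimen

    def test_single_species_genus_has_undefined_min_inter(self, toy_dm, toy_dataset):
        rows = {r.species: r for r in species_gap_rows(toy_dm, toy_dataset.taxonomy)}
        assert math.isnan(rows["Lygus rugulipennis"].min_inter_congeneric)
        assert rows["Lygus rugulipennis"].max_intra == pytest.approx(D_INTRA)

    def test_matches_brute_force_double_loop(self, rng):
        """avg min-inter from rows equals an independent all-pairs double loop."""
        ds, _ = simulate_dataset(
            SimulationConfig(n_subfamilies=2, seq_length=300, seed=11)
        )
        dm = distance_matrix(ds)
        rows = species_gap_rows(dm, ds.taxonomy)
        by_species = {}
        tax = ds.taxonomy
        for i, j in itertools.combinations(range(len(dm.ids)), 2):
            a, b = dm.ids[i], dm.ids[j]
            ra, rb = tax[a], tax[b]
            if ra.genus == rb.genus and ra.species != rb.species:
                d = dm.values[i, j]
                for sp in (ra.species, rb.species):
                    cur = by_species.get(sp, math.inf)
                    by_species[sp] = min(cur, d)
        got = {
            r.species: r.min_inter_congeneric
            for r in rows
            if not math.isnan(r.min_inter_congeneric)
        }
        assert got.keys() == by_species.keys()
        for sp in got:
            assert got[sp] == pytest.approx(by_species[sp], abs=0)

    def test_monotonic_under_data_growth(self, toy_dataset):
        """Adding a specimen never lowers max_intra nor raises min_inter."""
        base = toy_dataset.barcodes
        tax = list(toy_dataset.taxonomy.values())
        dm_small = distance_matrix(build_dataset(base[:-1], tax[:-1]))
        tax_small = {r.specimen_id: r for r in tax[:-1]}
        rows_small = {
            r.species: r for r in species_gap_rows(dm_small, tax_small)
        }
        dm_full = distance_matrix(toy_dataset)
        rows_full = {r.species: r for r in species_gap_rows(dm_full, toy_dataset.taxonomy)}
        for sp, small in rows_small.items():
            full = rows_full[sp]
            if not math.isnan(small.max_intra):
                assert full.max_intra >= small.max_intra
            if not math.isnan(small.min_inter_congeneric):
                assert full.min_inter_congeneric <= small.min_inter_congeneric


class TestGapReport:
    def test_arithmetic(self):
        rows = [
            SpeciesGapRow("S1", 2, max_intra=0.002, min_inter_congeneric=0.11),
            SpeciesGapRow("S2", 2, max_intra=0.004, min_inter_congeneric=0.13),
        ]
        rep = barcoding_gap_report(rows)
        assert rep.avg_max_intra == pytest.approx(0.3)
        assert rep.avg_min_inter_congeneric == pytest.approx(12.0)
        assert rep.gap_ratio == pytest.approx(40.0)
        assert rep.gap_criterion_met

    def test_undefined_values_excluded_from_means(self):
        rows = [
            SpeciesGapRow("S1", 2, max_intra=0.002, min_inter_congeneric=0.1),
            SpeciesGapRow("S2", 1, min_inter_congeneric=0.2),  # no intra pairs
            SpeciesGapRow("S3", 2, max_intra=0.004),  # lone species in genus
        ]
        rep = barcoding_gap_report(rows)
        assert rep.n_species_intra == 2
        assert rep.n_species_inter == 2
        assert rep.avg_max_intra == pytest.approx(0.3)
        assert rep.avg_min_inter_congeneric == pytest.approx(15.0)

    def test_all_zero_intra_flags_infinite_gap(self):
        rows = [SpeciesGapRow("S1", 2, max_intra=0.0, min_inter_congeneric=0.1)]
        rep = barcoding_gap_report(rows)
        assert rep.infinite_gap
        assert math.isinf(rep.gap_ratio)

    def test_toy_dataset_end_to_end(self, toy_dm, toy_dataset):
        rep = barcoding_gap_report(species_gap_rows(toy_dm, toy_dataset.taxonomy))
        assert rep.avg_max_intra == pytest.approx(D_INTRA * 100)
        assert rep.avg_min_inter_congeneric == pytest.approx(D_INTER * 100)
        assert rep.gap_ratio == pytest.approx(D_INTER / D_INTRA)


class TestLevelSummaries:
    def test_toy_values(self, toy_dm, toy_dataset):
        out = {(s.level, s.group): s for s in level_summaries(toy_dm, toy_dataset.taxonomy)}
        intra = out[("intraspecific", "overall")]
        assert intra.n_pairs == 2
        assert intra.mean == pytest.approx(D_INTRA * 100)
        cong = out[("interspecific-congeneric", "overall")]
        assert cong.n_pairs == 2  # a1-b1, a2-b1
        within = out[("interspecific-within-subfamily", "overall")]
        assert within.n_pairs == 2 + 6  # congeners + cross-genus pairs (3x2 specimens)
        assert within.min == cong.min  # superset includes congeneric pairs
        sub = out[("interspecific-within-subfamily", "Mirinae")]
        assert sub.n_pairs == within.n_pairs

    def test_empty_class_has_zero_pairs(self):
        dm = matrix_from(["x", "y"], {("x", "y"): 0.001})
        tax = taxdict([("x", "S1", "G1", "F1"), ("y", "S1", "G1", "F1")])
        out = {(s.level, s.group): s for s in level_summaries(dm, tax)}
        cong = out[("interspecific-congeneric", "overall")]
        assert cong.n_pairs == 0
        assert math.isnan(cong.mean)


class TestSubsetStats:
    def test_toy_enumeration(self):
        dm = matrix_from(
            ["a", "b", "c"],
            {("a", "b"): 0.002, ("a", "c"): 0.11, ("b", "c"): 0.12},
        )
        tax = taxdict(
            [("a", "S1", "G", "F"), ("b", "S1", "G", "F"), ("c", "S2", "G", "F")]
        )
        st = subset_stats(dm, tax, ["S1", "S2"])
        assert st["mean_inter"] == pytest.approx(11.5)
        assert st["mean_intra"] == pytest.approx(0.2)

    def test_single_species_list_has_undefined_inter(self, toy_dm, toy_dataset):
        st = subset_stats(toy_dm, toy_dataset.taxonomy, ["Apolygus lucorum"])
        assert math.isnan(st["mean_inter"])
        assert st["mean_intra"] == pytest.approx(D_INTRA * 100)

    def test_unknown_species_rejected(self, toy_dm, toy_dataset):
        with pytest.raises(ValueError, match="not in dataset"):
            subset_stats(toy_dm, toy_dataset.taxonomy, ["Nabis ferus"])


class TestDiscrimination:
    def shared_haplotype_setup(self):
        seq = "ACGT" * 20
        # well-separated congener: 12 transitions out of 80 sites
        other = "".join(
            "G" if (i % 4 == 0 and i < 48) else ch for i, ch in enumerate(seq)
        )
        barcodes = [
            AlignedBarcode("x1", seq),
            AlignedBarcode("y1", seq),  # identical heterospecific haplotype
            AlignedBarcode("z1", other),
        ]
        tax = [
            TaxonomyRecord("x1", "S1", "G", "F"),
            TaxonomyRecord("y1", "S2", "G", "F"),
            TaxonomyRecord("z1", "S3", "G", "F"),
        ]
        return build_dataset(barcodes, tax)

    @pytest.mark.parametrize("criterion", ["nearest-neighbor", "local-gap", "both"])
    def test_shared_haplotype_fails_under_every_criterion(self, criterion):
        ds = self.shared_haplotype_setup()
        dm = distance_matrix(ds)
        flags = discrimination_assessment(dm, ds.taxonomy, criterion=criterion)
        assert flags["S1"] == ("no", ["S2"])
        assert flags["S2"] == ("no", ["S1"])

    @pytest.mark.parametrize("criterion", ["nearest-neighbor", "local-gap", "both"])
    def test_well_separated_toy_passes(self, toy_dm, toy_dataset, criterion):
        flags = discrimination_assessment(toy_dm, toy_dataset.taxonomy, criterion=criterion)
        assert all(v[0] == "yes" for v in flags.values())

    def test_nearest_neighbor_tie_fails(self):
        # heterospecific at the same distance as the nearest conspecific
        dm = matrix_from(
            ["a", "b", "c"],
            {("a", "b"): 0.01, ("a", "c"): 0.01, ("b", "c"): 0.02},
        )
        tax = taxdict(
            [("a", "S1", "G", "F"), ("b", "S1", "G", "F"), ("c", "S2", "G", "F")]
        )
        flags = discrimination_assessment(dm, tax, criterion="nearest-neighbor")
        assert flags["S1"][0] == "no"
        assert "S2" in flags["S1"][1]

    def test_unknown_criterion_rejected(self, toy_dm, toy_dataset):
        with pytest.raises(ValueError, match="criterion"):
            discrimination_assessment(toy_dm, toy_dataset.taxonomy, criterion="bogus")


class TestParameterRecovery:
    def test_gap_ratio_recovered_on_default_synthetic_dataset(self):
        cfg = SimulationConfig(seed=5)
        ds, truth = simulate_dataset(cfg)
        dm = distance_matrix(ds)
        rep = barcoding_gap_report(species_gap_rows(dm, ds.taxonomy))
        configured = truth["configured_gap_ratio"]
        assert abs(rep.gap_ratio - configured) / configured < 0.25
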