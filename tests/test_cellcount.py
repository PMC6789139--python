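"""Detection, co-expression classification, subregion assignment, tabulation."""

import numpy as np
import pytest

from raphequant import cellcount, synth
from raphequant.cellcount import (DetectionPolicy, NoCellsError, SubregionLayout,
                                  Section)


def _section_from(arrs, um_per_px=2.0):
    return Section(channels=arrs, um_per_px=um_per_px)


class TestDetect:
    def test_blank_channel_yields_nothing(self):
        sec = _section_from({"reporter": np.zeros((64, 64))})
        assert cellcount.detect_cells(sec, "reporter") == []

    def test_saturated_channel_yields_nothing(self):
        sec = _section_from({"reporter": np.ones((64, 64))})
        assert cellcount.detect_cells(sec, "reporter") == []

    def test_planted_somata_recovered_exactly(self, clean_section, fixed_policy):
        _, section, truth = clean_section
        dets = cellcount.detect_cells(section, "reporter", fixed_policy)
        assert len(dets) == len(truth.cells) == 200

    def test_translation_equivariance(self, fixed_policy):
        spec = synth.SectionSpec(cells_per_subregion=10, clutter_density=0.0,
                                 noise_sd=0.0, seed=8)
        section, _ = synth.make_section(spec)
        img = section.channels["reporter"]
        pad = np.full((img.shape[0] + 10, img.shape[1] + 10), img.min())
        pad[10:, 10:] = img
        shifted = _section_from({"reporter": pad[:img.shape[0], :img.shape[1]]})
        base = cellcount.detect_cells(section, "reporter", fixed_policy)
        moved = cellcount.detect_cells(shifted, "reporter", fixed_policy)
        # objects shifted down/right by 10 px; those pushed off the canvas drop
        kept = [d for d in base
                if d.centroid_px[0] + 10 < img.shape[0] - 8
                and d.centroid_px[1] + 10 < img.shape[1] - 8]
        assert len(moved) >= len(kept)
        base_set = {(round(d.centroid_px[0] + 10, 1), round(d.centroid_px[1] + 10, 1))
                    for d in kept}
        moved_set = {(round(d.centroid_px[0], 1), round(d.centroid_px[1], 1))
                     for d in moved}
        assert base_set <= moved_set

    def test_row_major_ordering(self, clean_section, fixed_policy):
        _, section, _ = clean_section
        dets = cellcount.detect_cells(section, "reporter", fixed_policy)
        cents = [d.centroid_px for d in dets]
        assert cents == sorted(cents)

    def test_missing_channel_raises(self):
        sec = _section_from({"reporter": np.zeros((8, 8))})
        with pytest.raises(KeyError):
            cellcount.detect_cells(sec, "marker")


class TestCoexpression:
    def test_blank_marker_all_false(self, clean_section, fixed_policy):
        _, section, _ = clean_section
        dets = cellcount.detect_cells(section, "reporter", fixed_policy)
        blank = _section_from({"reporter": section.channels["reporter"],
                               "marker": np.zeros(section.shape)})
        dets = cellcount.classify_coexpression(dets, blank, "marker", fixed_policy)
        assert not any(d.coexpress["marker"] for d in dets)

    def test_marker_copy_of_reporter_all_true(self, clean_section, fixed_policy):
        _, section, _ = clean_section
        dets = cellcount.detect_cells(section, "reporter", fixed_policy)
        twin = _section_from({"reporter": section.channels["reporter"],
                              "marker": section.channels["reporter"].copy()})
        dets = cellcount.classify_coexpression(dets, twin, "marker", fixed_policy)
        assert all(d.coexpress["marker"] for d in dets)

    def test_recovered_fraction_within_binomial_ci(self, fixed_policy):
        spec = synth.SectionSpec(p_coexpress=0.9, cells_per_subregion=50, seed=21)
        section, truth = synth.make_section(spec)
        dets = cellcount.detect_cells(section, "reporter", fixed_policy)
        dets = cellcount.classify_coexpression(dets, section, "marker", fixed_policy)
        frac = np.mean([d.coexpress["marker"] for d in dets])
        half = 1.96 * np.sqrt(0.9 * 0.1 / len(dets))
        assert abs(frac - 0.9) <= half

    def test_missing_marker_channel_raises(self, clean_section, fixed_policy):
        _, section, _ = clean_section
        dets = cellcount.detect_cells(section, "reporter", fixed_policy)
        with pytest.raises(KeyError):
            cellcount.classify_coexpression(dets, section, "TH", fixed_policy)

    def test_raising_marker_threshold_never_adds_flags(self, clean_section):
        spec, section, _ = clean_section
        flags = []
        for thr in [0.2, 0.4, 0.6, 0.8]:
            pol = DetectionPolicy(threshold=thr)
            dets = cellcount.detect_cells(section, "reporter",
                                          DetectionPolicy(threshold=0.425))
            dets = cellcount.classify_coexpression(dets, section, "marker", pol)
            flags.append(sum(d.coexpress["marker"] for d in dets))
        assert flags == sorted(flags, reverse=True)


class TestSubregionsAndTables:
    def test_boundary_centroid_belongs_to_containing_halfopen_box(self):
        layout = SubregionLayout.grid_2x2(300)
        # x = 300 um is the left edge of the right-hand boxes (inclusive)
        assert layout.label_of(300.0, 0.0) == "lateral-right"
        assert layout.label_of(299.999, 0.0) == "lateral-left"
        assert layout.label_of(0.0, 300.0) == "dorsal"
        assert layout.label_of(600.0, 0.0) == "outside"

    def test_single_covering_box_leaves_none_outside(self, clean_section,
                                                     fixed_policy):
        _, section, _ = clean_section
        dets = cellcount.detect_cells(section, "reporter", fixed_policy)
        whole = SubregionLayout({"all": (0, 0, 1e6, 1e6)})
        dets = cellcount.assign_subregions(dets, whole, section.um_per_px)
        assert all(d.subregion == "all" for d in dets)

    def test_assignment_matches_truth_labels(self, clean_section, fixed_policy):
        spec, section, truth = clean_section
        dets = cellcount.detect_cells(section, "reporter", fixed_policy)
        dets = cellcount.assign_subregions(dets, spec.subregion_layout,
                                           section.um_per_px)
        tcells = truth.cells
        for d in dets:
            x, y = d.centroid_um(section.um_per_px)
            i = ((tcells.x_um - x) ** 2 + (tcells.y_um - y) ** 2).idxmin()
            assert d.subregion == tcells.loc[i, "subregion"]

    def test_empty_detections_give_zero_table(self):
        layout = SubregionLayout.grid_2x2()
        t = cellcount.tabulate([], "m1", marker="marker", layout=layout)
        assert t.total() == 0
        with pytest.raises(NoCellsError):
            cellcount.percent_coexpressing(t)

    def test_tabulate_matches_bruteforce_recount(self, clean_section,
                                                 fixed_policy):
        spec, section, _ = clean_section
        dets = cellcount.detect_cells(section, "reporter", fixed_policy)
        dets = cellcount.classify_coexpression(dets, section, "marker",
                                               fixed_policy)
        dets = cellcount.assign_subregions(dets, spec.subregion_layout,
                                           section.um_per_px)
        t = cellcount.tabulate(dets, "m1", marker="marker",
                               layout=spec.subregion_layout)
        inside = [d for d in dets if d.subregion != "outside"]
        assert t.total() == len(inside)
        assert t.total_double() == sum(d.coexpress["marker"] for d in inside)
        # conservation: pooled equals the sum over subregions
        assert t.total_double() == sum(t.n_double.values())

    @pytest.mark.parametrize("nd,nt,expect", [
        (1619, 1698, 95.3), (834, 907, 92.0), (128, 404, 31.7), (0, 100, 0.0)])
    def test_percentage_rounding(self, nd, nt, expect):
        t = cellcount.ColocTable("a", "m", {"s": nd}, {"s": nt - nd})
        assert cellcount.percent_coexpressing(t) == expect

    def test_partition_sums_to_100_before_rounding(self):
        t = cellcount.ColocTable("a", "m", {"s": 323}, {"s": 705 - 323})
        nd, nt = t.total_double(), t.total()
        assert 100 * nd / nt + 100 * (nt - nd) / nt == pytest.approx(100.0,
                                                                    abs=1e-12)


class TestPenetrance:
    def _table(self, animal, total, sections=None):
        return cellcount.ColocTable(animal, "m", {"s": total}, {"s": 0},
                                    n_sections_analyzed=sections,
                                    n_sections_possible=8 if sections else None)

    def test_identical_animals_have_zero_sem(self):
        g = cellcount.penetrance([self._table(f"a{i}", 300) for i in range(3)])
        assert (g.mean, g.sem, g.n) == (300.0, 0.0, 3)

    def test_single_animal_flagged(self):
        g = cellcount.penetrance([self._table("a0", 150)])
        assert g.single_animal and g.sem == 0.0 and g.n == 1

    def test_mean_matches_bruteforce(self, rng):
        totals = rng.integers(100, 400, size=5)
        g = cellcount.penetrance([self._table(f"a{i}", int(t))
                                  for i, t in enumerate(totals)])
        assert g.mean == pytest.approx(float(np.mean(totals)))
        assert g.sem == pytest.approx(float(np.std(totals, ddof=1) / np.sqrt(5)))

    def test_sparse_expression_animals_excluded(self):
        tables = [self._table("ok1", 300, sections=8),
                  self._table("ok2", 310, sections=6),
                  self._table("sparse", 90, sections=4)]
        g = cellcount.penetrance(tables)
        assert g.n == 2 and g.mean == 305.0
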