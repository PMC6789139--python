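"""End-to-end synthetic studies exercising the full pipeline.

Each function generates data with :mod:`raphequant.synth`, runs the relevant
analysis modules exactly as a user would, and returns recovered quantities
side by side with the planted truth.  They are used by the test suite, the
acceptance script and the examples; all randomness flows from the single
``seed`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import axonmap, cellcount, ephys, inputmap, stats, synth

__all__ = [
    "CohortResult",
    "run_coloc_animal",
    "specificity_penetrance_cohort",
    "specificity_penetrance_study",
    "inputmap_validation",
    "epsc_benchmark",
    "axon_recovery",
]


def run_coloc_animal(seed: int, p_coexpress: float, cells_per_subregion: int,
                     n_sections: int = 2, clutter: float = 0.2
                     ) -> tuple[cellcount.ColocTable, dict]:
    """Full colocalization pipeline for one synthetic animal.

    Renders ``n_sections`` two-channel sections, detects reporter somata,
    classifies marker co-expression, assigns subregions and merges the
    per-section tables into one per-animal table.  Returns the table plus the
    planted truth (true double count and true reporter total).
    """
    layout = cellcount.SubregionLayout.grid_2x2()
    # fixed threshold at the midpoint of the planted background/foreground
    # levels: separates hard-core-packed somata more reliably than a global
    # Otsu cut, whose lower threshold leaves bridges between close neighbors
    policy = cellcount.DetectionPolicy(threshold=0.425)
    n_double: dict[str, int] = {}
    n_only: dict[str, int] = {}
    truth_double = 0
    truth_total = 0
    for s in range(n_sections):
        spec = synth.SectionSpec(p_coexpress=p_coexpress,
                                 cells_per_subregion=cells_per_subregion,
                                 clutter_density=clutter,
                                 seed=seed * 1000 + s)
        section, truth = synth.make_section(spec)
        dets = cellcount.detect_cells(section, "reporter", policy)
        dets = cellcount.classify_coexpression(dets, section, "marker", policy)
        dets = cellcount.assign_subregions(dets, layout, section.um_per_px)
        table = cellcount.tabulate(dets, animal_id=f"a{seed}", marker="marker",
                                   layout=layout)
        for k in table.n_double:
            n_double[k] = n_double.get(k, 0) + table.n_double[k]
            n_only[k] = n_only.get(k, 0) + table.n_reporter_only[k]
        truth_double += int(truth.cells["coexpress"].sum())
        truth_total += len(truth.cells)
    merged = cellcount.ColocTable(animal_id=f"a{seed}", marker="marker",
                                  n_double=n_double, n_reporter_only=n_only)
    return merged, {"true_double": truth_double, "true_total": truth_total}


@dataclass
class CohortResult:
    """One two-genotype synthetic cohort run through the pipeline."""

    est_fraction_a: float       # pooled co-expression fraction, genotype A
    est_fraction_b: float
    n_cells_a: int              # pooled reporter-cell counts behind the fractions
    n_cells_b: int
    planted_p_a: float
    planted_p_b: float
    penetrance_a: cellcount.GroupSummary
    penetrance_b: cellcount.GroupSummary
    true_penetrance_a: float    # mean planted double count per animal
    true_penetrance_b: float
    welch: stats.TestResult


def specificity_penetrance_cohort(seed: int, p_a: float = 0.95, p_b: float = 0.92,
                                  cells_a: int = 42, cells_b: int = 22,
                                  n_animals: int = 5) -> CohortResult:
    """Two genotypes of 5 animals each, compared as in a Cre-line study.

    Defaults plant ~319 vs ~162 double-labeled cells per animal (penetrance)
    at co-expression probabilities 0.95 vs 0.92 (specificity), echoing the
    SERT-Cre vs ePET-Cre comparison scale.
    """
    out = {}
    for label, p, cells in [("a", p_a, cells_a), ("b", p_b, cells_b)]:
        tables, truths = [], []
        for i in range(n_animals):
            t, tr = run_coloc_animal(seed * 100 + (0 if label == "a" else 50) + i,
                                     p, cells)
            tables.append(t)
            truths.append(tr)
        n_pool = sum(t.total() for t in tables)
        est_frac = sum(t.total_double() for t in tables) / n_pool
        out[label] = {
            "tables": tables,
            "fraction": est_frac,
            "n_pool": n_pool,
            "penetrance": cellcount.penetrance(tables, group=label),
            "true_pen": float(np.mean([tr["true_double"] for tr in truths])),
        }
    pa, pb = out["a"]["penetrance"], out["b"]["penetrance"]
    welch = stats.welch_t_from_summaries(pa.mean, pa.sem, pa.n, pb.mean, pb.sem, pb.n,
                                         name="penetrance A vs B")
    return CohortResult(
        est_fraction_a=out["a"]["fraction"], est_fraction_b=out["b"]["fraction"],
        n_cells_a=out["a"]["n_pool"], n_cells_b=out["b"]["n_pool"],
        planted_p_a=p_a, planted_p_b=p_b,
        penetrance_a=pa, penetrance_b=pb,
        true_penetrance_a=out["a"]["true_pen"], true_penetrance_b=out["b"]["true_pen"],
        welch=welch)


def specificity_penetrance_study(seed: int, n_reps: int = 20) -> dict:
    """Replicate the cohort over seeds; summarize recovery and test power.

    Recovery is checked against the planted values: the pooled co-expression
    estimate must fall within the 95% binomial CI of the planted probability,
    and the penetrance group mean within the t-based 95% CI of the planted
    per-animal truth.
    """
    frac_ok_a = frac_ok_b = pen_ok_a = pen_ok_b = n_signif = 0
    reps: list[CohortResult] = []
    for r in range(n_reps):
        res = specificity_penetrance_cohort(seed + r)
        reps.append(res)
        # binomial CI of the planted p at the pooled cell count
        for which, p_true, est, n_pool, pen, true_pen in [
                ("a", res.planted_p_a, res.est_fraction_a, res.n_cells_a,
                 res.penetrance_a, res.true_penetrance_a),
                ("b", res.planted_p_b, res.est_fraction_b, res.n_cells_b,
                 res.penetrance_b, res.true_penetrance_b)]:
            lo, hi = _binom_ci(p_true, max(n_pool, 1))
            ok_f = lo <= est <= hi
            # t-based CI of the estimated group mean must cover the truth
            half = sps.t.ppf(0.975, pen.n - 1) * max(pen.sem, 1e-9)
            ok_p = abs(pen.mean - true_pen) <= max(half, 0.01 * true_pen)
            if which == "a":
                frac_ok_a += ok_f
                pen_ok_a += ok_p
            else:
                frac_ok_b += ok_f
                pen_ok_b += ok_p
        n_signif += res.welch.p < 0.05
    return {
        "n_reps": n_reps,
        "fraction_covered_a": frac_ok_a, "fraction_covered_b": frac_ok_b,
        "penetrance_covered_a": pen_ok_a, "penetrance_covered_b": pen_ok_b,
        "n_significant": n_signif,
        "mean_penetrance_a": float(np.mean([r.penetrance_a.mean for r in reps])),
        "mean_penetrance_b": float(np.mean([r.penetrance_b.mean for r in reps])),
        "mean_fraction_a": float(np.mean([r.est_fraction_a for r in reps])),
        "mean_fraction_b": float(np.mean([r.est_fraction_b for r in reps])),
        "reps": reps,
    }


def _binom_ci(p: float, n: int) -> tuple[float, float]:
    half = 1.96 * math.sqrt(p * (1 - p) / n)
    return p - half, p + half


DEFAULT_PLANTED_COUNTS = [5, 7, 11, 16, 25, 38, 57, 87, 132, 200, 304, 500]


def inputmap_validation(seed: int, planted: list[int] | None = None,
                        threshold: float = 0.425) -> dict:
    """Synthetic 12-region brain through the full input-mapping pipeline.

    Plants counts spanning 5-500 input neurons across regions, segments at a
    fixed threshold midway between background and soma intensity, removes the
    planted artifacts using their true ROIs, aggregates over sections and
    regresses automated pixel counts on the true (manual-equivalent) counts.
    """
    planted = planted or DEFAULT_PLANTED_COUNTS
    regions = [synth.RegionSpec(f"R{i:02d}") for i in range(len(planted))]
    spec = synth.BrainSeriesSpec(
        regions=regions,
        planted_counts={r.name: c for r, c in zip(regions, planted)},
        artifact_rate=0.5, clutter_density=0.2, seed=seed)
    sections, labelmaps, truth = synth.make_brain_series(spec)
    per_section = []
    for sec, lm in zip(sections, labelmaps):
        mask = inputmap.segment_positive(sec, threshold)
        mask = inputmap.remove_artifacts(mask, truth.artifact_rois or [])
        per_section.append(inputmap.assign_to_regions(mask, lm))
    brain = inputmap.aggregate_series(per_section)
    manual = {k: float(v) for k, v in (truth.region_counts or {}).items()}
    pixels = {k: float(brain.counts.get(k, 0)) for k in manual}
    validation = inputmap.validate_against_manual(manual, pixels)
    total_true = sum(manual.values())
    truth_frac = {k: 100.0 * v / total_true for k, v in manual.items()}
    keys = sorted(manual)
    rho = float(sps.spearmanr([truth_frac[k] for k in keys],
                              [(brain.fractions or {}).get(k, 0.0) for k in keys])
                .statistic)
    return {"brain": brain, "validation": validation, "truth": truth,
            "spearman_vs_truth": rho}


def epsc_benchmark(seed: int, n_cells: int = 200) -> dict:
    """Responder classification against planted flags over a cell population."""
    spec = synth.SweepSpec(n_cells=n_cells, p_responder=0.5, amp_pa=(70.0, 10.0),
                           baseline_noise_sd_pa=5.0, trace_dur_s=0.3,
                           stim_onset_s=0.2, seed=seed)
    sweepsets, truth = synth.make_sweeps(spec)
    baseline = [s for s in sweepsets if s.condition == "baseline"]
    results = [ephys.analyze_sweepset(s) for s in baseline]
    flags = {r.cell_id: r.responder for r in results}
    tr = truth.epsc.set_index("cell_id")
    agree = sum(flags[cid] == bool(tr.loc[cid, "responder"]) for cid in flags)
    frac, n_resp, n_tot = ephys.responder_fraction(results)
    resp_results = [r for r in results if r.responder]
    amp_err = (float(np.mean([abs(r.amplitude_pa - tr.loc[r.cell_id, "amp_pa"])
                              for r in resp_results])) if resp_results else 0.0)
    return {"agreement_pct": 100.0 * agree / len(flags),
            "responder_fraction_pct": frac, "n_responders": n_resp, "n_total": n_tot,
            "mean_abs_amp_error_pa": amp_err, "results": results, "truth": truth}


def axon_recovery(seed: int, coverage_target: float = 0.25,
                  threshold: float = 0.25) -> dict:
    """Axon field scored through subtract -> binarize -> coverage."""
    section, truth = synth.make_axon_field(coverage_target,
                                           synth.AxonFieldSpec(seed=seed))
    img = section.channels["axon"]
    shape = img.shape
    roi = axonmap.ROI(name="field", box=(0, 0, shape[0], shape[1]))
    sub = axonmap.subtract_background(img, radius=5)
    mask = axonmap.binarize(sub, threshold)
    res = axonmap.coverage(mask, roi)
    return {"true_coverage_pct": 100.0 * (truth.axon_coverage or 0.0),
            "recovered_coverage_pct": res.coverage_pct, "result": res}
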