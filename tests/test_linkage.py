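"""Map estimation, genotype probabilities, scans, thresholds and reporting."""

import numpy as np
import pandas as pd
import pytest

from ltqtl import linkage as lk
from ltqtl import phenotype as ph
from ltqtl import sim
from ltqtl.mapfun import haldane_cm, haldane_r
from conftest import single_qtl_config


# ---------------------------------------------------------------------------
# recombination fraction


def test_rf_identical_columns_zero(rng):
    g = rng.integers(0, 3, size=300)
    assert lk.estimate_rf(g, g) == pytest.approx(0.0, abs=1e-6)


def test_rf_independent_loci_half(rng):
    a = rng.binomial(2, 0.5, size=2000)
    b = rng.binomial(2, 0.5, size=2000)
    assert lk.estimate_rf(a, b) == pytest.approx(0.5, abs=0.03)


def test_rf_em_matches_grid_search_oracle():
    """EM maximiser agrees with brute-force likelihood over a 0.001 grid."""
    cfg = sim.CrossSimConfig(
        n_individuals=400,
        chromosomes=[sim.ChromSpec("1", (0.0, 25.0), (1, 2_000_000))],
        qtls=[],
        polygenic_sd=0.0,
        seed=17,
    )
    f2 = sim.simulate_f2(cfg)
    a, b = f2.genotypes.codes[:, 0], f2.genotypes.codes[:, 1]
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1.0)
    grid = np.arange(0.0005, 0.5, 0.001)
    ll = [lk.two_locus_loglik(counts, r) for r in grid]
    r_grid = grid[int(np.argmax(ll))]
    assert lk.estimate_rf(a, b) == pytest.approx(r_grid, abs=1e-3)


def test_rf_all_missing_errors():
    g1 = np.array([-1, -1, 0, 1])
    g2 = np.array([0, 1, -1, -1])
    with pytest.raises(ValueError):
        lk.estimate_rf(g1, g2)


# ---------------------------------------------------------------------------
# map building and summary


def test_build_map_zero_and_known_gaps():
    cfg = sim.CrossSimConfig(
        n_individuals=1000,
        chromosomes=[sim.ChromSpec("1", (0.0, 0.0, 20.0), (1, 2, 4_000_000))],
        qtls=[],
        polygenic_sd=0.0,
        seed=23,
    )
    f2 = sim.simulate_f2(cfg)
    info = f2.gmap.markers[["marker_id", "chrom", "bp"]]
    gmap = lk.build_map(f2.genotypes, info)
    cm = gmap.markers["cm"].to_numpy()
    assert cm[1] - cm[0] == pytest.approx(0.0, abs=1e-9)  # co-located markers
    # Haldane back-transform of r ~ 0.165 recovers ~20 cM
    assert cm[2] - cm[1] == pytest.approx(20.0, abs=4.0)


def test_haldane_inverse_exact():
    assert haldane_cm(haldane_r(20.0)) == pytest.approx(20.0, abs=1e-9)
    assert float(haldane_cm(0.165)) == pytest.approx(-50 * np.log(1 - 0.33), abs=1e-9)


def test_build_map_recovers_total_length():
    """Total recovered map length within 10% of the generating map at n=189."""
    cfg = single_qtl_config(seed=31, n=189, length_cm=130.0, spacing_cm=5.0)
    cfg.qtls = []
    f2 = sim.simulate_f2(cfg)
    info = f2.gmap.markers[["marker_id", "chrom", "bp"]]
    built = lk.build_map(f2.genotypes, info)
    total = lk.map_summary(built).total_cm
    assert abs(total - 130.0) / 130.0 < 0.10


def test_map_summary_arithmetic():
    # one chromosome, two markers
    m = lk.GeneticMap(pd.DataFrame(
        {"marker_id": ["a", "b"], "chrom": ["1", "1"], "cm": [0.0, 10.0],
         "bp": [1, 2]}
    ))
    s = lk.map_summary(m)
    assert s.total_cm == 10.0 and s.mean_interval_cm == 5.0
    # three chromosomes 100/200/300 cM, 60 markers
    rows = []
    for c, (length, k) in enumerate([(100.0, 20), (200.0, 20), (300.0, 20)], 1):
        for i in range(k):
            rows.append((f"m{c}_{i}", str(c), length * i / (k - 1), i + 1))
    s = lk.map_summary(lk.GeneticMap(pd.DataFrame(
        rows, columns=["marker_id", "chrom", "cm", "bp"])))
    assert s.total_cm == pytest.approx(600.0)
    assert s.mean_interval_cm == pytest.approx(10.0)
    assert s.markers_per_chrom == {"1": 20, "2": 20, "3": 20}


def test_map_order_validation():
    with pytest.raises(ValueError):
        lk.GeneticMap(pd.DataFrame(
            {"marker_id": ["a", "b"], "chrom": ["1", "1"],
             "cm": [0.0, 10.0], "bp": [5, 2]}  # cM order != bp order
        ))


def test_polymorphism_rate():
    assert lk.polymorphism_rate(509, 1288) == pytest.approx(39.5, abs=0.05)
    with pytest.raises(ValueError):
        lk.polymorphism_rate(10, 0)


# ---------------------------------------------------------------------------
# genotype probabilities


def _mini_geno(codes, cm=(0.0, 20.0)):
    n = len(codes)
    gmap = lk.GeneticMap(pd.DataFrame(
        {"marker_id": [f"m{j}" for j in range(len(cm))],
         "chrom": ["1"] * len(cm), "cm": list(cm),
         "bp": [(j + 1) * 1000 for j in range(len(cm))]}
    ))
    geno = lk.GenotypeMatrix(
        [f"i{i}" for i in range(n)], list(gmap.markers["marker_id"]),
        np.array(codes, dtype=np.int8),
    )
    return geno, gmap


def test_probabilities_at_observed_marker():
    geno, gmap = _mini_geno([[0, 0], [1, 1], [2, 2]])
    cfg = lk.ScanConfig(error_rate=0.0)
    probs = lk.genotype_probabilities(geno, gmap, cfg)
    at0 = np.where(probs.cm == 0.0)[0][0]
    assert np.allclose(probs.probs[0, at0], [1, 0, 0])
    assert np.allclose(probs.probs[1, at0], [0, 1, 0])
    assert np.allclose(probs.probs[2, at0], [0, 0, 1])


def test_probabilities_all_missing_gives_prior():
    geno, gmap = _mini_geno([[-1, -1], [-1, -1]])
    probs = lk.genotype_probabilities(geno, gmap, lk.ScanConfig())
    assert np.allclose(probs.probs, np.array([0.25, 0.5, 0.25]))


def test_probabilities_midpoint_closed_form():
    """Midpoint of AA----AA flanking markers matches the two-locus formula."""
    geno, gmap = _mini_geno([[0, 0]])
    cfg = lk.ScanConfig(error_rate=0.0, step_cm=10.0)
    probs = lk.genotype_probabilities(geno, gmap, cfg)
    mid = np.where(probs.cm == 10.0)[0][0]
    r = haldane_r(10.0)
    trans = lk._transition(r)
    closed = trans[0, :] * trans[:, 0]  # P(AA->s) * P(s->AA)
    closed = closed / closed.sum()
    assert np.allclose(probs.probs[0, mid], closed, atol=1e-12)


def test_probabilities_sum_to_one(qtl_scan):
    p = qtl_scan["probs"].probs
    assert np.allclose(p.sum(axis=2), 1.0, atol=1e-9)
    assert (p >= 0).all()


# ---------------------------------------------------------------------------
# scans


def test_scan_constant_phenotype_zero_lod(qtl_scan):
    probs = qtl_scan["probs"]
    y = pd.Series(5.0, index=probs.individual_ids)
    with pytest.warns(UserWarning, match="constant phenotype"):
        scan = lk.scan_im(probs, y)
    assert np.all(scan.lod == 0.0)


def test_hk_lod_equals_single_marker_regression(qtl_scan):
    """At a fully observed marker the HK LOD is the single-marker LOD."""
    probs = qtl_scan["probs"]
    f2 = qtl_scan["f2"]
    cfg = lk.ScanConfig(error_rate=0.0)
    probs0 = lk.genotype_probabilities(f2.genotypes, f2.gmap, cfg)
    rng = np.random.default_rng(2)
    marker_j = 10
    g = f2.genotypes.codes[:, marker_j].astype(float)
    y = pd.Series(g - 1 + rng.normal(0, 1, len(g)), index=probs.individual_ids)
    scan = lk.scan_im(probs0, y, cfg)
    at = np.where(np.isclose(probs0.cm, f2.gmap.markers["cm"].iloc[marker_j]))[0][0]
    # independent closed form: ordinary regression on (x_a, x_d)
    X = np.column_stack([np.ones(len(g)), g - 1, (g == 1).astype(float)])
    yv = y.to_numpy()
    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    rss1 = np.sum((yv - X @ beta) ** 2)
    rss0 = np.sum((yv - yv.mean()) ** 2)
    lod_closed = (len(g) / 2) * np.log10(rss0 / rss1)
    assert scan.lod[at] == pytest.approx(lod_closed, abs=1e-6)


def test_lod_affine_invariance(qtl_scan):
    probs, y = qtl_scan["probs"], qtl_scan["phenotype"]
    scan1 = lk.scan_im(probs, y)
    scan2 = lk.scan_im(probs, 3.7 * y - 11.0)
    assert np.allclose(scan1.lod, scan2.lod, atol=1e-8)
    assert np.all(scan1.lod >= 0) and np.all(np.isfinite(scan1.lod))


def test_cim_empty_cofactors_reduces_to_im(qtl_scan):
    probs, y, f2 = qtl_scan["probs"], qtl_scan["phenotype"], qtl_scan["f2"]
    im = lk.scan_im(probs, y)
    cim = lk.scan_cim(probs, y, [], f2.genotypes, f2.gmap)
    assert np.allclose(im.lod, cim.lod)
    assert cim.kind == "cim"


def test_cofactor_at_qtl_absorbs_signal(qtl_scan):
    """Conditioning on a marker at the QTL lowers LOD away from it."""
    probs, y, f2 = qtl_scan["probs"], qtl_scan["phenotype"], qtl_scan["f2"]
    im = lk.scan_im(probs, y)
    # cofactor = marker nearest the true QTL at 50 cM
    near = (f2.gmap.markers["cm"] - 50.0).abs().idxmin()
    cof = [f2.gmap.markers.loc[near, "marker_id"]]
    cim = lk.scan_cim(probs, y, cof, f2.genotypes, f2.gmap)
    far = np.abs(probs.cm - 50.0) > 20.0
    assert cim.lod[far].max() < im.lod[far].max()


def test_cim_localises_better_with_two_qtls():
    """CIM peak distance to truth is no worse than IM's, averaged over seeds."""
    a = sim.calibrate_additive_effects({"q1": 0.18, "q2": 0.18})
    cm = tuple(float(x) for x in range(0, 101, 5))
    bp = tuple(int(x * 2e5) + 1 for x in cm)
    err_im, err_cim = [], []
    for seed in range(8):
        cfg = sim.CrossSimConfig(
            n_individuals=189,
            chromosomes=[sim.ChromSpec("1", cm, bp), sim.ChromSpec("2", cm, bp)],
            qtls=[sim.QTLSpec("1", 30.0, a["q1"], 0.0, name="q1"),
                  sim.QTLSpec("2", 70.0, a["q2"], 0.0, name="q2")],
            polygenic_sd=0.0,
            seed=300 + seed,
        )
        f2 = sim.simulate_f2(cfg)
        y = ph.aggregate_families(ph.ltii_table(sim.simulate_family_phenotypes(f2, cfg)))
        scfg = lk.ScanConfig(seed=seed)
        probs = lk.genotype_probabilities(f2.genotypes, f2.gmap, scfg)
        im = lk.scan_im(probs, y, scfg)
        cof = lk.select_cofactors(f2.genotypes, y, scfg)
        cimr = lk.scan_cim(probs, y, cof, f2.genotypes, f2.gmap, scfg)
        for scan, errs in ((im, err_im), (cimr, err_cim)):
            for chrom, truth in (("1", 30.0), ("2", 70.0)):
                on = scan.chrom == chrom
                pk = np.argmax(scan.lod[on])
                errs.append(abs(scan.cm[on][pk] - truth))
    assert np.mean(err_cim) <= np.mean(err_im) + 1.0


def test_select_cofactors_behaviour(qtl_scan, rng):
    f2, y = qtl_scan["f2"], qtl_scan["phenotype"]
    # max cofactors 0 -> empty
    cfg0 = lk.ScanConfig(max_cofactors=0)
    assert lk.select_cofactors(f2.genotypes, y, cfg0) == []
    # strong QTL -> first pick is a marker near the QTL (50 cM, 5 cM spacing)
    picked = lk.select_cofactors(f2.genotypes, y, lk.ScanConfig(max_cofactors=3))
    first_cm = float(
        f2.gmap.markers.set_index("marker_id").loc[picked[0], "cm"]
    )
    assert abs(first_cm - 50.0) <= 10.0
    # null phenotype -> BIC stops early
    spurious = []
    for seed in range(10):
        y_null = pd.Series(
            np.random.default_rng(seed).normal(size=f2.genotypes.n_individuals),
            index=f2.genotypes.individual_ids,
        )
        spurious.append(len(lk.select_cofactors(f2.genotypes, y_null, lk.ScanConfig())))
    assert np.mean(spurious) <= 1.0


# ---------------------------------------------------------------------------
# permutations, intervals, reports


def test_permutation_threshold_edges(qtl_scan):
    probs, y = qtl_scan["probs"], qtl_scan["phenotype"]
    cfg = lk.ScanConfig(n_permutations=50, alpha=1.0, seed=4)
    thr, maxima = lk.permutation_threshold(probs, y, cfg, return_maxima=True)
    assert thr == pytest.approx(maxima.min())
    with pytest.raises(ValueError):
        lk.permutation_threshold(probs, y, lk.ScanConfig(n_permutations=10))


def test_permutation_threshold_below_real_peak(qtl_scan):
    probs, y, scan = qtl_scan["probs"], qtl_scan["phenotype"], qtl_scan["scan"]
    thr = lk.permutation_threshold(probs, y, lk.ScanConfig(n_permutations=100, seed=9))
    assert thr < scan.lod.max()  # planted QTL is genome-wide significant
    assert 1.0 < thr < 5.0  # sane genome-wide threshold magnitude


def _profile_scan(lods, cm=None, chrom="1"):
    lods = np.asarray(lods, float)
    cm = np.asarray(cm if cm is not None else np.arange(len(lods)), float)
    return lk.ScanResult(
        chrom=np.array([chrom] * len(lods), dtype=object),
        cm=cm,
        lod=lods,
        add_effect=np.zeros(len(lods)),
        dom_effect=np.zeros(len(lods)),
        r2=np.zeros(len(lods)),
        n_individuals=100,
    )


def _profile_map(cm, chrom="1"):
    return lk.GeneticMap(pd.DataFrame(
        {"marker_id": [f"mk{i}" for i in range(len(cm))],
         "chrom": [chrom] * len(cm), "cm": list(cm),
         "bp": [(i + 1) * 1000 for i in range(len(cm))]}
    ))


def test_support_interval_constructed_profile():
    """Profile [1,3,5,4,2] with drop 2 keeps positions with LOD >= 3."""
    scan = _profile_scan([1, 3, 5, 4, 2])
    gmap = _profile_map(range(5))
    si = lk.support_interval(scan, gmap, lod_drop=2.0)
    assert (si.left_cm, si.right_cm) == (1.0, 3.0)
    assert (si.left_marker, si.right_marker) == ("mk1", "mk3")
    assert si.contains(2.0)


def test_support_interval_infinite_drop_whole_chromosome():
    scan = _profile_scan([1, 3, 5, 4, 2])
    gmap = _profile_map(range(5))
    si = lk.support_interval(scan, gmap, lod_drop=np.inf)
    assert (si.left_cm, si.right_cm) == (0.0, 4.0)


def test_support_interval_one_sided_at_edge():
    scan = _profile_scan([5, 4, 2, 1, 1])
    gmap = _profile_map(range(5))
    si = lk.support_interval(scan, gmap, lod_drop=2.0)
    assert si.left_cm == 0.0 and si.right_cm == 1.0


def test_lod_to_r2_inversion():
    assert lk.lod_to_r2(3.01, 20) == pytest.approx(50.0, abs=0.1)


def test_report_no_peaks_empty():
    scan = _profile_scan([0.5, 1.0, 0.8])
    gmap = _profile_map(range(3))
    assert lk.report_qtls({"e1": scan}, 3.0, gmap) == []


def test_report_two_peaks_named_in_order():
    lods = [0] * 5 + [4, 5, 4] + [0] * 20 + [6, 7, 6] + [0] * 5
    scan = _profile_scan(lods, chrom="6")
    gmap = _profile_map(np.arange(len(lods)), chrom="6")
    reports = lk.report_qtls({"e1": scan}, 3.0, gmap)
    names = [r.name for r in reports]
    assert names == ["qLTT6.1", "qLTT6.2"]
    assert all(r.interval.contains(r.peak_cm) for r in reports)


def test_report_repeated_detection_flag():
    lods = [0] * 5 + [5, 6, 5] + [0] * 5
    scan1 = _profile_scan(lods)
    scan2 = _profile_scan(lods)
    gmap = _profile_map(np.arange(len(lods)))
    reports = lk.report_qtls({"e1": scan1, "e2": scan2}, 3.0, gmap)
    assert len(reports) == 2
    assert all(r.repeatedly_detected for r in reports)
    assert len({r.name for r in reports}) == 1
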