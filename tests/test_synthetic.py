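"""Ground-truth simulator: sampling structure, determinism, closure."""

import math
from collections import Counter

import numpy as np
import pytest

from tlskit.classification import classify_read, make_aligner, summarize_spectrum
from tlskit.constructs import default_constructs
from tlskit.quantify import fold_change, quantify
from tlskit.synthetic import (
    EXPECTED_CLASSIFICATION,
    TRUTH_CATEGORIES,
    ConditionTruth,
    GroundTruthConfig,
    dump_truth_config,
    load_truth_config,
    simulate_cell_assays,
    simulate_condition,
    simulate_study,
)


def _config(seed=1, **kwargs):
    defaults = dict(
        construct_id="TT_CPD",
        p_repair_lesion=0.4,
        spectrum={"ACCURATE": 0.5, "TARGETED": 0.1, "SEMI_TARGETED": 0.1,
                  "MIXED": 0.1, "DEL1": 0.1, "NON_TLS": 0.1},
        n_clones=30,
        replicates=3,
    )
    defaults.update(kwargs)
    return GroundTruthConfig(conditions={"cond": ConditionTruth(**defaults)}, seed=seed)


def test_zero_repair_probability_gives_zero_colonies():
    cfg = _config(p_repair_lesion=0.0)
    sim = simulate_condition(cfg, "cond")
    assert all(c.kanR == 0 for c in sim.counts)
    assert all(c.cmR > 0 for c in sim.counts)


def test_pure_accurate_spectrum_classifies_accurate(aligner):
    cfg = _config(spectrum={"ACCURATE": 1.0}, n_clones=40)
    sim = simulate_condition(cfg, "cond")
    construct = cfg.construct_for("cond")
    events = [classify_read(r, construct, aligner) for r in sim.reads]
    assert all(e.category.value == "ACCURATE" for e in events)


def test_uniform_spectrum_category_frequencies():
    """Multinomial sampling: each category within 3 SE of 1/6 at n = 10000."""
    p = 1 / 6
    cfg = _config(spectrum={c: p for c in TRUTH_CATEGORIES}, n_clones=10_000,
                  replicates=1)
    sim = simulate_condition(cfg, "cond")
    tallies = Counter(sim.truth["clone_categories"].values())
    se = math.sqrt(p * (1 - p) / 10_000)
    for cat in TRUTH_CATEGORIES:
        assert abs(tallies[cat] / 10_000 - p) < 3 * se, cat


def test_generator_classifier_closure(aligner):
    """Every emitted TLS-category read classifies back to its source category."""
    cfg = _config(n_clones=300, replicates=1, seed=9)
    sim = simulate_condition(cfg, "cond")
    construct = cfg.construct_for("cond")
    seen = set()
    for read in sim.reads:
        truth_cat = sim.truth["clone_categories"][read.clone_id]
        ev = classify_read(read, construct, aligner)
        assert ev.category.value == EXPECTED_CLASSIFICATION[truth_cat], (
            truth_cat, read.clone_id, ev.edit_summary)
        seen.add(truth_cat)
    assert seen == set(TRUTH_CATEGORIES)  # all emission paths exercised


def test_byte_identical_outputs_for_same_seed(tmp_path):
    cfg = _config(seed=12)
    p1 = simulate_study(cfg, tmp_path / "a")
    p2 = simulate_study(cfg, tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_adding_a_condition_leaves_other_streams_untouched():
    base = _config(seed=4)
    sim_before = simulate_condition(base, "cond")
    extended = GroundTruthConfig(
        conditions={"cond": base.conditions["cond"],
                    "other": ConditionTruth("CISPT_GG", 0.2, {"ACCURATE": 1.0})},
        seed=4,
    )
    sim_after = simulate_condition(extended, "cond")
    assert [r.sequence for r in sim_before.reads] == [r.sequence for r in sim_after.reads]
    assert sim_before.counts == sim_after.counts


def test_config_validation():
    with pytest.raises(ValueError, match="sums"):
        _config(spectrum={"ACCURATE": 0.5})
    with pytest.raises(ValueError, match="p_repair_lesion"):
        _config(p_repair_lesion=1.2)
    with pytest.raises(ValueError, match="unknown construct"):
        GroundTruthConfig(
            conditions={"c": ConditionTruth("NOPE", 0.5, {"ACCURATE": 1.0})}, seed=1
        )
    with pytest.raises(ValueError, match="n_effective"):
        GroundTruthConfig(conditions={}, seed=1, n_effective=0)


def test_truth_config_round_trip(tmp_path):
    cfg = _config(seed=33)
    path = tmp_path / "truth.json"
    dump_truth_config(cfg, path)
    loaded = load_truth_config(path)
    assert loaded.seed == cfg.seed
    assert loaded.conditions == cfg.conditions
    assert loaded.constructs == cfg.constructs


# -- end-to-end estimator consistency ------------------------------------


def _run_quantification(cfg, reference=None):
    import pandas as pd

    aligner = make_aligner()
    rows, events = [], []
    for cond in cfg.conditions:
        sim = simulate_condition(cfg, cond)
        construct = cfg.construct_for(cond)
        events.extend(classify_read(r, construct, aligner) for r in sim.reads)
        rows.extend(
            {"condition_id": c.condition_id, "replicate_id": c.replicate_id,
             "kanR": c.kanR, "cmR": c.cmR}
            for c in sim.counts
        )
    return quantify(pd.DataFrame(rows), events, reference_condition=reference)


def test_end_to_end_extent_recovery_within_monte_carlo_error():
    """Estimated TLS extent within 3 MC SE of p_repair x TLS fraction."""
    cfg = _config(seed=21, n_clones=120, replicates=3)
    cfg.n_effective = 500
    truth = cfg.conditions["cond"]
    q = _run_quantification(cfg)["cond"]
    # Poisson noise on summed colony counts plus binomial noise on the TLS fraction
    tot_kan = cfg.n_effective * truth.p_repair_lesion * 3
    tot_cm = cfg.n_effective * truth.p_repair_control * 3
    f = truth.fraction_tls
    rel_se = math.sqrt(1 / tot_kan + 1 / tot_cm + (1 - f) / (f * truth.n_clones))
    assert abs(q.tls_extent - truth.true_tls_extent) <= 3 * rel_se * truth.true_tls_extent


def test_fold_change_recovery_within_ten_percent():
    """True extent ratio 2 recovered within 10% at the stated design size."""
    spectrum = {"ACCURATE": 0.85, "TARGETED": 0.06, "SEMI_TARGETED": 0.02,
                "MIXED": 0.01, "DEL1": 0.01, "NON_TLS": 0.05}
    cfg = GroundTruthConfig(
        conditions={
            "hi": ConditionTruth("TT_CPD", 0.9, spectrum, p_repair_control=0.9,
                                 n_clones=100, replicates=3),
            "lo": ConditionTruth("TT_CPD", 0.45, spectrum, p_repair_control=0.9,
                                 n_clones=100, replicates=3),
        },
        seed=0,
        n_effective=1000,
    )
    quants = _run_quantification(cfg, reference="hi")
    est = fold_change(quants["hi"], quants["lo"])
    assert abs(est - 2.0) / 2.0 < 0.10


# -- cell assays ---------------------------------------------------------


def test_cell_assay_zero_positivity_gives_all_zero():
    foci, _ = simulate_cell_assays(
        {"wt": {6.0: (0.0, 2.0)}}, {}, seed=5, n_cells=50, replicates=2
    )
    assert (foci["focus_count"] == 0).all()


def test_cell_assay_positive_fraction_within_3se():
    foci, _ = simulate_cell_assays(
        {"wt": {6.0: (0.4, 3.0)}}, {}, seed=6, n_cells=1000, replicates=1
    )
    frac = (foci["focus_count"] >= 1).mean()
    se = math.sqrt(0.4 * 0.6 / 1000)
    assert abs(frac - 0.4) < 3 * se


def test_cell_assay_seed_reproducibility():
    a = simulate_cell_assays({"wt": {6.0: (0.4, 3.0)}}, {"wt": {5.0: 0.5}}, seed=8)
    b = simulate_cell_assays({"wt": {6.0: (0.4, 3.0)}}, {"wt": {5.0: 0.5}}, seed=8)
    assert a[0].equals(b[0]) and a[1].equals(b[1])


def test_cell_assay_invalid_parameters():
    with pytest.raises(ValueError):
        simulate_cell_assays({"wt": {6.0: (1.4, 3.0)}}, {}, seed=1)
    with pytest.raises(ValueError):
        simulate_cell_assays({}, {"wt": {5.0: -0.1}}, seed=1)
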