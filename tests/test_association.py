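import numpy as np
import pandas as pd
import pytest

from episplice.association_stats import (
    CorrectionSpec,
    apply_correction,
    bonferroni,
    build_matrix,
    correct_input,
    correct_nucleosome,
    one_tailed_t,
    significance_call,
    run_association_tests,
)
from episplice.profiling import BIN_IDS
from oracle import welch_one_tailed_p


def obs_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["event_id", "event_type", "site_index", "bin", "feature", "cell_line", "value", "missing"],
    )


def synthetic_obs(rng, n_ase=40, n_cne=60, shift=0.0, feature="f", etype="ES"):
    rows = []
    for grp, n, mu in ((etype, n_ase, shift), ("CNE", n_cne, 0.0)):
        for i in range(n):
            for b in BIN_IDS:
                rows.append((f"{grp}{i}", grp, 0, b, feature, "c1", rng.normal(mu, 1), False))
    return obs_frame(rows)


# ---------------------------------------------------------------------------
# the t-test


def test_identical_samples_give_half_with_cne_tie():
    out = one_tailed_t([1, 2, 3], [1, 2, 3])
    assert out.p_raw == 0.5 and out.direction == "higher_in_CNE"
    const = one_tailed_t([2, 2], [2, 2])
    assert const.degenerate and const.p_raw == 0.5


def test_welch_p_matches_closed_form():
    a, b = [5, 6, 7, 8], [1, 2, 3, 4]
    out = one_tailed_t(a, b)
    assert out.direction == "higher_in_ASE"
    assert out.p_raw == pytest.approx(welch_one_tailed_p(a, b), abs=1e-10)
    out2 = one_tailed_t([1.0, 2.0, 2.5], [4.0, 5.5, 6.0, 7.0])
    assert out2.direction == "higher_in_CNE"
    assert out2.p_raw == pytest.approx(welch_one_tailed_p([1.0, 2.0, 2.5], [4.0, 5.5, 6.0, 7.0]), abs=1e-10)


def test_insufficient_observations_raise():
    with pytest.raises(ValueError):
        one_tailed_t([1.0], [1, 2, 3])


def test_null_type_i_error_near_nominal(rng):
    # type-I error of the one-tailed test = rate of a false directional
    # claim against the one-sided null; with the tail picked post hoc the
    # chance of *either* direction reaching alpha is 2*alpha by design
    ase_claims = either = 0
    n_rep = 3000
    for _ in range(n_rep):
        out = one_tailed_t(rng.normal(size=50), rng.normal(size=50))
        if out.p_raw < 0.05:
            either += 1
            ase_claims += out.direction == "higher_in_ASE"
    # binomial noise at 3000 replicates: allow ~3 sd around the target
    assert 0.037 <= ase_claims / n_rep <= 0.063
    assert 0.08 <= either / n_rep <= 0.12


def test_pooling_consistent_cell_lines_sharpens_p(rng):
    a, b = rng.normal(0.5, 1, 50), rng.normal(0, 1, 80)
    single = one_tailed_t(a, b).p_raw
    pooled = one_tailed_t(np.tile(a, 3), np.tile(b, 3)).p_raw
    assert pooled < single


# ---------------------------------------------------------------------------
# adjustment and calls


def test_bonferroni_examples():
    assert bonferroni(0.001, 20) == pytest.approx(0.02)
    assert bonferroni(0.2, 10) == 1.0
    assert bonferroni(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        bonferroni(0.05, 0)


def test_significance_is_strict_below_alpha():
    assert significance_call(0.009)
    assert not significance_call(0.01)
    assert not significance_call(1.0)


# ---------------------------------------------------------------------------
# corrections


def test_input_subtraction_preserves_negatives():
    assert correct_input(10, 3) == 7
    assert correct_input(2, 5) == -3


def test_nucleosome_division_contract():
    assert correct_nucleosome(10, 0, 1) == 10
    assert correct_nucleosome(10, 2, 1e-12) == pytest.approx(5)
    with pytest.raises(ValueError):
        correct_nucleosome(1, 1, 0)


def test_zero_input_correction_is_identity(rng):
    obs = synthetic_obs(rng, shift=0.8)
    ref = obs.copy()
    ref["value"] = 0.0
    corrected = apply_correction(obs, ref, CorrectionSpec("input_subtract"))
    r0 = run_association_tests(obs)
    r1 = run_association_tests(corrected)
    assert np.allclose(r0["p_raw"], r1["p_raw"], atol=1e-12)


def test_constant_nucleosome_division_leaves_p_invariant(rng):
    obs = synthetic_obs(rng, shift=0.8)
    ref = obs.copy()
    ref["value"] = 7.0
    corrected = apply_correction(obs, ref, CorrectionSpec("nucleosome_divide", pseudocount=1.0))
    r0 = run_association_tests(obs)
    r1 = run_association_tests(corrected)
    # t is scale invariant: dividing every observation by a constant
    assert np.allclose(r0["p_raw"], r1["p_raw"], atol=1e-10)
    assert (r0["direction"] == r1["direction"]).all()


def test_shared_single_line_reference_broadcasts(rng):
    obs = synthetic_obs(rng)
    obs2 = obs.copy()
    obs2["cell_line"] = "c2"
    both = pd.concat([obs, obs2], ignore_index=True)
    ref = obs.copy()
    ref["value"] = 1.0
    out = apply_correction(both, ref, CorrectionSpec("input_subtract"))
    assert np.allclose(out["value"], both["value"] - 1.0)


# ---------------------------------------------------------------------------
# matrix assembly


def results_row(feature, etype, b, direction, p):
    return {
        "feature": feature, "event_type": etype, "bin": b, "n_ase": 10, "n_cne": 10,
        "mean_ase": 1.0, "mean_cne": 0.0, "direction": direction, "p_raw": p,
        "bonferroni_m": 1, "p_adj": p, "significant": p < 1e-2,
    }


def test_signed_log_p_signs():
    res = pd.DataFrame([
        results_row("f", "ES", "acceptor_exonic", "higher_in_ASE", 0.001),
        results_row("f", "ME", "acceptor_exonic", "higher_in_CNE", 0.001),
        results_row("f", "IR", "donor_intronic", "higher_in_ASE", 1.0),
    ])
    mat = build_matrix(res)
    assert mat.loc["f", ("ES", "acceptor_exonic")] == pytest.approx(3.0)
    assert mat.loc["f", ("ME", "acceptor_exonic")] == pytest.approx(-3.0)
    assert mat.loc["f", ("IR", "donor_intronic")] == 0.0
    assert mat.shape == (1, 20)
    assert np.isnan(mat.loc["f", ("A3SS", "acceptor_exonic")])


def test_duplicate_matrix_cells_rejected():
    res = pd.DataFrame([
        results_row("f", "ES", "acceptor_exonic", "higher_in_ASE", 0.1),
        results_row("f", "ES", "acceptor_exonic", "higher_in_CNE", 0.2),
    ])
    with pytest.raises(ValueError):
        build_matrix(res)


def test_matrix_sign_matches_direction_everywhere(rng):
    obs = pd.concat(
        [synthetic_obs(rng, shift=s, etype=t) for t, s in
         [("ES", 0.5), ("ME", -0.5), ("A3SS", 1.0), ("A5SS", 0.0), ("IR", -1.0)]],
        ignore_index=True,
    )
    res = run_association_tests(obs)
    mat = build_matrix(res)
    for _, r in res.iterrows():
        v = mat.loc[r["feature"], (r["event_type"], r["bin"])]
        if r["direction"] == "higher_in_ASE":
            assert v >= 0
        else:
            assert v <= 0


def test_no_cne_reference_raises(rng):
    obs = synthetic_obs(rng)
    with pytest.raises(ValueError):
        run_association_tests(obs[obs["event_type"] != "CNE"])
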