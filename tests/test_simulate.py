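"""Hierarchical sampling, selection handling, replayed truths, dataset I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from juncture.model_spec import canonical_cbt_model
from juncture.simulate import (
    DatasetIOError,
    PopulationConfig,
    ReplayContractError,
    SimulationNumericError,
    draw_population,
    read_dataset,
    replay,
    true_sample_effects,
    write_dataset,
)


def _zero_coefficient_model(**hierarchy):
    base = canonical_cbt_model()
    overrides = {
        "equations": {
            child: {"coefficients": {p: 0.0 for p in eq.parents}}
            for child, eq in base.equations.items()
            if eq.parents and eq.link != "deterministic-sum"
        }
    }
    if hierarchy:
        overrides["hierarchy"] = hierarchy
    return canonical_cbt_model(overrides)


# ---------------------------------------------------------------------------
# the draw


def test_patient_table_has_six_thousand_rows(canonical_draw):
    assert len(canonical_draw.patients) == 6000
    assert len(canonical_draw.practitioners) == 200
    assert len(canonical_draw.organizations) == 40


def test_same_seed_reproduces_different_seed_differs(small_model):
    a = draw_population(small_model, PopulationConfig.from_model(small_model, seed=5))
    b = draw_population(small_model, PopulationConfig.from_model(small_model, seed=5))
    c = draw_population(small_model, PopulationConfig.from_model(small_model, seed=6))
    for name in ("organizations", "practitioners", "patients"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
    assert not a.organizations.equals(c.organizations)


def test_symmetric_thresholds_give_half_probability():
    """All-zero indices: every decision node is a fair coin."""
    m = _zero_coefficient_model(
        organizations=100, practitioners_per_organization=5, patients_per_practitioner=10
    )
    ds = draw_population(m, PopulationConfig.from_model(m, seed=3))
    for node, n in (("D1", 100), ("D2", 100), ("T1", 5000)):
        mean = ds.values[node].mean()
        assert abs(mean - 0.5) < 3 * np.sqrt(0.25 / n), node


def test_selection_masks_downstream_variables(canonical_draw):
    org = canonical_draw.organizations
    non_impl = org[org["D1"] == 0]["organization_id"]
    assert len(non_impl) > 0
    assert org.loc[org["D1"] == 0, "D2"].isna().all()
    pract = canonical_draw.practitioners
    pat = canonical_draw.patients
    assert pract.loc[pract["organization_id"].isin(non_impl), ["X4", "X5"]].isna().all().all()
    assert pat.loc[pat["organization_id"].isin(non_impl), ["T1", "Y2"]].isna().all().all()
    # conservation and consistency across tables
    impl = org[org["D1"] == 1]["organization_id"]
    assert len(impl) + len(non_impl) == 40
    assert pat["T1"].notna().sum() == pat["organization_id"].isin(impl).sum()
    # baseline variables exist everywhere
    assert pat[["V1", "V2", "V3", "Y1"]].notna().all().all()


def test_variables_respect_their_kind(canonical_draw):
    pat = canonical_draw.patients.dropna()
    assert set(pat["T1"].unique()) <= {0.0, 1.0}
    assert set(pat["V2"].unique()) <= {0.0, 1.0}
    assert np.isfinite(pat["Y2"]).all()
    org = canonical_draw.organizations
    np.testing.assert_allclose(org["W"], org["W1"] + org["W2"])


def test_correlated_errors_hit_configured_correlation():
    """Z2 (organization) and X2 (practitioner) empirical correlation is
    within +/-0.05 of the configured 0.5 at 6000 practitioners."""
    m = canonical_cbt_model(
        {"hierarchy": {"organizations": 1200, "patients_per_practitioner": 1}}
    )
    ds = draw_population(m, PopulationConfig.from_model(m, seed=9))
    z2 = ds.broadcast("organization", "practitioner", ds.values["Z2"])
    x2 = ds.values["X2"]
    assert len(x2) == 6000
    assert abs(np.corrcoef(z2, x2)[0, 1] - 0.5) < 0.05


def test_nonfinite_coefficient_names_equation():
    m = canonical_cbt_model({"equations": {"Y2": {"coefficients": {"T1": np.inf}}}})
    with pytest.raises(SimulationNumericError, match="Y2"):
        draw_population(m, PopulationConfig.from_model(m, seed=0))


def test_raising_strategy_intercept_raises_enhanced_fraction():
    fractions = []
    for intercept in (-1.0, 0.0, 1.0):
        m = canonical_cbt_model({"equations": {"D2": {"intercept": intercept}}})
        ds = draw_population(m, PopulationConfig.from_model(m, seed=17))
        d2 = ds.organizations["D2"].dropna()
        fractions.append(d2.mean())
    assert fractions[0] < fractions[1] < fractions[2]


# ---------------------------------------------------------------------------
# sample truths by replay


def test_linear_effects_equal_coefficients_exactly(canonical_model, canonical_draw):
    truths = true_sample_effects(canonical_model, canonical_draw)
    assert truths["D2->X4"] == pytest.approx(0.5, abs=1e-12)
    assert truths["D2->X5"] == pytest.approx(0.5, abs=1e-12)
    assert truths["T1->Y2"] == pytest.approx(1.0, abs=1e-12)


def test_zero_coefficients_give_zero_true_effects():
    m = _zero_coefficient_model()
    ds = draw_population(m, PopulationConfig.from_model(m, seed=4))
    truths = true_sample_effects(m, ds)
    for key, value in truths.as_dict().items():
        assert value == pytest.approx(0.0, abs=1e-12), key


def test_ame_matches_finite_difference_of_replayed_probabilities(
    canonical_model, canonical_draw
):
    """Truth AME (density-times-coefficient form) equals a brute-force
    finite difference of assignment probabilities at delta = 1e-6."""
    m, ds = canonical_model, canonical_draw
    truths = true_sample_effects(m, ds)
    eq = m.equations["T1"]
    eligible = ds.broadcast("organization", "patient", ds.values["D1"]) == 1
    delta = 1e-6
    idx = np.zeros(ds.hierarchy.n_patients)
    idx_hi = np.zeros(ds.hierarchy.n_patients)
    for parent, coef in zip(eq.parents, eq.coefficients):
        vals = ds.broadcast(m.level_of(parent), "patient", ds.values[parent])
        idx += coef * vals
        idx_hi += coef * (vals + delta if parent == "X4" else vals)
    fd = np.mean((norm.cdf(idx_hi[eligible]) - norm.cdf(idx[eligible])) / delta)
    assert truths["X4->T1"] == pytest.approx(fd, abs=1e-6)


def test_replay_interventions_propagate(canonical_model, canonical_draw):
    forced = replay(canonical_model, canonical_draw, {"T1": 1.0})
    assert np.all(forced["T1"] == 1.0)
    diff = forced["Y2"] - canonical_draw.values["Y2"]
    untreated = canonical_draw.values["T1"] == 0
    np.testing.assert_allclose(diff[untreated], 1.0)
    np.testing.assert_allclose(diff[~untreated], 0.0)


def test_replay_requires_retained_errors(canonical_model, canonical_draw):
    stripped = canonical_draw.__class__(
        organizations=canonical_draw.organizations,
        practitioners=canonical_draw.practitioners,
        patients=canonical_draw.patients,
        values=canonical_draw.values,
        errors=None,
        pract_org=canonical_draw.pract_org,
        pat_pract=canonical_draw.pat_pract,
        hierarchy=canonical_draw.hierarchy,
    )
    with pytest.raises(ReplayContractError):
        replay(canonical_model, stripped, {"T1": 1.0})


# ---------------------------------------------------------------------------
# dataset bundle I/O


def test_bundle_round_trip(tmp_path, small_model):
    ds = draw_population(small_model, PopulationConfig.from_model(small_model, seed=8))
    out = tmp_path / "bundle"
    write_dataset(ds, out)
    back = read_dataset(out, model=small_model)
    for name in ("organizations", "practitioners", "patients"):
        pd.testing.assert_frame_equal(
            getattr(ds, name), getattr(back, name), check_exact=False, rtol=1e-12
        )
    # errors restored -> replayed truths agree with the original draw
    t0 = true_sample_effects(small_model, ds)
    t1 = true_sample_effects(small_model, back)
    for key in t0.as_dict():
        assert t0[key] == pytest.approx(t1[key], rel=1e-9)


def test_bundle_rejects_unknown_practitioner_reference(tmp_path, small_model):
    ds = draw_population(small_model, PopulationConfig.from_model(small_model, seed=8))
    out = tmp_path / "bundle"
    write_dataset(ds, out)
    patients = pd.read_csv(out / "patients.csv")
    patients.loc[0, "practitioner_id"] = 9999
    patients.to_csv(out / "patients.csv", index=False)
    with pytest.raises(DatasetIOError, match="unknown practitioner"):
        read_dataset(out)


def test_bundle_rejects_manifest_table_mismatch(tmp_path, small_model):
    ds = draw_population(small_model, PopulationConfig.from_model(small_model, seed=8))
    out = tmp_path / "bundle"
    write_dataset(ds, out)
    (out / "practitioners.csv").unlink()
    with pytest.raises(DatasetIOError, match="missing file"):
        read_dataset(out)


def test_degenerate_no_implementing_organizations(tmp_path):
    m = canonical_cbt_model(
        {
            "equations": {"D1": {"intercept": -50.0}},
            "hierarchy": {
                "organizations": 4,
                "practitioners_per_organization": 2,
                "patients_per_practitioner": 3,
            },
        }
    )
    ds = draw_population(m, PopulationConfig.from_model(m, seed=2))
    assert ds.organizations["D1"].sum() == 0
    assert ds.patients["Y2"].isna().all()
    out = tmp_path / "bundle"
    write_dataset(ds, out)
    back = read_dataset(out, model=m)
    assert back.patients["Y2"].isna().all()
    truths = true_sample_effects(m, ds)
    assert all(np.isnan(v) for v in truths.as_dict().values())
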