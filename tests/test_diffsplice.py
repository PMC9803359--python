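"""Per-event PSI linear models, BH correction and effect-size summaries."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicegrammar.as_events import find_events, orient_pair
from splicegrammar.diffsplice import (
    bh_fdr,
    call_significant,
    effect_size_by_category,
    fit_event_model,
    fit_events,
    label_lost_gained,
)
from splicegrammar.genome_annotation_io import TranscriptModel
from splicegrammar.synthetic_data import PsiSimSpec, simulate_psi


def small_design(genotypes, temperatures):
    rows = [
        (f"s{i}", g, t, 1)
        for i, (g, t) in enumerate(zip(genotypes, temperatures))
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "genotype", "temperature", "replicate"]
    ).set_index("sample_id")


def test_genotype_coefficient_closed_form():
    design = small_design(["wt", "wt", "mutant", "mutant"], [20] * 4)
    psi = pd.Series([0.2, 0.3, 0.7, 0.8], index=design.index)
    res = fit_event_model(psi, design, min_obs=2)
    assert res.coefficients["genotype"] == pytest.approx(0.5)
    assert res.delta_psi["pooled"] == pytest.approx(0.5)
    assert np.isnan(res.p_values["temperature"])  # single temperature level
    assert np.isnan(res.p_values["interaction"])


def test_constant_psi_is_degenerate():
    design = small_design(["wt"] * 3 + ["mutant"] * 3, [20, 20, 20, 20, 20, 20])
    psi = pd.Series([0.5] * 6, index=design.index)
    res = fit_event_model(psi, design, min_obs=3)
    assert res.degenerate
    assert not res.p_values
    assert res.delta_psi["pooled"] == pytest.approx(0.0)


def test_min_obs_filter_and_complete_case():
    design = small_design(["wt"] * 4 + ["mutant"] * 4, [20] * 8)
    psi = pd.Series([0.2, 0.25, np.nan, np.nan, 0.7, 0.72, np.nan, np.nan], index=design.index)
    res = fit_event_model(psi, design, min_obs=3)
    assert res.filtered  # only 2 per genotype observed
    res2 = fit_event_model(psi, design, min_obs=2)
    assert not res2.filtered
    # complete-case equivalence: fit on the observed subset gives identical p
    sub = design.iloc[[0, 1, 4, 5]]
    res3 = fit_event_model(psi.iloc[[0, 1, 4, 5]], sub, min_obs=2)
    assert res2.p_values["genotype"] == pytest.approx(res3.p_values["genotype"])
    assert res2.n_obs == res3.n_obs == 4


def test_rank_deficient_design_flagged():
    # mutants observed at one temperature only: interaction non-estimable
    design = small_design(
        ["wt"] * 4 + ["mutant"] * 4, [4, 4, 28, 28, 4, 4, 4, 4]
    )
    psi = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8], index=design.index)
    res = fit_event_model(psi, design, min_obs=2)
    assert res.degenerate
    assert not res.p_values


def test_null_pvalues_uniform():
    sim = simulate_psi(PsiSimSpec(n_events=1000, frac_genotype=0.0, sigma=0.05, seed=11))
    results = fit_events(sim.psi, sim.design)
    p = results["p_genotype"].dropna()
    ks = stats.kstest(p, "uniform").statistic
    assert ks < 0.05


def test_bh_fdr_oracle_values():
    assert bh_fdr([0.01]) == pytest.approx([0.01])
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    q = bh_fdr([0.5, np.nan, 0.01])
    assert np.isnan(q[1])
    assert q[2] == pytest.approx(0.02)
    p = np.array([0.001, 0.2, 0.9, 0.04])
    assert np.nanmin(bh_fdr(p)) >= p.min()
    with pytest.raises(ValueError):
        bh_fdr([1.5])


def test_bh_monotone_in_rank(rng):
    p = rng.uniform(size=200)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_call_significant_flags_and_partition():
    df = pd.DataFrame(
        {
            "q_genotype": [0.04, 0.06, 0.01, 0.2],
            "q_temperature": [0.2, 0.2, 0.01, 0.01],
            "q_interaction": [0.2, 0.2, 0.2, 0.01],
        },
        index=["a", "b", "c", "d"],
    )
    out = call_significant(df, alpha=0.05)
    assert list(out["sig_genotype"]) == [True, False, True, False]
    assert list(out["sig_class"]) == ["genotype", "none", "genotype+temperature", "interaction"]
    with pytest.raises(ValueError):
        call_significant(df, alpha=1.5)


def test_lost_gained_labels_follow_delta_sign():
    txs = [
        TranscriptModel("T1", "G", "c", "+", ((0, 100), (200, 300))),
        TranscriptModel("T2", "G", "c", "+", ((0, 126), (200, 300))),
    ]
    (ev,) = find_events(txs)
    pair = orient_pair(ev)
    # inclusion = shorter intron = downstream donor at 126
    assert not pair.upstream_is_inclusion
    lost, gained, shift = label_lost_gained(pair, delta_psi_inclusion=-0.3)
    assert lost is pair.downstream_window and gained is pair.upstream_window
    assert shift == -26  # usage moved upstream
    lost2, gained2, shift2 = label_lost_gained(pair, delta_psi_inclusion=+0.3)
    assert lost2 is pair.upstream_window
    assert shift2 == 26
    assert label_lost_gained(pair, np.nan) is None


def test_interaction_recovered_from_planted_profile():
    """A genotype effect that grows at high temperature (the canonical
    cryptic-donor pattern) yields a significant interaction term."""
    spec = PsiSimSpec(
        n_events=60,
        frac_genotype=1.0,
        delta_psi=0.15,
        frac_interaction=1.0,
        interaction_profile={4: 0.0, 12: 0.0, 20: 0.0, 28: 0.2},
        sigma=0.05,
        seed=7,
    )
    sim = simulate_psi(spec)
    results = fit_events(sim.psi, sim.design)
    assert (results["q_interaction"] < 0.05).mean() >= 0.9


def test_planted_genotype_effect_recovery():
    sim = simulate_psi(
        PsiSimSpec(n_events=400, frac_genotype=0.25, delta_psi=0.2, sigma=0.05, seed=5)
    )
    results = fit_events(sim.psi, sim.design)
    truth = sim.truth.set_index("event_id")
    sig = results["sig_genotype"]
    effects = truth["has_genotype_effect"]
    sensitivity = (sig & effects).sum() / effects.sum()
    fdr = (sig & ~effects).sum() / max(int(sig.sum()), 1)
    bias = (results["coef_genotype"] - truth["genotype_delta"])[effects].mean()
    assert sensitivity >= 0.8
    assert fdr <= 0.10
    assert abs(bias) <= 0.01


def test_effect_size_by_category_ordering():
    cats = ["A->U"] * 10 + ["same"] * 10
    sizes = [0.4 + 0.01 * i for i in range(10)] + [0.1 + 0.01 * i for i in range(10)]
    out = effect_size_by_category(cats, sizes)
    assert out.loc["A->U", "median"] > out.loc["same", "median"]
    assert out.loc["A->U", "n"] == 10
    single = effect_size_by_category(["A->U"], [0.5])
    assert single.loc["A->U", "n"] == 1
    # ordering stable under permutation of the input rows
    perm = np.random.default_rng(0).permutation(20)
    out2 = effect_size_by_category([cats[i] for i in perm], [sizes[i] for i in perm])
    pd.testing.assert_frame_equal(out, out2)
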