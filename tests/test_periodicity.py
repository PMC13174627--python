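import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import studentized_range

from ntprobe import periodicity as per
from ntprobe import synthetic as syn


def periodic_trace(period, n, amplitude=0.4, noise_sd=0.0, seed=0, base=2.0):
    """Probability trace oscillating with a given period, on the logit scale."""
    from scipy.special import expit

    shape = syn.phase_shape(period)
    j = np.arange(n)
    lg = base + amplitude * shape[j % period]
    if noise_sd > 0:
        lg = lg + np.random.default_rng(seed).normal(0, noise_sd, n)
    return expit(lg)


# ---------------------------------------------------------------------------
# trimming and detrending


def test_trim_tails_default_reproduces_published_scale():
    assert per.default_trim(24_576) == 4_800
    central = per.trim_tails(np.zeros(24_576))
    assert central.size == 14_976
    x = np.arange(10.0)
    assert np.array_equal(per.trim_tails(x, 0), x)
    assert np.array_equal(per.trim_tails(x, 2), x[2:8])
    with pytest.raises(ValueError):
        per.trim_tails(x, 5)


def test_detrend_constant_ramp_and_periodic():
    assert np.allclose(per.detrend(np.full(500, 0.7), 101), 0.0)
    ramp = np.linspace(0, 1, 500)
    resid = per.detrend(ramp, 101)
    assert np.max(np.abs(resid[100:400])) < 1e-12  # interior trend removed
    # boxcar leakage at period 24 / window 101 is sin(101*pi/24)/(101*sin(pi/24)) ~ 4.6%
    sig = 0.1 * np.sin(2 * np.pi * np.arange(2_400) / 24)
    resid = per.detrend(sig, 101)
    leak = abs(np.sin(np.pi * 101 / 24) / (101 * np.sin(np.pi / 24)))
    assert np.max(np.abs(resid[200:-200] - sig[200:-200])) < 1.05 * leak * 0.1
    with pytest.raises(ValueError):
        per.detrend(sig, 100)  # even window
    with pytest.raises(ValueError):
        per.detrend(np.zeros(50), 101)  # window >= length


# ---------------------------------------------------------------------------
# period estimation


def test_estimate_period_white_noise_flagged():
    x = np.random.default_rng(0).normal(size=14_976)
    est = per.estimate_period(x)
    assert est.period == 1 and not est.oscillating
    assert max(est.explained_variance.values()) < 0.2


def test_estimate_period_zero_variance_flagged():
    est = per.estimate_period(np.full(400, 0.5))
    assert est.period == 1 and not est.oscillating


def test_estimate_period_smallest_m_rule_for_pure_period_12():
    """EV is identical at 12, 24, 36, 48; the smallest-m rule picks 12."""
    trace = periodic_trace(12, 4_800)
    est = per.estimate_period(per.detrend(trace, 101))
    assert est.period == 12
    ev = est.explained_variance
    assert ev[12] == pytest.approx(ev[24], abs=1e-6)
    assert ev[12] == pytest.approx(ev[48], abs=1e-6)
    assert ev[6] < 0.99 * ev[12]


def test_estimate_period_default_preset_trace():
    params = syn.default_params(noise_sd=0.05, seed=1)
    trace = syn.simulate_central_trace(params, "exon", 1, n=14_976, seed=1)
    est = per.estimate_period(per.detrend(trace, 101))
    assert est.period == 24 and est.oscillating


def test_ev_analytic_value_on_known_signal():
    """EV(m) computed independently from group means on a tiny trace."""
    x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 1.0, 2.0])
    ev3 = per.explained_variance(x, 3)
    # brute force
    idx = np.arange(8) % 3
    means = np.array([x[idx == r].mean() for r in range(3)])
    ss_w = ((x - means[idx]) ** 2).sum()
    ss_t = ((x - x.mean()) ** 2).sum()
    assert ev3 == pytest.approx(1 - ss_w / ss_t, abs=1e-15)


@given(st.integers(0, 2**31 - 1))
def test_ev_monotone_along_divisor_chains(seed):
    """Finer residue classes never explain less variance: EV(km) >= EV(m)."""
    x = np.random.default_rng(seed).normal(size=480)
    for m, km in [(1, 6), (6, 24), (6, 12), (12, 48), (24, 48), (8, 40)]:
        assert per.explained_variance(x, km) >= per.explained_variance(x, m) - 1e-12


def test_estimate_period_requires_enough_data():
    with pytest.raises(ValueError, match="4 \\* m_max"):
        per.estimate_period(np.zeros(100), m_max=48)


# ---------------------------------------------------------------------------
# phase decomposition


def test_decimate_phases_shapes():
    x = np.arange(12.0)
    d = per.decimate_phases(x, 6)
    assert d.modulus == 6 and all(len(s) == 2 for s in d.subseries)
    assert np.array_equal(d.subseries[1], [1.0, 7.0])
    single = per.decimate_phases(x, 1)
    assert np.array_equal(single.subseries[0], x)


@given(st.integers(1, 10), st.integers(10, 60))
def test_decimate_interleave_identity(m, n):
    x = np.random.default_rng(n).normal(size=n)
    assert np.array_equal(per.interleave_phases(per.decimate_phases(x, m)), x)


def test_mod6_subseries_of_period24_trace_has_period_4():
    """Decimating a 24-periodic trace by 6 leaves a residual four-step cycle."""
    trace = periodic_trace(24, 4_800)
    d = per.decimate_phases(per.detrend(trace, 101), 6)
    for sub in d.subseries:
        est = per.estimate_period(sub, m_max=8)
        assert est.period == 4  # 4 subseries steps = 4 tokens = 24 nt


# ---------------------------------------------------------------------------
# amplitude


def test_estimate_amplitude_basics():
    const = np.full(100, 0.25)
    rep = per.estimate_amplitude(const, 24)
    assert rep.amp_range == 0.0 and rep.minimum == rep.maximum == 0.25
    with pytest.raises(ValueError):
        per.estimate_amplitude(const, 100)


def test_amplitude_phase_means_reproduce_injected_offsets():
    """Per-phase means equal the injected offsets mapped through inverse-logit."""
    from scipy.special import expit, logit

    params = syn.apoe850_mimic(noise_sd=0.0)
    trace = syn.simulate_central_trace(params, "exon", 1, n=2_400)
    rep = per.estimate_amplitude(trace, 24)
    expected = expit(logit(params.exon.p_high) + np.asarray(params.exon.phase_offsets))
    assert np.allclose(rep.phase_means, expected, atol=1e-12)
    assert (round(rep.minimum, 3), round(rep.maximum, 3)) == (0.938, 0.978)


# ---------------------------------------------------------------------------
# phase ANOVA + Tukey


def test_phase_anova_degenerate_constant_groups():
    rep = per.phase_anova(np.full(96, 0.5), period=24)
    assert rep.degenerate and rep.f_stat == 0.0 and rep.p_value == 1.0
    assert not rep.table["reject"].any()
    assert len(rep.table) == 276  # 24 choose 2


def test_phase_anova_pair_table_structure_and_symmetry():
    trace = periodic_trace(24, 2_400, noise_sd=0.05, seed=3)
    rep = per.phase_anova(trace, period=24)
    assert rep.n_groups == 24 and len(rep.table) == 24 * 23 // 2
    pairs = set(zip(rep.table["group_i"], rep.table["group_j"]))
    assert len(pairs) == 276 and all(i < j for i, j in pairs)
    assert rep.f_stat > 0


def test_tukey_detects_shifted_groups_and_matches_studentized_range():
    """Two groups shifted far apart are rejected; the adjusted p of a pair
    matches an independent studentized-range computation."""
    rng = np.random.default_rng(0)
    period, reps, sigma = 6, 40, 0.01
    x = rng.normal(0.5, sigma, period * reps)
    idx = np.arange(period * reps) % period
    x[idx == 2] += 10 * sigma  # shift one group by 10 sigma
    rep = per.phase_anova(x, period=period)
    involving_2 = rep.table[(rep.table.group_i == 2) | (rep.table.group_j == 2)]
    others = rep.table[(rep.table.group_i != 2) & (rep.table.group_j != 2)]
    assert involving_2["reject"].all()
    assert not others["reject"].any()
    # independent oracle for one pair: q = |diff| / sqrt(MSE / n_per_group)
    groups = [x[idx == r] for r in range(period)]
    mse = np.mean([g.var(ddof=1) for g in groups])
    df = x.size - period
    row = rep.table[(rep.table.group_i == 0) & (rep.table.group_j == 2)].iloc[0]
    q = abs(row["diff"]) / np.sqrt(mse / reps)
    p_oracle = studentized_range.sf(q, period, df)
    assert row["p_adj"] == pytest.approx(p_oracle, rel=1e-4, abs=1e-12)


def test_phase_anova_needs_two_per_group():
    with pytest.raises(ValueError, match="2 observations"):
        per.phase_anova(np.arange(30.0), period=24)


# ---------------------------------------------------------------------------
# rolling average and stabilization


def test_rolling_average_values():
    out = per.rolling_average(np.full(10, 3.0), 6)
    assert np.isnan(out[:5]).all() and np.allclose(out[5:], 3.0)
    out = per.rolling_average(np.array([0, 0, 0, 0, 0, 6.0]), 6)
    assert out[5] == 1.0
    with pytest.raises(ValueError):
        per.rolling_average(np.zeros(3), 6)


@given(st.integers(0, 2**31 - 1), st.integers(1, 8))
def test_rolling_average_matches_loop_oracle(seed, window):
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=40)
    out = per.rolling_average(x, window)
    for i in range(window - 1, 40):
        assert out[i] == pytest.approx(np.mean(x[i - window + 1 : i + 1]), abs=1e-12)
    assert np.isnan(out[: window - 1]).all()


def test_stabilization_constant_trace_and_never_reached():
    rep = per.stabilization_distances(np.full(100, 0.99))
    for e in rep.entries:
        assert (e.distance_from_start, e.distance_from_end) == (6, 6)
        assert e.reached_start and e.reached_end
    rep = per.stabilization_distances(np.full(100, 0.5))
    for e in rep.entries:
        assert not e.reached_start and e.distance_from_start is None


def test_stabilization_asymmetric_edges():
    """Slower leading-edge decay delays the start-side crossing."""
    params = syn.default_params(noise_sd=0.0)  # lambda_start=400 > lambda_end=150
    flat = syn.EmulatorParams(
        exon=syn.ChannelParams(0.97, 0.02, 0.30, (0.0,) * 24),
        intron=params.intron,
        lambda_start=400.0, lambda_end=150.0, noise_sd=0.0, w_sat=params.w_sat,
    )
    # constant-label noise-free trace equals one window's value vector
    trace = syn.emulate_window(np.ones(3_072, dtype=int), 0, flat).channels["exon"]
    rep = per.stabilization_distances(trace, thresholds=(0.90, 0.95))
    for e in rep.entries:
        assert e.reached_start and e.reached_end
        assert e.distance_from_start > e.distance_from_end
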