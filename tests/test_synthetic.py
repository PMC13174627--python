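import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

from ntprobe import genome_io as gio
from ntprobe import synthetic as syn


def zero_phase_params(**kw):
    """Default preset with the oscillation switched off."""
    p = syn.default_params(**kw)
    flat = syn.ChannelParams(
        p_high=p.exon.p_high, p_low=p.exon.p_low, mu0=p.exon.mu0,
        phase_offsets=(0.0,) * p.period,
    )
    flat_i = syn.ChannelParams(
        p_high=p.intron.p_high, p_low=p.intron.p_low, mu0=p.intron.mu0,
        phase_offsets=(0.0,) * p.period,
    )
    return syn.EmulatorParams(
        exon=flat, intron=flat_i, lambda_start=p.lambda_start,
        lambda_end=p.lambda_end, period=p.period, noise_sd=kw.get("noise_sd", 0.0),
        w_sat=p.w_sat, seed=p.seed,
    )


# ---------------------------------------------------------------------------
# parameter validation


def test_channel_params_ordering_enforced():
    with pytest.raises(ValueError):
        syn.ChannelParams(p_high=0.2, p_low=0.3, mu0=0.25, phase_offsets=(0.0,) * 24)
    with pytest.raises(ValueError):
        syn.EmulatorParams(
            exon=syn.ChannelParams(0.9, 0.1, 0.5, (0.0,) * 12),  # wrong offset length
            intron=syn.ChannelParams(0.9, 0.1, 0.5, (0.0,) * 24),
        )


def test_params_json_round_trip():
    p = syn.apoe850_mimic(noise_sd=0.01, seed=3)
    back = syn.params_from_dict(syn.params_to_dict(p))
    assert back == p


# ---------------------------------------------------------------------------
# synthetic genome


def test_generate_synthetic_genome_deterministic_and_consistent():
    spec = syn.SyntheticGenomeSpec(
        n_genes=3, intergenic_length_range=(500, 900),
        gene_length_range=(3_000, 5_000), seed=11,
    )
    g1, genes1 = syn.generate_synthetic_genome(spec)
    g2, genes2 = syn.generate_synthetic_genome(spec)
    assert g1 == g2
    assert [(x.symbol, x.region, [(e.start, e.end) for e in x.exons]) for x in genes1] == [
        (x.symbol, x.region, [(e.start, e.end) for e in x.exons]) for x in genes2
    ]
    # structural invariants
    for prev, nxt in zip(genes1, genes1[1:]):
        assert prev.region.end < nxt.region.start  # non-overlapping genes
    for gene in genes1:
        assert gene.exons[0].start == gene.region.start
        assert gene.exons[-1].end == gene.region.end
        for a, b in zip(gene.exons, gene.exons[1:]):
            assert a.end < b.start  # at least 1 nt of intron
    assert len(g1[spec.chrom_name]) >= genes1[-1].region.end


def test_generated_gff_recount_matches_exon_lengths(tmp_path):
    spec = syn.SyntheticGenomeSpec(
        n_genes=2, intergenic_length_range=(300, 600),
        gene_length_range=(3_000, 4_000), seed=5,
    )
    genome, genes = syn.generate_synthetic_genome(spec)
    fa, gff = tmp_path / "g.fa", tmp_path / "g.gff3"
    gio.write_fasta(genome, fa)
    gio.write_gff3(genes, gff)
    assert gio.read_genome(fa) == genome
    for gene in genes:
        back = gio.read_gene_model(gff, gene.symbol)
        track = gio.build_truth_track(back, back.region)
        assert int(track.labels.sum()) == sum(e.length for e in gene.exons)


def test_generate_empty_genome():
    spec = syn.SyntheticGenomeSpec(n_genes=0, intergenic_length_range=(1_000, 1_000))
    genome, genes = syn.generate_synthetic_genome(spec)
    assert genes == [] and len(genome["chrS"]) == 1_000


def test_generate_infeasible_exons():
    spec = syn.SyntheticGenomeSpec(
        n_genes=1, gene_length_range=(300, 400), exon_count_range=(8, 8),
        exon_length_range=(100, 100), intergenic_length_range=(100, 100),
    )
    with pytest.raises(ValueError):
        syn.generate_synthetic_genome(spec)


# ---------------------------------------------------------------------------
# emulate_window


def test_no_bias_limit_center_equals_p_high():
    """With zero phase/noise and g=1, the center of a large window sits at p_high."""
    params = zero_phase_params(noise_sd=0.0)
    W = params.w_sat * 2
    w = syn.emulate_window(np.ones(W, dtype=int), 0, params)
    center = w.channels["exon"][W // 2]
    assert center == pytest.approx(params.exon.p_high, abs=1e-4)
    # intron channel matches label 0 here -> its p_low
    assert w.channels["intron"][W // 2] == pytest.approx(params.intron.p_low, abs=1e-4)


def test_periodicity_by_construction():
    params = syn.default_params(noise_sd=0.0)
    w = syn.emulate_window(np.ones(240, dtype=int), 0, params)
    v = w.channels["exon"]
    # same phase, same edge regime apart -> compare k and k+24 deep inside
    assert v[96] != pytest.approx(v[100])  # oscillation present
    # periodic component: logit difference between k and k+P reflects only edges
    lg = logit(v)
    off = np.asarray(params.exon.phase_offsets)
    resid = lg - off[np.arange(240) % 24]
    assert np.all(np.diff(resid[:120]) > -1e-9)  # edge factor rises monotonically


def test_center_separation_grows_with_window_length():
    params = syn.default_params(noise_sd=0.0)
    seps = []
    for W in (24, 24_576):
        in_ex = syn.emulate_window(np.ones(W, dtype=int), 0, params).channels["exon"][W // 2]
        in_in = syn.emulate_window(np.zeros(W, dtype=int), 0, params).channels["exon"][W // 2]
        seps.append(in_ex - in_in)
    assert seps[1] > seps[0]


def test_length_separation_constant_beyond_w_sat():
    """With short decay lengths the central edge factor is exactly 1, so the
    central separation saturates exactly at w_sat."""
    base = zero_phase_params(noise_sd=0.0)
    params = syn.EmulatorParams(
        exon=base.exon, intron=base.intron, lambda_start=2.0, lambda_end=2.0,
        period=base.period, noise_sd=0.0, w_sat=768, seed=0,
    )
    seps = {}
    for W in (96, 192, 384, 768, 1_536, 3_072):
        a = syn.emulate_window(np.ones(W, dtype=int), 0, params).channels["exon"][W // 2]
        b = syn.emulate_window(np.zeros(W, dtype=int), 0, params).channels["exon"][W // 2]
        seps[W] = a - b
    ws = sorted(seps)
    assert all(seps[w1] <= seps[w2] for w1, w2 in zip(ws, ws[1:]))
    assert seps[768] == seps[1_536] == seps[3_072]
    assert seps[384] < seps[768]


def test_edge_attenuation_monotone_in_distance_to_nearest_edge():
    """|p - mu0| is nondecreasing in min(k+1, W-k) when both decay lengths match."""
    base = zero_phase_params(noise_sd=0.0)
    params = syn.EmulatorParams(
        exon=base.exon, intron=base.intron, lambda_start=80.0, lambda_end=80.0,
        period=base.period, noise_sd=0.0, w_sat=600, seed=0,
    )
    W = 600
    v = syn.emulate_window(np.ones(W, dtype=int), 0, params).channels["exon"]
    dist = np.minimum(np.arange(W) + 1, W - np.arange(W))
    dev = np.abs(v - params.exon.mu0)
    order = np.argsort(dist, kind="stable")
    assert np.all(np.diff(dev[order]) > -1e-12)


def test_emulate_window_input_validation():
    params = syn.default_params()
    with pytest.raises(ValueError, match="multiple"):
        syn.emulate_window(np.ones(25, dtype=int), 0, params)
    with pytest.raises(ValueError, match="binary"):
        syn.emulate_window(np.full(24, 2), 0, params)


@given(
    st.integers(0, 2**31 - 1),
    st.integers(1, 40),
    st.floats(0.0, 0.5),
)
def test_probabilities_always_bounded(seed, tokens, noise_sd):
    """Property sweep: outputs stay in [0, 1] for random labels/noise."""
    params = syn.default_params(noise_sd=noise_sd, seed=0)
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=6 * tokens)
    w = syn.emulate_window(labels, int(rng.integers(0, 24)), params, rng=rng)
    for ch in ("exon", "intron"):
        assert np.all(w.channels[ch] >= 0) and np.all(w.channels[ch] <= 1)


# ---------------------------------------------------------------------------
# predictor backends


def test_emulator_predictor_repeatable_and_keyed_by_window_start():
    params = syn.default_params(noise_sd=0.05, seed=9)
    pred = syn.EmulatorPredictor(params)
    win = syn.WindowInput(labels=np.ones(48, dtype=int), window_start=100)
    a = pred.predict(win).channels["exon"]
    b = pred.predict(win).channels["exon"]
    assert np.array_equal(a, b)  # bitwise identical across calls
    other = pred.predict(
        syn.WindowInput(labels=np.ones(48, dtype=int), window_start=101)
    ).channels["exon"]
    assert not np.array_equal(a, other)


def test_emulator_predictor_design_restriction():
    pred = syn.EmulatorPredictor(syn.default_params(), design_lengths=(24, 48))
    with pytest.raises(ValueError, match="unsupported window length"):
        pred.predict(syn.WindowInput(labels=np.ones(96, dtype=int), window_start=0))


def test_adapter_stub_raises():
    stub = syn.SegmentNTAdapter()
    with pytest.raises(syn.ModelNotInstalledError, match="model not installed"):
        stub.predict(syn.WindowInput(sequence="ACGTAC", window_start=0))


# ---------------------------------------------------------------------------
# presets and calibration


def test_apoe850_mimic_central_extrema():
    """Noise-free central-window values hit the configured oscillation extrema."""
    params = syn.apoe850_mimic(noise_sd=0.0)
    W = 24_576
    w = syn.emulate_window(np.ones(W, dtype=np.uint8), 0, params)
    central = slice(4_800, W - 4_800)
    ex, it = w.channels["exon"][central], w.channels["intron"][central]
    assert (round(ex.min(), 3), round(ex.max(), 3)) == (0.938, 0.978)
    assert (round(it.min(), 3), round(it.max(), 3)) == (0.079, 0.310)


def test_simulate_central_trace_matches_closed_form():
    params = syn.apoe850_mimic(noise_sd=0.0)
    tr = syn.simulate_central_trace(params, "intron", label=1, n=240)
    off = np.asarray(params.intron.phase_offsets)
    expected = expit(logit(params.intron.p_low) + off[np.arange(240) % 24])
    assert np.allclose(tr, expected)


def test_fit_edge_decay_recovers_lambda_start_within_20pct():
    params = zero_phase_params(noise_sd=0.0)  # lambda_start = 400
    W = 3_072
    # noise-free constant-label probe trace == a single window's value vector
    trace = syn.emulate_window(np.ones(W, dtype=int), 0, params).channels["exon"]
    est = syn.fit_edge_decay(trace, params, g=min(W, params.w_sat) / params.w_sat)
    assert abs(est - params.lambda_start) / params.lambda_start < 0.20
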