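import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trarep import (
    SimulationConfig,
    recombine_clone,
    sample_clone_frequencies,
    simulate_cross_reactive_experiment,
    simulate_sample,
    translate_codons,
    write_fastq,
)
from trarep.errors import ConfigurationError, JunctionError, ParameterError
from trarep.simulate import DOMINANT_PAIRS, INKT_PAIR, MAIT_PAIR


# ---------------------------------------------------------------------------
# clone abundances
# ---------------------------------------------------------------------------

def test_single_clone_takes_all_mass():
    cfg = SimulationConfig(n_clones=1, shared_fraction=0, spike_mait=0,
                           spike_inkt=0)
    assert sample_clone_frequencies(cfg).tolist() == [1.0]


def test_geometric_frequencies_by_hand():
    cfg = SimulationConfig(n_clones=3, abundance_law="geometric",
                           abundance_param=0.5, shared_fraction=0)
    np.testing.assert_allclose(
        sample_clone_frequencies(cfg), [4 / 7, 2 / 7, 1 / 7]
    )


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    n=st.integers(1, 300),
    law=st.sampled_from(["geometric", "dirichlet"]),
    param=st.floats(0.05, 1.0),
    seed=st.integers(0, 2**20),
)
def test_frequency_vector_contract(n, law, param, seed):
    cfg = SimulationConfig(n_clones=n, abundance_law=law, abundance_param=param,
                           seed=seed, shared_fraction=0)
    freqs = sample_clone_frequencies(cfg)
    assert len(freqs) == n
    assert (freqs > 0).all()
    assert abs(freqs.sum() - 1.0) <= 1e-9
    assert (np.diff(freqs) <= 1e-12).all()  # sorted descending


def test_invalid_config_rejected():
    with pytest.raises(ParameterError):
        SimulationConfig(error_rate=0.5).validate()
    with pytest.raises(ParameterError):
        SimulationConfig(abundance_law="zipf").validate()
    with pytest.raises(ParameterError):
        SimulationConfig(spike_mait=0.6, spike_inkt=0.3,
                         shared_fraction=0.3).validate()


# ---------------------------------------------------------------------------
# recombination
# ---------------------------------------------------------------------------

def test_recombine_direct_junction_translation(tiny_ref):
    v = tiny_ref.get("TRAV1")
    j = tiny_ref.get("TRAJ33")
    clone = recombine_clone(v, j, 0, 0, "", require_productive=False)
    v_part = v.sequence[v.anchor_offset:]
    j_part = j.sequence[: j.anchor_offset + 3]
    assert clone.junction_nt == v_part + j_part
    if clone.productive:
        assert clone.cdr3_aa == translate_codons(v_part + j_part)
        assert clone.cdr3_aa.startswith("C") and clone.cdr3_aa.endswith("F")


def test_recombine_redraws_frameshifting_insert(tiny_ref):
    v = tiny_ref.get("TRAV1")
    j = tiny_ref.get("TRAJ33")
    rng = np.random.default_rng(0)
    # a 1-nt insert shifts the frame whenever the trimless junction is in
    # frame; the operation must redraw until the junction is productive
    clone = recombine_clone(v, j, 0, 0, "A", require_productive=True, rng=rng)
    assert clone.productive
    assert len(clone.junction_nt) % 3 == 0
    assert clone.cdr3_aa.startswith("C") and clone.cdr3_aa.endswith("F")


@pytest.mark.parametrize("insert_len", range(7))
def test_recombine_frame_rule_enumerated(tiny_ref, insert_len):
    """Productivity requires junction length ≡ 0 (mod 3), for every insert."""
    v = tiny_ref.get("TRAV5-1")
    j = tiny_ref.get("TRAJ49")
    clone = recombine_clone(v, j, 0, 0, "A" * insert_len,
                            require_productive=False)
    expected_len = (len(v.sequence) - v.anchor_offset) + insert_len + (
        j.anchor_offset + 3
    )
    assert len(clone.junction_nt) == expected_len
    if clone.productive:
        assert expected_len % 3 == 0


def test_recombine_trim_past_anchor_rejected(tiny_ref):
    v = tiny_ref.get("TRAV1")
    j = tiny_ref.get("TRAJ33")
    v_tail = len(v.sequence) - (v.anchor_offset + 3)
    with pytest.raises(JunctionError):
        recombine_clone(v, j, v_tail + 1, 0, "")
    with pytest.raises(JunctionError):
        recombine_clone(v, j, 0, j.anchor_offset + 1, "")


# ---------------------------------------------------------------------------
# sample simulation
# ---------------------------------------------------------------------------

def test_zero_error_single_clone_reads_identical(mock_ref):
    cfg = SimulationConfig(n_clones=1, n_reads=10, error_rate=0.0,
                           spike_mait=0, spike_inkt=0, seed=4)
    reads, truth = simulate_sample(cfg, mock_ref, "one")
    assert len(reads) == 10
    assert len({r.sequence for r in reads}) == 1
    assert reads[0].sequence == truth.clones[0].full_sequence[:cfg.read_length]


def test_read_count_conservation_and_origins(mock_ref):
    cfg = SimulationConfig(n_clones=30, n_reads=1234, seed=2)
    reads, truth = simulate_sample(cfg, mock_ref, "s")
    assert len(reads) == 1234
    assert len(truth.per_read_origin) == 1234
    assert set(truth.per_read_origin) == {r.read_id for r in reads}
    assert abs(sum(c.frequency for c in truth.clones) - 1.0) < 1e-9


def test_determinism_byte_identical(mock_ref, tmp_path):
    cfg = SimulationConfig(n_clones=20, n_reads=500, error_rate=0.02, seed=9)
    out = []
    for name in ("a.fastq", "b.fastq"):
        reads, truth = simulate_sample(cfg, mock_ref, "s")
        write_fastq(reads, tmp_path / name)
        out.append((tmp_path / name).read_bytes())
    assert out[0] == out[1]


def test_spike_fraction_recovered(mock_ref):
    cfg = SimulationConfig(n_clones=50, n_reads=8000, error_rate=0.0,
                           spike_mait=0.2, spike_inkt=0.1, seed=6)
    reads, truth = simulate_sample(cfg, mock_ref, "s")
    n_mait = sum(
        1 for idx in truth.per_read_origin.values()
        if (truth.clones[idx].v_name, truth.clones[idx].j_name) == MAIT_PAIR
    )
    p = n_mait / cfg.n_reads
    se = np.sqrt(0.2 * 0.8 / cfg.n_reads)
    assert abs(p - 0.2) <= 3 * se


def test_error_positions_logged_and_calibrated(mock_ref):
    cfg = SimulationConfig(n_clones=10, n_reads=2000, error_rate=0.01, seed=13)
    reads, truth = simulate_sample(cfg, mock_ref, "s")
    total_errors = 0
    total_bases = 0
    for read in reads:
        clone = truth.clones[truth.per_read_origin[read.read_id]]
        template = clone.full_sequence[: cfg.read_length]
        diffs = [i for i, (x, y) in enumerate(zip(read.sequence, template))
                 if x != y]
        assert diffs == truth.error_positions[read.read_id]
        total_errors += len(diffs)
        total_bases += len(template)
    rate = total_errors / total_bases
    se = np.sqrt(0.01 * 0.99 / total_bases)
    assert abs(rate - 0.01) <= 3 * se


def test_missing_spike_gene_is_config_error():
    from trarep import build_mock_reference

    ref = build_mock_reference(2, 2, seed=1)  # no TRAV1/TRAJ33
    cfg = SimulationConfig(n_clones=10, n_reads=100, seed=1)
    with pytest.raises(ConfigurationError):
        simulate_sample(cfg, ref, "s")


def test_junction_not_covered_rejected(mock_ref):
    cfg = SimulationConfig(n_clones=5, n_reads=10, read_length=100, seed=1)
    with pytest.raises(ConfigurationError):
        simulate_sample(cfg, mock_ref, "s")


def test_nonproductive_fraction(mock_ref):
    cfg = SimulationConfig(n_clones=20, n_reads=500, seed=3,
                           nonproductive_fraction=0.25)
    _, truth = simulate_sample(cfg, mock_ref, "s")
    n_bad = sum(1 for c in truth.clones if not c.productive)
    assert n_bad == round(0.25 * 18)
    for c in truth.clones:
        if not c.productive:
            assert c.cdr3_aa == ""


# ---------------------------------------------------------------------------
# cross-reactive experiment
# ---------------------------------------------------------------------------

def test_shared_clone_count_exact(mock_ref):
    cfg = SimulationConfig(n_clones=10, n_reads=200, error_rate=0.0,
                           shared_fraction=0.3, seed=21)
    sims = simulate_cross_reactive_experiment(cfg, mock_ref)
    keys = {
        sid: {c.key for c in truth.clones}
        for sid, (_, truth) in sims.items()
    }
    assert len(keys["Ni-Pd"] & keys["Cr-Pd"]) == 3


def test_no_sharing_when_disabled(mock_ref):
    cfg = SimulationConfig(n_clones=10, n_reads=100, shared_fraction=0.0,
                           spike_mait=0, spike_inkt=0, seed=5)
    sims = simulate_cross_reactive_experiment(cfg, mock_ref)
    keys = [{c.key for c in truth.clones} for _, truth in sims.values()]
    assert not (keys[0] & keys[1])


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_dominant_shared_clones_planted(mock_ref, seed):
    cfg = SimulationConfig(n_clones=20, n_reads=100, seed=seed)
    sims = simulate_cross_reactive_experiment(cfg, mock_ref)
    for _, truth in sims.values():
        pairs = {(c.v_name, c.j_name) for c in truth.clones}
        for pair in DOMINANT_PAIRS:
            assert pair in pairs
        # the two headline clones hold the two largest true frequencies
        ranked = sorted(truth.clones, key=lambda c: -c.frequency)
        assert {(ranked[0].v_name, ranked[0].j_name),
                (ranked[1].v_name, ranked[1].j_name)} == set(DOMINANT_PAIRS)
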