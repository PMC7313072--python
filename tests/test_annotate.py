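import random

import pytest

from trarep import (
    Read,
    SimulationConfig,
    annotate_read,
    annotate_reads,
    assign_segments,
    simulate_sample,
    translate_codons,
)
from trarep.annotate import annotations_to_airr, read_fastx
from trarep.errors import InvalidInputError


@pytest.mark.parametrize(
    "nt, aa",
    [("TGT", "C"), ("TTTGGT", "FG"), ("TAA", "*"), ("TGCGCAATGTTC", "CAMF")],
)
def test_translate_codons(nt, aa):
    assert translate_codons(nt) == aa


def test_translate_rejects_bad_input():
    with pytest.raises(InvalidInputError):
        translate_codons("TGTA")
    with pytest.raises(InvalidInputError):
        translate_codons("TGN")


def _exact_read(ref, v_name, j_name, read_id="r1"):
    v = ref.get(v_name)
    j = ref.get(j_name)
    return Read(read_id, v.sequence + j.sequence), v, j


def test_exact_concatenation_recovers_both_segments(mock_ref):
    read, v, j = _exact_read(mock_ref, "TRAV3", "TRAJ37")
    v_aln, j_aln = assign_segments(read, mock_ref)
    assert v_aln.gene_name == "TRAV3" and v_aln.identity == 1.0
    assert j_aln.gene_name == "TRAJ37" and j_aln.identity == 1.0
    assert v_aln.read_interval == (0, len(v.sequence))
    assert j_aln.read_interval == (len(v.sequence), len(read.sequence))


def test_single_mismatch_does_not_flip_the_call(mock_ref):
    # the exact-match gene must beat any 1-nt-different competitor
    read, v, j = _exact_read(mock_ref, "TRAV8D-1", "TRAJ49")
    seq = list(read.sequence)
    seq[50] = "A" if seq[50] != "A" else "G"
    v_aln, j_aln = assign_segments(Read("r2", "".join(seq)), mock_ref)
    assert v_aln.gene_name == "TRAV8D-1"
    assert j_aln.gene_name == "TRAJ49"


def test_tie_break_is_lexicographic():
    """Equal score and identity: 'TRAV10' < 'TRAV2' in ASCII order."""
    from trarep.reference import GeneSegment, ReferenceSet

    core = "TGT" + "ACGGTCAGGTTCAAGGACCTGAAGCTGATC"
    v_a = GeneSegment("TRAV2", "V", core + "AAAAAAAAAA", 0)
    v_b = GeneSegment("TRAV10", "V", core + "TTTTTTTTTT", 0)
    j = GeneSegment("TRAJ2", "J", "ACGTTCGGTACGCGGATCAAGCTTACGGATCAAG", 3)
    ref = ReferenceSet([v_a, v_b], [j])
    ref.validate()
    read = Read("r", core + "GCGCGCGCGC" + j.sequence)
    v_aln, _ = assign_segments(read, ref, min_score=40, min_identity=0.5)
    assert v_aln.gene_name == "TRAV10"


def test_bare_v_segment_fails_with_no_j(mock_ref):
    v = mock_ref.get("TRAV4")
    ann = annotate_read(Read("r", v.sequence), mock_ref)
    assert ann.v_call == "TRAV4"
    assert ann.fail_reason in ("no_j", "low_score")
    assert not ann.productive and ann.cdr3_aa is None


def test_random_reads_fail(mock_ref):
    rng = random.Random(31)
    fails = 0
    for i in range(100):
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        ann = annotate_read(Read(f"r{i}", seq), mock_ref)
        if ann.fail_reason in ("no_v", "no_j", "low_score"):
            fails += 1
    assert fails >= 99


def test_zero_error_simulation_fully_recovered(mock_ref, clean_sample):
    """Error-free reads must receive exactly the true V, J and CDR3."""
    _, reads, truth, annotations = clean_sample
    for ann in annotations:
        clone = truth.clones[truth.per_read_origin[ann.read_id]]
        assert ann.productive
        assert (ann.v_call, ann.j_call, ann.cdr3_aa) == clone.key
        assert ann.cdr3_nt == clone.junction_nt


def test_stop_codon_in_junction_detected(mock_ref):
    from trarep import recombine_clone

    v = mock_ref.get("TRAV3")
    j = mock_ref.get("TRAJ37")
    v_len_from_anchor = len(v.sequence) - v.anchor_offset
    # put a TAA stop exactly in frame, then pad so the whole junction is too
    pad_before = (3 - v_len_from_anchor % 3) % 3
    pad_after = (3 - (j.anchor_offset + 3) % 3) % 3
    insert = "A" * pad_before + "TAA" + "A" * pad_after
    clone = recombine_clone(v, j, 0, 0, insert, require_productive=False)
    assert len(clone.junction_nt) % 3 == 0
    ann = annotate_read(Read("r", clone.full_sequence), mock_ref)
    assert not ann.productive
    assert ann.fail_reason == "stop_codon"


def test_out_of_frame_junction_detected(mock_ref):
    from trarep import recombine_clone

    v = mock_ref.get("TRAV3")
    j = mock_ref.get("TRAJ37")
    base = (len(v.sequence) - v.anchor_offset) + (j.anchor_offset + 3)
    shift = 1 if base % 3 == 0 else (3 - base % 3) + 1
    clone = recombine_clone(v, j, 0, 0, "A" * shift, require_productive=False)
    assert len(clone.junction_nt) % 3 != 0
    ann = annotate_read(Read("r", clone.full_sequence), mock_ref)
    assert ann.fail_reason == "out_of_frame"


@pytest.mark.parametrize("rates", [(0.0, 0.005, 0.01, 0.02)])
def test_accuracy_degrades_monotonically_with_error(mock_ref, rates):
    """Exact clonotype-key recovery is non-increasing in error rate."""
    accs = []
    for rate in rates:
        cfg = SimulationConfig(n_clones=40, n_reads=3000, error_rate=rate,
                               seed=29)
        reads, truth = simulate_sample(cfg, mock_ref, "mono")
        anns = annotate_reads(reads, mock_ref)
        ok = sum(
            (a.v_call, a.j_call, a.cdr3_aa)
            == truth.clones[truth.per_read_origin[a.read_id]].key
            for a in anns
        )
        accs.append(ok / len(anns))
    assert accs[0] == 1.0
    assert all(a >= b for a, b in zip(accs, accs[1:]))


def test_airr_table_shape(clean_sample):
    _, _, _, annotations = clean_sample
    df = annotations_to_airr(annotations)
    assert list(df.columns) == [
        "sequence_id", "v_call", "j_call", "junction", "junction_aa",
        "productive", "fail_reason",
    ]
    assert (df["productive"] == "T").all()
    assert df["junction_aa"].str.startswith("C").all()
    assert df["junction_aa"].str.endswith("F").all()


def test_fasta_and_fastq_inputs_equivalent(tmp_path, mock_ref, clean_sample):
    _, reads, _, _ = clean_sample
    sub = reads[:50]
    fastq = tmp_path / "r.fastq"
    fasta = tmp_path / "r.fasta"
    from trarep import write_fastq

    write_fastq(sub, fastq)
    fasta.write_text("".join(f">{r.read_id}\n{r.sequence}\n" for r in sub))
    from_fastq = annotate_reads(read_fastx(fastq), mock_ref)
    from_fasta = annotate_reads(read_fastx(fasta), mock_ref)
    assert [(a.v_call, a.j_call, a.cdr3_aa) for a in from_fastq] == [
        (a.v_call, a.j_call, a.cdr3_aa) for a in from_fasta
    ]
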