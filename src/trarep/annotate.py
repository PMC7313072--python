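"""Per-read V/J assignment and CDR3 extraction.

Each read is aligned locally against every candidate V and J segment; the
best-scoring segment of each class that passes the score and identity
thresholds becomes the call, and the CDR3 is cut out between the conserved
anchors mapped through the alignments: from the first base of the V
segment's Cys-104 codon to the last base of the J segment's Phe-118 codon,
inclusive (this equals the AIRR "junction").  A read is productive when
that span is in frame, free of stop codons, starts with C, ends with F,
and — when the read covers it — the residue after the Phe codon is the
conserved G.

A 9-mer prefilter skips segments sharing no exact 9-mer with the read;
if no candidate passes the thresholds the read is re-scored against the
full reference so the filter cannot change any call.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .align import (
    DEFAULT_SCORING,
    Scoring,
    SegmentAlignment,
    align_segment,
    encode,
    score_segment,
)
from .errors import InvalidInputError
from .reference import GeneSegment, ReferenceSet

_READ_ALPHABET = set("ACGTN")

#: default acceptance thresholds for a segment call
DEFAULT_MIN_SCORE = 40
DEFAULT_MIN_IDENTITY = 0.85

_PREFILTER_K = 9

FAIL_REASONS = (
    "none",
    "no_v",
    "no_j",
    "anchor_missing",
    "out_of_frame",
    "stop_codon",
    "low_score",
)


@dataclass(frozen=True)
class Read:
    """One merged amplicon read."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def validate(self) -> None:
        if not self.sequence:
            raise InvalidInputError(f"{self.read_id}: empty sequence")
        bad = set(self.sequence.upper()) - _READ_ALPHABET
        if bad:
            raise InvalidInputError(
                f"{self.read_id}: invalid characters {sorted(bad)}"
            )


@dataclass
class ReadAnnotation:
    """V/J calls, CDR3 and productivity for one read."""

    read_id: str
    v_call: str | None = None
    j_call: str | None = None
    cdr3_nt: str | None = None
    cdr3_aa: str | None = None
    productive: bool = False
    fail_reason: str = "none"


def translate_codons(nt: str) -> str:
    """Translate an in-frame nucleotide string (standard code, stops → '*')."""
    if len(nt) % 3 != 0:
        raise InvalidInputError(f"length {len(nt)} is not a multiple of 3")
    bad = set(nt.upper()) - set("ACGT")
    if bad:
        raise InvalidInputError(f"invalid characters {sorted(bad)}")
    return str(Seq(nt.upper()).translate())


# ---------------------------------------------------------------------------
# segment assignment
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class _SegmentIndex:
    """Per-reference cache of encoded sequences and 9-mer sets."""

    def __init__(self, reference: ReferenceSet):
        self.reference = reference
        self.codes = {s.name: encode(s.sequence) for s in reference.segments}
        self.kmers = {
            s.name: _kmers(s.sequence, _PREFILTER_K) for s in reference.segments
        }


_INDEX_CACHE: dict[int, _SegmentIndex] = {}


def _index_for(reference: ReferenceSet) -> _SegmentIndex:
    idx = _INDEX_CACHE.get(id(reference))
    if idx is None or idx.reference is not reference:
        idx = _SegmentIndex(reference)
        _INDEX_CACHE.clear()
        _INDEX_CACHE[id(reference)] = idx
    return idx


def _best_alignment(
    read_seq: str,
    segments: Sequence[GeneSegment],
    scoring: Scoring,
    min_score: int,
    min_identity: float,
    index: _SegmentIndex,
    read_kmers: set[str],
) -> tuple[SegmentAlignment | None, str]:
    """Best passing alignment in one segment class.

    Returns ``(alignment, status)`` with status ``ok``, ``low_score`` (an
    alignment exists but fails a threshold) or ``none``.
    """
    read_codes = encode(read_seq)

    def _rank(cands: Sequence[GeneSegment]) -> SegmentAlignment | None:
        scores = [
            score_segment(read_codes, index.codes[s.name], scoring) for s in cands
        ]
        best = max(scores, default=0)
        if best <= 0:
            return None
        tied = [s for s, sc in zip(cands, scores) if sc == best]
        alns = [align_segment(read_seq, s, scoring) for s in tied]
        # higher identity wins ties, then lexicographically smaller name
        alns.sort(key=lambda a: (-a.identity, a.gene_name))
        return alns[0]

    filtered = [s for s in segments if read_kmers & index.kmers[s.name]]
    aln = _rank(filtered) if filtered else None
    if aln is None or aln.score < min_score or aln.identity < min_identity:
        # prefilter fallback: a call may only be rejected after the full
        # reference has been scored, keeping the k-mer filter score-neutral
        if len(filtered) < len(segments):
            full = _rank(list(segments))
            if full is not None and (aln is None or full.score > aln.score):
                aln = full
    if aln is None:
        return None, "none"
    if aln.score < min_score or aln.identity < min_identity:
        return None, "low_score"
    return aln, "ok"


def assign_segments(
    read: Read,
    reference: ReferenceSet,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[SegmentAlignment | None, SegmentAlignment | None]:
    """Best V and J calls for one read (None where no segment passes)."""
    (v, _), (j, _) = assign_segments_detailed(
        read, reference, scoring, min_score, min_identity
    )
    return v, j


def assign_segments_detailed(
    read: Read,
    reference: ReferenceSet,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[
    tuple[SegmentAlignment | None, str], tuple[SegmentAlignment | None, str]
]:
    read.validate()
    seq = read.sequence.upper()
    index = _index_for(reference)
    read_kmers = _kmers(seq, _PREFILTER_K)
    v, v_status = _best_alignment(
        seq, reference.v_segments, scoring, min_score, min_identity, index, read_kmers
    )
    j, j_status = _best_alignment(
        seq, reference.j_segments, scoring, min_score, min_identity, index, read_kmers
    )
    if v is not None and j is not None:
        # V must begin upstream of J on the read; drop the weaker call
        if v.read_interval[0] >= j.read_interval[0]:
            if v.score >= j.score:
                j, j_status = None, "low_score"
            else:
                v, v_status = None, "low_score"
    return (v, v_status), (j, j_status)


# ---------------------------------------------------------------------------
# CDR3 extraction
# ---------------------------------------------------------------------------

def extract_cdr3(
    read: Read,
    v_aln: SegmentAlignment,
    j_aln: SegmentAlignment,
    reference: ReferenceSet,
) -> tuple[str | None, str | None, bool, str]:
    """Cut the CDR3 (junction) from a read through its V and J alignments.

    Returns ``(cdr3_nt, cdr3_aa, productive, fail_reason)``.  The anchor
    codons must be covered by the alignments and map onto the read without
    internal gaps; junction-proximal indels fail with ``anchor_missing``
    rather than guessing a frame.
    """
    seq = read.sequence.upper()
    v_seg = reference.get(v_aln.gene_name)
    j_seg = reference.get(j_aln.gene_name)

    va, ja = v_seg.anchor_offset, j_seg.anchor_offset
    if not v_aln.maps_contiguously(va, va + 3):
        return None, None, False, "anchor_missing"
    if not j_aln.maps_contiguously(ja, ja + 3):
        return None, None, False, "anchor_missing"
    start = v_aln.map_ref_to_read(va)
    end = j_aln.map_ref_to_read(ja) + 3
    if start is None or end is None or start >= end:
        return None, None, False, "anchor_missing"

    cdr3_nt = seq[start:end]
    if len(cdr3_nt) % 3 != 0:
        return cdr3_nt, None, False, "out_of_frame"
    if "N" in cdr3_nt:
        return cdr3_nt, None, False, "anchor_missing"
    aa = translate_codons(cdr3_nt)
    if "*" in aa:
        return cdr3_nt, None, False, "stop_codon"
    if not aa.startswith("C") or not aa.endswith("F"):
        return cdr3_nt, None, False, "anchor_missing"
    # conserved glycine after Phe-118, checked only when the read covers it
    if end + 3 <= len(seq):
        nxt = seq[end : end + 3]
        if "N" not in nxt and translate_codons(nxt) != "G":
            return cdr3_nt, None, False, "anchor_missing"
    return cdr3_nt, aa, True, "none"


def annotate_read(
    read: Read,
    reference: ReferenceSet,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> ReadAnnotation:
    """Full per-read annotation; never raises on a well-formed read."""
    (v, v_status), (j, j_status) = assign_segments_detailed(
        read, reference, scoring, min_score, min_identity
    )
    ann = ReadAnnotation(read_id=read.read_id)
    if v is None:
        ann.fail_reason = "low_score" if v_status == "low_score" else "no_v"
        ann.j_call = j.gene_name if j is not None else None
        return ann
    if j is None:
        ann.v_call = v.gene_name
        ann.fail_reason = "low_score" if j_status == "low_score" else "no_j"
        return ann
    ann.v_call = v.gene_name
    ann.j_call = j.gene_name
    cdr3_nt, cdr3_aa, productive, fail = extract_cdr3(read, v, j, reference)
    ann.cdr3_nt = cdr3_nt
    ann.cdr3_aa = cdr3_aa
    ann.productive = productive
    ann.fail_reason = fail
    return ann


def annotate_reads(
    reads: Iterable[Read],
    reference: ReferenceSet,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[ReadAnnotation]:
    """Annotate many reads, memoizing identical sequences."""
    cache: dict[str, ReadAnnotation] = {}
    out: list[ReadAnnotation] = []
    for read in reads:
        hit = cache.get(read.sequence)
        if hit is None:
            hit = annotate_read(read, reference, scoring, min_score, min_identity)
            cache[read.sequence] = hit
        out.append(
            ReadAnnotation(
                read_id=read.read_id,
                v_call=hit.v_call,
                j_call=hit.j_call,
                cdr3_nt=hit.cdr3_nt,
                cdr3_aa=hit.cdr3_aa,
                productive=hit.productive,
                fail_reason=hit.fail_reason,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O — FASTA/FASTQ in, AIRR Rearrangement TSV out
# ---------------------------------------------------------------------------

AIRR_COLUMNS = (
    "sequence_id",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "fail_reason",
)


def read_fastx(path: str | Path) -> list[Read]:
    """Read FASTA or FASTQ (gzip-transparent), qualities optional."""
    path = Path(path)
    opener = gzip.open if path.name.endswith(".gz") else open
    stem = path.name.removesuffix(".gz")
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    reads: list[Read] = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, fmt):
            quals = rec.letter_annotations.get("phred_quality")
            reads.append(
                Read(rec.id, str(rec.seq).upper(), tuple(quals) if quals else None)
            )
    return reads


def annotations_to_airr(annotations: Iterable[ReadAnnotation]):
    """AIRR Rearrangement table (pandas DataFrame) for a set of annotations."""
    import pandas as pd

    rows = [
        {
            "sequence_id": a.read_id,
            "v_call": a.v_call or "",
            "j_call": a.j_call or "",
            "junction": a.cdr3_nt or "",
            "junction_aa": a.cdr3_aa or "",
            "productive": "T" if a.productive else "F",
            "fail_reason": a.fail_reason,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=list(AIRR_COLUMNS))


def airr_to_annotations(df) -> list[ReadAnnotation]:
    """Rebuild annotations from an AIRR Rearrangement table."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ReadAnnotation(
                read_id=str(row.sequence_id),
                v_call=str(row.v_call) or None,
                j_call=str(row.j_call) or None,
                cdr3_nt=str(row.junction) or None,
                cdr3_aa=str(row.junction_aa) or None,
                productive=str(row.productive) == "T",
                fail_reason=str(getattr(row, "fail_reason", "none")) or "none",
            )
        )
    return out
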