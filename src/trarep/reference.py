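"""TRAV/TRAJ reference segments with conserved-anchor coordinates.

The clonotyping pipeline needs exactly two numbering facts from the IMGT
system: where the second conserved cysteine (position 104) sits in each V
segment and where the conserved phenylalanine (position 118, followed by a
glycine) sits in each J segment.  Those anchors delimit the CDR3.  Rather
than recomputing full IMGT gap numbering, every :class:`GeneSegment`
carries its anchor as explicit metadata: the 0-based offset of the first
base of the anchor codon.

Resolution is gene-level: allele suffixes (``*01``) are stripped and a
single sequence represents each gene, matching how repertoire results are
reported (e.g. ``TRAV8D-1``/``TRAJ49`` pairs, not alleles).

A reference can be loaded from FASTA using the header dialect
``name|V|anchor_offset`` / ``name|J|anchor_offset``, or from a plain FASTA
plus a two-column TSV sidecar mapping gene name to anchor offset.  A mock
reference builder generates fully valid segment sets for simulation and
testing without any external download.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    InvalidNameError,
    ParameterError,
    ReferenceConfigError,
    ReferenceValidationError,
)

_NT = set("ACGT")
_ALLELE_RE = re.compile(r"\*\d+$")

#: codons for the conserved residues flanking the CDR3
CYS_CODONS = ("TGT", "TGC")
PHE_CODONS = ("TTT", "TTC")


def normalize_gene_name(raw: str) -> str:
    """Normalize a TRAV/TRAJ gene symbol.

    Uppercases and strips an allele suffix (``*NN``), so ``Trav8d-1`` →
    ``TRAV8D-1`` and ``TRAJ33*01`` → ``TRAJ33``.  Idempotent.
    """
    name = raw.strip()
    if not name:
        raise InvalidNameError("gene name is empty")
    return _ALLELE_RE.sub("", name.upper())


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class GeneSegment:
    """One reference V or J segment with its conserved-anchor codon.

    ``anchor_offset`` is the 0-based offset of the first base of the anchor
    codon: the Cys-104 codon for a V segment, the Phe-118 codon for a J
    segment (whose next codon must encode the conserved Gly).
    """

    name: str
    segment_class: str  # "V" or "J"
    sequence: str
    anchor_offset: int
    functional: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_gene_name(self.name))
        object.__setattr__(self, "sequence", self.sequence.upper())

    def validate(self) -> None:
        """Raise :class:`ReferenceValidationError` on any invariant breach."""
        if self.segment_class not in ("V", "J"):
            raise ReferenceValidationError(
                f"{self.name}: segment_class must be 'V' or 'J', got "
                f"{self.segment_class!r}"
            )
        if not self.sequence:
            raise ReferenceValidationError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - _NT
        if bad:
            raise ReferenceValidationError(
                f"{self.name}: non-ACGT characters {sorted(bad)}"
            )
        if not 0 <= self.anchor_offset <= len(self.sequence) - 3:
            raise ReferenceValidationError(
                f"{self.name}: anchor_offset {self.anchor_offset} outside "
                f"sequence of length {len(self.sequence)}"
            )
        codon = self.anchor_codon
        if self.segment_class == "V":
            if translate_codon(codon) != "C":
                raise ReferenceValidationError(
                    f"{self.name}: V anchor codon {codon} does not encode the "
                    "conserved cysteine (position 104)"
                )
        else:
            if translate_codon(codon) != "F":
                raise ReferenceValidationError(
                    f"{self.name}: J anchor codon {codon} does not encode the "
                    "conserved phenylalanine (position 118)"
                )
            nxt = self.sequence[self.anchor_offset + 3 : self.anchor_offset + 6]
            if len(nxt) < 3 or translate_codon(nxt) != "G":
                raise ReferenceValidationError(
                    f"{self.name}: codon after the J anchor ({nxt or '∅'}) "
                    "does not encode the conserved glycine"
                )

    @property
    def anchor_codon(self) -> str:
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]


@dataclass
class ReferenceSet:
    """A validated collection of V and J segments."""

    v_segments: list[GeneSegment] = field(default_factory=list)
    j_segments: list[GeneSegment] = field(default_factory=list)
    version_tag: str = ""

    def validate(self) -> None:
        if not self.v_segments or not self.j_segments:
            raise ReferenceValidationError(
                "reference needs at least one V and one J segment"
            )
        names = [s.name for s in self.v_segments + self.j_segments]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ReferenceValidationError(f"duplicate gene names: {sorted(dupes)}")
        for seg in self.v_segments + self.j_segments:
            seg.validate()

    def get(self, name: str) -> GeneSegment:
        key = normalize_gene_name(name)
        for seg in self.v_segments + self.j_segments:
            if seg.name == key:
                return seg
        raise KeyError(key)

    def __contains__(self, name: str) -> bool:
        try:
            self.get(name)
            return True
        except KeyError:
            return False

    @property
    def segments(self) -> list[GeneSegment]:
        return list(self.v_segments) + list(self.j_segments)


# ---------------------------------------------------------------------------
# FASTA I/O — dialect "name|class|anchor_offset", or plain FASTA + sidecar
# ---------------------------------------------------------------------------

def write_reference_fasta(reference: ReferenceSet, path: str | Path) -> None:
    """Write a reference using the ``name|class|anchor`` header dialect."""
    records = [
        SeqRecord(
            Seq(seg.sequence),
            id=f"{seg.name}|{seg.segment_class}|{seg.anchor_offset}",
            description="",
        )
        for seg in reference.segments
    ]
    SeqIO.write(records, str(path), "fasta")


def load_anchor_sidecar(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV sidecar ``gene<TAB>anchor_offset``."""
    anchors: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ReferenceConfigError(f"malformed anchor sidecar line: {line!r}")
        anchors[normalize_gene_name(fields[0])] = int(fields[1])
    return anchors


def load_reference_fasta(
    path: str | Path,
    anchors: Mapping[str, int] | str | Path | None = None,
    version_tag: str = "",
) -> ReferenceSet:
    """Load and validate a reference FASTA.

    Headers of the form ``name|V|anchor`` are self-describing; otherwise an
    ``anchors`` mapping (or sidecar TSV path) must supply every gene's
    anchor offset, and the segment class is inferred from the gene name
    (``TRAV…`` → V, ``TRAJ…`` → J).

    All records are validated; failures are collected and raised together
    so the error message is a per-record report.
    """
    if isinstance(anchors, (str, Path)):
        anchors = load_anchor_sidecar(anchors)
    v_segments: list[GeneSegment] = []
    j_segments: list[GeneSegment] = []
    failures: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        if "|" in header:
            try:
                raw_name, seg_class, raw_anchor = header.split("|")[:3]
                anchor = int(raw_anchor)
            except ValueError as exc:
                raise ReferenceConfigError(
                    f"malformed reference header {header!r}: {exc}"
                ) from exc
        else:
            raw_name = header
            name = normalize_gene_name(raw_name)
            if anchors is None or name not in anchors:
                raise ReferenceConfigError(
                    f"no anchor entry for gene {name!r}; provide a sidecar"
                )
            anchor = int(anchors[name])
            if name.startswith("TRAV"):
                seg_class = "V"
            elif name.startswith("TRAJ"):
                seg_class = "J"
            else:
                raise ReferenceConfigError(
                    f"cannot infer segment class for {name!r}; use the "
                    "name|class|anchor header dialect"
                )
        seg = GeneSegment(raw_name, seg_class, str(record.seq), anchor)
        try:
            seg.validate()
        except ReferenceValidationError as exc:
            failures.append(str(exc))
            continue
        (v_segments if seg_class == "V" else j_segments).append(seg)
    if failures:
        raise ReferenceValidationError(
            "rejected {} record(s):\n  {}".format(len(failures), "\n  ".join(failures))
        )
    ref = ReferenceSet(v_segments, j_segments, version_tag or str(path))
    ref.validate()
    return ref


# ---------------------------------------------------------------------------
# Mock reference builder
# ---------------------------------------------------------------------------

# Genes that must exist so the headline cross-reactive clonotypes and the
# canonical invariant (MAIT/iNKT) receptors can be simulated.
NAMED_V = ("TRAV1", "TRAV5-1", "TRAV8D-1", "TRAV11")
NAMED_J = ("TRAJ18", "TRAJ33", "TRAJ37", "TRAJ49")

_STOPS = {"TAA", "TAG", "TGA"}


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def build_mock_reference(n_v: int, n_j: int, seed: int) -> ReferenceSet:
    """Construct a deterministic, fully valid mock TRAV/TRAJ reference.

    When ``n_v >= 5`` and ``n_j >= 5`` the set includes the named genes
    needed to simulate the headline clonotypes (TRAV8D-1/TRAJ49,
    TRAV5-1/TRAJ37) and the invariant receptors (TRAV1/TRAJ33 for MAIT,
    TRAV11/TRAJ18 for iNKT).  V sequences end within 15 nt after the anchor
    codon and J sequences start within 15 nt before it, so a 300-nt read
    anchored at the amplicon 5' end always covers the junction.
    """
    if n_v < 1 or n_j < 1:
        raise ParameterError("n_v and n_j must both be >= 1")
    rng = np.random.default_rng(seed)

    def _names(prefix: str, named: tuple[str, ...], n: int) -> list[str]:
        names = list(named) if n >= 5 else []
        i = 2
        while len(names) < n:
            cand = f"{prefix}{i}"
            if cand not in names:
                names.append(cand)
            i += 1
        return names[:n]

    v_names = _names("TRAV", NAMED_V, n_v)
    j_names = _names("TRAJ", NAMED_J, n_j)

    v_segments = []
    for name in v_names:
        anchor = int(rng.integers(150, 181))
        tail = int(rng.integers(8, 13))  # nt after the anchor codon, <= 15
        seq = _random_nt(rng, anchor) + ("TGT", "TGC")[rng.integers(2)]
        seq += _random_nt(rng, tail)
        v_segments.append(GeneSegment(name, "V", seq, anchor))

    j_segments = []
    for name in j_names:
        head = int(rng.integers(8, 13))  # nt before the anchor codon, <= 15
        tail = int(rng.integers(30, 46))
        seq = (
            _random_nt(rng, head)
            + ("TTT", "TTC")[rng.integers(2)]
            + "GG" + "ACGT"[rng.integers(4)]
            + _random_nt(rng, tail)
        )
        j_segments.append(GeneSegment(name, "J", seq, head))

    ref = ReferenceSet(v_segments, j_segments, f"mock-{n_v}v{n_j}j-seed{seed}")
    ref.validate()
    return ref
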