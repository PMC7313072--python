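"""Ground-truthed synthetic TCRα amplicon reads.

The generator emulates the data the repertoire analysis consumes: merged
single-end 300-nt amplicon reads from a skewed clone-abundance
distribution with a few dominant clonotypes, V–J junctional diversity
(3'-V trimming, N-insertion, 5'-J trimming), uniform per-base substitution
error, canonical invariant spike-ins (MAIT: TRAV1–TRAJ33, iNKT:
TRAV11–TRAJ18), and — for the two-group cross-reactivity design — a
planted set of clones shared between a nickel-sensitized and a
chromium-sensitized, palladium-challenged sample ("Ni-Pd" and "Cr-Pd"),
led by the dominant TRAV8D-1/TRAJ49 and TRAV5-1/TRAJ37 clonotypes.

Every read's clone of origin and every injected substitution are logged in
a :class:`GroundTruth`, so recovery can be scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import Read, translate_codons
from .errors import (
    ConfigurationError,
    JunctionError,
    ParameterError,
    RetryExhaustedError,
)
from .reference import GeneSegment, ReferenceSet

#: canonical invariant receptors (V gene, J gene)
MAIT_PAIR = ("TRAV1", "TRAJ33")
INKT_PAIR = ("TRAV11", "TRAJ18")

#: headline cross-reactive clonotypes planted as the dominant shared clones
DOMINANT_PAIRS = (("TRAV8D-1", "TRAJ49"), ("TRAV5-1", "TRAJ37"))

GROUP_A = "Ni-Pd"
GROUP_B = "Cr-Pd"

_NT = "ACGT"
_LUT = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate(_NT):
    _LUT[ord(_c)] = _i


@dataclass(frozen=True)
class TrueClone:
    """One simulated clonotype with its recombined sequence."""

    v_name: str
    j_name: str
    full_sequence: str
    junction_nt: str
    cdr3_aa: str
    frequency: float = 0.0
    productive: bool = True

    @property
    def key(self) -> tuple[str, str, str]:
        """Clonotype identity: (V, J, CDR3 amino-acid sequence)."""
        return (self.v_name, self.j_name, self.cdr3_aa)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated repertoire.

    Defaults are the package's standing conditions: 200 clones and 20,000
    reads per sample, geometric clone abundances decaying by 0.9 (the top
    clone holds ~10% of the repertoire), junctional trimming up to 6 nt and
    insertion up to 9 nt, 1% substitution error, 5% MAIT and 5% iNKT
    spike-ins, and 30% of clones shared between the two groups.
    """

    n_clones: int = 200
    n_reads: int = 20_000
    abundance_law: str = "geometric"
    abundance_param: float = 0.9
    trim_max: int = 6
    insert_max: int = 9
    error_rate: float = 0.01
    read_length: int = 300
    spike_mait: float = 0.05
    spike_inkt: float = 0.05
    shared_fraction: float = 0.3
    nonproductive_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 1 or self.n_reads < 1:
            raise ParameterError("n_clones and n_reads must be >= 1")
        if self.abundance_law not in ("dirichlet", "geometric"):
            raise ParameterError(f"unknown abundance law {self.abundance_law!r}")
        if self.abundance_param <= 0:
            raise ParameterError("abundance_param must be > 0")
        if self.abundance_law == "geometric" and self.abundance_param > 1:
            raise ParameterError("geometric decay ratio must be in (0, 1]")
        if not 0 <= self.error_rate <= 0.1:
            raise ParameterError("error_rate must be in [0, 0.1]")
        for name in ("spike_mait", "spike_inkt", "shared_fraction",
                     "nonproductive_fraction"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.spike_mait + self.spike_inkt + self.shared_fraction > 1:
            raise ParameterError(
                "spike_mait + spike_inkt + shared_fraction must be <= 1"
            )
        if self.trim_max < 0 or self.insert_max < 0 or self.read_length < 1:
            raise ParameterError("trim_max/insert_max/read_length out of range")


@dataclass
class GroundTruth:
    """The simulator's own record of what it generated."""

    sample_id: str
    clones: list[TrueClone]
    per_read_origin: dict[str, int] = field(default_factory=dict)
    error_positions: dict[str, list[int]] = field(default_factory=dict)

    def clone_counts(self) -> dict[tuple[str, str, str], int]:
        """Realized read count per clonotype key (productive clones)."""
        counts: dict[tuple[str, str, str], int] = {}
        for idx in self.per_read_origin.values():
            clone = self.clones[idx]
            if clone.productive:
                counts[clone.key] = counts.get(clone.key, 0) + 1
        return counts

    def validate(self) -> None:
        total = sum(c.frequency for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"clone frequencies sum to {total}, not 1")


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])


# ---------------------------------------------------------------------------
# clone abundances
# ---------------------------------------------------------------------------

def _frequency_vector(
    n: int, law: str, param: float, rng: np.random.Generator
) -> np.ndarray:
    if law == "geometric":
        # floor keeps the vector strictly positive when param**k underflows
        raw = np.maximum(param ** np.arange(n, dtype=float), 1e-300)
    else:
        raw = rng.dirichlet(np.full(n, param))
        raw = np.sort(raw)[::-1]
    freqs = raw / raw.sum()
    return freqs


def sample_clone_frequencies(config: SimulationConfig) -> np.ndarray:
    """Clone frequency vector under the configured abundance law.

    Length ``n_clones``, strictly positive, sorted descending, sums to 1;
    deterministic for a fixed seed.  Under the geometric law successive
    frequencies decay by ``abundance_param``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    return _frequency_vector(
        config.n_clones, config.abundance_law, config.abundance_param, rng
    )


# ---------------------------------------------------------------------------
# V(D)J recombination
# ---------------------------------------------------------------------------

def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, size=n))


def recombine_clone(
    v: GeneSegment,
    j: GeneSegment,
    trim_v: int,
    trim_j: int,
    insert_nt: str,
    require_productive: bool = True,
    rng: np.random.Generator | None = None,
    max_tries: int = 200,
) -> TrueClone:
    """Join a V and J segment with trimming and N-region insertion.

    The clone sequence is ``V[: len(V) - trim_v] + insert + J[trim_j:]``.
    When ``require_productive`` and the stated junction is out of frame or
    contains a stop codon, the insert is redrawn (length 0–6, random
    content) until the junction is productive, up to ``max_tries`` draws.
    """
    v_tail = len(v.sequence) - (v.anchor_offset + 3)
    if trim_v < 0 or trim_v > v_tail:
        raise JunctionError(
            f"trim_v={trim_v} would remove the {v.name} Cys-104 anchor"
        )
    if trim_j < 0 or trim_j > j.anchor_offset:
        raise JunctionError(
            f"trim_j={trim_j} would remove the {j.name} Phe-118 anchor"
        )
    if set(insert_nt) - set(_NT):
        raise JunctionError("insert_nt must be over {A,C,G,T}")

    def _build(insert: str) -> tuple[str, str, bool, str]:
        seq = v.sequence[: len(v.sequence) - trim_v] + insert + j.sequence[trim_j:]
        start = v.anchor_offset
        end = (len(v.sequence) - trim_v) + len(insert) + (j.anchor_offset - trim_j) + 3
        junction = seq[start:end]
        productive = len(junction) % 3 == 0
        aa = ""
        if productive:
            aa = translate_codons(junction)
            productive = "*" not in aa
            if not productive:
                aa = ""
        return seq, junction, productive, aa

    seq, junction, productive, aa = _build(insert_nt)
    if require_productive and not productive:
        if rng is None:
            raise RetryExhaustedError(
                "junction is nonproductive and no rng was given for redraws"
            )
        for _ in range(max_tries):
            insert_nt = _random_nt(rng, int(rng.integers(0, 7)))
            seq, junction, productive, aa = _build(insert_nt)
            if productive:
                break
        else:
            raise RetryExhaustedError(
                f"no productive junction for {v.name}/{j.name} in {max_tries} draws"
            )
    if not productive:
        aa = ""
    return TrueClone(
        v_name=v.name,
        j_name=j.name,
        full_sequence=seq,
        junction_nt=junction,
        cdr3_aa=aa,
        productive=productive,
    )


def _draw_clone(
    rng: np.random.Generator,
    reference: ReferenceSet,
    config: SimulationConfig,
    forbidden_keys: set,
    v_name: str | None = None,
    j_name: str | None = None,
    productive: bool = True,
) -> TrueClone:
    """Draw a clone with a fresh clonotype key (bounded redraws)."""
    invariant_pairs = {MAIT_PAIR, INKT_PAIR}
    for _ in range(500):
        if v_name is None:
            v = reference.v_segments[rng.integers(len(reference.v_segments))]
        else:
            v = reference.get(v_name)
        if j_name is None:
            j = reference.j_segments[rng.integers(len(reference.j_segments))]
        else:
            j = reference.get(j_name)
        if v_name is None and j_name is None and (v.name, j.name) in invariant_pairs:
            continue  # keep spike proportions exact
        v_tail = len(v.sequence) - (v.anchor_offset + 3)
        trim_v = int(rng.integers(0, min(config.trim_max, v_tail) + 1))
        trim_j = int(rng.integers(0, min(config.trim_max, j.anchor_offset) + 1))
        insert = _random_nt(rng, int(rng.integers(0, config.insert_max + 1)))
        try:
            clone = recombine_clone(
                v, j, trim_v, trim_j, insert, require_productive=productive, rng=rng
            )
        except RetryExhaustedError:
            continue
        if not productive and clone.productive:
            continue  # redraw until genuinely out of frame
        dedup_key = clone.key if clone.productive else (v.name, j.name, clone.junction_nt)
        if dedup_key in forbidden_keys:
            continue
        forbidden_keys.add(dedup_key)
        return clone
    raise RetryExhaustedError("could not draw a clone with a fresh clonotype key")


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

def _check_junction_covered(clone: TrueClone, v: GeneSegment, config: SimulationConfig):
    end = v.anchor_offset + len(clone.junction_nt)
    if end > config.read_length:
        raise ConfigurationError(
            f"clone {clone.v_name}/{clone.j_name}: junction ends at {end} nt, "
            f"beyond read_length={config.read_length}"
        )


def _generate_reads(
    clones: Sequence[TrueClone],
    freqs: np.ndarray,
    config: SimulationConfig,
    sample_id: str,
    rng: np.random.Generator,
) -> tuple[list[Read], GroundTruth]:
    counts = rng.multinomial(config.n_reads, freqs / freqs.sum())
    truth = GroundTruth(sample_id=sample_id, clones=list(clones))
    reads: list[Read] = []
    serial = 0
    for idx, (clone, count) in enumerate(zip(clones, counts)):
        if count == 0:
            continue
        template = clone.full_sequence[: config.read_length]
        length = len(template)
        if config.error_rate > 0:
            err = rng.random((count, length)) < config.error_rate
            shifts = rng.integers(1, 4, size=(count, length))
            base_codes = _LUT[np.frombuffer(template.encode(), dtype=np.uint8)]
        for r in range(count):
            read_id = f"{sample_id}:read{serial:06d}"
            serial += 1
            positions = (
                np.flatnonzero(err[r]) if config.error_rate > 0
                else np.empty(0, dtype=int)
            )
            if positions.size:
                mutated = base_codes.copy()
                mutated[positions] = (mutated[positions] + shifts[r, positions]) % 4
                seq = "".join(_NT[c] for c in mutated)
            else:
                seq = template
            reads.append(Read(read_id, seq))
            truth.per_read_origin[read_id] = idx
            truth.error_positions[read_id] = [int(p) for p in positions]
    truth.validate()
    return reads, truth


def _spike_clones(
    config: SimulationConfig,
    reference: ReferenceSet,
    rng: np.random.Generator,
    forbidden_keys: set,
) -> tuple[list[TrueClone], list[float]]:
    clones: list[TrueClone] = []
    freqs: list[float] = []
    for frac, (v_name, j_name), label in (
        (config.spike_mait, MAIT_PAIR, "MAIT"),
        (config.spike_inkt, INKT_PAIR, "iNKT"),
    ):
        if frac <= 0:
            continue
        if v_name not in reference or j_name not in reference:
            raise ConfigurationError(
                f"{label} spike-in requires {v_name} and {j_name} in the reference"
            )
        clones.append(
            _draw_clone(rng, reference, config, forbidden_keys, v_name, j_name)
        )
        freqs.append(frac)
    return clones, freqs


def _assemble_sample(
    config: SimulationConfig,
    reference: ReferenceSet,
    sample_id: str,
    conventional: Sequence[TrueClone],
    rng: np.random.Generator,
    forbidden_keys: set,
) -> tuple[list[Read], GroundTruth]:
    spikes, spike_freqs = _spike_clones(config, reference, rng, forbidden_keys)
    conv_mass = 1.0 - sum(spike_freqs)
    base = _frequency_vector(
        len(conventional), config.abundance_law, config.abundance_param, rng
    )
    freqs = np.concatenate([base * conv_mass, np.asarray(spike_freqs)])
    clones = [
        replace(c, frequency=float(f))
        for c, f in zip(list(conventional) + spikes, freqs)
    ]
    for clone in clones:
        _check_junction_covered(clone, reference.get(clone.v_name), config)
    return _generate_reads(clones, freqs, config, sample_id, rng)


def simulate_sample(
    config: SimulationConfig,
    reference: ReferenceSet,
    sample_id: str = "sample",
) -> tuple[list[Read], GroundTruth]:
    """Simulate one sample's reads plus its ground truth."""
    config.validate()
    rng = _sample_rng(config.seed, sample_id)
    n_spikes = (config.spike_mait > 0) + (config.spike_inkt > 0)
    n_conv = config.n_clones - n_spikes
    if n_conv < 1:
        raise ParameterError("n_clones leaves no conventional clones after spikes")
    forbidden: set = set()
    n_nonprod = int(round(config.nonproductive_fraction * n_conv))
    # productive clones are drawn first and therefore take the dominant
    # abundance slots; out-of-frame clones occupy the tail
    conventional = [
        _draw_clone(rng, reference, config, forbidden,
                    productive=(i < n_conv - n_nonprod))
        for i in range(n_conv)
    ]
    return _assemble_sample(config, reference, sample_id, conventional, rng, forbidden)


def simulate_cross_reactive_experiment(
    config: SimulationConfig,
    reference: ReferenceSet,
) -> dict[str, tuple[list[Read], GroundTruth]]:
    """Simulate the two-group design with planted shared clonotypes.

    Returns ``{"Ni-Pd": (reads, truth), "Cr-Pd": (reads, truth)}``.  The
    true clone sets of the two samples intersect in exactly
    ``round(shared_fraction * n_clones)`` clonotypes; the shared clones
    occupy the top abundance slots, led by the dominant TRAV8D-1/TRAJ49
    and TRAV5-1/TRAJ37 clonotypes when those genes are present.
    """
    config.validate()
    n_shared = int(round(config.shared_fraction * config.n_clones))
    n_spikes = (config.spike_mait > 0) + (config.spike_inkt > 0)
    n_conv = config.n_clones - n_spikes
    if n_conv < 1:
        raise ParameterError("n_clones leaves no conventional clones after spikes")
    if n_shared > n_conv:
        raise ParameterError(
            f"{n_shared} shared clones exceed the {n_conv} conventional slots"
        )

    shared_rng = _sample_rng(config.seed, "shared-clones")
    forbidden: set = set()
    shared: list[TrueClone] = []
    for i in range(n_shared):
        v_name = j_name = None
        if i < len(DOMINANT_PAIRS):
            cand_v, cand_j = DOMINANT_PAIRS[i]
            if cand_v in reference and cand_j in reference:
                v_name, j_name = cand_v, cand_j
        shared.append(
            _draw_clone(shared_rng, reference, config, forbidden, v_name, j_name)
        )

    out: dict[str, tuple[list[Read], GroundTruth]] = {}
    for sample_id in (GROUP_A, GROUP_B):
        rng = _sample_rng(config.seed, sample_id)
        sample_forbidden = set(forbidden)
        private = [
            _draw_clone(rng, reference, config, sample_forbidden)
            for _ in range(n_conv - n_shared)
        ]
        out[sample_id] = _assemble_sample(
            config, reference, sample_id, shared + private, rng, sample_forbidden
        )
        # private and spike keys of this sample must not reappear in the next
        forbidden = sample_forbidden
    return out


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    """Write reads as FASTQ with constant quality 'I' (Q40)."""
    with open(path, "w") as handle:
        for read in reads:
            handle.write(
                f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n"
            )


def write_truth(
    truth: GroundTruth, clone_path: str | Path, origin_path: str | Path,
    header: str = "",
) -> None:
    """Write the true clone table and the read-origin map as TSVs."""
    with open(clone_path, "w") as handle:
        if header:
            handle.write(header)
        handle.write(
            "clone_index\tv_call\tj_call\tjunction\tjunction_aa\t"
            "frequency\tproductive\n"
        )
        for i, c in enumerate(truth.clones):
            handle.write(
                f"{i}\t{c.v_name}\t{c.j_name}\t{c.junction_nt}\t{c.cdr3_aa}\t"
                f"{c.frequency:.10g}\t{'T' if c.productive else 'F'}\n"
            )
    with open(origin_path, "w") as handle:
        if header:
            handle.write(header)
        handle.write("read_id\tclone_index\tn_errors\terror_positions\n")
        for read_id, idx in truth.per_read_origin.items():
            pos = truth.error_positions.get(read_id, [])
            handle.write(
                f"{read_id}\t{idx}\t{len(pos)}\t{','.join(map(str, pos))}\n"
            )
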