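"""Clonotype collapse, copy counting, ranking and V–J usage.

A unique sequence read ("clonotype") is a read having no identity in TRAV,
TRAJ and the deduced amino-acid CDR3 with any other read: annotations are
grouped by exact string equality of ``(v_call, j_call, cdr3_aa)``.  Copy
numbers are the group sizes, ranks order clonotypes by descending copy
number (ties broken lexicographically for reproducibility), and percentage
occurrence frequencies are copy counts over the productive counted reads.
Nonproductive or failed reads are not counted, only tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .annotate import ReadAnnotation
from .errors import ParameterError

ClonotypeKey = tuple[str, str, str]


@dataclass
class Clonotype:
    """One (V, J, CDR3-aa) clonotype with its count, rank and frequency."""

    v_call: str
    j_call: str
    cdr3_aa: str
    copy_count: int
    rank: int = 0
    frequency_pct: float = 0.0

    @property
    def key(self) -> ClonotypeKey:
        return (self.v_call, self.j_call, self.cdr3_aa)


@dataclass
class RepertoireProfile:
    """One sample's ranked clonotype table plus V–J usage counts."""

    sample_id: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    total_counted_reads: int = 0
    n_failed_reads: int = 0

    @property
    def vj_matrix(self) -> pd.DataFrame:
        """V gene × J gene summed copy counts."""
        if not self.clonotypes:
            return pd.DataFrame()
        df = self.to_dataframe()
        return (
            df.pivot_table(
                index="v_call", columns="j_call", values="copy_count",
                aggfunc="sum", fill_value=0,
            )
            .sort_index(axis=0)
            .sort_index(axis=1)
        )

    def get(self, key: ClonotypeKey) -> Clonotype | None:
        for c in self.clonotypes:
            if c.key == key:
                return c
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": self.sample_id,
                    "rank": c.rank,
                    "v_call": c.v_call,
                    "j_call": c.j_call,
                    "junction_aa": c.cdr3_aa,
                    "copy_count": c.copy_count,
                    "frequency_pct": c.frequency_pct,
                }
                for c in self.clonotypes
            ],
            columns=[
                "sample_id", "rank", "v_call", "j_call", "junction_aa",
                "copy_count", "frequency_pct",
            ],
        )


def build_clonotypes(
    annotations: Iterable[ReadAnnotation], sample_id: str
) -> RepertoireProfile:
    """Collapse one sample's annotations into a ranked clonotype profile."""
    counts: dict[ClonotypeKey, int] = {}
    n_failed = 0
    for ann in annotations:
        if ann.productive and ann.v_call and ann.j_call and ann.cdr3_aa:
            key = (ann.v_call, ann.j_call, ann.cdr3_aa)
            counts[key] = counts.get(key, 0) + 1
        else:
            n_failed += 1
    # rank by descending copy count; lexicographic key order breaks ties
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    clonotypes = [
        Clonotype(v, j, aa, copy_count=n, rank=i + 1)
        for i, ((v, j, aa), n) in enumerate(ordered)
    ]
    profile = RepertoireProfile(
        sample_id=sample_id,
        clonotypes=clonotypes,
        total_counted_reads=sum(counts.values()),
        n_failed_reads=n_failed,
    )
    if profile.total_counted_reads:
        compute_frequencies(profile)
    return profile


def compute_frequencies(profile: RepertoireProfile) -> RepertoireProfile:
    """(Re)compute percentage occurrence frequencies in place; idempotent."""
    total = profile.total_counted_reads
    if total < 1:
        raise ParameterError(
            f"{profile.sample_id}: no counted reads, frequencies undefined"
        )
    for c in profile.clonotypes:
        c.frequency_pct = 100.0 * c.copy_count / total
    return profile


def vj_usage_matrix(profile: RepertoireProfile) -> pd.DataFrame:
    """Percentage of counted reads per (V gene, J gene) pair; sums to 100."""
    if profile.total_counted_reads < 1:
        raise ParameterError(
            f"{profile.sample_id}: no counted reads, usage undefined"
        )
    return profile.vj_matrix * (100.0 / profile.total_counted_reads)


def merge_profiles(
    a: RepertoireProfile, b: RepertoireProfile, sample_id: str
) -> RepertoireProfile:
    """Pool two profiles by summing copy counts per clonotype key."""
    counts: dict[ClonotypeKey, int] = {}
    for profile in (a, b):
        for c in profile.clonotypes:
            counts[c.key] = counts.get(c.key, 0) + c.copy_count
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    merged = RepertoireProfile(
        sample_id=sample_id,
        clonotypes=[
            Clonotype(v, j, aa, copy_count=n, rank=i + 1)
            for i, ((v, j, aa), n) in enumerate(ordered)
        ],
        total_counted_reads=a.total_counted_reads + b.total_counted_reads,
        n_failed_reads=a.n_failed_reads + b.n_failed_reads,
    )
    if merged.total_counted_reads:
        compute_frequencies(merged)
    return merged


def write_clonotype_tsv(
    profile: RepertoireProfile, path: str | Path, header: str = ""
) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(header)
        profile.to_dataframe().to_csv(handle, sep="\t", index=False)


def read_clonotype_tsv(path: str | Path) -> RepertoireProfile:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    clonotypes = [
        Clonotype(
            v_call=str(r.v_call),
            j_call=str(r.j_call),
            cdr3_aa=str(r.junction_aa),
            copy_count=int(r.copy_count),
            rank=int(r.rank),
            frequency_pct=float(r.frequency_pct),
        )
        for r in df.itertuples(index=False)
    ]
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else ""
    return RepertoireProfile(
        sample_id=sample_id,
        clonotypes=clonotypes,
        total_counted_reads=sum(c.copy_count for c in clonotypes),
    )
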