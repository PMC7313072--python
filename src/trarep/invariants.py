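"""Invariant T-cell flagging and cross-sample shared clonotypes.

MAIT cells carry the canonical Trav1–Traj33 α chain and iNKT cells carry
Trav11d–Traj18; a clonotype is flagged by its V–J pair alone (the CDR3 is
not consulted).  Mouse duplicate-locus naming varies across references, so
an alias table (default: TRAV11D → TRAV11) is applied before matching.

Sharing between two samples is the exact intersection of clonotype keys
(V, J, CDR3-aa); no frequency threshold is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .clonotype import Clonotype, RepertoireProfile
from .reference import normalize_gene_name

#: duplicate-locus aliases applied before invariant matching
DEFAULT_ALIASES: dict[str, str] = {"TRAV11D": "TRAV11"}


@dataclass(frozen=True)
class InvariantRule:
    """One canonical invariant receptor: label plus its V–J pair."""

    label: str
    v_name: str
    j_name: str


#: the two canonical invariant α chains
DEFAULT_RULES: tuple[InvariantRule, ...] = (
    InvariantRule("MAIT", "TRAV1", "TRAJ33"),
    InvariantRule("iNKT", "TRAV11", "TRAJ18"),
)


@dataclass
class SharedClonotypeReport:
    """Clonotypes present in both samples, with both frequencies."""

    sample_a_id: str
    sample_b_id: str
    shared: list[tuple[str, str, str, float, float]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.shared,
            columns=["v_call", "j_call", "junction_aa", "freq_in_a", "freq_in_b"],
        )


def _canon(name: str, aliases: Mapping[str, str]) -> str:
    norm = normalize_gene_name(name)
    return aliases.get(norm, norm)


def flag_invariant(
    clonotype: Clonotype,
    rules: Iterable[InvariantRule] = DEFAULT_RULES,
    aliases: Mapping[str, str] = DEFAULT_ALIASES,
) -> str | None:
    """Label of the first rule matching the clonotype's V–J pair, else None."""
    v = _canon(clonotype.v_call, aliases)
    j = _canon(clonotype.j_call, aliases)
    for rule in rules:
        if (_canon(rule.v_name, aliases), _canon(rule.j_name, aliases)) == (v, j):
            return rule.label
    return None


def find_shared_clonotypes(
    profile_a: RepertoireProfile, profile_b: RepertoireProfile
) -> SharedClonotypeReport:
    """Exact clonotype-key intersection of two profiles.

    Entries are ordered by descending ``min(freq_in_a, freq_in_b)`` (key
    lexicographic on ties), with both percentage frequencies attached.
    """
    freqs_b = {c.key: c.frequency_pct for c in profile_b.clonotypes}
    rows = [
        (c.v_call, c.j_call, c.cdr3_aa, c.frequency_pct, freqs_b[c.key])
        for c in profile_a.clonotypes
        if c.key in freqs_b
    ]
    rows.sort(key=lambda r: (-min(r[3], r[4]), r[:3]))
    return SharedClonotypeReport(profile_a.sample_id, profile_b.sample_id, rows)


def top_clonotype_table(
    profile: RepertoireProfile,
    k: int,
    rules: Iterable[InvariantRule] = DEFAULT_RULES,
    aliases: Mapping[str, str] = DEFAULT_ALIASES,
) -> pd.DataFrame:
    """Top-k clonotypes by rank, annotated with invariant labels."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rules = tuple(rules)
    top = sorted(profile.clonotypes, key=lambda c: c.rank)[:k]
    df = pd.DataFrame(
        [
            {
                "sample_id": profile.sample_id,
                "rank": c.rank,
                "v_call": c.v_call,
                "j_call": c.j_call,
                "junction_aa": c.cdr3_aa,
                "copy_count": c.copy_count,
                "frequency_pct": c.frequency_pct,
                "invariant": flag_invariant(c, rules, aliases) or "",
            }
            for c in top
        ],
        columns=[
            "sample_id", "rank", "v_call", "j_call", "junction_aa",
            "copy_count", "frequency_pct", "invariant",
        ],
    )
    return df


def load_rules(path: str | Path) -> tuple[InvariantRule, ...]:
    """Read a 3-column TSV rules file (label, v_name, j_name)."""
    rules: list[InvariantRule] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed invariant rule line: {line!r}")
        rules.append(InvariantRule(fields[0], fields[1], fields[2]))
    return tuple(rules)
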