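"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package: the alignment oracle is
a plain-Python three-matrix dynamic program, and the sharing oracle is a
quadratic double loop.
"""

from __future__ import annotations

NEG = float("-inf")


def local_affine_score(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -1,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> int:
    """Optimal Smith-Waterman score with affine gaps.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; an ``N``
    scores as a mismatch against every base including ``N``.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            ai, bj = a[i - 1].upper(), b[j - 1].upper()
            s = match if (ai == bj and ai in "ACGT") else mismatch
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def brute_shared_keys(profile_a, profile_b):
    """All clonotype keys present in both profiles, by double loop."""
    out = set()
    for ca in profile_a.clonotypes:
        for cb in profile_b.clonotypes:
            if (ca.v_call, ca.j_call, ca.cdr3_aa) == (
                cb.v_call,
                cb.j_call,
                cb.cdr3_aa,
            ):
                out.add((ca.v_call, ca.j_call, ca.cdr3_aa))
    return out
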