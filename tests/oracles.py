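"""Independent brute-force oracles used to check the production code.

These deliberately take the dumbest correct route — enumerate every
substring / every start position — and share no code with the package.
"""

from __future__ import annotations


def oracle_scan_positions(sequence: str, motif: str) -> list[int]:
    """1-based start positions of every (overlapping) motif occurrence."""
    return [
        i + 1
        for i in range(len(sequence) - len(motif) + 1)
        if sequence[i : i + len(motif)] == motif
    ]


def oracle_cleavage_sites(
    sequence: str, residues: set[str], proline_rule: bool
) -> set[int]:
    sites = set()
    for i in range(len(sequence) - 1):
        if sequence[i] in residues and not (proline_rule and sequence[i + 1] == "P"):
            sites.add(i)
    return sites


def oracle_digest(
    sequence: str,
    residues: set[str],
    proline_rule: bool,
    max_missed: int,
    min_length: int,
) -> set[tuple[str, int, int, int]]:
    """All (sequence, start, end, missed) digestion products, found by
    filtering every substring on boundary and site conditions."""
    sites = oracle_cleavage_sites(sequence, residues, proline_rule)
    boundaries = {0} | {i + 1 for i in sites} | {len(sequence)}
    out = set()
    for a in range(len(sequence)):
        for b in range(a + 1, len(sequence) + 1):
            if a not in boundaries or b not in boundaries:
                continue
            internal = sum(1 for i in sites if a <= i and i + 1 < b)
            if internal > max_missed or b - a < min_length:
                continue
            out.add((sequence[a:b], a + 1, b, internal))
    return out


def oracle_longest_shared(peptide: str, motif: str) -> int:
    """Length of the longest contiguous motif substring in the peptide."""
    best = 0
    for j in range(len(motif)):
        for k in range(j + 1, len(motif) + 1):
            if motif[j:k] in peptide:
                best = max(best, k - j)
    return best
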