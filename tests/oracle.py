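"""Brute-force SSR oracle, independent of the production scanner.

Enumerates every (start, period) pair, counts full perfect repeat units
by direct string comparison, and resolves overlapping candidates
leftmost-longest (then shortest-period). O(n^2)-ish; for test use only.
"""

from __future__ import annotations


def _minimal_period_len(unit: str) -> int:
    n = len(unit)
    for d in range(1, n + 1):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return d
    return n


def brute_force_ssrs(
    residues: str, thresholds: dict[int, int] | None = None
) -> list[tuple[int, int, int]]:
    """All maximal perfect runs as (start_1based, period, n_repeats)."""
    thresholds = thresholds or {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    n = len(residues)
    candidates: list[tuple[int, int, int]] = []
    for start in range(n):
        for p, min_rep in thresholds.items():
            unit = residues[start : start + p]
            if len(unit) < p or set(unit) - set("ACGT"):
                continue
            if _minimal_period_len(unit) != p:
                continue
            k = 1
            while residues[start + k * p : start + (k + 1) * p] == unit:
                k += 1
            if k >= min_rep:
                candidates.append((start, p, k))
    # identical resolution rule to the scanner: leftmost, longest, shortest period
    candidates.sort(key=lambda c: (c[0], -(c[1] * c[2]), c[1]))
    chosen: list[tuple[int, int, int]] = []
    max_end = -1
    for i0, p, k in candidates:
        if i0 > max_end:
            chosen.append((i0 + 1, p, k))
            max_end = i0 + p * k - 1
    return chosen
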