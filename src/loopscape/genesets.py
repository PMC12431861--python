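"""Set-overlap arithmetic for differential-gene comparisons.

Given the number of genes called differential in each of two conditions
and the size of the union of the two calls, inclusion-exclusion yields
the shared count and its percentage of the union — the summary used when
comparing condition-specific regulons.
"""

from __future__ import annotations

__all__ = ["shared_count", "shared_percent"]


def shared_count(n_a: int, n_b: int, n_union: int) -> int:
    """|A ∩ B| from |A|, |B| and |A ∪ B| by inclusion-exclusion."""
    n_shared = n_a + n_b - n_union
    if n_shared < 0 or n_shared > min(n_a, n_b):
        raise ValueError(
            f"inconsistent counts: |A|={n_a}, |B|={n_b}, |A∪B|={n_union}"
        )
    return n_shared


def shared_percent(n_a: int, n_b: int, n_union: int, ndigits: int = 1) -> float:
    """Shared genes as a percentage of the union, rounded for reporting."""
    return round(100.0 * shared_count(n_a, n_b, n_union) / n_union, ndigits)
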