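"""Small deterministic arithmetic over published summary counts.

These helpers re-derive the bookkeeping numbers a study reports (map
coverage, gene-model overlap percentages) from its printed counts; they do
no estimation of their own.
"""

from __future__ import annotations


def marker_density(n_markers: int, map_length_cM: float) -> float:
    """Mean map coverage in markers per cM."""
    if map_length_cM <= 0:
        raise ValueError("map length must be positive")
    return n_markers / map_length_cM


def gene_model_venn(n_total: int, n_triple: int, pairwise: dict[str, int]) -> dict:
    """Three-set overlap percentages from printed gene-model counts.

    ``pairwise`` holds the counts shared by exactly two genomes. The unique
    count is what remains after the triple- and double-shared models.
    Percentages are of the total, rounded to whole percent as such tallies
    are usually reported.
    """
    n_pair = sum(pairwise.values())
    n_unique = n_total - n_triple - n_pair
    if n_unique < 0:
        raise ValueError("overlap counts exceed the total")
    return {
        "n_unique": n_unique,
        "pct_triple_shared": round(100.0 * n_triple / n_total),
        "pct_unique": round(100.0 * n_unique / n_total),
        "pct_pairwise": {k: round(100.0 * v / n_total) for k, v in pairwise.items()},
    }
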