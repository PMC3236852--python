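"""Synthetic pathway fixture for the case-study harness.

A 4-gene DNA-damage-response module in the style of the ATM-p53-Wip1-Mdm2
circuit: ATM is repressed by Wip1, p53 is activated by ATM and repressed by
Mdm2, Wip1 is induced by p53, and Mdm2 is induced by p53/Wip1 and repressed
by ATM.  The don't-care map marks 12 truth-table entries as undetermined, so
the induced uncertainty class contains exactly 2**12 = 4096 networks.

This fixture is SYNTHETIC: it mirrors the structure (4 genes, full-state
truth columns, 12 undetermined entries) of published pathway-derived maps
but is not a transcription of any published truth table.
"""

from __future__ import annotations

from .networks import BooleanNetwork, DontCareMap, index_to_state

__all__ = ["GENE_NAMES", "p53_family_map", "p53_normal_network"]

GENE_NAMES = ("ATM", "p53", "Wip1", "Mdm2")

# per-gene state indices whose next value the pathway knowledge leaves open
_X_POSITIONS = {
    0: (3, 7, 11),    # ATM
    1: (1, 6, 13),    # p53
    2: (2, 9, 14),    # Wip1
    3: (4, 8, 12),    # Mdm2
}


def _rule(gene: int, state) -> int:
    atm, p53, wip1, mdm2 = state
    if gene == 0:
        return 1 - wip1                      # ATM = NOT Wip1
    if gene == 1:
        return atm & (1 - mdm2)              # p53 = ATM AND NOT Mdm2
    if gene == 2:
        return p53                           # Wip1 = p53
    return (p53 | wip1) & (1 - atm)          # Mdm2 = (p53 OR Wip1) AND NOT ATM


def p53_normal_network() -> BooleanNetwork:
    """The designated normal network: the map's rule-consistent completion."""
    n = 4
    predictors = tuple(tuple(range(n)) for _ in range(n))
    tables = tuple(
        tuple(_rule(g, index_to_state(s, n)) for s in range(1 << n))
        for g in range(n))
    return BooleanNetwork(n, predictors, tables)


def p53_family_map() -> DontCareMap:
    """Don't-care map with 12 undetermined entries (family size 4096)."""
    n = 4
    cols = []
    for g in range(n):
        col = [str(_rule(g, index_to_state(s, n))) for s in range(1 << n)]
        for s in _X_POSITIONS[g]:
            col[s] = "X"
        cols.append("".join(col))
    return DontCareMap(n, tuple(cols))
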