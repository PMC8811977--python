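"""Carbon pool naming and index conventions.

The model tracks 14 per-cell carbon pools (tons C/ha): five live pools and
nine dead organic matter (DOM) pools named by position (above/belowground)
and decay speed.  Array-valued state throughout the package uses the fixed
ordering defined here.
"""

from __future__ import annotations

LIVE_POOLS: tuple[str, ...] = (
    "Merchantable",
    "Foliage",
    "OtherWood",
    "CoarseRoot",
    "FineRoot",
)

DOM_POOLS: tuple[str, ...] = (
    "SnagStem",
    "SnagBranch",
    "AbovegroundMedium",
    "AbovegroundFast",
    "AbovegroundVeryFast",
    "AbovegroundSlow",
    "BelowgroundFast",
    "BelowgroundVeryFast",
    "BelowgroundSlow",
)

ALL_POOLS: tuple[str, ...] = LIVE_POOLS + DOM_POOLS

N_LIVE = len(LIVE_POOLS)
N_DOM = len(DOM_POOLS)
N_POOLS = len(ALL_POOLS)

POOL_INDEX: dict[str, int] = {name: i for i, name in enumerate(ALL_POOLS)}
#: index of a DOM pool within the 9-element DOM block
DOM_INDEX: dict[str, int] = {name: i for i, name in enumerate(DOM_POOLS)}

LIVE_SLICE = slice(0, N_LIVE)
DOM_SLICE = slice(N_LIVE, N_POOLS)

#: DOM pools that sit above ground; the non-emitted fraction of their decay
#: is transferred to AbovegroundSlow (belowground pools feed BelowgroundSlow).
ABOVEGROUND_DOM: frozenset[str] = frozenset(
    {"SnagStem", "SnagBranch", "AbovegroundMedium", "AbovegroundFast",
     "AbovegroundVeryFast", "AbovegroundSlow"}
)

#: pseudo-destinations used in disturbance matrices
ATMOSPHERE = "atmosphere"
EXPORT = "export"
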