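"""Deterministic, numeric-aware total order on node labels.

Every tie-break in the package (density ties, candidate ordering, gain
ties) funnels through this key so that results are reproducible and
independent of input ordering.
"""

from __future__ import annotations

import re

_CHUNK = re.compile(r"(\d+)")


def natural_key(label: str) -> tuple:
    """Sort key ordering ``"2" < "10"`` and ``"a2" < "a10" < "b1"``.

    Digit runs compare numerically, everything else lexicographically.
    """
    parts = _CHUNK.split(str(label))
    key: list[tuple[int, object]] = []
    for i, part in enumerate(parts):
        if i % 2:  # digit run
            key.append((0, int(part)))
        elif part:
            key.append((1, part))
    return tuple(key)


def sorted_nodes(nodes) -> list:
    return sorted(nodes, key=natural_key)
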