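"""Fixed module color sequence.

Modules are labeled by color in decreasing order of size, so "turquoise"
is always the largest module of a network, "blue" the second largest, and
so on. The reserved label ``grey`` marks background genes that belong to
no module and is never handed out by :func:`color_sequence`.
"""

from __future__ import annotations

from typing import Iterator

GREY = "grey"

#: Color labels handed out to modules in decreasing size order.
COLOR_SEQUENCE: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown",
    "steelblue", "paleturquoise", "violet", "darkolivegreen",
    "darkmagenta", "sienna", "yellowgreen", "skyblue3", "plum",
    "orangered", "mediumpurple",
)


def color_sequence(skip: set[str] | None = None) -> Iterator[str]:
    """Yield module color labels in the canonical order, indefinitely.

    After the named colors are exhausted, synthetic labels ``module41``,
    ``module42``, ... are produced so arbitrarily many modules can be
    labeled. Labels in *skip* (plus ``grey``) are never yielded.
    """
    skip = set(skip or ())
    skip.add(GREY)
    for c in COLOR_SEQUENCE:
        if c not in skip:
            yield c
    i = len(COLOR_SEQUENCE) + 1
    while True:
        c = f"module{i}"
        if c not in skip:
            yield c
        i += 1
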