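"""Qualitative ColorBrewer palettes used for dynamic-community coloring.

Hex values are the standard ColorBrewer qualitative schemes; they are
embedded here so that color assignment is fully deterministic and has no
runtime dependency.
"""

QUALITATIVE: dict[str, list[str]] = {
    "Set1": [
        "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
        "#ffff33", "#a65628", "#f781bf", "#999999",
    ],
    "Set2": [
        "#66c2a5", "#fc8d62", "#8da0cb", "#e78ac3", "#a6d854",
        "#ffd92f", "#e5c494", "#b3b3b3",
    ],
    "Dark2": [
        "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
        "#e6ab02", "#a6761d", "#666666",
    ],
    "Paired": [
        "#a6cee3", "#1f78b4", "#b2df8a", "#33a02c", "#fb9a99",
        "#e31a1c", "#fdbf6f", "#ff7f00", "#cab2d6", "#6a3d9a",
        "#ffff99", "#b15928",
    ],
}

DEFAULT_PALETTE = "Set1"


def get_palette(name: str) -> list[str]:
    """Return the hex color list for a qualitative palette.

    Raises
    ------
    KeyError
        If ``name`` is not a known palette.
    """
    try:
        return list(QUALITATIVE[name])
    except KeyError:
        raise KeyError(
            f"unknown palette {name!r}; available: {sorted(QUALITATIVE)}"
        ) from None
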