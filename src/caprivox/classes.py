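"""The 8-class vocalization context dictionary.

Goat calls are labeled by the context / putative emotional state in which
they were recorded.  The dictionary is fixed at eight classes; everything
downstream (folds, confusion matrices, heatmaps) indexes classes in this
order.
"""

from __future__ import annotations

CLASSES: tuple[str, ...] = (
    "heat",
    "feed",
    "parturition",
    "injury_death",
    "isolation",
    "reunion",
    "visitors",
    "separation",
)

CLASS_INDEX: dict[str, int] = {name: i for i, name in enumerate(CLASSES)}


def class_index(label: str) -> int:
    """Index of ``label`` in the class dictionary; raises on unknown labels."""
    try:
        return CLASS_INDEX[label]
    except KeyError:
        raise ValueError(
            f"unknown class label {label!r}; expected one of {CLASSES}"
        ) from None
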