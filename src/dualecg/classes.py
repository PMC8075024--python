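"""AAMI heartbeat class vocabulary shared across the package.

The ANSI/AAMI EC57 standard groups the MIT-BIH beat vocabulary into five
superclasses; the unclassifiable Q group is excluded here, leaving the four
classes this classifier predicts.
"""

from __future__ import annotations

# Canonical class order used for labels, confusion matrices and weights.
AAMI_CLASSES: tuple[str, ...] = ("N", "VEB", "SVEB", "F")

#: Sentinel for beats outside the four target classes (paced, unclassifiable,
#: non-beat annotations).
EXCLUDED = "EXCLUDED"

N_CLASSES = len(AAMI_CLASSES)

CLASS_TO_INDEX = {c: i for i, c in enumerate(AAMI_CLASSES)}


def class_index(label: str) -> int:
    """Map a class label to its canonical index, rejecting EXCLUDED."""
    try:
        return CLASS_TO_INDEX[label]
    except KeyError:
        raise ValueError(
            f"label {label!r} is not one of the four AAMI classes {AAMI_CLASSES}"
        ) from None
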