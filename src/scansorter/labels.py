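"""The eight scan-type classes and their frozen ordering.

The order is part of every persisted model artifact: predictions are
8-vectors indexed by this list, and permuting it would silently relabel
every output.  Treat it as an on-disk format constant.
"""

from __future__ import annotations

CLASS_LABELS: tuple[str, ...] = (
    "T1w",
    "T1wC",
    "T2w",
    "PDw",
    "T2w-FLAIR",
    "DWI",
    "PWI-DSC",
    "derived",
)

N_CLASSES = len(CLASS_LABELS)

#: scan types that may legitimately carry a temporal / b-value dimension
FOUR_D_CAPABLE: frozenset[str] = frozenset({"DWI", "PWI-DSC"})

ORIENTATIONS: tuple[str, ...] = ("axial", "coronal", "sagittal", "threeD")


def class_index(label: str) -> int:
    """Index of ``label`` in the frozen class order.

    Raises ``ValueError`` with the list of valid labels for anything else.
    """
    try:
        return CLASS_LABELS.index(label)
    except ValueError:
        raise ValueError(
            f"unknown scan type {label!r}; expected one of {list(CLASS_LABELS)}"
        ) from None
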