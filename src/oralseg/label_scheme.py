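"""The 36-structure instance label scheme for dental CBCT.

32 individual teeth coded by the FDI two-digit system (quadrant 1-4 x position
1-8), plus the maxilla, the mandible, and the two mandibular canals.  Internal
class indices are 1..36 in FDI quadrant order (11..18, 21..28, 31..38, 41..48
-> 1..32), maxilla=33, mandible=34, left canal=35, right canal=36; index 0 is
background.  "Left" is patient-left in patient coordinates (radiological
display mirrors it).  The index<->FDI mapping is part of the public contract
and is serialized alongside every segmentation this package writes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SchemeEntry", "LabelScheme", "default_scheme", "merge_to_semantic",
           "SEMANTIC_BACKGROUND", "SEMANTIC_TEETH", "SEMANTIC_MAXILLA",
           "SEMANTIC_MANDIBLE", "SEMANTIC_CANAL"]

SEMANTIC_BACKGROUND = 0
SEMANTIC_TEETH = 1
SEMANTIC_MAXILLA = 2
SEMANTIC_MANDIBLE = 3
SEMANTIC_CANAL = 4

_FDI_ORDER = [q * 10 + p for q in (1, 2, 3, 4) for p in range(1, 9)]

_POSITION_NAMES = ["central incisor", "lateral incisor", "canine",
                   "first premolar", "second premolar", "first molar",
                   "second molar", "third molar"]
_QUADRANT_NAMES = {1: "upper right", 2: "upper left",
                   3: "lower left", 4: "lower right"}


@dataclass(frozen=True)
class SchemeEntry:
    index: int
    name: str
    fdi_code: int | None
    color: tuple[int, int, int]
    semantic_group: str  # tooth | maxilla | mandible | canal


@dataclass(frozen=True)
class LabelScheme:
    entries: tuple[SchemeEntry, ...]
    _by_fdi: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "_by_fdi",
                           {e.fdi_code: e for e in self.entries if e.fdi_code})

    @property
    def num_classes(self) -> int:
        """Foreground classes (background excluded)."""
        return len(self.entries)

    def entry(self, index: int) -> SchemeEntry:
        e = self.entries[index - 1]
        assert e.index == index
        return e

    def fdi_to_index(self, fdi_code: int) -> int:
        if fdi_code not in self._by_fdi:
            raise KeyError(f"unknown FDI code {fdi_code}")
        return self._by_fdi[fdi_code].index

    def index_to_fdi(self, index: int) -> int | None:
        return self.entry(index).fdi_code

    @property
    def tooth_indices(self) -> list[int]:
        return [e.index for e in self.entries if e.semantic_group == "tooth"]

    def semantic_index(self, index: int) -> int:
        group = self.entry(index).semantic_group
        return {"tooth": SEMANTIC_TEETH, "maxilla": SEMANTIC_MAXILLA,
                "mandible": SEMANTIC_MANDIBLE, "canal": SEMANTIC_CANAL}[group]

    # -- serialisation -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps([{"index": e.index, "name": e.name,
                            "fdi_code": e.fdi_code, "color": list(e.color),
                            "semantic_group": e.semantic_group}
                           for e in self.entries], indent=2)

    @staticmethod
    def from_json(text: str) -> "LabelScheme":
        rows = json.loads(text)
        return LabelScheme(tuple(
            SchemeEntry(r["index"], r["name"], r["fdi_code"],
                        tuple(r["color"]), r["semantic_group"]) for r in rows))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @staticmethod
    def load(path: str | Path) -> "LabelScheme":
        return LabelScheme.from_json(Path(path).read_text())


def _tooth_color(i: int) -> tuple[int, int, int]:
    # deterministic, well-separated hues (golden-angle walk around the wheel)
    h = (i * 137.508) % 360.0
    c, x = 200, int(200 * (1 - abs((h / 60.0) % 2 - 1)))
    sector = int(h // 60) % 6
    rgb = [(c, x, 0), (x, c, 0), (0, c, x), (0, x, c), (x, 0, c), (c, 0, x)][sector]
    return tuple(min(255, v + 40) for v in rgb)


def default_scheme() -> LabelScheme:
    """The canonical 36-entry scheme (deterministic across versions)."""
    entries: list[SchemeEntry] = []
    for i, fdi in enumerate(_FDI_ORDER, start=1):
        q, p = divmod(fdi, 10)
        name = f"tooth {fdi} ({_QUADRANT_NAMES[q]} {_POSITION_NAMES[p - 1]})"
        entries.append(SchemeEntry(i, name, fdi, _tooth_color(i), "tooth"))
    entries.append(SchemeEntry(33, "maxilla", None, (241, 214, 145), "maxilla"))
    entries.append(SchemeEntry(34, "mandible", None, (177, 122, 101), "mandible"))
    entries.append(SchemeEntry(35, "mandibular canal left", None, (216, 101, 79), "canal"))
    entries.append(SchemeEntry(36, "mandibular canal right", None, (221, 130, 101), "canal"))
    return LabelScheme(tuple(entries))


def merge_to_semantic(lv, scheme: LabelScheme | None = None):
    """Collapse the 36-class instance map to 5 semantic classes.

    0=background, 1=teeth, 2=maxilla, 3=mandible, 4=canal.  A pure voxelwise
    relabelling: total foreground volume is conserved.
    """
    from .volume_io import LabelVolume  # local import to avoid a cycle

    if getattr(lv, "scheme_ref", None) == "semantic-5":  # already merged
        return LabelVolume(labels=lv.labels.copy(), spacing=lv.spacing,
                           origin=lv.origin,
                           axis_orientation=lv.axis_orientation,
                           scheme_ref="semantic-5")
    scheme = scheme or default_scheme()
    labels = np.asarray(lv.labels)
    present = np.unique(labels)
    lut = np.zeros(int(present.max()) + 1 if present.size else 1, dtype=lv.labels.dtype)
    for v in present:
        if v == 0:
            continue
        if v < 1 or v > scheme.num_classes:
            raise ValueError(f"label value {int(v)} is not in the scheme")
        lut[v] = scheme.semantic_index(int(v))
    merged = lut[labels]
    return LabelVolume(labels=merged, spacing=lv.spacing, origin=lv.origin,
                       axis_orientation=lv.axis_orientation,
                       scheme_ref="semantic-5")
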