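"""Template dictionary: (single-sided image, manual breast mask) pairs.

On disk a dictionary is a directory with a ``manifest.json`` listing, per
pair: id, relative image path, relative mask path, and free-form meta tags.
Images are stored as float32 NIfTI, masks as uint8 NIfTI.  All templates
must already be in canonical right-sided orientation (enforced at add
time via the ``flipped``/``side`` provenance of the image volume).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .volumes import (
    SegmentationMask,
    SingleBreastVolume,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

MANIFEST_NAME = "manifest.json"
MANIFEST_VERSION = "1"

__all__ = ["TemplatePair", "TemplateDictionary", "load_dictionary", "save_dictionary"]


@dataclass(frozen=True)
class TemplatePair:
    id: str
    image: SingleBreastVolume
    mask: SegmentationMask
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("template id must be non-empty")
        if self.image.shape != self.mask.shape:
            raise ValueError(f"template {self.id!r}: image/mask shape mismatch")
        if not np.allclose(self.image.spacing, self.mask.spacing, rtol=1e-4):
            raise ValueError(f"template {self.id!r}: image/mask spacing mismatch")
        if self.mask.n_voxels == 0:
            raise ValueError(f"template {self.id!r}: empty mask")


class TemplateDictionary:
    """Ordered collection of validated template pairs with unique ids."""

    def __init__(self, pairs: Optional[List[TemplatePair]] = None,
                 manifest_version: str = MANIFEST_VERSION):
        self.manifest_version = manifest_version
        self._pairs: List[TemplatePair] = []
        self._index: Dict[str, int] = {}
        for p in pairs or []:
            self.add(p)

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        return iter(self._pairs)

    def __contains__(self, tid: str) -> bool:
        return tid in self._index

    @property
    def ids(self) -> List[str]:
        return [p.id for p in self._pairs]

    def get(self, tid: str) -> TemplatePair:
        try:
            return self._pairs[self._index[tid]]
        except KeyError:
            raise KeyError(f"no template with id {tid!r}") from None

    def add(self, pair: TemplatePair) -> "TemplateDictionary":
        """Append a pair; ids must stay unique and images right-canonical."""
        if pair.id in self._index:
            raise ValueError(f"duplicate template id {pair.id!r}")
        # canonical orientation: either a native right side or a flipped left
        if pair.image.side == "left" and not pair.image.flipped:
            raise ValueError(f"template {pair.id!r}: left-sided image not canonicalized")
        self._index[pair.id] = len(self._pairs)
        self._pairs.append(pair)
        return self


def save_dictionary(d: TemplateDictionary, path) -> None:
    """Persist as manifest.json + per-pair NIfTI files."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in d:
        img_rel = f"{p.id}_image.nii.gz"
        msk_rel = f"{p.id}_mask.nii.gz"
        write_volume(p.image.image, p.image.spacing, root / img_rel)
        write_mask(p.mask, root / msk_rel)
        entries.append({
            "id": p.id,
            "image": img_rel,
            "mask": msk_rel,
            "meta": dict(p.meta),
            "side": p.image.side,
            "flipped": p.image.flipped,
        })
    manifest = {"manifest_version": d.manifest_version, "pairs": entries}
    with open(root / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def load_dictionary(path) -> TemplateDictionary:
    """Load and fully validate a dictionary directory."""
    root = Path(path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {root}")
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        entries = manifest["pairs"]
        version = manifest["manifest_version"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"corrupt manifest in {root}: {exc}") from exc

    d = TemplateDictionary(manifest_version=version)
    for e in entries:
        tid = e.get("id", "<missing id>")
        img_path = root / e["image"]
        msk_path = root / e["mask"]
        for f in (img_path, msk_path):
            if not f.exists():
                raise FileNotFoundError(
                    f"template {tid!r}: referenced file {f.name} is missing")
        img_data, spacing = read_volume(img_path)
        mask = read_mask(msk_path)
        img = SingleBreastVolume(
            image=np.clip(img_data, 0.0, 1.0),
            body_mask=(img_data > 0).astype(np.uint8),
            side=e.get("side", "right"),
            flipped=bool(e.get("flipped", False)),
            spacing=spacing,
        )
        d.add(TemplatePair(id=tid, image=img, mask=mask, meta=e.get("meta", {})))
    return d
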