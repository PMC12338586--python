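"""Controlled vocabularies mapping raster class IDs to FTU term names.

A vocabulary interprets the integer labels of a segmentation mask: each
term carries a class ID (the raster value), a display name, and a
hierarchical category path such as ``glandular / tumoral / GP4 /
cribriform``.  ID 0 is hard-reserved for Background and is never a term.

Config files are flat JSON: ``{"organ": ..., "version": ..., "terms":
[{"id": 3, "name": "...", "category_path": [...], "color": [r, g, b]},
...]}``.  Serialization is canonical (sorted keys, two-space indent) so a
save/load cycle is bit-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import VocabularyError

BACKGROUND_ID = 0
BACKGROUND_NAME = "Background"


@dataclass(frozen=True)
class VocabTerm:
    """One controlled-vocabulary term: a raster class ID and its meaning."""

    class_id: int
    name: str
    category_path: tuple[str, ...] = ()
    display_color: tuple[int, int, int] | None = None
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.class_id == BACKGROUND_ID:
            raise VocabularyError(
                f"class ID 0 is reserved for {BACKGROUND_NAME} and cannot be "
                f"assigned to term {self.name!r}"
            )
        if self.class_id < 0:
            raise VocabularyError(f"negative class ID {self.class_id} for {self.name!r}")
        if not self.name:
            raise VocabularyError("term name must be non-empty")


@dataclass(frozen=True)
class ControlledVocabulary:
    """An organ-specific set of FTU terms with ID<->name lookups."""

    terms: tuple[VocabTerm, ...]
    organ: str = ""
    version: str = ""
    _by_id: dict = field(init=False, repr=False, compare=False)
    _by_name: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.terms:
            raise VocabularyError("vocabulary has no terms")
        by_id: dict[int, VocabTerm] = {}
        by_name: dict[str, VocabTerm] = {}
        for t in self.terms:
            if t.class_id in by_id:
                raise VocabularyError(
                    f"duplicate class ID {t.class_id}: "
                    f"{by_id[t.class_id].name!r} vs {t.name!r}"
                )
            if t.name in by_name:
                raise VocabularyError(f"duplicate term name {t.name!r}")
            by_id[t.class_id] = t
            by_name[t.name] = t
        object.__setattr__(self, "_by_id", by_id)
        object.__setattr__(self, "_by_name", by_name)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, class_id: int) -> bool:
        return class_id in self._by_id

    @property
    def class_ids(self) -> list[int]:
        return sorted(self._by_id)

    def term(self, class_id: int) -> VocabTerm:
        try:
            return self._by_id[class_id]
        except KeyError:
            raise VocabularyError(
                f"class ID {class_id} not in {self.organ or 'this'} vocabulary"
            ) from None

    def id_to_name(self, class_id: int) -> str:
        if class_id == BACKGROUND_ID:
            return BACKGROUND_NAME
        return self.term(class_id).name

    def name_to_id(self, name: str) -> int:
        if name == BACKGROUND_NAME:
            return BACKGROUND_ID
        try:
            return self._by_name[name].class_id
        except KeyError:
            raise VocabularyError(
                f"term {name!r} not in {self.organ or 'this'} vocabulary"
            ) from None


def _term_from_dict(d: dict, where: str) -> VocabTerm:
    for key in ("id", "name"):
        if key not in d:
            raise VocabularyError(f"{where}: term entry missing {key!r}")
    color = d.get("color")
    return VocabTerm(
        class_id=int(d["id"]),
        name=str(d["name"]),
        category_path=tuple(d.get("category_path", ())),
        display_color=tuple(color) if color is not None else None,
        provisional=bool(d.get("provisional", False)),
    )


def load_vocabulary(path: str | Path) -> ControlledVocabulary:
    """Load and validate a vocabulary config (the FTU ID-and-class file)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise VocabularyError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict) or "terms" not in raw:
        raise VocabularyError(f"{path}: expected an object with a 'terms' list")
    terms = tuple(_term_from_dict(t, str(path)) for t in raw["terms"])
    return ControlledVocabulary(
        terms=terms, organ=str(raw.get("organ", "")), version=str(raw.get("version", ""))
    )


def save_vocabulary(vocab: ControlledVocabulary, path: str | Path) -> None:
    """Write a vocabulary config in the canonical (bit-stable) encoding."""
    doc = {
        "organ": vocab.organ,
        "version": vocab.version,
        "terms": [
            {
                "id": t.class_id,
                "name": t.name,
                "category_path": list(t.category_path),
                **({"color": list(t.display_color)} if t.display_color else {}),
                **({"provisional": True} if t.provisional else {}),
            }
            for t in vocab.terms
        ],
    }
    Path(path).write_text(
        json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def _load_packaged(name: str) -> ControlledVocabulary:
    ref = resources.files("ftuscope.data") / name
    with resources.as_file(ref) as p:
        return load_vocabulary(p)


def default_prostate_vocabulary() -> ControlledVocabulary:
    """The 17-term prostatic acinar adenocarcinoma vocabulary.

    Covers non-tumoral glands (normal, atrophic), the PIN precursor,
    Gleason-pattern tumoral terms (GP3; the GP4 subtypes cribriform,
    poorly formed, fused, glomeruloid; GP5 subtypes), stromal terms
    (nerve, vascular, inflammation) and artifact.  The GP5 subtype split
    is provisional (flagged in the config) and may be overridden by
    loading a custom config.
    """
    return _load_packaged("prostate_ftu_vocabulary.json")


def default_breast_vocabulary() -> ControlledVocabulary:
    """Breast adenocarcinoma vocabulary derived from the prostate scheme.

    Non-tumoral / precursor / tumoral glandular terms are substituted
    (normal duct and lobule, UDH, ADH, DCIS, LCIS, cribriform, solid —
    "solid" collapsing multiple high-grade patterns into one term) while
    the stromal and artifact terms are retained.
    """
    return _load_packaged("breast_ftu_vocabulary.json")
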