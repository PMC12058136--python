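"""Disease catalog: the ordered set of chronic-condition indicators under study.

The default catalog is the 32-condition chronic-disease battery used in
Spanish multimorbidity surveys, with short codes ``D1``..``D32`` and
human-readable labels. All downstream objects (cohorts, networks,
centrality tables) address diseases by catalog code, never by column
position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

_DEFAULT_LABELS = {
    "D1": "Hypertension",
    "D2": "Infarction",
    "D3": "Coronary disease",
    "D4": "Other heart",
    "D5": "Varicose veins",
    "D6": "Arthrosis",
    "D7": "Cervical pain",
    "D8": "Lumbar pain",
    "D9": "Allergy",
    "D10": "Asthma",
    "D11": "Respiratory disease",
    "D12": "Diabetes",
    "D13": "Stomach ulcer",
    "D14": "Urinary incontinence",
    "D15": "Cholesterol",
    "D16": "Cataracts",
    "D17": "Skin condition",
    "D18": "Constipation",
    "D19": "Hepatic dysfunction",
    "D20": "Depression",
    "D21": "Anxiety",
    "D22": "Other mental",
    "D23": "Stroke",
    "D24": "Migraine",
    "D25": "Haemorrhoids",
    "D26": "Cancer",
    "D27": "Osteoporosis",
    "D28": "Thyroid disease",
    "D29": "Kidney disease",
    "D30": "Prostate/Menopausal problems",
    "D31": "Accidents",
    "D32": "Obesity",
}


@dataclass(frozen=True)
class DiseaseCatalog:
    """Ordered list of disease codes plus display labels.

    Invariants: codes are unique, at least two of them, and every code has
    a label.
    """

    codes: tuple[str, ...]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = tuple(self.codes)
        object.__setattr__(self, "codes", codes)
        if len(codes) < 2:
            raise ValueError("catalog needs at least two disease codes")
        if len(set(codes)) != len(codes):
            raise ValueError("disease codes must be unique")
        labels = dict(self.labels) if self.labels else {c: c for c in codes}
        missing = [c for c in codes if c not in labels]
        if missing:
            raise ValueError(f"labels missing for codes: {missing}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in set(self.codes)

    def index(self, code: str) -> int:
        return self.codes.index(code)

    def label(self, code: str) -> str:
        return self.labels[code]

    @classmethod
    def default(cls) -> "DiseaseCatalog":
        """The standard 32-condition chronic-disease catalog."""
        return cls(codes=tuple(_DEFAULT_LABELS), labels=dict(_DEFAULT_LABELS))

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "DiseaseCatalog":
        codes = tuple(codes)
        return cls(codes=codes, labels={c: c for c in codes})

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({c: self.labels[c] for c in self.codes}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DiseaseCatalog":
        with open(path, encoding="utf-8") as fh:
            mapping = json.load(fh)
        return cls(codes=tuple(mapping), labels=dict(mapping))
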