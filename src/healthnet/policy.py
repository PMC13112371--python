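"""Policy-support scoring.

Pre-classified health-collaboration policy documents are scored with a
multiplicative rubric — base score 1, administrative-level weight
(national=3, provincial=2, municipal=1) and specificity weight
(detailed implementation rules=2, general guidance=1) — and summed into
the per-city annual Policy Support Intensity indicator. Every city in a
document's scope receives the document's full score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

LEVEL_WEIGHTS = {"national": 3.0, "provincial": 2.0, "municipal": 1.0}
SPECIFICITY_WEIGHTS = {"detailed": 2.0, "general": 1.0}


@dataclass(frozen=True)
class PolicyDocument:
    year: int
    level: str
    specificity: str
    scope: frozenset[str]

    def __post_init__(self) -> None:
        if self.level not in LEVEL_WEIGHTS:
            raise ValueError(
                f"unknown policy level {self.level!r}; expected one of {sorted(LEVEL_WEIGHTS)}")
        if self.specificity not in SPECIFICITY_WEIGHTS:
            raise ValueError(
                f"unknown specificity {self.specificity!r}; "
                f"expected one of {sorted(SPECIFICITY_WEIGHTS)}")
        if not self.scope:
            raise ValueError("policy document scope must name at least one city")


@dataclass
class PolicyCorpus:
    documents: list[PolicyDocument] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def merged(self, other: "PolicyCorpus") -> "PolicyCorpus":
        return PolicyCorpus(self.documents + other.documents)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": d.year, "level": d.level, "specificity": d.specificity,
             "cities": ";".join(sorted(d.scope))}
            for d in self.documents
        ]
        return pd.DataFrame(rows, columns=["year", "level", "specificity", "cities"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PolicyCorpus":
        docs = [
            PolicyDocument(
                year=int(row.year), level=str(row.level),
                specificity=str(row.specificity),
                scope=frozenset(str(row.cities).split(";")))
            for row in frame.itertuples()
        ]
        return cls(docs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PolicyCorpus":
        return cls.from_frame(pd.read_csv(path))


def score_policy(doc: PolicyDocument) -> float:
    """Weighted score: 1 x level weight x specificity weight."""
    return 1.0 * LEVEL_WEIGHTS[doc.level] * SPECIFICITY_WEIGHTS[doc.specificity]


def aggregate_policy_intensity(
    corpus: PolicyCorpus,
    cities: Sequence[str],
    years: Iterable[int],
) -> pd.DataFrame:
    """Per-city-year Policy Support Intensity.

    intensity(city, year) = sum of scores of documents whose scope contains
    the city and whose year matches; 0 when none. Returns a city x year
    DataFrame covering exactly the requested cities and years.
    """
    years = sorted(years)
    table = pd.DataFrame(0.0, index=list(cities), columns=years)
    table.index.name = "city"
    table.columns.name = "year"
    for doc in corpus:
        if doc.year not in table.columns:
            continue
        s = score_policy(doc)
        for city in doc.scope:
            if city in table.index:
                table.loc[city, doc.year] += s
    return table
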