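"""Keyword taxonomy mapping native service-type phrases to resource categories.

Seven categories are used throughout the package: six keyword-backed
categories (Diagnosis, Therapy, Health, Education, Recreation, Support)
plus ``Other``, the fallback for records no keyword captures.  The default
map below reproduces the curated service-type vocabulary of the major US
autism resource directories (Autism Speaks, Autism Source, Parents Helping
Parents); each comma- or semicolon-separated token is an independent phrase
matched exactly (after canonicalization) against a record's service types,
or as a whole-phrase substring of its website text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

CATEGORIES: tuple[str, ...] = (
    "Diagnosis",
    "Therapy",
    "Health",
    "Education",
    "Recreation",
    "Support",
    "Other",
)

KEYWORD_CATEGORIES: tuple[str, ...] = CATEGORIES[:-1]

#: Raw keyword rows, one string per category; both "," and ";" delimit phrases.
_RAW_KEYWORD_ROWS: dict[str, str] = {
    "Diagnosis": (
        "Diagnosis, Where to get an Autism Diagnosis, Diagnostic, "
        "Assessments and Diagnosis"
    ),
    "Therapy": (
        "Therapy; Early Intervention: Ages Birth-3; Interventions; Related Services; "
        "Early Intervention Services; Augmentative and Alternative Communication; "
        "Equine Therapy; Music Therapy; Occupational Therapy; Physical Therapy; "
        "Sensory Integration; Social Skills; Speech and Language Therapy; "
        "Applied Behavior Analysis (ABA); Floortime or DIR; Other Interventions; "
        "Picture Exchange Communication (PEC); Relationship Development Intervention (RDI); "
        "SCERTS Model; TEACCH; Verbal Behavior; Early Intervention; "
        "Related Services (Therapists); Speech/Language Therapy; Therapists; "
        "Art Therapy; instruction/intervention; Executive Function; "
        "ABA (Applied Behavior Analysis); Therapeutic; Speech"
    ),
    "Health": (
        "Health, Biomedical Interventions; Health Services; Health and Dental Services; "
        "Diet or Nutrition; Other Biomedical Interventions; First Responder Resources; "
        "Dentists; Family Practitioners; Gastroenterologists; "
        "Inpatient Treatment Care Centers; Neurologists; Other Professionals; "
        "Pediatricians: Developmental, Pediatricians: General, Psychiatrists, "
        "Psychologists, State Mental Health Centers, Blood Draw or Phlebotomists; "
        "Community Mental Health Centers; Crisis Intervention Services; "
        "Substance Abuse Treatment; Crisis/Crime Victim Services; Dentist; "
        "Mental Health Professional; Other Medical Services; Physician; Doctors"
    ),
    "Education": (
        "Education; Preschool Age: Ages 3-5; School Age: Ages 5-22; "
        "Post Secondary Education; Schools: Nonpublic (Private); Schools: Residential; "
        "Schools: Preschool; Transition to Adult Services; Academic Supports; "
        "Private/Non-Public School; Public School System; Job/Vocational; Transition; "
        "Living Skills; Schools; Tutoring; Academy; Preschool; Tutor; School; Learn; "
        "Teach; Pre-K"
    ),
    "Recreation": (
        "Recreation; Recreational and Leisure Activities; Day Programs; "
        "Recreation and Community Activities; Camps; After-School Programs; "
        "Camps and Recreation; Social Activities; After School Care: Children; "
        "Recreation; Play"
    ),
    "Support": (
        "Support; Support Groups; Community and Support Network; Advocates; "
        "Grandparents; Autism Speaks Communities; Local Autism Events; "
        "Local Autism Organizations; Military Family Resources; Online Support Groups; "
        "Religious Resources; Support Groups; Autism Society Affiliate (Chapter); "
        "Parent Training; Conferences; Other Local Organizations; "
        "Faith Community Services; Information and Support; Training; "
        "Support/Self Help Groups; Parent Support; Advocate-School District; "
        "Advocacy; Volunteer"
    ),
}

#: Phrases that mark a website as relevant to the autism community.
DEFAULT_AUTISM_RELEVANCE_KEYWORDS: tuple[str, ...] = (
    "autism",
    "autistic",
    "asd",
    "asperger",
    "developmental disorder",
)


def canonicalize_phrase(phrase: str) -> str:
    """Case-fold and collapse internal whitespace; punctuation is preserved."""
    return " ".join(phrase.casefold().split())


def _split_row(row: str) -> list[str]:
    phrases = []
    for token in re.split(r"[;,]", row):
        token = token.strip()
        if token:
            phrases.append(token)
    return phrases


@dataclass(frozen=True)
class KeywordMap:
    """Category → keyword phrases, stored canonicalized, plus relevance phrases.

    ``entries`` covers the six keyword-backed categories only; ``Other`` has no
    keywords by construction (it is the fallback).
    """

    entries: Mapping[str, tuple[str, ...]]
    autism_relevance_keywords: tuple[str, ...] = DEFAULT_AUTISM_RELEVANCE_KEYWORDS
    _phrase_to_categories: dict[str, frozenset[str]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for category, phrases in self.entries.items():
            if category not in KEYWORD_CATEGORIES:
                raise ValueError(f"unknown category {category!r}")
            if not phrases:
                raise ValueError(f"category {category!r} has no keyword phrases")
        lookup: dict[str, set[str]] = {}
        for category, phrases in self.entries.items():
            for phrase in phrases:
                lookup.setdefault(canonicalize_phrase(phrase), set()).add(category)
        object.__setattr__(
            self,
            "_phrase_to_categories",
            {p: frozenset(c) for p, c in lookup.items()},
        )

    @classmethod
    def from_phrases(
        cls,
        entries: Mapping[str, Iterable[str]],
        autism_relevance_keywords: Iterable[str] = DEFAULT_AUTISM_RELEVANCE_KEYWORDS,
    ) -> "KeywordMap":
        canon = {
            cat: tuple(dict.fromkeys(canonicalize_phrase(p) for p in phrases))
            for cat, phrases in entries.items()
        }
        return cls(canon, tuple(canonicalize_phrase(p) for p in autism_relevance_keywords))

    @classmethod
    def default(cls) -> "KeywordMap":
        return cls.from_phrases(
            {cat: _split_row(row) for cat, row in _RAW_KEYWORD_ROWS.items()}
        )

    @classmethod
    def from_yaml(cls, path) -> "KeywordMap":
        """Load from a YAML file with keys ``categories`` and optionally
        ``autism_relevance_keywords``."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        relevance = doc.get("autism_relevance_keywords", DEFAULT_AUTISM_RELEVANCE_KEYWORDS)
        return cls.from_phrases(doc["categories"], relevance)

    def categories_for_phrase(self, phrase: str) -> frozenset[str]:
        """Categories whose keyword list contains ``phrase`` exactly
        (after canonicalization); empty frozenset if none."""
        return self._phrase_to_categories.get(canonicalize_phrase(phrase), frozenset())

    def categories_in_text(self, text: str) -> frozenset[str]:
        """Categories with at least one keyword occurring as a whole-phrase,
        case-insensitive substring of ``text``."""
        canon_text = canonicalize_phrase(text)
        hits: set[str] = set()
        for phrase, cats in self._phrase_to_categories.items():
            if re.search(rf"(?<!\w){re.escape(phrase)}(?!\w)", canon_text):
                hits.update(cats)
        return frozenset(hits)

    def is_autism_relevant(self, text: str) -> bool:
        canon_text = canonicalize_phrase(text)
        return any(
            re.search(rf"(?<!\w){re.escape(kw)}(?!\w)", canon_text)
            for kw in self.autism_relevance_keywords
        )

    def phrases_for_category(self, category: str) -> tuple[str, ...]:
        return self.entries[category]


DEFAULT_KEYWORD_MAP = KeywordMap.default()
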