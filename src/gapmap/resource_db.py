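"""Resource-record validation, deduplication, and category allocation.

A resource is one geocoded service listing (a diagnostic clinic, a therapy
provider, a parent support group, ...).  Raw listings harvested from
directory databases are noisy: they contain post-office boxes, stale or
irrelevant websites, records with no usable contact information, and
near-duplicate entries re-geocoded by different sources.  This module
implements the cleaning pipeline:

1. :func:`validate_resource` — discard unmappable records, PO boxes and
   invalid street addresses, records whose website text shows no relation to
   autism services, and records with a broken/missing website and no email.
   Records with a broken website but an email address are retained as
   ``pending_email_validation``.
2. :func:`deduplicate` — collapse records that agree on rounded
   geo-coordinates and canonicalized program name, keeping the most complete
   record of each class and the union of its service types and categories.
3. :func:`categorize` — allocate each surviving record to one or more of the
   7 categories by exact-phrase matching of its native service types against
   the keyword taxonomy, falling back to whole-phrase matching of website
   text, and finally to ``Other``.
"""

from __future__ import annotations

import math
import re
import string
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .keywords import CATEGORIES, KeywordMap, DEFAULT_KEYWORD_MAP

# Validation statuses
VALID = "valid"
PENDING = "pending_email_validation"
DISCARDED = "discarded"

# Discard reasons
REASON_UNMAPPABLE = "unmappable"
REASON_PO_BOX = "po_box"
REASON_INVALID_ADDRESS = "invalid_address"
REASON_IRRELEVANT_WEBSITE = "irrelevant_website"
REASON_NO_CONTACT = "no_contact"

DISCARD_REASONS = (
    REASON_UNMAPPABLE,
    REASON_PO_BOX,
    REASON_INVALID_ADDRESS,
    REASON_IRRELEVANT_WEBSITE,
    REASON_NO_CONTACT,
)

DEFAULT_DEDUP_PRECISION = 4  # decimal degrees, ~11 m

_PO_BOX_RE = re.compile(r"\b(?:p\.?\s*o\.?\s*box|post\s+office\s+box)\b", re.IGNORECASE)
_STREET_NUMBER_RE = re.compile(r"\b\d{1,6}\b")
_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


@dataclass
class ResourceRecord:
    """One geocoded service listing with raw attributes and derived state."""

    program_name: str
    full_address: str = ""
    program_description: str = ""
    phone: str = ""
    email: str = ""
    url: str = ""
    latitude: float | None = None
    longitude: float | None = None
    service_types: tuple[str, ...] = ()
    website_text: str | None = None
    broken_url: bool = False
    categories: frozenset[str] = frozenset()
    status: str = ""
    discard_reason: str = ""

    def __post_init__(self) -> None:
        if self.latitude is not None and not math.isnan(self.latitude):
            if not -90.0 <= self.latitude <= 90.0:
                raise ValueError(f"latitude {self.latitude} out of range")
        if self.longitude is not None and not math.isnan(self.longitude):
            if not -180.0 <= self.longitude <= 180.0:
                raise ValueError(f"longitude {self.longitude} out of range")
        self.service_types = tuple(self.service_types)
        self.categories = frozenset(self.categories)

    @property
    def has_coordinates(self) -> bool:
        return (
            self.latitude is not None
            and self.longitude is not None
            and not math.isnan(self.latitude)
            and not math.isnan(self.longitude)
        )


def canonicalize_name(name: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    return " ".join(name.casefold().translate(_PUNCT_TABLE).split())


def _has_url(record: ResourceRecord) -> bool:
    return bool(record.url.strip()) and not record.broken_url


def _address_is_physical(address: str) -> bool:
    # minimal heuristic: a street number and at least one alphabetic word
    if _PO_BOX_RE.search(address):
        return False
    return bool(_STREET_NUMBER_RE.search(address)) and bool(
        re.search(r"[A-Za-z]{2,}", address)
    )


def validate_resource(
    record: ResourceRecord, keyword_map: KeywordMap = DEFAULT_KEYWORD_MAP
) -> ResourceRecord:
    """Return a copy of ``record`` with ``status`` and ``discard_reason`` set.

    Discard rules, in priority order: no usable geo-coordinates; PO box or
    non-physical address; website text present but unrelated to autism;
    broken/missing website with no email.  A broken/missing website *with* an
    email yields ``pending_email_validation``; otherwise the record is
    ``valid``.  No other field is altered.
    """
    if not record.has_coordinates:
        return replace(record, status=DISCARDED, discard_reason=REASON_UNMAPPABLE)
    if _PO_BOX_RE.search(record.full_address):
        return replace(record, status=DISCARDED, discard_reason=REASON_PO_BOX)
    if not _address_is_physical(record.full_address):
        return replace(record, status=DISCARDED, discard_reason=REASON_INVALID_ADDRESS)
    if record.website_text is not None and not keyword_map.is_autism_relevant(
        record.website_text
    ):
        return replace(record, status=DISCARDED, discard_reason=REASON_IRRELEVANT_WEBSITE)
    if not _has_url(record):
        if record.email.strip():
            return replace(record, status=PENDING, discard_reason="")
        return replace(record, status=DISCARDED, discard_reason=REASON_NO_CONTACT)
    return replace(record, status=VALID, discard_reason="")


def dedup_key(
    record: ResourceRecord, precision: int = DEFAULT_DEDUP_PRECISION
) -> tuple[float, float, str]:
    """Equivalence-class key: rounded coordinates + canonicalized name."""
    return (
        round(record.latitude, precision),
        round(record.longitude, precision),
        canonicalize_name(record.program_name),
    )


def _completeness(record: ResourceRecord) -> int:
    score = sum(
        bool(v.strip())
        for v in (
            record.program_description,
            record.phone,
            record.email,
            record.url,
        )
    )
    score += bool(record.website_text)
    score += bool(record.service_types)
    return score


def deduplicate(
    records: Sequence[ResourceRecord], precision: int = DEFAULT_DEDUP_PRECISION
) -> list[ResourceRecord]:
    """Collapse records sharing a :func:`dedup_key` class to one survivor.

    The survivor is the most complete record of its class (ties broken by
    input order); it inherits the union of service types and categories over
    the class.  Output order follows the first occurrence of each class, so
    the result is deterministic and permutation-independent up to that
    tie-break.
    """
    classes: dict[tuple, list[ResourceRecord]] = {}
    for rec in records:
        classes.setdefault(dedup_key(rec, precision), []).append(rec)
    survivors: list[ResourceRecord] = []
    for members in classes.values():
        best = max(members, key=_completeness)  # max() keeps the first tie
        service_types = tuple(
            dict.fromkeys(st for m in members for st in m.service_types)
        )
        categories = frozenset().union(*(m.categories for m in members))
        survivors.append(
            replace(best, service_types=service_types, categories=categories)
        )
    return survivors


def categorize(
    record: ResourceRecord, keyword_map: KeywordMap = DEFAULT_KEYWORD_MAP
) -> frozenset[str]:
    """Allocate a validated record to one or more of the 7 categories.

    Native service-type phrases are matched by exact (canonicalized) phrase
    equality against the keyword lists; only when a record carries no service
    type is its website text scanned for whole-phrase keyword occurrences.
    Records no keyword captures fall back to ``{"Other"}``.
    """
    hits: set[str] = set()
    if record.service_types:
        for phrase in record.service_types:
            hits.update(keyword_map.categories_for_phrase(phrase))
    elif record.website_text:
        hits.update(keyword_map.categories_in_text(record.website_text))
    if not hits:
        return frozenset({"Other"})
    return frozenset(hits)


def process_resources(
    records: Iterable[ResourceRecord],
    keyword_map: KeywordMap = DEFAULT_KEYWORD_MAP,
    dedup_precision: int = DEFAULT_DEDUP_PRECISION,
) -> tuple[list[ResourceRecord], list[ResourceRecord]]:
    """Full cleaning pipeline: validate → deduplicate → categorize.

    Returns ``(kept, discarded)``; ``kept`` records (valid or pending email
    validation) carry their category sets.
    """
    validated = [validate_resource(r, keyword_map) for r in records]
    kept = [r for r in validated if r.status != DISCARDED]
    discarded = [r for r in validated if r.status == DISCARDED]
    deduped = deduplicate(kept, dedup_precision)
    categorized = [
        replace(r, categories=categorize(r, keyword_map)) for r in deduped
    ]
    return categorized, discarded


def category_breakdown(records: Sequence[ResourceRecord]) -> pd.DataFrame:
    """Count and percent of records per category (Table-style breakdown).

    Because records may carry multiple categories, the per-category counts
    can sum to more than the total; the ``All resources`` row reports the
    number of records, not the column sum.  Percentages are half-up rounded
    to 2 decimal places.
    """
    if not records:
        raise ValueError("category breakdown undefined for zero records")
    total = len(records)
    rows = [("All resources", total, 100.0)]
    for cat in CATEGORIES:
        count = sum(cat in r.categories for r in records)
        rows.append((cat, count, percent_2dp(count, total)))
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def percent_2dp(count: int, total: int) -> float:
    """100*count/total, rounded half-up to two decimals."""
    from decimal import Decimal, ROUND_HALF_UP

    if total <= 0:
        raise ValueError("total must be positive")
    frac = (Decimal(count) * 100) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
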