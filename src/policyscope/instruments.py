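"""Policy-instrument coding: the Rothwell supply / environment / demand
taxonomy, tallies of human-coded text segments, and the share statistics
reported alongside them.

Rothwell's functional classification splits government measures into
supply-side instruments (direct provision of resources: services,
talent, funding, infrastructure, information, standards), environment
instruments (institutional conditions: plans, regulation, strategy,
fiscal policy, oversight, social climate) and demand-side instruments
(pull mechanisms: procurement, partnerships, exchange, pilots,
charity).  Coding itself is a human judgment performed upstream; this
module consumes the coded segments as data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "CodingFrame",
    "CodedSegment",
    "InstrumentTally",
    "DEFAULT_FRAME",
    "load_coding_frame",
    "tally",
    "shares",
    "read_segments_csv",
    "write_segments_csv",
    "percent",
]

CATEGORIES = ("supply", "environment", "demand")

# Default frame: the standard 17-subtool taxonomy for NCD policy
# (6 supply, 6 environment, 5 demand).
_DEFAULT_SUBTOOLS: dict[str, list[tuple[str, str]]] = {
    "supply": [
        ("public services", "health management for chronic disease populations and knowledge promotion"),
        ("talent development", "training professionals in chronic disease prevention and control"),
        ("financial investment", "providing financial support for prevention and control"),
        ("infrastructure development", "constructing prevention and control infrastructure"),
        ("information technology", "data and information support for patients and institutions"),
        ("standards and guidelines", "establishing guidelines and standardizing diagnosis and treatment"),
    ],
    "environment": [
        ("target planning", "developing prevention and control development plans"),
        ("regulatory control", "strengthening legal constraints"),
        ("strategic measures", "formulating series of prevention and control measures"),
        ("financial and tax policies", "financial and tax incentives and support"),
        ("supervision and evaluation", "supervision and evaluation of policy implementation"),
        ("social environment", "creating a positive social atmosphere"),
    ],
    "demand": [
        ("government procurement", "government purchase of medicines and services"),
        ("public-private partnership", "collaboration between government and social capital"),
        ("international exchange", "domestic and international academic exchange and cooperation"),
        ("demonstration and pilot programs", "establishing demonstration zones"),
        ("public welfare and charity", "encouraging public support for vulnerable populations"),
    ],
}

# Medical insurance is tallied as a demand-side tool in practice though
# absent from the base taxonomy; shipped as an opt-in extension.
MEDICAL_INSURANCE_EXTENSION = {
    "demand": [("medical insurance", "medical insurance coverage easing the burden of NCD patients")]
}


@dataclass(frozen=True)
class CodingFrame:
    """Ordered categories, each with its ordered named subtools."""

    subtools: Mapping[str, tuple[tuple[str, str], ...]]  # category -> ((name, definition), ...)

    def __post_init__(self) -> None:
        for cat in self.subtools:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}; expected one of {CATEGORIES}")
        names = [n for cat in self.categories for n, _ in self.subtools[cat]]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate subtool names: {dupes}")
        for cat in self.categories:
            if not self.subtools[cat]:
                raise ValueError(f"category {cat!r} has no subtools")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(c for c in CATEGORIES if c in self.subtools)

    @property
    def n_subtools(self) -> int:
        return sum(len(v) for v in self.subtools.values())

    def subtool_names(self, category: str) -> tuple[str, ...]:
        return tuple(n for n, _ in self.subtools[category])

    def category_of(self, subtool: str) -> str:
        for cat in self.categories:
            if subtool in self.subtool_names(cat):
                return cat
        raise KeyError(f"subtool {subtool!r} not in frame")

    def __contains__(self, pair: tuple[str, str]) -> bool:
        cat, sub = pair
        return cat in self.subtools and sub in self.subtool_names(cat)


DEFAULT_FRAME = CodingFrame(subtools={
    c: tuple(_DEFAULT_SUBTOOLS[c]) for c in CATEGORIES
})


def load_coding_frame(config: str | Path | Mapping | None = None,
                      extensions: Mapping[str, Sequence[tuple[str, str]]] | None = None
                      ) -> CodingFrame:
    """Build a coding frame from a YAML/JSON mapping, or the packaged
    default when no config is given.

    The config maps category -> list of subtools, each either a name or
    a {name: definition} mapping.  ``extensions`` appends extra subtools
    to the default frame (e.g. ``MEDICAL_INSURANCE_EXTENSION``).
    """
    if config is None:
        base = {c: list(_DEFAULT_SUBTOOLS[c]) for c in CATEGORIES}
    else:
        if isinstance(config, (str, Path)):
            config = yaml.safe_load(Path(config).read_text(encoding="utf-8"))
        base = {}
        for cat, entries in config.items():
            parsed = []
            for e in entries:
                if isinstance(e, str):
                    parsed.append((e, ""))
                elif isinstance(e, Mapping) and len(e) == 1:
                    ((name, definition),) = e.items()
                    parsed.append((str(name), str(definition)))
                else:
                    raise ValueError(f"malformed subtool entry under {cat!r}: {e!r}")
            base[cat] = parsed
    for cat, extra in (extensions or {}).items():
        if cat not in base:
            raise ValueError(f"extension targets unknown category {cat!r}")
        base[cat] = base[cat] + [tuple(e) for e in extra]
    return CodingFrame(subtools={c: tuple(v) for c, v in base.items()})


@dataclass(frozen=True)
class CodedSegment:
    """One human-coded text span assigned to a (category, subtool) pair."""

    doc_id: str
    category: str
    subtool: str
    locator: str = ""


@dataclass(frozen=True)
class InstrumentTally:
    """Exact counts per subtool, per category, and overall, in frame order."""

    frame: CodingFrame
    subtool_counts: Mapping[str, int]
    category_counts: Mapping[str, int]
    grand_total: int


def tally(segments: Iterable[CodedSegment], frame: CodingFrame) -> InstrumentTally:
    """Count coded segments against the frame; order-invariant.

    Segments naming an unknown (category, subtool) pair abort with a
    message listing every offending row.
    """
    sub_counts = {n: 0 for cat in frame.categories for n in frame.subtool_names(cat)}
    bad = []
    for i, seg in enumerate(segments):
        if (seg.category, seg.subtool) not in frame:
            bad.append(f"row {i}: ({seg.category!r}, {seg.subtool!r})")
        else:
            sub_counts[seg.subtool] += 1
    if bad:
        raise ValueError("segments outside the coding frame:\n" + "\n".join(bad))
    cat_counts = {cat: sum(sub_counts[n] for n in frame.subtool_names(cat))
                  for cat in frame.categories}
    return InstrumentTally(frame=frame, subtool_counts=sub_counts,
                           category_counts=cat_counts,
                           grand_total=sum(cat_counts.values()))


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    """100·count/denominator rounded half-up to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in share computation")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100) * Decimal(count) / Decimal(denominator))
                 .quantize(q, rounding=ROUND_HALF_UP))


def shares(t: InstrumentTally, level: str = "category", denominator: str = "grand",
           decimals: int = 1) -> list[dict]:
    """Percentage shares at the category or subtool level.

    ``denominator="grand"`` divides by the grand total; ``"category"``
    divides each subtool by its own category total (only meaningful at
    the subtool level).  Rounding is half-up at ``decimals`` places to
    match conventional reporting.
    Returns tidy rows: level, name, count, denominator, percent.
    """
    if level not in ("category", "subtool"):
        raise ValueError("level must be 'category' or 'subtool'")
    if denominator not in ("grand", "category"):
        raise ValueError("denominator must be 'grand' or 'category'")
    if t.grand_total == 0:
        raise ZeroDivisionError("tally is empty; shares undefined")
    rows = []
    if level == "category":
        for cat in t.frame.categories:
            rows.append({
                "level": "category", "name": cat,
                "count": t.category_counts[cat], "denominator": t.grand_total,
                "percent": percent(t.category_counts[cat], t.grand_total, decimals),
            })
    else:
        for cat in t.frame.categories:
            denom = t.grand_total if denominator == "grand" else t.category_counts[cat]
            if denom == 0:
                continue  # within-category shares are undefined for empty categories
            for name in t.frame.subtool_names(cat):
                rows.append({
                    "level": "subtool", "name": name,
                    "count": t.subtool_counts[name], "denominator": denom,
                    "percent": percent(t.subtool_counts[name], denom, decimals),
                })
    return rows


# ---------------------------------------------------------------------------
# CSV round-trip

_SEGMENT_FIELDS = ["doc_id", "category", "subtool", "locator"]


def write_segments_csv(segments: Sequence[CodedSegment], path) -> None:
    """Write segments to a CSV path or open text stream."""
    if hasattr(path, "write"):
        _write_segment_rows(path, segments)
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            _write_segment_rows(fh, segments)


def _write_segment_rows(fh, segments: Sequence[CodedSegment]) -> None:
    w = csv.DictWriter(fh, fieldnames=_SEGMENT_FIELDS)
    w.writeheader()
    for s in segments:
        w.writerow({"doc_id": s.doc_id, "category": s.category,
                    "subtool": s.subtool, "locator": s.locator})


def read_segments_csv(path: str | Path) -> list[CodedSegment]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_SEGMENT_FIELDS[:3]) <= set(reader.fieldnames):
            raise ValueError(f"segments CSV must have columns {_SEGMENT_FIELDS[:3]}")
        out = []
        for row in reader:
            out.append(CodedSegment(doc_id=row["doc_id"], category=row["category"],
                                    subtool=row["subtool"], locator=row.get("locator", "") or ""))
    if not out:
        raise ValueError(f"no segment rows in {path}")
    return out
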