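"""Content coding of within-group chat messages.

Chat transcripts from communication arms are segmented into message
units, and each unit is coded independently against six subject areas
(topical, functional-substantive, functional-maintenance,
social-ecological links, CPR group, harvesting strategy) carrying
twenty sub-categories in total.  A unit receives at most one
sub-category per area and may receive none (no relevance).  Each
sub-category is linked, with a sign, to the collective-action factors it
is judged to support or undermine; tallies roll up into signed factor
scores.  Double coding of a ~10% random sample by a second coder gives a
percent-agreement reliability check.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CodingScheme",
    "CodedMessage",
    "ValidationReport",
    "load_scheme",
    "load_default_scheme",
    "validate_coding",
    "tally_topics",
    "intercoder_agreement",
    "factor_rollup",
    "read_messages_csv",
    "write_messages_csv",
]


@dataclass(frozen=True)
class CodingScheme:
    """The coding framework: areas, sub-categories and signed factor links."""

    version: int
    factors: dict[str, str]                     # token -> display label
    areas: dict[str, dict[str, dict]]           # area -> sub_cat -> {label, factors}
    area_labels: dict[str, str]

    def sub_category_names(self) -> list[str]:
        return [sc for area in self.areas.values() for sc in area]

    def area_of(self, sub_category: str) -> str | None:
        for area, subs in self.areas.items():
            if sub_category in subs:
                return area
        return None

    def factor_links(self, sub_category: str) -> dict[str, int]:
        """Signed factor links for one sub-category (+1 / -1)."""
        area = self.area_of(sub_category)
        if area is None:
            raise KeyError(f"unknown sub-category {sub_category!r}")
        raw = self.areas[area][sub_category]["factors"]
        return {f: (1 if sign == "+" else -1) for f, sign in raw.items()}

    def to_yaml(self) -> str:
        doc = {
            "version": self.version,
            "factors": self.factors,
            "areas": {
                a: {
                    "label": self.area_labels[a],
                    "sub_categories": self.areas[a],
                }
                for a in self.areas
            },
        }
        return yaml.safe_dump(doc, sort_keys=False)


def _parse_scheme(doc: Mapping) -> CodingScheme:
    areas: dict[str, dict[str, dict]] = {}
    labels: dict[str, str] = {}
    for area, spec in doc["areas"].items():
        labels[area] = spec.get("label", area)
        areas[area] = dict(spec["sub_categories"])
    scheme = CodingScheme(
        version=int(doc.get("version", 1)),
        factors=dict(doc["factors"]),
        areas=areas,
        area_labels=labels,
    )
    names = scheme.sub_category_names()
    if len(names) != len(set(names)):
        raise ValueError("sub-category names must be unique across areas")
    return scheme


def load_scheme(path: str | Path) -> CodingScheme:
    """Load a coding scheme from a YAML file."""
    with open(path) as fh:
        return _parse_scheme(yaml.safe_load(fh))


def load_default_scheme() -> CodingScheme:
    """The packaged 6-area / 20-sub-category scheme."""
    ref = importlib.resources.files("cprlab").joinpath("data/coding_scheme.yaml")
    return _parse_scheme(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True)
class CodedMessage:
    """One chat message unit with up to one code per subject area."""

    group_id: str
    round: int
    sender: str
    codes: Mapping[str, str] = field(default_factory=dict)  # area -> sub-category
    text: str | None = None


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...]


def validate_coding(message: CodedMessage, scheme: CodingScheme) -> ValidationReport:
    """Check a coded message against the scheme.

    Valid iff every code's sub-category belongs to the area it is filed
    under (one code per area is structural: ``codes`` maps area to a
    single sub-category).  An uncoded message is valid — no relevance to
    any subject area.  Never raises on content; violations are returned.
    """
    violations: list[str] = []
    for area, sub in message.codes.items():
        if area not in scheme.areas:
            violations.append(f"unknown subject area {area!r}")
            continue
        true_area = scheme.area_of(sub)
        if true_area is None:
            violations.append(f"unknown sub-category {sub!r} (filed under {area!r})")
        elif true_area != area:
            violations.append(
                f"sub-category {sub!r} belongs to area {true_area!r}, not {area!r}"
            )
    if message.sender not in ("yellow", "red", "blue"):
        violations.append(f"unknown sender {message.sender!r}")
    return ValidationReport(ok=not violations, violations=tuple(violations))


def tally_topics(
    messages: Iterable[CodedMessage], scheme: CodingScheme | None = None
) -> pd.DataFrame:
    """Count codes per (group, round, sub-category).

    Returns a wide table with one row per group-round, one column per
    sub-category, plus ``total_messages`` = number of distinct message
    units in that group-round (a unit with no codes still counts as a
    message).  Invalid messages are rejected with their validation report.
    """
    scheme = scheme or load_default_scheme()
    names = scheme.sub_category_names()
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for i, msg in enumerate(messages):
        report = validate_coding(msg, scheme)
        if not report.ok:
            raise ValueError(
                f"message {i} (group {msg.group_id}, round {msg.round}) invalid: "
                + "; ".join(report.violations)
            )
        key = (msg.group_id, msg.round)
        row = counts.setdefault(key, {n: 0 for n in names} | {"total_messages": 0})
        row["total_messages"] += 1
        for sub in msg.codes.values():
            row[sub] += 1
    records = [
        {"group_id": g, "round": r, **row} for (g, r), row in sorted(counts.items())
    ]
    cols = ["group_id", "round", *names, "total_messages"]
    return pd.DataFrame(records, columns=cols)


def intercoder_agreement(
    coding_a: list[CodedMessage],
    coding_b: list[CodedMessage],
    scheme: CodingScheme | None = None,
    sample_frac: float = 0.10,
    seed: int | None = None,
) -> float:
    """Percent agreement between two coders on a random message sample.

    The two lists must code the same message units in the same order.
    A seeded sample of ``ceil(sample_frac * N)`` units is drawn; for each
    sampled unit every subject area is compared, and agreement is the
    percentage of matching (area, code) assignments — both-absent counts
    as a match.
    """
    scheme = scheme or load_default_scheme()
    if len(coding_a) != len(coding_b):
        raise ValueError(
            f"codings must align: {len(coding_a)} vs {len(coding_b)} messages"
        )
    for i, (a, b) in enumerate(zip(coding_a, coding_b)):
        if (a.group_id, a.round, a.sender) != (b.group_id, b.round, b.sender):
            raise ValueError(f"message {i}: identities differ between coders")
    n = len(coding_a)
    if n == 0:
        raise ValueError("cannot compute agreement on zero messages")
    if not (0 < sample_frac <= 1):
        raise ValueError("sample_frac must lie in (0, 1]")
    k = int(np.ceil(sample_frac * n))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    areas = list(scheme.areas)
    compared = 0
    matched = 0
    for i in idx:
        a, b = coding_a[i], coding_b[i]
        for area in areas:
            compared += 1
            if a.codes.get(area) == b.codes.get(area):
                matched += 1
    return 100.0 * matched / compared


def factor_rollup(
    tallies: pd.DataFrame, scheme: CodingScheme | None = None
) -> pd.DataFrame:
    """Roll sub-category counts up into signed collective-action factor scores.

    Each sub-category count contributes ``+count`` or ``-count`` to each
    factor it is linked to; unlinked sub-categories (off-topic tangents)
    contribute nowhere.  Returns one row per group-round with one column
    per factor.
    """
    scheme = scheme or load_default_scheme()
    names = [n for n in scheme.sub_category_names() if n in tallies.columns]
    out = tallies[["group_id", "round"]].copy()
    for factor in scheme.factors:
        score = np.zeros(len(tallies), dtype=float)
        for sub in names:
            sign = scheme.factor_links(sub).get(factor)
            if sign:
                score += sign * tallies[sub].to_numpy(dtype=float)
        out[factor] = score
    return out


_CSV_COLUMNS = ["group_id", "round", "sender", "text"]


def write_messages_csv(messages: Iterable[CodedMessage], path: str | Path,
                       scheme: CodingScheme | None = None) -> None:
    scheme = scheme or load_default_scheme()
    areas = list(scheme.areas)
    rows = []
    for m in messages:
        row = {
            "group_id": m.group_id,
            "round": m.round,
            "sender": m.sender,
            "text": m.text or "",
        }
        for area in areas:
            row[area] = m.codes.get(area, "")
        rows.append(row)
    pd.DataFrame(rows, columns=_CSV_COLUMNS + areas).to_csv(path, index=False)


def read_messages_csv(path: str | Path,
                      scheme: CodingScheme | None = None) -> list[CodedMessage]:
    scheme = scheme or load_default_scheme()
    areas = list(scheme.areas)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _CSV_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"messages CSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        codes = {a: row[a] for a in areas if a in df.columns and row[a]}
        out.append(
            CodedMessage(
                group_id=row["group_id"],
                round=int(row["round"]),
                sender=row["sender"],
                codes=codes,
                text=row.get("text") or None,
            )
        )
    return out
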