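"""Two-stage deduplication of spontaneous reports.

Spontaneous-reporting databases contain both re-submissions of the same case
(same CASEID, successive PRIMARYID versions) and independently entered copies
of the same clinical event (distinct CASEIDs with identical content). Stage 1
keeps, per CASEID, the most recent version (latest FDA date; ties broken by
the higher PRIMARYID, which carries the most complete information). Stage 2
drops reports that are field-identical on sex, age, reporting country, event
date, reaction set and harmonized drug-ingredient set.

Survivor rules are deterministic: stage 1 keeps the latest/highest version;
stage 2 keeps the lowest PRIMARYID of a field-identical group. A missing
value never matches another missing value, so reports lacking any of the six
stage-2 fields are never merged on that basis — deliberately stricter than
merging on shared absence, which would inflate deletion.

Both operations are idempotent and independent of input order.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .faers_io import SafetyReport, Sex

__all__ = ["dedupe_by_case", "dedupe_by_fields", "dedupe"]


def dedupe_by_case(
    reports: Sequence[SafetyReport], audit: Optional[list] = None
) -> list[SafetyReport]:
    """Keep one report per CASEID: latest FDA date, ties to higher PRIMARYID.

    Output is sorted by ascending caseid.
    """
    best: dict[int, SafetyReport] = {}
    for r in reports:
        cur = best.get(r.caseid)
        if cur is None:
            best[r.caseid] = r
        elif (r.fda_date.sort_key(), r.primaryid) > (cur.fda_date.sort_key(), cur.primaryid):
            if audit is not None:
                audit.append({"stage": "case", "dropped": cur.primaryid,
                              "kept": r.primaryid, "caseid": r.caseid,
                              "reason": "superseded version"})
            best[r.caseid] = r
        else:
            if audit is not None:
                audit.append({"stage": "case", "dropped": r.primaryid,
                              "kept": cur.primaryid, "caseid": r.caseid,
                              "reason": "superseded version"})
    return [best[c] for c in sorted(best)]


def _field_key(r: SafetyReport) -> Optional[tuple]:
    """The stage-2 six-field identity key, or None if any field is missing."""
    if r.sex is Sex.UNKNOWN or r.age_years is None or not r.country:
        return None
    if r.event_date is None:
        return None
    reactions = r.reactions
    ingredients = r.ingredient_set()
    if not reactions or not ingredients:
        return None
    return (r.sex, r.age_years, r.country, r.event_date, reactions, ingredients)


def dedupe_by_fields(
    reports: Sequence[SafetyReport], audit: Optional[list] = None
) -> list[SafetyReport]:
    """Drop reports field-identical on (sex, age, country, event date,
    reactions, ingredients), keeping the lowest PRIMARYID of each group.

    Reports with any of the six fields missing are never merged
    (missing != missing). Output sorted by ascending caseid, matching
    :func:`dedupe_by_case`.
    """
    kept: dict[tuple, SafetyReport] = {}
    unmergeable: list[SafetyReport] = []
    for r in reports:
        key = _field_key(r)
        if key is None:
            unmergeable.append(r)
            continue
        cur = kept.get(key)
        if cur is None:
            kept[key] = r
        elif r.primaryid < cur.primaryid:
            if audit is not None:
                audit.append({"stage": "fields", "dropped": cur.primaryid,
                              "kept": r.primaryid, "reason": "field-identical"})
            kept[key] = r
        else:
            if audit is not None:
                audit.append({"stage": "fields", "dropped": r.primaryid,
                              "kept": cur.primaryid, "reason": "field-identical"})
    out = list(kept.values()) + unmergeable
    return sorted(out, key=lambda r: (r.caseid, r.primaryid))


def dedupe(
    reports: Sequence[SafetyReport], audit: Optional[list] = None
) -> list[SafetyReport]:
    """Run both stages (case versions first, then field-identical copies)."""
    return dedupe_by_fields(dedupe_by_case(reports, audit), audit)
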