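"""Prey selectivity against field availability (Jacobs's index).

Jacobs's electivity index for item i compares the share of the item in
the diet (r_i) with its share in the environment (p_i):

    D_i = (r_i - p_i) / (r_i + p_i - 2 r_i p_i)

D ranges from -1 (complete avoidance: eaten never, available) through 0
(consumption proportional to availability) to +1 (exclusive selection:
eaten, never recorded as available). Unlike the raw difference r - p, D
is insensitive to how rare a resource is overall, which makes items of
very different availability comparable.

Here r_i is the item's relative read abundance renormalised *within its
prey group* (fish or benthic invertebrates are scored separately, each
on its own simplex) and p_i is the item's share of individuals counted
in the field survey for that group. Chironomid genera are merged to the
family Chironomidae on both sides before shares are computed, matching
the identification limit of typical benthos surveys.
"""

from __future__ import annotations

import math
from typing import Iterable

import pandas as pd

from .io import FieldSurveyTable, PreyTable, ValidationError, normalise_group
from .filtering import genus_of
from .metrics import compute_rra

#: chironomid genera collapsed to family level for the field comparison
DEFAULT_CHIRONOMID_GENERA = frozenset(
    {
        "Chironomus",
        "Cricotopus",
        "Polypedilum",
        "Tanytarsus",
        "Tanypus",
        "Orthocladius",
        "Microtendipes",
        "Glyptotendipes",
    }
)

CHIRONOMIDAE = "Chironomidae"


def jacobs_d(r: float, p: float) -> float:
    """Jacobs's D for use share ``r`` and availability share ``p``.

    Both arguments are fractions in [0, 1]. Returns NaN for the
    undefined r = p = 0 case (0/0).
    """
    for name, v in (("r", r), ("p", p)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    if r == p:
        # covers r = p = 1 (denominator 0) and removes float jitter at r == p
        return math.nan if r == 0.0 else 0.0
    d = (r - p) / (r + p - 2.0 * r * p)
    # |D| <= 1 analytically; clamp float rounding at the extremes
    return max(-1.0, min(1.0, d))


def _family_label(genus: str, merge: bool, chironomid_genera: frozenset[str]) -> str:
    return CHIRONOMIDAE if merge and genus in chironomid_genera else genus


def _faecal_shares(
    prey: PreyTable,
    group: str,
    merge_chironomidae: bool,
    chironomid_genera: frozenset[str],
    renormalise: bool,
) -> pd.Series:
    items = prey.group_items(group)
    if not items:
        return pd.Series(dtype=float)
    rra = compute_rra(prey)[items]
    labels = [
        _family_label(genus_of(i), merge_chironomidae, chironomid_genera) for i in items
    ]
    merged = rra.groupby(pd.Index(labels)).sum()
    if renormalise:
        return merged / merged.sum()
    return merged / 100.0


def _field_shares(
    survey: FieldSurveyTable,
    group: str,
    merge_chironomidae: bool,
    chironomid_genera: frozenset[str],
) -> pd.Series:
    counts = survey.genus_counts(group)
    if counts.empty:
        return pd.Series(dtype=float)
    labels = [
        _family_label(g, merge_chironomidae, chironomid_genera) for g in counts.index
    ]
    merged = counts.groupby(pd.Index(labels)).sum()
    return merged / merged.sum()


def group_selectivity(
    prey: PreyTable,
    survey: FieldSurveyTable,
    group: str,
    *,
    renormalise: bool = True,
    merge_chironomidae: bool = True,
    chironomid_genera: frozenset[str] = DEFAULT_CHIRONOMID_GENERA,
) -> pd.DataFrame:
    """Selectivity table for one prey group over faecal ∪ field items.

    Items detected only in faeces get p = 0 hence D = 1; items recorded
    only in the field get r = 0 hence D = -1. With ``renormalise`` off,
    r is the raw %RRA / 100 instead of the within-group share.
    """
    g = normalise_group(group)
    r = _faecal_shares(prey, g, merge_chironomidae, chironomid_genera, renormalise)
    p = _field_shares(survey, g, merge_chironomidae, chironomid_genera)
    names = sorted(set(r.index) | set(p.index))
    if not names:
        raise ValidationError(f"group {g!r} has no items in either source")
    rows = []
    for name in names:
        ri = float(r.get(name, 0.0))
        pi = float(p.get(name, 0.0))
        rows.append(
            {"item": name, "prey_group": g, "r": ri, "p": pi, "D": jacobs_d(ri, pi)}
        )
    df = pd.DataFrame(rows)
    return df.sort_values("D", ascending=False, kind="mergesort").reset_index(drop=True)


def faecal_field_overlap(
    prey: PreyTable,
    survey: FieldSurveyTable,
    group: str,
    *,
    merge_chironomidae: bool = True,
    chironomid_genera: frozenset[str] = DEFAULT_CHIRONOMID_GENERA,
) -> tuple[set[str], set[str], set[str]]:
    """(faecal-only, shared, field-only) genus-level name sets for a group."""
    g = normalise_group(group)
    faecal = {
        _family_label(genus_of(i), merge_chironomidae, chironomid_genera)
        for i in prey.group_items(g)
    }
    field = {
        _family_label(genus, merge_chironomidae, chironomid_genera)
        for genus in survey.genera(g)
    }
    return faecal - field, faecal & field, field - faecal


def overlap_report(
    prey: PreyTable, survey: FieldSurveyTable, groups: Iterable[str] = ("fish", "benthic_invertebrate")
) -> pd.DataFrame:
    """Long-form set-membership table over prey groups."""
    rows = []
    for group in groups:
        only_f, shared, only_s = faecal_field_overlap(prey, survey, group)
        for name in sorted(only_f):
            rows.append({"prey_group": normalise_group(group), "item": name, "membership": "faecal_only"})
        for name in sorted(shared):
            rows.append({"prey_group": normalise_group(group), "item": name, "membership": "shared"})
        for name in sorted(only_s):
            rows.append({"prey_group": normalise_group(group), "item": name, "membership": "field_only"})
    return pd.DataFrame(rows)
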