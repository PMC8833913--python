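"""Condition-unique ubiquitination calls and interactor-overlap testing.

The presence/absence logic here mirrors how diGly ubiquitome screens are
read: a peptidoform observed under one condition but never under the
reference condition is a condition-restricted ubiquitination event, and
the proteins carrying such events can be tested for enrichment against a
curated interactor list with an upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .digest import SiteAnnotation, parse_peptidoform

__all__ = [
    "UbEvent",
    "OverlapResult",
    "venn_counts",
    "unique_to_condition",
    "collapse_to_proteins",
    "interactor_overlap",
    "read_peptidoform_table",
    "read_interactor_list",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UbEvent:
    """One observed ubiquitinated peptidoform in one condition/stratum."""

    key: str  # normalized peptidoform identity (bare sequence + sites)
    condition: str
    mg132: bool
    sample: str = ""


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of a candidate protein set with an interactor list."""

    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    p_value: float
    members: frozenset[str] = frozenset()


def venn_counts(set_a: Iterable, set_b: Iterable) -> dict:
    """Two-set Venn partition: unique-to-A, shared, unique-to-B.

    Returns counts plus the member sets; the three counts always
    partition ``|A ∪ B|``.
    """
    a, b = set(set_a), set(set_b)
    shared = a & b
    return {
        "unique_a": len(a - b),
        "shared": len(shared),
        "unique_b": len(b - a),
        "members_unique_a": a - b,
        "members_shared": shared,
        "members_unique_b": b - a,
    }


def unique_to_condition(
    events: Iterable[UbEvent],
    target: str,
    reference: str,
    require_mg132: bool = True,
) -> set[str]:
    """Peptidoform keys observed under *target* and never under *reference*.

    Only events in the requested MG132 stratum are considered; "unique"
    is strict absence from the reference (presence/absence, no abundance
    tolerance).
    """
    events = list(events)
    seen_conditions = {e.condition for e in events}
    for label in (target, reference):
        if label not in seen_conditions:
            raise ValueError(f"condition {label!r} not present in events")
    stratum = [e for e in events if e.mg132 == require_mg132]
    target_keys = {e.key for e in stratum if e.condition == target}
    ref_keys = {e.key for e in stratum if e.condition == reference}
    return target_keys - ref_keys


def collapse_to_proteins(
    keys: Iterable[str],
    annotations: Mapping[str, Sequence[SiteAnnotation]],
) -> set[str]:
    """Collapse peptidoform keys to the set of parent protein IDs.

    Ambiguous peptides contribute every matched protein; each protein is
    counted once.  Keys without a mapping entry are counted and logged,
    never raised.
    """
    proteins: set[str] = set()
    unmapped = 0
    for key in keys:
        anns = annotations.get(key, ())
        if not anns:
            unmapped += 1
            continue
        proteins.update(a.protein_id for a in anns)
    if unmapped:
        logger.warning("%d peptidoform keys had no protein mapping", unmapped)
    return proteins


def interactor_overlap(
    candidates: Iterable[str],
    interactors: Iterable[str],
    universe_size: int,
) -> OverlapResult:
    """Upper-tail hypergeometric test of candidate/interactor overlap.

    ``p = P(X >= k)`` where X counts interactors among ``|candidates|``
    proteins drawn without replacement from a universe of
    ``universe_size`` containing ``|interactors|`` interactors.
    """
    cand, inter = set(candidates), set(interactors)
    union = cand | inter
    if universe_size < len(union):
        raise ValueError(
            f"universe_size {universe_size} smaller than |candidates ∪ "
            f"interactors| = {len(union)}"
        )
    k = len(cand & inter)
    # sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(inter), len(cand)))
    return OverlapResult(
        n_universe=universe_size,
        n_set_a=len(cand),
        n_set_b=len(inter),
        n_overlap=k,
        p_value=min(p, 1.0),
        members=frozenset(cand & inter),
    )


def read_peptidoform_table(path) -> list[UbEvent]:
    """Read a TSV of observed peptidoforms.

    Columns: ``sample``, ``condition``, ``mg132`` (0/1), ``peptidoform``
    (any supported modified-peptide dialect).  Events with identical key,
    condition, stratum and sample deduplicate.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "mg132", "peptidoform"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptidoform table missing columns: {sorted(missing)}")
    events = {
        UbEvent(
            key=parse_peptidoform(row.peptidoform).key,
            condition=row.condition,
            mg132=bool(int(row.mg132)),
            sample=row.sample,
        )
        for row in df.itertuples()
    }
    return sorted(events, key=lambda e: (e.condition, e.mg132, e.sample, e.key))


def read_interactor_list(path) -> set[str]:
    """One protein ID per line; blank lines and '#' comments ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split("\t")[0])
    return ids
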