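"""Reporter-type subgroup analysis: signal mining stratified by medical vs non-medical reporters.

Each stratum reruns the top-k ROR screening on the cohort reports filed by
that reporter class; the comparator background is restricted to the same
class by default so each stratum's disproportionality is internally
consistent (configurable, since an unrestricted database-wide comparator is
also defensible). Reports with unknown reporter class are excluded from
both strata.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .disproportionality import Level, SignalResult, top_terms
from .model import CaseReport
from .preprocess import MeddraMap

__all__ = ["SubgroupComparison", "subgroup_signals"]

STRATA = ("medical", "non_medical")


@dataclass
class SubgroupComparison:
    """Per-stratum signal lists and the common / unique significant term sets."""

    stratum_results: dict[str, list[SignalResult]]
    common: set[str]
    unique_medical: set[str]
    unique_non_medical: set[str]


def subgroup_signals(
    cohort: Sequence[CaseReport],
    background: Sequence[CaseReport],
    level: Level = "PT",
    k: int = 50,
    exclusion: Iterable[str] = (),
    meddra_map: Optional[MeddraMap] = None,
    label_terms: Iterable[str] = (),
    restrict_background: bool = True,
) -> SubgroupComparison:
    """Run the top-k ROR screening separately for each reporter stratum.

    ``common`` is the intersection of the strata's significant term sets;
    the unique sets are the respective differences, so the three sets are
    pairwise disjoint. A stratum with no reports simply yields an empty
    result list.
    """
    exclusion = tuple(exclusion)
    label_terms = tuple(label_terms)
    stratum_results: dict[str, list[SignalResult]] = {}
    significant: dict[str, set[str]] = {}
    for stratum in STRATA:
        sub_cohort = [r for r in cohort if r.reporter_class == stratum]
        comparator = (
            [r for r in background if r.reporter_class == stratum]
            if restrict_background else list(background)
        )
        if sub_cohort:
            results = top_terms(
                sub_cohort, comparator, level=level, k=k,
                exclusion=exclusion, meddra_map=meddra_map, label_terms=label_terms,
            )
        else:
            results = []
        stratum_results[stratum] = results
        significant[stratum] = {r.term for r in results if r.significant}
    common = significant["medical"] & significant["non_medical"]
    return SubgroupComparison(
        stratum_results=stratum_results,
        common=common,
        unique_medical=significant["medical"] - common,
        unique_non_medical=significant["non_medical"] - common,
    )
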