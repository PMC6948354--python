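"""ADME screening of raw herb components.

Compounds are screened on two pharmacokinetic axes: oral bioavailability
(OB, percent) and drug-likeness (DL, dimensionless). A compound is kept as
*active* when OB >= ob_min and DL >= dl_min (both inclusive), or when it is
on an explicit literature-rescue whitelist: compounds with poor predicted
ADME but reported therapeutic effects are curated in, not inferred.
"""

from __future__ import annotations

import logging
from typing import Iterable

from .models import Component, FilterReport

logger = logging.getLogger(__name__)

OB_MIN_DEFAULT = 30.0
DL_MIN_DEFAULT = 0.18


def passes_adme(component: Component, ob_min: float = OB_MIN_DEFAULT, dl_min: float = DL_MIN_DEFAULT) -> bool:
    """True when the component meets both ADME cutoffs (inclusive)."""
    return component.ob >= ob_min and component.dl >= dl_min


def filter_components(
    components: Iterable[Component],
    ob_min: float = OB_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
    rescue_ids: Iterable[str] = (),
) -> tuple[list[Component], FilterReport]:
    """Screen components to the active set.

    A component is active iff it passes both cutoffs or its id is in
    ``rescue_ids``. Rescued components are returned flagged ``rescued=True``.
    Rescue ids absent from the input produce a warning, not an error.

    Returns the active components (input order preserved) and a
    :class:`FilterReport` with kept / rescued / dropped counts.
    """
    components = list(components)
    rescue_ids = set(rescue_ids)
    missing = sorted(rescue_ids - {c.component_id for c in components})
    if missing:
        logger.warning("rescue ids not present in input: %s", ", ".join(missing))

    active: list[Component] = []
    report = FilterReport(total=len(components), missing_rescue_ids=missing)
    for comp in components:
        if passes_adme(comp, ob_min, dl_min):
            active.append(comp)
            report.passed += 1
        elif comp.component_id in rescue_ids:
            active.append(comp.with_rescued())
            report.rescued += 1
        else:
            report.dropped += 1
    return active, report
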