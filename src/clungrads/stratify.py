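"""Rule engines for pGGN risk stratification.

Three rule sets categorize a pure ground-glass nodule from its mean
diameter, its GGN-vessel-relationship (GVR) type, and a supplied flag for
other suspicious malignant imaging features:

* Lung-RADS 1.0: category 2 below 20 mm, category 3 at or above 20 mm.
* Lung-RADS v2022: the same with the cutoff moved to 30 mm.
* cLung-RADS v2022: GVR-driven — GVR I maps to category 2 (< 30 mm) or 3
  (>= 30 mm), GVR II to 3, GVR III to 4a and GVR IV to 4b at any size.

In every system a nodule whose base category is 3 or 4a/4b is upgraded to
4x when the suspicious-features flag is set; category-2 nodules are never
upgraded. A nodule is called *positive* (predicted invasive, surgical
candidate) in cLung-RADS v2022 when its category is 4a, 4b or 4x; in the
two baseline systems only 4x is reachable at or above category 4, so
positivity there means 4x.

Diameter thresholds are inclusive (>=) and compare raw millimetre values
without rounding.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

from .errors import ContractError, ValidationError
from .nodules import Category, Cohort, GVRType, Nodule

__all__ = [
    "SystemId",
    "StratifiedNodule",
    "categorize_lungrads10",
    "categorize_lungrads2022",
    "categorize_clungrads2022",
    "categorize",
    "is_positive",
    "stratify_cohort",
]


class SystemId(enum.Enum):
    LUNGRADS10 = "lungrads10"
    LUNGRADS2022 = "lungrads2022"
    CLUNGRADS2022 = "clungrads2022"

    def __str__(self) -> str:
        return self.value

    @classmethod
    def parse(cls, token: object) -> "SystemId":
        if isinstance(token, SystemId):
            return token
        text = str(token).strip().lower().replace("-", "").replace("_", "")
        aliases = {
            "lungrads10": cls.LUNGRADS10,
            "lungrads1.0": cls.LUNGRADS10,
            "lungradsv2022": cls.LUNGRADS2022,
            "lungrads2022": cls.LUNGRADS2022,
            "clungradsv2022": cls.CLUNGRADS2022,
            "clungrads2022": cls.CLUNGRADS2022,
            "clung": cls.CLUNGRADS2022,
        }
        if text in aliases:
            return aliases[text]
        raise ValidationError(f"unknown system {token!r}")


@dataclass(frozen=True)
class StratifiedNodule:
    nodule_id: str
    system: SystemId
    category: Category
    positive: bool


# Categories each system can actually emit for a pGGN. The baselines never
# produce 4a/4b (those require GVR information they ignore).
REACHABLE: dict[SystemId, frozenset[Category]] = {
    SystemId.LUNGRADS10: frozenset({Category.C2, Category.C3, Category.C4X}),
    SystemId.LUNGRADS2022: frozenset({Category.C2, Category.C3, Category.C4X}),
    SystemId.CLUNGRADS2022: frozenset(Category),
}

_UPGRADEABLE = {Category.C3, Category.C4A, Category.C4B}


def _require_diameter(nodule: Nodule) -> float:
    d = nodule.mean_diameter_mm
    if d is None:
        raise ValidationError(f"nodule {nodule.nodule_id}: mean_diameter_mm required")
    return d


def _upgrade_if_suspicious(base: Category, suspicious: bool) -> Category:
    # 4x requires base category 3 or 4; a suspicious category-2 nodule stays 2.
    if suspicious and base in _UPGRADEABLE:
        return Category.C4X
    return base


def _size_rule(nodule: Nodule, cutoff_mm: float) -> Category:
    base = Category.C2 if _require_diameter(nodule) < cutoff_mm else Category.C3
    return _upgrade_if_suspicious(base, nodule.suspicious_features)


def categorize_lungrads10(nodule: Nodule) -> Category:
    """Lung-RADS 1.0 for pGGNs: 20-mm cutoff, GVR ignored."""
    return _size_rule(nodule, 20.0)


def categorize_lungrads2022(nodule: Nodule) -> Category:
    """Lung-RADS v2022 for pGGNs: 30-mm cutoff, GVR ignored."""
    return _size_rule(nodule, 30.0)


def categorize_clungrads2022(nodule: Nodule) -> Category:
    """cLung-RADS v2022: GVR-type rules with a 30-mm split for GVR I."""
    if nodule.gvr is None:
        raise ValidationError(
            f"nodule {nodule.nodule_id}: cLung-RADS v2022 requires a GVR type"
        )
    d = _require_diameter(nodule)
    if nodule.gvr is GVRType.I:
        base = Category.C2 if d < 30.0 else Category.C3
    elif nodule.gvr is GVRType.II:
        base = Category.C3
    elif nodule.gvr is GVRType.III:
        base = Category.C4A
    else:
        base = Category.C4B
    return _upgrade_if_suspicious(base, nodule.suspicious_features)


_CATEGORIZERS = {
    SystemId.LUNGRADS10: categorize_lungrads10,
    SystemId.LUNGRADS2022: categorize_lungrads2022,
    SystemId.CLUNGRADS2022: categorize_clungrads2022,
}


def categorize(nodule: Nodule, system: SystemId) -> Category:
    """Dispatch to the rule set named by ``system``."""
    return _CATEGORIZERS[system](nodule)


def is_positive(system: SystemId, category: Category) -> bool:
    """Binary invasiveness call for a category under a system.

    cLung-RADS v2022 calls 4a-4x positive; the baselines call 4x positive
    (the only reachable category at or above 4 for a pGGN).
    """
    if category not in REACHABLE[system]:
        raise ContractError(
            f"category {category} is unreachable under {system}"
        )
    if system is SystemId.CLUNGRADS2022:
        return category.ordinal_rank >= Category.C4A.ordinal_rank
    return category is Category.C4X


def stratify_cohort(cohort: Cohort, system: SystemId) -> list[StratifiedNodule]:
    """Categorize every nodule in a cohort; all-or-nothing, order preserving."""
    out: list[StratifiedNodule] = []
    for nodule in cohort.nodules:
        category = categorize(nodule, system)
        out.append(
            StratifiedNodule(
                nodule_id=nodule.nodule_id,
                system=system,
                category=category,
                positive=is_positive(system, category),
            )
        )
    return out


def stratification_frame(stratified: Iterable[StratifiedNodule]):
    """Stratification results as a DataFrame (nodule_id, system, category,
    positive) ready for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "nodule_id": s.nodule_id,
                "system": str(s.system),
                "category": str(s.category),
                "positive": s.positive,
            }
            for s in stratified
        ],
        columns=["nodule_id", "system", "category", "positive"],
    )
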