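"""Attribute codebook for ego-network rosters.

An :class:`AttributeScheme` declares the categorical attributes an actor may
carry (with an ordered list of legal levels per attribute) and, for attributes
with more than two levels, a binary *recoding* used by the group-level E-I
index and the homophily classification.  The default scheme mirrors a
questionnaire administered to early adopters of community health
worker-delivered injectable contraceptives (CHWDIC) and the ten women of
reproductive age each of them named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple


class SchemeError(ValueError):
    """An attribute, level, or recoding is inconsistent with the scheme."""


#: Education recoding variants.  The roster codes education at three levels
#: (none / primary-or-secondary / tertiary) while homophily analyses split at
#: "less than secondary" vs "at least secondary"; the pooled middle level can
#: be assigned to either side, so both variants are provided.
EDU_RECODE_VARIANTS = ("pool-primary-up", "pool-primary-down")

LESS_THAN_SECONDARY = "less_than_secondary"
AT_LEAST_SECONDARY = "at_least_secondary"


@dataclass(frozen=True)
class AttributeScheme:
    """Codebook of categorical attributes, their levels, and binary recodings.

    Parameters
    ----------
    attributes
        Ordered mapping attribute name -> tuple of legal category labels.
    recodings
        Mapping attribute name -> {level: group label} collapsing the levels
        onto exactly two groups.  Attributes that are already binary need no
        entry; :meth:`binary_groups` falls back to the identity recode.
    """

    attributes: Mapping[str, Tuple[str, ...]]
    recodings: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, levels in self.attributes.items():
            if len(set(levels)) != len(levels):
                raise SchemeError(f"duplicate level in attribute {name!r}")
        for name, rec in self.recodings.items():
            if name not in self.attributes:
                raise SchemeError(f"recoding for unknown attribute {name!r}")
            levels = set(self.attributes[name])
            if set(rec) != levels:
                raise SchemeError(
                    f"recoding for {name!r} must cover all levels exactly"
                )
            if len(set(rec.values())) != 2:
                raise SchemeError(
                    f"recoding for {name!r} must map onto exactly two groups"
                )

    @property
    def names(self) -> List[str]:
        return list(self.attributes)

    def levels(self, attribute: str) -> Tuple[str, ...]:
        try:
            return self.attributes[attribute]
        except KeyError:
            raise SchemeError(f"unknown attribute {attribute!r}") from None

    def is_legal(self, attribute: str, value: Optional[str]) -> bool:
        return value is None or value in self.levels(attribute)

    def binary_groups(self, attribute: str) -> Tuple[str, str]:
        """The two group labels the attribute recodes onto."""
        rec = self.recode_map(attribute)
        seen: List[str] = []
        for g in rec.values():
            if g not in seen:
                seen.append(g)
        return seen[0], seen[1]

    def recode_map(self, attribute: str) -> Dict[str, str]:
        """level -> binary group, using the identity map for binary attributes."""
        levels = self.levels(attribute)
        if attribute in self.recodings:
            return dict(self.recodings[attribute])
        if len(levels) != 2:
            raise SchemeError(
                f"attribute {attribute!r} has {len(levels)} levels and no recoding"
            )
        return {lv: lv for lv in levels}


def default_scheme(edu_recode: str = "pool-primary-down") -> AttributeScheme:
    """The CHWDIC questionnaire scheme.

    ``edu_recode`` selects where the pooled "primary or secondary" education
    level falls when education is split at secondary school:
    ``pool-primary-up`` counts it as at-least-secondary, ``pool-primary-down``
    as less-than-secondary.
    """
    if edu_recode not in EDU_RECODE_VARIANTS:
        raise SchemeError(
            f"edu_recode must be one of {EDU_RECODE_VARIANTS}, got {edu_recode!r}"
        )
    pooled_group = (
        AT_LEAST_SECONDARY if edu_recode == "pool-primary-up" else LESS_THAN_SECONDARY
    )
    attributes = {
        "age_group": ("<30", ">=30"),
        "marital_status": ("single", "married"),
        "education": ("none", "primary_or_secondary", "tertiary"),
        "occupation": ("informal", "formal", "self_employed"),
        "ethnicity": ("Hausa", "Others"),
        "marriage_type": ("monogamy", "polygamy"),
        "fp_use": ("yes", "no"),
        "cbdic_use": ("yes", "no"),
        "relationship": (
            "relative_or_close_friend",
            "close_friend",
            "co_worker",
            "neighbour_or_acquaintance",
        ),
        "interaction_place": ("worship", "market_or_workplace", "social_visit"),
        "interaction_freq": ("weekly", "monthly", "yearly"),
    }
    recodings = {
        "education": {
            "none": LESS_THAN_SECONDARY,
            "primary_or_secondary": pooled_group,
            "tertiary": AT_LEAST_SECONDARY,
        },
        # relationship splits kin-like vs not; used only if someone asks for
        # an E-I index on it, not by the standard report.
        "relationship": {
            "relative_or_close_friend": "kin_or_close",
            "close_friend": "kin_or_close",
            "co_worker": "other",
            "neighbour_or_acquaintance": "other",
        },
        "occupation": {
            "informal": "informal",
            "formal": "formal_or_self",
            "self_employed": "formal_or_self",
        },
        "interaction_place": {
            "worship": "worship",
            "market_or_workplace": "elsewhere",
            "social_visit": "elsewhere",
        },
        "interaction_freq": {
            "weekly": "monthly_or_more",
            "monthly": "monthly_or_more",
            "yearly": "less_often",
        },
    }
    return AttributeScheme(attributes=attributes, recodings=recodings)


#: Attributes the study reports E-I indices and homophily sources for.
EI_ATTRIBUTES = ("ethnicity", "age_group", "education", "marriage_type")
HOMOPHILY_ATTRIBUTES = (
    "ethnicity",
    "cbdic_use",
    "age_group",
    "education",
    "marriage_type",
)
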