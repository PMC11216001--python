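"""Childcare state alphabet.

Main childcare provision is coded into seven core categories; a child's
longitudinal record is a length-4 vector over this alphabet (states at
roughly 10 months, 2, 3 and 4 years).
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class StateAlphabet:
    """Ordered set of childcare state codes with display labels and colors."""

    codes: tuple[str, ...]
    labels: dict[str, str] = field(default_factory=dict)
    colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.codes) < 2:
            raise ValueError("alphabet needs at least 2 states")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("alphabet codes must be unique")

    @property
    def size(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"state {code!r} not in alphabet {self.codes}") from None

    def label(self, code: str) -> str:
        return self.labels.get(code, code)

    def color(self, code: str) -> str:
        return self.colors.get(code, "#999999")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump({"codes": list(self.codes), "labels": dict(self.labels),
                            "colors": dict(self.colors)}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StateAlphabet":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(codes=tuple(d["codes"]), labels=d.get("labels", {}),
                   colors=d.get("colors", {}))


#: The seven-category childcare coding used throughout.
CHILDCARE_STATES = (
    "PrivateGroup",
    "LAGroup",
    "SingleProfessional",
    "FamilyFriends",
    "Grandparent",
    "Other",
    "None",
)

CHILDCARE_ALPHABET = StateAlphabet(
    codes=CHILDCARE_STATES,
    labels={
        "PrivateGroup": "Private group childcare",
        "LAGroup": "Local authority / community group childcare",
        "SingleProfessional": "Single professional care (childminder/nanny)",
        "FamilyFriends": "Family or friends informal childcare",
        "Grandparent": "Grandparent informal childcare",
        "Other": "Any other childcare",
        "None": "None (parental care only)",
    },
    colors={
        "PrivateGroup": "#e377c2",
        "LAGroup": "#ffdd44",
        "SingleProfessional": "#8c564b",
        "FamilyFriends": "#2ca02c",
        "Grandparent": "#ff7f0e",
        "Other": "#7f7f7f",
        "None": "#1f77b4",
    },
)

#: Number of sweeps in a childcare sequence (10 months, 2y, 3y, 4y).
N_SWEEPS = 4

SWEEP_COLUMNS = tuple(f"childcare_sw{t}" for t in range(1, N_SWEEPS + 1))

#: Education levels, highest to lowest (exposure; reference = Degree).
EDUCATION_LEVELS = ("Degree", "Highers", "UpperStdGrades", "LowerStdGradesOrNone")

#: Typology display names keyed by short code, in canonical order.
TYPOLOGY_NAMES = {
    "PFF": "Parents, friends & family",
    "GP": "Grandparents",
    "PG": "Private group childcare",
    "SP": "Single professional care",
}

#: Canonical per-sweep path for each latent typology.  Children mostly stay
#: with one provider before age three and move into a (local-authority)
#: universal place at sweep 4; private-group children tend to remain with
#: private providers, which can also deliver the universal entitlement.
CANONICAL_PATHS = {
    "PFF": ("None", "None", "None", "LAGroup"),
    "GP": ("Grandparent", "Grandparent", "Grandparent", "LAGroup"),
    "PG": ("PrivateGroup", "PrivateGroup", "PrivateGroup", "PrivateGroup"),
    "SP": ("SingleProfessional", "SingleProfessional", "SingleProfessional", "LAGroup"),
}
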