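"""ACMG/AMP evidence combination: criterion tags -> class 1-5.

Only the *combining* algebra is implemented here. Which criteria a
variant earns (PVS1, PM2, ...) is an upstream interpretation step and
arrives as input; this module turns a set of earned tags into one of the
five classes: 1 benign, 2 likely benign, 3 VUS (uncertain significance),
4 likely pathogenic, 5 pathogenic.

The default rule table encodes the 2015 ACMG/AMP combining rules. Rules
are data: each row states a class and minimum counts of evidence at each
strength (very strong / strong / moderate / supporting on the pathogenic
side; stand-alone / strong / supporting on the benign side). Counting is
done after any per-tag strength overrides. Each side takes the strongest
class among its fired rules. Contradictory evidence resolves to class 3
with ``fired_rule="conflict"``: either both sides fire a rule, or one
side fires while the other holds strong-or-stronger evidence (a BA1/BS*
tag against a pathogenic call, a PVS1/PS* tag against a benign call).
If nothing fires the result is class 3 ``"default_vus"``.

Because every rule is a lower-bound threshold and the winner is the
maximum class per side, range-limited guideline rules ("1 strong and 1-2
moderate" for likely pathogenic) need no upper bounds: with 3 moderates
the pathogenic rule also fires and wins.

``enumerate_oracle`` is a deliberately separate, literal transcription of
the combining-rule text as nested boolean conditions; it exists so the
table-driven engine can be checked exhaustively against an independent
code path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import yaml

PATHOGENIC_TAGS = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)
BENIGN_TAGS = frozenset(
    {"BA1"} | {f"BS{i}" for i in range(1, 5)} | {f"BP{i}" for i in range(1, 8)}
)
VALID_TAGS = PATHOGENIC_TAGS | BENIGN_TAGS


class Strength(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STAND_ALONE = "stand_alone"


def default_strength(tag: str) -> Strength:
    if tag == "PVS1":
        return Strength.VERY_STRONG
    if tag.startswith("PS") or tag.startswith("BS"):
        return Strength.STRONG
    if tag.startswith("PM"):
        return Strength.MODERATE
    if tag == "BA1":
        return Strength.STAND_ALONE
    return Strength.SUPPORTING  # PP*, BP*


class UnknownTagError(ValueError):
    pass


@dataclass(frozen=True)
class AcmgEvidence:
    """A set of earned criterion tags with optional strength overrides."""

    criteria: frozenset[str]
    overrides: tuple[tuple[str, Strength], ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.criteria) - VALID_TAGS
        if unknown:
            raise UnknownTagError(f"unknown ACMG tags: {sorted(unknown)}")
        for tag, _ in self.overrides:
            if tag not in self.criteria:
                raise UnknownTagError(f"strength override for absent tag {tag!r}")

    @classmethod
    def of(cls, *tags: str, **overrides: str) -> "AcmgEvidence":
        return cls(
            criteria=frozenset(tags),
            overrides=tuple((t, Strength(s)) for t, s in overrides.items()),
        )

    def strength_counts(self) -> tuple[dict[Strength, int], dict[Strength, int]]:
        """(pathogenic-side counts, benign-side counts) after overrides."""
        override_map = dict(self.overrides)
        path: dict[Strength, int] = {s: 0 for s in Strength}
        ben: dict[Strength, int] = {s: 0 for s in Strength}
        for tag in self.criteria:
            strength = override_map.get(tag, default_strength(tag))
            side = path if tag in PATHOGENIC_TAGS else ben
            side[strength] += 1
        return path, ben


CLASS_NAMES = {1: "benign", 2: "likely_benign", 3: "VUS", 4: "likely_pathogenic", 5: "pathogenic"}


@dataclass(frozen=True)
class AcmgClass:
    value: int
    fired_rule: str

    def __post_init__(self) -> None:
        if self.value not in CLASS_NAMES:
            raise ValueError(f"class must be 1-5, got {self.value}")

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.value]

    @property
    def possibly_causative(self) -> bool:
        """Classes 3-5 proceed to genotype-phenotype analysis."""
        return self.value >= 3


@dataclass(frozen=True)
class CombiningRule:
    """Minimum evidence counts at each strength implying a class."""

    name: str
    klass: int
    very_strong: int = 0
    strong: int = 0
    moderate: int = 0
    supporting: int = 0
    stand_alone: int = 0

    @property
    def benign_side(self) -> bool:
        return self.klass <= 2

    def fires(self, counts: Mapping[Strength, int]) -> bool:
        return (
            counts[Strength.VERY_STRONG] >= self.very_strong
            and counts[Strength.STRONG] >= self.strong
            and counts[Strength.MODERATE] >= self.moderate
            and counts[Strength.SUPPORTING] >= self.supporting
            and counts[Strength.STAND_ALONE] >= self.stand_alone
        )


def default_rule_table() -> list[CombiningRule]:
    """The 2015 ACMG/AMP combining rules as threshold rows."""
    return [
        # Pathogenic
        CombiningRule("P_vs_strong", 5, very_strong=1, strong=1),
        CombiningRule("P_vs_2moderate", 5, very_strong=1, moderate=2),
        CombiningRule("P_vs_mod_supp", 5, very_strong=1, moderate=1, supporting=1),
        CombiningRule("P_vs_2supporting", 5, very_strong=1, supporting=2),
        CombiningRule("P_2strong", 5, strong=2),
        CombiningRule("P_strong_3moderate", 5, strong=1, moderate=3),
        CombiningRule("P_strong_2mod_2supp", 5, strong=1, moderate=2, supporting=2),
        CombiningRule("P_strong_mod_4supp", 5, strong=1, moderate=1, supporting=4),
        # Likely pathogenic
        CombiningRule("LP_vs_moderate", 4, very_strong=1, moderate=1),
        CombiningRule("LP_strong_moderate", 4, strong=1, moderate=1),
        CombiningRule("LP_strong_2supporting", 4, strong=1, supporting=2),
        CombiningRule("LP_3moderate", 4, moderate=3),
        CombiningRule("LP_2mod_2supp", 4, moderate=2, supporting=2),
        CombiningRule("LP_mod_4supp", 4, moderate=1, supporting=4),
        # Benign
        CombiningRule("B_stand_alone", 1, stand_alone=1),
        CombiningRule("B_2strong", 1, strong=2),
        # Likely benign
        CombiningRule("LB_strong_supporting", 2, strong=1, supporting=1),
        CombiningRule("LB_2supporting", 2, supporting=2),
    ]


def load_rule_table(path) -> list[CombiningRule]:
    """Load a rule table from YAML: a list of {name, class, counts...} maps."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for row in raw:
        rules.append(
            CombiningRule(
                name=str(row["name"]),
                klass=int(row["class"]),
                very_strong=int(row.get("very_strong", 0)),
                strong=int(row.get("strong", 0)),
                moderate=int(row.get("moderate", 0)),
                supporting=int(row.get("supporting", 0)),
                stand_alone=int(row.get("stand_alone", 0)),
            )
        )
    return rules


def save_rule_table(path, rules: Sequence[CombiningRule]) -> None:
    rows = []
    for r in rules:
        row = {"name": r.name, "class": r.klass}
        for fld in ("very_strong", "strong", "moderate", "supporting", "stand_alone"):
            if getattr(r, fld):
                row[fld] = getattr(r, fld)
        rows.append(row)
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)


def combine(
    evidence: AcmgEvidence,
    rules: Optional[Sequence[CombiningRule]] = None,
) -> AcmgClass:
    """Combine evidence tags into a class 1-5.

    Deterministic and total over the evidence power set: each side takes
    its strongest fired rule; both sides firing is a conflict (class 3),
    neither side firing is the VUS default.
    """
    if rules is None:
        rules = default_rule_table()
    path_counts, benign_counts = evidence.strength_counts()

    best_path: Optional[CombiningRule] = None
    best_benign: Optional[CombiningRule] = None
    for rule in rules:
        counts = benign_counts if rule.benign_side else path_counts
        if not rule.fires(counts):
            continue
        if rule.benign_side:
            if best_benign is None or rule.klass < best_benign.klass:
                best_benign = rule
        else:
            if best_path is None or rule.klass > best_path.klass:
                best_path = rule

    strong_path = path_counts[Strength.VERY_STRONG] + path_counts[Strength.STRONG]
    strong_benign = benign_counts[Strength.STAND_ALONE] + benign_counts[Strength.STRONG]
    if best_path is not None and (best_benign is not None or strong_benign > 0):
        return AcmgClass(3, "conflict")
    if best_benign is not None and strong_path > 0:
        return AcmgClass(3, "conflict")
    if best_path is not None:
        return AcmgClass(best_path.klass, best_path.name)
    if best_benign is not None:
        return AcmgClass(best_benign.klass, best_benign.name)
    return AcmgClass(3, "default_vus")


def classify_evidence_map(
    evidence_by_key: Mapping,
    rules: Optional[Sequence[CombiningRule]] = None,
) -> dict:
    """Vectorized convenience: map each key's evidence to its class."""
    if rules is None:
        rules = default_rule_table()
    return {k: combine(ev, rules) for k, ev in evidence_by_key.items()}


# --------------------------------------------------------------------------
# Independent oracle: a literal transcription of the combining-rule text.
# Kept free of CombiningRule machinery on purpose.
# --------------------------------------------------------------------------

def _oracle_class(tags: frozenset[str]) -> int:
    vs = sum(1 for t in tags if t == "PVS1")
    ps = sum(1 for t in tags if t.startswith("PS"))
    pm = sum(1 for t in tags if t.startswith("PM"))
    pp = sum(1 for t in tags if t.startswith("PP"))
    ba = sum(1 for t in tags if t == "BA1")
    bs = sum(1 for t in tags if t.startswith("BS"))
    bp = sum(1 for t in tags if t.startswith("BP"))

    pathogenic = (
        (vs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (vs == 1 and pm == 1)
        or (ps == 1 and (pm == 1 or pm == 2))
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp == 1) or bp >= 2

    path_class = 5 if pathogenic else 4 if likely_pathogenic else None
    benign_class = 1 if benign else 2 if likely_benign else None
    # contradictory evidence: a classification on one side against
    # strong-or-stronger evidence on the other defaults to VUS
    if path_class is not None and (benign_class is not None or ba + bs > 0):
        return 3
    if benign_class is not None and vs + ps > 0:
        return 3
    if path_class is not None:
        return path_class
    if benign_class is not None:
        return benign_class
    return 3


DEFAULT_ORACLE_ALPHABET = ("PVS1", "PS1", "PS2", "PM1", "PM2", "PP1", "PP2", "BA1", "BS1", "BP1")


def enumerate_oracle(
    alphabet: Sequence[str] = DEFAULT_ORACLE_ALPHABET,
) -> dict[frozenset[str], int]:
    """Exhaustively classify every subset of ``alphabet`` (<= 12 tags)
    via the literal transcription of the combining-rule text."""
    if len(alphabet) > 12:
        raise ValueError("oracle alphabet limited to 12 tags (power-set tractability)")
    unknown = set(alphabet) - VALID_TAGS
    if unknown:
        raise UnknownTagError(f"unknown ACMG tags: {sorted(unknown)}")
    out: dict[frozenset[str], int] = {}
    for r in range(len(alphabet) + 1):
        for combo in itertools.combinations(alphabet, r):
            tags = frozenset(combo)
            out[tags] = _oracle_class(tags)
    return out
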