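"""N-glycan state space and Golgi enzyme reaction rules.

The model tracks each glycan as a composition vector along the canonical
mammalian N-glycan processing pathway: mannose trimming (Man1, Man2),
antenna initiation and branching (Mgat1, Mgat2, Mgat4, Mgat5), core
fucosylation (Fut8), galactosylation (GalT) and sialylation (SiaT).
Branch isomers are merged — the resolution matches capillary-electrophoresis
glycan profiling, which reports compositions, not arm positions.

Fut8 is special-cased: core fucosylation is slow relative to the other
transfers, so it is modelled as a two-step process.  A Fut8 firing puts the
glycan into a *locked* intermediate state in which no other enzyme can act;
a separate lock-resolution pseudo-reaction completes the transfer and sets
the core-fucose flag.  This decouples Fut8's slow rate from the shared
activity scale of the other enzymes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Callable, Iterable

__all__ = [
    "GlycanState",
    "EnzymeRule",
    "GlycanProfile",
    "ENZYME_NAMES",
    "LOCK_RESOLUTION",
    "MAN9",
    "MAN5",
    "default_rules",
    "lock_resolution_rule",
    "canonical_name",
    "applicable_rules",
    "enumerate_reachable_states",
    "rules_to_json",
    "rules_from_json",
]

#: Enzymes of the canonical pathway, in pathway order.
ENZYME_NAMES = (
    "Man1",
    "Mgat1",
    "Man2",
    "Fut8",
    "Mgat2",
    "Mgat4",
    "Mgat5",
    "GalT",
    "SiaT",
)

#: Name of the pseudo-reaction that completes a Fut8 lock.
LOCK_RESOLUTION = "LockResolution"


class InvalidGlycanError(ValueError):
    """A glycan state violating the structural invariants."""


@dataclass(frozen=True, slots=True)
class GlycanState:
    """Composition-coded state of one N-glycan.

    Parameters
    ----------
    man : int
        Mannose residues, 3-9.
    agn : int
        Antenna GlcNAc residues, 0-4.
    fuc : int
        Core fucose indicator (0 or 1).
    gal : int
        Galactose residues, at most ``agn``.
    sia : int
        Sialic acids, at most ``gal``.
    locked : bool
        True while a Fut8 fucosylation event is in progress; no other
        enzyme can act on a locked glycan.
    """

    man: int
    agn: int = 0
    fuc: int = 0
    gal: int = 0
    sia: int = 0
    locked: bool = False

    def validate(self) -> "GlycanState":
        if not (3 <= self.man <= 9):
            raise InvalidGlycanError(f"man={self.man} outside [3, 9]")
        if not (0 <= self.agn <= 4):
            raise InvalidGlycanError(f"agn={self.agn} outside [0, 4]")
        if self.fuc not in (0, 1):
            raise InvalidGlycanError(f"fuc={self.fuc} not in {{0, 1}}")
        if not (0 <= self.gal <= self.agn):
            raise InvalidGlycanError(f"gal={self.gal} outside [0, agn={self.agn}]")
        if not (0 <= self.sia <= self.gal):
            raise InvalidGlycanError(f"sia={self.sia} outside [0, gal={self.gal}]")
        if self.agn >= 1 and self.man > 5:
            raise InvalidGlycanError("antenna GlcNAc before trimming to Man5")
        if self.agn >= 2 and self.man != 3:
            raise InvalidGlycanError("second antenna before Man2 trimming to Man3")
        if self.locked and self.fuc != 0:
            raise InvalidGlycanError("locked state must be unfucosylated")
        return self

    @property
    def is_valid(self) -> bool:
        try:
            self.validate()
        except InvalidGlycanError:
            return False
        return True


MAN9 = GlycanState(man=9)
MAN5 = GlycanState(man=5)


@dataclass(frozen=True)
class EnzymeRule:
    """One enzymatic reaction: a guard predicate plus a state effect."""

    enzyme_name: str
    guard: Callable[[GlycanState], bool]
    effect: Callable[[GlycanState], GlycanState]
    #: identifiers used for JSON round-tripping
    guard_id: str = ""
    effect_id: str = ""

    def applies(self, state: GlycanState) -> bool:
        if state.locked and self.enzyme_name != LOCK_RESOLUTION:
            return False
        if not state.locked and self.enzyme_name == LOCK_RESOLUTION:
            return False
        return self.guard(state)

    def fire(self, state: GlycanState) -> GlycanState:
        if not self.applies(state):
            raise ValueError(f"rule {self.enzyme_name} does not apply to {state}")
        return self.effect(state).validate()


# --- named guards and effects (referenced by id in the JSON rule format) ---

_GUARDS: dict[str, Callable[[GlycanState], bool]] = {
    "man_gt5_no_antenna": lambda s: s.man > 5 and s.agn == 0,
    "is_man5": lambda s: s.man == 5 and s.agn == 0,
    "man5_one_antenna": lambda s: s.man == 5 and s.agn == 1,
    "fucosylatable": lambda s: s.agn >= 1 and s.fuc == 0 and s.gal == 0,
    "man3_one_antenna": lambda s: s.man == 3 and s.agn == 1,
    "man3_two_antennae": lambda s: s.man == 3 and s.agn == 2,
    "man3_three_antennae": lambda s: s.man == 3 and s.agn == 3,
    "galactosylatable": lambda s: s.agn >= 2 and s.gal < s.agn,
    "sialylatable": lambda s: s.sia < s.gal,
    "is_locked": lambda s: s.locked,
}

_EFFECTS: dict[str, Callable[[GlycanState], GlycanState]] = {
    "trim_mannose": lambda s: replace(s, man=s.man - 1),
    "add_antenna": lambda s: replace(s, agn=s.agn + 1),
    "trim_to_man3": lambda s: replace(s, man=3),
    "engage_lock": lambda s: replace(s, locked=True),
    "add_galactose": lambda s: replace(s, gal=s.gal + 1),
    "add_sialic_acid": lambda s: replace(s, sia=s.sia + 1),
    "resolve_lock": lambda s: replace(s, locked=False, fuc=1),
}

_RULE_TABLE = [
    # (enzyme, guard id, effect id)
    ("Man1", "man_gt5_no_antenna", "trim_mannose"),
    ("Mgat1", "is_man5", "add_antenna"),
    # Man2 performs two sequential trims; they are collapsed into one
    # reaction because no measured species lies between them.
    ("Man2", "man5_one_antenna", "trim_to_man3"),
    # Fut8 only acts on agalactosylated antennary glycans: galactosylation
    # blocks core fucosylation on the same structure.
    ("Fut8", "fucosylatable", "engage_lock"),
    ("Mgat2", "man3_one_antenna", "add_antenna"),
    ("Mgat4", "man3_two_antennae", "add_antenna"),
    ("Mgat5", "man3_three_antennae", "add_antenna"),
    ("GalT", "galactosylatable", "add_galactose"),
    ("SiaT", "sialylatable", "add_sialic_acid"),
]


def _make_rule(enzyme: str, guard_id: str, effect_id: str) -> EnzymeRule:
    return EnzymeRule(
        enzyme_name=enzyme,
        guard=_GUARDS[guard_id],
        effect=_EFFECTS[effect_id],
        guard_id=guard_id,
        effect_id=effect_id,
    )


def default_rules() -> list[EnzymeRule]:
    """The nine enzyme rules of the canonical Golgi processing pathway."""
    return [_make_rule(*row) for row in _RULE_TABLE]


def lock_resolution_rule() -> EnzymeRule:
    """Pseudo-rule completing an in-progress Fut8 fucosylation."""
    return _make_rule(LOCK_RESOLUTION, "is_locked", "resolve_lock")


def applicable_rules(state: GlycanState, rules: Iterable[EnzymeRule]) -> list[EnzymeRule]:
    """Rules whose guards hold on ``state`` (empty for a locked state)."""
    return [r for r in rules if r.applies(state)]


# ---------------------------------------------------------------------------
# Nomenclature

_NAMED_SPECIES: dict[tuple[int, int, int, int, int], str] = {
    (3, 1, 0, 0, 0): "G0-GN",
    (3, 2, 0, 0, 0): "G0",
    (3, 2, 1, 0, 0): "G0F",
    (3, 2, 0, 1, 0): "G1",
    (3, 2, 1, 1, 0): "G1F",
    (3, 2, 0, 2, 0): "G2",
    (3, 2, 1, 2, 0): "G2F",
}


def canonical_name(state: GlycanState) -> str:
    """Canonical glycoform name for a (resolved) glycan state.

    High-mannose forms are named ``Man5``..``Man9``; the measured complex
    biantennary species carry their conventional names (``G0``, ``G0F``,
    ``G1F``, ...; ``F`` marks core fucose, the digit counts galactoses,
    ``G0-GN`` lacks one antenna GlcNAc).  Any other composition gets a
    systematic ``M<man>A<agn>F<fuc>G<gal>S<sia>`` code, so the mapping is
    injective over the whole state space.
    """
    state.validate()
    if state.locked:
        raise InvalidGlycanError("locked intermediate states have no glycoform name")
    if state.agn == 0 and state.fuc == 0:
        return f"Man{state.man}"
    key = (state.man, state.agn, state.fuc, state.gal, state.sia)
    if key in _NAMED_SPECIES:
        return _NAMED_SPECIES[key]
    return f"M{state.man}A{state.agn}F{state.fuc}G{state.gal}S{state.sia}"


# ---------------------------------------------------------------------------
# Profiles


class GlycanProfile(dict):
    """Fractional abundance over named glycan species; values sum to 1."""

    TOL = 1e-9

    def __init__(self, fractions: dict[str, float]):
        super().__init__(fractions)
        self.validate()

    def validate(self) -> "GlycanProfile":
        if any(v < 0 for v in self.values()):
            raise ValueError("negative fraction in glycan profile")
        total = sum(self.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"profile fractions sum to {total}, not 1")
        return self

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "GlycanProfile":
        total = sum(counts.values())
        if total <= 0:
            raise ValueError("empty count set")
        return cls({k: v / total for k, v in counts.items()})


# ---------------------------------------------------------------------------
# Reachability


def enumerate_reachable_states(
    rules: Iterable[EnzymeRule],
    start: GlycanState = MAN9,
    include_lock_resolution: bool = True,
) -> list[GlycanState]:
    """Breadth-first closure of ``start`` under the rule effects.

    Includes locked intermediates whenever a locking rule is present; the
    lock-resolution pseudo-rule is appended automatically unless disabled.
    Returns states in deterministic BFS order (start first).
    """
    all_rules = list(rules)
    if include_lock_resolution and not any(
        r.enzyme_name == LOCK_RESOLUTION for r in all_rules
    ):
        all_rules.append(lock_resolution_rule())
    start.validate()
    seen: dict[GlycanState, None] = {start: None}
    frontier = [start]
    while frontier:
        nxt: list[GlycanState] = []
        for state in frontier:
            for rule in all_rules:
                if rule.applies(state):
                    child = rule.fire(state)
                    if child not in seen:
                        seen[child] = None
                        nxt.append(child)
        frontier = nxt
    return list(seen)


# ---------------------------------------------------------------------------
# JSON rule serialization — alternative topologies without code changes


def rules_to_json(rules: Iterable[EnzymeRule]) -> str:
    return json.dumps(
        [
            {"enzyme_name": r.enzyme_name, "guard": r.guard_id, "effect": r.effect_id}
            for r in rules
        ],
        indent=2,
    )


def rules_from_json(text: str) -> list[EnzymeRule]:
    rows = json.loads(text)
    rules = []
    for row in rows:
        if row["guard"] not in _GUARDS:
            raise KeyError(f"unknown guard id {row['guard']!r}")
        if row["effect"] not in _EFFECTS:
            raise KeyError(f"unknown effect id {row['effect']!r}")
        rules.append(_make_rule(row["enzyme_name"], row["guard"], row["effect"]))
    return rules
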